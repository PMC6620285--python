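"""Gene-level annotation of recurrent regions against the exon panel.

The array design is the closed world: a region's gene list contains
exactly the panel genes it overlaps by at least 1 bp, and every gene in
any output table is a panel member.  Regions hitting no gene are kept
and flagged intergenic (printed as "-" downstream).  Probes/genes can
additionally be clustered by the disease tags attached to the panel
(e.g. the ALS-linked gene list).
"""

from __future__ import annotations

import pandas as pd

from .simulate import chrom_sort_key

__all__ = [
    "gene_panel_from_probes",
    "annotate_regions",
    "cluster_by_disease",
    "cnv_gene_table",
]


def gene_panel_from_probes(
    panel: pd.DataFrame,
    tags: dict[str, set] | None = None,
) -> pd.DataFrame:
    """Collapse probe records to whole-gene spans with optional disease tags.

    ``tags`` maps gene symbol -> set of disease labels; a gene tagged
    "ALS" is flagged ``known_als``.
    """
    tags = tags or {}
    span = (
        panel[panel["gene"].astype(str) != ""]
        .groupby("gene")
        .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
        .reset_index()
    )
    span["tags"] = span["gene"].map(lambda g: frozenset(tags.get(g, ())))
    span["known_als"] = span["tags"].map(lambda t: "ALS" in t)
    span["_ck"] = span["chrom"].map(chrom_sort_key)
    span = span.sort_values(["_ck", "start"], kind="mergesort").drop(columns="_ck")
    return span.reset_index(drop=True)


def annotate_regions(regions: pd.DataFrame, gene_panel: pd.DataFrame) -> pd.DataFrame:
    """Attach the overlapping panel genes (position-sorted) to each region.

    Regions with no overlapping gene keep an empty tuple and are flagged
    ``intergenic``.  Zero-length query regions are rejected.
    """
    if (regions["end"] <= regions["start"]).any():
        raise ValueError("zero-length or inverted region in query")
    genes_col, intergenic = [], []
    for rec in regions.itertuples(index=False):
        hits = gene_panel[
            (gene_panel["chrom"] == rec.chrom)
            & (gene_panel["end"] > rec.start)
            & (gene_panel["start"] < rec.end)
        ].sort_values("start", kind="mergesort")
        genes = tuple(hits["gene"])
        genes_col.append(genes)
        intergenic.append(len(genes) == 0)
    out = regions.copy()
    out["genes"] = genes_col
    out["intergenic"] = intergenic
    return out


def cluster_by_disease(
    annotated: pd.DataFrame,
    gene_panel: pd.DataFrame,
    diseases: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-disease tables of recurrent CNV genes with direction and frequency.

    Each table lists the tagged genes hit by a recurrent region, one row
    per (gene, direction, scope) — gains and losses stay separate events.
    """
    all_tags = set()
    for t in gene_panel["tags"]:
        all_tags |= set(t)
    if diseases is None:
        diseases = sorted(all_tags)
    unknown = set(diseases) - all_tags
    if unknown:
        raise KeyError(f"disease tags not present on the panel: {sorted(unknown)}")

    gene_tags = dict(zip(gene_panel["gene"], gene_panel["tags"]))
    table = cnv_gene_table(annotated)
    out = {}
    for disease in diseases:
        members = {g for g, t in gene_tags.items() if disease in t}
        out[disease] = table[table["gene"].isin(members)].reset_index(drop=True)
    return out


def cnv_gene_table(annotated: pd.DataFrame) -> pd.DataFrame:
    """Explode annotated regions into one row per (gene, direction, scope).

    A gene hit by several same-direction regions keeps the highest
    carrier frequency.
    """
    rows = []
    for rec in annotated.itertuples(index=False):
        for gene in rec.genes:
            rows.append(
                {
                    "gene": gene,
                    "direction": rec.direction,
                    "scope": rec.scope,
                    "frequency_pct": rec.frequency_pct,
                    "chrom": rec.chrom,
                    "start": rec.start,
                    "end": rec.end,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["gene", "direction", "scope", "frequency_pct", "chrom", "start", "end"]
        )
    df = pd.DataFrame(rows)
    df = (
        df.sort_values("frequency_pct", ascending=False, kind="mergesort")
        .drop_duplicates(subset=["gene", "direction", "scope"], keep="first")
        .sort_values(["scope", "gene", "direction"], kind="mergesort")
    )
    return df.reset_index(drop=True)
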