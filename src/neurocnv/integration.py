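"""Integration of copy-number and expression calls per gene.

Each recurrent CNV gene and each significant DEG is joined by gene
symbol within its subgroup and classified by direction concordance:
``cnv_driven`` when the expression trend matches the copy-number change
(gain & up, or loss & down), ``discordant`` when it opposes it,
``cnv_only`` / ``expression_only`` when one signal is absent.  The
headline percentage is CNV-driven genes over the CNV-and-DEG overlap.
A randomized-group control reruns the whole chain on random
bipartitions of the case samples (group sizes preserved) to show the
overlap is a property of the real subgroups, not of the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import annotate_regions, cnv_gene_table
from .expression import call_degs
from .recurrence import (
    compute_penetrance,
    filter_case_exclusive,
    fragment_breakpoints,
    round_half_up,
    select_recurrent,
)

__all__ = [
    "overlap_cnv_deg",
    "concordance_summary",
    "randomized_group_control",
]

SUBGROUPS = ("group1", "group2")


def _resolve_cnv_genes(cnv_genes: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    """One CNV row per gene in a subgroup; direction ties resolve to the
    higher-frequency event (then gain)."""
    sub = cnv_genes[cnv_genes["scope"] == subgroup]
    if sub.empty:
        return sub
    sub = sub.sort_values(
        ["gene", "frequency_pct", "direction"],
        ascending=[True, False, True], kind="mergesort",
    )
    return sub.drop_duplicates("gene", keep="first")


def overlap_cnv_deg(cnv_genes: pd.DataFrame, degs: pd.DataFrame) -> pd.DataFrame:
    """Symbol-level join of recurrent CNV genes and significant DEGs.

    ``cnv_genes`` is the exploded gene table (gene, direction, scope,
    frequency_pct) with scope in {group1, group2}; ``degs`` the DEG
    table from :func:`neurocnv.expression.call_degs`.  Every gene with at
    least one signal appears exactly once per subgroup with a status in
    {cnv_driven, discordant, cnv_only, expression_only}.
    """
    records = []
    for subgroup in SUBGROUPS:
        cnv = _resolve_cnv_genes(cnv_genes, subgroup)
        cnv_map = {
            r.gene: (r.direction, r.frequency_pct) for r in cnv.itertuples(index=False)
        }
        sig = degs[(degs["subgroup"] == subgroup) & degs["significant"]]
        deg_map = {r.gene: (r.direction, r.fc) for r in sig.itertuples(index=False)}

        for gene in sorted(set(cnv_map) | set(deg_map)):
            cnv_dir, freq = cnv_map.get(gene, ("none", np.nan))
            expr_dir, fc = deg_map.get(gene, ("none", np.nan))
            if cnv_dir != "none" and expr_dir != "none":
                concordant = (cnv_dir == "gain") == (expr_dir == "up")
                status = "cnv_driven" if concordant else "discordant"
            elif cnv_dir != "none":
                status = "cnv_only"
            else:
                status = "expression_only"
            records.append(
                {
                    "gene": gene,
                    "subgroup": subgroup,
                    "cnv_direction": cnv_dir,
                    "expr_direction": expr_dir,
                    "status": status,
                    "cnv_frequency_pct": freq,
                    "fc": fc,
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "gene", "subgroup", "cnv_direction", "expr_direction",
            "status", "cnv_frequency_pct", "fc",
        ],
    )


def concordance_summary(records: pd.DataFrame) -> dict:
    """Counts and headline percentages per subgroup and overall.

    The percentage denominator is the CNV-and-DEG overlap (concordant +
    discordant); with an empty overlap the percentage is reported as
    None, not 0.  ``pct`` is rounded half-up to the nearest integer for
    the headline, ``pct_exact`` kept at two decimals.
    """
    def _one(sub: pd.DataFrame) -> dict:
        driven = sub[sub["status"] == "cnv_driven"]
        discordant = int((sub["status"] == "discordant").sum())
        n_driven = len(driven)
        overlap = n_driven + discordant
        up = int(((driven["cnv_direction"] == "gain") & (driven["expr_direction"] == "up")).sum())
        down = int(((driven["cnv_direction"] == "loss") & (driven["expr_direction"] == "down")).sum())
        if overlap:
            pct_exact = round_half_up(100.0 * n_driven / overlap, 2)
            pct = int(round_half_up(100.0 * n_driven / overlap, 0))
        else:
            pct_exact = pct = None
        return {
            "overlap": overlap,
            "cnv_driven": n_driven,
            "cnv_driven_up": up,
            "cnv_driven_down": down,
            "discordant": discordant,
            "cnv_only": int((sub["status"] == "cnv_only").sum()),
            "expression_only": int((sub["status"] == "expression_only").sum()),
            "pct_cnv_driven": pct,
            "pct_cnv_driven_exact": pct_exact,
        }

    out = {"overall": _one(records)}
    for subgroup in SUBGROUPS:
        out[subgroup] = _one(records[records["subgroup"] == subgroup])
    total_up = sum(out[s]["cnv_driven_up"] for s in SUBGROUPS)
    total_down = sum(out[s]["cnv_driven_down"] for s in SUBGROUPS)
    out["overall"]["cnv_driven_up_total"] = total_up
    out["overall"]["cnv_driven_down_total"] = total_down
    return out


# ---------------------------------------------------------------------------
# Randomized-group control
# ---------------------------------------------------------------------------

def _overlap_count(
    fragments: pd.DataFrame,
    control_calls: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    gene_panel: pd.DataFrame,
    min_pct: float,
    fc_threshold: float,
) -> int:
    """Total CNV-and-DEG overlap (both subgroups) under a given labelling.

    ``fragments`` are the label-independent atomic fragments of the case
    calls, precomputed once so random relabellings only redo penetrance.
    """
    pieces = []
    if not fragments.empty:
        pen = compute_penetrance(fragments, metadata)
        for scope in SUBGROUPS:
            regions = select_recurrent(pen, min_pct=min_pct, scope=scope)
            regions = filter_case_exclusive(regions, control_calls)
            if not regions.empty:
                pieces.append(cnv_gene_table(annotate_regions(regions, gene_panel)))
    cnv_genes = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(columns=["gene", "direction", "scope", "frequency_pct"])
    )
    degs = call_degs(gene_matrix, metadata, fc_threshold=fc_threshold)
    records = overlap_cnv_deg(cnv_genes, degs)
    return int(records["status"].isin(["cnv_driven", "discordant"]).sum())


def randomized_group_control(
    calls: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    gene_panel: pd.DataFrame,
    n_splits: int = 99,
    seed: int = 0,
    min_pct: float = 10.0,
    fc_threshold: float = 1.5,
) -> dict:
    """Null distribution of the CNV-and-DEG overlap under random case splits.

    Case samples are randomly re-partitioned into two pseudo-subgroups
    of the original sizes (sampling bipartitions with replacement);
    controls keep their labels.  For each split the full recurrence +
    DEG + overlap chain is rerun and the overlap size recorded.  The
    empirical p uses the add-one permutation estimator
    ``(1 + #{null >= observed}) / (n_splits + 1)``.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    control_ids = set(metadata.loc[metadata["group"] == "control", "sample_id"])
    fragments = fragment_breakpoints(calls[~calls["sample_id"].isin(control_ids)])
    control_calls = calls[calls["sample_id"].isin(control_ids)]
    observed = _overlap_count(fragments, control_calls, gene_matrix, metadata,
                              gene_panel, min_pct, fc_threshold)
    cases = metadata[metadata["group"] != "control"]
    n1 = int((metadata["group"] == "group1").sum())
    case_ids = cases["sample_id"].to_numpy()
    rng = np.random.default_rng(seed)

    null = np.empty(n_splits, dtype=int)
    for s in range(n_splits):
        perm = rng.permutation(case_ids)
        relabel = dict.fromkeys(perm[:n1], "group1")
        relabel.update(dict.fromkeys(perm[n1:], "group2"))
        pseudo = metadata.copy()
        pseudo["group"] = [
            relabel.get(sid, grp) for sid, grp in zip(pseudo["sample_id"], pseudo["group"])
        ]
        null[s] = _overlap_count(fragments, control_calls, gene_matrix, pseudo,
                                 gene_panel, min_pct, fc_threshold)

    p = (1 + int((null >= observed).sum())) / (n_splits + 1)
    return {
        "observed": observed,
        "null": null,
        "null_mean": float(null.mean()),
        "p_value": float(p),
        "n_splits": n_splits,
    }
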