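"""Synthetic cohort generator for matched aCGH + expression studies.

Emulates a two-subgroup case/control motor-cortex cohort profiled on a
custom exon-centric CGH array: a multi-thousand-probe panel laid out on
hg19-like chromosomes, planted recurrent subgroup-specific gains and
losses at chosen carrier frequencies, Gaussian probe noise, and a linear
expression matrix in which a configurable fraction of CNV genes shows
dosage-concordant differential expression.  Every planted signal is
recorded in a :class:`TruthSet` so downstream modules can be tested by
parameter recovery instead of against external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHROMOSOMES",
    "CohortDesign",
    "CnvSpec",
    "PlantedCnv",
    "DosageGene",
    "IndependentDeg",
    "TruthSet",
    "chrom_sort_key",
    "generate_panel",
    "generate_metadata",
    "generate_cohort",
    "generate_expression",
    "write_panel",
    "read_panel",
    "write_matrix",
    "read_matrix",
    "write_metadata",
    "read_metadata",
    "write_truth",
]

#: Synthetic autosome names; genes are laid out round-robin across these.
CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23))

GROUPS = ("control", "group1", "group2")


def chrom_sort_key(chrom: str):
    """Natural sort key for chromosome names (chr2 before chr10)."""
    tail = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(tail)) if tail.isdigit() else (1, tail)


@dataclass(frozen=True)
class CohortDesign:
    """Cohort geometry and noise/effect parameters.

    Defaults reproduce the study layout: 10 controls and 30 cases split
    17/13 into two transcriptome-defined subgroups.  ``gain_shift`` is
    one extra copy on a diploid background (log2(3/2) ~ +0.58) and
    ``loss_shift`` a heterozygous deletion (log2(1/2) = -1.0), so planted
    events clear the +-0.5 aberration filter at realistic noise.
    """

    n_control: int = 10
    n_group1: int = 17
    n_group2: int = 13
    noise_sigma: float = 0.15          # aCGH probe noise, log2-ratio units
    gain_shift: float = 0.58
    loss_shift: float = -1.0
    concordant_fraction: float = 0.5   # fraction of CNV genes with dosage response
    expr_noise_sigma: float = 0.2      # expression noise, log2 units
    # Planted expression |log2 shift| in carriers.  The subgroup-mean effect
    # is diluted by carrier frequency, so the shift must exceed
    # log2(1.5) / min carrier frequency for the FC gate to be reachable.
    expr_shift: float = 1.5
    n_independent_degs: int = 10       # CNV-independent DEGs planted per cohort
    gc_bias_slope: float = 0.0         # optional linear GC artifact (off by default)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_control, self.n_group1, self.n_group2) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.noise_sigma < 0 or self.expr_noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if not 0.0 <= self.concordant_fraction <= 1.0:
            raise ValueError("concordant_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CnvSpec:
    """A recurrent CNV to plant: genomic region, direction, target group, frequency."""

    chrom: str
    start: int
    end: int
    direction: str            # "gain" | "loss"
    subgroup: str             # "group1" | "group2" | "cases" | "control"
    frequency: float          # carrier fraction within the target group

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain/loss, got {self.direction!r}")
        if self.subgroup not in ("group1", "group2", "cases", "control"):
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must lie in [0, 1]")
        if self.start >= self.end:
            raise ValueError("empty region")


@dataclass(frozen=True)
class PlantedCnv:
    chrom: str
    start: int
    end: int
    direction: str
    subgroup: str
    carriers: tuple
    frequency: float
    probe_ids: tuple = ()

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass(frozen=True)
class DosageGene:
    gene: str
    log2_shift: float        # signed planted expression shift (0 if not concordant)
    concordant: bool
    direction: str = ""      # copy-number direction of the underlying CNV
    subgroup: str = ""
    carriers: tuple = ()


@dataclass(frozen=True)
class IndependentDeg:
    gene: str
    log2_shift: float
    subgroup: str


@dataclass(frozen=True)
class TruthSet:
    """Ground truth of a simulated cohort, for recovery tests."""

    planted_cnvs: tuple
    dosage_genes: tuple
    independent_degs: tuple
    seed: int

    def cnv_genes(self) -> list:
        return [d.gene for d in self.dosage_genes]


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

_PROBE_LEN = 60          # bp covered by one probe
_PROBE_GAP = 40          # gap between probes within an exon
_INTRON_GAP = 2_000
_INTERGENIC_GAP = 50_000
_CHROM_OFFSET = 100_000


def generate_panel(
    n_genes: int,
    exons_per_gene: int,
    probes_per_exon: int,
    seed: int,
) -> pd.DataFrame:
    """Lay out an exon-centric probe panel on synthetic chromosomes.

    Genes are placed round-robin across 22 autosomes, non-overlapping,
    each with ``exons_per_gene`` exons of ``probes_per_exon`` probes.
    GC fraction is drawn uniformly from [0.3, 0.7].

    Returns a DataFrame with columns ``probe_id, chrom, start, end, gene,
    exon, gc_fraction`` sorted by (chrom, start); coordinates are 0-based
    half-open.
    """
    if min(n_genes, exons_per_gene, probes_per_exon) < 1:
        raise ValueError("n_genes, exons_per_gene and probes_per_exon must be >= 1")
    rng = np.random.default_rng(seed)

    cursors = {c: _CHROM_OFFSET for c in CHROMOSOMES}
    rows = []
    for g in range(n_genes):
        gene = f"GENE{g + 1:04d}"
        chrom = CHROMOSOMES[g % len(CHROMOSOMES)]
        pos = cursors[chrom]
        for e in range(exons_per_gene):
            for p in range(probes_per_exon):
                start = pos
                end = start + _PROBE_LEN
                rows.append(
                    (f"{gene}_e{e + 1}_p{p + 1}", chrom, start, end, gene, e + 1)
                )
                pos = end + _PROBE_GAP
            pos += _INTRON_GAP
        cursors[chrom] = pos + _INTERGENIC_GAP

    panel = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "start", "end", "gene", "exon"]
    )
    panel["gc_fraction"] = rng.uniform(0.3, 0.7, size=len(panel))
    panel["_ck"] = panel["chrom"].map(chrom_sort_key)
    panel = panel.sort_values(["_ck", "start"], kind="mergesort").drop(columns="_ck")
    return panel.reset_index(drop=True)


def generate_metadata(design: CohortDesign) -> pd.DataFrame:
    """Sample sheet: sample_id and group for the whole cohort."""
    ids, groups = [], []
    for i in range(design.n_control):
        ids.append(f"CTRL{i + 1:02d}")
        groups.append("control")
    for i in range(design.n_group1):
        ids.append(f"SALS1_{i + 1:02d}")
        groups.append("group1")
    for i in range(design.n_group2):
        ids.append(f"SALS2_{i + 1:02d}")
        groups.append("group2")
    return pd.DataFrame({"sample_id": ids, "group": groups})


def _round_half_up_count(x: float) -> int:
    return int(np.floor(x + 0.5))


def _group_samples(metadata: pd.DataFrame, subgroup: str) -> list:
    if subgroup == "cases":
        mask = metadata["group"].isin(["group1", "group2"])
    else:
        mask = metadata["group"] == subgroup
    return metadata.loc[mask, "sample_id"].tolist()


# ---------------------------------------------------------------------------
# aCGH cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    panel: pd.DataFrame,
    design: CohortDesign,
    cnv_spec: Sequence[CnvSpec],
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Simulate per-sample probe log2 ratios with planted recurrent CNVs.

    Carriers for each spec entry are drawn without replacement from the
    target group using a dedicated RNG stream, so adding spec entries
    does not perturb earlier ones.  Carrier probes inside a planted
    region are shifted by ``gain_shift``/``loss_shift`` on top of
    Gaussian noise; every planted signal is recorded in the truth set,
    including the dosage-gene assignment used by
    :func:`generate_expression`.

    Returns ``(profiles, metadata, truth)`` where ``profiles`` is a
    probes x samples DataFrame indexed by probe_id.
    """
    metadata = generate_metadata(design)
    samples = metadata["sample_id"].tolist()
    n_probes = len(panel)

    rng = np.random.default_rng([design.seed, 0])
    values = rng.normal(0.0, design.noise_sigma, size=(n_probes, len(samples)))
    if design.gc_bias_slope != 0.0:
        gc = panel["gc_fraction"].to_numpy()
        values += design.gc_bias_slope * (gc - gc.mean())[:, None]

    chrom_arr = panel["chrom"].to_numpy()
    start_arr = panel["start"].to_numpy()
    end_arr = panel["end"].to_numpy()
    col = {s: j for j, s in enumerate(samples)}

    planted = []
    for i, spec in enumerate(cnv_spec):
        in_region = (chrom_arr == spec.chrom) & (end_arr > spec.start) & (start_arr < spec.end)
        idx = np.flatnonzero(in_region)
        if idx.size < 3:
            raise ValueError(
                f"planted region {spec.chrom}:{spec.start}-{spec.end} overlaps "
                f"{idx.size} probes; at least 3 are required to be callable"
            )
        pool = _group_samples(metadata, spec.subgroup)
        k = _round_half_up_count(spec.frequency * len(pool))
        entry_rng = np.random.default_rng([design.seed, 1, i])
        carriers = sorted(entry_rng.choice(pool, size=k, replace=False).tolist()) if k else []
        shift = design.gain_shift if spec.direction == "gain" else design.loss_shift
        for s in carriers:
            values[idx, col[s]] += shift
        planted.append(
            PlantedCnv(
                chrom=spec.chrom,
                start=spec.start,
                end=spec.end,
                direction=spec.direction,
                subgroup=spec.subgroup,
                carriers=tuple(carriers),
                frequency=spec.frequency,
                probe_ids=tuple(panel["probe_id"].iloc[idx]),
            )
        )

    dosage = _assign_dosage_genes(panel, planted, design)
    independent = _assign_independent_degs(panel, dosage, design)
    truth = TruthSet(
        planted_cnvs=tuple(planted),
        dosage_genes=dosage,
        independent_degs=independent,
        seed=design.seed,
    )
    profiles = pd.DataFrame(values, index=panel["probe_id"].to_numpy(), columns=samples)
    profiles.index.name = "probe_id"
    return profiles, metadata, truth


def _assign_dosage_genes(panel, planted, design: CohortDesign) -> tuple:
    """Pick which CNV genes respond in expression (dosage-concordant).

    Exactly round(concordant_fraction x n_cnv_genes) genes are flagged
    concordant; the rest carry the CNV with no expression response.
    """
    gene_info: dict[str, tuple] = {}
    gene_span = panel.groupby("gene").agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
    )
    for cnv in planted:
        hits = gene_span[
            (gene_span["chrom"] == cnv.chrom)
            & (gene_span["end"] > cnv.start)
            & (gene_span["start"] < cnv.end)
        ]
        for gene in hits.index:
            gene_info.setdefault(gene, (cnv.direction, cnv.subgroup, cnv.carriers))

    genes = sorted(gene_info)
    n_conc = _round_half_up_count(design.concordant_fraction * len(genes))
    pick_rng = np.random.default_rng([design.seed, 2])
    concordant = set(pick_rng.choice(genes, size=n_conc, replace=False).tolist()) if genes else set()

    out = []
    for gene in genes:
        direction, subgroup, carriers = gene_info[gene]
        is_conc = gene in concordant
        shift = 0.0
        if is_conc:
            shift = design.expr_shift if direction == "gain" else -design.expr_shift
        out.append(
            DosageGene(
                gene=gene,
                log2_shift=shift,
                concordant=is_conc,
                direction=direction,
                subgroup=subgroup,
                carriers=carriers,
            )
        )
    return tuple(out)


def _assign_independent_degs(panel, dosage, design: CohortDesign) -> tuple:
    cnv_genes = {d.gene for d in dosage}
    free = sorted(set(panel["gene"]) - cnv_genes)
    n = min(design.n_independent_degs, len(free))
    rng = np.random.default_rng([design.seed, 3])
    chosen = sorted(rng.choice(free, size=n, replace=False).tolist()) if n else []
    out = []
    for j, gene in enumerate(chosen):
        subgroup = "group1" if j % 2 == 0 else "group2"
        shift = design.expr_shift if j % 4 < 2 else -design.expr_shift
        out.append(IndependentDeg(gene=gene, log2_shift=shift, subgroup=subgroup))
    return tuple(out)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

_PROBES_PER_EXPR_GENE = 2
_N_UNMAPPED_PROBES = 5


def generate_expression(
    panel: pd.DataFrame,
    truth: TruthSet,
    design: CohortDesign,
    metadata: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a linear-intensity expression matrix matched to the cohort.

    Each panel gene gets two expression probes (so probe collapse has
    work to do) plus a few unannotated probes with no gene mapping.
    Dosage-concordant CNV genes are shifted in the CNV direction in
    carrier samples only; CNV-independent planted DEGs are shifted in
    every sample of their subgroup.  Intensities are ``2**log2`` and
    therefore strictly positive.

    Returns ``(matrix, probe_to_gene)``: a probes x samples DataFrame of
    linear intensities and the probe -> gene mapping (empty string for
    unmapped probes).
    """
    if metadata is None:
        metadata = generate_metadata(design)
    samples = metadata["sample_id"].tolist()
    genes = sorted(set(panel["gene"]), key=lambda g: g)

    rng = np.random.default_rng([design.seed, 4])
    baseline = {g: rng.normal(7.0, 1.0) for g in genes}

    probe_ids, probe_gene = [], []
    for g in genes:
        for p in range(_PROBES_PER_EXPR_GENE):
            probe_ids.append(f"EXP_{g}_{p + 1}")
            probe_gene.append(g)
    for u in range(_N_UNMAPPED_PROBES):
        probe_ids.append(f"EXP_UNMAPPED_{u + 1}")
        probe_gene.append("")

    probe_offset = rng.normal(0.0, 0.25, size=len(probe_ids))
    log2 = np.empty((len(probe_ids), len(samples)))
    base = np.array([baseline.get(g, 5.0) if g else 5.0 for g in probe_gene])
    log2[:] = (base + probe_offset)[:, None]
    log2 += rng.normal(0.0, design.expr_noise_sigma, size=log2.shape)

    col = {s: j for j, s in enumerate(samples)}
    gene_rows: dict[str, list] = {}
    for i, g in enumerate(probe_gene):
        if g:
            gene_rows.setdefault(g, []).append(i)

    for d in truth.dosage_genes:
        if not d.concordant or d.gene not in gene_rows:
            continue
        rows = gene_rows[d.gene]
        cols = [col[s] for s in d.carriers if s in col]
        if cols:
            log2[np.ix_(rows, cols)] += d.log2_shift
    for d in truth.independent_degs:
        if d.gene not in gene_rows:
            continue
        rows = gene_rows[d.gene]
        cols = [col[s] for s in _group_samples(metadata, d.subgroup)]
        if cols:
            log2[np.ix_(rows, cols)] += d.log2_shift

    matrix = pd.DataFrame(np.power(2.0, log2), index=probe_ids, columns=samples)
    matrix.index.name = "probe_id"
    mapping = pd.Series(probe_gene, index=probe_ids, name="gene")
    return matrix, mapping


# ---------------------------------------------------------------------------
# TSV round trips
# ---------------------------------------------------------------------------

def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    required = {"probe_id", "chrom", "start", "end", "gene", "gc_fraction"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel file {path} lacks columns: {sorted(missing)}")
    return panel


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(meta.columns):
        raise ValueError(f"metadata file {path} needs sample_id and group columns")
    bad = set(meta["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown groups in metadata: {sorted(bad)}")
    return meta


def write_truth(truth: TruthSet, path) -> None:
    """Truth sidecar as a flat TSV (one row per planted signal)."""
    rows = []
    for c in truth.planted_cnvs:
        rows.append(
            {
                "kind": "cnv",
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "direction": c.direction,
                "subgroup": c.subgroup,
                "frequency": c.frequency,
                "carriers": ",".join(c.carriers),
                "gene": "",
                "log2_shift": "",
                "concordant": "",
            }
        )
    for d in truth.dosage_genes:
        rows.append(
            {
                "kind": "dosage_gene",
                "chrom": "",
                "start": "",
                "end": "",
                "direction": d.direction,
                "subgroup": d.subgroup,
                "frequency": "",
                "carriers": ",".join(d.carriers),
                "gene": d.gene,
                "log2_shift": d.log2_shift,
                "concordant": int(d.concordant),
            }
        )
    for d in truth.independent_degs:
        rows.append(
            {
                "kind": "independent_deg",
                "chrom": "",
                "start": "",
                "end": "",
                "direction": "",
                "subgroup": d.subgroup,
                "frequency": "",
                "carriers": "",
                "gene": d.gene,
                "log2_shift": d.log2_shift,
                "concordant": "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
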