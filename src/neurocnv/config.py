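"""Pipeline configuration and end-to-end orchestration.

A single YAML config drives simulate -> call -> recurrence -> annotate
-> DEG -> integrate (and, when inputs are given, enrichment / network /
qPCR), with every threshold surfaced at its published default and a
manifest of inputs, seeds and output checksums for byte-identical
reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, downstream, expression, integration, recurrence, segmentation
from .simulate import (
    CnvSpec,
    CohortDesign,
    chrom_sort_key,
    generate_cohort,
    generate_expression,
    generate_panel,
    read_matrix,
    read_metadata,
    read_panel,
    write_matrix,
    write_metadata,
    write_panel,
    write_truth,
)

__all__ = ["PipelineConfig", "run_pipeline", "default_cnv_spec"]

log = logging.getLogger("neurocnv")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, defaulting to the published thresholds."""

    outdir: str = "neurocnv_out"
    seed: int = 0

    # synthetic cohort
    n_genes: int = 154
    exons_per_gene: int = 4
    probes_per_exon: int = 5
    n_control: int = 10
    n_group1: int = 17
    n_group2: int = 13
    noise_sigma: float = 0.15
    gain_shift: float = 0.58
    loss_shift: float = -1.0
    concordant_fraction: float = 0.5
    expr_noise_sigma: float = 0.2
    expr_shift: float = 1.0
    n_independent_degs: int = 10
    gc_bias_slope: float = 0.0
    cnv_spec: list = field(default_factory=list)  # list of CnvSpec-like dicts

    # segmentation
    adm_threshold: float = 6.0
    min_abs_log2: float = 0.5
    min_probes: int = 3
    gc_correct: bool = True
    smooth_window_bp: int | None = None
    threads: int = 1

    # recurrence
    recurrence_pct: float = 10.0
    case_exclusive: bool = True
    direction_matched: bool = True

    # differential expression
    fdr_alpha: float = 0.05
    tukey_alpha: float = 0.05
    fc_threshold: float = 1.5
    use_adjusted_p: bool = True

    # randomized-group control
    n_splits: int = 99

    # downstream (optional external inputs)
    gmt_path: str | None = None
    edges_path: str | None = None
    ct_path: str | None = None
    ct_reference_gene: str | None = None
    ct_calibrator: str | None = None
    degree_threshold: int = 10
    edge_confidence: float = 0.8
    ddct_gain: float = 1.4
    ddct_loss: float = 0.6
    ddct_diploid: tuple = (0.8, 1.2)

    # existing inputs (skip simulation when all three are given)
    panel_path: str | None = None
    profiles_path: str | None = None
    metadata_path: str | None = None
    expression_path: str | None = None
    probe_map_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def design(self) -> CohortDesign:
        return CohortDesign(
            n_control=self.n_control,
            n_group1=self.n_group1,
            n_group2=self.n_group2,
            noise_sigma=self.noise_sigma,
            gain_shift=self.gain_shift,
            loss_shift=self.loss_shift,
            concordant_fraction=self.concordant_fraction,
            expr_noise_sigma=self.expr_noise_sigma,
            expr_shift=self.expr_shift,
            n_independent_degs=self.n_independent_degs,
            gc_bias_slope=self.gc_bias_slope,
            seed=self.seed,
        )


def default_cnv_spec(panel: pd.DataFrame, n_per_subgroup: int = 10) -> list[CnvSpec]:
    """A standard planting plan: one region per chromosome, alternating
    subgroup and direction, at recurrence-table-like carrier frequencies.

    Losses are single/multi-exon deletions (5-15 probes, the event class
    the exon-centric design targets); gains span two adjacent genes
    (~40 probes), reflecting that duplications run larger than deletions
    and that a +0.58 single-copy gain needs ~30+ probes for its called
    mean to clear the 0.5 aberration filter reliably at realistic noise
    (a -1.0 deletion clears it from a handful of probes).
    """
    freqs = {
        "group1": [13 / 17, 15 / 17, 12 / 17],
        "group2": [10 / 13, 9 / 13, 8 / 13],
    }
    loss_probe_counts = [5, 8, 10, 12, 15]
    genes_by_chrom: dict[str, list[str]] = {}
    for gene, sub in panel.groupby("gene", sort=True):
        genes_by_chrom.setdefault(sub["chrom"].iloc[0], []).append(gene)
    for genes in genes_by_chrom.values():
        genes.sort(key=lambda g: panel.loc[panel["gene"] == g, "start"].min())
    chroms = sorted(genes_by_chrom, key=chrom_sort_key)

    spec = []
    for j in range(2 * n_per_subgroup):
        if j >= len(chroms):
            raise ValueError("not enough chromosomes for the requested plan")
        chrom = chroms[j]
        genes = genes_by_chrom[chrom]
        subgroup = "group1" if j % 2 == 0 else "group2"
        i = j // 2
        direction = "gain" if i % 2 == 0 else "loss"
        if direction == "gain" and len(genes) >= 2:
            probes = panel[panel["gene"].isin(genes[:2])]
        elif direction == "gain":
            probes = panel[panel["gene"] == genes[0]]
        else:
            want = loss_probe_counts[i % len(loss_probe_counts)]
            probes = (
                panel[panel["gene"] == genes[0]].sort_values("start").head(want)
            )
        spec.append(
            CnvSpec(
                chrom=chrom,
                start=int(probes["start"].min()),
                end=int(probes["end"].max()),
                direction=direction,
                subgroup=subgroup,
                frequency=freqs[subgroup][i % 3],
            )
        )
    return spec


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write an artifact manifest.

    Stage failures raise RuntimeError naming the stage.  Reruns with the
    same config are byte-identical (seeded RNG streams throughout).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "outputs": {}}
    design = config.design()

    def _stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - manifest must name the stage
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = result or {}
            log.info("stage %s: %s", name, result or {})
            return result
        return deco

    state: dict = {}

    @_stage("simulate")
    def _simulate():
        if config.panel_path and config.profiles_path and config.metadata_path:
            state["panel"] = read_panel(config.panel_path)
            state["profiles"] = read_matrix(config.profiles_path)
            state["metadata"] = read_metadata(config.metadata_path)
            if config.expression_path:
                state["expr_raw"] = read_matrix(config.expression_path)
                pm = pd.read_csv(config.probe_map_path, sep="\t", index_col=0)
                state["probe_map"] = pm.iloc[:, 0].fillna("")
            state["truth"] = None
            return {"source": "files"}
        panel = generate_panel(config.n_genes, config.exons_per_gene,
                               config.probes_per_exon, config.seed)
        spec = [CnvSpec(**s) if isinstance(s, dict) else s for s in config.cnv_spec]
        if not spec:
            spec = default_cnv_spec(panel)
        profiles, metadata, truth = generate_cohort(panel, design, spec)
        expr_raw, probe_map = generate_expression(panel, truth, design, metadata)
        state.update(panel=panel, profiles=profiles, metadata=metadata,
                     truth=truth, expr_raw=expr_raw, probe_map=probe_map)
        write_panel(panel, outdir / "panel.tsv")
        write_matrix(profiles, outdir / "profiles.tsv")
        write_metadata(metadata, outdir / "metadata.tsv")
        write_matrix(expr_raw, outdir / "expression_raw.tsv")
        probe_map.to_frame().to_csv(outdir / "probe_map.tsv", sep="\t")
        write_truth(truth, outdir / "truth.tsv")
        return {"n_probes": len(panel), "n_samples": len(metadata),
                "n_planted": len(truth.planted_cnvs)}

    @_stage("call_cnv")
    def _call():
        calls = segmentation.call_cnvs(
            state["profiles"], state["panel"],
            threshold=config.adm_threshold,
            min_abs_log2=config.min_abs_log2,
            min_probes=config.min_probes,
            do_gc_correct=config.gc_correct,
            smooth_window_bp=config.smooth_window_bp,
            n_jobs=config.threads,
        )
        state["calls"] = calls
        segmentation.write_seg(calls, outdir / "calls.seg")
        segmentation.write_bed(calls, outdir / "calls.bed")
        return {"n_calls": len(calls)}

    @_stage("recurrence")
    def _recurrence():
        counts = {}
        regions_by_scope = {}
        for scope in ("cases", "group1", "group2"):
            regions = recurrence.recurrent_regions(
                state["calls"], state["metadata"],
                min_pct=config.recurrence_pct, scope=scope,
                case_exclusive=config.case_exclusive,
                direction_matched=config.direction_matched,
            )
            regions_by_scope[scope] = regions
            counts[scope] = len(regions)
        state["regions"] = regions_by_scope
        return {"n_recurrent": counts}

    @_stage("annotate")
    def _annotate():
        gene_panel = annotation.gene_panel_from_probes(state["panel"])
        state["gene_panel"] = gene_panel
        annotated = {}
        tables = []
        for scope, regions in state["regions"].items():
            ann = annotation.annotate_regions(regions, gene_panel) if not regions.empty else regions.assign(genes=pd.Series(dtype=object), intergenic=pd.Series(dtype=bool))
            annotated[scope] = ann
            recurrence.write_recurrent_tsv(ann, outdir / f"recurrent_{scope}.tsv")
        state["annotated"] = annotated
        for scope in ("group1", "group2"):
            tables.append(annotation.cnv_gene_table(annotated[scope]))
        state["cnv_genes"] = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
        return {"n_cnv_genes": len(state["cnv_genes"])}

    @_stage("deg")
    def _deg():
        if "expr_raw" not in state:
            state["degs"] = pd.DataFrame(
                columns=["gene", "subgroup", "fc", "p_anova", "fdr", "p_tukey",
                         "direction", "significant"])
            return {"skipped": "no expression input"}
        norm = expression.normalize_expression(state["expr_raw"])
        gene_matrix = expression.collapse_probes(norm, state["probe_map"])
        state["gene_matrix"] = gene_matrix
        degs = expression.call_degs(
            gene_matrix, state["metadata"],
            fdr_alpha=config.fdr_alpha, tukey_alpha=config.tukey_alpha,
            fc_threshold=config.fc_threshold, use_adjusted=config.use_adjusted_p,
        )
        state["degs"] = degs
        degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)
        return {"n_significant": int(degs["significant"].sum())}

    @_stage("integrate")
    def _integrate():
        records = integration.overlap_cnv_deg(state["cnv_genes"], state["degs"])
        summary = integration.concordance_summary(records)
        state["concordance"] = records
        state["summary"] = summary
        records.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
        (outdir / "concordance_summary.json").write_text(
            json.dumps(summary, indent=2, default=str))
        return {"overall": summary["overall"]}

    @_stage("enrich")
    def _enrich():
        if not config.gmt_path:
            return {"skipped": "no GMT provided"}
        gene_sets = downstream.parse_gmt(config.gmt_path)
        universe = set(state["gene_panel"]["gene"])
        query = set(
            state["concordance"].loc[
                state["concordance"]["status"] == "cnv_driven", "gene"]
        ) & universe
        res = downstream.hypergeom_enrich(query, gene_sets, universe, strict=False)
        res.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        return {"n_terms": len(res)}

    @_stage("network")
    def _network():
        if not config.edges_path:
            return {"skipped": "no edge list provided"}
        edges = pd.read_csv(config.edges_path, sep="\t")
        nodes, edge_metrics, _ = downstream.network_hubs(
            edges, degree_threshold=config.degree_threshold,
            min_confidence=config.edge_confidence,
        )
        nodes.to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
        edge_metrics.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        return {"n_hubs": int(nodes["is_hub"].sum())}

    @_stage("qpcr")
    def _qpcr():
        if not config.ct_path:
            return {"skipped": "no Ct table provided"}
        ct = pd.read_csv(config.ct_path, sep="\t")
        res = downstream.ddct_classify(ct, config.ct_reference_gene,
                                       config.ct_calibrator)
        res.to_csv(outdir / "qpcr_classes.tsv", sep="\t", index=False)
        return {"n_records": len(res)}

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
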