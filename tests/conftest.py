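import pandas as pd
import pytest

import neurocnv as ncv
from neurocnv.config import default_cnv_spec

STUDY_SEED = 1


@pytest.fixture(scope="session")
def small_panel():
    """12 genes x 2 exons x 3 probes — enough for interval logic."""
    return ncv.generate_panel(12, 2, 3, seed=7)


@pytest.fixture(scope="session")
def study_cohort():
    """Full-size study-shaped cohort: 154-gene panel, 10/17/13 samples,
    default planting plan, noise 0.15.  Shared across tests (read-only)."""
    panel = ncv.generate_panel(154, 4, 5, seed=STUDY_SEED)
    design = ncv.CohortDesign(seed=STUDY_SEED)
    spec = default_cnv_spec(panel)
    profiles, metadata, truth = ncv.generate_cohort(panel, design, spec)
    return {
        "panel": panel,
        "design": design,
        "spec": spec,
        "profiles": profiles,
        "metadata": metadata,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def study_calls(study_cohort):
    return ncv.call_cnvs(study_cohort["profiles"], study_cohort["panel"])


@pytest.fixture(scope="session")
def study_expression(study_cohort):
    expr, probe_map = ncv.generate_expression(
        study_cohort["panel"], study_cohort["truth"], study_cohort["design"],
        study_cohort["metadata"],
    )
    gene_matrix = ncv.collapse_probes(ncv.normalize_expression(expr), probe_map)
    return {"raw": expr, "probe_map": probe_map, "gene_matrix": gene_matrix}


def metadata_for(n_control=10, n_group1=17, n_group2=13):
    return ncv.generate_metadata(
        ncv.CohortDesign(n_control=n_control, n_group1=n_group1, n_group2=n_group2)
    )


def make_calls(rows):
    """rows: (sample_id, chrom, start, end, direction[, mean])"""
    recs = []
    for r in rows:
        sample_id, chrom, start, end, direction = r[:5]
        mean = r[5] if len(r) > 5 else (1.0 if direction == "gain" else -1.0)
        recs.append(
            {
                "sample_id": sample_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "direction": direction,
                "n_probes": 5,
                "mean_log2": mean,
                "score": 10.0 if mean > 0 else -10.0,
            }
        )
    return pd.DataFrame(recs)
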