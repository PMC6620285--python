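"""Per-sample aCGH normalization and aberration calling.

The calling chain per sample is fixed: GC correction (2 kb-scale probe
GC content, binned-median detrending) -> diploid-peak centralization
(kernel-density mode shifted to zero) -> noise estimation via the
derivative log-ratio spread (DLRS) -> an ADM-2-style greedy interval
scan with score sqrt(n) * |mean| / sigma and sensitivity threshold 6.0
-> the aberration filter (|mean log2| >= 0.5 over >= 3 consecutive
probes).  All thresholds are inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import chrom_sort_key

__all__ = [
    "DegenerateProfileError",
    "gc_correct",
    "centralize",
    "estimate_dlrs",
    "adm2_scan",
    "filter_calls",
    "call_sample",
    "call_cnvs",
    "write_seg",
    "write_bed",
]

ADM_THRESHOLD = 6.0
MIN_ABS_LOG2 = 0.5
MIN_PROBES = 3


class DegenerateProfileError(ValueError):
    """Raised when a profile has no measurable noise (sigma = 0)."""


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def gc_correct(values: np.ndarray, gc_fraction: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Remove the GC-content trend from a probe log2-ratio vector.

    Probes are binned into ``n_bins`` equal-width bins over the observed
    GC range and each probe's value is reduced by its bin's median, which
    both detrends and re-centres the profile.
    """
    values = np.asarray(values, dtype=float)
    gc = np.asarray(gc_fraction, dtype=float)
    if gc.shape != values.shape:
        raise ValueError("gc_fraction must align with the profile")
    if np.isnan(gc).any():
        raise ValueError("panel lacks GC annotation for some probes")

    lo, hi = gc.min(), gc.max()
    if hi <= lo:
        return values - np.median(values)
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(gc, edges[1:-1]), 0, n_bins - 1)
    out = values.copy()
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            out[mask] -= np.median(values[mask])
    return out


def centralize(values: np.ndarray, min_probes: int = 30) -> tuple[np.ndarray, float]:
    """Shift a profile so its dominant copy-number state sits at log2 = 0.

    The diploid peak is located as the mode of a Gaussian kernel density
    estimate (Scott's bandwidth); the applied shift is the median of the
    values within +-0.1 of that mode, so after shifting that local median
    is exactly zero.  Returns ``(shifted_values, shift)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < min_probes:
        raise ValueError(f"centralization needs >= {min_probes} probes, got {values.size}")
    if np.std(values) == 0.0:
        shift = float(values[0])
        return values - shift, shift
    kde = stats.gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 2048)
    mode = float(grid[np.argmax(kde(grid))])
    near = values[np.abs(values - mode) <= 0.1]
    shift = float(np.median(near)) if near.size else mode
    return values - shift, shift


def estimate_dlrs(values: np.ndarray, chroms: np.ndarray) -> float:
    """Derivative log-ratio spread: robust probe-to-probe noise estimate.

    IQR of first differences of consecutive same-chromosome probes,
    scaled to a Gaussian sigma (/1.349) and divided by sqrt(2) because a
    difference of two independent probes doubles the variance.
    """
    values = np.asarray(values, dtype=float)
    chroms = np.asarray(chroms)
    diffs = []
    for c in pd.unique(chroms):
        v = values[chroms == c]
        if v.size >= 2:
            diffs.append(np.diff(v))
    if not diffs:
        raise ValueError("need at least one chromosome with >= 2 probes")
    d = np.concatenate(diffs)
    iqr = np.subtract(*np.percentile(d, [75, 25]))
    return float(iqr / 1.349 / np.sqrt(2.0))


def moving_average_smooth(values: np.ndarray, starts: np.ndarray, chroms: np.ndarray,
                          window_bp: int) -> np.ndarray:
    """Optional centred moving-average smoothing within chromosomes (reporting aid)."""
    out = values.astype(float).copy()
    half = window_bp / 2.0
    for c in pd.unique(chroms):
        mask = chroms == c
        pos = starts[mask].astype(float)
        v = values[mask]
        sm = np.empty_like(v)
        for i, p in enumerate(pos):
            w = np.abs(pos - p) <= half
            sm[i] = v[w].mean()
        out[mask] = sm
    return out


# ---------------------------------------------------------------------------
# ADM-2-style interval scan
# ---------------------------------------------------------------------------

def _best_interval(x: np.ndarray, sigma: float) -> tuple[int, int, float, float]:
    """Maximum-score contiguous interval of ``x``: score = sqrt(n)|mean|/sigma.

    Vectorized over all O(n^2) intervals; ties resolved to the smallest
    (start, end).  Returns (start, end_inclusive, mean, score).
    """
    n = x.size
    cs = np.concatenate(([0.0], np.cumsum(x)))
    best = (-1.0, 0, 0, 0.0)  # score, i, j, mean
    lengths = np.arange(1, n + 1, dtype=float)
    for i in range(n):
        sums = cs[i + 1:] - cs[i]
        means = sums / lengths[: n - i]
        scores = np.sqrt(lengths[: n - i]) * np.abs(means) / sigma
        j_rel = int(np.argmax(scores))
        sc = float(scores[j_rel])
        if sc > best[0] + 1e-15:
            best = (sc, i, i + j_rel, float(means[j_rel]))
    _, i, j, mean = best
    return i, j, mean, best[0]


def adm2_scan(
    values: np.ndarray,
    chroms: np.ndarray,
    sigma: float,
    threshold: float = ADM_THRESHOLD,
) -> pd.DataFrame:
    """Greedy iterative aberration scan over each chromosome.

    Repeatedly accepts the maximal-score contiguous probe interval
    (score >= ``threshold``), masks its probes, and rescans the remaining
    contiguous runs until nothing reaches the threshold.  Accepted
    intervals are disjoint.  The reported score is signed by the interval
    mean (positive = amplification, negative = deletion).

    Returns a DataFrame with probe-index extents ``i0``/``i1`` (global,
    inclusive) plus chrom, n_probes, mean_log2 and score.
    """
    values = np.asarray(values, dtype=float)
    chroms = np.asarray(chroms)
    if sigma <= 0 or not np.isfinite(sigma):
        raise DegenerateProfileError("profile noise sigma is zero; scoring undefined")

    records = []
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        runs = [(0, idx.size - 1)]  # inclusive local ranges still unmasked
        while runs:
            best = None
            for r, (a, b) in enumerate(runs):
                i, j, mean, score = _best_interval(values[idx[a : b + 1]], sigma)
                if best is None or score > best[0] + 1e-15:
                    best = (score, r, a + i, a + j, mean)
            score, r, i, j, mean = best
            if score < threshold:
                break
            records.append(
                {
                    "chrom": c,
                    "i0": int(idx[i]),
                    "i1": int(idx[j]),
                    "n_probes": j - i + 1,
                    "mean_log2": mean,
                    "score": score if mean >= 0 else -score,
                }
            )
            a, b = runs.pop(r)
            if i > a:
                runs.append((a, i - 1))
            if j < b:
                runs.append((j + 1, b))
    return pd.DataFrame(
        records, columns=["chrom", "i0", "i1", "n_probes", "mean_log2", "score"]
    )


def filter_calls(
    intervals: pd.DataFrame,
    panel: pd.DataFrame,
    sample_id: str,
    min_abs_log2: float = MIN_ABS_LOG2,
    min_probes: int = MIN_PROBES,
) -> pd.DataFrame:
    """Apply the aberration filter and materialize genomic CNV calls.

    Keeps intervals with |mean log2| >= ``min_abs_log2`` over at least
    ``min_probes`` probes (both inclusive); direction is gain for a
    positive mean, loss otherwise.  Coordinates are the probe extent,
    0-based half-open.
    """
    if intervals.empty:
        return _empty_calls()
    keep = (intervals["mean_log2"].abs() >= min_abs_log2) & (
        intervals["n_probes"] >= min_probes
    )
    kept = intervals[keep]
    if kept.empty:
        return _empty_calls()
    starts = panel["start"].to_numpy()
    ends = panel["end"].to_numpy()
    out = pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": kept["chrom"].to_numpy(),
            "start": starts[kept["i0"].to_numpy()],
            "end": ends[kept["i1"].to_numpy()],
            "direction": np.where(kept["mean_log2"] > 0, "gain", "loss"),
            "n_probes": kept["n_probes"].to_numpy(),
            "mean_log2": kept["mean_log2"].to_numpy(),
            "score": kept["score"].to_numpy(),
        }
    )
    out["_ck"] = out["chrom"].map(chrom_sort_key)
    out = out.sort_values(["_ck", "start"], kind="mergesort").drop(columns="_ck")
    return out.reset_index(drop=True)


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "sample_id", "chrom", "start", "end",
            "direction", "n_probes", "mean_log2", "score",
        ]
    )


def call_sample(
    values: np.ndarray,
    panel: pd.DataFrame,
    sample_id: str,
    threshold: float = ADM_THRESHOLD,
    min_abs_log2: float = MIN_ABS_LOG2,
    min_probes: int = MIN_PROBES,
    do_gc_correct: bool = True,
    smooth_window_bp: int | None = None,
) -> pd.DataFrame:
    """Normalize one sample and call its CNVs (GC -> centralize -> scan -> filter)."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(f"profile {sample_id} contains non-finite values")
    if do_gc_correct:
        values = gc_correct(values, panel["gc_fraction"].to_numpy())
    values, _ = centralize(values)
    chroms = panel["chrom"].to_numpy()
    if smooth_window_bp:
        values = moving_average_smooth(values, panel["start"].to_numpy(), chroms,
                                       smooth_window_bp)
    sigma = estimate_dlrs(values, chroms)
    if sigma <= 0:
        raise DegenerateProfileError(
            f"profile {sample_id} is noiseless-constant; cannot score aberrations"
        )
    intervals = adm2_scan(values, chroms, sigma, threshold=threshold)
    return filter_calls(intervals, panel, sample_id, min_abs_log2, min_probes)


def call_cnvs(
    profiles: pd.DataFrame,
    panel: pd.DataFrame,
    threshold: float = ADM_THRESHOLD,
    min_abs_log2: float = MIN_ABS_LOG2,
    min_probes: int = MIN_PROBES,
    do_gc_correct: bool = True,
    smooth_window_bp: int | None = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Call CNVs for every sample of a probes x samples log2-ratio matrix."""
    if list(profiles.index) != list(panel["probe_id"]):
        profiles = profiles.reindex(panel["probe_id"])
        if profiles.isna().any().any():
            raise ValueError("profile matrix does not cover the panel probes")

    def _one(s):
        return call_sample(
            profiles[s].to_numpy(), panel, s,
            threshold=threshold, min_abs_log2=min_abs_log2, min_probes=min_probes,
            do_gc_correct=do_gc_correct, smooth_window_bp=smooth_window_bp,
        )

    if n_jobs > 1:
        from joblib import Parallel, delayed

        pieces = Parallel(n_jobs=n_jobs)(delayed(_one)(s) for s in profiles.columns)
    else:
        pieces = [_one(s) for s in profiles.columns]
    pieces = [p for p in pieces if not p.empty]
    if not pieces:
        return _empty_calls()
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def write_seg(calls: pd.DataFrame, path) -> None:
    """SEG file (1-based inclusive coordinates, seg.mean = interval mean log2)."""
    seg = pd.DataFrame(
        {
            "ID": calls["sample_id"],
            "chrom": calls["chrom"],
            "loc.start": calls["start"] + 1,
            "loc.end": calls["end"],
            "num.mark": calls["n_probes"],
            "seg.mean": calls["mean_log2"].round(4),
        }
    )
    seg.to_csv(path, sep="\t", index=False)


def write_bed(calls: pd.DataFrame, path) -> None:
    """BED6: name = direction, score = |ADM score| capped at 1000."""
    bed = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["start"],
            "end": calls["end"],
            "name": calls["direction"],
            "score": calls["score"].abs().clip(upper=1000).round(2),
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
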