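import numpy as np
import pandas as pd
import pytest

import neurocnv as ncv
from neurocnv.segmentation import (
    DegenerateProfileError,
    adm2_scan,
    centralize,
    estimate_dlrs,
    filter_calls,
    gc_correct,
)


def brute_force_best_interval(x, sigma):
    """Independent O(n^2) oracle: exhaustively score every contiguous interval."""
    best = (-1.0, None, None, None)
    n = len(x)
    for i in range(n):
        total = 0.0
        for j in range(i, n):
            total += x[j]
            mean = total / (j - i + 1)
            score = np.sqrt(j - i + 1) * abs(mean) / sigma
            if score > best[0] + 1e-12:
                best = (score, i, j, mean)
    return best


class TestGcCorrect:
    def test_no_gc_dependence_recenters_only(self):
        rng = np.random.default_rng(0)
        gc = rng.uniform(0.3, 0.7, 500)
        v = rng.normal(0.2, 0.1, 500)
        out = gc_correct(v, gc)
        # flat GC trend: output is the input minus (roughly) its median,
        # up to per-bin median estimation noise (~sigma/sqrt(bin size))
        assert np.corrcoef(out, v - np.median(v))[0, 1] > 0.95
        assert np.std(out - (v - np.median(v))) < 3 * 0.1 / np.sqrt(500 / 20)

    def test_planted_linear_gc_term_removed(self):
        rng = np.random.default_rng(1)
        gc = rng.uniform(0.3, 0.7, 2000)
        v = 1.0 * gc  # pure GC artifact, slope 1 per gc unit, no noise
        out = gc_correct(v, gc)
        assert abs(np.corrcoef(out, gc)[0, 1]) < 0.05

    def test_correction_never_increases_gc_correlation(self):
        rng = np.random.default_rng(2)
        gc = rng.uniform(0.3, 0.7, 1000)
        v = 0.5 * gc + rng.normal(0, 0.15, 1000)
        out = gc_correct(v, gc)
        assert abs(np.corrcoef(out, gc)[0, 1]) <= abs(np.corrcoef(v, gc)[0, 1])

    def test_constant_profile_stays_constant(self):
        gc = np.linspace(0.3, 0.7, 100)
        out = gc_correct(np.full(100, 0.4), gc)
        assert np.allclose(out, 0.0)

    def test_missing_gc_rejected(self):
        with pytest.raises(ValueError, match="GC"):
            gc_correct(np.zeros(10), np.full(10, np.nan))


class TestCentralize:
    def test_recovers_gaussian_center(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0.3, 0.05, 5000)
        out, shift = centralize(v)
        assert shift == pytest.approx(0.3, abs=0.02)
        assert abs(np.median(out)) < 0.02

    def test_already_centered_profile_unmoved(self):
        rng = np.random.default_rng(4)
        v = rng.normal(0.0, 0.1, 2000)
        _, shift = centralize(v)
        assert abs(shift) < 0.02

    def test_bimodal_mode_wins_over_mean(self):
        # 70% diploid at 0, 30% duplicated at +0.58: the dominant density
        # peak, not the mean (~0.17), must set the shift.
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(0, 0.05, 700), rng.normal(0.58, 0.05, 300)])
        _, shift = centralize(v)
        assert abs(shift) < 0.05

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match="30"):
            centralize(np.zeros(10))


class TestDlrs:
    def test_iid_noise_scale_recovered(self):
        rng = np.random.default_rng(6)
        v = rng.normal(0, 0.2, 10_000)
        sigma = estimate_dlrs(v, np.repeat("chr1", 10_000))
        assert sigma == pytest.approx(0.2, rel=0.1)

    def test_constant_profile_gives_zero(self):
        assert estimate_dlrs(np.ones(100), np.repeat("chr1", 100)) == 0.0

    def test_single_step_barely_inflates_sigma(self):
        rng = np.random.default_rng(7)
        v = rng.normal(0, 0.2, 2000)
        stepped = v.copy()
        stepped[1000:] += 2.0  # one CNV edge
        chroms = np.repeat("chr1", 2000)
        assert estimate_dlrs(stepped, chroms) == pytest.approx(
            estimate_dlrs(v, chroms), rel=0.02
        )

    def test_chromosome_boundaries_not_crossed(self):
        # two flat chromosomes at different levels: no within-chrom change
        v = np.concatenate([np.zeros(50), np.ones(50)])
        chroms = np.repeat(["chr1", "chr2"], 50)
        assert estimate_dlrs(v, chroms) == 0.0


class TestAdm2Scan:
    def test_flat_profile_yields_nothing(self):
        out = adm2_scan(np.zeros(100), np.repeat("chr1", 100), sigma=0.2)
        assert out.empty

    def test_closed_form_score_on_clean_block(self):
        v = np.zeros(100)
        v[40:50] = 1.0
        out = adm2_scan(v, np.repeat("chr1", 100), sigma=0.2)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["i0"], row["i1"]) == (40, 49)
        assert row["score"] == pytest.approx(np.sqrt(10) * 1.0 / 0.2, rel=1e-12)
        assert row["mean_log2"] == pytest.approx(1.0)

    def test_negative_mean_gives_negative_score(self):
        v = np.zeros(60)
        v[10:20] = -1.0
        out = adm2_scan(v, np.repeat("chr1", 60), sigma=0.2)
        assert out.iloc[0]["score"] < 0

    def test_accepted_intervals_disjoint(self):
        rng = np.random.default_rng(8)
        v = rng.normal(0, 0.15, 300)
        v[30:60] += 1.0
        v[100:120] -= 1.0
        v[200:230] += 0.8
        out = adm2_scan(v, np.repeat("chr1", 300), sigma=0.15)
        taken = np.zeros(300, dtype=bool)
        for r in out.itertuples(index=False):
            span = slice(r.i0, r.i1 + 1)
            assert not taken[span].any()
            taken[span] = True

    def test_zero_sigma_raises_degenerate_error(self):
        with pytest.raises(DegenerateProfileError):
            adm2_scan(np.zeros(50), np.repeat("chr1", 50), sigma=0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_first_accepted_interval_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 0.15, 200)
        a, b = sorted(rng.integers(0, 200, 2))
        v[a : b + 1] += rng.choice([-1.0, 0.8])
        sigma = estimate_dlrs(v, np.repeat("chr1", 200))
        score, i, j, _ = brute_force_best_interval(v, sigma)
        out = adm2_scan(v, np.repeat("chr1", 200), sigma, threshold=0.0)
        first = out.iloc[0]
        assert (first["i0"], first["i1"]) == (i, j)
        assert abs(first["score"]) == pytest.approx(score, rel=1e-9)


class TestFilterCalls:
    def _panel(self, n=20):
        return pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(n)],
                "chrom": "chr1",
                "start": np.arange(n) * 100,
                "end": np.arange(n) * 100 + 60,
                "gene": "G",
                "gc_fraction": 0.5,
            }
        )

    def _intervals(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "i0", "i1", "n_probes",
                                           "mean_log2", "score"])

    def test_probe_minimum_is_inclusive_at_three(self):
        panel = self._panel()
        iv = self._intervals([("chr1", 0, 1, 2, 1.0, 9.0), ("chr1", 5, 7, 3, 1.0, 9.0)])
        out = filter_calls(iv, panel, "s1")
        assert len(out) == 1 and out.iloc[0]["n_probes"] == 3

    def test_amplitude_boundary_inclusive_at_half(self):
        panel = self._panel()
        iv = self._intervals(
            [("chr1", 0, 4, 5, 0.49, 9.0), ("chr1", 6, 10, 5, 0.50, 9.0)]
        )
        out = filter_calls(iv, panel, "s1")
        assert len(out) == 1 and out.iloc[0]["mean_log2"] == 0.50

    def test_direction_follows_sign(self):
        panel = self._panel()
        iv = self._intervals([("chr1", 0, 3, 4, -0.8, -9.0)])
        out = filter_calls(iv, panel, "s1")
        assert out.iloc[0]["direction"] == "loss"
        assert out.iloc[0]["start"] == 0 and out.iloc[0]["end"] == 360


class TestEndToEnd:
    def test_noiseless_roundtrip_recovers_exact_probe_extent(self, small_panel):
        design = ncv.CohortDesign(seed=11, noise_sigma=0.0)
        gene = small_panel[small_panel["gene"] == "GENE0005"]
        spec = [ncv.CnvSpec(gene["chrom"].iloc[0], int(gene["start"].min()),
                            int(gene["end"].max()), "loss", "group1", 3 / 17)]
        profiles, _, truth = ncv.generate_cohort(small_panel, design, spec)
        cnv = truth.planted_cnvs[0]
        # noiseless non-carrier profiles are degenerate by construction
        for carrier in cnv.carriers:
            with pytest.raises(DegenerateProfileError):
                ncv.call_sample(profiles[list(profiles)[0]].to_numpy(),
                                small_panel, "flat")
            calls = _call_with_floor_noise(profiles[carrier], small_panel, carrier)
            match = calls[(calls["chrom"] == cnv.chrom)
                          & (calls["direction"] == "loss")]
            assert len(match) == 1
            assert match.iloc[0]["start"] == gene["start"].min()
            assert match.iloc[0]["end"] == gene["end"].max()

    def test_sign_coherence_of_calls(self, study_calls):
        gains = study_calls[study_calls["direction"] == "gain"]
        losses = study_calls[study_calls["direction"] == "loss"]
        assert (gains["mean_log2"] > 0).all() and (gains["score"] > 0).all()
        assert (losses["mean_log2"] < 0).all() and (losses["score"] < 0).all()
        assert (study_calls["mean_log2"].abs() >= 0.5).all()
        assert (study_calls["n_probes"] >= 3).all()

    def test_per_sample_calls_disjoint(self, study_calls):
        for (_, chrom), sub in study_calls.groupby(["sample_id", "chrom"]):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()


def _call_with_floor_noise(profile, panel, sample_id):
    """Add a hair of noise so DLRS is nonzero but calls are unaffected."""
    rng = np.random.default_rng(0)
    v = profile.to_numpy() + rng.normal(0, 1e-6, len(profile))
    return ncv.call_sample(v, panel, sample_id, do_gc_correct=False)
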