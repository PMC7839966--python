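"""Sliding-window profile, per-class criteria, and their invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cetriplet.preprocess import ExpressionMatrix, ValidationError
from cetriplet.triplets import LNCRNA_CENTERED, MIRNA_CENTERED, MRNA_CENTERED
from cetriplet.windows import (
    CoreConfig,
    WindowProfile,
    detect_triplets,
    evaluate_candidate,
    sliding_profile,
    sliding_window_sccs,
    window_length,
    window_profile,
)
from cetriplet.synthetic import SyntheticConfig, generate_dataset


class TestWindowLength:
    def test_reference_cohort(self):
        assert window_length(376, 0.25) == 94

    def test_exact_quarter(self):
        assert window_length(100, 0.25) == 25

    def test_below_minimum_raises(self):
        with pytest.raises(ValidationError, match="window_fraction"):
            window_length(10, 0.25)  # floor gives 2 < 3

    def test_bad_fraction(self):
        with pytest.raises(ValidationError):
            window_length(100, 0.0)


class TestSlidingWindows:
    def test_window_count_and_oracle(self, rng):
        n, w = 200, 50
        x = rng.lognormal(0, 1, n)
        y = rng.lognormal(0, 1, n)
        starts, sccs = sliding_window_sccs(x, y, w)
        assert len(sccs) == 151  # floor((200-50)/1)+1
        for s, got in zip(starts, sccs):
            expected = spearmanr(x[s : s + w], y[s : s + w]).statistic
            assert got == pytest.approx(expected, abs=1e-12)

    def test_step_respects_window_count(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        starts, sccs = sliding_window_sccs(x, y, 30, step=7)
        assert len(sccs) == (100 - 30) // 7 + 1
        assert starts[1] - starts[0] == 7

    def test_single_window_degenerate(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        prof = window_profile(rng.normal(size=40), x, y,
                              [f"s{i:02d}" for i in range(40)], width=40)
        assert prof.n_windows == 1
        assert prof.delta_cor == pytest.approx(0.0)

    def test_constant_window_excluded_not_zeroed(self):
        # y constant in the first window only
        n, w = 12, 5
        x = np.arange(n, dtype=float)
        y = np.r_[np.ones(w), np.arange(1.0, n - w + 1)]
        centered = np.arange(n, dtype=float)
        prof = window_profile(centered, x, y, [f"s{i:02d}" for i in range(n)], w)
        assert np.isnan(prof.window_sccs[0])
        assert prof.n_excluded >= 1
        assert prof.evaluable
        assert not np.isnan(prof.max_scc)

    def test_all_windows_undefined_is_unevaluable(self):
        n, w = 10, 4
        y = np.ones(n)
        prof = window_profile(np.arange(n, dtype=float), np.arange(n, dtype=float),
                              y, [f"s{i:02d}" for i in range(n)], w)
        assert not prof.evaluable
        res = evaluate_candidate(prof, MIRNA_CENTERED)
        assert res.status == "unevaluable"


class TestProfileInvariances:
    def test_invariant_under_monotone_transform_of_centered(self, rng):
        n, w = 80, 20
        ids = [f"s{i:03d}" for i in range(n)]
        c = rng.lognormal(0, 1, n)
        x, y = rng.lognormal(0, 1, n), rng.lognormal(0, 1, n)
        p1 = window_profile(c, x, y, ids, w)
        p2 = window_profile(np.log(c), x, y, ids, w)
        np.testing.assert_allclose(p1.window_sccs, p2.window_sccs, atol=1e-15)

    def test_reversed_sort_reverses_profile(self, rng):
        n, w = 60, 15
        ids = [f"s{i:03d}" for i in range(n)]
        c = rng.normal(size=n)  # continuous: unique order
        x, y = rng.normal(size=n), rng.normal(size=n)
        p1 = window_profile(c, x, y, ids, w)
        p2 = window_profile(-c, x, y, ids, w)
        np.testing.assert_allclose(p1.window_sccs, p2.window_sccs[::-1], atol=1e-12)
        assert p1.delta_cor == pytest.approx(p2.delta_cor, abs=1e-12)

    def test_bitwise_reproducible(self, rng):
        n, w = 70, 20
        ids = [f"s{i:03d}" for i in range(n)]
        c, x, y = rng.normal(size=n), rng.normal(size=n), rng.normal(size=n)
        p1 = window_profile(c, x, y, ids, w)
        p2 = window_profile(c, x, y, ids, w)
        assert (p1.window_sccs == p2.window_sccs).all()

    def test_tie_break_is_deterministic(self):
        n, w = 12, 4
        c = np.zeros(n)  # fully tied: order must fall back to sample ids
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=n), rng.normal(size=n)
        ids = [f"s{i:02d}" for i in range(n)]
        p1 = window_profile(c, x, y, ids, w)
        p2 = window_profile(c, x, y, list(ids), w)
        assert (p1.window_sccs == p2.window_sccs).all()


def make_profile(max_scc, min_scc):
    sccs = np.array([min_scc, (min_scc + max_scc) / 2, max_scc])
    return WindowProfile(centered_rna="x", window_starts=np.arange(3),
                         window_sccs=sccs, n_excluded=0)


class TestEvaluateCandidate:
    @pytest.mark.parametrize(
        "cls,mx,mn,expect_pass",
        [
            (MIRNA_CENTERED, 0.60, 0.20, True),   # 0.60>0.520, Δ=0.40>0.300
            (MIRNA_CENTERED, 0.60, 0.45, False),  # Δ=0.15 too small
            (MIRNA_CENTERED, 0.50, 0.10, False),  # max below cut
            (LNCRNA_CENTERED, 0.30, -0.40, True),   # min<-0.311, Δ=0.70
            (LNCRNA_CENTERED, 0.30, -0.20, False),  # min above -0.311
            (MRNA_CENTERED, 0.20, -0.31, True),     # min<-0.305, Δ=0.51
            (MRNA_CENTERED, 0.20, -0.29, False),    # min above -0.305
        ],
    )
    def test_per_class_criteria(self, cls, mx, mn, expect_pass):
        res = evaluate_candidate(make_profile(mx, mn), cls)
        assert res.passed is expect_pass
        if not expect_pass:
            assert res.failed_criteria

    def test_asymmetric_negative_cuts(self):
        # -0.308 sits between the two cuts: passes mRNA-centered (-0.305)
        # but fails lncRNA-centered (-0.311)
        prof = make_profile(0.30, -0.308)
        assert evaluate_candidate(prof, MRNA_CENTERED).passed
        assert not evaluate_candidate(prof, LNCRNA_CENTERED).passed


def test_planted_profile_peaks_in_interior(small_dataset):
    """The window-SCC curve of a planted triplet has an interior maximum:
    coupling saturates at both miRNA extremes."""
    matrix, truth = small_dataset.matrix, small_dataset.truth.triplets
    cfg = CoreConfig()
    hits = 0
    for _, t in truth.iterrows():
        cand = {"lncrna": t.lncrna, "mirna": t.mirna, "mrna": t.mrna,
                "triplet_class": MIRNA_CENTERED}
        prof = sliding_profile(matrix, cand, cfg)
        imax = int(np.nanargmax(prof.window_sccs))
        interior = 0 < imax < prof.n_windows - 1
        exceeds_edges = (prof.max_scc > prof.window_sccs[0]
                         and prof.max_scc > prof.window_sccs[-1])
        hits += interior and exceeds_edges
    assert hits >= len(truth) - 1


def test_detect_triplets_false_positive_rate_low():
    """Independent RNAs pass the per-class criteria in < 5% of cases."""
    cfg = SyntheticConfig(n_samples=376, n_planted=170, coupling_strength=0.0,
                          shared_factor_sd=0.0, n_null_genes=0, n_null_mirnas=0,
                          seed=17)
    ds = generate_dataset(cfg)
    rows = []
    for cls in (LNCRNA_CENTERED, MIRNA_CENTERED, MRNA_CENTERED):
        for _, t in ds.truth.triplets.iterrows():
            rows.append({"lncrna": t.lncrna, "mirna": t.mirna, "mrna": t.mrna,
                         "triplet_class": cls})
    cands = pd.DataFrame(rows)  # 510 independent candidate evaluations
    detected = detect_triplets(ds.matrix, cands, CoreConfig())
    rate = (detected.status == "pass").mean()
    assert rate < 0.05
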