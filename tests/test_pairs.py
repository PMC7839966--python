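"""Spearman scoring, diagnostics, pool loading, and quantile screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cetriplet.pairs import (
    LNCRNA_MRNA,
    MIRNA_LNCRNA,
    MIRNA_MRNA,
    UndefinedCorrelationError,
    correlation_diagnostics,
    derive_typed_pairs,
    load_interaction_pool,
    retention_count,
    score_pairs,
    screen_pairs,
    spearman,
)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_perfect_antitone(self):
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_tied_ranks_match_hand_computation(self):
        # ranks of (1,2,2,4) with tie averaging: (1, 2.5, 2.5, 4);
        # ranks of (3,1,5,2): (3, 1, 4, 2); Pearson of those = -1.5/sqrt(22.5)
        expected = -1.5 / math.sqrt(22.5)
        assert spearman([1, 2, 2, 4], [3, 1, 5, 2]) == pytest.approx(
            expected, abs=1e-15
        )

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(0, 1, 20)
        y = rng.lognormal(0, 1, 20)
        base = spearman(x, y)
        assert spearman(np.log(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman(x, np.square(y)) == pytest.approx(base, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)  # continuous: no ties a.s.
        assert spearman(x, y) == pytest.approx(spearman(y, x), abs=1e-12)
        assert spearman(x, -y) == pytest.approx(-spearman(x, y), abs=1e-12)


class TestDiagnostics:
    def test_monotone_convex_relation(self, rng):
        # power law: linear on the doubly log scale, convex on the raw scale
        x = rng.lognormal(1.0, 0.8, 50)
        y = x**3
        d = correlation_diagnostics(x, y, pseudocount=1e-9)
        assert d["scc"] == pytest.approx(1.0)
        assert d["pcc_log"] > 0.999
        assert d["pcc"] < 1.0 - 1e-6

    def test_joint_linearity(self):
        x = np.arange(1.0, 21.0)
        d = correlation_diagnostics(x, 3 * x + 2)
        assert d["pcc"] == pytest.approx(1.0)

    def test_rank_beats_linear_on_reciprocal_noise(self):
        # lognormal x with y ~ c/x * noise: |PCC| < |SCC| on average,
        # the regime created by the RPM-vs-FPKM magnitude gap
        rng = np.random.default_rng(42)
        wins = 0
        for _ in range(100):
            x = rng.lognormal(3, 1.2, 100)
            y = 50.0 / x * rng.lognormal(0, 0.4, 100)
            d = correlation_diagnostics(x, y)
            wins += abs(d["pcc"]) < abs(d["scc"])
        assert wins > 80


class TestInteractionPool:
    def test_union_of_sources(self, tmp_path):
        f1 = tmp_path / "a.tsv"
        f1.write_text("mirna\ttarget\tsource\nm1\tg1\ttoolA\nm1\tg2\ttoolA\n")
        f2 = tmp_path / "b.tsv"
        f2.write_text("mirna\ttarget\tsource\nm1\tg1\ttoolB\n")
        pool = load_interaction_pool([f1, f2])
        assert len(pool) == 2
        row = pool[(pool.mirna == "m1") & (pool.target == "g1")].iloc[0]
        assert row.sources == "toolA;toolB"

    def test_empty_file_list(self):
        assert load_interaction_pool([]).empty

    def test_overlapping_files_set_union(self, tmp_path):
        pairs = [("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m2", "g2"),
                 ("m3", "g3"), ("m3", "g4"), ("m4", "g1")]
        f1 = tmp_path / "a.tsv"
        f1.write_text("mirna\ttarget\tsource\n" + "".join(
            f"{m}\t{g}\tA\n" for m, g in pairs[:5]))
        f2 = tmp_path / "b.tsv"
        f2.write_text("mirna\ttarget\tsource\n" + "".join(
            f"{m}\t{g}\tB\n" for m, g in pairs[2:]))  # 3 overlaps
        pool = load_interaction_pool([f1, f2])
        assert len(pool) == 7

    def test_unknown_ids_dropped(self, tmp_path):
        f = tmp_path / "a.tsv"
        f.write_text("mirna\ttarget\tsource\nm1\tg1\tA\nmx\tg1\tA\n")
        pool = load_interaction_pool([f], known_ids={"m1", "g1"})
        assert len(pool) == 1


def test_derive_typed_pairs_shares_mirna(tiny_matrix):
    pool = pd.DataFrame(
        {
            "mirna": ["mir-a", "mir-a", "mir-b"],
            "target": ["LNC-A", "GENE-A", "GENE-B"],
            "sources": ["x", "x", "x"],
        }
    )
    typed = derive_typed_pairs(pool, tiny_matrix.rna_class)
    assert len(typed[MIRNA_LNCRNA]) == 1
    assert len(typed[MIRNA_MRNA]) == 2
    # only LNC-A/GENE-A share mir-a; GENE-B shares no miRNA with a lncRNA
    assert typed[LNCRNA_MRNA][["rna_a", "rna_b"]].values.tolist() == [
        ["LNC-A", "GENE-A"]
    ]


def test_score_pairs_matches_scalar_spearman(tiny_matrix):
    pairs = pd.DataFrame(
        {"rna_a": ["mir-a", "mir-b"], "rna_b": ["LNC-A", "GENE-B"],
         "sources": ["x", "x"]}
    )
    scored = score_pairs(tiny_matrix, pairs)
    for _, r in scored.iterrows():
        expected = spearman(tiny_matrix.row(r.rna_a), tiny_matrix.row(r.rna_b))
        assert r.scc == pytest.approx(expected, abs=1e-12)


def make_scored(sccs):
    n = len(sccs)
    return pd.DataFrame(
        {
            "rna_a": [f"a{i:04d}" for i in range(n)],
            "rna_b": [f"b{i:04d}" for i in range(n)],
            "sources": "x",
            "scc": sccs,
        }
    )


class TestScreenPairs:
    def test_single_most_negative_retained(self, rng):
        scored = make_scored(rng.uniform(-1, 1, 1000))
        res = screen_pairs(scored, MIRNA_MRNA, retain_fraction=0.001)
        assert len(res.retained) == 1
        assert res.retained.scc.iloc[0] == pytest.approx(scored.scc.min())

    def test_floor_rule_at_reference_pool_size(self):
        # 0.1% of 2,608,237 pairs -> 2,608 retained by floor semantics
        assert retention_count(2_608_237, 0.001) == 2608

    def test_brute_force_sort_oracle(self, rng):
        sccs = rng.uniform(-1, 1, 500)
        res = screen_pairs(make_scored(sccs), LNCRNA_MRNA, retain_fraction=0.01)
        expected = sorted(sccs)[-5:]  # positive tail, 5 most extreme
        assert sorted(res.retained.scc) == pytest.approx(sorted(expected))
        assert res.threshold == pytest.approx(min(expected))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(1, 400), st.floats(0.001, 0.999))
    def test_retained_count_is_floor(self, n, frac):
        rng = np.random.default_rng(n)
        res = screen_pairs(make_scored(rng.uniform(-1, 1, n)), MIRNA_MRNA,
                           retain_fraction=frac)
        assert len(res.retained) == math.floor(frac * n)

    def test_stability(self, rng):
        scored = make_scored(rng.uniform(-1, 1, 300))
        r1 = screen_pairs(scored, MIRNA_MRNA, retain_fraction=0.05)
        r2 = screen_pairs(scored.sample(frac=1, random_state=0), MIRNA_MRNA,
                          retain_fraction=0.05)
        pd.testing.assert_frame_equal(r1.retained, r2.retained)

    def test_fixed_cutoff_mode(self, rng):
        scored = make_scored(rng.uniform(-1, 1, 200))
        res = screen_pairs(scored, MIRNA_MRNA, fixed_cutoff=-0.311)
        assert (res.retained.scc < -0.311).all()
        assert len(res.retained) == int((scored.scc < -0.311).sum())
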