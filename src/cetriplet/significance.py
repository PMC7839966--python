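"""Permutation null for ΔCor and Bonferroni correction.

The null asks how large a correlation difference arises when the two sample
subsets being compared are *not* conditioned on the centered RNA: for each
repetition two disjoint subsets of ``subset_size`` samples are drawn
uniformly at random, the non-centered pair's SCC is computed on each, and
the absolute difference of the two SCCs is the null ΔCor.  The p-value is
the fraction of null ΔCor values exceeding the observed ΔCor (the range of
the sliding-window profile).  p-values are Bonferroni-corrected for the
total number of candidate triplets.

Note that the null statistic (|difference of two subset SCCs|) and the
observed statistic (range over many overlapping windows) are not drawn from
the same distribution on exchangeable data, so the p-values are screening
scores rather than calibrated tail probabilities; see the methods note.  An
optional ``null_mode="profile"`` draws the null by re-sorting the samples
with a random permutation and recomputing the full window range, which is
exchangeable with the observed statistic and yields calibrated p-values.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import rowwise_rank_corr
from .preprocess import ExpressionMatrix, ValidationError
from .windows import CLASS_ROLES, CoreConfig, sliding_window_sccs, sort_order, window_length

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """The permutation scheme is infeasible for the given cohort."""


@dataclass(frozen=True)
class PermutationConfig:
    """Parameters of the permutation test.

    ``subset_size`` defaults to the sliding-window width so null and
    observed SCCs share their sample size.  ``smoothed`` switches the
    estimator from k/n to (k+1)/(n+1) for users who want to avoid p = 0.
    ``null_mode`` selects the null statistic: ``"two-subset"`` (default,
    the difference of two disjoint random subsets) or ``"profile"``
    (window range under a random re-sort).
    """

    n_permutations: int = 100
    subset_size: int | None = None
    seed: int = 0
    alpha_adjusted: float = 0.01
    smoothed: bool = False
    null_mode: str = "two-subset"
    max_redraws: int = 20

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not 0.0 < self.alpha_adjusted <= 1.0:
            raise ValidationError("alpha_adjusted must lie in (0, 1]")
        if self.null_mode not in ("two-subset", "profile"):
            raise ValidationError(f"unknown null_mode: {self.null_mode}")


def triplet_rng(config: PermutationConfig, triplet_key: str) -> np.random.Generator:
    """Deterministic per-triplet generator derived from the config seed.

    The per-triplet offset is a CRC-32 of the triplet's identity, so the
    null draws do not depend on the order in which candidates are processed.
    """
    offset = zlib.crc32(triplet_key.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), offset]))


def _null_two_subset(
    x: np.ndarray,
    y: np.ndarray,
    subset_size: int,
    n_draws: int,
    rng: np.random.Generator,
    max_redraws: int,
) -> np.ndarray:
    """n_draws null ΔCor values: |SCC(subset1) - SCC(subset2)|, disjoint subsets."""
    n = x.size
    need = n_draws
    out: list[np.ndarray] = []
    for _ in range(max_redraws):
        idx = np.argsort(rng.random((need, n)), axis=1)[:, : 2 * subset_size]
        a, b = idx[:, :subset_size], idx[:, subset_size:]
        s1 = rowwise_rank_corr(x[a], y[a])
        s2 = rowwise_rank_corr(x[b], y[b])
        delta = np.abs(s1 - s2)
        ok = ~np.isnan(delta)
        out.append(delta[ok])
        need -= int(ok.sum())
        if need == 0:
            return np.concatenate(out)
    raise ConfigurationError(
        "could not draw enough permutations with a defined SCC "
        f"({need} missing after {max_redraws} redraw rounds)"
    )


def _null_profile_range(
    x: np.ndarray,
    y: np.ndarray,
    width: int,
    step: int,
    n_draws: int,
    rng: np.random.Generator,
    max_redraws: int,
) -> np.ndarray:
    """n_draws null ΔCor values: window range under a random sample order."""
    n = x.size
    out: list[float] = []
    attempts = 0
    while len(out) < n_draws:
        if attempts >= max_redraws * n_draws:
            raise ConfigurationError("too many unevaluable null profiles")
        attempts += 1
        order = rng.permutation(n)
        _, sccs = sliding_window_sccs(x[order], y[order], width, step)
        defined = sccs[~np.isnan(sccs)]
        if defined.size == 0:
            continue
        out.append(float(defined.max() - defined.min()))
    return np.asarray(out)


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    observed_delta: float,
    config: PermutationConfig,
    subset_size: int,
    rng: np.random.Generator,
    step: int = 1,
) -> float:
    """Permutation p-value of one observed ΔCor.

    ``x`` and ``y`` are the full-cohort expression vectors of the
    non-centered pair.  Deterministic given ``rng``'s state.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if config.null_mode == "two-subset":
        if 2 * subset_size > n:
            raise ConfigurationError(
                f"two disjoint subsets of {subset_size} need >= {2 * subset_size} "
                f"samples, got {n}"
            )
        null = _null_two_subset(
            x, y, subset_size, config.n_permutations, rng, config.max_redraws
        )
    else:
        null = _null_profile_range(
            x, y, subset_size, step, config.n_permutations, rng, config.max_redraws
        )
    k = int((null > observed_delta).sum())
    if config.smoothed:
        return (k + 1) / (config.n_permutations + 1)
    return k / config.n_permutations


def bonferroni(p_values, n_tests: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * n_tests), elementwise."""
    p = np.asarray(p_values, dtype=float)
    if p.size and n_tests < p.size:
        raise ValidationError("n_tests must be >= the number of p-values")
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * n_tests)


def add_significance(
    matrix: ExpressionMatrix,
    detected: pd.DataFrame,
    core_config: CoreConfig | None = None,
    perm_config: PermutationConfig | None = None,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Permutation-test every passing candidate and Bonferroni-correct.

    ``n_tests`` defaults to the total number of candidate triplets (all
    classes, passing or not) — the correction is for everything that was
    tried, not only for what passed.  Non-passing rows keep NaN p-values
    and ``significant = False``.
    """
    core_config = core_config or CoreConfig()
    perm_config = perm_config or PermutationConfig()
    n_tests = n_tests if n_tests is not None else len(detected)
    width = window_length(matrix.n_samples, core_config.window_fraction)
    subset_size = perm_config.subset_size or width

    p_values = np.full(len(detected), np.nan)
    for i, (_, cand) in enumerate(detected.iterrows()):
        if cand["status"] != "pass":
            continue
        _, a_field, b_field = CLASS_ROLES[cand["triplet_class"]]
        key = "|".join(
            [cand["lncrna"], cand["mirna"], cand["mrna"], cand["triplet_class"]]
        )
        p_values[i] = permutation_pvalue(
            matrix.row(cand[a_field]),
            matrix.row(cand[b_field]),
            float(cand["delta_cor"]),
            perm_config,
            subset_size,
            triplet_rng(perm_config, key),
            step=core_config.step,
        )
    out = detected.copy()
    out["p_value"] = p_values
    with np.errstate(invalid="ignore"):
        out["p_adjusted"] = np.minimum(1.0, p_values * n_tests)
    out["significant"] = out["p_adjusted"] < perm_config.alpha_adjusted
    out.loc[out["p_adjusted"].isna(), "significant"] = False
    out["significant"] = out["significant"].astype(bool)
    n_sig = int(out["significant"].sum())
    log.info(
        "%d of %d passing candidates significant at adjusted p < %g "
        "(Bonferroni over %d tests)",
        n_sig, int((out["status"] == "pass").sum()),
        perm_config.alpha_adjusted, n_tests,
    )
    return out
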