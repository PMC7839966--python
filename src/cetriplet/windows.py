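"""The sliding-window detection core.

For each candidate triplet, samples are sorted in ascending order of the
*centered* RNA's expression (the RNA naming the class).  A window of fixed
width slides over the sorted samples, and within each window the Spearman
coefficient of the two *other* RNAs is computed.  The resulting window-SCC
profile summarises how the strength of the remaining pairwise association
varies along the centered RNA's abundance; its maximum, minimum and range
(ΔCor = max - min) feed the per-class pass criteria:

* lncRNA-centered: min window SCC (miRNA vs mRNA) below the miRNA-mRNA cut;
* mRNA-centered:   min window SCC (miRNA vs lncRNA) below the miRNA-lncRNA cut;
* miRNA-centered:  max window SCC (lncRNA vs mRNA) above the lncRNA-mRNA cut;
* all classes:     ΔCor above ``delta_min``.

Note the deliberate asymmetry of the negative cuts: the lncRNA-centered
class watches the miRNA-mRNA pair and therefore uses the miRNA-mRNA
threshold, and vice versa for the mRNA-centered class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._stats import rowwise_rank_corr
from .preprocess import ExpressionMatrix, ValidationError
from .triplets import (
    LNCRNA_CENTERED,
    MIRNA_CENTERED,
    MRNA_CENTERED,
    TRIPLET_CLASSES,
)

#: per class: (centered RNA field, first non-centered field, second)
CLASS_ROLES = {
    LNCRNA_CENTERED: ("lncrna", "mirna", "mrna"),
    MIRNA_CENTERED: ("mirna", "lncrna", "mrna"),
    MRNA_CENTERED: ("mrna", "mirna", "lncrna"),
}

MIN_WINDOW = 3  # smallest sample count with a defined rank correlation


@dataclass(frozen=True)
class CoreConfig:
    """Detection parameters.

    The window covers a fixed fraction of the cohort (default 25%, i.e. a
    94-sample window on a 376-patient cohort) and advances one sample at a
    time.  The SCC cuts are the realised 0.1%-quantile screening thresholds
    of the reference cohort and can be re-derived from data via the
    screening stage.
    """

    window_fraction: float = 0.25
    step: int = 1
    delta_min: float = 0.300
    neg_cut_mirna_mrna: float = -0.311
    neg_cut_mirna_lncrna: float = -0.305
    pos_cut_lncrna_mrna: float = 0.520

    def __post_init__(self) -> None:
        if not 0.0 < self.window_fraction <= 1.0:
            raise ValidationError("window_fraction must lie in (0, 1]")
        if self.step < 1:
            raise ValidationError("step must be >= 1")
        if self.delta_min < 0:
            raise ValidationError("delta_min must be >= 0")


def window_length(n_samples: int, fraction: float = 0.25) -> int:
    """Window width: floor(fraction * n_samples), at least :data:`MIN_WINDOW`.

    (376, 0.25) gives the 94-sample window of the reference cohort.
    """
    if n_samples < 8:
        raise ValidationError("need at least 8 samples")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must lie in (0, 1]")
    w = math.floor(fraction * n_samples)
    if w < MIN_WINDOW:
        raise ValidationError(
            f"window of {w} samples is below the minimum of {MIN_WINDOW}; "
            "use a larger window_fraction"
        )
    return w


@dataclass
class WindowProfile:
    """The ordered window-SCC curve of one candidate triplet."""

    centered_rna: str
    window_starts: np.ndarray
    window_sccs: np.ndarray  # NaN where the SCC was undefined in a window
    n_excluded: int  # windows excluded for undefined SCC

    max_scc: float = field(init=False)
    min_scc: float = field(init=False)
    delta_cor: float = field(init=False)
    evaluable: bool = field(init=False)

    def __post_init__(self) -> None:
        defined = self.window_sccs[~np.isnan(self.window_sccs)]
        self.evaluable = defined.size > 0
        if self.evaluable:
            self.max_scc = float(defined.max())
            self.min_scc = float(defined.min())
            self.delta_cor = self.max_scc - self.min_scc
        else:
            self.max_scc = self.min_scc = self.delta_cor = float("nan")

    @property
    def n_windows(self) -> int:
        return int(self.window_sccs.size)


def sliding_window_sccs(
    x: np.ndarray, y: np.ndarray, width: int, step: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Window-start offsets and window-wise Spearman coefficients.

    ``x`` and ``y`` must already be in the desired sample order; the number
    of windows is floor((n - width) / step) + 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if width > n:
        raise ValidationError(f"window width {width} exceeds {n} samples")
    xw = sliding_window_view(x, width)[::step]
    yw = sliding_window_view(y, width)[::step]
    starts = np.arange(0, n - width + 1, step)
    return starts, rowwise_rank_corr(xw, yw)


def sort_order(
    centered: np.ndarray, sample_ids: Sequence[str]
) -> np.ndarray:
    """Ascending order of the centered RNA, ties broken by sample id.

    The lexicographic tie-break makes the sort — and hence the whole
    profile — deterministic for tied expression values.
    """
    return np.lexsort((np.asarray(sample_ids, dtype=str), centered))


def window_profile(
    centered: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    sample_ids: Sequence[str],
    width: int,
    step: int = 1,
    centered_rna: str = "",
) -> WindowProfile:
    """Profile of SCC(x, y) along windows of samples sorted by ``centered``."""
    order = sort_order(np.asarray(centered, dtype=float), sample_ids)
    starts, sccs = sliding_window_sccs(
        np.asarray(x, dtype=float)[order], np.asarray(y, dtype=float)[order],
        width, step,
    )
    return WindowProfile(
        centered_rna=centered_rna,
        window_starts=starts,
        window_sccs=sccs,
        n_excluded=int(np.isnan(sccs).sum()),
    )


def sliding_profile(
    matrix: ExpressionMatrix,
    triplet: dict | pd.Series,
    config: CoreConfig | None = None,
) -> WindowProfile:
    """Window-SCC profile for one candidate triplet row.

    ``triplet`` needs the fields ``lncrna``, ``mirna``, ``mrna`` and
    ``triplet_class``; the class decides which RNA sorts the samples and
    which pair is tracked inside the windows.
    """
    config = config or CoreConfig()
    cls = triplet["triplet_class"]
    if cls not in CLASS_ROLES:
        raise ValidationError(f"unknown triplet class: {cls}")
    c_field, a_field, b_field = CLASS_ROLES[cls]
    width = window_length(matrix.n_samples, config.window_fraction)
    return window_profile(
        matrix.row(triplet[c_field]),
        matrix.row(triplet[a_field]),
        matrix.row(triplet[b_field]),
        matrix.sample_ids,
        width,
        config.step,
        centered_rna=str(triplet[c_field]),
    )


@dataclass
class EvaluationResult:
    """Pass/fail of one candidate with the named failing criteria."""

    status: str  # "pass" | "fail" | "unevaluable"
    failed_criteria: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def evaluate_candidate(
    profile: WindowProfile, triplet_class: str, config: CoreConfig | None = None
) -> EvaluationResult:
    """Apply the per-class extremum and ΔCor criteria to one profile."""
    config = config or CoreConfig()
    if triplet_class not in TRIPLET_CLASSES:
        raise ValidationError(f"unknown triplet class: {triplet_class}")
    if not profile.evaluable:
        return EvaluationResult(status="unevaluable")
    failed: list[str] = []
    if triplet_class == LNCRNA_CENTERED:
        if not profile.min_scc < config.neg_cut_mirna_mrna:
            failed.append(
                f"min_scc {profile.min_scc:.3f} >= {config.neg_cut_mirna_mrna}"
            )
    elif triplet_class == MRNA_CENTERED:
        if not profile.min_scc < config.neg_cut_mirna_lncrna:
            failed.append(
                f"min_scc {profile.min_scc:.3f} >= {config.neg_cut_mirna_lncrna}"
            )
    else:  # miRNA-centered
        if not profile.max_scc > config.pos_cut_lncrna_mrna:
            failed.append(
                f"max_scc {profile.max_scc:.3f} <= {config.pos_cut_lncrna_mrna}"
            )
    if not profile.delta_cor > config.delta_min:
        failed.append(f"delta_cor {profile.delta_cor:.3f} <= {config.delta_min}")
    return EvaluationResult(
        status="pass" if not failed else "fail",
        failed_criteria=tuple(failed),
    )


def detect_triplets(
    matrix: ExpressionMatrix,
    candidates: pd.DataFrame,
    config: CoreConfig | None = None,
) -> pd.DataFrame:
    """Run the sliding-window evaluation over a candidate table.

    Returns the candidate table extended with ``max_scc, min_scc, delta_cor,
    n_windows, n_excluded, status, fail_reasons``.
    """
    config = config or CoreConfig()
    rows = []
    for _, cand in candidates.iterrows():
        prof = sliding_profile(matrix, cand, config)
        res = evaluate_candidate(prof, cand["triplet_class"], config)
        rows.append(
            {
                "max_scc": prof.max_scc,
                "min_scc": prof.min_scc,
                "delta_cor": prof.delta_cor,
                "n_windows": prof.n_windows,
                "n_excluded": prof.n_excluded,
                "status": res.status,
                "fail_reasons": ";".join(res.failed_criteria),
            }
        )
    extra = pd.DataFrame(
        rows,
        columns=["max_scc", "min_scc", "delta_cor", "n_windows",
                 "n_excluded", "status", "fail_reasons"],
        index=candidates.index,
    )
    return pd.concat([candidates, extra], axis=1)
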