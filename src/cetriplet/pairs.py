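"""Typed RNA-pair construction, Spearman scoring, and extreme-quantile screening.

A miRNA-target interaction pool (predicted + experimentally validated edges,
supplied as TSV) implies three pair types:

* miRNA-lncRNA and miRNA-mRNA pairs — the pool edges themselves;
* lncRNA-mRNA pairs — every lncRNA and mRNA that share at least one miRNA
  in the pool (candidate competing pairs).

Each pair gets a whole-cohort Spearman coefficient (SCC), and only the most
extreme ``retain_fraction`` (default 0.1%) per type survives: the most
*negative* tail for miRNA-target pairs (repression) and the most *positive*
tail for lncRNA-mRNA pairs (co-regulation through shared miRNAs).
Alternatively a fixed SCC cutoff can be applied to reproduce a previously
realised screening regime on new data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import normalized_ranks
from .preprocess import ExpressionMatrix, ParseError, ValidationError, _read_tsv

log = logging.getLogger(__name__)

MIRNA_LNCRNA = "miRNA-lncRNA"
MIRNA_MRNA = "miRNA-mRNA"
LNCRNA_MRNA = "lncRNA-mRNA"
PAIR_TYPES = (MIRNA_LNCRNA, MIRNA_MRNA, LNCRNA_MRNA)

#: screening tail per pair type: miRNA represses its targets, ceRNA partners
#: co-vary positively.
TAIL = {MIRNA_LNCRNA: "negative", MIRNA_MRNA: "negative", LNCRNA_MRNA: "positive"}


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (a constant vector has no rank variance)."""


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation (Pearson correlation of average ranks).

    Raises
    ------
    UndefinedCorrelationError
        If either vector is constant; callers must treat the pair as
        unscreenable rather than as uncorrelated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector: SCC undefined")
    return float(stats.spearmanr(x, y).statistic)


def correlation_diagnostics(
    x: Sequence[float], y: Sequence[float], pseudocount: float = 1.0
) -> dict[str, float]:
    """Pearson, log-Pearson and Spearman coefficients of one pair.

    The comparison illustrates why rank correlation is used: with miRNA on an
    RPM scale and genes on an FPKM scale the raw-value Pearson coefficient is
    compressed by the magnitude gap, while the Spearman coefficient is
    invariant under the log transform.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scc = spearman(x, y)
    pcc = float(stats.pearsonr(x, y).statistic)
    pcc_log = float(
        stats.pearsonr(np.log(x + pseudocount), np.log(y + pseudocount)).statistic
    )
    return {"pcc": pcc, "pcc_log": pcc_log, "scc": scc}


# ---------------------------------------------------------------------------
# interaction pool


def load_interaction_pool(
    paths: Iterable[str | Path], known_ids: set[str] | None = None
) -> pd.DataFrame:
    """Union miRNA-target TSV files into one deduplicated pool.

    Each file needs columns ``mirna``, ``target``, ``source``.  Duplicate
    (miRNA, target) rows are merged with their source tags unioned into a
    semicolon-joined, sorted string.  Pairs mentioning an id absent from
    ``known_ids`` (when given) are dropped with a logged count.
    """
    frames = []
    for p in paths:
        df = _read_tsv(p, dtype=str)
        need = {"mirna", "target", "source"}
        if not need.issubset(df.columns):
            raise ParseError(f"interaction file {p} must have columns {sorted(need)}")
        frames.append(df[["mirna", "target", "source"]])
    if not frames:
        return pd.DataFrame(columns=["mirna", "target", "sources"])
    pool = pd.concat(frames, ignore_index=True)
    if known_ids is not None:
        ok = pool["mirna"].isin(known_ids) & pool["target"].isin(known_ids)
        if (~ok).any():
            log.info("dropped %d pool edge(s) with ids absent from the "
                     "expression matrix", int((~ok).sum()))
        pool = pool[ok]
    merged = (
        pool.groupby(["mirna", "target"], sort=True)["source"]
        .apply(lambda s: ";".join(sorted(set(s))))
        .reset_index()
        .rename(columns={"source": "sources"})
    )
    return merged


def derive_typed_pairs(
    pool: pd.DataFrame, rna_class: pd.Series
) -> dict[str, pd.DataFrame]:
    """Split the pool into the three typed pair tables.

    lncRNA-mRNA pairs are formed only from a lncRNA and an mRNA sharing at
    least one pool miRNA (the sponging mechanism requires a shared miRNA),
    not from the full cross product.
    """
    cls = pool["target"].map(rna_class)
    ml = pool[cls == "lncRNA"].rename(columns={"mirna": "rna_a", "target": "rna_b"})
    mg = pool[cls == "mRNA"].rename(columns={"mirna": "rna_a", "target": "rna_b"})
    lg = (
        pool[cls == "lncRNA"][["mirna", "target"]]
        .rename(columns={"target": "lncrna"})
        .merge(
            pool[cls == "mRNA"][["mirna", "target"]].rename(columns={"target": "mrna"}),
            on="mirna",
        )[["lncrna", "mrna"]]
        .drop_duplicates()
        .sort_values(["lncrna", "mrna"], kind="mergesort")
        .reset_index(drop=True)
    )
    lg = lg.rename(columns={"lncrna": "rna_a", "mrna": "rna_b"})
    lg["sources"] = "shared-miRNA"
    return {
        MIRNA_LNCRNA: ml[["rna_a", "rna_b", "sources"]].reset_index(drop=True),
        MIRNA_MRNA: mg[["rna_a", "rna_b", "sources"]].reset_index(drop=True),
        LNCRNA_MRNA: lg[["rna_a", "rna_b", "sources"]],
    }


def score_pairs(matrix: ExpressionMatrix, pairs: pd.DataFrame) -> pd.DataFrame:
    """Attach the whole-cohort SCC to each pair row.

    Pairs whose SCC is undefined (a constant expression vector) are excluded
    with a logged count, so they never enter quantile computation.
    """
    if pairs.empty:
        out = pairs.copy()
        out["scc"] = pd.Series(dtype=float)
        return out
    nr = normalized_ranks(matrix.values.to_numpy(dtype=float))
    index = matrix.values.index
    ia = index.get_indexer(pairs["rna_a"])
    ib = index.get_indexer(pairs["rna_b"])
    if (ia < 0).any() or (ib < 0).any():
        bad = pairs.loc[(ia < 0) | (ib < 0), ["rna_a", "rna_b"]]
        raise ValidationError(
            f"pair ids missing from the matrix: {bad.values.tolist()[:5]}"
        )
    scc = np.einsum("ij,ij->i", nr[ia], nr[ib])
    out = pairs.copy()
    out["scc"] = np.clip(scc, -1.0, 1.0)
    n_undef = int(out["scc"].isna().sum())
    if n_undef:
        log.info("excluded %d pair(s) with undefined SCC (constant vector)", n_undef)
        out = out[out["scc"].notna()]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# screening


def retention_count(pool_size: int, retain_fraction: float) -> int:
    """Number of pairs kept by the quantile rule: floor(fraction * pool)."""
    if not 0.0 < retain_fraction < 1.0:
        raise ValidationError("retain_fraction must lie in (0, 1)")
    return math.floor(retain_fraction * pool_size)


@dataclass
class ScreenResult:
    """Outcome of screening one pair type."""

    pair_type: str
    direction: str  # "negative" or "positive"
    retain_fraction: float | None
    fixed_cutoff: float | None
    pool_size: int
    threshold: float  # realised SCC of the least extreme retained pair
    retained: pd.DataFrame = field(repr=False)

    def report(self) -> dict:
        return {
            "pair_type": self.pair_type,
            "direction": self.direction,
            "retain_fraction": self.retain_fraction,
            "fixed_cutoff": self.fixed_cutoff,
            "pool_size": self.pool_size,
            "threshold": None if np.isnan(self.threshold) else round(self.threshold, 6),
            "retained": int(len(self.retained)),
        }


def screen_pairs(
    scored: pd.DataFrame,
    pair_type: str,
    direction: str | None = None,
    retain_fraction: float = 0.001,
    fixed_cutoff: float | None = None,
) -> ScreenResult:
    """Keep the extreme tail of a scored pair table.

    Default mode retains exactly ``floor(retain_fraction * pool_size)`` pairs,
    the most negative (miRNA-target types) or most positive (lncRNA-mRNA)
    ones; ties at the boundary are broken deterministically by ascending
    (rna_a, rna_b).  The realised threshold is the SCC of the least extreme
    retained pair.  With ``fixed_cutoff`` set, all pairs strictly beyond the
    cutoff are retained instead (strictly below for the negative tail,
    strictly above for the positive one).
    """
    if direction is None:
        direction = TAIL[pair_type]
    if direction not in ("negative", "positive"):
        raise ValidationError(f"unknown screening direction: {direction}")
    n = len(scored)
    ascending = direction == "negative"
    ordered = scored.sort_values(
        ["scc", "rna_a", "rna_b"], ascending=[ascending, True, True],
        kind="mergesort",
    ).reset_index(drop=True)

    if fixed_cutoff is not None:
        if ascending:
            retained = ordered[ordered["scc"] < fixed_cutoff]
        else:
            retained = ordered[ordered["scc"] > fixed_cutoff]
        threshold = float(fixed_cutoff)
        frac = None
    else:
        k = retention_count(n, retain_fraction) if n else 0
        if k == 0:
            log.warning("screening %s retains 0 of %d pairs", pair_type, n)
        retained = ordered.iloc[:k]
        threshold = float(retained["scc"].iloc[-1]) if k else float("nan")
        frac = retain_fraction
    return ScreenResult(
        pair_type=pair_type,
        direction=direction,
        retain_fraction=frac,
        fixed_cutoff=fixed_cutoff,
        pool_size=n,
        threshold=threshold,
        retained=retained.reset_index(drop=True),
    )
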