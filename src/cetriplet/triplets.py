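"""Candidate triplet assembly from screened pairs.

A candidate (lncRNA, miRNA, mRNA) is admitted under up to three classes,
named for the RNA whose abundance will condition the sliding-window analysis:

* ``lncRNA-centered``  — miRNA-lncRNA and lncRNA-mRNA pairs retained;
* ``miRNA-centered``   — miRNA-lncRNA and miRNA-mRNA pairs retained;
* ``mRNA-centered``    — miRNA-mRNA and lncRNA-mRNA pairs retained.

In every class both miRNA-side edges (miRNA-lncRNA and miRNA-mRNA) must
exist in the interaction pool — without predicted/validated binding of the
miRNA to *both* targets the sponging mechanism is impossible — but only the
two class-defining pairs must additionally have survived screening.
"""

from __future__ import annotations

import logging

import pandas as pd

from .pairs import LNCRNA_MRNA, MIRNA_LNCRNA, MIRNA_MRNA, ScreenResult

log = logging.getLogger(__name__)

LNCRNA_CENTERED = "lncRNA-centered"
MIRNA_CENTERED = "miRNA-centered"
MRNA_CENTERED = "mRNA-centered"
TRIPLET_CLASSES = (LNCRNA_CENTERED, MIRNA_CENTERED, MRNA_CENTERED)

#: the pair type NOT required to be retained for each class
MISSING_PAIR = {
    LNCRNA_CENTERED: MIRNA_MRNA,
    MIRNA_CENTERED: LNCRNA_MRNA,
    MRNA_CENTERED: MIRNA_LNCRNA,
}

CANDIDATE_COLUMNS = [
    "lncrna", "mirna", "mrna", "triplet_class",
    "scc_pair1", "scc_pair2", "missing_pair",
]


def _retained_frame(res: ScreenResult, a: str, b: str) -> pd.DataFrame:
    df = res.retained[["rna_a", "rna_b", "scc"]].copy()
    return df.rename(columns={"rna_a": a, "rna_b": b})


def build_candidates(
    screened: dict[str, ScreenResult],
    pool_pairs: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Enumerate candidate triplets of all three classes.

    Parameters
    ----------
    screened : dict
        One :class:`~cetriplet.pairs.ScreenResult` per pair type.
    pool_pairs : dict
        The typed pair tables derived from the interaction pool (pre-
        screening); used for the pool-membership requirement on the
        miRNA-side edges.

    Returns
    -------
    pandas.DataFrame
        Columns ``lncrna, mirna, mrna, triplet_class, scc_pair1, scc_pair2,
        missing_pair``; at most one row per (triplet, class); sorted by
        (class, lncrna, mirna, mrna).  ``scc_pair1``/``scc_pair2`` are the
        whole-cohort SCCs of the two retained class-defining pairs, ordered
        miRNA-lncRNA, miRNA-mRNA, lncRNA-mRNA.
    """
    ml = _retained_frame(screened[MIRNA_LNCRNA], "mirna", "lncrna")
    mg = _retained_frame(screened[MIRNA_MRNA], "mirna", "mrna")
    lg = _retained_frame(screened[LNCRNA_MRNA], "lncrna", "mrna")
    if ml.empty and mg.empty and lg.empty:
        log.warning("all screened pair sets are empty: no candidates")
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)

    pool_ml = set(map(tuple, pool_pairs[MIRNA_LNCRNA][["rna_a", "rna_b"]].values))
    pool_mg = set(map(tuple, pool_pairs[MIRNA_MRNA][["rna_a", "rna_b"]].values))

    frames = []

    # class I (lncRNA-centered): miRNA-lncRNA and lncRNA-mRNA retained,
    # miRNA-mRNA edge present in the pool.
    c1 = ml.merge(lg, on="lncrna", suffixes=("_ml", "_lg"))
    if len(c1):
        keep = [mt in pool_mg for mt in zip(c1["mirna"], c1["mrna"])]
        c1 = c1[keep]
    c1 = c1.assign(triplet_class=LNCRNA_CENTERED, missing_pair=MIRNA_MRNA)
    c1 = c1.rename(columns={"scc_ml": "scc_pair1", "scc_lg": "scc_pair2"})
    frames.append(c1)

    # class II (miRNA-centered): miRNA-lncRNA and miRNA-mRNA retained; both
    # edges are pool members by construction (retained subsets of the pool).
    c2 = ml.merge(mg, on="mirna", suffixes=("_ml", "_mg"))
    c2 = c2.assign(triplet_class=MIRNA_CENTERED, missing_pair=LNCRNA_MRNA)
    c2 = c2.rename(columns={"scc_ml": "scc_pair1", "scc_mg": "scc_pair2"})
    frames.append(c2)

    # class III (mRNA-centered): miRNA-mRNA and lncRNA-mRNA retained,
    # miRNA-lncRNA edge present in the pool.
    c3 = mg.merge(lg, on="mrna", suffixes=("_mg", "_lg"))
    if len(c3):
        keep = [ml_ in pool_ml for ml_ in zip(c3["mirna"], c3["lncrna"])]
        c3 = c3[keep]
    c3 = c3.assign(triplet_class=MRNA_CENTERED, missing_pair=MIRNA_LNCRNA)
    c3 = c3.rename(columns={"scc_mg": "scc_pair1", "scc_lg": "scc_pair2"})
    frames.append(c3)

    out = pd.concat([f[CANDIDATE_COLUMNS] for f in frames], ignore_index=True)
    out = out.drop_duplicates(subset=["lncrna", "mirna", "mrna", "triplet_class"])
    out = out.sort_values(
        ["triplet_class", "lncrna", "mirna", "mrna"], kind="mergesort"
    ).reset_index(drop=True)
    if out.empty:
        log.warning("no candidate triplets could be assembled")
    return out


def deduplicate_triplets(triplets: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-class rows to one row per (lncRNA, miRNA, mRNA).

    A triplet detected under several classes is reported once, with its
    classes joined by ``+`` in canonical class order.
    """
    if triplets.empty:
        return pd.DataFrame(columns=["lncrna", "mirna", "mrna", "classes"])
    order = {c: i for i, c in enumerate(TRIPLET_CLASSES)}
    agg = (
        triplets.groupby(["lncrna", "mirna", "mrna"], sort=True)["triplet_class"]
        .apply(lambda s: "+".join(sorted(set(s), key=order.get)))
        .reset_index()
        .rename(columns={"triplet_class": "classes"})
    )
    return agg
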