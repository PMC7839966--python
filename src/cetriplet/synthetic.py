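"""Synthetic expression data with planted ceRNA triplets.

The generator emulates the data regime the pipeline is built for: a bulk
tumour cohort with miRNA expression on an RPM scale (median ~1e3) and
gene expression on an FPKM scale (median ~10) — magnitudes differing by
orders of magnitude, the regime in which raw-value Pearson correlation
collapses while rank correlation does not.

Planted mechanism
-----------------
Each planted triplet has a latent miRNA activity ``A ~ lognormal``; the
observed miRNA is ``mirna_scale * A`` times multiplicative noise.  Both
targets (lncRNA and mRNA) are repressed through a saturating Hill function
with a basal floor::

    f(A) = basal + (1 - basal) / (1 + (A/K)**hill),   K = median(A)

and share a per-sample co-regulation factor ``exp(c)``, so that

* miRNA is negatively rank-correlated with both targets,
* lncRNA and mRNA are positively rank-correlated,
* the lncRNA-mRNA coupling is strongest at intermediate miRNA abundance:
  at low A the repression is saturated near 1, at high A near ``basal``,
  so the shared f(A) component — the dominant source of coupling — varies
  most where A crosses K.  The window-SCC profile therefore has an interior
  maximum.

``coupling_strength`` raises f(A) to a power (0 removes the miRNA's effect
on the targets entirely — a negative control), and ``shared_factor_sd``
scales the miRNA-independent co-regulation.  Null RNAs are independent
lognormals.  Everything is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, ValidationError

MIRNA_NOISE_SD = 0.2  # log-scale measurement noise on observed miRNA


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults mirror the reference cohort regime.

    ``n_samples`` = 376 so the default 25% window is 94 samples.  Scales are
    medians: RPM ~1e3 for miRNAs, FPKM ~10 for genes.  ``noise_sd``,
    ``shared_factor_sd`` and ``latent_sd`` are standard deviations on the
    natural-log scale.
    """

    n_samples: int = 376
    n_planted: int = 50
    n_null_genes: int = 60  # split half lncRNA, half mRNA
    n_null_mirnas: int = 20
    mirna_scale: float = 1e3
    gene_scale: float = 10.0
    coupling_strength: float = 1.0
    hill_coefficient: float = 8.0
    basal_fraction: float = 0.05
    shared_factor_sd: float = 0.18
    noise_sd: float = 0.30
    latent_sd: float = 1.0
    n_decoy_edges: int = 300
    n_duplicate_patients: int = 0  # patients given a second replicate sample
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, 1) < 1 or self.n_samples < 8:
            raise ValidationError("n_samples must be >= 8")
        if min(self.n_planted, self.n_null_genes, self.n_null_mirnas,
               self.n_decoy_edges, self.n_duplicate_patients) < 0:
            raise ValidationError("counts must be >= 0")
        if self.noise_sd < 0 or self.shared_factor_sd < 0 or self.latent_sd < 0:
            raise ValidationError("scale parameters must be >= 0")
        if self.coupling_strength < 0:
            raise ValidationError("coupling_strength must be >= 0")
        if self.hill_coefficient < 1:
            raise ValidationError("hill_coefficient must be >= 1")
        if not 0.0 <= self.basal_fraction < 1.0:
            raise ValidationError("basal_fraction must lie in [0, 1)")


@dataclass
class TruthTable:
    """Planted triplets with their generative parameters, plus RNA labels."""

    triplets: pd.DataFrame  # lncrna, mirna, mrna, hill, basal, coupling
    rna_labels: pd.Series  # per RNA id: "planted" | "null"


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix
    truth: TruthTable
    pool: pd.DataFrame  # mirna, target, source
    sample_map: pd.DataFrame  # sample_id, patient_id
    config: SyntheticConfig = field(repr=False)


def _repression(a: np.ndarray, k: float, cfg: SyntheticConfig) -> np.ndarray:
    f = cfg.basal_fraction + (1.0 - cfg.basal_fraction) / (1.0 + (a / k) ** cfg.hill_coefficient)
    return f ** cfg.coupling_strength


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the expression matrix, truth table and interaction pool."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    patients = [f"P{i:04d}" for i in range(n)]

    ids: list[str] = []
    classes: list[str] = []
    rows: list[np.ndarray] = []
    labels: dict[str, str] = {}
    truth_rows = []

    for i in range(cfg.n_planted):
        mir_id, lnc_id, mrna_id = f"mir-p{i:03d}", f"LNC-P{i:03d}", f"GENE-P{i:03d}"
        a = rng.lognormal(0.0, cfg.latent_sd, n)
        k = float(np.median(a))
        mir = cfg.mirna_scale * a * rng.lognormal(0.0, MIRNA_NOISE_SD, n)
        f = _repression(a, k, cfg)
        shared = rng.lognormal(0.0, cfg.shared_factor_sd, n)
        lnc = cfg.gene_scale * f * shared * rng.lognormal(0.0, cfg.noise_sd, n)
        mrna = cfg.gene_scale * f * shared * rng.lognormal(0.0, cfg.noise_sd, n)
        ids += [mir_id, lnc_id, mrna_id]
        classes += ["miRNA", "lncRNA", "mRNA"]
        rows += [mir, lnc, mrna]
        labels.update({mir_id: "planted", lnc_id: "planted", mrna_id: "planted"})
        truth_rows.append(
            {
                "lncrna": lnc_id, "mirna": mir_id, "mrna": mrna_id,
                "hill": cfg.hill_coefficient, "basal": cfg.basal_fraction,
                "coupling": cfg.coupling_strength,
            }
        )

    null_lnc = [f"LNC-N{i:03d}" for i in range(cfg.n_null_genes // 2)]
    null_mrna = [f"GENE-N{i:03d}" for i in range(cfg.n_null_genes - cfg.n_null_genes // 2)]
    null_mir = [f"mir-n{i:03d}" for i in range(cfg.n_null_mirnas)]
    for gid in null_lnc:
        ids.append(gid); classes.append("lncRNA")
        rows.append(cfg.gene_scale * rng.lognormal(0.0, 1.0, n))
        labels[gid] = "null"
    for gid in null_mrna:
        ids.append(gid); classes.append("mRNA")
        rows.append(cfg.gene_scale * rng.lognormal(0.0, 1.0, n))
        labels[gid] = "null"
    for mid in null_mir:
        ids.append(mid); classes.append("miRNA")
        rows.append(cfg.mirna_scale * rng.lognormal(0.0, 1.0, n))
        labels[mid] = "null"

    values = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, n)),
                          index=ids, columns=patients)
    matrix = ExpressionMatrix(values, pd.Series(classes, index=ids))

    # interaction pool: planted miRNA -> its two targets, decoys among nulls
    pool_rows = []
    for t in truth_rows:
        pool_rows.append({"mirna": t["mirna"], "target": t["lncrna"], "source": "planted"})
        pool_rows.append({"mirna": t["mirna"], "target": t["mrna"], "source": "planted"})
    null_targets = null_lnc + null_mrna
    if null_mir and null_targets and cfg.n_decoy_edges:
        possible = [(m, t) for m in null_mir for t in null_targets]
        take = min(cfg.n_decoy_edges, len(possible))
        picks = rng.choice(len(possible), size=take, replace=False)
        for j in sorted(picks):
            m, t = possible[j]
            pool_rows.append({"mirna": m, "target": t, "source": "decoy"})
    pool = pd.DataFrame(pool_rows, columns=["mirna", "target", "source"])

    # replicate structure: some patients contribute two samples
    if cfg.n_duplicate_patients > cfg.n_samples:
        raise ValidationError("n_duplicate_patients cannot exceed n_samples")
    if cfg.n_duplicate_patients:
        sample_rows = [{"sample_id": f"{p}-01", "patient_id": p} for p in patients]
        for p in patients[: cfg.n_duplicate_patients]:
            sample_rows.append({"sample_id": f"{p}-02", "patient_id": p})
    else:  # patient-level data: samples and patients coincide
        sample_rows = [{"sample_id": p, "patient_id": p} for p in patients]
    sample_map = pd.DataFrame(sample_rows, columns=["sample_id", "patient_id"])

    truth = TruthTable(
        triplets=pd.DataFrame(
            truth_rows, columns=["lncrna", "mirna", "mrna", "hill", "basal", "coupling"]
        ),
        rna_labels=pd.Series(labels, dtype=str),
    )
    return SyntheticDataset(matrix=matrix, truth=truth, pool=pool,
                            sample_map=sample_map, config=cfg)


def replicated_matrix(
    dataset: SyntheticDataset, jitter_sd: float = 0.05
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Expand the patient-level matrix into per-sample columns.

    Patients listed twice in the sample map get two jittered replicate
    columns; merging the result by patient mean recovers (approximately) the
    patient-level values.  Used to exercise the merge stage.
    """
    cfg = dataset.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**16 + 1]))
    base = dataset.matrix.values
    cols = {}
    mapping = {}
    for _, row in dataset.sample_map.iterrows():
        s, p = row["sample_id"], row["patient_id"]
        jit = rng.lognormal(0.0, jitter_sd, base.shape[0]) if jitter_sd > 0 else 1.0
        cols[s] = base[p].to_numpy() * jit
        mapping[s] = p
    values = pd.DataFrame(cols, index=base.index)
    return ExpressionMatrix(values, dataset.matrix.rna_class), mapping


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the TSV fixtures the pipeline consumes, plus the truth table.

    If the config asked for replicate samples, the expression table holds
    per-sample columns (to be merged by the preprocess stage); otherwise it
    is the patient-level matrix with an identity sample map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "class_map": outdir / "class_map.tsv",
        "sample_map": outdir / "sample_map.tsv",
        "interactions": outdir / "interactions.tsv",
        "truth": outdir / "truth_triplets.tsv",
    }
    if dataset.config.n_duplicate_patients:
        raw, _ = replicated_matrix(dataset)
        raw.write_tsv(paths["expression"])
    else:
        dataset.matrix.write_tsv(paths["expression"])
    dataset.matrix.rna_class.rename("rna_class").to_csv(
        paths["class_map"], sep="\t", index_label="rna_id"
    )
    dataset.sample_map.to_csv(paths["sample_map"], sep="\t", index=False)
    dataset.pool.to_csv(paths["interactions"], sep="\t", index=False)
    dataset.truth.triplets.to_csv(paths["truth"], sep="\t", index=False)
    return paths
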