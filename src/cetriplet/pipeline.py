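"""End-to-end orchestration: preprocess -> screen -> build -> detect -> permute -> export.

The pipeline is configured by a :class:`PipelineConfig` (loadable from YAML)
and writes every stage's output as TSV plus a JSON run report with the
counts, realised thresholds and seed, so a run is fully reproducible and
auditable.  Two runs with identical config and seed produce byte-identical
output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import network, pairs, preprocess, significance, triplets, windows
from .preprocess import FilterCriteria, ValidationError
from .significance import PermutationConfig
from .windows import CoreConfig

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"

#: the realised screening cutoffs of the reference cohort, usable as fixed
#: cutoffs on new data via ``use_fixed_cutoffs``.
REFERENCE_CUTOFFS = {
    pairs.MIRNA_LNCRNA: -0.305,
    pairs.MIRNA_MRNA: -0.311,
    pairs.LNCRNA_MRNA: 0.520,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """File paths plus every stage's parameters."""

    expression: str = ""
    class_map: str = ""
    interactions: list[str] = field(default_factory=list)
    outdir: str = "cetriplet_out"
    sample_map: str | None = None
    keep_list: str | None = None
    retain_fraction: float = 0.001
    use_fixed_cutoffs: bool = False
    seed: int = 0
    filter: FilterCriteria = field(default_factory=FilterCriteria)
    core: CoreConfig = field(default_factory=CoreConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("filter", FilterCriteria), ("core", CoreConfig),
                         ("permutation", PermutationConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if not self.expression or not self.class_map:
            raise ValidationError("config needs 'expression' and 'class_map' paths")
        for p in [self.expression, self.class_map, *(self.interactions or []),
                  *( [self.sample_map] if self.sample_map else [] )]:
            if not Path(p).exists():
                raise ValidationError(f"input file does not exist: {p}")
        if not 0.0 < self.retain_fraction < 1.0:
            raise ValidationError("retain_fraction must lie in (0, 1)")

    def echo(self) -> dict:
        d = asdict(self)
        # the permutation seed follows the pipeline seed unless set explicitly
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the run report (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "config": config.echo()}
    perm_config = PermutationConfig(
        **{**asdict(config.permutation), "seed": config.seed}
    )

    # ---- preprocess ----------------------------------------------------
    stage = "preprocess"
    try:
        class_map = preprocess.read_class_map(config.class_map)
        matrix = preprocess.read_expression_table(config.expression, class_map)
        n_raw_samples = matrix.n_samples
        if config.sample_map:
            sample_map = preprocess.read_sample_map(config.sample_map)
            matrix = preprocess.merge_patient_samples(matrix, sample_map)
        keep = None
        if config.keep_list:
            keep = set(Path(config.keep_list).read_text().split())
        matrix = preprocess.filter_expressed(matrix, config.filter, keep)
        matrix.write_tsv(outdir / "filtered_expression.tsv", FLOAT_FORMAT)
        report["stages"][stage] = {
            "raw_samples": n_raw_samples,
            "patients": matrix.n_samples,
            "retained": matrix.class_counts(),
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- screen --------------------------------------------------------
    stage = "screen"
    try:
        pool = pairs.load_interaction_pool(
            config.interactions, known_ids=set(matrix.rna_ids)
        )
        typed = pairs.derive_typed_pairs(pool, matrix.rna_class)
        screened = {}
        for ptype, table in typed.items():
            scored = pairs.score_pairs(matrix, table)
            cutoff = REFERENCE_CUTOFFS[ptype] if config.use_fixed_cutoffs else None
            screened[ptype] = pairs.screen_pairs(
                scored, ptype,
                retain_fraction=config.retain_fraction,
                fixed_cutoff=cutoff,
            )
            fname = ptype.replace("-", "_").lower() + "_retained.tsv"
            screened[ptype].retained.to_csv(
                outdir / fname, sep="\t", index=False, float_format=FLOAT_FORMAT
            )
        report["stages"][stage] = {p: s.report() for p, s in screened.items()}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- build ---------------------------------------------------------
    stage = "build"
    try:
        candidates = triplets.build_candidates(screened, typed)
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False,
                          float_format=FLOAT_FORMAT)
        per_class = candidates["triplet_class"].value_counts().to_dict() \
            if len(candidates) else {}
        report["stages"][stage] = {
            "candidates": int(len(candidates)),
            "per_class": {c: int(per_class.get(c, 0))
                          for c in triplets.TRIPLET_CLASSES},
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- detect --------------------------------------------------------
    stage = "detect"
    try:
        detected = windows.detect_triplets(matrix, candidates, config.core)
        detected.to_csv(outdir / "detection.tsv", sep="\t", index=False,
                        float_format=FLOAT_FORMAT)
        report["stages"][stage] = {
            "evaluated": int(len(detected)),
            "passed": int((detected["status"] == "pass").sum())
            if len(detected) else 0,
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- permute -------------------------------------------------------
    stage = "permute"
    try:
        final = significance.add_significance(
            matrix, detected, config.core, perm_config, n_tests=len(candidates)
        )
        final.to_csv(outdir / "competing_triplets.tsv", sep="\t", index=False,
                     float_format=FLOAT_FORMAT)
        sig = final[final["significant"]] if len(final) else final
        unique = triplets.deduplicate_triplets(sig)
        unique.to_csv(outdir / "competing_triplets_unique.tsv", sep="\t",
                      index=False)
        report["stages"][stage] = {
            "tested": int((detected["status"] == "pass").sum())
            if len(detected) else 0,
            "significant_rows": int(len(sig)),
            "unique_triplets": int(len(unique)),
            "n_tests": int(len(candidates)),
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- export --------------------------------------------------------
    stage = "export"
    try:
        nodes, edges = network.export_network(unique)
        network.write_network(nodes, edges, outdir)
        report["stages"][stage] = {"nodes": int(len(nodes)),
                                   "edges": int(len(edges))}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
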