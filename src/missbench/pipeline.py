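"""Configuration and orchestration of reproducible report bundles.

A run config (YAML or dict) names the inputs and parameters; ``run`` executes
the requested stages — per-set benchmark rows, the substitution-matrix
analysis, structure annotation — and writes a manifest recording the config
hash, input checksums and output checksums, so a rerun can be verified
byte-for-byte.  A stage failure aborts the run with a stage-labeled error
and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .benchmark import benchmark_protein_set, write_report_tsv
from .io import (
    read_clinical_table,
    read_confidence,
    read_protein_lengths,
    read_protein_set,
    read_region_table,
    read_score_table,
)
from .metrics import AmbiguousPolicy, ThresholdScheme
from .structure import annotate_structure, residue_profile
from .substitution import (
    asymmetric_pairs,
    blosum_correlation,
    label_flip_pairs,
    mean_substitution_matrix,
    write_pair_report,
)

log = logging.getLogger("missbench")


@dataclass
class RunConfig:
    """Validated inputs and parameters of one pipeline run."""

    scores: str
    clinical: str
    lengths: str
    sets: list[str] = field(default_factory=list)
    score_dialect: str = "canonical"
    regions: str | None = None
    region_type: str | None = None
    region_mode: str = "inside"
    confidence: str | None = None
    plddt_min: float = 50.0
    min_stars: int = 1
    benign_cutoff: float = 0.340
    pathogenic_cutoff: float = 0.564
    ambiguous_policy: str = "error"  # "error" | "exclude"
    snv_restrict: bool = False
    substitution_restriction: str | None = None  # None | "all" | "snv_only"
    min_delta: float = 0.2
    annotate: list[dict] = field(default_factory=list)  # {structure, layout, protein_acc?}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def scheme(self) -> ThresholdScheme:
        return ThresholdScheme(self.benign_cutoff, self.pathogenic_cutoff)

    def policy(self) -> AmbiguousPolicy:
        mapping = {
            "error": AmbiguousPolicy.AS_ERROR,
            "exclude": AmbiguousPolicy.EXCLUDED,
        }
        if self.ambiguous_policy not in mapping:
            raise ValueError(
                f"ambiguous_policy must be 'error' or 'exclude', "
                f"got {self.ambiguous_policy!r}"
            )
        return mapping[self.ambiguous_policy]

    def validate(self) -> None:
        self.scheme()  # raises on disordered thresholds
        self.policy()
        if self.min_stars < 0:
            raise ValueError("min_stars must be >= 0")
        for path in self._input_paths():
            if not Path(path).exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")

    def _input_paths(self) -> list[str]:
        paths = [self.scores, self.clinical, self.lengths, *self.sets]
        for optional in (self.regions, self.confidence):
            if optional:
                paths.append(optional)
        for spec in self.annotate:
            paths.append(spec["structure"])
        return paths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the configured stages; returns (and writes) the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    stage = "load"
    try:
        scores = read_score_table(config.scores, config.score_dialect)
        clinical, _ = read_clinical_table(config.clinical, min_stars=config.min_stars)
        metas = read_protein_lengths(config.lengths)
        regions = read_region_table(config.regions) if config.regions else None
        confidence = (
            read_confidence(config.confidence) if config.confidence else None
        )

        stage = "benchmark"
        reports = []
        for set_path in config.sets:
            pset = read_protein_set(set_path)
            reports.append(
                benchmark_protein_set(
                    pset,
                    scores,
                    clinical,
                    metas,
                    regions=regions,
                    region_type=config.region_type,
                    region_mode=config.region_mode,
                    confidence=confidence,
                    plddt_min=config.plddt_min,
                    scheme=config.scheme(),
                    policy=config.policy(),
                    snv_restrict=config.snv_restrict,
                )
            )
        if reports:
            report_path = outdir / "report.tsv"
            write_report_tsv(reports, report_path)
            created.append(report_path)

        if config.substitution_restriction:
            stage = "substitution"
            matrix = mean_substitution_matrix(
                scores, config.substitution_restriction
            )
            matrix_path = outdir / "matrix.tsv"
            matrix.to_tsv(matrix_path)
            created.append(matrix_path)
            pairs_path = outdir / "pairs.tsv"
            write_pair_report(
                asymmetric_pairs(matrix, config.min_delta),
                label_flip_pairs(matrix, config.scheme()),
                pairs_path,
            )
            created.append(pairs_path)
            try:
                corr = blosum_correlation(matrix)
                (outdir / "blosum_fit.json").write_text(
                    json.dumps(
                        {
                            "r": corr.r,
                            "p_value": corr.p_value,
                            "slope": corr.slope,
                            "intercept": corr.intercept,
                            "n_points": corr.n_points,
                        },
                        indent=2,
                    )
                    + "\n"
                )
                created.append(outdir / "blosum_fit.json")
            except ValueError:
                log.warning("too few matrix cells for the BLOSUM62 fit; skipped")

        stage = "annotate"
        for spec in config.annotate:
            struct_path = Path(spec["structure"])
            acc = spec.get("protein_acc", struct_path.stem)
            layout = spec.get("layout", "qb")
            profile = residue_profile(
                [s for s in scores if s.protein_acc == acc]
            )
            annotated = annotate_structure(
                struct_path.read_text(), profile, layout
            )
            out_path = outdir / f"{struct_path.stem}_annotated.pdb"
            out_path.write_text(annotated)
            created.append(out_path)
    except Exception as exc:
        for path in created:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"[{stage}] {exc}") from exc

    stage = "manifest"
    config_blob = json.dumps(
        {k: getattr(config, k) for k in config.__dataclass_fields__},
        sort_keys=True,
        default=str,
    )
    manifest = {
        "software": f"missbench {__version__}",
        "config": json.loads(config_blob),
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "inputs": {p: _sha256(Path(p)) for p in config._input_paths()},
        "outputs": {str(p): _sha256(p) for p in created},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
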