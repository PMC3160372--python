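"""End-to-end workflow: differential expression -> RCR -> verification.

Every artifact written by the pipeline begins with provenance comment lines
(``# key=value``) recording the package version, the seed, a hash of the
full configuration and every numeric threshold used, so a run can be
re-executed byte-identically from its own outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .diffexp import DEThresholds, DifferentialExpression
from .errors import ConfigError, RcrnetError, StageError
from .expression import load_expression
from .graph import load_graph
from .rcr import RCRConfig, ReverseCausalReasoning
from .verification import (DatasetOutcome, build_consistency_matrix,
                           coverage_report, load_annotations)

log = logging.getLogger("rcrnet")


@dataclass
class RunConfig:
    """Paths plus thresholds for one pipeline run."""

    graph_path: str
    matrix_path: str
    groups_path: str
    annotation_path: str | None = None        # probe -> gene
    kb_path: str | None = None                # reasoning substrate; default graph
    expected_directions_path: str | None = None
    out_dir: str = "rcrnet-out"
    dataset_id: str = "dataset"
    observed_direction: int = +1
    normalize: str = "none"                   # none | quantile | rma
    matrix_scale: str = "linear"
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    rcr: RCRConfig = field(default_factory=RCRConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Path | str, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        thresholds = DEThresholds(**doc.pop("thresholds", {}))
        rcr = RCRConfig(**doc.pop("rcr", {}))
        try:
            return cls(thresholds=thresholds, rcr=rcr, **doc)
        except TypeError as exc:
            raise ConfigError(f"bad run config: {exc}") from None

    def validate_paths(self) -> None:
        required = [self.graph_path, self.matrix_path, self.groups_path]
        optional = [self.annotation_path, self.kb_path,
                    self.expected_directions_path]
        for p in required:
            if not Path(p).exists():
                raise ConfigError(f"required input missing: {p}")
        for p in optional:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured input missing: {p}")

    def to_dict(self) -> dict:
        return {
            "graph_path": self.graph_path,
            "matrix_path": self.matrix_path,
            "groups_path": self.groups_path,
            "annotation_path": self.annotation_path,
            "kb_path": self.kb_path,
            "expected_directions_path": self.expected_directions_path,
            "out_dir": self.out_dir,
            "dataset_id": self.dataset_id,
            "observed_direction": self.observed_direction,
            "normalize": self.normalize,
            "matrix_scale": self.matrix_scale,
            "thresholds": self.thresholds.to_dict(),
            "rcr": self.rcr.to_dict(),
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def provenance_header(config: RunConfig) -> list[str]:
    lines = [
        f"# rcrnet version={__version__}",
        f"# config_hash={config.config_hash()}",
        f"# seed={config.seed}",
    ]
    for key, value in sorted(config.thresholds.to_dict().items()):
        lines.append(f"# de.{key}={value}")
    for key, value in sorted(config.rcr.to_dict().items()):
        lines.append(f"# rcr.{key}={value}")
    return lines


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute de -> rcr -> verify; return the artifact paths written.

    The verification stage is skipped (with a log notice) when no
    expected-direction annotation file is configured; earlier artifacts are
    left intact.  Any stage failure raises :class:`StageError` naming the
    stage.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = provenance_header(config)
    artifacts: dict[str, Path] = {}

    try:
        dialect = ("native-json" if config.graph_path.endswith(".json")
                   else "native-tsv")
        graph = load_graph(config.graph_path, dialect)
        kb = graph
        if config.kb_path:
            kb_dialect = ("native-json" if config.kb_path.endswith(".json")
                          else "native-tsv")
            kb = load_graph(config.kb_path, kb_dialect)
        matrix = load_expression(config.matrix_path, config.groups_path,
                                 config.annotation_path,
                                 scale=config.matrix_scale)
    except RcrnetError as exc:
        raise StageError("load", str(exc)) from exc
    except OSError as exc:
        raise StageError("load", str(exc)) from exc

    try:
        results = DifferentialExpression(
            matrix, normalize=config.normalize
        ).fit()
        state_changes = results.state_changes(config.thresholds)
        sc_path = out_dir / "state_changes.tsv"
        state_changes.save(sc_path, header_lines=header)
        artifacts["state_changes"] = sc_path
        log.info("de: %d state changes over %d measured genes",
                 len(state_changes), len(state_changes.universe))
    except RcrnetError as exc:
        raise StageError("de", str(exc)) from exc

    try:
        rcr_results = ReverseCausalReasoning(kb, state_changes, config.rcr).fit()
        hyp_path = out_dir / "hypotheses.tsv"
        rcr_results.save(hyp_path, header_lines=header)
        artifacts["hypotheses"] = hyp_path
        log.info("rcr: %d hypotheses scored, %d significant",
                 len(rcr_results.hypotheses), len(rcr_results.significant))
    except RcrnetError as exc:
        raise StageError("rcr", str(exc)) from exc

    if config.expected_directions_path is None:
        log.info("verify: skipped (no expected-direction annotations "
                 "configured); earlier artifacts intact")
        return artifacts
    try:
        annotations = load_annotations(config.expected_directions_path)
        outcome = DatasetOutcome(
            dataset_id=config.dataset_id,
            observed_direction=config.observed_direction,
            hypotheses=rcr_results.hypotheses,
        )
        matrix_path = out_dir / "consistency_matrix.tsv"
        consistency = build_consistency_matrix([outcome], annotations)
        consistency.save(matrix_path, header_lines=header)
        artifacts["consistency_matrix"] = matrix_path

        report = coverage_report(
            network=graph, kb=kb, outcomes=[outcome], config=config.rcr,
            universes={config.dataset_id: set(state_changes.universe)},
        )
        coverage_path = out_dir / "coverage.json"
        coverage_path.write_text(json.dumps({
            "provenance": {
                "version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
            },
            "coverage": report.to_dict(),
            "consistency_counts": consistency.counts(),
        }, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        artifacts["coverage"] = coverage_path
    except RcrnetError as exc:
        raise StageError("verify", str(exc)) from exc
    return artifacts
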