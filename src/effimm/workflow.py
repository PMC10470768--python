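"""Orchestration of the structural arm into a single JSON mechanism report."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .mechanism import ClassifierConfig, classify_mechanism
from .structio import ActiveSiteSpec, DomainPartition, StructureModel, read_structure
from .surface import EISENBERG_SIGMA, SasaParams, SolvationParams

__all__ = ["AnalysisConfig", "run_mechanism_report", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1


@dataclasses.dataclass
class AnalysisConfig:
    """Serializable bundle of every threshold the structural pipeline uses."""

    probe_radius: float = 1.4
    n_points: int = 960
    sigma_table: str = "eisenberg"
    contact_cutoff: float = 4.5
    rsasa_threshold: float = 0.25
    split_angle_min: float = 60.0
    conf_change_rmsd_min: float = 5.0
    occlusion_min: float = 0.5
    plugging_gain_min: float = 15.0
    pairing_mode: str = "number"
    min_body: int = 15
    rmsd_tol: float = 2.0
    seed: int = 0

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "AnalysisConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def classifier_config(self) -> ClassifierConfig:
        if self.sigma_table != "eisenberg":
            raise ValueError(f"unknown sigma table {self.sigma_table!r}")
        return ClassifierConfig(
            split_angle_min=self.split_angle_min,
            conf_change_rmsd_min=self.conf_change_rmsd_min,
            occlusion_min=self.occlusion_min,
            plugging_gain_min=self.plugging_gain_min,
            pairing_mode=self.pairing_mode,
            min_body=self.min_body,
            rmsd_tol=self.rmsd_tol,
            sasa_params=SasaParams(self.probe_radius, self.n_points),
            solvation_params=EISENBERG_SIGMA,
        )


def run_mechanism_report(
    effector_free: StructureModel | str | Path | None,
    complex_structure: StructureModel | str | Path,
    effector_chains: Sequence[str],
    immunity_chains: Sequence[str],
    site: ActiveSiteSpec,
    partition: Optional[DomainPartition] = None,
    config: Optional[AnalysisConfig] = None,
    out_path: Optional[str | Path] = None,
) -> Dict:
    """Run sasa -> interface -> conformation -> mechanism and emit a JSON report.

    Structures may be given as paths (parsed with default settings) or as
    already-built models.  The report echoes every threshold used, carries
    the full feature set and rule trace, and -- being free of runtime state
    -- is byte-identical across reruns with the same inputs and config.
    On a stage failure a partial report with a failure marker is written
    before the error propagates.
    """
    config = config or AnalysisConfig()
    report: Dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "status": "incomplete",
    }
    stage = "read_structures"
    try:
        if isinstance(effector_free, (str, Path)):
            effector_free = read_structure(effector_free)
        if isinstance(complex_structure, (str, Path)):
            complex_structure = read_structure(complex_structure)
        report["inputs"] = {
            "effector_free": None if effector_free is None else effector_free.id,
            "complex": complex_structure.id,
            "effector_chains": list(effector_chains),
            "immunity_chains": list(immunity_chains),
            "site": sorted(f"{c}:{n}" for c, n in site.residues),
        }
        stage = "classify"
        call = classify_mechanism(
            effector_free, complex_structure, effector_chains, immunity_chains,
            site, partition, config.classifier_config(),
        )
        report["label"] = call.label
        report["no_free_state"] = call.no_free_state
        report["features"] = dataclasses.asdict(call.features)
        report["rule_trace"] = call.rule_trace
        report["status"] = "ok"
    except Exception as exc:
        report["status"] = "failed"
        report["failed_stage"] = stage
        report["error"] = str(exc)
        if out_path is not None:
            _write_json(report, out_path)
        raise RuntimeError(f"mechanism report failed at stage {stage!r}: {exc}") from exc

    if out_path is not None:
        _write_json(report, out_path)
    return report


def _write_json(report: Dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
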