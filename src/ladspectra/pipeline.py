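"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate.

``run_pipeline`` executes the stages in method order (discretization,
support-set selection, pattern generation, classification, cross-validation,
preceded by simulation and preprocessing), writes every intermediate
artifact to the output directory, and records a manifest with the config,
the per-stage derived seeds and a SHA-256 checksum of each artifact.  A
rerun with the same config reproduces identical checksums.

Seed scheme: stage ``i`` uses ``numpy.random.SeedSequence([master_seed, i])``
reduced to a 31-bit integer, so stages are independently rerunnable and the
master seed alone pins the whole run.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .base import ConfigError
from .synthetic import SyntheticConfig, generate_cohort
from .preprocess import BinningSpec, build_feature_matrix
from .fit import LADPipelineConfig, fit_lad_pipeline
from .model import predict_matrix, risk_groups, roc_auc
from .validate import CVConfig, cross_validate
from . import io as lio

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

#: Stage order and indices for the seed fan-out.
STAGES = (
    "simulate", "preprocess", "discretize", "supportset",
    "patterns", "train", "risk", "crossvalidate",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic 31-bit per-stage seed derived from the master seed."""
    i = STAGES.index(stage)
    ss = np.random.SeedSequence([int(master_seed), i])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Nested configuration of the whole run; unknown keys are rejected."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    binning: BinningSpec = field(default_factory=BinningSpec)
    lad: LADPipelineConfig = field(default_factory=LADPipelineConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    standard_window: float = 10.0
    risk_group_count: int = 5
    master_seed: int = 0

    def __post_init__(self) -> None:
        # fan the master seed out to the stages that consume randomness
        object.__setattr__(
            self, "synthetic",
            SyntheticConfig.from_dict(
                {**self.synthetic.to_dict(), "seed": stage_seed(self.master_seed, "simulate")}
            ),
        )
        object.__setattr__(
            self, "cv",
            CVConfig(k=self.cv.k, repeats=self.cv.repeats,
                     seed=stage_seed(self.master_seed, "crossvalidate"),
                     stratified=self.cv.stratified,
                     unclassified_policy=self.cv.unclassified_policy),
        )

    def to_dict(self) -> dict:
        return {
            "synthetic": self.synthetic.to_dict(),
            "binning": {"low": self.binning.low, "high": self.binning.high,
                        "width": self.binning.width},
            "lad": self.lad.to_dict(),
            "cv": self.cv.to_dict(),
            "standard_window": self.standard_window,
            "risk_group_count": self.risk_group_count,
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - {"synthetic", "binning", "lad", "cv",
                            "standard_window", "risk_group_count", "master_seed"}
        if unknown:
            raise ConfigError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "synthetic" in d:
            kwargs["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "binning" in d:
            b = d["binning"]
            unknown_b = set(b) - {"low", "high", "width"}
            if unknown_b:
                raise ConfigError(f"unknown binning keys: {sorted(unknown_b)}")
            kwargs["binning"] = BinningSpec(**b)
        if "lad" in d:
            kwargs["lad"] = LADPipelineConfig.from_dict(d["lad"])
        if "cv" in d:
            c = dict(d["cv"])
            unknown_c = set(c) - {"k", "repeats", "seed", "stratified",
                                  "unclassified_policy"}
            if unknown_c:
                raise ConfigError(f"unknown cv keys: {sorted(unknown_c)}")
            kwargs["cv"] = CVConfig(**c)
        for key in ("standard_window", "risk_group_count", "master_seed"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir, run_cv: bool = True) -> dict:
    """Execute every stage, write artifacts, and return the manifest dict.

    The manifest (also written as ``manifest.json``) lists, per stage, the
    artifact paths, their SHA-256 checksums and wall-clock timings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.master_seed, s) for s in STAGES},
        "stages": {},
    }

    def _stage(name: str, paths: dict[str, Path], t0: float) -> None:
        manifest["stages"][name] = {
            "artifacts": {k: str(p.name) for k, p in paths.items()},
            "checksums": {k: _sha256(p) for k, p in paths.items()},
            "seconds": round(time.perf_counter() - t0, 3),
        }

    t0 = time.perf_counter()
    records = generate_cohort(config.synthetic)
    p_spectra, p_cmanifest = out / "spectra.tsv", out / "cohort.json"
    lio.write_records_tsv(records, p_spectra)
    lio.write_cohort_manifest(config.synthetic, p_cmanifest)
    _stage("simulate", {"spectra": p_spectra, "cohort_manifest": p_cmanifest}, t0)

    t0 = time.perf_counter()
    matrix, qc = build_feature_matrix(
        records, config.binning,
        standard_mz=config.synthetic.standard_mz, window=config.standard_window,
    )
    p_matrix, p_qc = out / "matrix.csv", out / "qc.json"
    lio.write_feature_matrix(matrix, p_matrix)
    lio._write(p_qc, qc)
    _stage("preprocess", {"matrix": p_matrix, "qc": p_qc}, t0)

    t0 = time.perf_counter()
    fitted = fit_lad_pipeline(matrix, config.lad)
    p_cuts = out / "cutpoints.json"
    lio.write_cutpoints(fitted.cuts, p_cuts)
    _stage("discretize", {"cutpoints": p_cuts}, t0)

    t0 = time.perf_counter()
    p_ss = out / "support_set.json"
    lio.write_support_set(fitted.support_set, p_ss)
    _stage("supportset", {"support_set": p_ss}, t0)

    t0 = time.perf_counter()
    p_pat = out / "patterns.json"
    lio.write_patterns(fitted.candidates, p_pat, matrix.bin_centers)
    _stage("patterns", {"patterns": p_pat}, t0)

    t0 = time.perf_counter()
    p_model = out / "model.json"
    lio.write_model(fitted.model, p_model, matrix.bin_centers)
    _stage("train", {"model": p_model}, t0)

    t0 = time.perf_counter()
    results = predict_matrix(fitted.model, matrix)
    p_pred = out / "predictions.csv"
    lio.write_predictions(results, matrix.patient_ids, matrix.labels, p_pred)
    table = risk_groups(results, matrix.labels, matrix.patient_ids,
                        g=config.risk_group_count)
    p_rg = out / "risk_groups.csv"
    lio.write_risk_groups(table, p_rg)
    auc = roc_auc([r.risk for r in results], matrix.labels)
    p_auc = out / "roc.json"
    lio.write_auc(auc, p_auc)
    _stage("risk", {"predictions": p_pred, "risk_groups": p_rg, "roc": p_auc}, t0)

    if run_cv:
        t0 = time.perf_counter()
        report = cross_validate(matrix, config.lad, config.cv)
        p_cvj, p_cvc = out / "cv_report.json", out / "cv_records.csv"
        lio.write_cv_report(report, p_cvj, p_cvc)
        _stage("crossvalidate", {"cv_report": p_cvj, "cv_records": p_cvc}, t0)

    p_manifest = out / "manifest.json"
    # manifest checksum excludes timings so reruns are comparable
    stable = {
        "config": manifest["config"],
        "stage_seeds": manifest["stage_seeds"],
        "checksums": {s: v["checksums"] for s, v in manifest["stages"].items()},
    }
    manifest["run_checksum"] = hashlib.sha256(
        lio.canonical_json(stable).encode()
    ).hexdigest()
    lio._write(p_manifest, manifest)
    return manifest
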