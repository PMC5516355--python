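"""Readers and writers for every pipeline artifact.

Dialects
--------
* Peak lists: TSV with columns ``patient_id, replicate_id, label, mz,
  intensity`` — one row per peak, replicate rows contiguous, peaks sorted by
  m/z within a replicate.
* Feature matrix: CSV, UTF-8, header row mandatory, '.' decimal separator;
  first column ``patient_id``, second ``label``, remaining columns headed by
  bin centers.
* Cutpoints, support sets, patterns, models, QC and CV reports: JSON written
  canonically — fixed key order, floats at 10 significant digits — so that
  serialize -> parse -> serialize is byte-identical.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .base import ParseError, ConfigError
from .synthetic import SpectrumRecord, SyntheticConfig
from .preprocess import FeatureMatrix
from .discretize import CutpointSet
from .support import SupportSet
from .patterns import Literal, Pattern, GE, LT
from .model import LADModel, DiscriminantResult, RiskGroupTable, AUCResult
from .validate import CVReport, CVConfig

__all__ = [
    "canonical_json",
    "write_records_tsv", "read_records_tsv",
    "write_cohort_manifest",
    "write_feature_matrix", "read_feature_matrix",
    "write_cutpoints", "read_cutpoints",
    "write_support_set", "read_support_set",
    "pattern_to_dict", "pattern_from_dict",
    "write_patterns", "read_patterns",
    "write_model", "read_model",
    "render_pattern", "parse_pattern_text",
    "write_predictions", "write_risk_groups", "write_auc",
    "write_cv_report",
]


# ---------------------------------------------------------------- canonical JSON

def _fmt(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if value is None:
        return "null"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        f = float(value)
        if math.isnan(f):
            return "null"  # JSON has no NaN; null round-trips canonically
        if math.isinf(f):
            raise ConfigError("cannot serialize infinite float to JSON")
        if f == int(f) and abs(f) < 1e15:
            return f"{f:.1f}"
        return format(f, ".10g")
    if isinstance(value, str):
        return json.dumps(value, ensure_ascii=False)
    if isinstance(value, dict):
        items = ", ".join(f"{json.dumps(str(k))}: {_fmt(v)}" for k, v in value.items())
        return "{" + items + "}"
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_fmt(v) for v in value) + "]"
    if isinstance(value, np.ndarray):
        return _fmt(value.tolist())
    raise ConfigError(f"cannot serialize {type(value).__name__} to JSON")


def canonical_json(obj: Any) -> str:
    """Canonical JSON text: insertion key order, floats at 10 significant
    digits, integral floats as 'x.0'.  Idempotent under parse -> re-serialize."""
    return _fmt(obj) + "\n"


def _write(path, obj: Any) -> None:
    Path(path).write_text(canonical_json(obj), encoding="utf-8")


def _read(path) -> Any:
    return json.loads(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------- peak lists

def write_records_tsv(records: Sequence[SpectrumRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\treplicate_id\tlabel\tmz\tintensity\n")
        for rec in records:
            lab = rec.label if rec.label is not None else ""
            for mz, inten in zip(rec.mz, rec.intensity):
                fh.write(f"{rec.patient_id}\t{rec.replicate_id}\t{lab}\t"
                         f"{format(float(mz), '.10g')}\t{format(float(inten), '.10g')}\n")


def read_records_tsv(path) -> list[SpectrumRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "label": str})
    required = ["patient_id", "replicate_id", "label", "mz", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing TSV columns {missing}")
    records = []
    for (pid, rep), grp in df.groupby(["patient_id", "replicate_id"], sort=False):
        labels = grp["label"].where(grp["label"].notna(), None).unique().tolist()
        if len(labels) != 1:
            raise ParseError(f"{path}: conflicting labels for {pid}/{rep}")
        records.append(SpectrumRecord(
            patient_id=str(pid), replicate_id=int(rep),
            label=None if labels[0] in (None, "") else str(labels[0]),
            mz=grp["mz"].to_numpy(float), intensity=grp["intensity"].to_numpy(float),
        ))
    return records


def write_cohort_manifest(config: SyntheticConfig, path) -> None:
    _write(path, {"generator": "ladspectra.synthetic", "seed": config.seed,
                  "config": config.to_dict()})


# ---------------------------------------------------------------- feature matrix

def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        centers = ",".join(format(float(c), ".10g") for c in matrix.bin_centers)
        fh.write(f"patient_id,label,{centers}\n")
        for pid, lab, row in zip(matrix.patient_ids, matrix.labels, matrix.values):
            vals = ",".join(format(float(v), ".10g") for v in row)
            fh.write(f"{pid},{lab if lab is not None else ''},{vals}\n")


def read_feature_matrix(path) -> FeatureMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
        if header[:2] != ["patient_id", "label"]:
            raise ParseError(
                f"{path}:1: header must start with 'patient_id,label', got {header[:2]}"
            )
        try:
            centers = np.array([float(c) for c in header[2:]])
        except ValueError as exc:
            raise ParseError(f"{path}:1: non-numeric bin center in header: {exc}") from None
        ids, labels, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            if len(parts) != 2 + centers.size:
                raise ParseError(
                    f"{path}:{lineno}: expected {2 + centers.size} fields, got {len(parts)}"
                )
            ids.append(parts[0])
            labels.append(parts[1] if parts[1] else None)
            vals = np.empty(centers.size)
            for j, tok in enumerate(parts[2:]):
                try:
                    v = float(tok)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: column {j + 3} ({header[2 + j]}): "
                        f"non-numeric value {tok!r}"
                    ) from None
                if v < 0:
                    raise ParseError(
                        f"{path}:{lineno}: column {j + 3} ({header[2 + j]}): "
                        f"negative intensity {tok}"
                    )
                vals[j] = v
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return FeatureMatrix(patient_ids=ids, labels=labels, bin_centers=centers,
                         values=np.vstack(rows))


# ---------------------------------------------------------------- cutpoints / support

def write_cutpoints(cuts: CutpointSet, path) -> None:
    _write(path, {
        "n_features": cuts.n_features,
        "cutpoints": {str(f): cuts.cutpoints[f] for f in sorted(cuts.cutpoints)},
    })


def read_cutpoints(path) -> CutpointSet:
    d = _read(path)
    return CutpointSet(
        cutpoints={int(f): [float(c) for c in cs] for f, cs in d["cutpoints"].items()},
        n_features=int(d["n_features"]),
    )


def write_support_set(ss: SupportSet, path) -> None:
    _write(path, {
        "method": ss.method,
        "columns": [{"column": k, "feature": f, "cutpoint": c}
                    for k, (f, c) in zip(ss.column_indices, ss.descriptors)],
        "source_features": ss.source_features,
        "meta": {k: v for k, v in ss.meta.items() if k != "trace"},
    })


def read_support_set(path) -> SupportSet:
    d = _read(path)
    return SupportSet(
        column_indices=[int(c["column"]) for c in d["columns"]],
        descriptors=[(int(c["feature"]), float(c["cutpoint"])) for c in d["columns"]],
        method=str(d["method"]),
        meta=dict(d.get("meta", {})),
    )


# ---------------------------------------------------------------- patterns / model

def pattern_to_dict(p: Pattern, bin_centers: np.ndarray | None = None) -> dict:
    lits = []
    for l in p.literals:
        entry = {"feature": l.feature}
        if bin_centers is not None:
            entry["mz"] = float(bin_centers[l.feature])
        entry["cutpoint"] = l.cutpoint
        entry["direction"] = l.direction
        lits.append(entry)
    return {
        "sign": p.sign,
        "literals": lits,
        "prevalence": p.prevalence,
        "homogeneity": p.homogeneity,
        "own_covered": p.own_covered,
        "other_covered": p.other_covered,
        "own_total": p.own_total,
        "covered": sorted(p.covered),
    }


def pattern_from_dict(d: dict) -> Pattern:
    return Pattern(
        sign=str(d["sign"]),
        literals=tuple(
            Literal(int(l["feature"]), float(l["cutpoint"]), str(l["direction"]))
            for l in d["literals"]
        ),
        prevalence=float(d["prevalence"]),
        homogeneity=float(d["homogeneity"]),
        covered=frozenset(int(i) for i in d["covered"]),
        own_covered=int(d["own_covered"]),
        other_covered=int(d["other_covered"]),
        own_total=int(d["own_total"]),
    )


def write_patterns(patterns: Sequence[Pattern], path,
                   bin_centers: np.ndarray | None = None) -> None:
    _write(path, {"patterns": [pattern_to_dict(p, bin_centers) for p in patterns]})


def read_patterns(path) -> list[Pattern]:
    return [pattern_from_dict(d) for d in _read(path)["patterns"]]


def write_model(model: LADModel, path, bin_centers: np.ndarray | None = None) -> None:
    _write(path, {
        "positive_patterns": [pattern_to_dict(p, bin_centers)
                              for p in model.positive_patterns],
        "negative_patterns": [pattern_to_dict(p, bin_centers)
                              for p in model.negative_patterns],
        "meta": {k: model.meta[k] for k in sorted(model.meta)
                 if isinstance(model.meta[k], (int, float, str, bool))},
    })


def read_model(path) -> LADModel:
    d = _read(path)
    return LADModel(
        positive_patterns=[pattern_from_dict(x) for x in d["positive_patterns"]],
        negative_patterns=[pattern_from_dict(x) for x in d["negative_patterns"]],
        meta=dict(d.get("meta", {})),
    )


# ---------------------------------------------------------------- text rendering

def render_pattern(p: Pattern, bin_centers: np.ndarray) -> str:
    """Human-readable conjunction, e.g.
    ``m/z 9940 < 0.575 AND m/z 11274 >= 0.055``."""
    parts = [
        f"m/z {format(float(bin_centers[l.feature]), 'g')} {l.direction} "
        f"{format(l.cutpoint, '.10g')}"
        for l in p.literals
    ]
    return " AND ".join(parts)


def parse_pattern_text(text: str, bin_centers: np.ndarray) -> tuple[Literal, ...]:
    """Parse a rendered conjunction back into literals (inverse of
    :func:`render_pattern` for valid renderings)."""
    centers = np.asarray(bin_centers, dtype=float)
    literals = []
    for clause in text.split(" AND "):
        tok = clause.strip().split()
        if len(tok) != 4 or tok[0] != "m/z" or tok[2] not in (GE, LT):
            raise ParseError(f"cannot parse pattern clause {clause!r}")
        mz, cut = float(tok[1]), float(tok[3])
        hits = np.flatnonzero(np.isclose(centers, mz, rtol=0, atol=1e-9))
        if hits.size != 1:
            raise ParseError(f"clause {clause!r}: m/z {mz} matches "
                             f"{hits.size} bin centers")
        literals.append(Literal(int(hits[0]), cut, tok[2]))
    return tuple(literals)


# ---------------------------------------------------------------- result tables

def write_predictions(results: Sequence[DiscriminantResult],
                      patient_ids: Sequence[str],
                      labels: Sequence[str | None], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id,p,n,delta,risk,predicted,label\n")
        for pid, lab, r in zip(patient_ids, labels, results):
            fh.write(f"{pid},{r.p},{r.n},{format(r.delta, '.10g')},"
                     f"{format(r.risk, '.10g')},{r.predicted},"
                     f"{lab if lab is not None else ''}\n")


def write_risk_groups(table: RiskGroupTable, path) -> None:
    table.table.to_csv(path, index=False, float_format="%.10g")


def write_auc(res: AUCResult, path) -> None:
    _write(path, {
        "auc": res.auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
        "ci_method": res.method,
        "n_positive": res.n_positive, "n_negative": res.n_negative,
    })


def write_cv_report(report: CVReport, json_path, csv_path=None) -> None:
    recs = report.records.drop(columns=["test_ids"])
    _write(json_path, {
        "config": report.config.to_dict(),
        "aggregates": report.aggregates,
        "records": recs.replace({float("nan"): None}).to_dict(orient="records"),
    })
    if csv_path is not None:
        report.records.to_csv(csv_path, index=False, float_format="%.10g")
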