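"""RTOG 0915 compliance bands and per-metric deviation classification.

A metric band ``(lower, upper)`` is the minor-deviation interval of the
protocol: values at or below ``lower`` are per protocol, values in
``(lower, upper]`` are minor deviations, values above ``upper`` are major
deviations.  The boundary rule is deliberately strict at the lower edge
and inclusive at the upper edge — a plan printed at exactly the lower
bound passes, one at exactly the upper bound is still only a minor
deviation.

R50% and D2cm bands depend on PTV volume; the default criteria table
linearly interpolates monotone bound functions between published
(volume, band) anchors and clamps outside the anchor range.  OAR limits
are single thresholds ("dose to X cc > L Gy" is a deviation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Mapping, NamedTuple, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import PlanMetrics

PER_PROTOCOL = "per_protocol"
MINOR = "minor"
MAJOR = "major"
NOT_APPLICABLE = "not_applicable"

#: metrics entering the plan-level spillage compliance verdict
SPILLAGE_METRICS = ("r100", "r50", "d2cm_pct", "lung_v20_pct")

_EPS = 1e-9  # absorbs float noise at band boundaries


class MetricBand(NamedTuple):
    lower: float
    upper: float


@dataclass
class CriteriaTable:
    """Compliance thresholds: fixed bands, volume-dependent anchors, OAR limits."""

    r100_band: MetricBand
    v20_band: MetricBand
    r50_anchors: List[Tuple[float, MetricBand]]
    d2cm_anchors: List[Tuple[float, MetricBand]]
    oar_limits: Dict[str, float]

    def __post_init__(self) -> None:
        for name, anchors in (("r50", self.r50_anchors), ("d2cm", self.d2cm_anchors)):
            if not anchors:
                raise ValidationError(f"{name} anchors are empty")
            vols = [v for v, _ in anchors]
            if any(b <= a for a, b in zip(vols, vols[1:])):
                raise ValidationError(f"{name} anchor volumes must be strictly increasing")
            for v, band in anchors:
                if band.lower > band.upper:
                    raise ValidationError(f"invalid {name} band {band} at {v} cc")


def load_criteria(path=None) -> CriteriaTable:
    """Load a criteria file (JSON); the packaged default when path is None."""
    if path is None:
        text = resources.files("sbrtqa.data").joinpath("rtog0915_criteria.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    return CriteriaTable(
        r100_band=MetricBand(*raw["r100_band"]),
        v20_band=MetricBand(*raw["v20_band_pct"]),
        r50_anchors=[(v, MetricBand(lo, hi)) for v, lo, hi in raw["r50_anchors"]],
        d2cm_anchors=[(v, MetricBand(lo, hi)) for v, lo, hi in raw["d2cm_anchors"]],
        oar_limits={k: float(v) for k, v in raw["oar_limits_gy"].items()},
    )


def interpolate_band(criteria: CriteriaTable, metric: str, ptv_cc: float) -> MetricBand:
    """Volume-interpolated minor-deviation band for R50% or D2cm."""
    if ptv_cc <= 0:
        raise ValidationError(f"PTV volume must be > 0, got {ptv_cc}")
    if metric == "r50":
        anchors = criteria.r50_anchors
    elif metric in ("d2cm", "d2cm_pct"):
        anchors = criteria.d2cm_anchors
    else:
        raise ValidationError(f"no volume-dependent band for metric {metric!r}")
    vols = np.array([v for v, _ in anchors])
    lowers = np.array([b.lower for _, b in anchors])
    uppers = np.array([b.upper for _, b in anchors])
    # np.interp clamps outside the anchor range by construction
    return MetricBand(
        float(np.interp(ptv_cc, vols, lowers)),
        float(np.interp(ptv_cc, vols, uppers)),
    )


def classify(value: float, band: MetricBand) -> str:
    """per_protocol iff value <= lower; minor iff lower < value <= upper."""
    if value <= band.lower + _EPS:
        return PER_PROTOCOL
    if value <= band.upper + _EPS:
        return MINOR
    return MAJOR


def check_oar(value: float, limit: float) -> str:
    """Single-threshold OAR check: exceeding the limit is a deviation."""
    if limit <= 0:
        raise ValidationError(f"OAR limit must be > 0, got {limit}")
    return PER_PROTOCOL if value <= limit + _EPS else MINOR


@dataclass
class MetricResult:
    metric: str
    value: Optional[float]
    band: Optional[MetricBand]
    category: str


@dataclass
class ComplianceReport:
    """Per-metric classification plus the plan-level compliance flag."""

    patient_id: str
    results: List[MetricResult]

    @property
    def fully_compliant(self) -> bool:
        """True when no spillage metric deviates and no OAR limit is exceeded."""
        return all(
            r.category in (PER_PROTOCOL, NOT_APPLICABLE) for r in self.results
        )

    def category(self, metric: str) -> str:
        for r in self.results:
            if r.metric == metric:
                return r.category
        raise KeyError(metric)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": self.patient_id,
                "metric": r.metric,
                "value": r.value,
                "band_low": r.band.lower if r.band else np.nan,
                "band_high": r.band.upper if r.band else np.nan,
                "category": r.category,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


MetricsLike = Union[PlanMetrics, Mapping[str, float]]


def _get(metrics: MetricsLike, key: str):
    if isinstance(metrics, PlanMetrics):
        return getattr(metrics, key, None)
    return metrics.get(key)


def evaluate_plan(metrics: MetricsLike, criteria: CriteriaTable) -> ComplianceReport:
    """Classify every metric of one plan against the criteria table.

    ``metrics`` may be a :class:`~sbrtqa.metrics.PlanMetrics` or any
    mapping with the same field names (e.g. a cohort-table row).  The four
    spillage metrics and the PTV volume are required; OAR metrics are
    classified when present.
    """
    ptv_cc = _get(metrics, "ptv_cc")
    if ptv_cc is None or ptv_cc <= 0:
        raise ValidationError("ptv_cc is required for band interpolation")
    required = {
        "r100": MetricBand(*(criteria.r100_band)),
        "r50": interpolate_band(criteria, "r50", ptv_cc),
        "d2cm_pct": interpolate_band(criteria, "d2cm", ptv_cc),
        "lung_v20_pct": MetricBand(*(criteria.v20_band)),
    }
    results: List[MetricResult] = []
    for name, band in required.items():
        value = _get(metrics, name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValidationError(f"required metric {name!r} missing")
        results.append(MetricResult(name, float(value), band, classify(float(value), band)))
    for name, limit in criteria.oar_limits.items():
        value = _get(metrics, name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            results.append(MetricResult(name, None, None, NOT_APPLICABLE))
        else:
            results.append(
                MetricResult(name, float(value), MetricBand(limit, limit), check_oar(float(value), limit))
            )
    pid = _get(metrics, "patient_id") or "anon"
    return ComplianceReport(str(pid), results)
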