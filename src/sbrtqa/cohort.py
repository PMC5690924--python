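"""Radiobiology and cohort-level analysis.

Provides the linear-quadratic biologically effective dose (BED), cohort
summary statistics (AVG/STDEV rows), per-metric deviation counting, the
distance-versus-rib-dose association, and the embedded 20-patient
peripheral lung SBRT reference cohort.

The reference cohort ships as a packaged CSV transcribed from published
per-patient evaluation tables: PTV volume, prescription (54 Gy/3 fx for
patients 1-5, 50 Gy/5 fx for 6-20), the four spillage metrics with their
per-patient R50%/D2cm minor-deviation bands, OAR doses, and the rib dose
set with the 3D isocenter-to-rib distance.  The file is checksummed at
load time so silent edits surface as packaging errors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import compliance as cmp
from .errors import SbrtqaError, ValidationError

_FIXTURE_SHA256 = "d4709ed79e33af66adc8f9761e4f7e59504a9f3d5ceefb9b14713769c6b86be0"

#: Protocol reference BED3 values (Gy) displayed alongside cohort means for
#: rib maximum point dose and rib D1cc.  Stored as published constants; the
#: underlying derivation is not reproduced here.
RTOG_BED3_REFERENCE_GY = {"rib_dmax_gy": 165.0, "rib_d1cc_gy": 112.0}


@dataclass
class BEDParams:
    """Linear-quadratic parameters: alpha/beta ratio (Gy) and fraction count."""

    alpha_beta: float = 3.0
    n_fractions: int = 5

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValidationError(f"alpha/beta must be > 0, got {self.alpha_beta}")
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValidationError(f"n_fractions must be a positive int, got {self.n_fractions}")
        self.n_fractions = int(self.n_fractions)


def bed(total_dose: float, params: BEDParams) -> float:
    """Biologically effective dose, BED = n d (1 + d / (alpha/beta)).

    ``d = total_dose / n`` assumes the dose is delivered in equal
    fractions; for a dose metric (e.g. the rib Dmax) this is the standard
    uniform dose-per-fraction reading of the LQ model.
    """
    if total_dose < 0:
        raise ValidationError(f"total dose must be >= 0, got {total_dose}")
    d = total_dose / params.n_fractions
    return total_dose * (1.0 + d / params.alpha_beta)


def bed_column(cohort: pd.DataFrame, field: str, alpha_beta: float = 3.0) -> pd.Series:
    """Per-patient BED of one dose column using each patient's fractionation."""
    if field not in cohort or "n_fractions" not in cohort:
        raise ValidationError(f"cohort lacks {field!r} or n_fractions")
    return pd.Series(
        [
            bed(row[field], BEDParams(alpha_beta, int(row["n_fractions"])))
            for _, row in cohort.iterrows()
        ],
        index=cohort.index,
        name=f"bed{alpha_beta:g}_{field}",
    )


def summarize(cohort: pd.DataFrame, field: str) -> Dict[str, Optional[float]]:
    """Mean, sample SD (n-1), min and max of one cohort column."""
    if field not in cohort:
        raise ValidationError(f"unknown field {field!r}")
    vals = cohort[field].dropna().astype(float)
    if vals.size < 2:
        return {
            "mean": float(vals.mean()) if vals.size else None,
            "sd": None,
            "min": float(vals.min()) if vals.size else None,
            "max": float(vals.max()) if vals.size else None,
            "n": int(vals.size),
        }
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "n": int(vals.size),
    }


def deviation_counts(cohort: pd.DataFrame, criteria: cmp.CriteriaTable) -> Dict[str, int]:
    """Minor/major deviation counts per spillage metric plus full compliance.

    ``fully_compliant`` counts patients whose four spillage categories
    (R100%, R50%, D2cm, V20) are all per-protocol.
    """
    counts = {f"{m}_minor": 0 for m in cmp.SPILLAGE_METRICS}
    counts.update({f"{m}_major": 0 for m in cmp.SPILLAGE_METRICS})
    counts["fully_compliant"] = 0
    for _, row in cohort.iterrows():
        report = cmp.evaluate_plan(row.to_dict(), criteria)
        clean = True
        for m in cmp.SPILLAGE_METRICS:
            cat = report.category(m)
            if cat == cmp.MINOR:
                counts[f"{m}_minor"] += 1
                clean = False
            elif cat == cmp.MAJOR:
                counts[f"{m}_major"] += 1
                clean = False
        if clean:
            counts["fully_compliant"] += 1
    return counts


def distance_dose_association(
    cohort: pd.DataFrame,
    distance_field: str = "iso_to_rib_cm",
    dose_field: str = "rib_dmax_gy",
) -> Tuple[Optional[float], pd.DataFrame]:
    """Rank correlation between isocenter-to-rib distance and rib Dmax.

    Returns (Spearman rho, binned means) where the bins are the
    qualitative proximity bands < 2 cm, 2-5 cm, > 5 cm.  rho is None when
    undefined (constant input or < 3 complete pairs).
    """
    sub = cohort[[distance_field, dose_field]].dropna()
    if len(sub) < 3:
        raise ValidationError("need at least 3 patients with distance and dose")
    x = sub[distance_field].to_numpy(float)
    y = sub[dose_field].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        rho = None
    else:
        rho = float(stats.spearmanr(x, y).statistic)
    bins = pd.cut(x, [-np.inf, 2.0, 5.0, np.inf], labels=["<2 cm", "2-5 cm", ">5 cm"])
    binned = (
        pd.DataFrame({"band": bins, dose_field: y})
        .groupby("band", observed=False)[dose_field]
        .agg(["count", "mean"])
        .reset_index()
    )
    return rho, binned


def reference_cohort() -> pd.DataFrame:
    """The embedded 20-patient reference cohort (checksummed)."""
    blob = resources.files("sbrtqa.data").joinpath("cohort_fixture.csv").read_bytes()
    digest = hashlib.sha256(blob).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise SbrtqaError(
            f"cohort fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(blob))
    if len(df) != 20 or df["patient_id"].duplicated().any():
        raise SbrtqaError("cohort fixture must hold 20 unique patients")
    return df


def cohort_summary_table(cohort: pd.DataFrame, fields=None) -> pd.DataFrame:
    """AVG/STDEV summary rows for the standard metric columns."""
    if fields is None:
        fields = [
            c
            for c in cohort.columns
            if c not in ("patient_id", "total_dose_gy", "n_fractions")
            and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    rows = []
    for f in fields:
        s = summarize(cohort, f)
        rows.append({"metric": f, **s})
    return pd.DataFrame(rows)
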