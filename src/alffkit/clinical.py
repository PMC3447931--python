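"""VOI extraction and clinical correlation.

The progression rate is (40 - ALSFRS) / disease duration in months.  VOI
means are arithmetic means of the standardized ALFF within a mask, and the
association with clinical variables is the Pearson correlation with a
two-tailed Student-t p-value (uncorrected at 0.05, with an optional
Bonferroni switch).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import BrainMask, InputError, ScalarMap

__all__ = [
    "ClinicalRecord",
    "CorrelationResult",
    "progression_rate",
    "voi_mean",
    "pearson_corr",
    "correlate_vois",
    "CLINICAL_VARIABLES",
]

CLINICAL_VARIABLES = ("duration_months", "progression_rate", "alsfrs")

ALSFRS_MAX = 40.0


@dataclass
class ClinicalRecord:
    """One subject's clinical fields; patients carry ALSFRS and duration."""

    subject_id: str
    group: str
    age_years: float
    sex: str  # "M" / "F"
    handedness: str = "R"
    onset_site: str = ""
    alsfrs: Optional[float] = None
    duration_months: Optional[float] = None

    def __post_init__(self) -> None:
        if self.alsfrs is not None and not 0 <= self.alsfrs <= ALSFRS_MAX:
            raise InputError(f"ALSFRS must be in [0, {ALSFRS_MAX}], got {self.alsfrs}")
        if self.duration_months is not None and self.duration_months <= 0:
            raise InputError(f"duration must be > 0 months, got {self.duration_months}")

    @property
    def progression_rate(self) -> Optional[float]:
        if self.alsfrs is None or self.duration_months is None:
            return None
        return progression_rate(self.alsfrs, self.duration_months)


def progression_rate(alsfrs: float, duration_months: float) -> float:
    """(40 - ALSFRS) / disease duration, per month."""
    if duration_months <= 0:
        raise InputError(f"duration must be > 0, got {duration_months}")
    if not 0 <= alsfrs <= ALSFRS_MAX:
        raise InputError(f"ALSFRS must be in [0, {ALSFRS_MAX}], got {alsfrs}")
    return (ALSFRS_MAX - alsfrs) / duration_months


def voi_mean(malff: ScalarMap, voi: BrainMask) -> float:
    """Arithmetic mean of the map over the VOI voxels."""
    if voi.shape != malff.shape:
        raise InputError(f"VOI grid {voi.shape} != map grid {malff.shape}")
    return float(malff.data[voi.data].mean())


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def pearson_corr(x, y) -> CorrelationResult:
    """Sample Pearson r with two-tailed p via t = r*sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1D of equal length")
    n = x.size
    if n < 3:
        raise InputError(f"need n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("zero variance in input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p=p)


def correlate_vois(
    malff_maps: Sequence[ScalarMap],
    vois: dict,
    clinical: pd.DataFrame,
    variables: Sequence[str] = CLINICAL_VARIABLES,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Correlate per-patient VOI mean mALFF with clinical variables.

    ``malff_maps`` are the patients' maps in the same order as the rows of
    ``clinical``; ``vois`` maps a VOI name to a BrainMask.  One row per
    (VOI, variable) with r, n, p and a significance flag at two-tailed
    0.05 (uncorrected unless ``bonferroni``).
    """
    if len(malff_maps) != len(clinical):
        raise InputError("one map per clinical row required")
    if len(malff_maps) < 3:
        raise InputError("need >= 3 patients")
    missing = [v for v in variables if v not in clinical.columns]
    if missing:
        raise InputError(f"clinical table lacks columns: {missing}")
    alpha = 0.05 / (len(vois) * len(variables)) if bonferroni else 0.05
    rows = []
    for voi_name, voi in vois.items():
        means = np.array([voi_mean(m, voi) for m in malff_maps])
        for var in variables:
            res = pearson_corr(means, clinical[var].to_numpy(dtype=float))
            rows.append({
                "voi": voi_name,
                "variable": var,
                "r": res.r,
                "n": res.n,
                "p": res.p,
                "significant": res.p < alpha,
            })
    return pd.DataFrame(rows)
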