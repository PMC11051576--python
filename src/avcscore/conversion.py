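"""Linear conversion between contrast-derived calcium volume and Agatston units.

On contrast-enhanced CT the calcium burden of the aortic valve is
measured as a suprathreshold *volume* (mm^3); clinical decision
thresholds, however, are expressed in native-scan Agatston units.  The
two are linked by an ordinary-least-squares line fitted on a paired
training cohort:

    calculated Agatston = a + b * AVC_CECT(mm^3)

The shipped preset ``"paper-2024"`` carries the published constants
a = 691, b = 1.83 derived in a severe-aortic-stenosis TAVI-planning
cohort.  The intercept is deliberately free (not forced through zero):
cohorts recruited for intervention contain no calcium-free valves, so
the fitted line does not pass through the origin and transplanting the
preset to a different population or protocol is not advised — calibrate
locally with :func:`calibrate` instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConversionModel",
    "PRESETS",
    "get_preset",
    "apply_conversion",
    "calibrate",
]

logger = logging.getLogger("avcscore.conversion")


@dataclass(frozen=True)
class ConversionModel:
    """Linear volume-to-Agatston map with optional fit diagnostics."""

    intercept: float  # Agatston units
    slope: float  # Agatston units per mm^3
    r2: Optional[float] = None
    n: Optional[int] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("model coefficients must be finite")

    def predict(self, volume_mm3):
        return self.intercept + self.slope * np.asarray(volume_mm3, dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ConversionModel":
        d = json.loads(Path(path).read_text())
        return cls(**{k: d.get(k) for k in ("intercept", "slope", "r2", "n", "name")})


PRESETS: dict[str, ConversionModel] = {
    "paper-2024": ConversionModel(intercept=691.0, slope=1.83, name="paper-2024"),
}


def get_preset(name: str) -> ConversionModel:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown conversion preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def apply_conversion(volume_mm3: float, model: ConversionModel) -> float:
    """Calculated Agatston units for a contrast-derived calcium volume."""
    if volume_mm3 < 0:
        raise ValueError(f"calcium volume must be >= 0, got {volume_mm3}")
    return float(model.intercept + model.slope * volume_mm3)


def calibrate(
    cohort: pd.DataFrame, force_zero_intercept: bool = False
) -> ConversionModel:
    """Fit the volume-to-Agatston line on a paired cohort by OLS.

    ``cohort`` needs columns ``native_agatston`` (response) and
    ``cect_volume_mm3`` (regressor); at least 3 rows with non-constant
    volumes.  ``force_zero_intercept`` reproduces the through-origin
    variant used by some earlier approaches, for comparison only.
    """
    x = np.asarray(cohort["cect_volume_mm3"], dtype=float)
    y = np.asarray(cohort["native_agatston"], dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("calibration needs at least 3 paired measurements")
    if np.ptp(x) == 0:
        raise ValueError("calcium volumes are constant; slope is unidentifiable")

    if force_zero_intercept:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        resid = y - slope * x
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    else:
        fit = stats.linregress(x, y)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    logger.info(
        "calibrated conversion: a=%.3f, b=%.5f, R2=%.4f, n=%d",
        intercept,
        slope,
        r2,
        n,
    )
    return ConversionModel(intercept=intercept, slope=slope, r2=r2, n=n)
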