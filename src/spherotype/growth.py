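"""Growth quantification: brightfield area, diameter, percent of control,
absolute GI50 dose-response fits, and correlation summaries.

The dose-response model is the four-parameter logistic in log10
concentration; the absolute GI50 is the concentration at which the fitted
curve crosses 50% inhibition of the untreated control, obtained from the
relative IC50 by ``IC50_rel * ((Top - 50)/(50 - Bottom))^(1/Hill)``.  A
curve whose plateau (Top) does not exceed 50% never reaches absolute 50%
inhibition and the GI50 is reported as undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from skimage.filters import threshold_otsu

__all__ = [
    "segment_spheroid_area",
    "diameter_from_area",
    "percent_of_control",
    "DoseResponse",
    "GI50Fit",
    "four_param_logistic",
    "fit_absolute_gi50",
    "correlate",
]


def segment_spheroid_area(tl_image: np.ndarray, pixel_size_um: float
                          ) -> tuple[float, np.ndarray]:
    """Spheroid area (mm^2) from a transmitted-light image where the
    spheroid is darker than the background: Otsu threshold on the inverted
    image, fill holes, keep the largest connected component."""
    img = np.asarray(tl_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single 2D TL image")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if img.max() <= img.min():
        raise ValueError("blank image: no foreground to segment")
    inv = img.max() - img
    mask = inv > threshold_otsu(inv)
    if not mask.any():
        raise ValueError("empty segmentation mask")
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    sizes = np.bincount(labels.ravel())[1:]
    largest = mask & (labels == (int(np.argmax(sizes)) + 1))
    area_mm2 = float(largest.sum()) * (pixel_size_um / 1000.0) ** 2
    return area_mm2, largest


def diameter_from_area(area_mm2: float) -> float:
    """Equivalent-circle diameter in μm: d = 2000 * sqrt(A / pi)."""
    if area_mm2 <= 0:
        raise ValueError("area must be > 0")
    return 2000.0 * math.sqrt(area_mm2 / math.pi)


def percent_of_control(records: pd.DataFrame) -> pd.DataFrame:
    """Percent-of-control growth per (day, concentration).

    ``records`` needs columns ``day, concentration_ug_ml, area_mm2`` (an
    optional ``experiment`` column separates independent experiments, and
    an optional ``cell_line`` column is carried through).  Replicates are
    averaged within each experiment, the treated/control ratio is taken
    per day within each experiment, and ratios are then averaged across
    experiments.  ``percent_inhibition = 100 - percent_of_control``.
    """
    df = records.copy()
    for col in ("day", "concentration_ug_ml", "area_mm2"):
        if col not in df:
            raise ValueError(f"records missing column {col!r}")
    if "experiment" not in df:
        df["experiment"] = 0
    if "cell_line" not in df:
        df["cell_line"] = "all"

    results = []
    for (line, exp), grp in df.groupby(["cell_line", "experiment"]):
        means = (
            grp.groupby(["day", "concentration_ug_ml"])["area_mm2"]
            .mean()
            .reset_index()
        )
        for day, day_grp in means.groupby("day"):
            ctrl = day_grp[day_grp["concentration_ug_ml"] == 0]
            if ctrl.empty:
                raise ValueError(f"missing day-{day} control "
                                 f"({line}, experiment {exp})")
            ctrl_area = float(ctrl["area_mm2"].iloc[0])
            g = day_grp.copy()
            g["percent_of_control"] = 100.0 * g["area_mm2"] / ctrl_area
            g["cell_line"] = line
            g["experiment"] = exp
            results.append(g.drop(columns=["area_mm2"]))
    pooled = pd.concat(results, ignore_index=True)
    out = (
        pooled.groupby(["cell_line", "day", "concentration_ug_ml"])
        ["percent_of_control"].mean().reset_index()
    )
    out["percent_inhibition"] = 100.0 - out["percent_of_control"]
    return out


@dataclass(frozen=True)
class DoseResponse:
    """Percent growth inhibition vs concentration, replicates allowed
    (equal-length vectors; concentration 0 rows are ignored by the fit)."""

    concentrations_ug_ml: np.ndarray
    percent_inhibition: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_ug_ml, dtype=float)
        y = np.asarray(self.percent_inhibition, dtype=float)
        if c.shape != y.shape:
            raise ValueError("concentration/inhibition length mismatch")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "concentrations_ug_ml", c)
        object.__setattr__(self, "percent_inhibition", y)


@dataclass
class GI50Fit:
    gi50_absolute: float
    ic50_relative: float
    hill_slope: float
    top: float      # fitted plateau = Emax (% inhibition)
    bottom: float
    converged: bool
    gi50_defined: bool
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "gi50_absolute": self.gi50_absolute,
            "ic50_relative": self.ic50_relative,
            "hill_slope": self.hill_slope,
            "emax": self.top,
            "bottom": self.bottom,
            "converged": self.converged,
            "gi50_defined": self.gi50_defined,
            "message": self.message,
        }


def four_param_logistic(log10_c: np.ndarray, bottom: float, top: float,
                        log_ic50: float, hill: float) -> np.ndarray:
    """Y = Bottom + (Top - Bottom) / (1 + 10^((logIC50 - X) * Hill))."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - log10_c) * hill))


def absolute_from_relative(ic50_rel: float, top: float, bottom: float,
                           hill: float) -> float:
    """Concentration where the fitted 4PL crosses Y = 50.

    Solving Bottom + (Top - Bottom)/(1 + 10^((logIC50 - X) * Hill)) = 50
    for X gives IC50_rel * ((50 - Bottom)/(Top - 50))^(1/Hill); with
    Bottom = 0 and Top < 100 this is always >= IC50_rel (reaching an
    absolute 50% needs more drug than the curve's own midpoint).
    """
    return ic50_rel * ((50.0 - bottom) / (top - 50.0)) ** (1.0 / hill)


def fit_absolute_gi50(dr: DoseResponse) -> GI50Fit:
    """Least-squares 4PL fit of percent inhibition vs log10 concentration
    with Bottom constrained to [0, 100] and Top to [0, 100]; the absolute
    GI50 is derived from the fitted curve's crossing of 50% inhibition."""
    mask = dr.concentrations_ug_ml > 0
    c = dr.concentrations_ug_ml[mask]
    y = dr.percent_inhibition[mask]
    if np.unique(c).size < 4:
        raise ValueError("need >= 4 distinct non-zero concentrations")
    x = np.log10(c)

    top0 = float(np.clip(np.max(y), 1.0, 100.0))
    mid0 = float(np.median(x))
    p0 = (0.0, top0, mid0, 1.0)
    lo = (0.0, 0.0, x.min() - 3.0, 0.05)
    hi = (100.0, 100.0, x.max() + 3.0, 10.0)
    try:
        popt, _ = optimize.curve_fit(
            four_param_logistic, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
        converged = True
        message = ""
    except RuntimeError as exc:
        return GI50Fit(gi50_absolute=float("nan"), ic50_relative=float("nan"),
                       hill_slope=float("nan"), top=float("nan"),
                       bottom=float("nan"), converged=False,
                       gi50_defined=False, message=str(exc))
    bottom, top, log_ic50, hill = (float(v) for v in popt)
    ic50_rel = 10.0 ** log_ic50
    defined = top > 50.0 > bottom
    gi50_abs = (
        absolute_from_relative(ic50_rel, top, bottom, hill)
        if defined else float("nan")
    )
    if not defined:
        message = "fitted plateau does not cross 50% inhibition"
    return GI50Fit(gi50_absolute=gi50_abs, ic50_relative=ic50_rel,
                   hill_slope=hill, top=top, bottom=bottom,
                   converged=converged, gi50_defined=defined, message=message)


def correlate(x, y) -> tuple[float, float, float]:
    """Sample Pearson correlation with two-sided t-distribution p-value.
    Returns (r, p, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, float(res.pvalue), r * r
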