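"""Ratiometric lysosomal pH estimation.

Lysosomes are loaded with a pH-sensitive 488 nm dextran (Oregon Green) and a
pH-insensitive 555 nm loading-control dextran (Alexa Fluor 555); the
488/555 intensity ratio of each lysosome object is converted to absolute pH
through a calibration curve built from nigericin-clamped buffer standards
(pH 4–8). Linear, 3rd-order polynomial and 4-parameter-logistic calibration
models are offered; whichever is fitted must be strictly monotone in pH
over the calibration range, so inversion is a unique root find.

Downstream, per-well mean pH is the statistical unit (wells of neuron
culture, not individual lysosomes, to avoid pseudo-replication), proton
concentrations are reported in micromolar both as the mean of per-object
``10^(-pH)`` and as ``10^(-mean pH)``, and groups are compared with Welch
t-tests on per-well means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError, MonotonicityError, ValidationError

logger = logging.getLogger(__name__)

CALIBRATION_MODELS = ("linear", "cubic", "logistic4")
_MIN_POINTS = {"linear": 3, "cubic": 5, "logistic4": 5}


@dataclass
class CalibrationCurve:
    """A fitted, strictly monotone ratio ↔ pH mapping.

    ``coefficients`` are polynomial coefficients in increasing degree for
    ``linear``/``cubic`` (ratio = c0 + c1·pH + ...), or ``(bottom, top,
    mid_pH, slope)`` for the 4-parameter logistic. ``ratio_range`` is the
    image of ``ph_range`` under the curve.
    """

    model: str
    coefficients: tuple[float, ...]
    ph_range: tuple[float, float]
    ratio_range: tuple[float, float]
    r_squared: float

    def predict(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        if self.model in ("linear", "cubic"):
            return np.polynomial.polynomial.polyval(ph, self.coefficients)
        bottom, top, mid, slope = self.coefficients
        return bottom + (top - bottom) / (1.0 + np.exp(-slope * (ph - mid)))

    def invert(self, ratio: float) -> tuple[float, bool]:
        """Unique pH with curve(pH) = ratio, by bisection to 1e-6 pH.

        Ratios outside the curve's range are clamped to the nearer range
        endpoint and flagged ``in_range = False``.
        """
        lo, hi = self.ph_range
        r_lo, r_hi = float(self.predict(lo)), float(self.predict(hi))
        increasing = r_hi > r_lo
        r_min, r_max = min(r_lo, r_hi), max(r_lo, r_hi)
        if ratio < r_min or ratio > r_max:
            at_low_ratio = ratio < r_min
            ph = (lo if increasing else hi) if at_low_ratio else (hi if increasing else lo)
            return ph, False
        ph = float(optimize.brentq(lambda p: float(self.predict(p)) - ratio, lo, hi,
                                   xtol=1e-9))
        return ph, True

    def invert_many(self, ratios: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        ph = np.empty(len(ratios))
        ok = np.empty(len(ratios), dtype=bool)
        for i, r in enumerate(np.asarray(ratios, dtype=float)):
            ph[i], ok[i] = self.invert(float(r))
        return ph, ok

    def summary(self) -> str:
        coef = ", ".join(f"{c:.6g}" for c in self.coefficients)
        return (
            f"Calibration curve ({self.model})\n"
            f"  coefficients: [{coef}]\n"
            f"  pH range:     [{self.ph_range[0]:g}, {self.ph_range[1]:g}]\n"
            f"  ratio range:  [{self.ratio_range[0]:.4g}, {self.ratio_range[1]:.4g}]\n"
            f"  R^2:          {self.r_squared:.6f}"
        )


class CalibrationModel:
    """Fit a ratio-vs-pH calibration curve from buffer standards.

    Parameters
    ----------
    buffer_ph, ratio : sequences
        Known buffer pH values (within ``ph_range``) and their observed
        488/555 mean ratios (positive).
    model : {"linear", "cubic", "logistic4"}
    ph_range : (float, float)
        Valid calibration range, default (4, 8).
    """

    def __init__(self, buffer_ph: Sequence[float], ratio: Sequence[float],
                 model: str = "linear", ph_range: tuple[float, float] = (4.0, 8.0)) -> None:
        if model not in CALIBRATION_MODELS:
            raise ValidationError(f"unknown calibration model {model!r}")
        self.ph = np.asarray(buffer_ph, dtype=float)
        self.ratio = np.asarray(ratio, dtype=float)
        self.model = model
        self.ph_range = (float(ph_range[0]), float(ph_range[1]))
        if (self.ratio <= 0).any():
            raise ValidationError("calibration ratios must be positive")
        if len(self.ph) < _MIN_POINTS[model]:
            raise InsufficientDataError(
                f"{model} calibration needs >= {_MIN_POINTS[model]} points; got {len(self.ph)}"
            )

    def fit(self) -> CalibrationCurve:
        if self.model in ("linear", "cubic"):
            deg = 1 if self.model == "linear" else 3
            coef = np.polynomial.polynomial.polyfit(self.ph, self.ratio, deg)
            coefficients = tuple(float(c) for c in coef)
            fitted = np.polynomial.polynomial.polyval(self.ph, coef)
        else:
            coefficients, fitted = self._fit_logistic4()
        curve = CalibrationCurve(
            model=self.model,
            coefficients=coefficients,
            ph_range=self.ph_range,
            ratio_range=(0.0, 0.0),
            r_squared=_r2(self.ratio, np.asarray(fitted)),
        )
        self._check_monotone(curve)
        lo, hi = self.ph_range
        r_lo, r_hi = float(curve.predict(lo)), float(curve.predict(hi))
        curve.ratio_range = (min(r_lo, r_hi), max(r_lo, r_hi))
        return curve

    def _fit_logistic4(self):
        y = self.ratio
        p0 = [float(y.min()), float(y.max()), float(np.median(self.ph)), 1.0]

        def f(ph, bottom, top, mid, slope):
            return bottom + (top - bottom) / (1.0 + np.exp(-slope * (ph - mid)))

        popt, _ = optimize.curve_fit(f, self.ph, y, p0=p0, maxfev=20000)
        return tuple(float(c) for c in popt), f(self.ph, *popt)

    def _check_monotone(self, curve: CalibrationCurve) -> None:
        grid = np.linspace(*self.ph_range, 1001)
        vals = curve.predict(grid)
        d = np.diff(vals)
        if not ((d > 0).all() or (d < 0).all()):
            raise MonotonicityError(
                f"fitted {self.model} curve is not strictly monotone over "
                f"pH {self.ph_range}; consider the linear or logistic4 model"
            )


def _r2(obs: np.ndarray, fit: np.ndarray) -> float:
    ss_res = float(np.sum((obs - fit) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot


def fit_calibration(points: pd.DataFrame, model: str = "linear",
                    ph_range: tuple[float, float] = (4.0, 8.0)) -> CalibrationCurve:
    """Fit a calibration curve from a ``buffer_pH``/``mean_ratio`` table."""
    return CalibrationModel(points["buffer_pH"], points["mean_ratio"],
                            model=model, ph_range=ph_range).fit()


def invert_ratio_to_ph(ratio: float, curve: CalibrationCurve) -> tuple[float, bool]:
    """pH of one 488/555 ratio under a fitted curve (clamped + flagged out of range)."""
    return curve.invert(ratio)


def ph_to_proton_uM(ph) -> np.ndarray | float:
    """Proton concentration in micromolar: 10^(-pH) × 10^6."""
    return 10.0 ** (-np.asarray(ph, dtype=float)) * 1e6 if np.ndim(ph) else 10.0 ** (-ph) * 1e6


def proton_fold_change(ph_a: float, ph_b: float) -> float:
    """[H+] fold change of A over B from the pH difference: 10^(pH_B − pH_A)."""
    return 10.0 ** (ph_b - ph_a)


class PHAssayModel:
    """Per-lysosome pH from fluorescence objects plus a calibration curve.

    Parameters
    ----------
    objects : DataFrame
        Per-object table (``object_id, well_id, group, i488, i555``;
        optional ``background_488``/``background_555`` trigger background
        subtraction).
    curve : CalibrationCurve
    min_objects_per_well : int
        Wells with fewer in-range objects are flagged ``low_count``.
    """

    def __init__(self, objects: pd.DataFrame, curve: CalibrationCurve,
                 min_objects_per_well: int = 20) -> None:
        self.objects = objects
        self.curve = curve
        self.min_objects_per_well = int(min_objects_per_well)

    def fit(self) -> "PHAssayResults":
        d = self.objects.copy()
        i488 = d["i488"].to_numpy(dtype=float)
        i555 = d["i555"].to_numpy(dtype=float)
        if "background_488" in d.columns:
            i488 = i488 - d["background_488"].to_numpy(dtype=float)
        if "background_555" in d.columns:
            i555 = i555 - d["background_555"].to_numpy(dtype=float)
        if (i555 <= 0).any():
            raise ValidationError("background-corrected i555 must stay positive")
        d["ratio"] = i488 / i555
        ph, in_range = self.curve.invert_many(d["ratio"].to_numpy())
        d["pH"] = ph
        d["in_range"] = in_range
        d["proton_uM"] = ph_to_proton_uM(d["pH"].to_numpy())
        wells = self._well_summary(d)
        return PHAssayResults(self, d, wells)

    def _well_summary(self, d: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for (well, group), sub in d.groupby(["well_id", "group"], sort=True):
            ok = sub[sub["in_range"]]
            if len(ok) == 0:
                logger.warning("well %s excluded: no in-range objects", well)
                continue
            rows.append({
                "well_id": well,
                "group": group,
                "n_objects": len(ok),
                "mean_pH": float(ok["pH"].mean()),
                "sd_pH": float(ok["pH"].std(ddof=1)) if len(ok) > 1 else 0.0,
                "mean_proton_uM": float(ok["proton_uM"].mean()),
                "proton_uM_of_mean_pH": float(ph_to_proton_uM(ok["pH"].mean())),
                "low_count": len(ok) < self.min_objects_per_well,
            })
        return pd.DataFrame(rows)


@dataclass
class GroupPHComparison:
    """Group-level pH contrast on per-well means (Welch t-test)."""

    group_a: str
    group_b: str
    mean_ph_a: float
    sd_ph_a: float
    mean_ph_b: float
    sd_ph_b: float
    n_wells_a: int
    n_wells_b: int
    p_value: float
    #: mean over wells of per-object-averaged [H+] (micromolar)
    proton_uM_a: float
    proton_uM_b: float
    #: 10^(-group mean pH), micromolar
    proton_uM_of_mean_a: float
    proton_uM_of_mean_b: float
    #: fold change of per-well-averaged [H+], A over B
    proton_fold_change_wells: float
    #: 10^(mean pH_B − mean pH_A)
    proton_fold_change_of_means: float

    def summary(self) -> str:
        return (
            f"Lysosomal pH: {self.group_a} vs {self.group_b}\n"
            f"  {self.group_a}: pH {self.mean_ph_a:.2f} ± {self.sd_ph_a:.2f}"
            f" ({self.n_wells_a} wells), [H+] ≈ {self.proton_uM_a:.1f} μM"
            f" (10^-mean pH: {self.proton_uM_of_mean_a:.1f} μM)\n"
            f"  {self.group_b}: pH {self.mean_ph_b:.2f} ± {self.sd_ph_b:.2f}"
            f" ({self.n_wells_b} wells), [H+] ≈ {self.proton_uM_b:.1f} μM"
            f" (10^-mean pH: {self.proton_uM_of_mean_b:.1f} μM)\n"
            f"  proton fold change (A/B): {self.proton_fold_change_wells:.2f}"
            f" (from mean pH: {self.proton_fold_change_of_means:.2f})\n"
            f"  Welch p (well means): {self.p_value:.3g}"
        )


class PHAssayResults:
    """Per-object pH calls and per-well summaries."""

    def __init__(self, model: PHAssayModel, per_object: pd.DataFrame,
                 wells: pd.DataFrame) -> None:
        self.model = model
        self.per_object = per_object
        self.wells = wells

    def group_compare(self, group_a: str, group_b: str) -> GroupPHComparison:
        """Welch t-test on per-well mean pH; needs >= 3 wells per group."""
        wa = self.wells[self.wells["group"] == group_a]
        wb = self.wells[self.wells["group"] == group_b]
        if len(wa) < 3 or len(wb) < 3:
            raise InsufficientDataError("group comparison needs >= 3 wells per group")
        tt = stats.ttest_ind(wa["mean_pH"], wb["mean_pH"], equal_var=False)
        mean_a, mean_b = float(wa["mean_pH"].mean()), float(wb["mean_pH"].mean())
        return GroupPHComparison(
            group_a=group_a, group_b=group_b,
            mean_ph_a=mean_a, sd_ph_a=float(wa["mean_pH"].std(ddof=1)),
            mean_ph_b=mean_b, sd_ph_b=float(wb["mean_pH"].std(ddof=1)),
            n_wells_a=len(wa), n_wells_b=len(wb),
            p_value=float(tt.pvalue),
            proton_uM_a=float(wa["mean_proton_uM"].mean()),
            proton_uM_b=float(wb["mean_proton_uM"].mean()),
            proton_uM_of_mean_a=float(ph_to_proton_uM(mean_a)),
            proton_uM_of_mean_b=float(ph_to_proton_uM(mean_b)),
            proton_fold_change_wells=float(wa["mean_proton_uM"].mean() / wb["mean_proton_uM"].mean()),
            proton_fold_change_of_means=proton_fold_change(mean_a, mean_b),
        )

    def summary(self) -> str:
        lines = ["pH assay summary",
                 f"  objects: {len(self.per_object)}"
                 f" ({int(self.per_object['in_range'].sum())} in calibration range)",
                 f"  wells:   {len(self.wells)}"]
        for grp, sub in self.wells.groupby("group"):
            lines.append(
                f"  {grp}: mean pH {sub['mean_pH'].mean():.3f}"
                f" ± {sub['mean_pH'].std(ddof=1):.3f} across {len(sub)} wells"
            )
        return "\n".join(lines)
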