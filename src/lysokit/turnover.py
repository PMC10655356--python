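"""Dynamic-SILAC turnover kinetics.

After switching post-mitotic neurons to heavy-lysine medium, pre-existing
(light) protein decays while newly synthesized (heavy) protein accumulates.
Under first-order kinetics with degradation rate constant ``k`` the light
fraction at time ``t`` is ``exp(-k t)``, so the heavy-to-light ratio is

    Ψ(t) = H/L = exp(k t) - 1,

which inverts to the single-time-point half-life estimator

    t_1/2 = t_s · ln 2 / ln(1 + Ψ),

with ``t_s`` the sampling time after the medium switch. No correction for
amino-acid recycling is applied anywhere in this module (recycling is minor
in culture), and no dilution-by-division correction is needed because the
design targets post-mitotic neurons.

Two estimators are provided:

* :func:`single_timepoint_half_life` — the closed form above at one
  sampling time (96 h in the study design);
* :func:`fit_first_order_decay` — nonlinear least squares of the observed
  light fraction ``L/(L+H)`` against ``exp(-k t)`` over a multi-day course
  (1, 2, 4, 6 days in the study design), reporting R² on the fraction scale.

Peptide-level half-lives are aggregated to apparent protein half-lives by
averaging the finite, uncensored half-lives of unique peptides, per
biological replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError, InsufficientOverlapError, ValidationError

LN2 = math.log(2.0)

#: censoring labels
CENSOR_NONE = "none"
CENSOR_TOO_FAST = "too_fast"
CENSOR_TOO_SLOW = "too_slow"
CENSOR_MISSING = "missing"


@dataclass
class LabelRatio:
    """Heavy-to-light label ratio of one peptide observation.

    ``psi`` is H/L (NaN when undefined); ``heavy_fraction`` is
    θ = H/(H+L); ``censored`` marks the degenerate cases: L = 0 with H > 0
    means turnover was complete before sampling (``too_fast``), H = L = 0 is
    ``missing``.
    """

    psi: float
    heavy_fraction: float
    time_h: float
    censored: str = CENSOR_NONE


def label_ratio(intensity_light: float, intensity_heavy: float, time_h: float = float("nan")) -> LabelRatio:
    """Compute Ψ = H/L and θ = H/(H+L) for one observation."""
    if intensity_light < 0 or intensity_heavy < 0:
        raise ValidationError("intensities must be non-negative")
    if intensity_light == 0 and intensity_heavy == 0:
        return LabelRatio(float("nan"), float("nan"), time_h, CENSOR_MISSING)
    if intensity_light == 0:
        return LabelRatio(float("inf"), 1.0, time_h, CENSOR_TOO_FAST)
    psi = intensity_heavy / intensity_light
    theta = intensity_heavy / (intensity_heavy + intensity_light)
    return LabelRatio(psi, theta, time_h)


@dataclass
class HalfLifeEstimate:
    """A peptide- or protein-level half-life with its provenance.

    ``half_life_days`` may be ``inf`` (no measurable decay, ``too_slow``).
    ``r_squared`` is populated only by the multi-time-point fit.
    ``half_life_days * rate_k_per_day == ln 2`` whenever both are finite.
    """

    subject_id: str
    level: str  # "peptide" | "protein"
    method: str  # "single_timepoint" | "multi_timepoint"
    half_life_days: float
    rate_k_per_day: float
    r_squared: float | None = None
    n_points: int = 1
    censored: str = CENSOR_NONE


def single_timepoint_half_life(
    psi: float,
    sampling_time_h: float,
    subject_id: str = "",
    fast_censor_factor: float = 20.0,
) -> HalfLifeEstimate:
    """Half-life from one heavy-to-light ratio: t_1/2 = t_s·ln2/ln(1+Ψ).

    Ψ = 0 (no heavy signal) yields an infinite half-life flagged
    ``too_slow``. Ratios implying a half-life below ``t_s / fast_censor_factor``
    are outside the single-time-point dynamic range and flagged ``too_fast``.
    The estimate is strictly decreasing in Ψ.
    """
    if sampling_time_h <= 0:
        raise ValidationError("sampling_time_h must be positive")
    if not np.isfinite(psi) or psi < 0:
        raise ValidationError(f"psi must be finite and >= 0; got {psi}")
    ts_days = sampling_time_h / 24.0
    if psi == 0.0:
        return HalfLifeEstimate(subject_id, "peptide", "single_timepoint",
                                float("inf"), 0.0, None, 1, CENSOR_TOO_SLOW)
    half_life_days = ts_days * LN2 / math.log1p(psi)
    k = LN2 / half_life_days
    censored = CENSOR_TOO_FAST if half_life_days < ts_days / fast_censor_factor else CENSOR_NONE
    return HalfLifeEstimate(subject_id, "peptide", "single_timepoint",
                            half_life_days, k, None, 1, censored)


def fit_first_order_decay(
    times_h: Sequence[float],
    light_fractions: Sequence[float],
    subject_id: str = "",
) -> HalfLifeEstimate:
    """Least-squares fit of light_fraction(t) = exp(-k t) over a time course.

    Requires >= 3 distinct timepoints. The rate is initialized from a
    log-linear regression of -ln(fraction) on time and refined by nonlinear
    least squares on the fraction scale; R² is computed on the fraction
    scale. If the data show no decay (initial slope <= 0) the estimate is
    flagged ``too_slow`` with an infinite half-life.
    """
    t = np.asarray(times_h, dtype=float) / 24.0  # days
    f = np.asarray(light_fractions, dtype=float)
    ok = np.isfinite(t) & np.isfinite(f)
    t, f = t[ok], f[ok]
    if len(np.unique(t)) < 3:
        raise InsufficientDataError(
            f"decay fit needs >= 3 distinct timepoints; got {len(np.unique(t))}"
        )
    if (f < 0).any():
        raise ValidationError("light fractions must be non-negative")

    # log-linear initialization on strictly positive fractions
    pos = f > 0
    fp = np.clip(f[pos], 1e-12, None)
    slope = (
        float(np.polyfit(t[pos], -np.log(fp), 1)[0]) if pos.sum() >= 2 else float("nan")
    )
    if not np.isfinite(slope) or slope <= 0:
        return HalfLifeEstimate(subject_id, "peptide", "multi_timepoint",
                                float("inf"), 0.0, _r_squared(f, np.ones_like(f)),
                                len(t), CENSOR_TOO_SLOW)
    k0 = slope
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, k: np.exp(-k * tt), t, f, p0=[k0],
            bounds=(1e-12, np.inf), maxfev=10000,
        )
        k = float(popt[0])
    except RuntimeError:
        k = k0
    fitted = np.exp(-k * t)
    r2 = _r_squared(f, fitted)
    return HalfLifeEstimate(subject_id, "peptide", "multi_timepoint",
                            LN2 / k, k, r2, len(t), CENSOR_NONE)


def _r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else float("-inf")
    return 1.0 - ss_res / ss_tot


def peptide_to_protein(
    estimates: Iterable[HalfLifeEstimate],
    subject_id: str = "",
) -> HalfLifeEstimate | None:
    """Average uncensored finite peptide half-lives into an apparent protein half-life.

    Censored or infinite peptide estimates are excluded; if none remain the
    protein value is missing (``None``), never zero. The mean is
    order-invariant by construction.
    """
    values = [e.half_life_days for e in estimates
              if e.censored == CENSOR_NONE and np.isfinite(e.half_life_days)]
    methods = {e.method for e in estimates}
    method = methods.pop() if len(methods) == 1 else "mixed"
    if not values:
        return None
    mean = float(np.mean(values))
    return HalfLifeEstimate(subject_id, "protein", method, mean, LN2 / mean,
                            None, len(values), CENSOR_NONE)


# ---------------------------------------------------------------------------
# Model / Results surface over a tidy peptide table
# ---------------------------------------------------------------------------

class HalfLifeModel:
    """Protein half-life estimation from a tidy peptide observation table.

    Parameters
    ----------
    peptides : DataFrame
        Tidy table as produced by :func:`lysokit.io.read_peptide_table` /
        :func:`lysokit.simulate.generate_dsilac` (columns
        ``peptide_sequence, protein_id, group, replicate, time_h,
        intensity_light, intensity_heavy, missed_cleavages, is_unique``).
    sampling_time_h : float
        Sampling time used by the single-time-point estimator (96 h default).
    exclude_missed_cleavages : bool
        Drop peptides with missed cleavages before ratio computation
        (default True: with heavy-lysine labeling, multi-lysine peptides
        carry mixed label states).
    fast_censor_factor : float
        Single-time-point estimates below ``t_s / factor`` are censored.
    """

    def __init__(
        self,
        peptides: pd.DataFrame,
        sampling_time_h: float = 96.0,
        exclude_missed_cleavages: bool = True,
        fast_censor_factor: float = 20.0,
    ) -> None:
        self.sampling_time_h = float(sampling_time_h)
        self.fast_censor_factor = float(fast_censor_factor)
        data = peptides
        if exclude_missed_cleavages and "missed_cleavages" in data.columns:
            data = data[data["missed_cleavages"] == 0]
        self.data = data.reset_index(drop=True)

    # -- fitting -----------------------------------------------------------

    def fit(self, method: str = "single_timepoint") -> "HalfLifeResults":
        if method == "single_timepoint":
            peptide_df = self._fit_single()
        elif method == "multi_timepoint":
            peptide_df = self._fit_multi()
        else:
            raise ValidationError(f"unknown method {method!r}")
        protein_df = self._aggregate(peptide_df)
        return HalfLifeResults(self, method, peptide_df, protein_df)

    def _fit_single(self) -> pd.DataFrame:
        d = self.data[np.isclose(self.data["time_h"], self.sampling_time_h)]
        if d.empty:
            raise InsufficientDataError(
                f"no observations at sampling time {self.sampling_time_h} h"
            )
        L = d["intensity_light"].to_numpy(dtype=float)
        H = d["intensity_heavy"].to_numpy(dtype=float)
        ts_days = self.sampling_time_h / 24.0
        psi = np.full(len(d), np.nan)
        half = np.full(len(d), np.nan)
        cens = np.full(len(d), CENSOR_NONE, dtype=object)
        both_zero = (L == 0) & (H == 0)
        no_light = (L == 0) & (H > 0)
        no_heavy = (H == 0) & (L > 0)
        regular = (L > 0) & (H > 0)
        cens[both_zero] = CENSOR_MISSING
        cens[no_light] = CENSOR_TOO_FAST
        cens[no_heavy] = CENSOR_TOO_SLOW
        psi[regular] = H[regular] / L[regular]
        psi[no_heavy] = 0.0
        half[no_heavy] = np.inf
        half[regular] = ts_days * LN2 / np.log1p(psi[regular])
        too_fast = regular & (half < ts_days / self.fast_censor_factor)
        cens[too_fast] = CENSOR_TOO_FAST
        out = pd.DataFrame({
            "subject_id": d["peptide_sequence"].to_numpy(),
            "protein_id": d["protein_id"].to_numpy(),
            "group": d["group"].to_numpy(),
            "replicate": d["replicate"].to_numpy(),
            "is_unique": d["is_unique"].to_numpy(),
            "level": "peptide",
            "method": "single_timepoint",
            "psi": psi,
            "half_life_days": half,
            "rate_k_per_day": np.where(np.isfinite(half) & (half > 0), LN2 / half, 0.0),
            "r_squared": np.nan,
            "n_points": 1,
            "censored": cens,
        })
        return out

    def _fit_multi(self) -> pd.DataFrame:
        d = self.data.copy()
        total = d["intensity_light"] + d["intensity_heavy"]
        with np.errstate(invalid="ignore", divide="ignore"):
            d["light_fraction"] = np.where(total > 0, d["intensity_light"] / total, np.nan)
        rows = []
        keys = ["peptide_sequence", "protein_id", "group", "replicate", "is_unique"]
        for (seq, prot, grp, rep, uniq), sub in d.groupby(keys, sort=True):
            sub = sub.dropna(subset=["light_fraction"])
            if sub["time_h"].nunique() < 3:
                continue
            est = fit_first_order_decay(sub["time_h"], sub["light_fraction"], subject_id=seq)
            rows.append({
                "subject_id": seq, "protein_id": prot, "group": grp,
                "replicate": rep, "is_unique": uniq, "level": "peptide",
                "method": "multi_timepoint", "psi": np.nan,
                "half_life_days": est.half_life_days,
                "rate_k_per_day": est.rate_k_per_day,
                "r_squared": est.r_squared, "n_points": est.n_points,
                "censored": est.censored,
            })
        if not rows:
            raise InsufficientDataError("no peptide had >= 3 quantified timepoints")
        return pd.DataFrame(rows)

    def _aggregate(self, peptide_df: pd.DataFrame) -> pd.DataFrame:
        """Per (protein, group, replicate) mean of uncensored unique-peptide half-lives."""
        usable = peptide_df[
            peptide_df["is_unique"]
            & (peptide_df["censored"] == CENSOR_NONE)
            & np.isfinite(peptide_df["half_life_days"])
        ]
        grouped = usable.groupby(["protein_id", "group", "replicate"], sort=True)
        agg = grouped["half_life_days"].agg(["mean", "size"]).reset_index()
        agg = agg.rename(columns={"mean": "half_life_days", "size": "n_points"})
        agg["subject_id"] = agg["protein_id"]
        agg["level"] = "protein"
        agg["method"] = peptide_df["method"].iloc[0]
        agg["rate_k_per_day"] = LN2 / agg["half_life_days"]
        agg["r_squared"] = np.nan
        agg["censored"] = CENSOR_NONE
        cols = ["subject_id", "protein_id", "group", "replicate", "level", "method",
                "half_life_days", "rate_k_per_day", "r_squared", "n_points", "censored"]
        return agg[cols]


class HalfLifeResults:
    """Peptide- and protein-level half-life estimates from :class:`HalfLifeModel`."""

    def __init__(self, model: HalfLifeModel, method: str,
                 peptide_estimates: pd.DataFrame, protein_estimates: pd.DataFrame) -> None:
        self.model = model
        self.method = method
        self.peptide_estimates = peptide_estimates
        self.protein_estimates = protein_estimates

    def protein_half_lives(self, group: str | None = None) -> pd.Series:
        """Mean protein half-life across replicates (optionally one group)."""
        d = self.protein_estimates
        if group is not None:
            d = d[d["group"] == group]
        return d.groupby("protein_id")["half_life_days"].mean()

    def halflife_matrix(self, groups: Sequence[str] | None = None) -> tuple[pd.DataFrame, dict]:
        """Protein × sample matrix of per-replicate half-lives.

        Sample columns are ``{group}_{replicate}``; returns the matrix and
        the sample→group map, the inputs of the differential-turnover model.
        """
        d = self.protein_estimates
        if groups is not None:
            d = d[d["group"].isin(groups)]
        d = d.assign(sample=d["group"].astype(str) + "_" + d["replicate"].astype(str))
        mat = d.pivot_table(index="protein_id", columns="sample",
                            values="half_life_days", aggfunc="mean")
        group_of = dict(zip(d["sample"], d["group"]))
        return mat, group_of

    def result_table(self) -> pd.DataFrame:
        """Long-format TSV-ready table of all estimates (peptide + protein)."""
        return pd.concat([self.peptide_estimates.drop(columns=["psi"], errors="ignore"),
                          self.protein_estimates], ignore_index=True)

    def summary(self) -> str:
        prot = self.protein_estimates
        lines = [
            "Half-life estimation summary",
            f"  method:               {self.method}",
            f"  sampling time:        {self.model.sampling_time_h:g} h",
            f"  peptide estimates:    {len(self.peptide_estimates)}"
            f" ({int((self.peptide_estimates['censored'] != CENSOR_NONE).sum())} censored)",
            f"  protein estimates:    {len(prot)}"
            f" across {prot['protein_id'].nunique()} proteins",
        ]
        for grp, sub in prot.groupby("group"):
            med = sub.groupby("protein_id")["half_life_days"].mean().median()
            lines.append(f"  median protein half-life [{grp}]: {med:.3f} days")
        return "\n".join(lines)


@dataclass
class EstimatorComparison:
    """Agreement between multi- and single-time-point protein half-lives."""

    pearson_r: float
    slope: float
    n_shared: int
    table: pd.DataFrame

    def summary(self) -> str:
        return (
            "Estimator comparison (log10 half-lives)\n"
            f"  shared proteins: {self.n_shared}\n"
            f"  Pearson r:       {self.pearson_r:.4f}\n"
            f"  slope:           {self.slope:.4f}"
        )


def compare_estimators(multi: pd.Series, single: pd.Series,
                       min_shared: int = 10) -> EstimatorComparison:
    """Correlate protein half-lives from the decay fit and the single-point formula.

    Both inputs are protein-indexed half-lives in days. Pearson r and the
    concordance slope are computed on log10 half-lives over the shared,
    finite, positive subset.
    """
    joined = pd.concat({"multi": multi, "single": single}, axis=1, join="inner")
    joined = joined[np.isfinite(joined).all(axis=1) & (joined > 0).all(axis=1)]
    if len(joined) < min_shared:
        raise InsufficientOverlapError(
            f"only {len(joined)} proteins shared between estimators (need >= {min_shared})"
        )
    x = np.log10(joined["multi"].to_numpy())
    y = np.log10(joined["single"].to_numpy())
    r = float(stats.pearsonr(x, y).statistic)
    slope = float(np.polyfit(x, y, 1)[0])
    return EstimatorComparison(r, slope, len(joined), joined.reset_index())
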