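"""Three-phase NDVI development model on a heading-centred thermal-time axis.

The canopy cycle is modelled in thermal time (degree days above a 0 degC base,
accumulated from sowing and centred so the heading date sits at 0 degC days):

* growing phase      f(TT) = a1*TT + b1        (sowing -> NDVI maximum)
* flowering plateau  g(TT) = a2*TT + b2        (NDVI maximum -> senescence onset)
* senescence         h(TT) = NDVI_final + NDVI_amplitude / (1 + exp(a3*TT + b3))

NDVI_final is the lowest post-peak NDVI observed before harvest and
NDVI_amplitude the drop from the flowering line at the phase boundary down to
NDVI_final; both are held fixed while (a3, b3) are fitted by nonlinear least
squares. Stay-green statistics follow from the logistic quantiles:

    TFN90 = (-ln 9 - b3)/a3   onset, 90% of the amplitude remaining
    TFN50 = -b3/a3            mid-senescence
    TFN10 = (ln 9 - b3)/a3    end of the rapid phase
    TFN1  = (ln 99 - b3)/a3   end of senescence

and phase areas integrate the fitted curves: GPA over the growing phase, FPA
over the flowering plateau, SPA over the senescence curve (closed-form
antiderivative), DPA = FPA + SPA.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .data import TrialDataError, WeatherSeries

LN9 = math.log(9.0)
LN99 = math.log(99.0)

#: remaining-amplitude fraction -> trait name
TFN_FRACTIONS = {0.90: "TFN90", 0.50: "TFN50", 0.10: "TFN10", 0.01: "TFN1"}

MIN_OBSERVATIONS = 8          # series below this are never fitted
MIN_SENESCENCE_POINTS = 3


class PhenologyError(ValueError):
    pass


@dataclass
class ThermalTimeAxis:
    """Date -> cumulative thermal time (base 0 degC), centred on heading."""

    location: str
    dates: list[dt.date]
    tt: np.ndarray                 # heading-centred degree days
    heading_reference: float       # cumulative TT at heading (before centring)

    def tt_of(self, date: dt.date) -> float:
        i = (date - self.dates[0]).days
        if i < 0 or i >= len(self.dates):
            raise PhenologyError(
                f"date {date} outside thermal axis coverage "
                f"[{self.dates[0]}, {self.dates[-1]}]"
            )
        return float(self.tt[i])

    @property
    def tt_sowing(self) -> float:
        return float(self.tt[0])


def build_thermal_axis(weather: WeatherSeries, sowing_date: dt.date,
                       heading_date: dt.date, *,
                       base_temperature: float = 0.0) -> ThermalTimeAxis:
    """Accumulate max(daily mean temperature - base, 0) from sowing; centre at heading.

    TT(d) = sum over sowing..d of max((tmin+tmax)/2 - base, 0), then shifted so
    TT(heading) = 0. The sowing day itself contributes, so TT(sowing) is one
    day's warmth below zero of the uncentred scale.
    """
    end = weather.frame["date"].iloc[-1]
    sub = weather.window(sowing_date, end)
    if not (sowing_date <= heading_date <= end):
        raise PhenologyError(
            f"heading date {heading_date} outside weather coverage"
        )
    tmean = (sub["tmin"].to_numpy() + sub["tmax"].to_numpy()) / 2.0
    daily = np.maximum(tmean - base_temperature, 0.0)
    cum = np.cumsum(daily)
    ref = float(cum[(heading_date - sowing_date).days])
    dates = list(sub["date"])
    return ThermalTimeAxis(weather.location, dates, cum - ref, ref)


@dataclass
class NDVISeries:
    """Per-plot NDVI observations on a heading-centred thermal-time axis."""

    plot_id: str
    tt: np.ndarray
    ndvi: np.ndarray
    tt_sowing: float

    def __post_init__(self) -> None:
        self.tt = np.asarray(self.tt, dtype=float)
        self.ndvi = np.asarray(self.ndvi, dtype=float)
        if self.tt.shape != self.ndvi.shape:
            raise PhenologyError(f"{self.plot_id}: tt/ndvi length mismatch")
        if np.any(np.diff(self.tt) < 0):
            raise PhenologyError(f"{self.plot_id}: tt must be sorted ascending")
        if np.any((self.ndvi < -0.1) | (self.ndvi > 1.0)):
            raise PhenologyError(f"{self.plot_id}: NDVI outside [-0.1, 1]")

    def __len__(self) -> int:
        return len(self.tt)


@dataclass
class PhenologyModel:
    plot_id: str
    a1: float = np.nan
    b1: float = np.nan
    a2: float = np.nan
    b2: float = np.nan
    a3: float = np.nan
    b3: float = np.nan
    ndvi_final: float = np.nan
    ndvi_amplitude: float = np.nan
    tt_sowing: float = np.nan
    tt_nmax: float = np.nan
    tt_flower_end: float = np.nan
    r_growing: float = np.nan
    r_flowering: float = np.nan
    r_senescence: float = np.nan
    senescence_available: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class PhenologyTraits:
    plot_id: str
    nmax: float = np.nan
    tfn90: float = np.nan
    tfn50: float = np.nan
    tfn10: float = np.nan
    tfn1: float = np.nan
    gpa: float = np.nan
    fpa: float = np.nan
    spa: float = np.nan
    dpa: float = np.nan
    ta: float = np.nan


# ---------------------------------------------------------------------------
# Curve primitives


def logistic_ndvi(tt: np.ndarray, a3: float, b3: float,
                  ndvi_final: float, ndvi_amplitude: float) -> np.ndarray:
    """h(TT); evaluated through expit for overflow safety."""
    return ndvi_final + ndvi_amplitude * expit(-(a3 * np.asarray(tt, float) + b3))


def logistic_antiderivative(t: float, a3: float, b3: float,
                            ndvi_final: float, ndvi_amplitude: float) -> float:
    """H(t) = final*t + amplitude*(t - ln(1 + e^(a3 t + b3))/a3)."""
    return float(ndvi_final * t
                 + ndvi_amplitude * (t - np.logaddexp(0.0, a3 * t + b3) / a3))


def _pearson_fit_r(fitted: np.ndarray, observed: np.ndarray) -> float:
    """|Pearson r| between fitted and observed; 1.0 for a 2-point exact fit."""
    if len(observed) < 2:
        return np.nan
    sf, so = np.std(fitted), np.std(observed)
    if sf == 0 or so == 0:
        # constant fit: perfect iff observations constant and equal
        return 1.0 if np.allclose(fitted, observed) else 0.0
    return float(abs(np.corrcoef(fitted, observed)[0, 1]))


def fit_line(tt: np.ndarray, ndvi: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least-squares line; returns (slope, intercept, |r| fit quality)."""
    tt = np.asarray(tt, float)
    ndvi = np.asarray(ndvi, float)
    if len(tt) < 2:
        raise PhenologyError("need >= 2 points for a line fit")
    if np.ptp(tt) == 0:
        raise PhenologyError("all thermal times identical; line undefined")
    slope, intercept = np.polyfit(tt, ndvi, 1)
    r = _pearson_fit_r(slope * tt + intercept, ndvi)
    return float(slope), float(intercept), r


fit_growing = fit_line
fit_flowering = fit_line


@dataclass
class SenescenceFit:
    a3: float
    b3: float
    r: float
    sse: float
    converged: bool


# deterministic multi-start jitter factors on the a3 initial value
_START_FACTORS = (1.0, 0.5, 1.5, 0.75, 1.25)


def _plausible_midpoint(a3: float, b3: float, tt_sen: np.ndarray) -> bool:
    """Reject runaway logistic fits: the midpoint must sit in or near the
    senescence window (within half the window span on either side)."""
    if not np.isfinite(a3) or a3 <= 0:
        return False
    mid = -b3 / a3
    span = float(tt_sen[-1] - tt_sen[0])
    return tt_sen[0] - 0.5 * span <= mid <= tt_sen[-1] + 0.5 * span


def fit_senescence(tt: np.ndarray, ndvi: np.ndarray, ndvi_final: float,
                   ndvi_amplitude: float,
                   init: tuple[float, float] | None = None,
                   n_starts: int = len(_START_FACTORS)) -> SenescenceFit:
    """Fit (a3, b3) of the logistic decline with final/amplitude held fixed.

    Initialisation: a3 = 4/span of the senescence thermal times, b3 chosen so
    the midpoint sits at the median tt; five deterministic restarts jitter a3
    before the fit is declared failed. a3 is constrained positive.
    """
    tt = np.asarray(tt, float)
    ndvi = np.asarray(ndvi, float)
    if len(tt) < 2:
        raise PhenologyError("need >= 2 senescence points")
    if ndvi_amplitude <= 0:
        raise PhenologyError("ndvi_amplitude must be positive")

    span = np.ptp(tt)
    if span == 0:
        raise PhenologyError("all senescence thermal times identical")
    a3_base = init[0] if init is not None else 4.0 / span
    med = float(np.median(tt))

    def residuals(p: np.ndarray) -> np.ndarray:
        return logistic_ndvi(tt, p[0], p[1], ndvi_final, ndvi_amplitude) - ndvi

    best: SenescenceFit | None = None
    for fac in _START_FACTORS[:n_starts]:
        a0 = a3_base * fac
        b0 = init[1] if (init is not None and fac == 1.0) else -a0 * med
        try:
            res = least_squares(residuals, x0=[a0, b0],
                                bounds=([1e-8, -np.inf], [np.inf, np.inf]),
                                ftol=1e-14, xtol=1e-14, gtol=1e-14)
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        fit = SenescenceFit(
            a3=float(res.x[0]), b3=float(res.x[1]),
            r=_pearson_fit_r(
                logistic_ndvi(tt, res.x[0], res.x[1], ndvi_final, ndvi_amplitude),
                ndvi),
            sse=sse, converged=bool(res.success))
        if fit.converged and (best is None or fit.sse < best.sse):
            best = fit
        if best is not None and best.sse < 1e-12:
            break
    if best is None:
        return SenescenceFit(np.nan, np.nan, np.nan, np.inf, False)
    return best


# ---------------------------------------------------------------------------
# Phase segmentation


@dataclass
class Segmentation:
    growing: np.ndarray          # indices into the series, includes the peak
    flowering: np.ndarray        # peak + early post-peak points
    senescence: np.ndarray
    tt_nmax: float
    tt_flower_end: float
    available: bool
    note: str = ""


def segment_phases(series: NDVISeries, *,
                   rule: str = "joint_sse") -> Segmentation:
    """Assign observations to the three phases.

    Growing runs up to and including the NDVI maximum. The flowering /
    senescence breakpoint among post-peak points is found by exhaustive
    search minimising the summed squared error of a line on the left and the
    logistic on the right (``rule='joint_sse'``, deterministic). The
    alternative ``rule='logistic_all'`` fits the logistic to all post-peak
    points and cuts at the 99%-remaining quantile. Fewer than 3 post-peak
    points leaves the senescence side unavailable.
    """
    n = len(series)
    if n < MIN_OBSERVATIONS:
        return Segmentation(np.arange(n), np.array([], int), np.array([], int),
                            np.nan, np.nan, False,
                            f"only {n} observations (<{MIN_OBSERVATIONS})")
    peak = int(np.argmax(series.ndvi))
    growing = np.arange(peak + 1)
    post = np.arange(peak + 1, n)
    tt_nmax = float(series.tt[peak])
    if len(post) < MIN_SENESCENCE_POINTS:
        return Segmentation(growing, np.array([], int), np.array([], int),
                            tt_nmax, np.nan, False,
                            f"only {len(post)} post-peak points")

    if rule == "logistic_all":
        return _segment_logistic_all(series, growing, post, peak, tt_nmax)
    if rule != "joint_sse":
        raise PhenologyError(f"unknown segmentation rule {rule!r}")

    tt, ndvi = series.tt, series.ndvi
    final = float(np.min(ndvi[post]))
    best = None
    # flowering keeps the peak plus >=2 post-peak points; senescence >=3
    lo = 2 if len(post) >= 5 else 1
    for s in range(lo, len(post) - MIN_SENESCENCE_POINTS + 1):
        fl = np.concatenate(([peak], post[:s]))
        se = post[s:]
        try:
            a2, b2, _ = fit_line(tt[fl], ndvi[fl])
        except PhenologyError:
            continue
        ttfe = float(tt[post[s - 1]])
        amp = (a2 * ttfe + b2) - final
        if amp <= 0:
            continue
        sen_fit = fit_senescence(tt[se], ndvi[se], final, amp, n_starts=2)
        if not sen_fit.converged or \
                not _plausible_midpoint(sen_fit.a3, sen_fit.b3, tt[se]):
            continue
        sse_left = float(np.sum((a2 * tt[fl] + b2 - ndvi[fl]) ** 2))
        total = sse_left + sen_fit.sse
        if best is None or total < best[0] - 1e-15:
            best = (total, s)
    if best is None:
        # no admissible split; fall back to peak-anchored flowering stub
        return Segmentation(growing, np.array([peak]), post, tt_nmax,
                            tt_nmax, True, "no admissible breakpoint; "
                            "flowering collapsed to the peak")
    s = best[1]
    return Segmentation(growing, np.concatenate(([peak], post[:s])), post[s:],
                        tt_nmax, float(tt[post[s - 1]]), True)


def _segment_logistic_all(series: NDVISeries, growing: np.ndarray,
                          post: np.ndarray, peak: int,
                          tt_nmax: float) -> Segmentation:
    tt, ndvi = series.tt, series.ndvi
    final = float(np.min(ndvi[post]))
    amp0 = float(ndvi[peak]) - final
    if amp0 <= 0:
        return Segmentation(growing, np.array([], int), np.array([], int),
                            tt_nmax, np.nan, False, "non-positive amplitude")
    fit = fit_senescence(tt[post], ndvi[post], final, amp0)
    if not fit.converged:
        return Segmentation(growing, np.array([], int), np.array([], int),
                            tt_nmax, np.nan, False, "logistic fit failed")
    tt99 = (-LN99 - fit.b3) / fit.a3   # 99% of amplitude remaining
    fl_mask = tt[post] <= tt99
    fl = np.concatenate(([peak], post[fl_mask]))
    se = post[~fl_mask]
    if len(se) < MIN_SENESCENCE_POINTS:
        se = post
        fl = np.array([peak])
    ttfe = float(tt[fl[-1]])
    return Segmentation(growing, fl, se, tt_nmax, ttfe, True)


# ---------------------------------------------------------------------------
# Stay-green statistics and areas


def tfn(a3: float, b3: float, remaining_fraction: float) -> float:
    """Thermal time at which ``remaining_fraction`` of the amplitude remains.

    TFNx solves h(TT) = final + x*amplitude, i.e. TT = (ln((1-x)/x) - b3)/a3.
    For the canonical fractions this reduces to the quantile formulas
    TFN90 = (-ln9 - b3)/a3, TFN50 = -b3/a3, TFN10 = (ln9 - b3)/a3,
    TFN1 = (ln99 - b3)/a3.
    """
    if not (a3 > 0):
        raise PhenologyError("a3 must be positive")
    if not (0 < remaining_fraction < 1):
        raise PhenologyError("remaining fraction must be in (0, 1)")
    return (math.log((1.0 - remaining_fraction) / remaining_fraction) - b3) / a3


def _line_integral(a: float, b: float, t0: float, t1: float) -> float:
    return a * (t1 ** 2 - t0 ** 2) / 2.0 + b * (t1 - t0)


def phase_areas(model: PhenologyModel, *, ta_mode: str = "measured",
                series: NDVISeries | None = None) -> dict[str, float]:
    """Areas under the fitted phase curves, in NDVI * degC days.

    GPA integrates the growing line from sowing to the NDVI maximum, FPA the
    flowering line to the phase boundary, SPA the logistic (closed form) from
    the boundary to TFN1; DPA = FPA + SPA. TA is by default the trapezoid
    area under the *measured* points from sowing to the last observation
    (``ta_mode='measured'``, requires ``series``); ``ta_mode='modelled'``
    returns GPA + DPA instead.
    """
    out = {k: np.nan for k in ("GPA", "FPA", "SPA", "DPA", "TA")}
    if np.isfinite(model.a1):
        out["GPA"] = _line_integral(model.a1, model.b1, model.tt_sowing,
                                    model.tt_nmax)
    if model.senescence_available and np.isfinite(model.a3):
        tfn1 = tfn(model.a3, model.b3, 0.01)
        if np.isfinite(model.a2):
            out["FPA"] = _line_integral(model.a2, model.b2, model.tt_nmax,
                                        model.tt_flower_end)
        h = lambda t: logistic_antiderivative(t, model.a3, model.b3,
                                              model.ndvi_final,
                                              model.ndvi_amplitude)
        out["SPA"] = h(tfn1) - h(model.tt_flower_end)
        if np.isfinite(out["FPA"]):
            out["DPA"] = out["FPA"] + out["SPA"]
    if ta_mode == "measured":
        if series is not None:
            out["TA"] = float(np.trapezoid(series.ndvi, series.tt))
    elif ta_mode == "modelled":
        if np.isfinite(out["GPA"]) and np.isfinite(out["DPA"]):
            out["TA"] = out["GPA"] + out["DPA"]
    else:
        raise PhenologyError(f"unknown ta_mode {ta_mode!r}")
    return out


# ---------------------------------------------------------------------------
# Per-plot fit and cohort pipeline


def fit_plot(series: NDVISeries, *, rule: str = "joint_sse",
             ta_mode: str = "measured") -> tuple[PhenologyModel, PhenologyTraits]:
    """Fit the three-phase model to one plot and derive its stay-green traits."""
    model = PhenologyModel(plot_id=series.plot_id, tt_sowing=series.tt_sowing)
    traits = PhenologyTraits(plot_id=series.plot_id)
    if len(series):
        traits.nmax = float(np.max(series.ndvi))
    seg = segment_phases(series, rule=rule)
    model.tt_nmax = seg.tt_nmax
    model.tt_flower_end = seg.tt_flower_end
    if seg.note:
        model.flags.append(seg.note)

    tt, ndvi = series.tt, series.ndvi
    if len(seg.growing) >= 2 and np.ptp(tt[seg.growing]) > 0:
        model.a1, model.b1, model.r_growing = fit_line(tt[seg.growing],
                                                       ndvi[seg.growing])
    if not seg.available:
        return model, traits

    post = np.concatenate((seg.flowering[1:], seg.senescence)) \
        if len(seg.flowering) else seg.senescence
    model.ndvi_final = float(np.min(ndvi[post])) if len(post) else np.nan

    if len(seg.flowering) >= 2:
        model.a2, model.b2, model.r_flowering = fit_line(tt[seg.flowering],
                                                         ndvi[seg.flowering])
        anchor = model.a2 * model.tt_flower_end + model.b2
    else:
        anchor = float(ndvi[seg.flowering[0]]) if len(seg.flowering) else traits.nmax
        model.flags.append("flowering line unavailable; amplitude anchored at peak")
    model.ndvi_amplitude = anchor - model.ndvi_final
    if not (model.ndvi_amplitude > 0):
        model.flags.append("non-positive amplitude; senescence unavailable")
        return model, traits

    fit = fit_senescence(tt[seg.senescence], ndvi[seg.senescence],
                         model.ndvi_final, model.ndvi_amplitude)
    if not fit.converged:
        model.flags.append("senescence fit did not converge")
        return model, traits
    if not _plausible_midpoint(fit.a3, fit.b3, tt[seg.senescence]):
        model.flags.append("implausible senescence parameters; fit rejected")
        return model, traits
    model.a3, model.b3, model.r_senescence = fit.a3, fit.b3, fit.r
    model.senescence_available = True

    for frac, name in TFN_FRACTIONS.items():
        setattr(traits, name.lower(), tfn(model.a3, model.b3, frac))
    areas = phase_areas(model, ta_mode=ta_mode, series=series)
    traits.gpa, traits.fpa = areas["GPA"], areas["FPA"]
    traits.spa, traits.dpa, traits.ta = areas["SPA"], areas["DPA"], areas["TA"]
    return model, traits


def phenology_pipeline(series_list: list[NDVISeries], *, rule: str = "joint_sse",
                       ta_mode: str = "measured"
                       ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Fit every plot; return (traits table, model table, fit-quality report).

    Plots whose senescence cannot be fitted are listed in the report under
    ``unavailable`` with their flags — never dropped silently.
    """
    trait_rows, model_rows, unavailable = [], [], []
    for series in series_list:
        model, traits = fit_plot(series, rule=rule, ta_mode=ta_mode)
        trait_rows.append(vars(traits).copy())
        row = {k: v for k, v in vars(model).items() if k != "flags"}
        row["flags"] = ";".join(model.flags)
        model_rows.append(row)
        if not model.senescence_available:
            unavailable.append((series.plot_id, ";".join(model.flags)))
    traits_df = pd.DataFrame(trait_rows)
    models_df = pd.DataFrame(model_rows)
    report = {"n_plots": len(series_list), "n_fitted": len(series_list) - len(unavailable),
              "unavailable": unavailable}
    for phase in ("r_growing", "r_flowering", "r_senescence"):
        vals = models_df[phase].dropna() if len(models_df) else pd.Series(dtype=float)
        report[f"mean_{phase}"] = float(vals.mean()) if len(vals) else np.nan
        report[f"sd_{phase}"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
    return traits_df, models_df, report


def series_from_table(ndvi: pd.DataFrame, axes: dict[str, ThermalTimeAxis],
                      plot_locations: dict[str, str]) -> list[NDVISeries]:
    """Build per-plot NDVISeries from a long (plot_id, date, ndvi) table.

    ``axes`` maps plot_id -> ThermalTimeAxis (one axis per plot, since the
    heading reference is genotype- and location-specific).
    """
    out = []
    for pid, sub in ndvi.groupby("plot_id"):
        axis = axes.get(pid)
        if axis is None:
            continue
        tts = np.array([axis.tt_of(d) for d in sub["date"]])
        order = np.argsort(tts, kind="stable")
        out.append(NDVISeries(str(pid), tts[order],
                              sub["ndvi"].to_numpy()[order], axis.tt_sowing))
    return out
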