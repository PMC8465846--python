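"""Synthetic multi-location hybrid wheat trial generator.

Emulates the study design this package analyses: an incomplete factorial of
19 CMS females x 16 restorer males with 92 selected hybrids (every male in
at least 3 crosses, every female in at least 2), grown with the 35 parents,
four replicated checks and one unreplicated check as an augmented design of
160 entries in eight blocks at three sites in northern France.

Genetic architecture is additive + dominance: parents draw additive values
per trait; a hybrid's true value is the mid-parent plus a dominance
deviation parameterised directly as a target mid-parent heterosis percent
(no claim about wheat genetics — just the simplest architecture producing
the configured heterosis). Trait correlations come from a single shared
latent factor per genotype (grain yield loads positively, protein content
negatively), and senescence timing is generated from heading date so the
two are negatively correlated. Plot observations add location, block,
genotype x location and residual noise. NDVI series follow the three-phase
curve (growing line, flowering plateau, logistic senescence) evaluated on
each plot's own heading-centred thermal-time axis, with Gaussian noise and
clipping to [0, 1].

Everything is deterministic under a fixed seed; sub-generators derive their
streams from the master seed by fixed offsets. True genotype values, true
variance components and true phenology parameters are emitted alongside the
data (``truth/``) for recovery tests — the analysis pipeline never reads
them.
"""

from __future__ import annotations

import datetime as dt
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (Genotype, PlotRecord, TraitTable, TrialData, TrialMeta,
                   WeatherSeries, write_trial)
from .phenology import LN9, LN99, build_thermal_axis, logistic_ndvi


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TraitArchitecture:
    """Per-trait generative parameters, all in the trait's own units."""

    mean: float           # parent-population mean
    additive_sd: float    # SD of parent true values
    dominance_pct: float  # target mean mid-parent heterosis, percent
    gxl_sd: float         # genotype x location SD
    residual_sd: float    # plot residual SD
    latent_loading: float = 0.0  # loading on the shared genotype factor

    def __post_init__(self) -> None:
        for name in ("additive_sd", "gxl_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")


# Defaults follow the study's printed descriptive statistics (trait means,
# genetic / GxL / residual variances) and its per-trait mean mid-parent
# heterosis. Latent loadings of +-0.894 put the *genetic* GPC-YLD
# correlation near -0.8, which after attenuation by GxL and residual noise
# leaves the adjusted-mean correlation near the -0.57 the analysis should see.
DEFAULT_TRAITS: dict[str, TraitArchitecture] = {
    # YLD/GPC additive SDs are calibrated above the printed genetic variances:
    # with the printed values the adjusted-mean GPC-YLD correlation and the
    # hybrid protein-deviation offset come out far weaker than the study
    # reports, so the genetic signal is set to reproduce the observables.
    "YLD":   TraitArchitecture(8.5, 0.90, 5.0, math.sqrt(0.37),
                               math.sqrt(0.39), latent_loading=0.894),
    "GPC":   TraitArchitecture(11.9, 0.90, -0.7, math.sqrt(0.20),
                               math.sqrt(0.30), latent_loading=-0.894),
    "SW":    TraitArchitecture(81.7, math.sqrt(1.1), 0.8, math.sqrt(0.61),
                               math.sqrt(0.47)),
    "HD":    TraitArchitecture(132.6, math.sqrt(3.9), -2.3, math.sqrt(0.96),
                               math.sqrt(0.66)),
    "HT":    TraitArchitecture(93.4, math.sqrt(7.1), 6.7, 0.0, math.sqrt(3.1)),
    "SEEDA": TraitArchitecture(16.0, math.sqrt(0.89), 5.6, math.sqrt(0.26),
                               math.sqrt(0.33)),
    "SEEDL": TraitArchitecture(6.3, math.sqrt(0.22), 2.0, math.sqrt(0.056),
                               math.sqrt(0.067)),
    "SEEDW": TraitArchitecture(3.5, math.sqrt(0.09), 3.3, math.sqrt(0.04),
                               math.sqrt(0.048)),
    "TKW":   TraitArchitecture(41.1, math.sqrt(2.9), 7.7, math.sqrt(2.0),
                               math.sqrt(0.82)),
    # senescence onset in degC days after heading; residual variation enters
    # through NDVI noise rather than a direct plot residual. The additive SD
    # is likewise calibrated so the heading-date correlation survives
    # curve-fitting noise at the reported strength.
    "TFN90": TraitArchitecture(567.2, 12.0, 5.8, math.sqrt(27.0), 0.0),
}

MEASURED_TRAITS = ("YLD", "GPC", "SW", "HD", "HT", "SEEDA", "SEEDL", "SEEDW", "TKW")

#: Table-1-shaped site metadata (coordinates, dates, plot sizes).
DEFAULT_SITES = (
    TrialMeta("Moinville-la-Jeulin", 48.38, 1.70, 12.4,
              dt.date(2019, 10, 25), dt.date(2020, 7, 11)),
    TrialMeta("Arvillers", 49.73, 2.65, 10.6,
              dt.date(2019, 10, 29), dt.date(2020, 7, 29)),
    TrialMeta("Pomacle", 49.33, 4.15, 12.0,
              dt.date(2019, 10, 12), dt.date(2020, 7, 19)),
)


@dataclass
class SimulationConfig:
    n_females: int = 19
    n_males: int = 16
    n_hybrids: int = 92
    n_locations: int = 3
    n_blocks: int = 8
    replicated_checks: int = 4
    unreplicated_checks: int = 1
    traits: dict[str, TraitArchitecture] = field(
        default_factory=lambda: dict(DEFAULT_TRAITS))
    dominance_sd_ratio: float = 0.2   # dominance-deviation SD / additive SD
    hd_tfn_r: float = -0.85           # genetic heading-date/senescence-onset corr
                                      # (attenuates to ~-0.78 in adjusted means)
    block_sd_ratio: float = 0.5       # block SD / residual SD
    loc_sd_ratio: float = 1.0         # location SD / GxL SD
    # NDVI curve shape
    ndvi_noise_sd: float = 0.02
    a3_mean: float = 0.02             # logistic senescence rate, 1/(degC day)
    a3_cv: float = 0.05               # genotype-level CV of a3
    a3_plot_cv: float = 0.02          # extra plot-level CV of a3
    ndvi_final_mean: float = 0.15
    final_genotype_sd: float = 0.015
    nmax_mean: float = 0.88
    nmax_genotype_sd: float = 0.015   # genetic variation of the NDVI maximum
    nmax_dominance_pct: float = 1.2   # hybrid gain in Nmax, percent
    curve_plot_sd: float = 0.01       # plot-level jitter of nmax/final
    flowering_drop: float = 0.05      # NDVI decline over the flowering plateau
    timepoints: tuple[int, ...] = (14, 14, 13)  # per location, as in the field
    # weather shape: annual sinusoid tuned so a ~260-day cycle sums to
    # ~2700-3000 degC days with mean ~10.4 degC
    weather_annual_mean: float = 12.2
    weather_annual_amplitude: float = 7.5
    weather_daily_sd: float = 2.0
    weather_halfrange: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hybrids > self.n_females * self.n_males:
            raise SimulationError("n_hybrids exceeds the full factorial")
        if self.n_hybrids < 3 * self.n_males or self.n_hybrids < 2 * self.n_females:
            raise SimulationError(
                "n_hybrids too small for >=3 crosses per male and >=2 per female")

    def rng(self, offset: int) -> np.random.Generator:
        # fixed offsets per sub-generator; keeps every stream reproducible
        return np.random.default_rng((int(self.seed) % (2 ** 31)) * 16 + offset)


@dataclass
class SimulatedTruth:
    genotype_values: pd.DataFrame    # genotype_id, trait, true_value
    variance_components: pd.DataFrame  # trait, sigma2_g, sigma2_gxl, sigma2_res
    heterosis: pd.DataFrame          # trait, true_mean_mp_heterosis_pct
    phenology: pd.DataFrame          # per-plot true curve parameters
    gxl_effects: pd.DataFrame        # genotype_id, location, trait, effect


# ---------------------------------------------------------------------------
# Panel and crossing scheme


def simulate_panel(config: SimulationConfig
                   ) -> tuple[dict[str, Genotype], pd.DataFrame, pd.DataFrame]:
    """Panel, pedigree and true genotype values.

    Crosses are sampled so every male sires >= 3 hybrids and every female
    mothers >= 2; hybrid truth = mid-parent + dominance deviation implied by
    the configured heterosis target.
    """
    rng = config.rng(1)
    females = [f"FEM{i + 1:02d}" for i in range(config.n_females)]
    males = [f"MA{i + 1:02d}" for i in range(config.n_males)]
    checks_r = [f"CHKR{i + 1}" for i in range(config.replicated_checks)]
    checks_u = [f"CHKU{i + 1}" for i in range(config.unreplicated_checks)]

    pairs: set[tuple[str, str]] = set()
    for m in males:  # guarantee >=3 per male
        for f in rng.choice(females, size=3, replace=False):
            pairs.add((str(f), m))
    counts_f = pd.Series([p[0] for p in pairs]).value_counts()
    for f in females:  # then >=2 per female
        need = 2 - int(counts_f.get(f, 0))
        if need > 0:
            free = [m for m in males if (f, m) not in pairs]
            for m in rng.choice(free, size=need, replace=False):
                pairs.add((f, str(m)))
    remaining = [(f, m) for f in females for m in males if (f, m) not in pairs]
    if len(pairs) > config.n_hybrids:
        raise SimulationError(
            f"minimum crossing constraints need {len(pairs)} hybrids "
            f"(> n_hybrids={config.n_hybrids})")
    extra = rng.choice(len(remaining), size=config.n_hybrids - len(pairs),
                       replace=False)
    pairs |= {remaining[i] for i in extra}

    panel: dict[str, Genotype] = {}
    for f in females:
        panel[f] = Genotype(f, "female_parent")
    for m in males:
        panel[m] = Genotype(m, "male_parent")
    for c in checks_r:
        panel[c] = Genotype(c, "check_replicated")
    for c in checks_u:
        panel[c] = Genotype(c, "check_unreplicated")
    pedigree_rows = []
    for f, m in sorted(pairs):
        hid = f"{f}x{m}"
        panel[hid] = Genotype(hid, "hybrid", female_id=f, male_id=m)
        pedigree_rows.append({"hybrid_id": hid, "female_id": f, "male_id": m})
    pedigree = pd.DataFrame(pedigree_rows)

    # --- true genotype values -------------------------------------------------
    lines = females + males + checks_r + checks_u
    latent = {g: rng.standard_normal() for g in lines}
    values: dict[str, dict[str, float]] = {g: {} for g in panel}
    z_std: dict[str, dict[str, float]] = {g: {} for g in lines}
    for trait, arch in config.traits.items():
        if trait == "TFN90":
            continue  # generated below, from HD
        lam = arch.latent_loading
        for g in lines:
            z = lam * latent[g] + math.sqrt(max(1 - lam * lam, 0.0)) \
                * rng.standard_normal()
            z_std[g][trait] = z
            values[g][trait] = arch.mean + arch.additive_sd * z
    # senescence onset anti-correlated with heading date
    tfn = config.traits["TFN90"]
    r = config.hd_tfn_r
    for g in lines:
        z = r * z_std[g]["HD"] + math.sqrt(1 - r * r) * rng.standard_normal()
        values[g]["TFN90"] = tfn.mean + tfn.additive_sd * z
    # hybrids: mid-parent + dominance. The deviation is proportional to the
    # hybrid's own mid-parent, so the configured percent is exactly the
    # expected per-hybrid mid-parent heterosis.
    for row in pedigree.itertuples():
        for trait, arch in config.traits.items():
            mp = (values[row.female_id][trait] + values[row.male_id][trait]) / 2
            dom = arch.dominance_pct / 100.0 * mp \
                + config.dominance_sd_ratio * arch.additive_sd * rng.standard_normal()
            values[row.hybrid_id][trait] = mp + dom

    truth = pd.DataFrame(
        [{"genotype_id": g, "trait": t, "true_value": v}
         for g, tv in values.items() for t, v in tv.items()]
    )
    return panel, pedigree, truth


# ---------------------------------------------------------------------------
# Field layout and plot-level traits


def simulate_trial(config: SimulationConfig, panel: dict[str, Genotype],
                   truth: pd.DataFrame, sites: tuple[TrialMeta, ...]
                   ) -> tuple[list[PlotRecord], TraitTable, pd.DataFrame]:
    """Augmented layout plus plot-level observations.

    observation = genotype truth + location effect + block effect + GxL draw
    + residual. Returns (plots, plot-level TraitTable, GxL effect table); the
    GxL table also feeds the NDVI generator so senescence timing and the
    recorded heading dates stay mutually consistent.
    """
    rng = config.rng(2)
    tv = truth.pivot(index="genotype_id", columns="trait", values="true_value")
    reps = [g for g, gt in panel.items() if gt.role == "check_replicated"]
    singles = sorted(g for g, gt in panel.items() if gt.role != "check_replicated")
    per_block = len(singles) // config.n_blocks

    all_traits = list(config.traits)
    locations = [s.location for s in sites]
    loc_eff = {(loc, t): rng.normal(0, config.loc_sd_ratio * a.gxl_sd)
               for loc in locations for t, a in config.traits.items()}
    gxl_rows = []
    gxl = {}
    for loc in locations:
        for g in sorted(panel):
            for t, a in config.traits.items():
                e = rng.normal(0, a.gxl_sd) if a.gxl_sd > 0 else 0.0
                gxl[(g, loc, t)] = e
                gxl_rows.append({"genotype_id": g, "location": loc,
                                 "trait": t, "effect": e})

    plots: list[PlotRecord] = []
    trait_rows = []
    for li, site in enumerate(sites):
        loc = site.location
        order = list(rng.permutation(singles))
        block_eff = {(b, t): rng.normal(0, config.block_sd_ratio * a.residual_sd)
                     for b in range(1, config.n_blocks + 1)
                     for t, a in config.traits.items()}
        counter = 0
        for b in range(1, config.n_blocks + 1):
            entries = list(reps) + order[(b - 1) * per_block: b * per_block]
            if b == config.n_blocks:  # leftovers when not divisible
                entries += order[config.n_blocks * per_block:]
            for g in entries:
                counter += 1
                pid = f"{loc[:3].upper()}-B{b}-{counter:03d}"
                plots.append(PlotRecord(pid, loc, b, g))
                for t in MEASURED_TRAITS:
                    a = config.traits[t]
                    val = (tv.loc[g, t] + loc_eff[(loc, t)] + block_eff[(b, t)]
                           + gxl[(g, loc, t)]
                           + (rng.normal(0, a.residual_sd) if a.residual_sd > 0
                              else 0.0))
                    trait_rows.append({"unit": pid, "location": loc, "trait": t,
                                       "value": float(val), "level": "plot"})
    traits = TraitTable(pd.DataFrame(trait_rows))
    return plots, traits, pd.DataFrame(gxl_rows)


# ---------------------------------------------------------------------------
# Weather


def simulate_weather(config: SimulationConfig, site: TrialMeta,
                     rng: np.random.Generator | None = None) -> WeatherSeries:
    """Sinusoidal annual temperature with daily noise; deterministic per seed.

    Daily mean = annual_mean + amplitude * cos(2*pi*(doy - 197)/365.25)
    (warmest mid-July), tmin/tmax symmetric around it. Rainfall is a sparse
    exponential draw. Parameters default so a 260-day autumn-sown cycle sums
    to roughly 2700-3000 degC days.
    """
    if rng is None:
        # stable per-site stream (zlib.crc32 is process-independent, unlike hash)
        rng = config.rng(3 + zlib.crc32(site.location.encode()) % 7)
    start = site.sowing_date - dt.timedelta(days=3)
    n_days = (site.harvest_date - start).days + 1
    rows = []
    for i in range(n_days):
        day = start + dt.timedelta(days=i)
        doy = day.timetuple().tm_yday
        seasonal = config.weather_annual_mean + config.weather_annual_amplitude \
            * math.cos(2 * math.pi * (doy - 197) / 365.25)
        tmean = seasonal + rng.normal(0, config.weather_daily_sd)
        half = config.weather_halfrange + abs(rng.normal(0, 1.0))
        rain = float(rng.exponential(4.0)) if rng.random() < 0.35 else 0.0
        rows.append({"date": day, "tmin": round(tmean - half, 2),
                     "tmax": round(tmean + half, 2), "rainfall": round(rain, 2)})
    return WeatherSeries(site.location, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# NDVI time series


def _nearest_date(axis, target_tt: float) -> int:
    return int(np.argmin(np.abs(axis.tt - target_tt)))


def simulate_ndvi(config: SimulationConfig, sites: tuple[TrialMeta, ...],
                  weather: dict[str, WeatherSeries], plots: list[PlotRecord],
                  traits: TraitTable, truth: pd.DataFrame,
                  gxl: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plot NDVI observations and the true phenology parameters.

    Each plot gets 13-14 dated observations following the three-phase curve:
    a rising line from emergence (~150 degC days after sowing) to the NDVI
    maximum just before heading, a gently declining plateau, and a logistic
    decline whose midpoint is set by the plot's true senescence onset
    (genotype TFN90 truth + its GxL effect). The last observation sits at
    harvest, deep in the logistic tail, so the lowest observed NDVI
    approximates the asymptote. Gaussian noise is added and values are
    clipped to [0, 1].
    """
    rng = config.rng(4)
    site_by_loc = {s.location: s for s in sites}
    tfn90_truth = truth[truth["trait"] == "TFN90"].set_index("genotype_id")[
        "true_value"]
    gxl_tfn = gxl[gxl["trait"] == "TFN90"].set_index(
        ["genotype_id", "location"])["effect"]
    hd_plot = traits.frame[(traits.frame["trait"] == "HD")
                           & (traits.frame["level"] == "plot")]
    hd_by_plot = hd_plot.set_index("unit")["value"]

    # genotype-level curve parameters (drawn first so they are reproducible
    # regardless of plot order); hybrids inherit mid-parent nmax + dominance
    genotypes = sorted({p.genotype_id for p in plots})
    hybrids = [g for g in genotypes if "x" in g]
    curve: dict[str, tuple[float, float, float]] = {}
    for g in genotypes:
        if "x" in g:
            continue
        curve[g] = (
            config.nmax_mean + config.nmax_genotype_sd * rng.standard_normal(),
            config.ndvi_final_mean
            + config.final_genotype_sd * rng.standard_normal(),
            config.a3_mean * (1 + config.a3_cv * rng.standard_normal()),
        )
    for g in hybrids:
        f, m = g.split("x")
        dom = config.nmax_dominance_pct / 100.0 * config.nmax_mean
        curve[g] = (
            (curve[f][0] + curve[m][0]) / 2 + dom,
            (curve[f][1] + curve[m][1]) / 2,
            (curve[f][2] + curve[m][2]) / 2,
        )

    loc_index = {s.location: i for i, s in enumerate(sites)}
    ndvi_rows, truth_rows = [], []
    for plot in plots:
        site = site_by_loc[plot.location]
        hd_days = float(hd_by_plot[plot.plot_id])
        heading = dt.date(site.harvest_date.year, 1, 1) \
            + dt.timedelta(days=int(round(hd_days)) - 1)
        axis = build_thermal_axis(weather[plot.location], site.sowing_date,
                                  heading)
        tt_harvest = float(axis.tt[-1])

        nmax_g, final_g, a3_g = curve[plot.genotype_id]
        a3 = max(a3_g * (1 + config.a3_plot_cv * rng.standard_normal()),
                 config.a3_mean * 0.5)
        tfn90 = float(tfn90_truth[plot.genotype_id]
                      + gxl_tfn.get((plot.genotype_id, plot.location), 0.0))
        tfn50 = tfn90 + LN9 / a3
        b3 = -a3 * tfn50
        final = float(np.clip(
            final_g + config.curve_plot_sd * rng.standard_normal(), 0.05, 0.3))
        nmax = float(np.clip(
            nmax_g + config.curve_plot_sd * rng.standard_normal(), 0.7, 0.97))
        amp = nmax - config.flowering_drop - final

        i_emerg = _nearest_date(axis, axis.tt_sowing + 150.0)
        i_nmax = _nearest_date(axis, -60.0)
        i_fe = _nearest_date(axis, tfn50 - LN99 / a3)
        i_harvest = len(axis.tt) - 1
        tt_nmax = float(axis.tt[i_nmax])
        tt_fe = float(axis.tt[i_fe])

        a1 = (nmax - 0.08) / (tt_nmax - axis.tt[i_emerg])
        b1 = nmax - a1 * tt_nmax
        a2 = ((final + amp) - nmax) / (tt_fe - tt_nmax)
        b2 = nmax - a2 * tt_nmax

        n_points = config.timepoints[loc_index[plot.location]
                                     % len(config.timepoints)]
        n_grow = n_points - 10  # peak + 3 flowering + 6 senescence fixed
        idx_grow = np.unique(np.linspace(i_emerg, i_nmax - 4,
                                         n_grow).round().astype(int))
        idx_flower = np.unique(np.linspace(i_nmax + 3, i_fe,
                                           3).round().astype(int))
        # weekly-style senescence coverage: five visits across the logistic
        # transition (93% .. 7% of amplitude remaining) plus one at harvest
        sen_targets = [tfn50 + math.log((1 - q) / q) / a3
                       for q in (0.93, 0.75, 0.50, 0.25, 0.07)]
        idx_sen = sorted({min(max(_nearest_date(axis, t), i_fe + 2),
                              i_harvest) for t in sen_targets} | {i_harvest})

        def emit(i: int, value: float) -> None:
            noisy = value + (rng.normal(0, config.ndvi_noise_sd)
                             if config.ndvi_noise_sd > 0 else 0.0)
            ndvi_rows.append({"plot_id": plot.plot_id,
                              "date": axis.dates[i].isoformat(),
                              "ndvi": float(np.clip(noisy, 0.0, 1.0))})

        for i in idx_grow:
            emit(i, a1 * axis.tt[i] + b1)
        emit(i_nmax, nmax)
        for i in idx_flower:
            emit(i, a2 * axis.tt[i] + b2)
        for i in idx_sen:
            emit(i, float(logistic_ndvi(axis.tt[i], a3, b3, final, amp)))

        truth_rows.append({
            "plot_id": plot.plot_id, "genotype_id": plot.genotype_id,
            "location": plot.location, "heading_date": heading.isoformat(),
            "a1": a1, "b1": b1, "a2": a2, "b2": b2, "a3": a3, "b3": b3,
            "ndvi_final": final, "ndvi_amplitude": amp,
            "tt_nmax": tt_nmax, "tt_flower_end": tt_fe,
            "tfn90": tfn90, "tfn50": tfn50, "tt_harvest": tt_harvest,
        })
    ndvi = pd.DataFrame(ndvi_rows)
    ndvi["date"] = pd.to_datetime(ndvi["date"]).dt.date
    return ndvi, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Full bundle


def simulate(config: SimulationConfig | None = None
             ) -> tuple[TrialData, SimulatedTruth]:
    """Generate the complete trial bundle plus its ground truth."""
    config = config or SimulationConfig()
    sites = DEFAULT_SITES[: config.n_locations]
    if len(sites) < config.n_locations:
        extra = [replace(DEFAULT_SITES[0], location=f"Site{i}")
                 for i in range(len(DEFAULT_SITES), config.n_locations)]
        sites = tuple(sites) + tuple(extra)
    panel, pedigree, truth = simulate_panel(config)
    plots, traits, gxl = simulate_trial(config, panel, truth, tuple(sites))
    weather = {s.location: simulate_weather(config, s) for s in sites}
    ndvi, pheno_truth = simulate_ndvi(config, tuple(sites), weather, plots,
                                      traits, truth, gxl)
    data = TrialData(panel=panel, meta={s.location: s for s in sites},
                     plots=plots, traits=traits, ndvi=ndvi, weather=weather)
    vc = pd.DataFrame(
        [{"trait": t, "sigma2_g": _true_sigma2_g(config, t),
          "sigma2_gxl": a.gxl_sd ** 2, "sigma2_res": a.residual_sd ** 2}
         for t, a in config.traits.items()])
    het = pd.DataFrame([{"trait": t, "true_mean_mp_heterosis_pct": a.dominance_pct}
                        for t, a in config.traits.items()])
    return data, SimulatedTruth(truth, vc, het, pheno_truth, gxl)


def _true_sigma2_g(config: SimulationConfig, trait: str) -> float:
    # additive variance among parents; dominance adds spread among hybrids
    return config.traits[trait].additive_sd ** 2


def write_bundle(data: TrialData, truth: SimulatedTruth,
                 directory: str | Path) -> None:
    """Write the CSV bundle read_trial consumes, plus truth/*.csv."""
    d = Path(directory)
    write_trial(data, d)
    tdir = d / "truth"
    tdir.mkdir(parents=True, exist_ok=True)
    truth.genotype_values.to_csv(tdir / "genotype_values.csv", index=False)
    truth.variance_components.to_csv(tdir / "variance_components.csv", index=False)
    truth.heterosis.to_csv(tdir / "heterosis.csv", index=False)
    truth.phenology.to_csv(tdir / "phenology.csv", index=False)
    truth.gxl_effects.to_csv(tdir / "gxl_effects.csv", index=False)
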