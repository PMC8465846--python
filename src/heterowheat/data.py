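"""Domain types, CSV I/O, design validation and derived-trait arithmetic.

The trial layout mirrors an augmented field design: a panel of parent lines
(CMS females and restorer males), F1 hybrids, replicated check varieties in
every block and one unreplicated check, grown at several locations. All
tables are plain UTF-8 CSV; the column contracts are documented in
``docs/data_dictionary.md``.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: The 21 traits of the combined descriptive table, in measured -> estimated
#: -> modelled order (the convention used for correlation matrices).
TRAITS: tuple[str, ...] = (
    "YLD", "GPC", "SW", "HD", "HT", "SEEDA", "SEEDL", "SEEDW", "TKW",
    "GPY", "GPSM",
    "Nmax", "GPA", "FPA", "SPA", "DPA", "TA", "TFN90", "TFN50", "TFN10", "TFN1",
)

ROLES = (
    "female_parent",
    "male_parent",
    "hybrid",
    "check_replicated",
    "check_unreplicated",
)

LEVELS = ("plot", "location_blue", "combined_blue")


class TrialDataError(ValueError):
    """Raised when an input table violates a hard invariant."""


def parse_date(value: str | dt.date) -> dt.date:
    """Parse DD/MM/YYYY (field-book dialect) or ISO-8601 dates.

    Ambiguous strings (e.g. 03/04/2020 read as either dialect) are fine —
    both dialects are unambiguous given their separators — but anything that
    parses under neither is rejected rather than guessed.
    """
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    s = str(value).strip()
    for fmt in ("%d/%m/%Y", "%Y-%m-%d"):
        try:
            return dt.datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    raise TrialDataError(f"unparseable date {value!r}; expected DD/MM/YYYY or YYYY-MM-DD")


@dataclass(frozen=True)
class Genotype:
    id: str
    role: str
    female_id: str | None = None
    male_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TrialDataError(f"unknown role {self.role!r} for genotype {self.id!r}")
        has_parents = self.female_id is not None and self.male_id is not None
        if (self.role == "hybrid") != has_parents:
            raise TrialDataError(
                f"genotype {self.id!r}: female_id/male_id must be present iff role is hybrid"
            )


@dataclass(frozen=True)
class TrialMeta:
    location: str
    latitude: float
    longitude: float
    plot_size: float  # m^2
    sowing_date: dt.date
    harvest_date: dt.date
    sowing_density_factor: float = 0.85  # applied to hybrids relative to lines

    def __post_init__(self) -> None:
        if self.harvest_date <= self.sowing_date:
            raise TrialDataError(
                f"{self.location}: harvest_date must be after sowing_date"
            )
        if not (0.0 < self.sowing_density_factor <= 1.0):
            raise TrialDataError(
                f"{self.location}: sowing_density_factor must be in (0, 1]"
            )


@dataclass
class WeatherSeries:
    """Daily weather at one location: tmin/tmax in deg C, rainfall in mm."""

    location: str
    frame: pd.DataFrame  # columns: date (datetime.date), tmin, tmax, rainfall

    def __post_init__(self) -> None:
        df = self.frame
        required = {"date", "tmin", "tmax", "rainfall"}
        if not required.issubset(df.columns):
            raise TrialDataError(f"weather for {self.location}: missing columns {required - set(df.columns)}")
        dates = pd.to_datetime(df["date"]).dt.date
        if not dates.is_monotonic_increasing:
            raise TrialDataError(f"weather for {self.location}: dates not sorted")
        deltas = np.diff([d.toordinal() for d in dates])
        if len(deltas) and not np.all(deltas == 1):
            raise TrialDataError(f"weather for {self.location}: dates not contiguous")
        if (df["tmax"] < df["tmin"]).any():
            bad = df.loc[df["tmax"] < df["tmin"], "date"].tolist()
            raise TrialDataError(f"weather for {self.location}: tmax < tmin on {bad[:5]}")
        object.__setattr__(self, "frame", df.assign(date=dates).reset_index(drop=True))

    def window(self, start: dt.date, end: dt.date) -> pd.DataFrame:
        """Inclusive date window; raises naming missing dates on a coverage gap."""
        df = self.frame
        mask = (df["date"] >= start) & (df["date"] <= end)
        sub = df.loc[mask]
        expected = (end - start).days + 1
        if len(sub) != expected:
            have = set(sub["date"])
            missing = [start + dt.timedelta(days=i) for i in range(expected)
                       if start + dt.timedelta(days=i) not in have]
            raise TrialDataError(
                f"weather for {self.location}: missing {len(missing)} day(s), "
                f"first {missing[:3]}"
            )
        return sub.reset_index(drop=True)


@dataclass(frozen=True)
class PlotRecord:
    plot_id: str
    location: str
    block: int
    genotype_id: str

    def __post_init__(self) -> None:
        if not (1 <= int(self.block)):
            raise TrialDataError(f"plot {self.plot_id}: block must be >= 1")


class TraitTable:
    """Long-format trait records at plot or adjusted-mean level.

    One value per (unit, trait, level); missing values are explicit NaN,
    never silently zero-filled.
    """

    COLUMNS = ("unit", "location", "trait", "value", "level")

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                raise TrialDataError(f"trait table missing column {col!r}")
        unknown = set(df["trait"]) - set(TRAITS)
        if unknown:
            raise TrialDataError(f"unknown trait name(s): {sorted(unknown)}")
        bad_level = set(df["level"]) - set(LEVELS)
        if bad_level:
            raise TrialDataError(f"unknown level(s): {sorted(bad_level)}")
        key = ["unit", "location", "trait", "level"]
        dup = df.duplicated(subset=key)
        if dup.any():
            rows = df.loc[dup, key].head(5).to_dict("records")
            raise TrialDataError(f"duplicate (unit, trait, level) rows: {rows}")
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        self.frame = df.reset_index(drop=True)[list(self.COLUMNS)]

    def at_level(self, level: str) -> pd.DataFrame:
        return self.frame[self.frame["level"] == level].reset_index(drop=True)

    def wide(self, level: str) -> pd.DataFrame:
        """Pivot one level to unit x trait (NaN where missing)."""
        sub = self.at_level(level)
        if level == "plot" or sub["location"].notna().all() and level == "location_blue":
            index = ["unit", "location"] if level != "combined_blue" else ["unit"]
        else:
            index = ["unit"]
        return sub.pivot_table(index=index, columns="trait", values="value",
                               aggfunc="first").reset_index()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TrialData:
    """Everything one trial campaign loads: panel, layout, traits, NDVI, weather."""

    panel: dict[str, Genotype]
    meta: dict[str, TrialMeta]
    plots: list[PlotRecord]
    traits: TraitTable
    ndvi: pd.DataFrame  # plot_id, date, ndvi
    weather: dict[str, WeatherSeries]

    @property
    def pedigree(self) -> pd.DataFrame:
        rows = [
            {"hybrid_id": g.id, "female_id": g.female_id, "male_id": g.male_id}
            for g in self.panel.values()
            if g.role == "hybrid"
        ]
        return pd.DataFrame(rows, columns=["hybrid_id", "female_id", "male_id"])


# ---------------------------------------------------------------------------
# CSV I/O


FILES = {
    "genotypes": "genotypes.csv",
    "plots": "plots.csv",
    "traits": "traits_long.csv",
    "ndvi": "ndvi_long.csv",
    "weather": "weather.csv",
    "meta": "trial_meta.csv",
}


def read_trial(directory: str | Path) -> TrialData:
    """Load and cross-validate a full CSV bundle from ``directory``.

    Hard errors: unresolved genotype references (named in the message) and
    duplicate (plot, trait) rows. Softer design oddities are the business of
    :func:`validate_design`, which never fails.
    """
    d = Path(directory)
    paths = {k: d / v for k, v in FILES.items()}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise TrialDataError(f"missing input file(s): {missing}")

    gdf = pd.read_csv(paths["genotypes"], dtype=str)
    panel: dict[str, Genotype] = {}
    for row in gdf.to_dict("records"):
        g = Genotype(
            id=row["id"],
            role=row["role"],
            female_id=row.get("female_id") if pd.notna(row.get("female_id")) else None,
            male_id=row.get("male_id") if pd.notna(row.get("male_id")) else None,
        )
        panel[g.id] = g
    for g in panel.values():
        if g.role == "hybrid":
            for pid in (g.female_id, g.male_id):
                if pid not in panel:
                    raise TrialDataError(
                        f"hybrid {g.id!r} references unknown parent {pid!r}"
                    )

    mdf = pd.read_csv(paths["meta"])
    meta = {
        str(r["location"]): TrialMeta(
            location=str(r["location"]),
            latitude=float(r["latitude"]),
            longitude=float(r["longitude"]),
            plot_size=float(r["plot_size_m2"]),
            sowing_date=parse_date(r["sowing_date"]),
            harvest_date=parse_date(r["harvest_date"]),
            sowing_density_factor=float(r.get("sowing_density_factor", 0.85)),
        )
        for r in mdf.to_dict("records")
    }

    pdf = pd.read_csv(paths["plots"], dtype={"plot_id": str, "location": str,
                                             "genotype_id": str})
    plots = []
    seen: set[tuple[str, int, str]] = set()
    for r in pdf.to_dict("records"):
        rec = PlotRecord(r["plot_id"], r["location"], int(r["block"]), r["genotype_id"])
        key = (rec.location, rec.block, rec.plot_id)
        if key in seen:
            raise TrialDataError(f"duplicate plot key {key}")
        seen.add(key)
        if rec.genotype_id not in panel:
            raise TrialDataError(
                f"plot {rec.plot_id!r} references unknown genotype {rec.genotype_id!r}"
            )
        if rec.location not in meta:
            raise TrialDataError(f"plot {rec.plot_id!r}: unknown location {rec.location!r}")
        plots.append(rec)
    plot_loc = {p.plot_id: p.location for p in plots}

    tdf = pd.read_csv(paths["traits"], dtype={"plot_id": str})
    bad = set(tdf["plot_id"]) - set(plot_loc)
    if bad:
        raise TrialDataError(f"traits_long references unknown plot(s): {sorted(bad)[:5]}")
    long = pd.DataFrame({
        "unit": tdf["plot_id"],
        "location": tdf["plot_id"].map(plot_loc),
        "trait": tdf["trait"],
        "value": tdf["value"],
        "level": "plot",
    })
    traits = TraitTable(long)

    ndvi = pd.read_csv(paths["ndvi"], dtype={"plot_id": str})
    bad = set(ndvi["plot_id"]) - set(plot_loc)
    if bad:
        raise TrialDataError(f"ndvi_long references unknown plot(s): {sorted(bad)[:5]}")
    ndvi["date"] = [parse_date(v) for v in ndvi["date"]]

    wdf = pd.read_csv(paths["weather"])
    wdf["date"] = [parse_date(v) for v in wdf["date"]]
    weather = {
        loc: WeatherSeries(loc, sub.drop(columns="location").reset_index(drop=True))
        for loc, sub in wdf.groupby("location")
    }
    log.info("read_trial: %d genotypes, %d plots, %d trait rows, %d NDVI rows",
             len(panel), len(plots), len(traits), len(ndvi))
    return TrialData(panel, meta, plots, traits, ndvi, weather)


def write_trial(data: TrialData, directory: str | Path) -> dict[str, Path]:
    """Write a TrialData bundle back to the canonical CSV files (lossless)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {k: d / v for k, v in FILES.items()}

    pd.DataFrame(
        [{"id": g.id, "role": g.role, "female_id": g.female_id, "male_id": g.male_id}
         for g in data.panel.values()]
    ).to_csv(out["genotypes"], index=False)

    pd.DataFrame(
        [{"location": m.location, "latitude": m.latitude, "longitude": m.longitude,
          "plot_size_m2": m.plot_size, "sowing_date": m.sowing_date.isoformat(),
          "harvest_date": m.harvest_date.isoformat(),
          "sowing_density_factor": m.sowing_density_factor}
         for m in data.meta.values()]
    ).to_csv(out["meta"], index=False)

    pd.DataFrame(
        [{"plot_id": p.plot_id, "location": p.location, "block": p.block,
          "genotype_id": p.genotype_id} for p in data.plots]
    ).to_csv(out["plots"], index=False)

    plot_level = data.traits.at_level("plot")
    pd.DataFrame({"plot_id": plot_level["unit"], "trait": plot_level["trait"],
                  "value": plot_level["value"]}).to_csv(out["traits"], index=False)

    ndvi = data.ndvi.copy()
    ndvi["date"] = [d_.isoformat() for d_ in ndvi["date"]]
    ndvi.to_csv(out["ndvi"], index=False)

    frames = []
    for loc, ws in data.weather.items():
        f = ws.frame.copy()
        f.insert(0, "location", loc)
        f["date"] = [d_.isoformat() for d_ in f["date"]]
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(out["weather"], index=False)
    return out


# ---------------------------------------------------------------------------
# Design validation and metadata summaries


def validate_design(panel: Mapping[str, Genotype],
                    plots: Iterable[PlotRecord]) -> dict:
    """Report-only audit of the augmented design.

    Returns entries per block, replication counts per genotype, and the
    hybrid counts per male and per female parent. Never raises: an odd design
    is reported, not rejected.
    """
    plots = list(plots)
    df = pd.DataFrame(
        [{"plot_id": p.plot_id, "location": p.location, "block": p.block,
          "genotype_id": p.genotype_id} for p in plots],
        columns=["plot_id", "location", "block", "genotype_id"],
    )
    hybrids = [g for g in panel.values() if g.role == "hybrid"]
    per_male = pd.Series([g.male_id for g in hybrids]).value_counts().sort_index()
    per_female = pd.Series([g.female_id for g in hybrids]).value_counts().sort_index()
    n_males = sum(1 for g in panel.values() if g.role == "male_parent")
    n_females = sum(1 for g in panel.values() if g.role == "female_parent")
    if df.empty:
        entries = pd.DataFrame(columns=["location", "block", "n_entries"])
        repl = pd.DataFrame(columns=["location", "genotype_id", "n_plots"])
    else:
        entries = (df.groupby(["location", "block"]).size()
                     .rename("n_entries").reset_index())
        repl = (df.groupby(["location", "genotype_id"]).size()
                  .rename("n_plots").reset_index())
    return {
        "n_plots": len(df),
        "entries_per_block": entries,
        "replication": repl,
        "hybrids_per_male": per_male,
        "hybrids_per_female": per_female,
        "mean_hybrids_per_male": len(hybrids) / n_males if n_males else float("nan"),
        "mean_hybrids_per_female": len(hybrids) / n_females if n_females else float("nan"),
    }


def cycle_duration(meta: TrialMeta) -> int:
    """Sowing-to-harvest duration in whole days."""
    days = (meta.harvest_date - meta.sowing_date).days
    if days < 0:  # unreachable through TrialMeta, kept for raw-date callers
        raise TrialDataError("harvest before sowing")
    return days


def weather_summary(weather: WeatherSeries, meta: TrialMeta, *,
                    frost_threshold: float = 0.0,
                    hot_threshold: float = 25.0) -> dict[str, float]:
    """Cycle climate summary over [sowing, harvest], both days inclusive.

    Daily mean temperature is (tmin + tmax)/2. Frost days count tmin below
    ``frost_threshold``; hot days count tmax above ``hot_threshold`` — the
    convention is configurable because trial reports rarely state it.
    """
    sub = weather.window(meta.sowing_date, meta.harvest_date)
    tmean = (sub["tmin"] + sub["tmax"]) / 2.0
    return {
        "mean_temp": float(tmean.mean()),
        "sum_temp": float(tmean.sum()),
        "n_frost_days": int((sub["tmin"] < frost_threshold).sum()),
        "n_hot_days": int((sub["tmax"] > hot_threshold).sum()),
        "cumulative_rainfall": float(sub["rainfall"].sum()),
    }


# ---------------------------------------------------------------------------
# Derived traits


def derive_gpy(yld: float, gpc: float) -> float:
    """Grain protein yield (t/ha) from yield (t/ha) and protein content (%)."""
    yld = np.asarray(yld, dtype=float)
    gpc = np.asarray(gpc, dtype=float)
    if np.any(yld < 0):
        raise TrialDataError("derive_gpy: negative yield")
    if np.any((gpc < 0) | (gpc > 100)):
        raise TrialDataError("derive_gpy: GPC outside [0, 100]%")
    return yld * gpc / 100.0


def derive_gpsm(yld: float, tkw: float) -> float:
    """Grains per square meter from yield (t/ha) and thousand-kernel weight (g).

    1 t/ha = 100 g/m2, so grains/m2 = yld*1e5/TKW.
    """
    yld = np.asarray(yld, dtype=float)
    tkw = np.asarray(tkw, dtype=float)
    if np.any(tkw <= 0):
        raise TrialDataError("derive_gpsm: TKW must be positive")
    if np.any(yld < 0):
        raise TrialDataError("derive_gpsm: negative yield")
    return yld * 1e5 / tkw


def fill_derived_traits(traits: TraitTable, *, tolerance: float = 0.02) -> TraitTable:
    """Recompute GPY and GPSM from YLD/GPC/TKW where absent.

    Supplied values win; a relative gap above ``tolerance`` versus the
    derivation is logged as a consistency warning, never overwritten.
    """
    df = traits.frame
    plot = df[df["level"] == "plot"]
    wide = plot.pivot_table(index=["unit", "location"], columns="trait",
                            values="value", aggfunc="first")
    new_rows = []
    for (unit, loc), row in wide.iterrows():
        for name, fn, args in (
            ("GPY", derive_gpy, ("YLD", "GPC")),
            ("GPSM", derive_gpsm, ("YLD", "TKW")),
        ):
            inputs = [row.get(a, np.nan) for a in args]
            if any(pd.isna(v) for v in inputs):
                continue
            derived = float(fn(*inputs))
            supplied = row.get(name, np.nan)
            if pd.isna(supplied):
                new_rows.append({"unit": unit, "location": loc, "trait": name,
                                 "value": derived, "level": "plot"})
            elif derived != 0 and abs(supplied - derived) / abs(derived) > tolerance:
                log.warning("plot %s: supplied %s=%.4g disagrees with derived %.4g",
                            unit, name, supplied, derived)
    if not new_rows:
        return traits
    return TraitTable(pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True))
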