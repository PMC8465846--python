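"""Stage orchestration: each stage reads the CSV artifacts of its
predecessors from a working directory and writes its own atomically.

Stages and their products::

    simulate      genotypes.csv plots.csv traits_long.csv ndvi_long.csv
                  weather.csv trial_meta.csv truth/*.csv
    phenology     phenology_traits.csv phenology_models.csv
    stats         blues_location.csv blues_combined.csv heritability.csv
    heterosis     heterosis_records.csv heterosis_summary.csv
    associations  correlations.csv ancova_results.csv gpd.csv
    report        report.md
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import heterosis as het
from . import phenology as phen
from . import trial_stats as tstats
from .data import TraitTable, TrialData, fill_derived_traits, read_trial
from .simulate import SimulationConfig, simulate, write_bundle

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int = 2):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    workdir: str = "."
    scope: str = "combined"              # heterosis/associations BLUE scope
    ta_mode: str = "measured"            # total-area convention
    boundary_rule: str = "joint_sse"     # flowering/senescence breakpoint rule
    heterosis_test: str = "one_sample"   # or 'two_sample'
    include_checks: bool = False         # checks in hybrid-vs-line contrasts
    top_k: int = 5                       # high-yield subset size in the report
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> str:
        # workdir is a path, not an analysis setting: keep it out so two runs
        # of the same configuration produce identical artifacts
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "workdir"}
        payload = json.dumps(payload, sort_keys=True)
        digest = hashlib.sha256(payload.encode()).hexdigest()[:12]
        return f"config {payload} hash={digest}"


def _atomic_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


def _require(d: Path, filename: str, producer: str) -> Path:
    p = d / filename
    if not p.exists():
        raise PipelineError(
            f"missing artifact {filename!r}; run the {producer!r} subcommand first")
    return p


# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> None:
    sim = SimulationConfig(seed=cfg.seed)
    data, truth = simulate(sim)
    write_bundle(data, truth, cfg.workdir)
    log.info("simulate: %d genotypes, %d plots, %d NDVI rows",
             len(data.panel), len(data.plots), len(data.ndvi))


def _load(cfg: PipelineConfig) -> TrialData:
    d = Path(cfg.workdir)
    _require(d, "genotypes.csv", "simulate")
    return read_trial(d)


def stage_phenology(cfg: PipelineConfig) -> None:
    data = _load(cfg)
    d = Path(cfg.workdir)
    hd = data.traits.frame[(data.traits.frame["trait"] == "HD")
                           & (data.traits.frame["level"] == "plot")]
    hd_by_plot = hd.set_index("unit")["value"]
    axes: dict[str, phen.ThermalTimeAxis] = {}
    plot_loc = {}
    for plot in data.plots:
        plot_loc[plot.plot_id] = plot.location
        if plot.plot_id not in hd_by_plot.index or \
                pd.isna(hd_by_plot[plot.plot_id]):
            continue
        site = data.meta[plot.location]
        heading = dt.date(site.harvest_date.year, 1, 1) + dt.timedelta(
            days=int(round(float(hd_by_plot[plot.plot_id]))) - 1)
        axes[plot.plot_id] = phen.build_thermal_axis(
            data.weather[plot.location], site.sowing_date, heading)
    series = phen.series_from_table(data.ndvi, axes, plot_loc)
    traits_df, models_df, report = phen.phenology_pipeline(
        series, rule=cfg.boundary_rule, ta_mode=cfg.ta_mode)
    _atomic_csv(traits_df, d / "phenology_traits.csv")
    _atomic_csv(models_df, d / "phenology_models.csv")
    log.info("phenology: fitted %d/%d plots; mean R growing %.3f flowering %.3f "
             "senescence %.3f", report["n_fitted"], report["n_plots"],
             report["mean_r_growing"], report["mean_r_flowering"],
             report["mean_r_senescence"])


def _full_plot_traits(cfg: PipelineConfig, data: TrialData) -> pd.DataFrame:
    """Plot-level traits + derived GPY/GPSM + modelled phenology traits."""
    d = Path(cfg.workdir)
    _require(d, "phenology_traits.csv", "phenology")
    pheno = pd.read_csv(d / "phenology_traits.csv", dtype={"plot_id": str})
    plot_loc = {p.plot_id: p.location for p in data.plots}
    rows = []
    rename = {"nmax": "Nmax", "tfn90": "TFN90", "tfn50": "TFN50",
              "tfn10": "TFN10", "tfn1": "TFN1", "gpa": "GPA", "fpa": "FPA",
              "spa": "SPA", "dpa": "DPA", "ta": "TA"}
    for rec in pheno.to_dict("records"):
        for col, trait in rename.items():
            rows.append({"unit": rec["plot_id"], "location": plot_loc.get(rec["plot_id"]),
                         "trait": trait, "value": rec.get(col), "level": "plot"})
    merged = TraitTable(pd.concat([data.traits.frame, pd.DataFrame(rows)],
                                  ignore_index=True))
    return fill_derived_traits(merged).frame


def stage_stats(cfg: PipelineConfig) -> None:
    data = _load(cfg)
    d = Path(cfg.workdir)
    traits_long = _full_plot_traits(cfg, data)
    plots = pd.DataFrame([{"plot_id": p.plot_id, "location": p.location,
                           "block": p.block, "genotype_id": p.genotype_id}
                          for p in data.plots])
    try:
        loc_blues = tstats.fit_blues(traits_long, plots, scope="single_location")
        comb_blues = tstats.fit_blues(traits_long, plots, scope="combined")
        herit = tstats.heritability_table(traits_long, plots)
    except tstats.TrialStatsError as exc:
        raise PipelineError(f"stats stage failed: {exc}", exit_code=3) from exc
    _atomic_csv(loc_blues, d / "blues_location.csv")
    _atomic_csv(comb_blues, d / "blues_combined.csv")
    _atomic_csv(herit, d / "heritability.csv")
    log.info("stats: %d location BLUEs, %d combined BLUEs, %d h2 rows",
             len(loc_blues), len(comb_blues), len(herit))


def _read_blues(cfg: PipelineConfig) -> pd.DataFrame:
    d = Path(cfg.workdir)
    name = "blues_combined.csv" if cfg.scope == "combined" else "blues_location.csv"
    return pd.read_csv(_require(d, name, "stats"), dtype={"unit": str})


def stage_heterosis(cfg: PipelineConfig) -> None:
    data = _load(cfg)
    d = Path(cfg.workdir)
    blues = _read_blues(cfg)
    if cfg.scope == "combined":
        records, skipped = het.compute_heterosis(blues, data.pedigree,
                                                 level="combined_blue")
        summary = het.summary_table(records, test=cfg.heterosis_test)
    else:  # per-location heterosis, stacked with a location column
        recs, sums, skipped = [], [], []
        for loc, sub in blues.groupby("location"):
            r, sk = het.compute_heterosis(sub, data.pedigree,
                                          level="location_blue")
            s = het.summary_table(r, test=cfg.heterosis_test)
            r.insert(0, "location", loc)
            s.insert(0, "location", loc)
            recs.append(r)
            sums.append(s)
            skipped += sk
        records = pd.concat(recs, ignore_index=True)
        summary = pd.concat(sums, ignore_index=True)
    _atomic_csv(records, d / "heterosis_records.csv")
    _atomic_csv(summary, d / "heterosis_summary.csv")
    if skipped:
        log.info("heterosis: skipped %d incomplete trios", len(skipped))


def _blues_wide_with_groups(cfg: PipelineConfig, data: TrialData,
                            blues: pd.DataFrame) -> pd.DataFrame:
    level = "combined_blue" if cfg.scope == "combined" else "location_blue"
    sub = blues[blues["level"] == level]
    wide = sub.pivot_table(index="unit", columns="trait", values="value",
                           aggfunc="first").reset_index()
    roles = pd.Series({g.id: g.role for g in data.panel.values()})
    labels = assoc.group_labels(roles, include_checks=cfg.include_checks)
    wide["group"] = wide["unit"].map(labels)
    return wide


def stage_associations(cfg: PipelineConfig) -> None:
    data = _load(cfg)
    d = Path(cfg.workdir)
    wide = _blues_wide_with_groups(cfg, data, _read_blues(cfg))
    corr = assoc.correlation_matrix(wide)
    _atomic_csv(corr, d / "correlations.csv")
    contrast = wide.dropna(subset=["group"])
    rows = []
    try:
        gpd = assoc.grain_protein_deviation(contrast)
        rows.append({"analysis": "GPD", "group_offset": gpd.group_offset,
                     "offset_p": gpd.offset_p, "n_hybrid": gpd.n_hybrid,
                     "n_line": gpd.n_line, "slope": gpd.slope})
        _atomic_csv(gpd.gpd.rename("GPD").reset_index(), d / "gpd.csv")
    except assoc.AssociationError as exc:
        log.warning("GPD unavailable: %s", exc)
    ancova = assoc.ancova_table(contrast)
    _atomic_csv(ancova, d / "ancova_results.csv")
    if rows:
        _atomic_csv(pd.DataFrame(rows), d / "gpd_test.csv")
    log.info("associations: %d correlation cells, %d ancovas",
             len(corr), len(ancova))


def stage_report(cfg: PipelineConfig) -> None:
    d = Path(cfg.workdir)
    herit = pd.read_csv(_require(d, "heritability.csv", "stats"))
    summary = pd.read_csv(_require(d, "heterosis_summary.csv", "heterosis"))
    blues = _read_blues(cfg)
    level = "combined_blue" if cfg.scope == "combined" else "location_blue"
    wide = blues[blues["level"] == level].pivot_table(
        index="unit", columns="trait", values="value", aggfunc="first")
    lines = ["# Trial analysis report", "", cfg.echo(), "",
             "## Descriptive statistics (adjusted means)", ""]
    desc = pd.DataFrame({
        "mean": wide.mean().round(1), "min": wide.min().round(1),
        "max": wide.max().round(1)})
    comb = herit[herit["scope"] == "combined"].set_index("trait")
    if len(comb):
        desc["h2"] = comb["h2"].round(2)
    lines.append(desc.to_csv())
    lines += ["## Heterosis summary", "", summary.round(3).to_csv(index=False)]
    anc_path = d / "ancova_results.csv"
    if anc_path.exists():
        lines += ["## Hybrid-vs-line contrasts", "",
                  pd.read_csv(anc_path).round(4).to_csv(index=False)]
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    os.close(fd)
    Path(tmp).write_text("\n".join(lines))
    os.replace(tmp, d / "report.md")


STAGES = {
    "simulate": stage_simulate,
    "phenology": stage_phenology,
    "stats": stage_stats,
    "heterosis": stage_heterosis,
    "associations": stage_associations,
    "report": stage_report,
}
STAGE_ORDER = ["simulate", "phenology", "stats", "heterosis",
               "associations", "report"]


def run(subcommand: str, cfg: PipelineConfig) -> None:
    """Run one stage, or every stage in order for ``all``."""
    log.info(cfg.echo())
    names = STAGE_ORDER if subcommand == "all" else [subcommand]
    unknown = [n for n in names if n not in STAGES]
    if unknown:
        raise PipelineError(f"unknown subcommand(s): {unknown}")
    for name in names:
        STAGES[name](cfg)
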