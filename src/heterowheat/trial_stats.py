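"""Adjusted means (BLUEs) and broad-sense heritability for augmented trials.

Per location the fixed model is Y_ij = mu + alpha_i + beta_j + eps_ij with
sum-to-zero constraints; the genotype adjusted mean is the marginal
(emmeans-style) mean over blocks. Across locations the additive fixed model
mu + alpha_i + beta_j(k) + L_k is used for BLUEs (the full genotype x
location interaction is saturated with one plot per cell in an augmented
design, so it is only estimated as a random component).

Variance components come from REML (random genotype intercept, plus a
genotype x location variance component in the combined scope; blocks and
locations fixed), and broad-sense heritability follows

    single site :  h2 = s2_G / (s2_G + s2_res / n)
    combined    :  h2 = s2_G / (s2_G + s2_GxL / l + s2_res / (n*l))

with n the average number of replicates per genotype per location and l the
number of locations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)


class TrialStatsError(ValueError):
    pass


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_gxl: float      # 0 / NaN for single-location scope
    sigma2_res: float
    n_bar: float           # replicates per genotype per location
    l: int                 # number of locations in scope
    truncated: bool = False  # any component clipped at the zero boundary

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_res"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise TrialStatsError(f"{name} must be >= 0")
        if self.n_bar < 1:
            raise TrialStatsError("n_bar must be >= 1")


@dataclass
class HeritabilityEstimate:
    trait: str
    scope: str             # 'single_location' or 'combined'
    h2: float
    components: VarianceComponents


def _plot_frame(traits_long: pd.DataFrame, plots: pd.DataFrame,
                trait: str) -> pd.DataFrame:
    """Join plot-level values of one trait with the design columns."""
    sub = traits_long[(traits_long["trait"] == trait)
                      & (traits_long["level"] == "plot")]
    df = sub.merge(plots, left_on="unit", right_on="plot_id", how="left",
                   suffixes=("", "_plot"))
    if "location_plot" in df.columns:
        df["location"] = df["location"].fillna(df["location_plot"])
    df = df.dropna(subset=["value"])
    df = df[["plot_id", "location", "block", "genotype_id", "value"]].copy()
    df["loc_block"] = df["location"].astype(str) + ":" + df["block"].astype(str)
    return df.reset_index(drop=True)


def _check_estimable(df: pd.DataFrame, terms: list[str]) -> None:
    """Raise naming aliased terms when the fixed design is rank-deficient."""
    mats = [pd.get_dummies(df[t], drop_first=True, dtype=float) for t in terms]
    X = pd.concat([pd.Series(1.0, index=df.index, name="const"), *mats], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise TrialStatsError(
            f"confounded design: terms {terms} are aliased "
            f"(rank {rank} < {X.shape[1]} columns)"
        )


def fit_blues(traits_long: pd.DataFrame, plots: pd.DataFrame, *,
              scope: str = "single_location",
              traits: list[str] | None = None) -> pd.DataFrame:
    """Fixed-effects adjusted means per genotype.

    Returns a long frame (unit=genotype_id, location, trait, value, level)
    where level is ``location_blue`` or ``combined_blue``. Genotypes missing
    from some location contribute their observed cells only; the additive
    model keeps their adjusted mean estimable (logged).
    """
    if scope not in ("single_location", "combined"):
        raise TrialStatsError(f"unknown scope {scope!r}")
    traits = traits or sorted(traits_long["trait"].unique())
    out_rows = []
    for trait in traits:
        df = _plot_frame(traits_long, plots, trait)
        if df.empty:
            continue
        if scope == "single_location":
            for loc, sub in df.groupby("location"):
                for gid, blue in _blues_one(sub, "block").items():
                    out_rows.append({"unit": gid, "location": loc, "trait": trait,
                                     "value": blue, "level": "location_blue"})
        else:
            if df["location"].nunique() < 2:
                raise TrialStatsError("combined scope requires >= 2 locations")
            n_cells = df.groupby("genotype_id")["location"].nunique()
            partial = n_cells[n_cells < df["location"].nunique()]
            if len(partial):
                log.info("%s: %d genotype(s) missing from some location; "
                         "adjusted means use observed cells", trait, len(partial))
            for gid, blue in _blues_one(df, "loc_block").items():
                out_rows.append({"unit": gid, "location": None, "trait": trait,
                                 "value": blue, "level": "combined_blue"})
    return pd.DataFrame(out_rows, columns=["unit", "location", "trait",
                                           "value", "level"])


def _blues_one(df: pd.DataFrame, block_col: str) -> dict[str, float]:
    """Marginal genotype means from the sum-to-zero fixed-effects fit."""
    genotypes = sorted(df["genotype_id"].unique())
    blocks = sorted(df[block_col].unique())
    if len(genotypes) == 1 or len(blocks) == 1:
        return {g: float(sub["value"].mean())
                for g, sub in df.groupby("genotype_id")}
    _check_estimable(df, ["genotype_id", block_col])
    model = smf.ols(
        f"value ~ C(genotype_id, Sum) + C({block_col}, Sum)", data=df
    ).fit()
    # emmeans: predict over the full genotype x block grid, average per genotype
    grid = pd.MultiIndex.from_product(
        [genotypes, blocks], names=["genotype_id", block_col]
    ).to_frame(index=False)
    grid["pred"] = model.predict(grid)
    return grid.groupby("genotype_id")["pred"].mean().to_dict()


# ---------------------------------------------------------------------------
# Variance components


def estimate_variance_components(traits_long: pd.DataFrame, plots: pd.DataFrame,
                                 trait: str, *, scope: str = "single_location",
                                 location: str | None = None
                                 ) -> VarianceComponents:
    """REML variance components with genotype (and genotype x location) random.

    Negative estimates cannot occur under REML's boundary handling here, but
    estimates at the zero boundary are flagged via ``truncated``.
    """
    df = _plot_frame(traits_long, plots, trait)
    if scope == "single_location":
        if location is not None:
            df = df[df["location"] == location]
        locs = df["location"].unique()
        if len(locs) != 1:
            raise TrialStatsError(
                "single_location scope needs exactly one location "
                f"(got {sorted(locs)}); pass location="
            )
        return _reml_single(df)
    if scope != "combined":
        raise TrialStatsError(f"unknown scope {scope!r}")
    if df["location"].nunique() < 2:
        raise TrialStatsError("combined scope requires >= 2 locations")
    return _reml_combined(df)


def _fit_mixed(md) -> "sm.regression.mixed_linear_model.MixedLMResults":
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (["lbfgs"], ["powell"], ["cg"]):
            try:
                res = md.fit(reml=True, method=method, maxiter=400)
            except Exception:
                continue
            if res.converged:
                return res
    raise TrialStatsError("REML did not converge under lbfgs/powell/cg")


def _reml_single(df: pd.DataFrame) -> VarianceComponents:
    n_bar = len(df) / df["genotype_id"].nunique()
    if df["value"].nunique() == 1:
        return VarianceComponents(0.0, np.nan, 0.0, n_bar, 1, truncated=True)
    fixed = "value ~ C(block, Sum)" if df["block"].nunique() > 1 else "value ~ 1"
    # REML is degenerate when the data are noiseless given genotype + block;
    # detect and return the limit directly
    sat = smf.ols(f"{fixed} + C(genotype_id)", data=df).fit()
    if sat.ssr / len(df) < 1e-12 * max(float(df["value"].var()), 1e-12):
        gmeans = pd.Series(sat.fittedvalues - sat.fittedvalues.mean()
                           ).groupby(df["genotype_id"].values).mean()
        return VarianceComponents(float(gmeans.var(ddof=1)), np.nan, 0.0,
                                  n_bar, 1, truncated=True)
    md = smf.mixedlm(fixed, data=df, groups=df["genotype_id"])
    res = _fit_mixed(md)
    s2g = float(res.cov_re.iloc[0, 0])
    s2r = float(res.scale)
    return VarianceComponents(max(s2g, 0.0), np.nan, max(s2r, 0.0), n_bar, 1,
                              truncated=bool(s2g < 1e-10))


def _reml_combined(df: pd.DataFrame) -> VarianceComponents:
    l = df["location"].nunique()
    if df["value"].nunique() == 1:
        n_bar = len(df) / df["genotype_id"].nunique() / l
        return VarianceComponents(0.0, 0.0, 0.0, max(n_bar, 1.0), l, truncated=True)
    md = smf.mixedlm("value ~ C(loc_block, Sum)", data=df,
                     groups=df["genotype_id"], re_formula="1",
                     vc_formula={"gxl": "0 + C(location)"})
    res = _fit_mixed(md)
    s2g = float(res.cov_re.iloc[0, 0])
    s2gxl = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    s2r = float(res.scale)
    n_bar = len(df) / df["genotype_id"].nunique() / l
    return VarianceComponents(max(s2g, 0.0), max(s2gxl, 0.0), max(s2r, 0.0),
                              max(n_bar, 1.0), l,
                              truncated=bool(min(s2g, s2gxl) < 1e-10))


def variance_components_moments(df: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments components for a *balanced* single-site design.

    Expected mean squares of the one-way genotype classification with n
    replicates: E[MSG] = s2_res + n*s2_G, E[MSE] = s2_res. Intended as the
    independent oracle path for REML tests; requires equal replication.
    """
    counts = df.groupby("genotype_id")["value"].count()
    if counts.nunique() != 1:
        raise TrialStatsError("moments estimator requires balanced replication")
    n = int(counts.iloc[0])
    groups = df.groupby("genotype_id")["value"]
    grand = df["value"].mean()
    g = counts.index.size
    msg = n * float(((groups.mean() - grand) ** 2).sum()) / (g - 1)
    if n > 1:
        sse = float(((df["value"] - df["genotype_id"].map(groups.mean())) ** 2).sum())
        mse = sse / (g * (n - 1))
    else:
        mse = 0.0
    s2g = max((msg - mse) / n, 0.0)
    return VarianceComponents(s2g, np.nan, mse, float(n), 1,
                              truncated=bool(msg < mse))


# ---------------------------------------------------------------------------
# Heritability


def heritability(components: VarianceComponents, *, scope: str,
                 trait: str = "") -> HeritabilityEstimate:
    """Broad-sense heritability from variance components (see module docstring)."""
    c = components
    if scope == "single_location":
        denom = c.sigma2_g + c.sigma2_res / c.n_bar
    elif scope == "combined":
        gxl = 0.0 if not np.isfinite(c.sigma2_gxl) else c.sigma2_gxl
        denom = c.sigma2_g + gxl / c.l + c.sigma2_res / (c.n_bar * c.l)
    else:
        raise TrialStatsError(f"unknown scope {scope!r}")
    if denom == 0:
        if c.sigma2_g == 0:
            return HeritabilityEstimate(trait, scope, 0.0, c)
        raise TrialStatsError("zero phenotypic variance")
    return HeritabilityEstimate(trait, scope, c.sigma2_g / denom, c)


def heritability_table(traits_long: pd.DataFrame, plots: pd.DataFrame, *,
                       traits: list[str] | None = None) -> pd.DataFrame:
    """h2 and components for every trait, per location and combined."""
    traits = traits or sorted(traits_long["trait"].unique())
    locations = sorted(plots["location"].unique())
    rows = []
    for trait in traits:
        jobs = [("single_location", loc) for loc in locations]
        if len(locations) >= 2:
            jobs.append(("combined", None))
        for scope, loc in jobs:
            try:
                vc = estimate_variance_components(
                    traits_long, plots, trait, scope=scope, location=loc)
                est = heritability(vc, scope=scope, trait=trait)
            except TrialStatsError as exc:
                log.warning("h2 %s/%s/%s failed: %s", trait, scope, loc, exc)
                continue
            rows.append({
                "trait": trait, "scope": scope, "location": loc,
                "h2": est.h2, "sigma2_g": vc.sigma2_g,
                "sigma2_gxl": vc.sigma2_gxl, "sigma2_res": vc.sigma2_res,
                "n_bar": vc.n_bar, "l": vc.l, "truncated": vc.truncated,
            })
    return pd.DataFrame(rows)
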