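"""Trait correlation matrices and hybrid-vs-line contrast models.

Three analyses share this module:

* pairwise-complete Pearson correlations over genotype adjusted means, with
  two-sided p-values and 0.05/0.01/0.001 significance stars;
* grain protein deviation (GPD): the residual of grain protein content
  regressed on grain yield over the whole panel, plus the hybrid-vs-line
  offset from GPC ~ YLD + group;
* group ANCOVAs for a response given a covariate (TKW | GPSM, TFN90 | HD,
  YLD | HD): an additive model tests the vertical offset between hybrids and
  lines at equal covariate, an interaction model tests whether the two
  slopes differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .data import TRAITS


class AssociationError(ValueError):
    pass


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for threshold, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p < threshold:
            return mark
    return "n.s."


def correlation_matrix(wide: pd.DataFrame, *,
                       trait_order: list[str] | None = None,
                       min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations over a unit x trait frame.

    Returns a long frame (trait_a, trait_b, r, p, n, stars), symmetric with a
    unit diagonal. Cells with fewer than ``min_pairs`` complete pairs or a
    constant trait are reported with NaN r rather than dropped.
    """
    order = trait_order or [t for t in TRAITS if t in wide.columns]
    missing = [t for t in order if t not in wide.columns]
    if missing:
        raise AssociationError(f"traits not in table: {missing}")
    rows = []
    for i, ta in enumerate(order):
        for tb in order[i:]:
            x, y = wide[ta].to_numpy(float), wide[tb].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if ta == tb:
                r, p = (1.0, 0.0) if n else (np.nan, np.nan)
            elif n < min_pairs or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                res = stats.pearsonr(x[ok], y[ok])
                r, p = float(res.statistic), float(res.pvalue)
            for a, b in ((ta, tb),) if ta == tb else ((ta, tb), (tb, ta)):
                rows.append({"trait_a": a, "trait_b": b, "r": r, "p": p,
                             "n": n, "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def correlation_square(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long correlation frame to a square r matrix."""
    return long.pivot(index="trait_a", columns="trait_b", values="r")


@dataclass
class GpdResult:
    gpd: pd.Series            # per-genotype residual, indexed by unit
    slope: float              # GPC-on-YLD regression slope
    intercept: float
    group_offset: float       # hybrid minus line GPC at equal yield
    offset_p: float
    n_hybrid: int
    n_line: int


def grain_protein_deviation(wide: pd.DataFrame, *,
                            group_col: str = "group") -> GpdResult:
    """GPD per genotype and the hybrid-vs-line offset.

    ``wide`` needs columns YLD, GPC and a group column with values
    'hybrid'/'line' (checks should already be excluded). GPD is the residual
    of GPC ~ YLD fitted over the whole panel; the offset comes from the
    joint model GPC ~ YLD + group.
    """
    df = wide.dropna(subset=["YLD", "GPC", group_col]).copy()
    if df["YLD"].nunique() < 2:
        raise AssociationError("degenerate yield variance; GPD undefined")
    base = smf.ols("GPC ~ YLD", data=df).fit()
    gpd = base.resid
    if "unit" in df.columns:
        gpd = pd.Series(gpd.to_numpy(), index=df["unit"], name="GPD")
    groups = set(df[group_col])
    if groups != {"hybrid", "line"}:
        raise AssociationError(f"need both 'hybrid' and 'line' groups, got {groups}")
    joint = smf.ols(f"GPC ~ YLD + C({group_col}, Treatment('line'))",
                    data=df).fit()
    term = f"C({group_col}, Treatment('line'))[T.hybrid]"
    return GpdResult(
        gpd=gpd, slope=float(base.params["YLD"]),
        intercept=float(base.params["Intercept"]),
        group_offset=float(joint.params[term]),
        offset_p=float(joint.pvalues[term]),
        n_hybrid=int((df[group_col] == "hybrid").sum()),
        n_line=int((df[group_col] == "line").sum()),
    )


@dataclass
class AncovaResult:
    response: str
    covariate: str
    group_offset: float        # hybrid minus line at equal covariate
    offset_p: float
    slope_difference: float    # hybrid slope minus line slope
    slope_difference_p: float
    slopes: dict[str, float]   # per-group slope from the interaction model
    intercepts: dict[str, float]
    n: dict[str, int]


def group_ancova(wide: pd.DataFrame, response: str, covariate: str, *,
                 group_col: str = "group", min_per_group: int = 3
                 ) -> AncovaResult:
    """Offset and slope-difference tests between hybrids and lines.

    The additive model ``response ~ covariate + group`` supplies the vertical
    group offset and its p-value; the interaction model
    ``response ~ covariate * group`` supplies the per-group slopes and the
    slope-difference p-value.
    """
    df = wide.dropna(subset=[response, covariate, group_col]).copy()
    counts = df[group_col].value_counts()
    if len(counts) < 2:
        raise AssociationError(
            f"need two groups for the contrast, got {list(counts.index)}")
    if (counts < min_per_group).any():
        raise AssociationError(
            f"fewer than {min_per_group} complete genotypes in a group: "
            f"{counts.to_dict()}")
    ref = "line" if "line" in counts.index else sorted(counts.index)[0]
    other = [g for g in counts.index if g != ref][0]
    coding = f"C({group_col}, Treatment('{ref}'))"
    add = smf.ols(f"{response} ~ {covariate} + {coding}", data=df).fit()
    inter = smf.ols(f"{response} ~ {covariate} * {coding}", data=df).fit()
    gterm = f"{coding}[T.{other}]"
    sterm = f"{covariate}:{coding}[T.{other}]"
    slope_ref = float(inter.params[covariate])
    slope_diff = float(inter.params[sterm])
    int_ref = float(inter.params["Intercept"])
    return AncovaResult(
        response=response, covariate=covariate,
        group_offset=float(add.params[gterm]),
        offset_p=float(add.pvalues[gterm]),
        slope_difference=slope_diff,
        slope_difference_p=float(inter.pvalues[sterm]),
        slopes={ref: slope_ref, other: slope_ref + slope_diff},
        intercepts={ref: int_ref,
                    other: int_ref + float(inter.params[gterm])},
        n=counts.to_dict(),
    )


#: the hybrid-vs-line contrasts reported by the pipeline
STANDARD_ANCOVAS = (("TKW", "GPSM"), ("TFN90", "HD"), ("YLD", "HD"))


def ancova_table(wide: pd.DataFrame, *, pairs=STANDARD_ANCOVAS,
                 group_col: str = "group") -> pd.DataFrame:
    rows = []
    for response, covariate in pairs:
        if response not in wide.columns or covariate not in wide.columns:
            continue
        try:
            res = group_ancova(wide, response, covariate, group_col=group_col)
        except AssociationError:
            continue
        rows.append({
            "response": res.response, "covariate": res.covariate,
            "group_offset": res.group_offset, "offset_p": res.offset_p,
            "slope_difference": res.slope_difference,
            "slope_difference_p": res.slope_difference_p,
            **{f"slope_{g}": s for g, s in res.slopes.items()},
            **{f"n_{g}": v for g, v in res.n.items()},
        })
    return pd.DataFrame(rows)


def group_labels(panel_roles: pd.Series, *, include_checks: bool = False
                 ) -> pd.Series:
    """Map genotype roles to 'hybrid'/'line' (checks excluded by default)."""
    out = pd.Series(index=panel_roles.index, dtype=object)
    out[panel_roles == "hybrid"] = "hybrid"
    out[panel_roles.isin(["female_parent", "male_parent"])] = "line"
    if include_checks:
        out[panel_roles.str.startswith("check")] = "line"
    return out
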