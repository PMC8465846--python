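"""Mid-parent and best-parent heterosis from genotype adjusted means.

For hybrid i with parents F and M and trait values on any common scale,

    mid-parent heterosis  Het_i = (HYB_i - (F_i + M_i)/2) / ((F_i + M_i)/2) * 100
    best-parent heterosis Bet_i = (HYB_i - max(F_i, M_i)) / max(F_i, M_i) * 100

No record is produced for a hybrid whose own value or either parent value is
missing. Per-trait summaries report the count, mean, a one-sample two-sided
Student t-test of the per-hybrid heterosis values against zero, min, max,
the coefficient of variation sigma/mu and the share of positive records; a
two-sample hybrids-vs-parents variant of the test is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class HeterosisError(ValueError):
    pass


RECORD_COLUMNS = ["hybrid_id", "trait", "hybrid_value", "female_value",
                  "male_value", "mid_parent", "best_parent",
                  "het_mp", "het_bp", "undefined"]


def compute_heterosis(blues: pd.DataFrame, pedigree: pd.DataFrame, *,
                      level: str = "combined_blue"
                      ) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Per-(hybrid, trait) heterosis records from a long BLUE table.

    ``blues`` has columns unit/trait/value/level; ``pedigree`` maps
    hybrid_id -> female_id, male_id. Returns (records, skip list) where the
    skip list holds (hybrid, trait, reason) for incomplete trios. Records
    with a zero mid-parent are flagged ``undefined`` and excluded from
    summaries downstream.
    """
    sub = blues[blues["level"] == level] if "level" in blues.columns else blues
    values = {(r.unit, r.trait): r.value for r in sub.itertuples()
              if pd.notna(r.value)}
    traits = sorted(sub["trait"].unique())
    rows, skipped = [], []
    for ped in pedigree.itertuples():
        for trait in traits:
            trio = [values.get((g, trait))
                    for g in (ped.hybrid_id, ped.female_id, ped.male_id)]
            if any(v is None for v in trio):
                which = ["hybrid", "female", "male"][
                    [v is None for v in trio].index(True)]
                skipped.append((ped.hybrid_id, trait, f"missing {which} value"))
                continue
            hyb, fem, mal = map(float, trio)
            mp = (fem + mal) / 2.0
            bp = max(fem, mal)
            undefined = mp == 0 or bp == 0
            rows.append({
                "hybrid_id": ped.hybrid_id, "trait": trait,
                "hybrid_value": hyb, "female_value": fem, "male_value": mal,
                "mid_parent": mp, "best_parent": bp,
                "het_mp": np.nan if mp == 0 else (hyb - mp) / mp * 100.0,
                "het_bp": np.nan if bp == 0 else (hyb - bp) / bp * 100.0,
                "undefined": undefined,
            })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS), skipped


@dataclass
class HeterosisSummary:
    trait: str
    kind: str               # 'mid_parent' or 'best_parent'
    n_hybrids: int
    mean_pct: float
    p_value: float
    min_pct: float
    max_pct: float
    cv: float               # sigma/mu
    frac_positive: float


_KIND_COL = {"mid_parent": "het_mp", "best_parent": "het_bp"}


def summarize_heterosis(records: pd.DataFrame, trait: str, kind: str, *,
                        test: str = "one_sample",
                        ) -> HeterosisSummary:
    """Summary statistics for one trait and heterosis kind.

    ``test='one_sample'`` (default) tests the per-hybrid heterosis values
    against zero; ``test='two_sample'`` runs Welch's t-test of hybrid values
    against the pooled parent values instead.
    """
    if kind not in _KIND_COL:
        raise HeterosisError(f"kind must be one of {sorted(_KIND_COL)}")
    sub = records[(records["trait"] == trait) & (~records["undefined"])]
    het = sub[_KIND_COL[kind]].dropna().to_numpy()
    n = len(het)
    if n == 0:
        raise HeterosisError(f"no records for trait {trait!r}")
    mean = float(np.mean(het))
    if n < 2:
        p = np.nan
    elif test == "one_sample":
        if np.std(het, ddof=1) == 0:
            p = 0.0 if mean != 0 else 1.0
        else:
            p = float(stats.ttest_1samp(het, 0.0).pvalue)
    elif test == "two_sample":
        hyb = sub["hybrid_value"].to_numpy()
        par = np.concatenate([sub["female_value"].to_numpy(),
                              sub["male_value"].to_numpy()])
        p = float(stats.ttest_ind(hyb, par, equal_var=False).pvalue)
    else:
        raise HeterosisError(f"unknown test {test!r}")
    sd = float(np.std(het, ddof=1)) if n > 1 else np.nan
    return HeterosisSummary(
        trait=trait, kind=kind, n_hybrids=n, mean_pct=mean, p_value=p,
        min_pct=float(np.min(het)), max_pct=float(np.max(het)),
        cv=sd / mean if (n > 1 and mean != 0) else np.nan,
        frac_positive=float(np.mean(het > 0)),
    )


def summary_table(records: pd.DataFrame, *, test: str = "one_sample"
                  ) -> pd.DataFrame:
    """Both heterosis kinds for every trait present in ``records``."""
    rows = []
    for trait in sorted(records["trait"].unique()):
        for kind in ("mid_parent", "best_parent"):
            try:
                rows.append(vars(summarize_heterosis(records, trait, kind,
                                                     test=test)))
            except HeterosisError:
                continue
    return pd.DataFrame(rows)


def top_k_subset(blues: pd.DataFrame, records: pd.DataFrame, k: int, *,
                 rank_trait: str = "YLD", level: str = "combined_blue",
                 test: str = "one_sample") -> pd.DataFrame:
    """Heterosis summaries restricted to the k highest-yielding hybrids.

    Ranking uses the ``rank_trait`` BLUE; ties break by hybrid id so the
    subset is deterministic.
    """
    sub = blues[blues["level"] == level] if "level" in blues.columns else blues
    hybrids = records["hybrid_id"].unique()
    ranking = (sub[(sub["trait"] == rank_trait) & (sub["unit"].isin(hybrids))]
               .sort_values(["value", "unit"], ascending=[False, True]))
    if k > len(ranking):
        raise HeterosisError(f"k={k} exceeds {len(ranking)} ranked hybrids")
    keep = set(ranking["unit"].head(k))
    return summary_table(records[records["hybrid_id"].isin(keep)], test=test)
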