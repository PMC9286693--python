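"""Comparison machinery: effect models, binwise tests, fit correlations.

Accuracy effects are estimated with a binomial-family fixed-effects GLM
(logit link) of trial correctness on noise intensity, noise position and
group, with cluster-robust standard errors by trained replication.  The
coding is chosen so the expected signs under the empirical effects are all
negative: intensity is scaled to [0, 1] (1 = strongest noise), position is
an indicator for word-initial masking, group an indicator for the
non-native version.

Looking preferences are tested per timestep bin with paired one-tailed
t-tests of the item-level bin mean against the item-level baseline.

Fit-to-data measures correlate condition-cell means between a model table
and a human table, either over all cells (overall fit) or over
within-factor difference vectors (factor-focused fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "EffectEstimate",
    "effect_model_accuracy",
    "binwise_ttests",
    "overall_fit",
    "factor_focused_fit",
]


@dataclass(frozen=True)
class EffectEstimate:
    term: str
    coef: float
    se: float
    z: float
    p: float


def _design(trials: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    X = pd.DataFrame(index=trials.index)
    dropped = []
    sd = trials["sd"].astype(float)
    if sd.nunique() > 1:
        X["intensity"] = (sd - sd.min()) / (sd.max() - sd.min())
    else:
        dropped.append("intensity")
    if trials["position"].nunique() > 1:
        X["position_initial"] = (trials["position"] == "initial").astype(float)
    else:
        dropped.append("position_initial")
    if trials["version"].nunique() > 1:
        X["group_nonnative"] = (trials["version"] == "nonnative").astype(float)
    else:
        dropped.append("group_nonnative")
    for term in dropped:
        warnings.warn(f"single-level factor dropped from accuracy model: {term}")
    return X, dropped


def effect_model_accuracy(trials: pd.DataFrame) -> dict[str, EffectEstimate]:
    """Binomial GLM of correctness on intensity, position and group.

    ``trials`` is an offline trial table (columns sd, position, version,
    correct, replication).  Replication ids serve as cluster labels for
    robust standard errors.  Single-level factors are dropped with a
    warning.  Returns estimates keyed by term name.
    """
    X, _ = _design(trials)
    X = sm.add_constant(X, has_constant="add")
    y = trials["correct"].astype(float)
    groups = trials["replication"].astype("category").cat.codes
    model = sm.GLM(y, X, family=sm.families.Binomial())
    if groups.nunique() > 1:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(groups)})
    else:
        res = model.fit()
    out = {}
    for term in X.columns:
        if term == "const":
            continue
        out[term] = EffectEstimate(
            term=term,
            coef=float(res.params[term]),
            se=float(res.bse[term]),
            z=float(res.tvalues[term]),
            p=float(res.pvalues[term]),
        )
    return out


def binwise_ttests(per_item: pd.DataFrame, value: str = "log_pref_raw",
                   baseline_t: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Paired one-tailed t-tests of each timestep bin against baseline.

    ``per_item`` needs columns ``word``, ``t`` and the value column; items
    are matched across bins.  The alternative hypothesis is that the bin
    mean exceeds the baseline mean.  Zero-variance differences with a
    nonzero mean yield a missing p; all-zero differences yield t = 0,
    p = 0.5 (no evidence either way).
    """
    wide = per_item.pivot_table(index="word", columns="t", values=value)
    if wide.shape[0] < 2:
        raise ValueError("binwise tests require at least 2 items")
    base = wide[baseline_t]
    rows = []
    for t in sorted(c for c in wide.columns if c != baseline_t):
        diff = (wide[t] - base).dropna()
        degenerate = len(diff) < 2 or diff.std(ddof=1) <= 1e-12 * max(1.0, diff.abs().max())
        if degenerate:
            if len(diff) >= 2 and np.allclose(diff, 0.0):
                stat, p = 0.0, 0.5
            else:
                stat, p = float("nan"), float("nan")
        else:
            stat, p = scipy.stats.ttest_rel(wide[t].dropna(), base.loc[diff.index],
                                            alternative="greater")
            stat, p = float(stat), float(p)
        rows.append({"t": t, "t_stat": stat, "p": p,
                     "significant": bool(p < alpha) if np.isfinite(p) else False})
    return pd.DataFrame(rows)


def _match_cells(model_table: pd.DataFrame, human_table: pd.DataFrame,
                 measure: str, factors: Sequence[str]) -> pd.DataFrame:
    m = model_table[model_table["measure"] == measure]
    h = human_table[human_table["measure"] == measure]
    merged = m.merge(h, on=list(factors), suffixes=("_model", "_human"))
    return merged


_FACTORS = ("intensity", "position", "group")


def overall_fit(model_table: pd.DataFrame, human_table: pd.DataFrame,
                measure: str, factors: Sequence[str] = _FACTORS
                ) -> tuple[float, float]:
    """Pearson r (and p) between model and human cell means over all
    factor-level combinations of a measure."""
    merged = _match_cells(model_table, human_table, measure, factors)
    if len(merged) < 3:
        raise ValueError(f"overall fit needs at least 3 matched cells, got {len(merged)}")
    r, p = scipy.stats.pearsonr(merged["value_model"], merged["value_human"])
    return float(r), float(p)


def factor_focused_fit(model_table: pd.DataFrame, human_table: pd.DataFrame,
                       measure: str, factor: str, baseline_level,
                       factors: Sequence[str] = _FACTORS) -> tuple[float, float]:
    """Fit focused on one factor: correlate model and human difference
    vectors (level minus baseline level, within every combination of the
    other factors).

    Returns (r, p); r is NaN when either difference vector is constant
    (e.g. a baseline model with exactly zero group differences), which is
    reported as a non-capture.
    """
    merged = _match_cells(model_table, human_table, measure, factors)
    others = [f for f in factors if f != factor]
    levels = sorted(merged[factor].unique())
    if baseline_level not in levels or len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels incl. baseline")
    base = merged[merged[factor] == baseline_level].set_index(others)
    diffs_m, diffs_h = [], []
    for level in levels:
        if level == baseline_level:
            continue
        cur = merged[merged[factor] == level].set_index(others)
        missing = base.index.difference(cur.index).tolist() \
            + cur.index.difference(base.index).tolist()
        if missing:
            raise ValueError(f"incomplete cells for {factor}={level}: {missing}")
        cur = cur.loc[base.index]
        diffs_m.extend((cur["value_model"] - base["value_model"]).tolist())
        diffs_h.extend((cur["value_human"] - base["value_human"]).tolist())
    dm, dh = np.asarray(diffs_m), np.asarray(diffs_h)
    if dm.std() == 0 or dh.std() == 0:
        return float("nan"), float("nan")
    r, p = scipy.stats.pearsonr(dm, dh)
    return float(r), float(p)
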