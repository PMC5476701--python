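"""Group-level inference.

Covers the Box-Cox normalization transform, repeated-measures ANOVA on
mixed-effect models (per-fly random intercept; group as between factor,
trial as within factor), the hemisphere-difference test, and the
Spearman/regression analysis of shock-response strength versus the
current each fly received.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Box-Cox

@dataclass(frozen=True)
class BoxCoxResult:
    transformed: np.ndarray
    lmbda: float
    shift: float  # added to the data before transforming (0 if all > 0)


def boxcox_transform(values, grid_step: float = 0.01,
                     grid_range: tuple[float, float] = (-3.0, 3.0)
                     ) -> BoxCoxResult:
    """Box-Cox power transform with λ chosen by profile likelihood on a
    fixed grid.

    y -> (y^λ - 1)/λ (natural log at λ = 0). Non-positive inputs are
    shifted to min + 1e-6 of the range first; the shift is returned so
    it can be reported alongside λ. Deterministic.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 5:
        raise StatsError("Box-Cox needs at least 5 observations")
    rng_ = y.max() - y.min()
    if rng_ == 0:
        raise StatsError("constant input: Box-Cox λ is unidentifiable")
    shift = 0.0
    if y.min() <= 0:
        shift = -y.min() + 1e-6 * rng_
        y = y + shift
    lams = np.arange(grid_range[0], grid_range[1] + grid_step / 2, grid_step)
    lls = np.array([sps.boxcox_llf(lam, y) for lam in lams])
    lam = float(lams[np.argmax(lls)])
    if abs(lam) < grid_step / 2:
        lam = 0.0
        transformed = np.log(y)
    else:
        transformed = (y ** lam - 1.0) / lam
    return BoxCoxResult(transformed=transformed, lmbda=lam, shift=shift)


# ---------------------------------------------------------------------------
# Mixed-effect repeated-measures ANOVA

@dataclass(frozen=True)
class GroupEffectResult:
    compartment: str | None
    genotype: str | None
    effect: str  # "group", "trial", "group x trial", or "hemisphere"
    F: float
    df: tuple[int, float]
    p: float
    transform_lambda: float | None = None


def fit_group_model(
    table: pd.DataFrame,
    *,
    dv: str = "strength",
    transform: str | None = None,
    compartment: str | None = None,
    genotype: str | None = None,
    drop_reference_trial: bool = True,
) -> list[GroupEffectResult]:
    """Repeated-measures ANOVA on the mixed model
    dv ~ group + trial + group:trial with a per-fly random intercept.

    Expects a single-cell table (one genotype x compartment) with
    columns fly_id, group, trial, ``dv`` and optionally
    reference_trial. Only trials present in both groups are used, and
    reference-trial rows (identically zero) are dropped. With a single
    within-subject trial level the model degenerates to a one-way
    between-group ANOVA, consistent with a two-sample t-type test.
    ``transform="boxcox"`` applies the Box-Cox transform (used for the
    skewed DAN data) before fitting.
    """
    df = table.copy()
    for col in ("fly_id", "group", "trial", dv):
        if col not in df.columns:
            raise StatsError(f"missing column {col!r}")
    if drop_reference_trial and "reference_trial" in df.columns:
        df = df[df.trial != df.reference_trial]
    trials = [t for t in sorted(df.trial.unique())
              if set(df.loc[df.trial == t, "group"]) == {"paired", "unpaired"}]
    df = df[df.trial.isin(trials)]
    if df.groupby("group")["fly_id"].nunique().min() < 2 or len(df) == 0:
        raise StatsError("need at least 2 flies per group on common trials")

    lam = None
    if transform == "boxcox":
        res = boxcox_transform(df[dv].to_numpy())
        df = df.assign(**{dv: res.transformed})
        lam = res.lmbda

    if len(trials) == 1:
        paired = df.loc[df.group == "paired", dv]
        unpaired = df.loc[df.group == "unpaired", dv]
        F, p = sps.f_oneway(paired, unpaired)
        results = [GroupEffectResult(compartment, genotype, "group",
                                     float(F), (1, len(df) - 2), float(p),
                                     lam)]
        return results

    aov = pg.mixed_anova(data=df, dv=dv, within="trial", subject="fly_id",
                         between="group", correction=False)
    name_map = {"group": "group", "trial": "trial",
                "Interaction": "group x trial"}
    results = []
    for _, row in aov.iterrows():
        effect = name_map.get(row["Source"], row["Source"])
        results.append(GroupEffectResult(
            compartment, genotype, effect, float(row["F"]),
            (int(row["DF1"]), float(row["DF2"])), float(row["p_unc"]), lam))
    return results


def group_effect_p(table: pd.DataFrame, **kwargs) -> float:
    """p-value of the between-group effect; convenience for effect
    tables."""
    for res in fit_group_model(table, **kwargs):
        if res.effect == "group":
            return res.p
    raise StatsError("no group effect in model output")


def hemisphere_test(
    table: pd.DataFrame,
    *,
    dv: str = "strength",
    compartment: str | None = None,
    genotype: str | None = None,
) -> GroupEffectResult:
    """Within-fly hemisphere comparison (left vs right).

    Repeated-measures ANOVA with hemisphere as the fixed within-subject
    factor and fly as the random intercept, on per-fly-per-hemisphere
    mean strengths. Flies measured in only one hemisphere are dropped.
    """
    for col in ("fly_id", "hemisphere", dv):
        if col not in table.columns:
            raise StatsError(f"missing column {col!r}")
    agg = (table.groupby(["fly_id", "hemisphere"])[dv].mean().reset_index())
    counts = agg.groupby("fly_id")["hemisphere"].nunique()
    both = counts[counts == 2].index
    agg = agg[agg.fly_id.isin(both)]
    if agg.fly_id.nunique() < 3:
        raise StatsError("need at least 3 flies with both hemispheres")
    aov = pg.rm_anova(data=agg, dv=dv, within="hemisphere", subject="fly_id",
                      detailed=True)
    row = aov[aov.Source == "hemisphere"].iloc[0]
    return GroupEffectResult(
        compartment, genotype, "hemisphere", float(row["F"]),
        (int(row["DF"]), float(aov[aov.Source == "Error"].iloc[0]["DF"])),
        float(row["p_unc"]))


# ---------------------------------------------------------------------------
# Shock-current correlation (dose-response)

@dataclass(frozen=True)
class CorrelationResult:
    compartment: str | None
    rho: float
    p: float
    n: int
    regression_slope: float      # ΔF/F per log10(nA)
    regression_intercept: float


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (no ties)."""
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    d = rx[perms] - ry
    r = 1.0 - 6.0 * (d * d).sum(axis=1) / (n * (n * n - 1))
    return float(np.mean(np.abs(r) >= abs(rho) - 1e-12))


def shock_current_correlation(
    strengths, currents_na, compartment: str | None = None
) -> CorrelationResult:
    """Spearman rank correlation of US response strength versus shock
    current, plus the OLS regression of strength on log10(current/nA).

    The p-value is an exact permutation value for n <= 10 without ties,
    else the asymptotic t-approximation.
    """
    s = np.asarray(strengths, dtype=float)
    c = np.asarray(currents_na, dtype=float)
    if s.size != c.size:
        raise StatsError("strengths and currents differ in length")
    if s.size < 3:
        raise StatsError("need at least 3 (strength, current) pairs")
    if np.any(c <= 0):
        raise StatsError("currents must be > 0")
    rho, p_asym = sps.spearmanr(s, c)
    no_ties = (np.unique(s).size == s.size) and (np.unique(c).size == c.size)
    if s.size <= 10 and no_ties and math.isfinite(rho):
        p = _spearman_exact_p(c, s, rho)
    else:
        p = float(p_asym)
    slope, intercept = np.polyfit(np.log10(c), s, 1)
    return CorrelationResult(
        compartment=compartment, rho=float(rho), p=float(p), n=int(s.size),
        regression_slope=float(slope), regression_intercept=float(intercept))
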