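"""Effect summaries for the simulated cross-sectional study.

The original analysis fit generalized linear mixed models; with one eye
per mouse in a cross-sectional design the mouse random intercept
collapses into between-mouse variance, so the pipeline first averages
everything within mouse (and side), then contrasts groups directly:
normal-theory Welch differences with 95% CIs for thickness and MCP/AR
outcomes, and a gamma GLM with log link for contrast sensitivity, whose
exponentiated group coefficient is the fold change.  No multiplicity
adjustment is applied (all contrasts are planned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "EffectEstimate",
    "per_mouse_summary",
    "mean_difference",
    "gamma_fold_change",
    "light_dark_contrast",
    "mixed_model_contrast",
]

OUTCOME_COLUMNS = ("elm_rpe_um", "mcp_ar", "ipl_um", "inl_opl_um", "onl_um", "cs", "acuity_cd")


@dataclass(frozen=True)
class EffectEstimate:
    outcome: str
    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n_per_group: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("estimate must lie inside its confidence interval")

    def format(self, units: str = "") -> str:
        u = f" {units}" if units else ""
        return (
            f"{self.outcome} [{self.contrast}]: mean {self.estimate:.2f}{u}, "
            f"95% CI {self.ci_low:.2f}-{self.ci_high:.2f}{u} (p = {self.p:.2g}, "
            f"n = {self.n_per_group[0]}/{self.n_per_group[1]})"
        )


def per_mouse_summary(
    records: pd.DataFrame,
    *,
    collapse_sides: bool = False,
) -> pd.DataFrame:
    """Arithmetic mean of every outcome within mouse (and side unless
    ``collapse_sides``), keeping the group/condition labels.

    Raises on duplicate keys that carry conflicting labels.
    """

    keys = ["mouse", "group", "condition"] + ([] if collapse_sides else ["side"])
    check = records.groupby("mouse")[["group", "condition"]].nunique()
    if (check > 1).any().any():
        raise ValueError("conflicting group/condition labels within a mouse")
    value_cols = [c for c in OUTCOME_COLUMNS if c in records.columns]
    return records.groupby(keys, as_index=False)[value_cols].mean()


def _welch(a: np.ndarray, b: np.ndarray, alpha: float):
    res = sps.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return float(res.pvalue), float(ci.low), float(ci.high)


def mean_difference(
    group_a: np.ndarray,
    group_b: np.ndarray,
    *,
    alpha: float = 0.05,
    outcome: str = "",
    contrast: str = "A-B",
) -> EffectEstimate:
    """Difference of means, ``mean(A) - mean(B)``, with Welch two-sample
    confidence interval and p-value."""

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    est = float(a.mean() - b.mean())
    if a.std() == 0 and b.std() == 0:
        # degenerate: no variance anywhere
        p = 1.0 if est == 0 else 0.0
        return EffectEstimate(outcome, contrast, est, est, est, max(p, np.finfo(float).tiny) if est == 0 else np.finfo(float).tiny, (a.size, b.size))
    p, lo, hi = _welch(a, b, alpha)
    return EffectEstimate(outcome, contrast, est, lo, hi, float(p), (a.size, b.size))


def gamma_fold_change(
    group_a: np.ndarray,
    group_b: np.ndarray,
    *,
    alpha: float = 0.05,
    outcome: str = "cs",
    contrast: str = "B/A",
) -> EffectEstimate:
    """Fold change of group B relative to group A from a two-group gamma
    GLM with log link (fit by IRLS; Pearson-moment dispersion), with a
    Wald confidence interval on the log scale.

    For this model the point estimate equals the ratio of sample means.
    """

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("gamma model requires strictly positive values")
    if a.std() == 0 and b.std() == 0:
        # no within-group dispersion: the GLM fold is the exact mean ratio
        # with a zero-width interval
        fold = float(b.mean() / a.mean())
        p = 1.0 if fold == 1.0 else np.finfo(float).tiny
        return EffectEstimate(outcome, contrast, fold, fold, fold, p, (a.size, b.size))
    y = np.concatenate([a, b])
    X = np.column_stack([np.ones(y.size), np.r_[np.zeros(a.size), np.ones(b.size)]])
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit()
    beta = float(res.params[1])
    se = float(res.bse[1])
    z = sps.norm.ppf(1 - alpha / 2)
    p = float(2 * sps.norm.sf(abs(beta) / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return EffectEstimate(
        outcome,
        contrast,
        float(np.exp(beta)),
        float(np.exp(beta - z * se)),
        float(np.exp(beta + z * se)),
        max(p, np.finfo(float).tiny),
        (a.size, b.size),
    )


def mixed_model_contrast(
    records: pd.DataFrame,
    outcome: str,
    *,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Optional mixed-model route: linear mixed model with a random
    intercept per mouse on the eye-side records (no prior per-mouse
    averaging), fixed effect = condition, dark minus light.

    This delegates to statsmodels MixedLM; the default per-mouse-summary
    contrasts are statistically equivalent for balanced cross-sectional
    designs and remain the primary route.
    """

    needed = {"mouse", "condition", outcome}
    if not needed <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(needed)}")
    df = records.dropna(subset=[outcome]).copy()
    if set(df["condition"]) != {"light", "dark"}:
        raise ValueError("need exactly the conditions 'light' and 'dark'")
    df["is_dark"] = (df["condition"] == "dark").astype(float)
    model = sm.MixedLM(df[outcome].to_numpy(),
                       np.column_stack([np.ones(len(df)), df["is_dark"].to_numpy()]),
                       groups=df["mouse"].to_numpy())
    res = model.fit(reml=True)
    est = float(res.params[1])
    se = float(res.bse[1])
    z = sps.norm.ppf(1 - alpha / 2)
    p = float(2 * sps.norm.sf(abs(est) / se)) if se > 0 else 1.0
    n_dark = df.loc[df.is_dark == 1, "mouse"].nunique()
    n_light = df.loc[df.is_dark == 0, "mouse"].nunique()
    return EffectEstimate(outcome, "dark-light (mixed)", est, est - z * se,
                          est + z * se, max(p, np.finfo(float).tiny),
                          (n_dark, n_light))


def light_dark_contrast(
    records: pd.DataFrame,
    outcome: str,
    *,
    alpha: float = 0.05,
    collapse_sides: bool = True,
    use_gamma: bool | None = None,
) -> EffectEstimate:
    """Dark-minus-light contrast of a per-mouse-summarized outcome
    (between-mouse, cross-sectional).  Contrast sensitivity uses the
    gamma log-link fold change (dark/light); everything else uses the
    normal-theory mean difference."""

    summ = per_mouse_summary(records, collapse_sides=collapse_sides)
    if not collapse_sides:
        summ = summ.groupby(["mouse", "group", "condition"], as_index=False)[outcome].mean()
    present = set(summ["condition"])
    if not {"light", "dark"} <= present:
        raise ValueError(f"need both conditions, found {sorted(present)}")
    dark = summ.loc[summ.condition == "dark", outcome].to_numpy()
    light = summ.loc[summ.condition == "light", outcome].to_numpy()
    if use_gamma is None:
        use_gamma = outcome == "cs"
    if use_gamma:
        return gamma_fold_change(light, dark, alpha=alpha, outcome=outcome,
                                 contrast="dark/light")
    return mean_difference(dark, light, alpha=alpha, outcome=outcome,
                           contrast="dark-light")
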