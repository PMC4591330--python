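"""Model comparison and group-comparison reporting.

Hazard ratios from models with different covariates are not directly
comparable, so predictive models are ranked by Royston's D-based explained
variation.  The prognostic index PI = x'beta of each subject (baseline
covariates) is ranked, mapped to expected standard-normal order statistics
(rankits, Blom's approximation), scaled by kappa = sqrt(8/pi), and the
survival model is refitted with that single regressor; its coefficient is
the separation statistic D.  Explained variation is then

    R2_D = (D**2 / kappa**2) / (pi**2 / 6 + D**2 / kappa**2),

which lies in [0, 1], equals 0 when the model separates nothing, and is
invariant to affine rescaling of any covariate (only PI ranks matter).

Group contrasts (MVC vs no-MVC, glaucoma vs control) use the Wilcoxon
rank-sum test for continuous variables and Fisher's exact test for 2x2
categorical tables (chi-squared for wider tables, which have no exact scipy
routine).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survival import EpisodeTable, WeibullTDModel, WeibullTDResults

__all__ = ["RoystonR2Result", "GroupComparison", "royston_r2", "compare_groups"]

KAPPA = math.sqrt(8.0 / math.pi)
SIGMA2 = math.pi**2 / 6.0


@dataclass(frozen=True)
class RoystonR2Result:
    """Royston's prognostic separation D and the derived explained variation."""

    D: float
    r2: float
    kappa: float = KAPPA
    sigma2: float = SIGMA2
    degenerate: bool = False  # constant prognostic index

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0 or np.isnan(self.r2)):
            raise ValueError("r2 must lie in [0, 1]")


def _rankits(values: np.ndarray) -> np.ndarray:
    """Expected normal order statistics via Blom's approximation
    Phi^{-1}((r - 3/8) / (n + 1/4)), with average ranks for ties."""
    r = stats.rankdata(values, method="average")
    n = len(values)
    return stats.norm.ppf((r - 0.375) / (n + 0.25))


def royston_r2(fit: WeibullTDResults, episodes: EpisodeTable) -> RoystonR2Result:
    """Royston's modified R² for a fitted Weibull model.

    The PI uses each subject's baseline covariate vector (a time-dependent
    PI is undefined in the D framework).  A constant PI (e.g. all
    coefficients zero) yields D = 0 and R² = 0, flagged as degenerate.
    """
    if not fit.model.covariates:
        raise ValueError("royston_r2 requires a model with at least one covariate")
    base = episodes.baseline()
    pi = base[fit.model.covariates].to_numpy() @ fit.beta.to_numpy()
    if np.ptp(pi) == 0.0:
        return RoystonR2Result(D=0.0, r2=0.0, degenerate=True)
    z = pd.Series(_rankits(pi) / KAPPA, index=base.index, name="pi_rankit")

    df = episodes.data.merge(
        z.rename_axis("subject_id").reset_index(), on="subject_id", how="inner"
    )
    refit = WeibullTDModel(
        df[["subject_id", "start", "stop", "event", "pi_rankit"]],
        covariates=["pi_rankit"],
    ).fit()
    D = float(refit.beta.iloc[0])
    r2 = (D**2 / KAPPA**2) / (SIGMA2 + D**2 / KAPPA**2)
    return RoystonR2Result(D=D, r2=float(r2))


@dataclass(frozen=True)
class GroupComparison:
    """One variable's between-group contrast, formatted for a Table-1 row."""

    variable: str
    group_a: str
    group_b: str
    summary_a: str
    summary_b: str
    p_value: float
    test_name: str


def _fmt_cont(x: np.ndarray) -> str:
    return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"


def compare_groups(
    df: pd.DataFrame,
    group_col: str,
    variables: Sequence[str],
    categorical: Sequence[str] = (),
) -> list[GroupComparison]:
    """Compare every variable between the two levels of ``group_col``.

    Continuous variables: Wilcoxon rank-sum (Mann-Whitney U) with mean ± SD
    summaries.  Categorical variables: Fisher's exact test when the
    contingency table is 2x2, otherwise Pearson chi-squared; summaries are
    n (%) of the most common level.
    """
    levels = [lv for lv in df[group_col].dropna().unique()]
    if len(levels) != 2:
        raise ValueError(f"{group_col!r} must have exactly 2 levels, got {levels}")
    a, b = sorted(map(str, levels))
    da = df[df[group_col].astype(str) == a]
    db = df[df[group_col].astype(str) == b]
    if len(da) == 0 or len(db) == 0:
        raise ValueError("both groups must be non-empty")
    categorical = set(categorical)
    out = []
    for var in variables:
        xa, xb = da[var].dropna(), db[var].dropna()
        if var in categorical:
            table = pd.crosstab(df[group_col].astype(str), df[var])
            if table.shape == (2, 2):
                _, p = stats.fisher_exact(table.to_numpy())
                test = "Fisher's exact"
            else:
                p = stats.chi2_contingency(table.to_numpy()).pvalue
                test = "chi-squared"
            lead = table.columns[np.argmax(table.sum(axis=0).to_numpy())]
            ca, cb = (xa == lead).sum(), (xb == lead).sum()
            sa = f"{ca} ({100 * ca / len(xa):.1f}% {lead})"
            sb = f"{cb} ({100 * cb / len(xb):.1f}% {lead})"
        else:
            _, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            test = "rank-sum"
            sa, sb = _fmt_cont(xa.to_numpy()), _fmt_cont(xb.to_numpy())
        out.append(
            GroupComparison(
                variable=var,
                group_a=a,
                group_b=b,
                summary_a=sa,
                summary_b=sb,
                p_value=float(p),
                test_name=test,
            )
        )
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tabular view of compare_groups output."""
    return pd.DataFrame(
        [
            {
                "variable": c.variable,
                c.group_a: c.summary_a,
                c.group_b: c.summary_b,
                "p_value": c.p_value,
                "test": c.test_name,
            }
            for c in comparisons
        ]
    )
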