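"""Quadratic developmental-trajectory model for ROI ALFF.

ALFF in a region of interest is modelled per diagnosis group as a quadratic
function of age, y = b0 + b1*age + b2*age^2, by ordinary least squares.
Model significance is the overall F test of the quadratic model against the
intercept-only model, with (2, n-3) degrees of freedom — the hypothesis
that age carries any (linear or quadratic) information about ALFF.

Ages are mean-centered internally before the quadratic term is built, which
keeps the normal equations well conditioned; reported coefficients are
transformed back to the raw-age basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QuadraticAgeModel", "QuadraticFit", "fit_quadratic", "compare_group_trajectories"]


@dataclass
class QuadraticFit:
    """Results of a quadratic age fit for one group."""

    group: str
    coefficients: tuple[float, float, float]  # raw-age basis (b0, b1, b2)
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    n: int
    ages: np.ndarray
    values: np.ndarray

    def predict(self, ages) -> np.ndarray:
        b0, b1, b2 = self.coefficients
        a = np.asarray(ages, dtype=float)
        return b0 + b1 * a + b2 * a**2

    def summary(self) -> str:
        b0, b1, b2 = self.coefficients
        return (
            f"Quadratic age trajectory [{self.group}] (n={self.n})\n"
            f"  ALFF = {b0:.4f} + {b1:.4f}*age + {b2:.5f}*age^2\n"
            f"  R^2 = {self.r_squared:.3f}, F({self.df[0]},{self.df[1]}) = "
            f"{self.f_stat:.2f}, p = {self.p_value:.4f}"
        )


class QuadraticAgeModel:
    """OLS model of ROI ALFF against age and age squared.

    Parameters
    ----------
    ages, values
        Per-subject age (years) and ROI mean standardized ALFF.
    group
        Label carried through to the results (e.g. "TC" or "ASD").
    """

    def __init__(self, ages, values, group: str = ""):
        self.ages = np.asarray(ages, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.group = group
        if self.ages.shape != self.values.shape or self.ages.ndim != 1:
            raise ValueError("ages and values must be matching 1D arrays")
        if len(self.ages) < 4:
            raise ValueError("need at least 4 subjects for a quadratic fit")
        if np.ptp(self.ages) == 0:
            raise ValueError("ages are all equal; quadratic model is degenerate")

    def fit(self) -> QuadraticFit:
        n = len(self.ages)
        mu = self.ages.mean()
        a = self.ages - mu
        X = np.column_stack([np.ones(n), a, a**2])
        if np.linalg.matrix_rank(X) < 3:
            raise ValueError("degenerate ages: quadratic design is collinear")
        beta, *_ = np.linalg.lstsq(X, self.values, rcond=None)
        fitted = X @ beta
        ss_res = float(((self.values - fitted) ** 2).sum())
        ss_tot = float(((self.values - self.values.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        df = (2, n - 3)
        if ss_res <= 0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = ((ss_tot - ss_res) / df[0]) / (ss_res / df[1])
            p = float(stats.f.sf(f_stat, *df))
        # back-transform centered-basis coefficients to the raw-age basis
        c0, c1, c2 = beta
        raw = (c0 - c1 * mu + c2 * mu**2, c1 - 2 * c2 * mu, c2)
        return QuadraticFit(
            self.group, tuple(float(b) for b in raw), float(r2), float(f_stat), df,
            float(p), n, self.ages, self.values,
        )


def fit_quadratic(ages, alff_values, group: str = "") -> QuadraticFit:
    """Functional wrapper around :class:`QuadraticAgeModel`."""
    return QuadraticAgeModel(ages, alff_values, group).fit()


def compare_group_trajectories(
    fit_tc: QuadraticFit, fit_asd: QuadraticFit, n_curve: int = 50
) -> dict:
    """Side-by-side report of two group fits on the same ROI.

    Returns a coefficient/statistics table and both fitted curves sampled
    over the pooled age range.
    """
    table = pd.DataFrame([
        {
            "group": f.group,
            "n": f.n,
            "b0": f.coefficients[0],
            "b1": f.coefficients[1],
            "b2": f.coefficients[2],
            "r_squared": f.r_squared,
            "f_stat": f.f_stat,
            "df1": f.df[0],
            "df2": f.df[1],
            "p_value": f.p_value,
        }
        for f in (fit_tc, fit_asd)
    ])
    lo = min(fit_tc.ages.min(), fit_asd.ages.min())
    hi = max(fit_tc.ages.max(), fit_asd.ages.max())
    grid = np.linspace(lo, hi, n_curve)
    curves = pd.DataFrame({
        "age": grid,
        fit_tc.group or "TC": fit_tc.predict(grid),
        fit_asd.group or "ASD": fit_asd.predict(grid),
    })
    return {"table": table, "curves": curves}


def plot_trajectories(fit_tc: QuadraticFit, fit_asd: QuadraticFit, path=None):
    """Diagnostic scatter + fitted-curve plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for f, color in ((fit_tc, "tab:blue"), (fit_asd, "tab:red")):
        ax.scatter(f.ages, f.values, s=12, color=color, alpha=0.6, label=f"{f.group} (p={f.p_value:.3f})")
        grid = np.linspace(f.ages.min(), f.ages.max(), 100)
        ax.plot(grid, f.predict(grid), color=color)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("ROI mean standardized ALFF")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
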