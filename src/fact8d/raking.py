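"""Survey raking (iterative proportional fitting) with the study's rules.

A demographic variable is raked on only when any of its category shares
deviates from the population marginal by at least 2.0 percentage points.
Respondents with missing demographics keep weight exactly 1 and are
excluded from the fitting; converged weights are normalized to sum to the
number of raked respondents. Variance inflation from weighting is
summarized as the percentage increase in coefficient standard errors of
the weighted versus unweighted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "RakingResult",
    "Raker",
    "load_targets",
    "select_raking_variables",
    "rake",
    "variance_inflation",
]

DEFAULT_TRIGGER = 0.02  # 2.0 percentage points
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 50


def load_targets(targets) -> dict[str, pd.Series]:
    """Normalize population targets to {variable: Series(category -> share)}.

    Accepts a long frame with columns (variable, category, population_share)
    or a path to such a CSV. Printed marginals are often rounded so shares
    are renormalized to sum exactly to 1; a variable off by more than 1%
    before renormalization is rejected.
    """
    if isinstance(targets, dict):
        frames = {v: pd.Series(d, dtype=float) for v, d in targets.items()}
    else:
        if not isinstance(targets, pd.DataFrame):
            targets = pd.read_csv(targets)
        frames = {
            var: grp.set_index("category")["population_share"].astype(float)
            for var, grp in targets.groupby("variable", sort=False)
        }
    out = {}
    for var, s in frames.items():
        total = s.sum()
        if not np.isclose(total, 1.0, atol=0.01):
            raise ValueError(f"targets for {var} sum to {total:.4f}, not 1")
        if (s < 0).any():
            raise ValueError(f"negative target share for {var}")
        out[var] = s / total
    return out


def _sample_shares(sample: pd.DataFrame, var: str, weights: np.ndarray | None = None) -> pd.Series:
    col = sample[var]
    obs = col.notna()
    if weights is None:
        return col[obs].value_counts(normalize=True)
    w = pd.Series(weights, index=sample.index)[obs]
    return w.groupby(col[obs]).sum() / w.sum()


def select_raking_variables(
    sample: pd.DataFrame,
    targets,
    threshold: float = DEFAULT_TRIGGER,
) -> tuple[list[str], pd.DataFrame]:
    """Select variables whose sample shares deviate from the population by
    >= ``threshold`` (absolute, proportion scale) in any category.

    Returns (selected variables, deviation table with one row per
    variable-category). Missing values are excluded from sample shares.
    """
    tdict = load_targets(targets)
    rows = []
    selected = []
    for var, tgt in tdict.items():
        if var not in sample.columns:
            raise ValueError(f"sample lacks variable {var!r}")
        shares = _sample_shares(sample, var)
        stray = set(shares.index) - set(tgt.index)
        if stray:
            raise ValueError(f"{var}: sample categories not in targets: {sorted(stray)}")
        dev = pd.DataFrame(
            {
                "variable": var,
                "category": tgt.index,
                "sample_share": shares.reindex(tgt.index).fillna(0.0).to_numpy(),
                "population_share": tgt.to_numpy(),
            }
        )
        dev["abs_deviation"] = (dev["sample_share"] - dev["population_share"]).abs()
        rows.append(dev)
        if (dev["abs_deviation"] >= threshold).any():
            selected.append(var)
    return selected, pd.concat(rows, ignore_index=True)


@dataclass
class RakingResult:
    """IPF output: per-respondent weights (1 for missing-demographic rows),
    convergence diagnostics and the selection deviation table."""

    weights: pd.Series
    iterations: int
    converged: bool
    selected_variables: list[str]
    deviations: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.weights.rename("weight").to_csv(path)


def rake(
    sample: pd.DataFrame,
    selected_variables: list[str],
    targets,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> RakingResult:
    """Iterative proportional fitting over the selected variables.

    Cyclically rescales weights so each variable's weighted category shares
    hit the population targets; stops when the largest marginal discrepancy
    falls below ``tol`` (checked after each full cycle) or at ``max_iter``
    cycles (flagged, not fatal). Rows missing any selected variable are
    pinned to weight 1 and excluded; final weights are scaled to sum to the
    number of raked rows.
    """
    if not selected_variables:
        raise ValueError("at least one variable must be selected for raking")
    tdict = load_targets(targets)
    for var in selected_variables:
        if var not in tdict:
            raise ValueError(f"no targets for variable {var!r}")
    complete = sample[selected_variables].notna().all(axis=1)
    raked = sample.loc[complete]
    n_raked = len(raked)
    if n_raked == 0:
        raise ValueError("no rows with complete demographics on the selected variables")
    # infeasibility: an empty sample category with positive target can never be matched
    for var in selected_variables:
        tgt = tdict[var]
        present = set(raked[var].unique())
        empty = [c for c in tgt.index if tgt[c] > 0 and c not in present]
        if empty:
            raise ValueError(f"{var}: empty sample categories with positive target: {empty}")

    w = np.ones(n_raked)
    cats = {var: raked[var].to_numpy() for var in selected_variables}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for var in selected_variables:
            tgt = tdict[var]
            shares = pd.Series(w).groupby(pd.Series(cats[var])).sum() / w.sum()
            factor = (tgt / shares.reindex(tgt.index)).fillna(1.0)
            w = w * factor.reindex(pd.Series(cats[var])).to_numpy()
        w = w * n_raked / w.sum()
        worst = 0.0
        for var in selected_variables:
            shares = pd.Series(w).groupby(pd.Series(cats[var])).sum() / w.sum()
            tgt = tdict[var]
            worst = max(worst, float((shares.reindex(tgt.index).fillna(0.0) - tgt).abs().max()))
        if worst < tol:
            converged = True
            break
    weights = pd.Series(1.0, index=sample.index, name="weight")
    weights.loc[raked.index] = w
    return RakingResult(
        weights=weights,
        iterations=it,
        converged=converged,
        selected_variables=list(selected_variables),
    )


class Raker(BaseEstimator):
    """sklearn-style wrapper: select trigger variables and fit IPF weights.

    Parameters
    ----------
    targets : frame, path or {variable: {category: share}}
        Population marginals.
    variables : list of str, optional
        Rake on exactly these; default selects by the deviation trigger.
    threshold : float
        Selection trigger on the absolute share deviation (default 0.02).
    """

    def __init__(
        self,
        targets=None,
        variables: list[str] | None = None,
        threshold: float = DEFAULT_TRIGGER,
        max_iter: int = DEFAULT_MAX_ITER,
        tol: float = DEFAULT_TOL,
    ):
        self.targets = targets
        self.variables = variables
        self.threshold = threshold
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, demographics: pd.DataFrame, y=None) -> "Raker":
        targets = self.targets
        if targets is None:
            from .simulate import load_population_table

            targets = load_population_table()
        selected, deviations = select_raking_variables(demographics, targets, self.threshold)
        if self.variables is not None:
            selected = list(self.variables)
        res = rake(demographics, selected, targets, max_iter=self.max_iter, tol=self.tol)
        res.deviations = deviations
        self.result_ = res
        self.weights_ = res.weights
        self.selected_variables_ = res.selected_variables
        self.deviations_ = deviations
        self.iterations_ = res.iterations
        self.converged_ = res.converged
        return self

    def transform(self, demographics: pd.DataFrame) -> pd.Series:
        """Weights aligned to the given frame's index (1 where unseen)."""
        return self.weights_.reindex(demographics.index).fillna(1.0)


def variance_inflation(unweighted_fit, weighted_fit) -> dict:
    """Percentage increase in coefficient SEs of the weighted versus the
    unweighted model: per coefficient and the mean across coefficients."""
    from .estimation import compare_fits

    rep = compare_fits(unweighted_fit, weighted_fit)
    return {
        "per_coefficient_pct": rep["se_inflation_pct"],
        "mean_pct": rep["mean_se_inflation_pct"],
    }
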