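"""QALY-anchored conditional logit estimation for paired DCE data.

The random-utility model gives option j of choice set s for respondent i the
utility

    U_isj = alpha * TIME_isj + beta' X_isj * TIME_isj + eps_isj

with i.i.d. Gumbel errors, where X is the vector of level dummies (levels
2..5 of each dimension, level 1 the reference) so that every quality
decrement is expressed per life-year and utility tends to zero with TIME
(the QALY "zero condition"). With two alternatives per choice set the model
reduces to a binary logit on within-set feature differences with no
intercept, which is how it is fitted here: Newton-Raphson on the concave
log-likelihood with analytic gradient and Hessian, respondent-clustered
sandwich covariance, and McFadden pseudo-R^2 against the equal-share null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .descriptive import DIMENSIONS

__all__ = [
    "MergeMap",
    "normalize_merge_map",
    "feature_names",
    "features_from_levels",
    "difference_features",
    "loglik_and_gradient",
    "build_design_matrix",
    "ChoiceMatrix",
    "ConditionalLogitQALY",
    "cluster_sandwich_vcov",
    "compare_fits",
    "ConvergenceError",
]

# partition of levels 2..5 of each dimension into runs of adjacent levels
# sharing one dummy column, e.g. {"worry": ((2, 3), (4,), (5,))}
MergeMap = Mapping[str, Sequence[Sequence[int]]]


class ConvergenceError(RuntimeError):
    pass


def normalize_merge_map(merge_map: MergeMap | None) -> dict[str, tuple[tuple[int, ...], ...]]:
    """Fill in unmerged dimensions and validate that each dimension's groups
    partition levels 2..5 into runs of adjacent levels."""
    out: dict[str, tuple[tuple[int, ...], ...]] = {}
    merge_map = merge_map or {}
    for dim in DIMENSIONS:
        groups = merge_map.get(dim)
        if groups is None:
            out[dim] = ((2,), (3,), (4,), (5,))
            continue
        norm = tuple(tuple(sorted(int(l) for l in g)) for g in groups)
        flat = [l for g in norm for l in g]
        if sorted(flat) != [2, 3, 4, 5]:
            raise ValueError(f"{dim}: groups must partition levels 2..5, got {groups}")
        for g in norm:
            if list(g) != list(range(g[0], g[-1] + 1)):
                raise ValueError(f"{dim}: group {g} is not a run of adjacent levels")
        out[dim] = tuple(sorted(norm))
    unknown = set(merge_map) - set(DIMENSIONS)
    if unknown:
        raise ValueError(f"unknown dimensions in merge map: {sorted(unknown)}")
    return out


def _group_label(dim: str, group: tuple[int, ...]) -> str:
    if len(group) == 1:
        return f"{dim}_L{group[0]}"
    return f"{dim}_L{group[0]}-{group[-1]}"


def feature_names(merge_map: MergeMap | None = None) -> list[str]:
    """Column names: TIME then per-dimension level-group dummies x TIME."""
    mm = normalize_merge_map(merge_map)
    names = ["TIME"]
    for dim in DIMENSIONS:
        for group in mm[dim]:
            names.append(_group_label(dim, group) + "xTIME")
    return names


def features_from_levels(
    levels: np.ndarray, durations: np.ndarray, merge_map: MergeMap | None = None
) -> np.ndarray:
    """Model features for alternatives given (n, 8) levels in 1..5 and (n,)
    durations in years: TIME followed by level dummies multiplied by TIME."""
    levels = np.asarray(levels)
    durations = np.asarray(durations, dtype=float)
    if levels.ndim != 2 or levels.shape[1] != len(DIMENSIONS):
        raise ValueError(f"levels must be (n, {len(DIMENSIONS)})")
    if np.any((levels < 1) | (levels > 5)):
        bad = levels[(levels < 1) | (levels > 5)]
        raise ValueError(f"levels outside 1..5: {np.unique(bad).tolist()}")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    mm = normalize_merge_map(merge_map)
    cols = [durations]
    for j, dim in enumerate(DIMENSIONS):
        lv = levels[:, j]
        for group in mm[dim]:
            dummy = np.isin(lv, group).astype(float)
            cols.append(dummy * durations)
    return np.column_stack(cols)


def difference_features(
    choice_sets: pd.DataFrame, merge_map: MergeMap | None = None, keys: Sequence[str] = ("set_id",)
) -> tuple[np.ndarray, list[str]]:
    """Within-set feature differences (option A minus option B), one row per
    choice set, ordered by the key columns."""
    keys = list(keys)
    df = choice_sets.sort_values(keys + ["option"], kind="stable")
    a = df[df["option"] == "A"]
    b = df[df["option"] == "B"]
    if len(a) != len(b):
        raise ValueError("each choice set needs exactly one option A and one option B")
    if not (a[keys].to_numpy() == b[keys].to_numpy()).all():
        raise ValueError("options A and B are misaligned across choice sets")
    xa = features_from_levels(a[list(DIMENSIONS)].to_numpy(), a["duration_years"].to_numpy(), merge_map)
    xb = features_from_levels(b[list(DIMENSIONS)].to_numpy(), b["duration_years"].to_numpy(), merge_map)
    return xa - xb, feature_names(merge_map)


@dataclass
class ChoiceMatrix:
    """Differenced design matrix for estimation: one row per choice set."""

    x: np.ndarray  # (n_sets, p) feature differences A - B
    y: np.ndarray  # 1 if presented option A chosen
    groups: np.ndarray  # respondent id per choice set
    names: list[str]
    data_hash: int


def _hash_choice_data(df: pd.DataFrame) -> int:
    cols = ["respondent_id", "set_id", "option", "duration_years", "chosen", *DIMENSIONS]
    h = pd.util.hash_pandas_object(df[cols].reset_index(drop=True), index=False)
    return int(h.to_numpy().sum() % (2**63))


def build_design_matrix(choices: pd.DataFrame, merge_map: MergeMap | None = None) -> ChoiceMatrix:
    """Turn long-format choice data (two rows per respondent-set, one
    ``chosen`` flag set) into the differenced estimation matrix."""
    required = {"respondent_id", "set_id", "option", "duration_years", "chosen", *DIMENSIONS}
    missing = required - set(choices.columns)
    if missing:
        raise ValueError(f"choice data missing columns: {sorted(missing)}")
    keys = ["respondent_id", "set_id"]
    counts = choices.groupby(keys, sort=False)["chosen"].agg(["size", "sum"])
    if not (counts["size"] == 2).all():
        raise ValueError("every (respondent, set) must have exactly 2 alternatives")
    if not (counts["sum"] == 1).all():
        raise ValueError("every (respondent, set) must have exactly one chosen alternative")
    x, names = difference_features(choices, merge_map, keys=keys)
    df = choices.sort_values(keys + ["option"], kind="stable")
    a = df[df["option"] == "A"]
    y = a["chosen"].to_numpy().astype(float)
    groups = a["respondent_id"].to_numpy()
    return ChoiceMatrix(x=x, y=y, groups=groups, names=names, data_hash=_hash_choice_data(choices))


def _expand_weights(sample_weight, groups: np.ndarray) -> np.ndarray:
    if sample_weight is None:
        return np.ones(len(groups))
    if isinstance(sample_weight, pd.Series):
        w = pd.Series(groups).map(sample_weight)
        if w.isna().any():
            missing = sorted(set(groups) - set(sample_weight.index))
            raise ValueError(f"no weight for respondents: {missing[:5]} ...")
        return w.to_numpy(dtype=float)
    w = np.asarray(sample_weight, dtype=float)
    if len(w) != len(groups):
        raise ValueError("sample_weight must be a per-respondent Series or per-set array")
    return w


def _check_separation(x: np.ndarray, y: np.ndarray, names: list[str]) -> None:
    sign = 2 * y - 1  # +1 when A chosen
    for j in range(x.shape[1]):
        xs = x[:, j]
        nz = xs != 0
        if nz.any() and np.all(np.sign(xs[nz]) == sign[nz]):
            warnings.warn(
                f"column {names[j]} perfectly predicts choice (separation); "
                "its coefficient is unbounded",
                RuntimeWarning,
            )


def _newton_logit(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    beta0: np.ndarray | None = None,
    gtol: float = 1e-6,
    lltol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, np.ndarray, int, bool]:
    """Newton-Raphson for no-intercept binary logit. Returns (coef, loglik,
    observed information, n_iter, converged)."""
    n, p = x.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()

    def loglik(b):
        eta = x @ b
        # log sigma(eta) computed stably
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    ll = loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = x.T @ (w * (y - mu))
        wt = w * mu * (1 - mu)
        info = (x * wt[:, None]).T @ x  # observed information (= -Hessian)
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix at iteration {it}") from err
        # step-halving safeguard (likelihood is concave; full steps almost
        # always accepted); the accept tolerance must dominate the rounding
        # noise of a large-sample log-likelihood
        accept_tol = 1e-10 * (1.0 + abs(ll))
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = loglik(cand)
            if ll_new >= ll - accept_tol:
                break
            scale *= 0.5
        else:
            raise ConvergenceError(f"step halving failed at iteration {it} (ll={ll:.6f})")
        rel = abs(ll_new - ll) / (abs(ll) + 1e-12)
        beta, ll = cand, ll_new
        # Newton converges quadratically, so the gradient criterion is the
        # stop rule; a likelihood plateau that step-halving cannot improve
        # (lltol with a crushed step) means a genuine stall, e.g. separation.
        if rel < lltol and scale < 1e-6:
            break
    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    wt = w * mu * (1 - mu)
    info = (x * wt[:, None]).T @ x
    return beta, ll, info, it, converged


def loglik_and_gradient(
    x: np.ndarray, y: np.ndarray, coef: np.ndarray, w: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Weighted log-likelihood and score of the paired-choice logit at an
    arbitrary coefficient vector (x = per-set feature differences A - B,
    y = 1 when A chosen)."""
    if w is None:
        w = np.ones(len(y))
    eta = x @ coef
    ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
    mu = 1.0 / (1.0 + np.exp(-eta))
    grad = x.T @ (w * (y - mu))
    return ll, grad


def cluster_sandwich_vcov(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    coef: np.ndarray,
    groups: np.ndarray,
    correction: bool = True,
) -> np.ndarray:
    """Respondent-clustered sandwich covariance H^-1 (sum_c g_c g_c') H^-1
    with per-cluster score sums g_c and observed information H, times the
    finite-sample factor G/(G-1) when ``correction`` is set."""
    eta = x @ coef
    mu = 1.0 / (1.0 + np.exp(-eta))
    scores = x * (w * (y - mu))[:, None]
    wt = w * mu * (1 - mu)
    info = (x * wt[:, None]).T @ x
    codes, _ = pd.factorize(groups)
    g = codes.max() + 1
    cluster_scores = np.zeros((g, x.shape[1]))
    np.add.at(cluster_scores, codes, scores)
    meat = cluster_scores.T @ cluster_scores
    hinv = np.linalg.inv(info)
    vcov = hinv @ meat @ hinv
    if correction and g > 1:
        vcov *= g / (g - 1)
    return 0.5 * (vcov + vcov.T)


class ConditionalLogitQALY(BaseEstimator):
    """Conditional logit for paired choice sets under the QALY-anchored
    utility model, sklearn-style.

    Parameters
    ----------
    merge_map : mapping, optional
        Per-dimension grouping of adjacent levels sharing one dummy (the
        monotonicity device of the constrained model). ``None`` fits the
        full 32-dummy model plus duration.
    gtol, lltol, max_iter
        Newton-Raphson controls: convergence requires max |gradient| below
        ``gtol``; a relative log-likelihood change below ``lltol`` that
        step-halving cannot improve stops iteration as a stall.
    cluster_correction : bool
        Apply the G/(G-1) finite-sample factor to the clustered sandwich.

    Attributes (after ``fit``)
    --------------------------
    coef_, feature_names_, alpha_ (duration coefficient), beta_ (pandas
    Series over the level-dummy terms), vcov_ (clustered), vcov_naive_,
    se_, loglik_, null_loglik_, pseudo_r2_, n_respondents_, n_choicesets_,
    converged_, n_iter_, weighted_, merge_map_, data_hash_.
    """

    def __init__(
        self,
        merge_map: MergeMap | None = None,
        gtol: float = 1e-6,
        lltol: float = 1e-10,
        max_iter: int = 100,
        cluster_correction: bool = True,
    ):
        self.merge_map = merge_map
        self.gtol = gtol
        self.lltol = lltol
        self.max_iter = max_iter
        self.cluster_correction = cluster_correction

    def fit(self, data: pd.DataFrame, sample_weight=None) -> "ConditionalLogitQALY":
        """Fit on long-format choice data. ``sample_weight`` is a
        per-respondent pandas Series of probability weights (or None); the
        covariance is always the respondent-clustered sandwich."""
        cm = build_design_matrix(data, self.merge_map)
        return self._fit_matrix(cm, sample_weight)

    def _fit_matrix(self, cm: ChoiceMatrix, sample_weight=None) -> "ConditionalLogitQALY":
        w = _expand_weights(sample_weight, cm.groups)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        _check_separation(cm.x, cm.y, cm.names)
        coef, ll, info, n_iter, converged = _newton_logit(
            cm.x, cm.y, w, gtol=self.gtol, lltol=self.lltol, max_iter=self.max_iter
        )
        if not converged:
            raise ConvergenceError(
                f"Newton-Raphson did not converge in {n_iter} iterations "
                f"(loglik={ll:.4f}); check for separation or collinearity"
            )
        self.coef_ = coef
        self.feature_names_ = list(cm.names)
        self.alpha_ = float(coef[0])
        self.beta_ = pd.Series(coef[1:], index=cm.names[1:])
        self.vcov_ = cluster_sandwich_vcov(
            cm.x, cm.y, w, coef, cm.groups, correction=self.cluster_correction
        )
        self.vcov_naive_ = np.linalg.inv(info)
        self.se_ = pd.Series(np.sqrt(np.diag(self.vcov_)), index=cm.names)
        self.loglik_ = ll
        self.null_loglik_ = float(-np.sum(w) * np.log(2.0))
        self.pseudo_r2_ = float(1.0 - ll / self.null_loglik_)
        self.n_respondents_ = int(pd.unique(cm.groups).size)
        self.n_choicesets_ = int(len(cm.y))
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.weighted_ = sample_weight is not None
        self.merge_map_ = normalize_merge_map(self.merge_map)
        self.data_hash_ = cm.data_hash
        self._cm = cm
        self._w = w
        return self

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        """P(choose presented option A) per choice set, ordered by
        (respondent_id, set_id)."""
        x, _ = difference_features(data, self.merge_map, keys=["respondent_id", "set_id"])
        return 1.0 / (1.0 + np.exp(-(x @ self.coef_)))

    def zvalues(self) -> pd.Series:
        return pd.Series(self.coef_ / self.se_.to_numpy(), index=self.feature_names_)

    def summary(self) -> pd.DataFrame:
        from scipy import stats

        z = self.zvalues()
        return pd.DataFrame(
            {
                "coef": self.coef_,
                "se": self.se_.to_numpy(),
                "z": z.to_numpy(),
                "p": 2 * stats.norm.sf(np.abs(z.to_numpy())),
            },
            index=self.feature_names_,
        )

    def to_dict(self) -> dict:
        """JSON-serializable fit record."""
        return {
            "feature_names": self.feature_names_,
            "coef": self.coef_.tolist(),
            "vcov": self.vcov_.tolist(),
            "loglik": self.loglik_,
            "null_loglik": self.null_loglik_,
            "pseudo_r2": self.pseudo_r2_,
            "n_respondents": self.n_respondents_,
            "n_choicesets": self.n_choicesets_,
            "weighted": self.weighted_,
            "merge_map": {d: [list(g) for g in gs] for d, gs in self.merge_map_.items()},
        }


def compare_fits(fit_a: ConditionalLogitQALY, fit_b: ConditionalLogitQALY) -> dict:
    """Compare two fits on the same data: change in pseudo-R^2 and parameter
    count (b relative to a), and per-coefficient SE inflation in percent for
    the features the two models share."""
    if fit_a.data_hash_ != fit_b.data_hash_:
        raise ValueError("fits were estimated on different data")
    common = [n for n in fit_a.feature_names_ if n in set(fit_b.feature_names_)]
    se_a = fit_a.se_[common]
    se_b = fit_b.se_[common]
    inflation = 100.0 * (se_b - se_a) / se_a
    return {
        "delta_pseudo_r2": fit_b.pseudo_r2_ - fit_a.pseudo_r2_,
        "delta_n_params": len(fit_b.coef_) - len(fit_a.coef_),
        "se_inflation_pct": inflation,
        "mean_se_inflation_pct": float(inflation.mean()),
    }
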