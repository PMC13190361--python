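"""Value sets: preference weights beta/alpha, monotonicity, and scoring.

A value set assigns each (dimension, level) a utility decrement from full
health, obtained as the ratio of the level coefficient to the survival
(duration) coefficient in the fitted conditional logit. Standard errors of
the ratios come from the delta method on the clustered covariance. A health
state's utility is 1 plus the sum of its eight decrements (level 1
contributing 0), so the scale is anchored at 1 = full health and 0 = dead,
with values below 0 (worse than dead) possible for severe states.

Monotonicity -- worse levels never carrying smaller decrements -- is
enforced by iteratively combining adjacent disordered levels into a shared
dummy and refitting (the constrained "Model 2").
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .descriptive import (
    DIMENSIONS,
    HealthState,
    MissingItemError,
    map_response_to_state,
)
from .estimation import (
    ConditionalLogitQALY,
    MergeMap,
    compare_fits,
    normalize_merge_map,
)

__all__ = [
    "ValueSet",
    "load_uk_valueset",
    "preference_weights",
    "detect_disorder",
    "MonotonicConditionalLogit",
    "enforce_monotonicity",
    "score_state",
    "score_factg_frame",
    "score_factg_file",
    "cluster_bootstrap_ratio_se",
]

_FEATURE_RE = re.compile(r"^(?P<dim>[a-z]+)_L(?P<lo>\d)(?:-(?P<hi>\d))?xTIME$")


def _parse_feature(name: str) -> tuple[str, tuple[int, ...]]:
    m = _FEATURE_RE.match(name)
    if not m:
        raise ValueError(f"not a level feature: {name!r}")
    lo = int(m.group("lo"))
    hi = int(m.group("hi") or lo)
    return m.group("dim"), tuple(range(lo, hi + 1))


@dataclass
class ValueSet:
    """Per-(dimension, level) utility decrements with standard errors.

    ``decrements`` maps (dimension, level in 2..5) to a (usually negative)
    decrement; merged levels carry identical values and are listed in
    ``merge_map``. Level 1 of every dimension has decrement 0 by anchoring.
    """

    decrements: dict[tuple[str, int], float]
    ses: dict[tuple[str, int], float] = field(default_factory=dict)
    merge_map: dict[str, tuple[tuple[int, ...], ...]] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            for level in (2, 3, 4, 5):
                if (dim, level) not in self.decrements:
                    raise ValueError(f"value set incomplete: missing ({dim}, {level})")

    def decrement(self, dim: str, level: int) -> float:
        if level == 1:
            return 0.0
        return self.decrements[(dim, level)]

    def utility(self, state: HealthState) -> float:
        """1 + sum of decrements; additive and order-independent."""
        return 1.0 + sum(self.decrement(d, state[d]) for d in DIMENSIONS)

    def min_utility(self) -> float:
        return self.utility(HealthState.worst())

    def is_monotone(self) -> bool:
        """Worsening any single dimension never increases utility."""
        for dim in DIMENSIONS:
            vals = [0.0] + [self.decrements[(dim, l)] for l in (2, 3, 4, 5)]
            if any(vals[i] < vals[i + 1] for i in range(4)):
                return False
        return True

    def to_frame(self, decimals: int | None = 3) -> pd.DataFrame:
        """Tabular form (dimension, level, decrement, se, merged_with);
        ratios are conventionally reported to 3 decimals."""
        mm = self.merge_map or {}
        rows = []
        for dim in DIMENSIONS:
            groups = {l: g for g in mm.get(dim, ()) for l in g if len(g) > 1}
            for level in (2, 3, 4, 5):
                g = groups.get(level)
                rows.append(
                    {
                        "dimension": dim,
                        "level": level,
                        "decrement": self.decrements[(dim, level)],
                        "se": self.ses.get((dim, level), np.nan),
                        "merged_with": f"{g[0]}-{g[-1]}" if g else "",
                    }
                )
        df = pd.DataFrame(rows)
        if decimals is not None:
            df["decrement"] = df["decrement"].round(decimals)
            df["se"] = df["se"].round(decimals)
        return df

    def to_csv(self, path, decimals: int | None = 3) -> None:
        self.to_frame(decimals).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "ValueSet":
        dec, ses = {}, {}
        merge: dict[str, set[tuple[int, ...]]] = {}
        for _, row in df.iterrows():
            key = (row["dimension"], int(row["level"]))
            dec[key] = float(row["decrement"])
            if "se" in df.columns and pd.notna(row.get("se")):
                ses[key] = float(row["se"])
            mw = row.get("merged_with")
            if isinstance(mw, str) and mw:
                lo, hi = (int(x) for x in mw.split("-"))
                merge.setdefault(row["dimension"], set()).add(tuple(range(lo, hi + 1)))
        merge_map = None
        if merge:
            merge_map = {}
            for dim, groups in merge.items():
                merged_levels = {l for g in groups for l in g}
                singles = [(l,) for l in (2, 3, 4, 5) if l not in merged_levels]
                merge_map[dim] = tuple(sorted(list(groups) + singles))
        return cls(decrements=dec, ses=ses, merge_map=merge_map, provenance=provenance or {})

    @classmethod
    def from_csv(cls, path, provenance: dict | None = None) -> "ValueSet":
        return cls.from_frame(pd.read_csv(path), provenance=provenance)


def load_uk_valueset() -> ValueSet:
    """Load the package's example UK-style value-set table.

    The table is SYNTHETIC: a stand-in for the study's published value set
    (which lives in journal supplementary material not shipped here),
    constructed to honour the published anchor facts -- the fatigue level-3
    decrement -0.047 and worry level-3 decrement -0.002 of the worked
    scoring example, an all-worst utility of -0.402, pain and nausea as the
    largest decrements, and within-dimension monotonicity (with worry
    levels 2-3 sharing a merged decrement). Real analyses should load the
    published table with :meth:`ValueSet.from_csv`.
    """
    ref = importlib.resources.files("fact8d.data") / "uk_valueset_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        vs = ValueSet.from_csv(path, provenance={"source": "synthetic UK-style example table"})
    return vs


def preference_weights(fit: ConditionalLogitQALY, min_alpha_z: float = 2.0) -> ValueSet:
    """Preference weights as coefficient ratios beta/alpha with delta-method
    SEs from the clustered covariance:

        Var(b/a) = Var(b)/a^2 + b^2 Var(a)/a^4 - 2 b Cov(a,b)/a^3

    Raises when the duration coefficient is non-positive or statistically
    indistinguishable from zero (|alpha|/SE < ``min_alpha_z``), since the
    QALY anchor is then undefined.
    """
    alpha = fit.alpha_
    se_alpha = float(fit.se_["TIME"])
    if alpha <= 0:
        raise ValueError(f"duration coefficient must be positive, got {alpha:.4g}")
    if alpha / se_alpha < min_alpha_z:
        raise ValueError(
            f"duration coefficient too weak for anchoring (z = {alpha / se_alpha:.2f})"
        )
    names = fit.feature_names_
    var = np.diag(fit.vcov_)
    dec: dict[tuple[str, int], float] = {}
    ses: dict[tuple[str, int], float] = {}
    for j, name in enumerate(names):
        if name == "TIME":
            continue
        dim, levels = _parse_feature(name)
        b = fit.coef_[j]
        vb = var[j]
        cov_ab = fit.vcov_[0, j]
        w = b / alpha
        vw = vb / alpha**2 + b**2 * var[0] / alpha**4 - 2 * b * cov_ab / alpha**3
        for level in levels:
            dec[(dim, level)] = float(w)
            ses[(dim, level)] = float(np.sqrt(max(vw, 0.0)))
    return ValueSet(
        decrements=dec,
        ses=ses,
        merge_map=fit.merge_map_,
        provenance={"weighted": fit.weighted_, "n_respondents": fit.n_respondents_},
    )


def detect_disorder(fit: ConditionalLogitQALY) -> dict[str, list[tuple[tuple[int, ...], tuple[int, ...]]]]:
    """Adjacent level groups whose coefficients are disordered: the less
    severe group has a strictly larger (more negative) decrement than the
    next group. Returns {dimension: [(group_lo, group_hi), ...]}."""
    coef = pd.Series(fit.coef_, index=fit.feature_names_)
    out: dict[str, list] = {}
    for dim in DIMENSIONS:
        groups = fit.merge_map_[dim]
        vals = []
        for g in groups:
            name = [n for n in fit.feature_names_ if n != "TIME" and _parse_feature(n) == (dim, g)]
            vals.append(float(coef[name[0]]))
        for i in range(len(groups) - 1):
            if vals[i] < vals[i + 1]:  # less severe more negative -> disorder
                out.setdefault(dim, []).append((groups[i], groups[i + 1]))
    return out


def _merge_groups(merge_map, disorders, merge_all: bool) -> dict:
    new_map = {d: [list(g) for g in gs] for d, gs in merge_map.items()}
    applied = False
    for dim, pairs in disorders.items():
        for lo, hi in pairs:
            groups = new_map[dim]
            # find current groups containing lo/hi (may have been merged already this pass)
            gi = next(i for i, g in enumerate(groups) if lo[0] in g)
            gj = next(i for i, g in enumerate(groups) if hi[0] in g)
            if gi == gj:
                continue
            merged = sorted(set(groups[gi]) | set(groups[gj]))
            groups[min(gi, gj)] = merged
            del groups[max(gi, gj)]
            applied = True
            if not merge_all:
                return {d: tuple(tuple(g) for g in gs) for d, gs in new_map.items()}
        if applied and not merge_all:
            break
    return {d: tuple(tuple(g) for g in gs) for d, gs in new_map.items()}


class MonotonicConditionalLogit(BaseEstimator):
    """Constrained conditional logit ("Model 2"): refit with adjacent
    disordered levels combined until every dimension is monotone.

    Parameters mirror :class:`ConditionalLogitQALY`; ``merge_all_per_pass``
    merges every detected adjacent disorder before each refit (default), or
    one at a time when False.

    After ``fit``: ``fit_`` (the final constrained fit), ``model1_fit_``,
    ``merge_map_``, ``n_refits_``, ``delta_pseudo_r2_`` (Model 2 minus
    Model 1), ``collapsed_dimensions_`` (dimensions reduced to one level
    group, flagged but allowed).
    """

    def __init__(
        self,
        merge_all_per_pass: bool = True,
        max_refits: int = 20,
        cluster_correction: bool = True,
    ):
        self.merge_all_per_pass = merge_all_per_pass
        self.max_refits = max_refits
        self.cluster_correction = cluster_correction

    def fit(self, data: pd.DataFrame, sample_weight=None) -> "MonotonicConditionalLogit":
        base = ConditionalLogitQALY(cluster_correction=self.cluster_correction)
        base.fit(data, sample_weight=sample_weight)
        self.model1_fit_ = base
        current = base
        merge_map = base.merge_map_
        refits = 0
        while True:
            disorders = detect_disorder(current)
            if not disorders:
                break
            if refits >= self.max_refits:
                raise RuntimeError("monotonicity enforcement did not terminate")
            merge_map = _merge_groups(merge_map, disorders, self.merge_all_per_pass)
            current = ConditionalLogitQALY(
                merge_map=merge_map, cluster_correction=self.cluster_correction
            ).fit(data, sample_weight=sample_weight)
            refits += 1
        self.fit_ = current
        self.merge_map_ = normalize_merge_map(merge_map)
        self.n_refits_ = refits
        self.delta_pseudo_r2_ = compare_fits(base, current)["delta_pseudo_r2"]
        self.collapsed_dimensions_ = [d for d in DIMENSIONS if len(self.merge_map_[d]) == 1]
        return self

    def value_set(self) -> ValueSet:
        return preference_weights(self.fit_)


def enforce_monotonicity(
    data: pd.DataFrame, sample_weight=None, merge_all_per_pass: bool = True
) -> tuple[ConditionalLogitQALY, dict]:
    """Functional wrapper around :class:`MonotonicConditionalLogit`;
    returns (constrained fit, merge map)."""
    est = MonotonicConditionalLogit(merge_all_per_pass=merge_all_per_pass)
    est.fit(data, sample_weight=sample_weight)
    return est.fit_, est.merge_map_


def score_state(state: HealthState, vs: ValueSet) -> float:
    """Utility of a health state: 1 + the sum of its level decrements."""
    return vs.utility(state)


def score_factg_frame(responses: pd.DataFrame, vs: ValueSet) -> pd.DataFrame:
    """Score FACT-G responses row-wise: map items to a FACT-8D state, then
    apply the additive scoring rule. Per-row failures (missing items) are
    collected into an ``error`` column rather than aborting the file."""
    utilities, errors = [], []
    for _, row in responses.iterrows():
        try:
            state = map_response_to_state(row)
            utilities.append(score_state(state, vs))
            errors.append("")
        except (MissingItemError, ValueError) as err:
            utilities.append(np.nan)
            errors.append(str(err))
    out = responses.copy()
    out["utility"] = utilities
    out["error"] = errors
    return out


def score_factg_file(in_path, vs: ValueSet, out_path) -> pd.DataFrame:
    from .descriptive import read_factg_responses

    scored = score_factg_frame(read_factg_responses(in_path), vs)
    scored.to_csv(out_path, index=False)
    return scored


def cluster_bootstrap_ratio_se(
    fit: ConditionalLogitQALY, n_boot: int = 500, seed: int = 0
) -> pd.Series:
    """Nonparametric respondent-cluster bootstrap SEs of the beta/alpha
    ratios (resample respondents with replacement, refit, recompute the
    ratios). Used as the independent check on the delta-method SEs."""
    cm = fit._cm
    w = fit._w
    rng = np.random.default_rng(seed)
    ids, codes = np.unique(cm.groups, return_inverse=True)
    by_resp = [np.flatnonzero(codes == i) for i in range(len(ids))]
    ratios = []
    from .estimation import _newton_logit

    for _ in range(n_boot):
        pick = rng.integers(0, len(ids), size=len(ids))
        rows = np.concatenate([by_resp[i] for i in pick])
        coef, *_rest = _newton_logit(cm.x[rows], cm.y[rows], w[rows], beta0=fit.coef_)
        ratios.append(coef[1:] / coef[0])
    arr = np.asarray(ratios)
    return pd.Series(arr.std(axis=0, ddof=1), index=fit.feature_names_[1:])
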