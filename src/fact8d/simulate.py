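"""Synthetic valuation cohorts: Gumbel-noise choices under known truth.

Because the study's raw survey data are not deposited, every downstream
stage is exercised on simulated cohorts: respondents receive 16 choice sets
from the 800-set design, choose by the QALY-anchored random-utility model
(utility alpha*TIME + beta'X*TIME plus i.i.d. Gumbel noise), and carry
categorical demographics drawn from a configurable sample distribution that
deviates from population marginals by stated amounts (so the raking trigger
fires as it did in the study). Pathology injections (straight-liners,
fast random responders) emulate the data-quality patterns the QC metrics
are designed to surface.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptive import DIMENSIONS

__all__ = [
    "TrueParameters",
    "SimulatedCohort",
    "default_true_parameters",
    "load_population_table",
    "simulate_choices",
    "simulate_demographics",
    "simulate_completion_times",
    "inject_pathologies",
    "simulate_cohort",
]

# non-quota demographic variables (quota sampling fixed sex and age)
NON_QUOTA_VARIABLES = ("country_of_birth", "education", "marital_status", "household_ownership")

# Completion-time model: lognormal matched to a 13.1-minute median with an
# interquartile range of roughly 9.3-18.7 minutes.
MEDIAN_COMPLETION_SECONDS = 13.1 * 60
COMPLETION_LOG_SD = 0.52


@dataclass(frozen=True)
class TrueParameters:
    """Known truth for simulation: utility per life-year ``alpha`` (> 0) and
    per-(dimension, level) per-life-year decrements ``beta`` (<= 0),
    with level 1 implicitly zero. ``noise_scale`` is the Gumbel scale
    (1 fixes the logit normalization; signal strength is tuned via the
    coefficient magnitudes)."""

    alpha: float
    beta: Mapping[tuple[str, int], float]
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        for dim in DIMENSIONS:
            for level in (2, 3, 4, 5):
                if (dim, level) not in self.beta:
                    raise ValueError(f"beta missing ({dim}, {level})")

    def is_monotone(self) -> bool:
        """True when decrements weakly worsen with severity in every
        dimension (level 1 counts as zero)."""
        for dim in DIMENSIONS:
            vals = [0.0] + [self.beta[(dim, l)] for l in (2, 3, 4, 5)]
            for i in range(4):
                if vals[i] < vals[i + 1]:
                    return False
        return True

    def systematic_utility(self, levels: np.ndarray, durations: np.ndarray) -> np.ndarray:
        """V = alpha*T + sum_d beta[d, level_d]*T for (n, 8) levels, (n,) T."""
        levels = np.asarray(levels)
        t = np.asarray(durations, dtype=float)
        dec = np.zeros(len(t))
        for j, dim in enumerate(DIMENSIONS):
            lut = np.array([0.0, 0.0] + [self.beta[(dim, l)] for l in (2, 3, 4, 5)])
            dec += lut[levels[:, j]]
        return self.alpha * t + dec * t

    def true_ratios(self) -> pd.Series:
        """True preference-weight decrements beta/alpha keyed like the
        estimator's feature names."""
        idx, vals = [], []
        for dim in DIMENSIONS:
            for level in (2, 3, 4, 5):
                idx.append(f"{dim}_L{level}xTIME")
                vals.append(self.beta[(dim, level)] / self.alpha)
        return pd.Series(vals, index=idx)


def load_population_table() -> pd.DataFrame:
    """Shipped demographic table: variable, category, population_share (UK
    census marginals as printed) and sample_share (the study sample's
    composition, used as the simulation default)."""
    ref = importlib.resources.files("fact8d.data") / "uk_population_targets.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def default_true_parameters(alpha: float = 0.4, noise_scale: float = 1.0) -> TrueParameters:
    """Truth loosely calibrated to the study's qualitative findings: pain
    and nausea carry the largest decrements; beta = alpha * decrement so the
    implied value set matches the package's example table."""
    from .valueset import load_uk_valueset

    vs = load_uk_valueset()
    beta = {
        (dim, level): alpha * vs.decrement(dim, level)
        for dim in DIMENSIONS
        for level in (2, 3, 4, 5)
    }
    return TrueParameters(alpha=alpha, beta=beta, noise_scale=noise_scale)


def _design_arrays(choice_sets: pd.DataFrame):
    cs = choice_sets.sort_values(["set_id", "option"], kind="stable")
    a = cs[cs["option"] == "A"]
    b = cs[cs["option"] == "B"]
    set_ids = a["set_id"].to_numpy()
    la = a[list(DIMENSIONS)].to_numpy()
    lb = b[list(DIMENSIONS)].to_numpy()
    da = a["duration_years"].to_numpy(dtype=float)
    db = b["duration_years"].to_numpy(dtype=float)
    pos = {s: i for i, s in enumerate(set_ids)}
    return pos, la, lb, da, db


def simulate_choices(
    choice_sets: pd.DataFrame,
    allocation: pd.DataFrame,
    params: TrueParameters,
    seed: int,
) -> pd.DataFrame:
    """Simulate every allocated task: presented sides per the allocation's
    ``flip`` flag, utilities from ``params`` plus Gumbel noise, chosen =
    argmax. With ``noise_scale`` 0 choices are deterministic in the sign of
    the systematic utility difference (exact ties decided by a fair coin).

    Returns long-format choice data: two rows per task with presented
    option labels and a 0/1 ``chosen`` flag.
    """
    rng = np.random.default_rng(seed)
    pos, la, lb, da, db = _design_arrays(choice_sets)
    va = params.systematic_utility(la, da)
    vb = params.systematic_utility(lb, db)

    idx = allocation["set_id"].map(pos).to_numpy()
    flip = allocation["flip"].to_numpy(dtype=bool)
    n = len(allocation)

    v_pres_a = np.where(flip, vb[idx], va[idx])
    v_pres_b = np.where(flip, va[idx], vb[idx])
    if params.noise_scale > 0:
        eps = rng.gumbel(scale=params.noise_scale, size=(n, 2))
        chose_a = (v_pres_a + eps[:, 0]) > (v_pres_b + eps[:, 1])
    else:
        dv = v_pres_a - v_pres_b
        coin = rng.integers(0, 2, size=n).astype(bool)
        chose_a = np.where(dv == 0, coin, dv > 0)

    lev_pres_a = np.where(flip[:, None], lb[idx], la[idx])
    lev_pres_b = np.where(flip[:, None], la[idx], lb[idx])
    dur_pres_a = np.where(flip, db[idx], da[idx])
    dur_pres_b = np.where(flip, da[idx], db[idx])

    fa = pd.DataFrame(lev_pres_a, columns=list(DIMENSIONS))
    fa.insert(0, "respondent_id", allocation["respondent_id"].to_numpy())
    fa.insert(1, "set_id", allocation["set_id"].to_numpy())
    fa.insert(2, "option", "A")
    fa["duration_years"] = dur_pres_a
    fa["chosen"] = chose_a.astype(int)
    fb = pd.DataFrame(lev_pres_b, columns=list(DIMENSIONS))
    fb.insert(0, "respondent_id", allocation["respondent_id"].to_numpy())
    fb.insert(1, "set_id", allocation["set_id"].to_numpy())
    fb.insert(2, "option", "B")
    fb["duration_years"] = dur_pres_b
    fb["chosen"] = (~chose_a).astype(int)
    out = pd.concat([fa, fb], ignore_index=True)
    return out.sort_values(["respondent_id", "set_id", "option"], kind="stable").reset_index(
        drop=True
    )


def simulate_demographics(
    n: int,
    category_distributions: Mapping[str, Mapping[str, float]] | None = None,
    missing_rate: float = 13 / 2054,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw i.i.d. categorical demographics.

    The default sampling distribution is the study sample's composition
    (which deviates from the population marginals by the stated amounts,
    e.g. education level 4 at 50.5% vs 27.0%), so variable selection for
    raking fires exactly as in the study. ``missing_rate`` blanks the four
    non-quota variables for a random subset (about 13 of 2054 by default).

    Returns (demographics frame indexed by respondent_id, targets frame
    with variable/category/population_share).
    """
    rng = np.random.default_rng(seed)
    table = load_population_table()
    if category_distributions is None:
        category_distributions = {
            var: dict(zip(grp["category"], grp["sample_share"]))
            for var, grp in table.groupby("variable", sort=False)
        }
    data: dict[str, np.ndarray] = {}
    for var, dist in category_distributions.items():
        cats = list(dist)
        p = np.asarray([dist[c] for c in cats], dtype=float)
        if p.min() < 0:
            raise ValueError(f"{var}: negative category probability")
        p = p / p.sum()  # printed shares are rounded; renormalize
        data[var] = rng.choice(cats, size=n, p=p)
    demo = pd.DataFrame(data)
    demo.index.name = "respondent_id"
    if missing_rate > 0:
        miss = rng.random(n) < missing_rate
        for var in NON_QUOTA_VARIABLES:
            if var in demo.columns:
                demo.loc[miss, var] = np.nan
    targets = table[["variable", "category", "population_share"]].copy()
    return demo, targets


def simulate_completion_times(n: int, seed: int) -> pd.Series:
    """Total survey time in seconds, lognormal with a ~13-minute median."""
    rng = np.random.default_rng(seed)
    t = rng.lognormal(mean=np.log(MEDIAN_COMPLETION_SECONDS), sigma=COMPLETION_LOG_SD, size=n)
    return pd.Series(t, name="completion_seconds").rename_axis("respondent_id")


def inject_pathologies(
    choices: pd.DataFrame,
    completion_times: pd.Series,
    all_A_fraction: float = 0.0,
    all_B_fraction: float = 0.0,
    fast_random_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list]]:
    """Overwrite designated respondents' answers with pathological patterns.

    Straight-liners always pick the presented A (or B) side; fast random
    responders pick uniformly at random and get completion times drawn from
    the bottom of the time distribution, emulating disengaged speeding.
    Returns modified (choices, completion_times) plus the injected ids.
    """
    for frac in (all_A_fraction, all_B_fraction, fast_random_fraction):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    choices = choices.copy()
    completion_times = completion_times.copy()
    ids = pd.unique(choices["respondent_id"])
    rng.shuffle(ids)
    n_a = int(round(all_A_fraction * len(ids)))
    n_b = int(round(all_B_fraction * len(ids)))
    n_f = int(round(fast_random_fraction * len(ids)))
    if n_a + n_b + n_f > len(ids):
        raise ValueError("pathology fractions overlap: sum exceeds 1")
    ids_a = list(ids[:n_a])
    ids_b = list(ids[n_a : n_a + n_b])
    ids_f = list(ids[n_a + n_b : n_a + n_b + n_f])

    is_a_row = choices["option"] == "A"
    mask_a = choices["respondent_id"].isin(ids_a)
    choices.loc[mask_a, "chosen"] = is_a_row[mask_a].astype(int)
    mask_b = choices["respondent_id"].isin(ids_b)
    choices.loc[mask_b, "chosen"] = (~is_a_row[mask_b]).astype(int)

    if ids_f:
        mask_f = choices["respondent_id"].isin(ids_f)
        sub = choices.loc[mask_f, ["respondent_id", "set_id"]].drop_duplicates()
        pick_a = pd.Series(
            rng.integers(0, 2, size=len(sub)).astype(bool),
            index=pd.MultiIndex.from_frame(sub),
        )
        key = pd.MultiIndex.from_frame(choices.loc[mask_f, ["respondent_id", "set_id"]])
        chose_a = pick_a.reindex(key).to_numpy()
        choices.loc[mask_f, "chosen"] = np.where(
            is_a_row[mask_f], chose_a, ~chose_a
        ).astype(int)
        # speeding: completion times in the fastest tail (~quarter of the median)
        completion_times.loc[ids_f] = rng.lognormal(
            mean=np.log(MEDIAN_COMPLETION_SECONDS / 4), sigma=0.2, size=len(ids_f)
        )
    return choices, completion_times, {"all_A": ids_a, "all_B": ids_b, "fast_random": ids_f}


@dataclass
class SimulatedCohort:
    """Everything a downstream stage needs, plus the generating truth."""

    choices: pd.DataFrame
    demographics: pd.DataFrame
    targets: pd.DataFrame
    completion_times: pd.Series
    allocation: pd.DataFrame
    truth: TrueParameters
    injected: dict[str, list] = field(default_factory=dict)


def simulate_cohort(
    choice_sets: pd.DataFrame,
    n_respondents: int = 2054,
    params: TrueParameters | None = None,
    seed: int = 0,
    missing_rate: float = 13 / 2054,
    all_A_fraction: float = 0.0,
    all_B_fraction: float = 0.0,
    fast_random_fraction: float = 0.0,
) -> SimulatedCohort:
    """One-call cohort: allocation, choices, demographics, times, optional
    pathologies. Child seeds are spawned deterministically from ``seed``."""
    from .design import allocate_blocks

    ss = np.random.SeedSequence(seed)
    s_alloc, s_choice, s_demo, s_time, s_path = [
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5)
    ]
    if params is None:
        params = default_true_parameters()
    allocation = allocate_blocks(choice_sets, range(n_respondents), seed=s_alloc)
    choices = simulate_choices(choice_sets, allocation, params, seed=s_choice)
    demographics, targets = simulate_demographics(
        n_respondents, missing_rate=missing_rate, seed=s_demo
    )
    times = simulate_completion_times(n_respondents, seed=s_time)
    times.index = pd.Index(range(n_respondents), name="respondent_id")
    injected: dict[str, list] = {}
    if all_A_fraction or all_B_fraction or fast_random_fraction:
        choices, times, injected = inject_pathologies(
            choices,
            times,
            all_A_fraction=all_A_fraction,
            all_B_fraction=all_B_fraction,
            fast_random_fraction=fast_random_fraction,
            seed=s_path,
        )
    return SimulatedCohort(
        choices=choices,
        demographics=demographics,
        targets=targets,
        completion_times=times,
        allocation=allocation,
        truth=params,
        injected=injected,
    )
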