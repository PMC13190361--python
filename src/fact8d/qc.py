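"""Data-quality metrics for DCE responses.

Two screens from the study protocol: straight-liners (respondents choosing
the presented Option A, or B, in every task) and completion-time deciles,
each decile refitted with the unconstrained conditional logit so that low
pseudo-R^2 or few significant coefficients flag low-quality strata.
Flagged respondents are reported, not excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import ConditionalLogitQALY, ConvergenceError

__all__ = ["QCReport", "qc_straightliners", "qc_time_deciles", "build_qc_report"]


def qc_straightliners(choices: pd.DataFrame) -> tuple[list, int]:
    """Respondents whose chosen options were all presented-A or all
    presented-B. Returns (ids, tally)."""
    chosen = choices[choices["chosen"] == 1]
    opts = chosen.groupby("respondent_id")["option"].agg(["nunique", "first"])
    flagged = opts[opts["nunique"] == 1].index.tolist()
    return flagged, len(flagged)


def qc_time_deciles(
    choices: pd.DataFrame,
    completion_times: pd.Series,
    n_deciles: int = 10,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Split respondents into completion-time deciles (ties broken by
    respondent id) and fit the unconstrained model per decile.

    Returns one row per decile: n_respondents, pseudo_r2, n_significant
    (coefficients with robust two-sided p < ``alpha_level``), median_time,
    and a ``fitted`` flag (False when a decile is too small or the fit
    fails; such deciles are reported but skipped).
    """
    ids = pd.Index(pd.unique(choices["respondent_id"]))
    times = completion_times.reindex(ids)
    if times.isna().any():
        missing = ids[times.isna()][:5].tolist()
        raise ValueError(f"completion times missing for respondents {missing}")
    if len(ids) < n_deciles:
        raise ValueError(f"cannot form {n_deciles} deciles from {len(ids)} respondents")
    order = pd.DataFrame({"time": times.to_numpy(), "rid": ids}).sort_values(
        ["time", "rid"], kind="stable"
    )
    decile = np.floor(np.arange(len(order)) * n_deciles / len(order)).astype(int)
    order["decile"] = decile
    rows = []
    for d, grp in order.groupby("decile"):
        sub = choices[choices["respondent_id"].isin(grp["rid"])]
        row = {
            "decile": int(d) + 1,
            "n_respondents": len(grp),
            "median_time": float(grp["time"].median()),
            "pseudo_r2": np.nan,
            "n_significant": np.nan,
            "fitted": False,
        }
        n_sets = len(sub) // 2
        if n_sets > 2 * 33:  # need headroom over the 33 parameters
            try:
                fit = ConditionalLogitQALY().fit(sub)
                pvals = fit.summary()["p"]
                row.update(
                    pseudo_r2=fit.pseudo_r2_,
                    n_significant=int((pvals < alpha_level).sum()),
                    fitted=True,
                )
            except (ConvergenceError, np.linalg.LinAlgError):
                pass
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class QCReport:
    """Flow tallies, straight-liner flags and the per-decile fit table."""

    n_entered: int
    n_completed_any: int
    n_completed_all: int
    straightliner_ids: list
    straightliner_tally: int
    decile_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (self.n_completed_all <= self.n_completed_any <= self.n_entered):
            raise ValueError("flow tallies must satisfy all <= any <= entered")

    def to_dict(self) -> dict:
        return {
            "n_entered": self.n_entered,
            "n_completed_any": self.n_completed_any,
            "n_completed_all": self.n_completed_all,
            "straightliner_tally": self.straightliner_tally,
            "straightliner_ids": [str(i) for i in self.straightliner_ids],
            "deciles": (
                self.decile_table.to_dict(orient="records")
                if self.decile_table is not None
                else None
            ),
        }


def build_qc_report(
    choices: pd.DataFrame,
    completion_times: pd.Series | None = None,
    n_entered: int | None = None,
    n_deciles: int = 10,
) -> QCReport:
    """Assemble the QC report; completers are respondents with all 16 tasks
    answered (the analysis sample)."""
    per_resp = choices.groupby("respondent_id")["set_id"].nunique()
    n_any = int((per_resp > 0).sum())
    n_all = int((per_resp == 16).sum())
    ids, tally = qc_straightliners(choices)
    table = None
    if completion_times is not None:
        table = qc_time_deciles(choices, completion_times, n_deciles=n_deciles)
    return QCReport(
        n_entered=n_entered if n_entered is not None else n_any,
        n_completed_any=n_any,
        n_completed_all=n_all,
        straightliner_ids=ids,
        straightliner_tally=tally,
        decile_table=table,
    )
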