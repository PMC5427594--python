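"""Scenario comparison tables.

One row per scenario with the achieved mean kinships, migrant contribution,
mean EBV, selected-sire fraction and contribution spread, plus per-bound flags
telling whether each constraint was active (achieved value at its limit within
tolerance) or slack (satisfied with margin).  Display output rounds to three
decimals; the machine channel keeps full precision.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import pandas as pd

from .ocs import BoundSet, ScenarioResult

__all__ = ["ScenarioTable", "summarize"]

_BOUND_OF = {"fA": "ub_fA", "fB": "ub_fB", "fC": "ub_fC", "fD": "ub_fD",
             "MC": "ub_MC", "EBV": "lb_EBV"}
_ATTR_OF = {"fA": "fA_bar", "fB": "fB_bar", "fC": "fC_bar", "fD": "fD_val",
            "MC": "mc_bar", "EBV": "ebv_bar"}


@dataclass
class ScenarioTable:
    frame: pd.DataFrame           # full precision
    slack_flags: pd.DataFrame     # "" (unbounded) / "active" / "slack"

    def to_tsv(self, path=None) -> str | None:
        out = self.frame.to_csv(path, sep="\t", index=True,
                                index_label="scenario")
        return out

    def display(self) -> pd.DataFrame:
        return self.frame.round(3)

    def to_markdown(self) -> str:
        return self.display().to_markdown()


def summarize(results: dict[str, ScenarioResult],
              feas_tol: float = 1e-6, log=None) -> ScenarioTable:
    """Assemble results into a comparison table with activity flags.

    A bound counts as active when the achieved value is within 10x the
    feasibility tolerance of its limit — separating numerical grazing of the
    limit from genuine slack.
    """
    if not results:
        raise ValueError("no scenario results")
    slack_tol = 10.0 * feas_tol
    rows, flags = {}, {}
    for name, res in results.items():
        a = res.achieved
        rows[name] = {
            "fA": a.fA_bar, "fB": a.fB_bar, "fC": a.fC_bar, "fD": a.fD_val,
            "MC": a.mc_bar, "EBV": a.ebv_bar,
            "Selected": res.selected_fraction,
            "SD_cs": res.sd_male_contributions,
            "status": res.solver_status,
        }
        row_flags = {}
        for col, bname in _BOUND_OF.items():
            limit = getattr(res.bounds, bname)
            if limit is None or res.solver_status == "infeasible":
                row_flags[col] = ""
            else:
                achieved = getattr(a, _ATTR_OF[col])
                row_flags[col] = ("active" if abs(achieved - limit) <= slack_tol
                                  else "slack")
        flags[name] = row_flags
        if log is not None:
            print(f"[scenario {name}] status={res.solver_status} "
                  f"selected={res.selected_fraction:.4g}", file=log or sys.stderr)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame = frame.loc[list(results)]
    return ScenarioTable(frame=frame,
                         slack_flags=pd.DataFrame.from_dict(flags, orient="index"))
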