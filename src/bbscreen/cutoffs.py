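"""Cutoff-pair derivation by exhaustive grid search under acceptance constraints.

Every (ApoE4p, pTau181) grid pair is evaluated with the two-step rule on the
reference-known rows of a training cohort; pairs meeting both constraints
(screen-out strictly above the floor, 1-NPV at or below the ceiling) form the
feasible set, and the chosen pair maximises screen-out with deterministic tie
breaking (smaller 1-NPV, then larger pTau cutoff, then larger ApoE4p cutoff).
An empty feasible set is a valid outcome, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .metrics import AgreementReport, confusion, metrics
from .reference import NEGATIVE, POSITIVE, UNKNOWN, add_composite_column
from .rule import RuleCutoffs, classify_frame
from .transfer import DEFAULT_MAX_ONE_MINUS_NPV, DEFAULT_MIN_SCREEN_OUT

__all__ = ["ConstraintSpec", "CutoffSearchResult", "grid_search"]


@dataclass(frozen=True)
class ConstraintSpec:
    """Acceptance constraints on a candidate rule.

    ``min_screen_out`` bounds (strictly, from below) the screen-out rate among
    *reference-negative* participants — the fraction of amyloid-negative
    individuals the rule spares from confirmatory testing, i.e. the NPA.
    ``max_one_minus_npv`` bounds (non-strictly, from above) the fraction of
    screened-out participants who are actually amyloid positive.
    """

    min_screen_out: float = DEFAULT_MIN_SCREEN_OUT
    max_one_minus_npv: float = DEFAULT_MAX_ONE_MINUS_NPV

    def __post_init__(self):
        for name in ("min_screen_out", "max_one_minus_npv"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def satisfied_by(self, report: AgreementReport) -> bool:
        if report.npa is None or not report.npa > self.min_screen_out:
            return False
        # an undefined 1-NPV (no negative calls) cannot violate the ceiling
        if report.one_minus_npv is not None and report.one_minus_npv > self.max_one_minus_npv:
            return False
        return True


@dataclass(frozen=True)
class CutoffSearchResult:
    feasible: list[tuple[RuleCutoffs, AgreementReport]]
    chosen: RuleCutoffs | None
    objective: float | None  # screen-out rate of the chosen pair
    evaluated: pd.DataFrame = field(repr=False, default=None)

    def frontier_frame(self) -> pd.DataFrame:
        rows = [
            {
                "apoe4p_cutoff": c.apoe4p_cutoff,
                "ptau_cutoff": c.ptau_cutoff,
                "screen_out_rate": r.screen_out_rate,
                "one_minus_npv": r.one_minus_npv,
                "ppa": r.ppa,
                "npa": r.npa,
                "ppv": r.ppv,
            }
            for c, r in self.feasible
        ]
        return pd.DataFrame(rows)


def _evaluation_frame(cohort: Cohort | pd.DataFrame) -> pd.DataFrame:
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    if "composite_amyloid" not in df.columns:
        df = add_composite_column(df)
    return df


def grid_search(
    cohort: Cohort | pd.DataFrame,
    apoe4p_grid: Sequence[float],
    ptau_grid: Sequence[float],
    constraints: ConstraintSpec = ConstraintSpec(),
) -> CutoffSearchResult:
    """Evaluate the rule at every grid pair on reference-known rows.

    The 2x2 metrics and the screen-out rate are both computed over rows with
    known composite amyloid status, mirroring how the constraints are phrased
    (screen-out of reference-negative individuals).
    """
    apoe4p_grid = sorted(set(float(x) for x in apoe4p_grid))
    ptau_grid = sorted(set(float(x) for x in ptau_grid))
    if not apoe4p_grid or not ptau_grid:
        raise ValueError("cutoff grids must be non-empty")
    df = _evaluation_frame(cohort)
    known = df[df["composite_amyloid"].isin([POSITIVE, NEGATIVE])]
    if len(known) == 0:
        raise ValueError("cohort has no rows with known amyloid status")

    rows = []
    feasible: list[tuple[RuleCutoffs, AgreementReport]] = []
    for a_cut in apoe4p_grid:
        for p_cut in ptau_grid:
            cutoffs = RuleCutoffs(apoe4p_cutoff=a_cut, ptau_cutoff=p_cut)
            called = classify_frame(known, cutoffs)
            counts = confusion(called["bbbm_call"], called["composite_amyloid"])
            report = metrics(counts)
            ok = constraints.satisfied_by(report)
            rows.append(
                {
                    "apoe4p_cutoff": a_cut,
                    "ptau_cutoff": p_cut,
                    "screen_out_rate": report.screen_out_rate,
                    "one_minus_npv": report.one_minus_npv,
                    "ppa": report.ppa,
                    "npa": report.npa,
                    "ppv": report.ppv,
                    "feasible": ok,
                }
            )
            if ok:
                feasible.append((cutoffs, report))

    chosen = None
    objective = None
    if feasible:
        def sort_key(item: tuple[RuleCutoffs, AgreementReport]):
            c, r = item
            onpv = r.one_minus_npv if r.one_minus_npv is not None else -1.0
            return (
                -r.screen_out_rate,
                onpv,
                -c.ptau_cutoff,
                -c.apoe4p_cutoff,
            )

        chosen, chosen_report = min(feasible, key=sort_key)
        objective = chosen_report.screen_out_rate
    return CutoffSearchResult(
        feasible=feasible,
        chosen=chosen,
        objective=objective,
        evaluated=pd.DataFrame(rows),
    )
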