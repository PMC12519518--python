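"""The two-step blood-biomarker pre-screening rule and the blinding pass-through.

Step 1: ApoE4p concentration strictly above the carrier cutoff (default
0.668 µg/mL) is called positive on the carrier branch; the pTau step is not
consulted.  Step 2: remaining participants are positive iff pTau181 is at or
above its cutoff (default 0.830 pg/mL, non-strict).  Inequality senses are
deliberate and tested: a value exactly at the ApoE4p cutoff falls through to
the pTau step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .reference import NEGATIVE, POSITIVE

BRANCH_CARRIER = "carrier"
BRANCH_PTAU_HIGH = "noncarrier_ptau_high"
BRANCH_PTAU_LOW = "noncarrier_ptau_low"

__all__ = [
    "RuleCutoffs",
    "BBBMCall",
    "classify",
    "classify_frame",
    "blinding_invite",
    "BRANCH_CARRIER",
    "BRANCH_PTAU_HIGH",
    "BRANCH_PTAU_LOW",
]


@dataclass(frozen=True)
class RuleCutoffs:
    """Decision thresholds with their inequality senses.

    apoe4p_cutoff: strictly greater than the cutoff => carrier (positive).
    ptau_cutoff: greater than or equal to the cutoff => positive.
    """

    apoe4p_cutoff: float = 0.668  # µg/mL
    ptau_cutoff: float = 0.830    # pg/mL

    def __post_init__(self):
        if not (self.apoe4p_cutoff > 0 and self.ptau_cutoff > 0):
            raise ValueError("cutoffs must be strictly positive")


DEFAULT_CUTOFFS = RuleCutoffs()


@dataclass(frozen=True)
class BBBMCall:
    call: str    # positive / negative
    branch: str  # carrier / noncarrier_ptau_high / noncarrier_ptau_low

    def __post_init__(self):
        pos_branches = {BRANCH_CARRIER, BRANCH_PTAU_HIGH}
        expected = POSITIVE if self.branch in pos_branches else NEGATIVE
        if self.call != expected:
            raise ValueError(f"call {self.call!r} inconsistent with branch {self.branch!r}")


def classify(
    apoe4p_conc: float, ptau181: float, cutoffs: RuleCutoffs = DEFAULT_CUTOFFS
) -> BBBMCall:
    """Apply the two-step rule to one participant. Total on complete inputs only."""
    for name, v in (("apoe4p_conc", apoe4p_conc), ("ptau181", ptau181)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"{name} is missing; the rule requires complete marker values")
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")
    if apoe4p_conc > cutoffs.apoe4p_cutoff:
        return BBBMCall(call=POSITIVE, branch=BRANCH_CARRIER)
    if ptau181 >= cutoffs.ptau_cutoff:
        return BBBMCall(call=POSITIVE, branch=BRANCH_PTAU_HIGH)
    return BBBMCall(call=NEGATIVE, branch=BRANCH_PTAU_LOW)


def classify_frame(
    df: pd.DataFrame, cutoffs: RuleCutoffs = DEFAULT_CUTOFFS
) -> pd.DataFrame:
    """Vectorised rule: adds bbbm_call and bbbm_branch columns to a copy of df."""
    apoe = df["apoe4p_conc"].to_numpy(dtype=float)
    ptau = df["ptau181"].to_numpy(dtype=float)
    if np.isnan(apoe).any() or np.isnan(ptau).any():
        raise ValueError("missing marker values; the rule requires complete inputs")
    if (apoe <= 0).any() or (ptau <= 0).any():
        raise ValueError("marker concentrations must be strictly positive")
    carrier = apoe > cutoffs.apoe4p_cutoff
    ptau_high = ~carrier & (ptau >= cutoffs.ptau_cutoff)
    out = df.copy()
    out["bbbm_branch"] = np.where(
        carrier, BRANCH_CARRIER, np.where(ptau_high, BRANCH_PTAU_HIGH, BRANCH_PTAU_LOW)
    )
    out["bbbm_call"] = np.where(carrier | ptau_high, POSITIVE, NEGATIVE)
    return out


def blinding_invite(
    calls: Sequence[str] | np.ndarray | pd.Series,
    pass_fraction: float,
    seed: int = 0,
    mode: str = "bernoulli",
) -> tuple[np.ndarray, np.ndarray]:
    """Invitation flags under the blinding pass-through.

    All rule-positive participants are invited.  Negatives are invited with
    probability ``pass_fraction`` — independently in ``bernoulli`` mode, or as
    an exact without-replacement quota of round(pass_fraction * n_negative) in
    ``quota`` mode.

    Returns ``(invited, subset)`` where subset is 1 for invited positives,
    2 for invited negatives and 0 for excluded participants.
    """
    if not (0.0 <= pass_fraction <= 1.0):
        raise ValueError(f"pass_fraction must be in [0, 1], got {pass_fraction}")
    if mode not in ("bernoulli", "quota"):
        raise ValueError(f"mode must be 'bernoulli' or 'quota', got {mode!r}")
    calls = np.asarray(calls, dtype=object)
    bad = set(np.unique(calls)) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"calls must be positive/negative, found {sorted(bad)}")
    positive = calls == POSITIVE
    rng = np.random.default_rng(seed)
    invited = positive.copy()
    neg_idx = np.flatnonzero(~positive)
    if mode == "bernoulli":
        invited[neg_idx] = rng.random(len(neg_idx)) < pass_fraction
    else:
        k = int(round(pass_fraction * len(neg_idx)))
        if k > 0:
            invited[rng.choice(neg_idx, size=k, replace=False)] = True
    subset = np.zeros(len(calls), dtype=int)
    subset[positive] = 1
    subset[invited & ~positive] = 2
    return invited, subset
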