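"""Composite amyloid-positivity reference from CSF and PET results.

A CSF call is positive when the CSF pTau181/Abeta42 ratio strictly exceeds
0.04.  The composite call follows an OR-rule: any positive modality makes the
composite positive; if only one modality is available its result is used; the
composite is unknown only when both modalities are missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"
MISSING = "missing"
UNKNOWN = "unknown"

CSF_RATIO_CUTOFF = 0.04  # strict: ratio == 0.04 is negative

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "MISSING",
    "UNKNOWN",
    "CSF_RATIO_CUTOFF",
    "csf_ratio_call",
    "composite_amyloid_status",
    "add_composite_column",
]


def csf_ratio_call(csf_ptau181: float, csf_abeta42: float) -> str:
    """Dichotomise the CSF pTau181/Abeta42 ratio at the (strict) 0.04 cutoff."""
    if not (csf_ptau181 > 0 and csf_abeta42 > 0):
        raise ValueError(
            f"CSF concentrations must be strictly positive, got "
            f"pTau181={csf_ptau181}, Abeta42={csf_abeta42}"
        )
    return POSITIVE if csf_ptau181 / csf_abeta42 > CSF_RATIO_CUTOFF else NEGATIVE


def composite_amyloid_status(pet_call: str, csf_call: str) -> str:
    """OR-rule composite of the two modality calls."""
    valid = {POSITIVE, NEGATIVE, MISSING}
    if pet_call not in valid or csf_call not in valid:
        raise ValueError(f"calls must be in {sorted(valid)}, got ({pet_call}, {csf_call})")
    if POSITIVE in (pet_call, csf_call):
        return POSITIVE
    if NEGATIVE in (pet_call, csf_call):
        return NEGATIVE
    return UNKNOWN


def add_composite_column(df: pd.DataFrame, column: str = "composite_amyloid") -> pd.DataFrame:
    """Vectorised composite call on a cohort table.

    Uses ``pet_result`` and, where both CSF analytes are present, the ratio
    call; writes the composite into ``column`` of a copy of the frame.
    """
    out = df.copy()
    pet = out["pet_result"].fillna(MISSING).replace("", MISSING).to_numpy(dtype=object)
    ptau = out["csf_ptau181"].to_numpy(dtype=float)
    ab42 = out["csf_abeta42"].to_numpy(dtype=float)
    csf_known = ~(np.isnan(ptau) | np.isnan(ab42))
    if np.any(csf_known & ((ptau <= 0) | (ab42 <= 0))):
        raise ValueError("CSF concentrations must be strictly positive where present")
    csf_pos = np.zeros(len(out), dtype=bool)
    csf_pos[csf_known] = ptau[csf_known] / ab42[csf_known] > CSF_RATIO_CUTOFF

    pet_pos = pet == POSITIVE
    pet_neg = pet == NEGATIVE
    csf_neg = csf_known & ~csf_pos
    composite = np.where(
        pet_pos | csf_pos,
        POSITIVE,
        np.where(pet_neg | csf_neg, NEGATIVE, UNKNOWN),
    )
    out[column] = composite
    return out
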