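"""Prevalence-transfer calculus.

PPA and NPA are treated as transportable (prevalence-invariant) properties of
the rule; PPV, 1-NPV and the expected negative fraction at any target
prevalence then follow from Bayes' theorem:

    PPV      = PPA*pi / (PPA*pi + (1-NPA)*(1-pi))
    1-NPV    = (1-PPA)*pi / ((1-PPA)*pi + NPA*(1-pi))
    neg frac = (1-PPA)*pi + NPA*(1-pi)

This is the assumption implicit in projecting a historic cohort's operating
point onto a prospective population at a different prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .metrics import ConfusionCounts

__all__ = [
    "OperatingPoint",
    "TransferReport",
    "ppv_at",
    "one_minus_npv_at",
    "expected_negative_fraction",
    "mixture_prevalence",
    "predict_performance",
    "DEFAULT_MIN_SCREEN_OUT",
    "DEFAULT_MAX_ONE_MINUS_NPV",
]

# acceptance constraints: screen-out strictly > 40%, 1-NPV <= 2%
DEFAULT_MIN_SCREEN_OUT = 0.40
DEFAULT_MAX_ONE_MINUS_NPV = 0.02


@dataclass(frozen=True)
class OperatingPoint:
    """(prevalence, PPA, NPA) triple, optionally backed by source counts."""

    prevalence: float
    ppa: float
    npa: float
    source_counts: ConfusionCounts | None = None

    def __post_init__(self):
        for name in ("prevalence", "ppa", "npa"):
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"{name} is undefined; cannot form an operating point")
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_counts(cls, counts: ConfusionCounts) -> "OperatingPoint":
        pos = counts.tp + counts.fn
        neg = counts.tn + counts.fp
        if pos == 0 or neg == 0 or counts.n_known == 0:
            raise ValueError("counts must contain both reference classes")
        return cls(
            prevalence=pos / counts.n_known,
            ppa=counts.tp / pos,
            npa=counts.tn / neg,
            source_counts=counts,
        )


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def ppv_at(prevalence: float, ppa: float, npa: float) -> float | None:
    """Bayes PPV at the given prevalence; None when the denominator is zero."""
    _check_unit("prevalence", prevalence)
    _check_unit("ppa", ppa)
    _check_unit("npa", npa)
    denom = ppa * prevalence + (1.0 - npa) * (1.0 - prevalence)
    if denom == 0.0:
        return None
    return ppa * prevalence / denom


def one_minus_npv_at(prevalence: float, ppa: float, npa: float) -> float | None:
    """Bayes 1-NPV at the given prevalence; None when the denominator is zero."""
    _check_unit("prevalence", prevalence)
    _check_unit("ppa", ppa)
    _check_unit("npa", npa)
    denom = (1.0 - ppa) * prevalence + npa * (1.0 - prevalence)
    if denom == 0.0:
        return None
    return (1.0 - ppa) * prevalence / denom


def expected_negative_fraction(prevalence: float, ppa: float, npa: float) -> float:
    """Expected fraction of rule-negative calls among reference-known
    participants (the screen-out projection on the confirmed denominator)."""
    _check_unit("prevalence", prevalence)
    _check_unit("ppa", ppa)
    _check_unit("npa", npa)
    return (1.0 - ppa) * prevalence + npa * (1.0 - prevalence)


def mixture_prevalence(
    carrier_prev: float, prev_carrier: float, prev_noncarrier: float
) -> float:
    """Overall prevalence implied by the carrier-status mixture."""
    _check_unit("carrier_prev", carrier_prev)
    _check_unit("prev_carrier", prev_carrier)
    _check_unit("prev_noncarrier", prev_noncarrier)
    return carrier_prev * prev_carrier + (1.0 - carrier_prev) * prev_noncarrier


@dataclass(frozen=True)
class TransferReport:
    """Predicted performance at a target prevalence, with acceptance flags."""

    target_prevalence: float
    ppa: float
    npa: float
    ppv: float | None
    one_minus_npv: float | None
    expected_negative_fraction: float
    enrichment: float | None  # predicted PPV / target prevalence
    # the screen-out constraint is on amyloid-negative individuals, whose
    # screen-out rate is the (prevalence-invariant) NPA
    passes_screen_out: bool   # NPA strictly > min_screen_out
    passes_one_minus_npv: bool  # predicted 1-NPV <= max_one_minus_npv
    min_screen_out: float = DEFAULT_MIN_SCREEN_OUT
    max_one_minus_npv: float = DEFAULT_MAX_ONE_MINUS_NPV

    @property
    def passes(self) -> bool:
        return self.passes_screen_out and self.passes_one_minus_npv

    def to_dict(self) -> dict:
        return {
            "target_prevalence": self.target_prevalence,
            "ppa": self.ppa,
            "npa": self.npa,
            "ppv": self.ppv,
            "one_minus_npv": self.one_minus_npv,
            "expected_negative_fraction": self.expected_negative_fraction,
            "enrichment": self.enrichment,
            "passes_screen_out": self.passes_screen_out,
            "passes_one_minus_npv": self.passes_one_minus_npv,
            "passes": self.passes,
            "min_screen_out": self.min_screen_out,
            "max_one_minus_npv": self.max_one_minus_npv,
        }


def predict_performance(
    source: OperatingPoint,
    target_prevalence: float,
    min_screen_out: float = DEFAULT_MIN_SCREEN_OUT,
    max_one_minus_npv: float = DEFAULT_MAX_ONE_MINUS_NPV,
) -> TransferReport:
    """Hold (PPA, NPA) fixed and project performance onto a new prevalence."""
    _check_unit("target_prevalence", target_prevalence)
    ppv = ppv_at(target_prevalence, source.ppa, source.npa)
    onpv = one_minus_npv_at(target_prevalence, source.ppa, source.npa)
    neg_frac = expected_negative_fraction(target_prevalence, source.ppa, source.npa)
    enrichment = None
    if ppv is not None and target_prevalence > 0:
        enrichment = ppv / target_prevalence
    return TransferReport(
        target_prevalence=target_prevalence,
        ppa=source.ppa,
        npa=source.npa,
        ppv=ppv,
        one_minus_npv=onpv,
        expected_negative_fraction=neg_frac,
        enrichment=enrichment,
        passes_screen_out=source.npa > min_screen_out,
        passes_one_minus_npv=(onpv is not None and onpv <= max_one_minus_npv),
        min_screen_out=min_screen_out,
        max_one_minus_npv=max_one_minus_npv,
    )
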