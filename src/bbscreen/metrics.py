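"""Confusion counts against the amyloid reference and agreement metrics.

Metric formulas: prevalence = (TP+FN)/(P+N), PPA = TP/(TP+FN),
NPA = TN/(TN+FP), PPV = TP/(TP+FP), 1-NPV = FN/(TN+FN), each reported with a
Wilson score interval.  A metric whose denominator is zero is undefined
(``None``), never silently 0.  The screen-out rate uses all participants with
a rule result as denominator, which may exceed the reference-confirmed subset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .reference import NEGATIVE, POSITIVE, UNKNOWN

__all__ = [
    "ConfusionCounts",
    "AgreementReport",
    "confusion",
    "metrics",
    "wilson_ci",
    "format_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts among reference-known participants plus rule totals.

    ``n_total_with_bbbm`` / ``n_negative_calls`` cover every participant with a
    rule result, including those whose reference status is unknown; they feed
    the screen-out denominator.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    n_total_with_bbbm: int | None = None
    n_negative_calls: int | None = None

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        known = self.tp + self.fp + self.tn + self.fn
        if self.n_total_with_bbbm is None:
            object.__setattr__(self, "n_total_with_bbbm", known)
        if self.n_negative_calls is None:
            object.__setattr__(self, "n_negative_calls", self.tn + self.fn)
        if known > self.n_total_with_bbbm:
            raise ValueError("tp+fp+tn+fn exceeds n_total_with_bbbm")
        if self.tn + self.fn > self.n_negative_calls:
            raise ValueError("tn+fn exceeds n_negative_calls")

    @property
    def n_known(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class AgreementReport:
    """Point estimates (None when the denominator is zero) with Wilson CIs."""

    prevalence: float | None
    ppa: float | None
    npa: float | None
    ppv: float | None
    one_minus_npv: float | None
    screen_out_rate: float | None
    ci_level: float = 0.95
    ci: dict = field(default_factory=dict)  # metric name -> (lower, upper)

    def to_dict(self) -> dict:
        return {
            "prevalence": self.prevalence,
            "ppa": self.ppa,
            "npa": self.npa,
            "ppv": self.ppv,
            "one_minus_npv": self.one_minus_npv,
            "screen_out_rate": self.screen_out_rate,
            "ci_level": self.ci_level,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def confusion(
    bbbm_calls: Sequence[str], composite_amyloid: Sequence[str]
) -> ConfusionCounts:
    """Tally rule calls against reference status; unknown references are
    excluded from the 2x2 but kept in the rule totals."""
    calls = np.asarray(bbbm_calls, dtype=object)
    amyloid = np.asarray(composite_amyloid, dtype=object)
    if len(calls) != len(amyloid):
        raise ValueError(
            f"length mismatch: {len(calls)} calls vs {len(amyloid)} reference entries"
        )
    bad = set(np.unique(calls)) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"rule calls must be positive/negative, found {sorted(bad)}")
    bad = set(np.unique(amyloid)) - {POSITIVE, NEGATIVE, UNKNOWN}
    if bad:
        raise ValueError(f"reference entries must be positive/negative/unknown, found {sorted(bad)}")
    call_pos = calls == POSITIVE
    ref_pos = amyloid == POSITIVE
    ref_neg = amyloid == NEGATIVE
    return ConfusionCounts(
        tp=int(np.sum(call_pos & ref_pos)),
        fp=int(np.sum(call_pos & ref_neg)),
        tn=int(np.sum(~call_pos & ref_neg)),
        fn=int(np.sum(~call_pos & ref_pos)),
        n_total_with_bbbm=len(calls),
        n_negative_calls=int(np.sum(~call_pos)),
    )


def wilson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval, bounds clipped to [0, 1]."""
    if trials < 1:
        raise ValueError("wilson_ci requires trials >= 1")
    if not (0 <= successes <= trials):
        raise ValueError(f"successes must be in [0, {trials}], got {successes}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = norm.ppf(0.5 + level / 2.0)
    p = successes / trials
    denom = 1.0 + z * z / trials
    centre = (p + z * z / (2.0 * trials)) / denom
    half = z * math.sqrt(p * (1.0 - p) / trials + z * z / (4.0 * trials * trials)) / denom
    # boundaries are exact: 0 successes pins the lower bound, all successes the upper
    lower = 0.0 if successes == 0 else max(0.0, centre - half)
    upper = 1.0 if successes == trials else min(1.0, centre + half)
    return lower, upper


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(counts: ConfusionCounts, ci_level: float = 0.95) -> AgreementReport:
    """Agreement metrics with Wilson intervals for PPA, NPA, PPV and 1-NPV."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    report_ci: dict[str, tuple[float, float]] = {}
    for name, num, den in (
        ("ppa", tp, tp + fn),
        ("npa", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("one_minus_npv", fn, tn + fn),
    ):
        if den > 0:
            report_ci[name] = wilson_ci(num, den, ci_level)
    return AgreementReport(
        prevalence=_ratio(tp + fn, counts.n_known),
        ppa=_ratio(tp, tp + fn),
        npa=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        one_minus_npv=_ratio(fn, tn + fn),
        screen_out_rate=_ratio(counts.n_negative_calls, counts.n_total_with_bbbm),
        ci_level=ci_level,
        ci=report_ci,
    )


def _fmt_pct(value: float | None, decimals: int = 1) -> str:
    return "NA" if value is None else f"{100.0 * value:.{decimals}f}%"


def format_report(report: AgreementReport, title: str = "") -> str:
    """Render a report as a small text table (percentages to one decimal)."""
    lines = []
    if title:
        lines.append(title)
    for name, value in (
        ("Screen-out rate", report.screen_out_rate),
        ("Prevalence", report.prevalence),
        ("PPA", report.ppa),
        ("NPA", report.npa),
        ("PPV", report.ppv),
        ("1-NPV", report.one_minus_npv),
    ):
        key = name.lower().replace("-", "_").replace(" ", "_")
        key = {"1_npv": "one_minus_npv", "screen_out_rate": "screen_out_rate"}.get(key, key)
        cell = _fmt_pct(value)
        if key in report.ci:
            lo, hi = report.ci[key]
            cell += f" ({_fmt_pct(lo)}-{_fmt_pct(hi)})"
        lines.append(f"{name:<16}{cell}")
    return "\n".join(lines)
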