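"""Full-pipeline orchestration: arms, funnels, and serialized reports.

The experiment splits a cohort into three arms: a pre-screening arm where a
negative rule call excludes the participant (up to the blinding pass-through),
a direct-entry arm where the rule is recorded but never excludes, and a
historic-imaging pass-through arm.  Per-arm funnels and agreement reports are
collected into a FlowReport whose JSON serialisation is byte-identical across
reruns with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, CohortSpec, generate_cohort
from .cutoffs import ConstraintSpec
from .metrics import AgreementReport, confusion, metrics
from .reference import NEGATIVE, POSITIVE, add_composite_column
from .rule import RuleCutoffs, blinding_invite, classify_frame
from .risk import PREDICTOR_SETS, fit_logistic, predictiveness_curves

logger = logging.getLogger(__name__)

__all__ = ["FlowConfig", "FlowReport", "run_prescreen_arm", "run_direct_arm", "run_experiment"]


@dataclass(frozen=True)
class FlowConfig:
    """Configuration for a full experiment run."""

    cohort_spec: CohortSpec | None = None
    cohort_csv: str | None = None
    group_probs: tuple[float, float, float] = (0.78, 0.22, 0.0)  # prescreen/direct/historic
    blind_fraction: float = 0.10
    blind_mode: str = "bernoulli"
    attrition: float = 0.0  # invitees lost before confirmatory testing
    cutoffs: RuleCutoffs = field(default_factory=RuleCutoffs)
    constraints: ConstraintSpec = field(default_factory=ConstraintSpec)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if (self.cohort_spec is None) == (self.cohort_csv is None):
            raise ValueError("exactly one of cohort_spec or cohort_csv must be given")
        probs = np.asarray(self.group_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("group_probs must be three non-negative values summing to 1")
        if not (0.0 <= self.blind_fraction <= 1.0):
            raise ValueError("blind_fraction must be in [0, 1]")
        if self.blind_mode not in ("bernoulli", "quota"):
            raise ValueError("blind_mode must be 'bernoulli' or 'quota'")
        if not (0.0 <= self.attrition <= 1.0):
            raise ValueError("attrition must be in [0, 1]")

    def config_hash(self) -> str:
        payload = {
            "cohort_spec": self.cohort_spec.to_flat_dict() if self.cohort_spec else None,
            "cohort_csv": self.cohort_csv,
            "group_probs": list(self.group_probs),
            "blind_fraction": self.blind_fraction,
            "blind_mode": self.blind_mode,
            "attrition": self.attrition,
            "cutoffs": dataclasses.asdict(self.cutoffs),
            "constraints": dataclasses.asdict(self.constraints),
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class FlowReport:
    """Per-group funnel counts and agreement reports plus provenance."""

    groups: dict = field(default_factory=dict)  # name -> {"counts": ..., "report(s)": ...}
    acceptance: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def convert(obj):
            if isinstance(obj, AgreementReport):
                return obj.to_dict()
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, np.bool_):
                return bool(obj)
            return obj

        return {
            "groups": convert(self.groups),
            "acceptance": convert(self.acceptance),
            "provenance": convert(self.provenance),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _funnel_check(counts: dict) -> None:
    if counts["bbbm_positive"] + counts["bbbm_negative"] != counts["blood_tested"]:
        raise AssertionError("funnel conservation violated: calls do not partition tested")
    if counts["invited"] > counts["blood_tested"]:
        raise AssertionError("funnel conservation violated: invited exceeds tested")
    if counts["confirmed"] > counts["invited"]:
        raise AssertionError("funnel conservation violated: confirmed exceeds invited")


def run_prescreen_arm(
    df: pd.DataFrame, config: FlowConfig, seed: int | None = None
) -> dict:
    """Pre-screening arm: classify, blind-invite, attrition, then confirm.

    Subset 1 = invited rule-positives (PPV reported); Subset 2 = invited
    rule-negatives (1-NPV reported).  Prevalence/PPA/NPA are deliberately
    omitted: the negatives reaching confirmation are a blinded sample, not the
    full negative stratum.
    """
    seed = config.seed if seed is None else seed
    called = classify_frame(df, config.cutoffs)
    invited, subset = blinding_invite(
        called["bbbm_call"], config.blind_fraction, seed=seed, mode=config.blind_mode
    )
    called = called.assign(invited=invited, subset=subset)
    rng = np.random.default_rng(seed + 1)
    retained = invited & (rng.random(len(called)) >= config.attrition)
    called = add_composite_column(called)
    known = called["composite_amyloid"].isin([POSITIVE, NEGATIVE]).to_numpy()
    confirmed = retained & known

    counts = {
        "blood_tested": len(called),
        "bbbm_positive": int((called["bbbm_call"] == POSITIVE).sum()),
        "bbbm_negative": int((called["bbbm_call"] == NEGATIVE).sum()),
        "invited": int(invited.sum()),
        "invited_subset1": int((subset == 1).sum()),
        "invited_subset2": int((subset == 2).sum()),
        "confirmed": int(confirmed.sum()),
        "amyloid_positive": int(
            (called.loc[confirmed, "composite_amyloid"] == POSITIVE).sum()
        ),
    }
    _funnel_check(counts)

    reports: dict[str, AgreementReport] = {}
    for label, sub in (("subset1", 1), ("subset2", 2)):
        mask = confirmed & (subset == sub)
        if mask.sum() > 0:
            c = confusion(
                called.loc[mask, "bbbm_call"], called.loc[mask, "composite_amyloid"]
            )
            reports[label] = metrics(c)
    screen_out = counts["bbbm_negative"] / counts["blood_tested"] if counts["blood_tested"] else None
    return {"counts": counts, "screen_out_rate": screen_out, "reports": reports, "frame": called}


def run_direct_arm(df: pd.DataFrame, config: FlowConfig) -> dict:
    """Direct-entry arm: the rule is recorded for all but excludes no one;
    the full agreement report is computed retrospectively on reference-known rows."""
    if len(df) == 0:
        raise ValueError("direct arm received an empty cohort")
    called = classify_frame(df, config.cutoffs)
    called = called.assign(invited=True, subset=0)
    called = add_composite_column(called)
    known = called[called["composite_amyloid"].isin([POSITIVE, NEGATIVE])]
    counts = {
        "blood_tested": len(called),
        "bbbm_positive": int((called["bbbm_call"] == POSITIVE).sum()),
        "bbbm_negative": int((called["bbbm_call"] == NEGATIVE).sum()),
        "invited": len(called),
        "confirmed": len(known),
        "amyloid_positive": int((known["composite_amyloid"] == POSITIVE).sum()),
    }
    _funnel_check(counts)
    report = None
    if len(known) > 0:
        c = confusion(known["bbbm_call"], known["composite_amyloid"])
        # screen-out over everyone with a rule result, not just the confirmed
        c = dataclasses.replace(
            c,
            n_total_with_bbbm=counts["blood_tested"],
            n_negative_calls=counts["bbbm_negative"],
        )
        report = metrics(c)
    return {"counts": counts, "report": report, "frame": called}


def run_historic_arm(df: pd.DataFrame, config: FlowConfig) -> dict:
    """Historic-imaging pass-through: amyloid assessed directly, rule overlaid."""
    called = classify_frame(df, config.cutoffs)
    called = called.assign(invited=True, subset=0)
    called = add_composite_column(called)
    known = called[called["composite_amyloid"].isin([POSITIVE, NEGATIVE])]
    counts = {
        "blood_tested": len(called),
        "bbbm_positive": int((called["bbbm_call"] == POSITIVE).sum()),
        "bbbm_negative": int((called["bbbm_call"] == NEGATIVE).sum()),
        "invited": len(called),
        "confirmed": len(known),
        "amyloid_positive": int((known["composite_amyloid"] == POSITIVE).sum()),
    }
    _funnel_check(counts)
    return {"counts": counts, "frame": called}


def run_experiment(config: FlowConfig) -> FlowReport:
    """Simulate or load the cohort, split into arms, run every arm, and
    (optionally) write cohort CSV, report JSON, a text table, and curve CSVs."""
    if config.cohort_spec is not None:
        cohort = generate_cohort(config.cohort_spec)
    else:
        cohort = Cohort.from_csv(config.cohort_csv)
    df = cohort.df
    rng = np.random.default_rng(config.seed)
    arm = rng.choice(3, size=len(df), p=list(config.group_probs))
    logger.info("cohort of %d split into arms: %s", len(df), np.bincount(arm, minlength=3))

    report = FlowReport()
    frames = {}
    if (arm == 0).any():
        frag = run_prescreen_arm(df[arm == 0].reset_index(drop=True), config, seed=config.seed + 10)
        frames["group1"] = frag.pop("frame")
        report.groups["group1"] = frag
    if (arm == 1).any():
        frag = run_direct_arm(df[arm == 1].reset_index(drop=True), config)
        frames["group2"] = frag.pop("frame")
        report.groups["group2"] = frag
    if (arm == 2).any():
        frag = run_historic_arm(df[arm == 2].reset_index(drop=True), config)
        frames["group3"] = frag.pop("frame")
        report.groups["group3"] = frag

    # acceptance flags: the screen-out criterion applies to amyloid-negative
    # individuals (the NPA of the direct arm's retrospective report, where the
    # full negative stratum is observable); overall screen-out is informational
    screen_out = None
    if "group1" in report.groups:
        screen_out = report.groups["group1"]["screen_out_rate"]
    elif "group2" in report.groups:
        g2c = report.groups["group2"]["counts"]
        screen_out = g2c["bbbm_negative"] / g2c["blood_tested"]
    npa = None
    one_minus_npv = None
    g2_report = report.groups.get("group2", {}).get("report")
    if g2_report is not None:
        npa = g2_report.npa
        one_minus_npv = g2_report.one_minus_npv
    report.acceptance = {
        "screen_out_rate": screen_out,
        "screen_out_negatives": npa,
        "one_minus_npv": one_minus_npv,
        "passes_screen_out": (
            npa is not None and npa > config.constraints.min_screen_out
        ),
        "passes_one_minus_npv": (
            one_minus_npv is not None
            and one_minus_npv <= config.constraints.max_one_minus_npv
        ),
    }
    report.provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort.csv")
        (out / "report.json").write_text(report.to_json() + "\n")
        _write_table(report, out / "table1.tsv")
        if "group2" in frames:
            _write_curves(frames["group2"], config, out / "curves_group2.csv")
        logger.info("outputs written to %s", out)
    return report


def _write_table(report: FlowReport, path: Path) -> None:
    rows = []
    for group, frag in sorted(report.groups.items()):
        counts = frag["counts"]
        row = {"group": group, **counts}
        rep = frag.get("report")
        if rep is not None:
            for k in ("prevalence", "ppa", "npa", "ppv", "one_minus_npv", "screen_out_rate"):
                v = getattr(rep, k)
                row[k] = "" if v is None else f"{100 * v:.1f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_curves(frame: pd.DataFrame, config: FlowConfig, path: Path) -> None:
    known = frame[frame["composite_amyloid"].isin([POSITIVE, NEGATIVE])]
    if known["composite_amyloid"].nunique() < 2:
        logger.warning("skipping curves: single amyloid class in direct arm")
        return
    model = fit_logistic(known, PREDICTOR_SETS["ptau_apoe4p"], cutoffs=config.cutoffs)
    profile = predictiveness_curves(model.fitted, known["composite_amyloid"])
    profile.to_frame().to_csv(path, index=False)
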