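"""Synthetic screening-cohort generation.

Cohorts are drawn from a stratified mixture: ApoE4-protein carrier status is
Bernoulli, amyloid status is Bernoulli conditional on carriage, and every
plasma marker is log10-normal within its (amyloid, carrier) stratum.  Marker
locations are calibration targets, not constants: :func:`derive_stratum_operating_points`
decomposes an algorithm-level (PPA, NPA) target into the sensitivity and
specificity the pTau181 step must achieve among non-carriers, and
:func:`calibrate_marker_location` places a log10-normal so a given cutoff
attains a given exceedance probability.  The shipped factory specs use these
two utilities so that the default rule cutoffs recover the target operating
point on a large generated cohort.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "SpecValidationError",
    "InfeasibleTargetError",
    "LogNormalByStratum",
    "LogNormalByAmyloid",
    "CohortSpec",
    "ParticipantRecord",
    "Cohort",
    "generate_cohort",
    "derive_stratum_operating_points",
    "calibrate_marker_location",
    "apply_assay_perturbation",
    "a4_like_spec",
    "group2_like_spec",
    "PLASMA_MARKERS",
    "ALL_MARKERS",
    "COHORT_COLUMNS",
]

#: plasma markers modelled per (amyloid, carrier) stratum
PLASMA_MARKERS = ("ptau181", "gfap", "abeta42", "abeta40")
#: every assayed plasma column (ApoE4p concentration comes from a mixture, not strata)
ALL_MARKERS = ("apoe4p_conc",) + PLASMA_MARKERS

COHORT_COLUMNS = (
    "id",
    "amyloid_true",
    "apoe4p_carrier_true",
    "apoe4p_conc",
    "ptau181",
    "gfap",
    "abeta42",
    "abeta40",
    "pet_result",
    "csf_ptau181",
    "csf_abeta42",
)


class SpecValidationError(ValueError):
    """Raised when a cohort specification field violates its invariant."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class InfeasibleTargetError(ValueError):
    """Raised when a requested operating point cannot be decomposed into
    per-stratum sensitivities/specificities in [0, 1]."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise SpecValidationError(name, f"must be a probability in [0, 1], got {value}")


def _check_pos(name: str, value: float) -> None:
    if not value > 0:
        raise SpecValidationError(name, f"must be strictly positive, got {value}")


Stratum = tuple[int, int]  # (amyloid, carrier)
_STRATA: tuple[Stratum, ...] = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class LogNormalByStratum:
    """log10-normal parameters keyed by (amyloid, carrier) stratum."""

    loc: Mapping[Stratum, float]
    scale: Mapping[Stratum, float]

    @classmethod
    def from_amyloid(
        cls, loc_negative: float, loc_positive: float, scale: float
    ) -> "LogNormalByStratum":
        """Same distribution for carriers and non-carriers within amyloid status."""
        return cls(
            loc={(0, 0): loc_negative, (0, 1): loc_negative,
                 (1, 0): loc_positive, (1, 1): loc_positive},
            scale={s: scale for s in _STRATA},
        )

    def validate(self, name: str) -> None:
        for s in _STRATA:
            if s not in self.loc or s not in self.scale:
                raise SpecValidationError(name, f"missing stratum {s}")
            _check_pos(f"{name}.scale{s}", self.scale[s])


@dataclass(frozen=True)
class LogNormalByAmyloid:
    """log10-normal parameters keyed by amyloid status (CSF model)."""

    loc_negative: float
    loc_positive: float
    scale_negative: float
    scale_positive: float

    def validate(self, name: str) -> None:
        _check_pos(f"{name}.scale_negative", self.scale_negative)
        _check_pos(f"{name}.scale_positive", self.scale_positive)


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of a synthetic screening cohort.

    Concentration units follow the assay conventions: ApoE4p in µg/mL, all
    other plasma markers and CSF analytes in pg/mL.  All locations/scales are
    on the log10 scale.
    """

    n_participants: int
    carrier_prevalence: float
    amyloid_prev_carrier: float
    amyloid_prev_noncarrier: float
    markers: Mapping[str, LogNormalByStratum]
    apoe4p_noncarrier_loc: float
    apoe4p_noncarrier_scale: float
    apoe4p_carrier_loc: float
    apoe4p_carrier_scale: float
    csf_ptau181: LogNormalByAmyloid
    csf_abeta42: LogNormalByAmyloid
    assay_cv: float = 0.0
    preanalytical_bias: Mapping[str, float] = field(default_factory=dict)
    confirm_fraction: float = 1.0
    carrier_misclass_rate: float = 0.0
    log_correlation: np.ndarray | None = None  # 4x4, order PLASMA_MARKERS
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_participants, (int, np.integer)) or self.n_participants < 1:
            raise SpecValidationError("n_participants", "must be an integer >= 1")
        _check_prob("carrier_prevalence", self.carrier_prevalence)
        _check_prob("amyloid_prev_carrier", self.amyloid_prev_carrier)
        _check_prob("amyloid_prev_noncarrier", self.amyloid_prev_noncarrier)
        _check_prob("confirm_fraction", self.confirm_fraction)
        _check_prob("carrier_misclass_rate", self.carrier_misclass_rate)
        mix = (self.carrier_prevalence * self.amyloid_prev_carrier
               + (1 - self.carrier_prevalence) * self.amyloid_prev_noncarrier)
        if not (0.0 <= mix <= 1.0):
            raise SpecValidationError("mixture_prevalence", f"out of [0, 1]: {mix}")
        for m in PLASMA_MARKERS:
            if m not in self.markers:
                raise SpecValidationError("markers", f"missing marker {m!r}")
            self.markers[m].validate(f"markers[{m!r}]")
        _check_pos("apoe4p_noncarrier_scale", self.apoe4p_noncarrier_scale)
        _check_pos("apoe4p_carrier_scale", self.apoe4p_carrier_scale)
        self.csf_ptau181.validate("csf_ptau181")
        self.csf_abeta42.validate("csf_abeta42")
        if self.assay_cv < 0:
            raise SpecValidationError("assay_cv", f"must be >= 0, got {self.assay_cv}")
        for m, b in self.preanalytical_bias.items():
            if m not in ALL_MARKERS:
                raise SpecValidationError("preanalytical_bias", f"unknown marker {m!r}")
            _check_pos(f"preanalytical_bias[{m!r}]", b)
        if self.log_correlation is not None:
            corr = np.asarray(self.log_correlation, dtype=float)
            if corr.shape != (4, 4):
                raise SpecValidationError("log_correlation", "must be 4x4")
            if not np.allclose(corr, corr.T):
                raise SpecValidationError("log_correlation", "must be symmetric")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise SpecValidationError("log_correlation", "must be positive semi-definite")

    @property
    def mixture_prevalence(self) -> float:
        return (self.carrier_prevalence * self.amyloid_prev_carrier
                + (1 - self.carrier_prevalence) * self.amyloid_prev_noncarrier)

    # -- flat key/value round trip -------------------------------------------------

    def to_flat_dict(self) -> dict:
        d: dict[str, object] = {
            "n_participants": int(self.n_participants),
            "carrier_prevalence": float(self.carrier_prevalence),
            "amyloid_prev_carrier": float(self.amyloid_prev_carrier),
            "amyloid_prev_noncarrier": float(self.amyloid_prev_noncarrier),
            "apoe4p_noncarrier_loc": float(self.apoe4p_noncarrier_loc),
            "apoe4p_noncarrier_scale": float(self.apoe4p_noncarrier_scale),
            "apoe4p_carrier_loc": float(self.apoe4p_carrier_loc),
            "apoe4p_carrier_scale": float(self.apoe4p_carrier_scale),
            "assay_cv": float(self.assay_cv),
            "confirm_fraction": float(self.confirm_fraction),
            "carrier_misclass_rate": float(self.carrier_misclass_rate),
            "seed": int(self.seed),
        }
        for m in PLASMA_MARKERS:
            p = self.markers[m]
            for (a, c) in _STRATA:
                d[f"{m}.loc.a{a}c{c}"] = float(p.loc[(a, c)])
                d[f"{m}.scale.a{a}c{c}"] = float(p.scale[(a, c)])
        for name, p in (("csf_ptau181", self.csf_ptau181), ("csf_abeta42", self.csf_abeta42)):
            d[f"{name}.loc_negative"] = float(p.loc_negative)
            d[f"{name}.loc_positive"] = float(p.loc_positive)
            d[f"{name}.scale_negative"] = float(p.scale_negative)
            d[f"{name}.scale_positive"] = float(p.scale_positive)
        for m, b in sorted(self.preanalytical_bias.items()):
            d[f"preanalytical_bias.{m}"] = float(b)
        if self.log_correlation is not None:
            corr = np.asarray(self.log_correlation, dtype=float)
            for i, mi in enumerate(PLASMA_MARKERS):
                for j, mj in enumerate(PLASMA_MARKERS):
                    if i < j:
                        d[f"log_correlation.{mi}.{mj}"] = float(corr[i, j])
        return d

    @classmethod
    def from_flat_dict(cls, d: Mapping[str, object]) -> "CohortSpec":
        d = dict(d)
        markers = {}
        for m in PLASMA_MARKERS:
            loc = {(a, c): float(d.pop(f"{m}.loc.a{a}c{c}")) for (a, c) in _STRATA}
            scale = {(a, c): float(d.pop(f"{m}.scale.a{a}c{c}")) for (a, c) in _STRATA}
            markers[m] = LogNormalByStratum(loc=loc, scale=scale)
        csf = {}
        for name in ("csf_ptau181", "csf_abeta42"):
            csf[name] = LogNormalByAmyloid(
                loc_negative=float(d.pop(f"{name}.loc_negative")),
                loc_positive=float(d.pop(f"{name}.loc_positive")),
                scale_negative=float(d.pop(f"{name}.scale_negative")),
                scale_positive=float(d.pop(f"{name}.scale_positive")),
            )
        bias = {}
        corr_entries = {}
        for key in list(d):
            if key.startswith("preanalytical_bias."):
                bias[key.split(".", 1)[1]] = float(d.pop(key))
            elif key.startswith("log_correlation."):
                _, mi, mj = key.split(".")
                corr_entries[(mi, mj)] = float(d.pop(key))
        corr = None
        if corr_entries:
            corr = np.eye(4)
            idx = {m: i for i, m in enumerate(PLASMA_MARKERS)}
            for (mi, mj), v in corr_entries.items():
                corr[idx[mi], idx[mj]] = corr[idx[mj], idx[mi]] = v
        return cls(
            n_participants=int(d.pop("n_participants")),
            carrier_prevalence=float(d.pop("carrier_prevalence")),
            amyloid_prev_carrier=float(d.pop("amyloid_prev_carrier")),
            amyloid_prev_noncarrier=float(d.pop("amyloid_prev_noncarrier")),
            markers=markers,
            apoe4p_noncarrier_loc=float(d.pop("apoe4p_noncarrier_loc")),
            apoe4p_noncarrier_scale=float(d.pop("apoe4p_noncarrier_scale")),
            apoe4p_carrier_loc=float(d.pop("apoe4p_carrier_loc")),
            apoe4p_carrier_scale=float(d.pop("apoe4p_carrier_scale")),
            csf_ptau181=csf["csf_ptau181"],
            csf_abeta42=csf["csf_abeta42"],
            assay_cv=float(d.pop("assay_cv", 0.0)),
            preanalytical_bias=bias,
            confirm_fraction=float(d.pop("confirm_fraction", 1.0)),
            carrier_misclass_rate=float(d.pop("carrier_misclass_rate", 0.0)),
            log_correlation=corr,
            seed=int(d.pop("seed", 0)),
        )

    def to_config(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True, default_flow_style=False)

    @classmethod
    def from_config(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_flat_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ParticipantRecord:
    """One screened individual; ground truth always present, reference tests optional."""

    id: str
    amyloid_true: int
    apoe4p_carrier_true: int
    apoe4p_conc: float
    ptau181: float
    gfap: float
    abeta42: float
    abeta40: float
    pet_result: str  # positive / negative / missing
    csf_ptau181: float | None
    csf_abeta42: float | None


@dataclass(frozen=True)
class Cohort:
    """Ordered participant table plus provenance of how it was generated."""

    df: pd.DataFrame
    spec_used: CohortSpec | None = None
    seed_used: int | None = None

    def __post_init__(self):
        missing = [c for c in COHORT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if self.df["id"].duplicated().any():
            raise ValueError("cohort record ids must be unique")
        if self.spec_used is not None and len(self.df) != self.spec_used.n_participants:
            raise ValueError("cohort length does not match spec n_participants")

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[ParticipantRecord]:
        for row in self.df.itertuples(index=False):
            yield ParticipantRecord(
                id=row.id,
                amyloid_true=int(row.amyloid_true),
                apoe4p_carrier_true=int(row.apoe4p_carrier_true),
                apoe4p_conc=float(row.apoe4p_conc),
                ptau181=float(row.ptau181),
                gfap=float(row.gfap),
                abeta42=float(row.abeta42),
                abeta40=float(row.abeta40),
                pet_result=str(row.pet_result),
                csf_ptau181=None if pd.isna(row.csf_ptau181) else float(row.csf_ptau181),
                csf_abeta42=None if pd.isna(row.csf_abeta42) else float(row.csf_abeta42),
            )

    def to_csv(self, path_or_buf) -> None:
        out = self.df.copy()
        out["pet_result"] = out["pet_result"].replace("missing", "")
        out.to_csv(path_or_buf, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path_or_buf) -> "Cohort":
        df = pd.read_csv(
            path_or_buf,
            dtype={"id": str, "pet_result": str},
            keep_default_na=True,
        )
        df["pet_result"] = df["pet_result"].fillna("").replace("", "missing")
        return cls(df=df)


def mixture_check(spec: CohortSpec) -> float:
    spec.validate()
    return spec.mixture_prevalence


def derive_stratum_operating_points(
    p_carrier: float,
    prev_carrier: float,
    prev_noncarrier: float,
    target_ppa: float,
    target_npa: float,
) -> tuple[float, float]:
    """Decompose an algorithm-level (PPA, NPA) target into the pTau step's
    required sensitivity and specificity among non-carriers.

    The carrier branch classifies every carrier positive, so

        PPA = P(carrier | A+) + P(non-carrier | A+) * Se_ptau
        NPA = P(non-carrier | A-) * Sp_ptau

    which invert to the returned pair.  Raises :class:`InfeasibleTargetError`
    when either solution falls outside [0, 1].
    """
    for name, v in (
        ("p_carrier", p_carrier),
        ("prev_carrier", prev_carrier),
        ("prev_noncarrier", prev_noncarrier),
        ("target_ppa", target_ppa),
        ("target_npa", target_npa),
    ):
        _check_prob(name, v)
    pi = p_carrier * prev_carrier + (1 - p_carrier) * prev_noncarrier
    if not (0.0 < pi < 1.0):
        raise InfeasibleTargetError(f"implied overall prevalence {pi} not in (0, 1)")
    p_carrier_given_pos = p_carrier * prev_carrier / pi
    if target_ppa < p_carrier_given_pos - 1e-12:
        raise InfeasibleTargetError(
            f"target PPA {target_ppa} below P(carrier|A+) = {p_carrier_given_pos:.6f}; "
            "the carrier step alone already exceeds the target"
        )
    if 1.0 - p_carrier_given_pos < 1e-15:
        se_ptau = 0.0
    else:
        se_ptau = (target_ppa - p_carrier_given_pos) / (1.0 - p_carrier_given_pos)
    p_noncarrier_given_neg = (1 - p_carrier) * (1 - prev_noncarrier) / (1 - pi)
    if p_noncarrier_given_neg <= 0:
        raise InfeasibleTargetError("no amyloid-negative non-carriers exist in this mixture")
    sp_ptau = target_npa / p_noncarrier_given_neg
    if sp_ptau > 1.0 + 1e-12:
        raise InfeasibleTargetError(
            f"target NPA {target_npa} requires pTau specificity {sp_ptau:.6f} > 1 "
            f"given P(non-carrier|A-) = {p_noncarrier_given_neg:.6f}"
        )
    return min(max(se_ptau, 0.0), 1.0), min(max(sp_ptau, 0.0), 1.0)


def calibrate_marker_location(
    cutoff: float, tail_probability: float, log10_scale: float
) -> float:
    """Location µ of a log10-normal such that P(X >= cutoff) = tail_probability."""
    _check_pos("cutoff", cutoff)
    if not (0.0 < tail_probability < 1.0):
        raise SpecValidationError("tail_probability", "must be in (0, 1)")
    _check_pos("log10_scale", log10_scale)
    return float(np.log10(cutoff) - log10_scale * norm.ppf(1.0 - tail_probability))


def _cv_to_log10_sigma(cv: float) -> float:
    # lognormal with fractional CV c has sigma_ln = sqrt(ln(1+c^2))
    return float(np.sqrt(np.log1p(cv * cv)) / np.log(10.0))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort per the stratified log10-normal model; deterministic in seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants

    carrier = rng.random(n) < spec.carrier_prevalence
    amy_p = np.where(carrier, spec.amyloid_prev_carrier, spec.amyloid_prev_noncarrier)
    amyloid = rng.random(n) < amy_p

    # ApoE4p concentration mixture; optional component misassignment knob
    comp = carrier.copy()
    if spec.carrier_misclass_rate > 0:
        flip = rng.random(n) < spec.carrier_misclass_rate
        comp = comp ^ flip
    apoe_loc = np.where(comp, spec.apoe4p_carrier_loc, spec.apoe4p_noncarrier_loc)
    apoe_scale = np.where(comp, spec.apoe4p_carrier_scale, spec.apoe4p_noncarrier_scale)
    apoe4p = 10.0 ** (apoe_loc + apoe_scale * rng.standard_normal(n))

    # plasma markers: stratified log10-normal, optionally correlated on log scale
    if spec.log_correlation is not None:
        corr = np.asarray(spec.log_correlation, dtype=float)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(4))
        z = rng.standard_normal((n, 4)) @ chol.T
    else:
        z = rng.standard_normal((n, 4))
    values = {}
    stratum_code = amyloid.astype(int) * 2 + carrier.astype(int)  # 0..3
    for j, m in enumerate(PLASMA_MARKERS):
        params = spec.markers[m]
        loc = np.empty(4)
        scale = np.empty(4)
        for (a, c) in _STRATA:
            loc[a * 2 + c] = params.loc[(a, c)]
            scale[a * 2 + c] = params.scale[(a, c)]
        values[m] = 10.0 ** (loc[stratum_code] + scale[stratum_code] * z[:, j])
    values["apoe4p_conc"] = apoe4p

    # pre-analytical bias and assay noise on all plasma assays
    sigma = _cv_to_log10_sigma(spec.assay_cv)
    for m in ALL_MARKERS:
        b = spec.preanalytical_bias.get(m, 1.0)
        if b != 1.0:
            values[m] = values[m] * b
        if sigma > 0:
            values[m] = values[m] * 10.0 ** rng.normal(0.0, sigma, n)

    # reference tests: confirmed participants get a PET read and CSF analytes
    confirmed = rng.random(n) < spec.confirm_fraction
    pet = np.where(confirmed, np.where(amyloid, "positive", "negative"), "missing")
    csf_vals = {}
    for name, params in (("csf_ptau181", spec.csf_ptau181), ("csf_abeta42", spec.csf_abeta42)):
        loc = np.where(amyloid, params.loc_positive, params.loc_negative)
        scale = np.where(amyloid, params.scale_positive, params.scale_negative)
        v = 10.0 ** (loc + scale * rng.standard_normal(n))
        csf_vals[name] = np.where(confirmed, v, np.nan)

    width = max(6, len(str(n)))
    df = pd.DataFrame(
        {
            "id": [f"P{i:0{width}d}" for i in range(1, n + 1)],
            "amyloid_true": amyloid.astype(int),
            "apoe4p_carrier_true": carrier.astype(int),
            "apoe4p_conc": values["apoe4p_conc"],
            "ptau181": values["ptau181"],
            "gfap": values["gfap"],
            "abeta42": values["abeta42"],
            "abeta40": values["abeta40"],
            "pet_result": pet,
            "csf_ptau181": csf_vals["csf_ptau181"],
            "csf_abeta42": csf_vals["csf_abeta42"],
        }
    )
    return Cohort(df=df, spec_used=spec, seed_used=spec.seed)


def apply_assay_perturbation(
    cohort: Cohort,
    bias_per_marker: Mapping[str, float] | None = None,
    cv: float = 0.0,
    seed: int = 0,
) -> Cohort:
    """Return a new cohort with plasma values multiplied by bias and lognormal noise.

    Ground-truth and reference columns are untouched.
    """
    if cv < 0:
        raise SpecValidationError("cv", f"must be >= 0, got {cv}")
    bias_per_marker = dict(bias_per_marker or {})
    for m, b in bias_per_marker.items():
        if m not in ALL_MARKERS:
            raise SpecValidationError("bias_per_marker", f"unknown marker {m!r}")
        _check_pos(f"bias_per_marker[{m!r}]", b)
    rng = np.random.default_rng(seed)
    df = cohort.df.copy()
    sigma = _cv_to_log10_sigma(cv)
    for m in ALL_MARKERS:
        col = df[m].to_numpy(dtype=float)
        col = col * bias_per_marker.get(m, 1.0)
        if sigma > 0:
            col = col * 10.0 ** rng.normal(0.0, sigma, len(df))
        df[m] = col
    return Cohort(df=df, spec_used=cohort.spec_used, seed_used=cohort.seed_used)


# ---------------------------------------------------------------------------
# calibrated factory specs
# ---------------------------------------------------------------------------

_DEFAULT_CUTOFF_APOE4P = 0.668  # µg/mL
_DEFAULT_CUTOFF_PTAU = 0.830    # pg/mL


def calibrated_spec(
    n_participants: int,
    carrier_prevalence: float,
    amyloid_prev_carrier: float,
    amyloid_prev_noncarrier: float,
    target_ppa: float,
    target_npa: float,
    seed: int = 0,
    ptau_scale: float = 0.20,
    apoe4p_cutoff: float = _DEFAULT_CUTOFF_APOE4P,
    ptau_cutoff: float = _DEFAULT_CUTOFF_PTAU,
    assay_cv: float = 0.0,
    confirm_fraction: float = 1.0,
    preanalytical_bias: Mapping[str, float] | None = None,
) -> CohortSpec:
    """Build a spec whose pTau181 strata are placed so the given cutoffs hit
    the requested algorithm-level operating point.

    The pTau step sensitivity/specificity among non-carriers come from
    :func:`derive_stratum_operating_points`; the amyloid-positive and
    amyloid-negative pTau locations then come from
    :func:`calibrate_marker_location` at the pTau cutoff.  Carriers share the
    same within-amyloid pTau distribution as non-carriers (the pTau step is
    never consulted for carriers, so this is immaterial to the operating point).
    """
    pi = (carrier_prevalence * amyloid_prev_carrier
          + (1 - carrier_prevalence) * amyloid_prev_noncarrier)
    if 0.0 < pi < 1.0:
        se_ptau, sp_ptau = derive_stratum_operating_points(
            carrier_prevalence,
            amyloid_prev_carrier,
            amyloid_prev_noncarrier,
            target_ppa,
            target_npa,
        )
        loc_pos = calibrate_marker_location(ptau_cutoff, se_ptau, ptau_scale)
        loc_neg = calibrate_marker_location(ptau_cutoff, 1.0 - sp_ptau, ptau_scale)
    else:
        # degenerate prevalence: no operating point to hit; separate the
        # amyloid strata symmetrically around the cutoff
        loc_pos = float(np.log10(ptau_cutoff)) + ptau_scale
        loc_neg = float(np.log10(ptau_cutoff)) - ptau_scale
    markers = {
        "ptau181": LogNormalByStratum.from_amyloid(loc_neg, loc_pos, ptau_scale),
        # Directionality mirrors the observed panel: GFAP up with amyloid,
        # Abeta42 down, Abeta40 essentially flat.  Magnitudes chosen so the
        # pTau181+ApoE4p combination dominates the alternatives.
        "gfap": LogNormalByStratum.from_amyloid(np.log10(95.0), np.log10(130.0), 0.18),
        "abeta42": LogNormalByStratum.from_amyloid(np.log10(44.0), np.log10(38.0), 0.12),
        "abeta40": LogNormalByStratum.from_amyloid(np.log10(295.0), np.log10(300.0), 0.12),
    }
    return CohortSpec(
        n_participants=n_participants,
        carrier_prevalence=carrier_prevalence,
        amyloid_prev_carrier=amyloid_prev_carrier,
        amyloid_prev_noncarrier=amyloid_prev_noncarrier,
        markers=markers,
        # mixture components sit ~5 scale units away from the 0.668 µg/mL
        # cutoff so threshold carriage and true carriage agree by construction
        apoe4p_noncarrier_loc=float(np.log10(0.35)),
        apoe4p_noncarrier_scale=0.06,
        apoe4p_carrier_loc=float(np.log10(1.20)),
        apoe4p_carrier_scale=0.05,
        csf_ptau181=LogNormalByAmyloid(
            loc_negative=float(np.log10(15.0)), loc_positive=float(np.log10(28.0)),
            scale_negative=0.08, scale_positive=0.08,
        ),
        csf_abeta42=LogNormalByAmyloid(
            loc_negative=float(np.log10(1000.0)), loc_positive=float(np.log10(350.0)),
            scale_negative=0.08, scale_positive=0.08,
        ),
        assay_cv=assay_cv,
        preanalytical_bias=dict(preanalytical_bias or {}),
        confirm_fraction=confirm_fraction,
        seed=seed,
    )


def a4_like_spec(n_participants: int, seed: int = 0, **kwargs) -> CohortSpec:
    """Cohort calibrated to the historic-cohort operating point
    (carrier prevalence 34.9%, amyloid prevalence 28.9%/8.63% by carriage,
    rule PPA 95.5% / NPA 45.8% at the default cutoffs)."""
    return calibrated_spec(
        n_participants,
        carrier_prevalence=0.349,
        amyloid_prev_carrier=0.289,
        amyloid_prev_noncarrier=0.0863,
        target_ppa=0.955,
        target_npa=0.458,
        seed=seed,
        **kwargs,
    )


def group2_like_spec(n_participants: int, seed: int = 0, **kwargs) -> CohortSpec:
    """Cohort calibrated to the direct-entry arm operating point
    (carrier prevalence 29.1%, amyloid prevalence 21.3%/8.65% by carriage,
    rule PPA 94.6% / NPA 44.5% at the default cutoffs)."""
    return calibrated_spec(
        n_participants,
        carrier_prevalence=0.291,
        amyloid_prev_carrier=0.213,
        amyloid_prev_noncarrier=0.0865,
        target_ppa=0.946,
        target_npa=0.445,
        seed=seed,
        **kwargs,
    )
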