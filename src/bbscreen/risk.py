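"""Logistic risk models, risk-percentile predictiveness curves, and AUCs.

The deployed-rule risk model is ``amyloid ~ ApoE4p(binary) + log10(pTau181)``;
alternative marker combinations swap the continuous predictor.  Predictiveness
curves plot PPV and 1-NPV against the percentile of fitted risk — the
percentile equals the hypothetical screen-out rate.  Raw curves use empirical
ranks (ties in fitted risk stay on the same side of every cut); smoothing is
monotone (pool-adjacent-violators) regression on the percentile grid, a
dependency-light stand-in for constrained additive smoothing whose binding
constraint is the same monotonicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .reference import NEGATIVE, POSITIVE
from .rule import DEFAULT_CUTOFFS, RuleCutoffs

__all__ = [
    "RiskModel",
    "RiskProfile",
    "SeparationWarning",
    "fit_logistic",
    "predictiveness_curves",
    "optimal_curves",
    "pava",
    "auc",
    "compare_combinations",
    "PREDICTOR_SETS",
]

#: predictor sets for the three published marker combinations
PREDICTOR_SETS = {
    "ptau_apoe4p": ("apoe4p_binary", "log10_ptau181"),
    "gfap_apoe4p": ("apoe4p_binary", "log10_gfap"),
    "ab4240_apoe4p": ("apoe4p_binary", "log10_abeta_ratio"),
}

COMBO_LABELS = {
    "ptau_apoe4p": "pTau181 + ApoE4p",
    "gfap_apoe4p": "GFAP + ApoE4p",
    "ab4240_apoe4p": "Abeta42/Abeta40 + ApoE4p",
}


class SeparationWarning(UserWarning):
    """Emitted when the logistic fit detects (quasi-)perfect separation."""


@dataclass(frozen=True)
class RiskModel:
    predictors: tuple[str, ...]
    intercept: float
    coef: np.ndarray
    fitted: np.ndarray  # per-participant probabilities, order of the input frame
    converged: bool
    separation: bool
    n_iter: int
    log_likelihood: float


def design_matrix(
    df: pd.DataFrame,
    predictor_names: Sequence[str],
    cutoffs: RuleCutoffs = DEFAULT_CUTOFFS,
) -> np.ndarray:
    """Build the model matrix (without intercept) for the named predictors.

    ``apoe4p_binary`` dichotomises the ApoE4p concentration at the carrier
    cutoff; ``log10_<marker>`` log10-transforms a concentration column;
    ``log10_abeta_ratio`` is log10(Abeta42/Abeta40).
    """
    cols = []
    for name in predictor_names:
        if name == "apoe4p_binary":
            cols.append((df["apoe4p_conc"].to_numpy(dtype=float) > cutoffs.apoe4p_cutoff).astype(float))
        elif name == "log10_abeta_ratio":
            cols.append(np.log10(df["abeta42"].to_numpy(dtype=float) / df["abeta40"].to_numpy(dtype=float)))
        elif name.startswith("log10_"):
            marker = name[len("log10_"):]
            cols.append(np.log10(df[marker].to_numpy(dtype=float)))
        elif name in df.columns:
            cols.append(df[name].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown predictor {name!r}")
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise ValueError("predictors contain missing values")
    return X


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """Iteratively reweighted least squares for the logistic likelihood."""
    n, p = X.shape
    Xi = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    # intercept at the empirical log-odds speeds convergence
    ybar = min(max(y.mean(), 1e-8), 1 - 1e-8)
    beta[0] = np.log(ybar / (1 - ybar))
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = np.clip(Xi @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = Xi * w[:, None]
        try:
            beta = np.linalg.solve(Xi.T @ WX, Xi.T @ (w * z))
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(np.sqrt(w)[:, None] * Xi, np.sqrt(w) * z, rcond=None)[0]
        eta = np.clip(Xi @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = Xi @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    separation = bool(np.all((mu > 0.5) == (y == 1)) and np.max(np.abs(eta)) > 15)
    return beta, mu, converged, separation, n_iter, ll_old


def fit_logistic(
    df: pd.DataFrame,
    predictor_names: Sequence[str],
    outcome: str = "composite_amyloid",
    cutoffs: RuleCutoffs = DEFAULT_CUTOFFS,
) -> RiskModel:
    """Maximum-likelihood logistic fit of amyloid status on the predictors.

    The outcome column may hold positive/negative strings or 0/1 integers.
    Rows with unknown outcome must be filtered by the caller.
    """
    col = df[outcome]
    if col.dtype == object:
        bad = set(col.unique()) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"outcome contains non-binary entries: {sorted(bad)}")
        y = (col == POSITIVE).to_numpy(dtype=float)
    else:
        y = col.to_numpy(dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("numeric outcome must be 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome has a single class; logistic fit is undefined")
    X = design_matrix(df, predictor_names, cutoffs)
    beta, mu, converged, separation, n_iter, ll = _irls(X, y)
    if separation:
        warnings.warn(
            "perfect separation detected; coefficients are unbounded in the limit",
            SeparationWarning,
            stacklevel=2,
        )
    return RiskModel(
        predictors=tuple(predictor_names),
        intercept=float(beta[0]),
        coef=beta[1:].copy(),
        fitted=mu,
        converged=converged,
        separation=separation,
        n_iter=n_iter,
        log_likelihood=ll,
    )


# ---------------------------------------------------------------------------
# monotone smoothing
# ---------------------------------------------------------------------------

def pava(y: Sequence[float], weights: Sequence[float] | None = None, increasing: bool = True) -> np.ndarray:
    """Pool-adjacent-violators: weighted least-squares monotone fit."""
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != y.shape:
        raise ValueError("weights must match y in shape")
    if not increasing:
        return -pava(-y, w, increasing=True)
    # blocks as (value, weight, count) with merging from the left
    values: list[float] = []
    wts: list[float] = []
    counts: list[int] = []
    for yi, wi in zip(y, w):
        values.append(float(yi))
        wts.append(float(wi))
        counts.append(1)
        while len(values) > 1 and values[-2] > values[-1]:
            v = (values[-2] * wts[-2] + values[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wts[-2] += wts[-1]
            counts[-2] += counts[-1]
            values[-2] = v
            values.pop()
            wts.pop()
            counts.pop()
    return np.repeat(values, counts)


# ---------------------------------------------------------------------------
# predictiveness curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskProfile:
    """Per-percentile curves; q is the fraction screened out (bottom of risk)."""

    q: np.ndarray
    risk: np.ndarray                 # smallest retained fitted risk at each cut
    ppv_raw: np.ndarray              # NaN where undefined (q = 1)
    one_minus_npv_raw: np.ndarray    # NaN where undefined (q = 0)
    ppv_smooth: np.ndarray
    one_minus_npv_smooth: np.ndarray
    ppv_opt: np.ndarray
    one_minus_npv_opt: np.ndarray
    prevalence: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q": self.q,
                "risk": self.risk,
                "ppv_raw": self.ppv_raw,
                "one_minus_npv_raw": self.one_minus_npv_raw,
                "ppv_smooth": self.ppv_smooth,
                "one_minus_npv_smooth": self.one_minus_npv_smooth,
                "ppv_opt": self.ppv_opt,
                "one_minus_npv_opt": self.one_minus_npv_opt,
            }
        )


def optimal_curves(q: np.ndarray, prevalence: float) -> tuple[np.ndarray, np.ndarray]:
    """Best achievable PPV / 1-NPV at each screen-out fraction q.

    A perfect ranking screens out only negatives until they are exhausted
    (q = 1 - prevalence), after which every additional screened-out
    participant is a positive.
    """
    q = np.asarray(q, dtype=float)
    pi = float(prevalence)
    ppv = np.where(q <= 1.0 - pi, np.minimum(pi / np.maximum(1.0 - q, 1e-300), 1.0), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        onpv = np.where(q <= 1.0 - pi, 0.0, (q - (1.0 - pi)) / np.maximum(q, 1e-300))
    return ppv, onpv


def predictiveness_curves(fitted: Sequence[float], amyloid_truth: Sequence[object]) -> RiskProfile:
    """Rank by fitted risk and trace PPV / 1-NPV over achievable cuts.

    ``amyloid_truth`` may be 0/1 or positive/negative strings.  Cuts are the
    boundaries of tie groups of the fitted risk, so every reported q is an
    achievable empirical screen-out fraction.
    """
    fitted = np.asarray(fitted, dtype=float)
    truth = np.asarray(amyloid_truth)
    if truth.dtype == object or truth.dtype.kind in "US":
        y = (truth == POSITIVE).astype(int)
        bad = set(np.unique(truth)) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"truth contains non-binary entries: {sorted(bad)}")
    else:
        y = truth.astype(int)
    if len(fitted) != len(y):
        raise ValueError("fitted and truth must be aligned")
    n = len(y)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == n:
        raise ValueError("both truth classes are required for predictiveness curves")
    order = np.argsort(fitted, kind="stable")
    f_sorted = fitted[order]
    y_sorted = y[order]
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])  # positives among bottom k

    # achievable cuts: k = 0 and the right edge of every tie group
    boundaries = [0]
    k = 0
    while k < n:
        j = k + 1
        while j < n and f_sorted[j] == f_sorted[k]:
            j += 1
        boundaries.append(j)
        k = j
    ks = np.asarray(boundaries)

    q = ks / n
    with np.errstate(invalid="ignore", divide="ignore"):
        onpv_raw = np.where(ks > 0, cum_pos[ks] / np.maximum(ks, 1), np.nan)
        ppv_raw = np.where(ks < n, (n_pos - cum_pos[ks]) / np.maximum(n - ks, 1), np.nan)
    # risk at the cut: the smallest retained fitted value (last value at k = n)
    risk = np.where(ks < n, f_sorted[np.minimum(ks, n - 1)], f_sorted[-1])

    prevalence = n_pos / n

    # monotone smoothing on the defined portions of each raw curve
    ppv_smooth = np.full_like(ppv_raw, np.nan)
    mask = ~np.isnan(ppv_raw)
    ppv_smooth[mask] = pava(ppv_raw[mask], increasing=True)
    onpv_smooth = np.full_like(onpv_raw, np.nan)
    mask = ~np.isnan(onpv_raw)
    onpv_smooth[mask] = pava(onpv_raw[mask], increasing=True)

    ppv_opt, onpv_opt = optimal_curves(q, prevalence)
    return RiskProfile(
        q=q,
        risk=risk,
        ppv_raw=ppv_raw,
        one_minus_npv_raw=onpv_raw,
        ppv_smooth=ppv_smooth,
        one_minus_npv_smooth=onpv_smooth,
        ppv_opt=ppv_opt,
        one_minus_npv_opt=onpv_opt,
        prevalence=prevalence,
        n=n,
    )


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(scores: Sequence[float], amyloid_truth: Sequence[object]) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 1/2."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(amyloid_truth)
    if truth.dtype == object or truth.dtype.kind in "US":
        y = (truth == POSITIVE).astype(int)
    else:
        y = truth.astype(int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single truth class")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compare_combinations(
    df: pd.DataFrame,
    outcome: str = "composite_amyloid",
    cutoffs: RuleCutoffs = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Fit one logistic model per marker combination and tabulate AUCs.

    Returns a frame with columns combo, label, auc, n, sorted by AUC
    descending.
    """
    rows = []
    for combo, predictors in PREDICTOR_SETS.items():
        model = fit_logistic(df, predictors, outcome=outcome, cutoffs=cutoffs)
        rows.append(
            {
                "combo": combo,
                "label": COMBO_LABELS[combo],
                "auc": auc(model.fitted, df[outcome]),
                "n": len(df),
            }
        )
    return pd.DataFrame(rows).sort_values("auc", ascending=False, ignore_index=True)
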