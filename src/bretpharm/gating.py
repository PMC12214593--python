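"""4PL concentration-response fitting and responder gating.

Every (receptor, GRK condition, arrestin, sensor) concentration series
is fitted with the four-parameter logistic model by multi-start
nonlinear least squares.  A condition counts as *responding* only when

* a fit could be defined (optimizer converged with a numerically
  identifiable Jacobian),
* the absolute Hill slope exceeds 0.1 (strict), and
* log10(EC50/uM) falls inside the closed interval [-3, 0.3],

and it is not on the manual override list.  Non-responding conditions
are assigned a gated value of exactly zero; responding ones carry the
observed response at the highest tested ligand concentration.  The
EC50 window reflects the tested concentration range: fits whose
inflection lies outside it cannot be sigmoidal over the applied
ligand concentrations.

No parameter bounds are imposed during optimization; plausibility is
enforced by the gates so that flat or noise-chasing fits are rejected
rather than silently pushed onto a bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .bret import KEY_COLUMNS
from .fourpl import fourpl

__all__ = [
    "FourPLFit",
    "GateRules",
    "GateDecision",
    "fit_4pl",
    "gate_response",
    "apply_gates",
]

# A fit whose Jacobian condition number exceeds this is treated as not
# identifiable ("no fit could be defined"): for flat data the EC50/Hill
# columns vanish, and for step-like noise fits all points sit on the
# sigmoid plateaus where those derivatives are numerically zero.
_MAX_CONDITION = 1e8


@dataclass(frozen=True)
class FourPLFit:
    """Best-of-starts 4PL least-squares fit.

    When ``converged`` is False the parameter fields hold the best
    attempt but must not be interpreted.
    """

    bottom: float
    top: float
    log_ec50: float
    hill: float
    converged: bool
    rss: float


@dataclass(frozen=True)
class GateRules:
    """Responder gate thresholds and manual overrides.

    ``hill_min_abs`` is a strict lower bound on |Hill slope|; the EC50
    window ``[log_ec50_low, log_ec50_high]`` is closed at both ends.
    ``manual_overrides`` lists condition keys forced to non-responding
    regardless of the fit (concentration-independent signal drift that
    the automated gates cannot see).
    """

    hill_min_abs: float = 0.1
    log_ec50_low: float = -3.0
    log_ec50_high: float = 0.3
    manual_overrides: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.hill_min_abs <= 0:
            raise ValueError("hill_min_abs must be positive")
        if self.log_ec50_low >= self.log_ec50_high:
            raise ValueError("log_ec50_low must be below log_ec50_high")


@dataclass(frozen=True)
class GateDecision:
    status: str  # "responding" | "non_responding"
    reasons: frozenset
    gated_value: float


def _starts(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Multi-start policy: EC50 at min/median/max tested log
    concentration crossed with an ascending and descending Hill slope;
    asymptotes initialised from the response extremes."""
    b0, t0 = float(np.min(y)), float(np.max(y))
    if b0 == t0:
        t0 = b0 + 1.0  # give the optimizer a nonzero span to shrink
    anchors = (float(np.min(x)), float(np.median(x)), float(np.max(x)))
    return [
        np.array([b0, t0, le, h]) for le in anchors for h in (1.0, -1.0)
    ]


def fit_4pl(x, y) -> FourPLFit:
    """Fit the 4PL model by multi-start unbounded least squares.

    ``x`` is log10 concentration (uM), ``y`` the anchored response.  At
    least four distinct concentrations and finite values are required.
    The start with the lowest residual sum of squares wins;
    ``converged`` is False when no start converges or the winning fit's
    Jacobian is rank-deficient (unidentifiable parameters, e.g. flat
    data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in concentration-response data")
    if np.unique(x).size < 4:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, False, np.nan)

    def residual(p):
        return fourpl(x, *p) - y

    def jacobian(p):
        bottom, top, log_ec50, hill = p
        z = np.clip((log_ec50 - x) * hill, -50.0, 50.0)
        s = 1.0 / (1.0 + 10.0 ** z)
        slope = np.log(10.0) * (top - bottom) * s * (1.0 - s)
        return np.column_stack(
            [1.0 - s, s, -slope * hill, -slope * (log_ec50 - x)]
        )

    best = None
    for p0 in _starts(x, y):
        try:
            res = least_squares(
                residual,
                p0,
                jac=jacobian,
                method="trf",
                ftol=1e-10,
                xtol=1e-10,
                gtol=1e-10,
                max_nfev=400,
            )
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, False, np.nan)
    rss, p = best
    sv = np.linalg.svd(jacobian(p), compute_uv=False)
    identifiable = bool(sv[-1] > sv[0] * (1.0 / _MAX_CONDITION))
    bottom, top, log_ec50, hill = (float(v) for v in p)
    # The model is invariant under (bottom, top, hill) -> (top, bottom,
    # -hill); report the canonical form with top >= bottom so the Hill
    # sign encodes the curve direction, as dose-response software does.
    if top < bottom:
        bottom, top, hill = top, bottom, -hill
    return FourPLFit(bottom, top, log_ec50, hill, identifiable, rss)


def gate_response(
    fit: FourPLFit,
    max_conc_response: float,
    rules: GateRules = GateRules(),
    key=None,
) -> GateDecision:
    """Apply the responder gate to one fitted condition.

    ``max_conc_response`` is the observed (anchored) response at the
    highest tested ligand concentration; it becomes the gated value of
    responding conditions.  Non-responders are assigned exactly zero.
    """
    reasons: set[str] = set()
    if key is not None and key in rules.manual_overrides:
        reasons.add("manual")
    if not fit.converged:
        reasons.add("no_fit")
    else:
        if not abs(fit.hill) > rules.hill_min_abs:
            reasons.add("hill_gate")
        if not rules.log_ec50_low <= fit.log_ec50 <= rules.log_ec50_high:
            reasons.add("ec50_gate")
    if reasons:
        return GateDecision("non_responding", frozenset(reasons), 0.0)
    return GateDecision("responding", frozenset(), float(max_conc_response))


def apply_gates(
    concresp: pd.DataFrame, rules: GateRules = GateRules()
) -> pd.DataFrame:
    """Fit and gate every condition of a concentration-response table.

    Returns one row per condition key with the fitted parameters, the
    gate status, the reason codes (semicolon-joined, empty for
    responders) and the gated value.
    """
    rows = []
    seen = set()
    for key, group in concresp.groupby(KEY_COLUMNS, sort=True):
        if key in seen:
            raise ValueError(f"duplicate condition key {key}")
        seen.add(key)
        group = group.sort_values("log10_conc_uM")
        if group["log10_conc_uM"].duplicated().any():
            raise ValueError(f"duplicate concentrations for {key}")
        fit = fit_4pl(group["log10_conc_uM"], group["response"])
        decision = gate_response(
            fit, group["response"].iloc[-1], rules=rules, key=key
        )
        rows.append(
            dict(
                zip(KEY_COLUMNS, key),
                bottom=fit.bottom,
                top=fit.top,
                log_ec50=fit.log_ec50,
                hill=fit.hill,
                converged=fit.converged,
                rss=fit.rss,
                status=decision.status,
                reasons=";".join(sorted(decision.reasons)),
                gated_value=decision.gated_value,
            )
        )
    return pd.DataFrame(rows)
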