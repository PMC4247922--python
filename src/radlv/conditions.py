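"""Checkers for the algebraic coexistence/stability hypotheses of the model.

Every sufficient condition the analysis of the switched competition model
rests on is implemented as an explicit checker that returns a
:class:`ConditionReport` carrying the boolean verdict together with all
intermediate quantities (slacks, the mu coefficients of the dosage-window
arithmetic, the decay constant eta, window endpoints), so borderline cases
are always visible rather than silently rounded.

All inequalities are strict, matching the analysis; a configurable margin
can demand extra slack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import ModelParams, TreatmentSchedule

__all__ = [
    "AuxiliaryLV",
    "ConditionReport",
    "check_baseline_cancer_wins",
    "lv_equilibrium",
    "check_coexistence",
    "dosage_window",
    "coexistence_window_exact",
    "check_positive_orbit_stability",
    "check_eradication_stability",
    "check_cancer_win_stability",
    "check_saddle_case",
]


@dataclass(frozen=True)
class AuxiliaryLV:
    """Autonomous two-species competitive Lotka-Volterra normal form.

    du/dt = u*(b1 - a11*u - a12*v), dv/dt = v*(b2 - a21*u - a22*v),
    all coefficients strictly positive.  Used as the comparison system whose
    constant-treatment dynamics bound the switched system from below.
    """

    b1: float
    b2: float
    a11: float
    a12: float
    a21: float
    a22: float

    def __post_init__(self) -> None:
        for name in ("b1", "b2", "a11", "a12", "a21", "a22"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ConditionReport:
    """Named verdict with every intermediate quantity that produced it."""

    name: str
    verdict: bool
    intermediates: dict[str, float] = field(default_factory=dict)
    window: tuple[float, float] | None = None
    notes: str = ""
    aux: AuxiliaryLV | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "name": self.name,
            "verdict": self.verdict,
            "intermediates": self.intermediates,
            "window": list(self.window) if self.window else None,
            "notes": self.notes,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def table(self) -> str:
        """Human-readable rendering: one line per intermediate quantity."""
        lines = [f"{self.name}: {'PASS' if self.verdict else 'FAIL'}"]
        for key, val in self.intermediates.items():
            lines.append(f"  {key:32s} = {val: .6g}")
        if self.window is not None:
            lines.append(f"  admissible gamma window         = ({self.window[0]:.6g}, {self.window[1]:.6g})")
        if self.notes:
            lines.append(f"  note: {self.notes}")
        return "\n".join(lines)


def check_baseline_cancer_wins(
    p: ModelParams, margin: float = 0.0
) -> ConditionReport:
    """Untreated-baseline regime: cancer outcompetes healthy tissue.

    Requires K1 < alpha2/beta2 and K2 > alpha1/beta1, under which the
    untreated competition model has the globally stable equilibrium
    (0, K2) for positive initial values.
    """
    slack1 = p.alpha2 / p.beta2 - p.K1
    slack2 = p.K2 - p.alpha1 / p.beta1
    return ConditionReport(
        name="baseline_cancer_wins",
        verdict=slack1 > margin and slack2 > margin,
        intermediates={
            "alpha2/beta2 - K1": slack1,
            "K2 - alpha1/beta1": slack2,
        },
    )


def lv_equilibrium(aux: AuxiliaryLV) -> tuple[float, float, str]:
    """Interior equilibrium of the competitive system and its character.

    Solves a11*u + a12*v = b1, a21*u + a22*v = b2.  The equilibrium is
    globally asymptotically stable when a11/a21 > b1/b2 > a12/a22 and a
    saddle when the chain is reversed; otherwise 'neither'.
    """
    det = aux.a11 * aux.a22 - aux.a12 * aux.a21
    scale = max(abs(aux.a11 * aux.a22), abs(aux.a12 * aux.a21), 1e-30)
    if abs(det) / scale < 1e-14:
        raise ValueError("interaction matrix is singular")
    ustar = (aux.b1 * aux.a22 - aux.a12 * aux.b2) / det
    vstar = (aux.a11 * aux.b2 - aux.b1 * aux.a21) / det
    ratio_lo = aux.a12 / aux.a22
    ratio_mid = aux.b1 / aux.b2
    ratio_hi = aux.a11 / aux.a21
    if ratio_hi > ratio_mid > ratio_lo:
        classification = "globally_stable"
    elif ratio_lo > ratio_mid > ratio_hi:
        classification = "saddle"
    else:
        classification = "neither"
    return ustar, vstar, classification


def _coexistence_pieces(p: ModelParams, gamma: float) -> dict[str, float]:
    return {
        "alpha2 - gamma": p.alpha2 - gamma,
        "upper_ratio alpha1/(K1 beta2)": p.alpha1 / (p.K1 * p.beta2),
        "middle_ratio (alpha1-eps*gamma)/(alpha2-gamma)": (
            (p.alpha1 - p.epsilon * gamma) / (p.alpha2 - gamma)
            if p.alpha2 != gamma
            else np.inf
        ),
        "lower_ratio K2 beta1/alpha2": p.K2 * p.beta1 / p.alpha2,
    }


def check_coexistence(
    p: ModelParams, schedule: TreatmentSchedule, margin: float = 0.0
) -> ConditionReport:
    """Permanence of both populations under the given dose rate.

    Requires alpha2 - gamma > 0 together with the strict ratio chain
    alpha1/(K1*beta2) > (alpha1 - eps*gamma)/(alpha2 - gamma) > K2*beta1/alpha2,
    under which the comparison system (constant-treatment lower bound) has a
    globally stable interior equilibrium, so both cell types stay bounded
    away from zero.  The induced comparison system is attached as ``aux``.
    """
    g = schedule.gamma
    if p.alpha2 - g <= margin:
        return ConditionReport(
            name="coexistence",
            verdict=False,
            intermediates={"alpha2 - gamma": p.alpha2 - g},
            notes="alpha2 - gamma <= 0: cancer-cell net on-phase rate not positive",
        )
    pieces = _coexistence_pieces(p, g)
    hi = pieces["upper_ratio alpha1/(K1 beta2)"]
    mid = pieces["middle_ratio (alpha1-eps*gamma)/(alpha2-gamma)"]
    lo = pieces["lower_ratio K2 beta1/alpha2"]
    verdict = (hi - mid > margin) and (mid - lo > margin)
    aux = None
    if p.alpha1 - p.epsilon * g > 0:
        aux = AuxiliaryLV(
            b1=p.alpha1 - p.epsilon * g,
            b2=p.alpha2 - g,
            a11=p.alpha1 / p.K1,
            a12=p.beta1,
            a21=p.beta2,
            a22=p.alpha2 / p.K2,
        )
    return ConditionReport(
        name="coexistence",
        verdict=verdict,
        intermediates=pieces,
        aux=aux,
    )


def dosage_window(p: ModelParams) -> ConditionReport:
    """Necessary dose-rate range for coexistence, by the mu-coefficient cases.

    With mu1 = (alpha1 - K2*beta1) + eps*(alpha2 - K1*beta2) and
    mu2 = alpha2*(alpha1 - K2*beta1) + alpha1*(alpha2 - K1*beta2), the
    admissible gamma interval is dispatched on the signs of mu1 and mu2:

    * mu1 > 0, mu2 > 0: (0, min(mu2/mu1, alpha1/eps, alpha2));
      mu1 > 0, mu2 <= 0: empty.
    * mu1 = 0: (0, min(alpha1/eps, alpha2)) if mu2 > 0, else empty.
    * mu1 < 0, mu2 >= 0: (0, min(alpha1/eps, alpha2));
      mu1 < 0, mu2 < 0: (mu2/mu1, min(alpha1/eps, alpha2)) when nonempty.

    The bound is necessary (obtained by summing the two coexistence
    inequalities) but not sufficient pointwise; use
    :func:`coexistence_window_exact` for the sharp interval.
    """
    d1 = p.alpha1 - p.K2 * p.beta1
    d2 = p.alpha2 - p.K1 * p.beta2
    mu1 = d1 + p.epsilon * d2
    mu2 = p.alpha2 * d1 + p.alpha1 * d2
    cap = min(p.alpha1 / p.epsilon, p.alpha2)
    inter = {
        "mu1": mu1,
        "mu2": mu2,
        "min(alpha1/eps, alpha2)": cap,
    }
    window: tuple[float, float] | None = None
    notes = ""
    if mu1 > 0:
        case = "a"
        if mu2 > 0:
            window = (0.0, min(mu2 / mu1, cap))
            inter["mu2/mu1"] = mu2 / mu1
        else:
            notes = "gamma is inexistent (mu1 > 0, mu2 <= 0)"
    elif mu1 == 0:
        case = "b"
        if mu2 > 0:
            window = (0.0, cap)
        else:
            notes = "gamma is inexistent (mu1 = 0, mu2 <= 0)"
    else:
        case = "c"
        if mu2 >= 0:
            window = (0.0, cap)
        else:
            lower = mu2 / mu1
            inter["mu2/mu1"] = lower
            if lower < cap:
                window = (lower, cap)
            else:
                notes = "gamma is inexistent (mu2/mu1 >= min(alpha1/eps, alpha2))"
    inter["case"] = {"a": 0.0, "b": 1.0, "c": 2.0}[case]
    return ConditionReport(
        name=f"dosage_window(case {case})",
        verdict=window is not None,
        intermediates=inter,
        window=window,
        notes=notes,
    )


def coexistence_window_exact(p: ModelParams) -> tuple[float, float] | None:
    """Sharp gamma interval on which the coexistence ratio chain holds.

    The middle ratio f(g) = (alpha1 - eps*g)/(alpha2 - g) is a Moebius
    function of g, monotone on g < alpha2 with slope sign sgn(alpha1 -
    eps*alpha2), so each of the two strict inequalities cuts a half-line in
    gamma; the window is the intersection with 0 < g < min(alpha1/eps,
    alpha2).  Returns None when empty.
    """
    c_lo = p.K2 * p.beta1 / p.alpha2
    c_hi = p.alpha1 / (p.K1 * p.beta2)
    lo, hi = 0.0, min(p.alpha1 / p.epsilon, p.alpha2)

    # (alpha1 - eps g) - c (alpha2 - g) > 0  <=>  (c - eps) g > c alpha2 - alpha1
    def half_line(c: float, want_positive: bool) -> tuple[float, float]:
        slope = c - p.epsilon
        intercept = p.alpha1 - c * p.alpha2
        # want: intercept + slope * g  > 0 (if want_positive) or < 0
        if not want_positive:
            slope, intercept = -slope, -intercept
        if abs(slope) < 1e-300:
            return (0.0, np.inf) if intercept > 0 else (np.inf, -np.inf)
        g_star = -intercept / slope
        return (g_star, np.inf) if slope > 0 else (-np.inf, g_star)

    for c, want in ((c_lo, True), (c_hi, False)):
        a, b = half_line(c, want)
        lo, hi = max(lo, a), min(hi, b)
    return (lo, hi) if lo < hi else None


def check_positive_orbit_stability(
    p: ModelParams, margin: float = 0.0
) -> ConditionReport:
    """Global stability condition for the interior periodic solution.

    Requires alpha1 > K1*beta2 and alpha2 > K2*beta1 (self-limitation
    dominates cross-competition in both species).
    """
    slack1 = p.alpha1 - p.K1 * p.beta2
    slack2 = p.alpha2 - p.K2 * p.beta1
    return ConditionReport(
        name="positive_orbit_stability",
        verdict=slack1 > margin and slack2 > margin,
        intermediates={
            "alpha1 - K1*beta2": slack1,
            "alpha2 - K2*beta1": slack2,
        },
    )


def check_eradication_stability(
    p: ModelParams,
    schedule: TreatmentSchedule,
    sigma1: float,
    margin: float = 0.0,
) -> ConditionReport:
    """Global stability condition for the cancer-eradication orbit.

    Requires beta1 < beta2, alpha1 - eps*gamma - (alpha1/K1)*sigma1 < 0,
    alpha2 - gamma < 0, and gamma*(omega - L) < eta*omega, where
    -eta = max(alpha1 - eps*gamma - alpha1*sigma1/K1, alpha2 - gamma) and
    sigma1 is the per-period minimum of the eradication orbit's
    healthy-cell component (supplied by the caller so figure-derived and
    recomputed values can be compared side by side).
    """
    if sigma1 <= 0:
        raise ValueError("sigma1 must be strictly positive")
    g, w, L = schedule.gamma, schedule.omega, schedule.L
    q1 = p.alpha1 - p.epsilon * g - p.alpha1 * sigma1 / p.K1
    q2 = p.alpha2 - g
    eta = -max(q1, q2)
    slack_beta = p.beta2 - p.beta1
    slack_decay = eta * w - g * (w - L)
    verdict = (
        slack_beta > margin
        and q1 < -margin
        and q2 < -margin
        and slack_decay > margin
    )
    return ConditionReport(
        name="eradication_stability",
        verdict=verdict,
        intermediates={
            "beta2 - beta1": slack_beta,
            "alpha1 - eps*gamma - alpha1*sigma1/K1": q1,
            "alpha2 - gamma": q2,
            "eta": eta,
            "gamma*(omega-L)": g * (w - L),
            "eta*omega": eta * w,
            "eta*omega - gamma*(omega-L)": slack_decay,
        },
    )


def check_cancer_win_stability(
    p: ModelParams,
    schedule: TreatmentSchedule,
    sigma2: float,
    margin: float = 0.0,
) -> ConditionReport:
    """Global stability condition for the cancer-win orbit.

    Requires alpha1 > K1*beta2, alpha2 > K2*beta1 and
    alpha1 + (beta2 - beta1)*sigma2 < 0, where sigma2 is the per-period
    minimum of the cancer-win orbit's cancer-cell component.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be strictly positive")
    slack1 = p.alpha1 - p.K1 * p.beta2
    slack2 = p.alpha2 - p.K2 * p.beta1
    q3 = p.alpha1 + (p.beta2 - p.beta1) * sigma2
    return ConditionReport(
        name="cancer_win_stability",
        verdict=slack1 > margin and slack2 > margin and q3 < -margin,
        intermediates={
            "alpha1 - K1*beta2": slack1,
            "alpha2 - K2*beta1": slack2,
            "alpha1 + (beta2-beta1)*sigma2": q3,
        },
    )


def check_saddle_case(
    p: ModelParams, schedule: TreatmentSchedule, margin: float = 0.0
) -> ConditionReport:
    """Reversed ratio chain: the comparison equilibrium is a saddle.

    alpha2 - gamma > 0 with alpha1/(K1*beta2) <
    (alpha1 - eps*gamma)/(alpha2 - gamma) < K2*beta1/alpha2.  When this
    holds, no dynamical conclusion is available for the switched system —
    the regime is flagged as an open problem, not analysed.
    """
    g = schedule.gamma
    if p.alpha2 - g <= margin:
        return ConditionReport(
            name="saddle_case",
            verdict=False,
            intermediates={"alpha2 - gamma": p.alpha2 - g},
        )
    pieces = _coexistence_pieces(p, g)
    hi = pieces["upper_ratio alpha1/(K1 beta2)"]
    mid = pieces["middle_ratio (alpha1-eps*gamma)/(alpha2-gamma)"]
    lo = pieces["lower_ratio K2 beta1/alpha2"]
    verdict = (mid - hi > margin) and (lo - mid > margin)
    return ConditionReport(
        name="saddle_case",
        verdict=verdict,
        intermediates=pieces,
        notes="open problem — no dynamical conclusion" if verdict else "",
    )
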