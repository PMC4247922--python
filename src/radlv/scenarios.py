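"""Named scenario fixtures, a random-parameter sampler, sweeps and reports.

Three families of scenarios ship with the package, matching the numerical
regimes the model exhibits:

* ``set1-*`` — coexistence: a moderate dose inside the admissible window
  yields a globally stable interior 50-hour periodic solution.
* ``set2-*`` — cancer eradication: a strong, long dose drives the cancer
  cells extinct, leaving a 10-hour periodic healthy-cell orbit.
* ``set3-*`` — cancer win: strong cross-competition plus a short dose lets
  the cancer cells take over on a 10-hour periodic orbit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import closed_form, conditions
from .model import ModelParams, State, TreatmentSchedule
from .simulate import PeriodicOrbit, StabilityReport, assess_stability, find_periodic_orbit

__all__ = [
    "Scenario",
    "ScenarioReport",
    "SET1_PARAMS",
    "SET2_PARAMS",
    "SET3_PARAMS",
    "scenario_names",
    "load_scenario",
    "run_scenario",
    "sweep",
    "sample_params",
]

SET1_PARAMS = ModelParams(
    alpha1=0.1, alpha2=0.45, K1=0.65, K2=1.0, beta1=0.11, beta2=0.15, epsilon=0.05
)
SET2_PARAMS = ModelParams(
    alpha1=0.2, alpha2=0.5, K1=0.65, K2=1.0, beta1=0.5, beta2=0.55, epsilon=0.3
)
SET3_PARAMS = ModelParams(
    alpha1=0.2, alpha2=0.5, K1=0.65, K2=1.0, beta1=0.48, beta2=0.05, epsilon=0.3
)

#: common starting concentrations for all scenarios
INITIAL_STATE = State(0.5, 0.8)


@dataclass(frozen=True)
class Scenario:
    name: str
    params: ModelParams
    schedule: TreatmentSchedule
    initial_state: State
    horizon: float  # periods used for orbit finding
    expectation: str  # coexist | eradicate | cancer_win


def _registry() -> dict[str, Scenario]:
    reg: dict[str, Scenario] = {}
    for L in (15, 30, 45):
        name = f"set1-L{L}"
        reg[name] = Scenario(
            name,
            SET1_PARAMS,
            TreatmentSchedule(gamma=0.35, omega=50.0, L=float(L)),
            INITIAL_STATE,
            horizon=20,
            expectation="coexist",
        )
    for gamma, L in ((0.65, 8), (0.65, 9), (0.75, 8), (0.8, 8)):
        name = f"set2-L{L}-g{gamma}"
        reg[name] = Scenario(
            name,
            SET2_PARAMS,
            TreatmentSchedule(gamma=gamma, omega=10.0, L=float(L)),
            INITIAL_STATE,
            horizon=20,
            expectation="eradicate",
        )
    for gamma, L in ((0.4, 2), (0.6, 1)):
        name = f"set3-g{gamma}-L{L}"
        reg[name] = Scenario(
            name,
            SET3_PARAMS,
            TreatmentSchedule(gamma=gamma, omega=10.0, L=float(L)),
            INITIAL_STATE,
            horizon=20,
            expectation="cancer_win",
        )
    return reg


_REGISTRY = _registry()

_EXPECTED_CLASS = {
    "coexist": "interior",
    "eradicate": "eradication",
    "cancer_win": "cancer_win",
}


def scenario_names() -> list[str]:
    return sorted(_REGISTRY)


def load_scenario(name: str) -> Scenario:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        ) from None


@dataclass
class ScenarioReport:
    scenario: Scenario
    orbit: PeriodicOrbit
    reports: dict[str, conditions.ConditionReport]
    stability: StabilityReport | None
    matches_expectation: bool
    sigma1_closed_form: float | None = None
    sigma1_swapped: float | None = None
    sigma2_closed_form: float | None = None
    notes: list[str] = field(default_factory=list)


def run_scenario(
    s: Scenario,
    assess: bool = True,
    n_perturbations: int = 20,
    seed: int = 0,
    swap_phases: bool = False,
) -> ScenarioReport:
    """Run all applicable checkers, locate the orbit, probe its stability.

    For eradication scenarios the healthy-cell orbit minimum sigma1 is
    reported both under the treatment-first phase convention and under the
    swapped-duration alternative, because the stability verdict differs
    between them; neither is silently preferred.
    """
    p, sched = s.params, s.schedule
    reports: dict[str, conditions.ConditionReport] = {
        "baseline_cancer_wins": conditions.check_baseline_cancer_wins(p),
        "dosage_window": conditions.dosage_window(p),
        "coexistence": conditions.check_coexistence(p, sched),
        "positive_orbit_stability": conditions.check_positive_orbit_stability(p),
    }
    thresholds = closed_form.existence_thresholds(p, sched)
    notes: list[str] = []

    orbit = find_periodic_orbit(p, sched, s.initial_state)
    report = ScenarioReport(
        scenario=s,
        orbit=orbit,
        reports=reports,
        stability=None,
        matches_expectation=orbit.classification == _EXPECTED_CLASS[s.expectation],
        notes=notes,
    )

    if thresholds["eradication_exists"]:
        sl = closed_form.SwitchedLogistic.healthy(p, sched, swap_phases=False)
        sigma1, _ = closed_form.orbit_minimum(sl)
        sl_swap = closed_form.SwitchedLogistic.healthy(p, sched, swap_phases=True)
        sigma1_swap, _ = closed_form.orbit_minimum(sl_swap)
        report.sigma1_closed_form = sigma1
        report.sigma1_swapped = sigma1_swap
        reports["eradication_stability"] = conditions.check_eradication_stability(
            p, sched, sigma1
        )
        reports["eradication_stability_swapped_sigma1"] = (
            conditions.check_eradication_stability(p, sched, sigma1_swap)
        )
        if (
            reports["eradication_stability"].verdict
            != reports["eradication_stability_swapped_sigma1"].verdict
        ):
            notes.append(
                "eradication-stability verdict differs between the "
                f"treatment-first sigma1={sigma1:.6f} and the swapped-duration "
                f"sigma1={sigma1_swap:.6f}; both are reported"
            )
    if thresholds["cancer_win_exists"]:
        sl2 = closed_form.SwitchedLogistic.cancer(p, sched, swap_phases=swap_phases)
        if sl2.exists():
            sigma2, _ = closed_form.orbit_minimum(sl2)
            report.sigma2_closed_form = sigma2
            reports["cancer_win_stability"] = conditions.check_cancer_win_stability(
                p, sched, sigma2
            )

    if not report.matches_expectation:
        notes.append(
            f"orbit classification {orbit.classification!r} does not match "
            f"expectation {s.expectation!r}"
        )
    if assess:
        report.stability = assess_stability(
            p, sched, orbit, n_perturbations=n_perturbations, seed=seed
        )
    return report


def sweep(
    p: ModelParams,
    base_schedule: TreatmentSchedule,
    gamma_grid,
    L_grid,
    guess: State = INITIAL_STATE,
) -> pd.DataFrame:
    """Grid of (gamma, L): condition verdicts, orbit class and sigma values.

    Deterministic; one row per grid point, tidy columns ready for CSV.
    """
    rows = []
    for gamma in gamma_grid:
        for L in L_grid:
            if gamma == 0.0:
                # untreated baseline: classification follows from the
                # cancer-wins condition, no switching dynamics to solve
                base = conditions.check_baseline_cancer_wins(p)
                rows.append(
                    {
                        "gamma": gamma,
                        "L": L,
                        "classification": "cancer_win" if base.verdict else "other",
                        "coexistence": False,
                        "eradication_exists": True,
                        "cancer_win_exists": True,
                        "sigma1": np.nan,
                        "sigma2": p.K2 if base.verdict else np.nan,
                        "orbit_mean_x1": 0.0,
                        "orbit_mean_x2": p.K2 if base.verdict else np.nan,
                    }
                )
                continue
            sched = TreatmentSchedule(gamma=float(gamma), omega=base_schedule.omega, L=float(L))
            coex = conditions.check_coexistence(p, sched)
            thr = closed_form.existence_thresholds(p, sched)
            orbit = find_periodic_orbit(p, sched, guess)
            sigma1 = sigma2 = np.nan
            if thr["eradication_exists"]:
                sl = closed_form.SwitchedLogistic.healthy(p, sched)
                if sl.exists():
                    sigma1 = closed_form.orbit_minimum(sl)[0]
            if thr["cancer_win_exists"]:
                sl2 = closed_form.SwitchedLogistic.cancer(p, sched)
                if sl2.exists():
                    sigma2 = closed_form.orbit_minimum(sl2)[0]
            rows.append(
                {
                    "gamma": gamma,
                    "L": L,
                    "classification": orbit.classification,
                    "coexistence": coex.verdict,
                    "eradication_exists": thr["eradication_exists"],
                    "cancer_win_exists": thr["cancer_win_exists"],
                    "sigma1": sigma1,
                    "sigma2": sigma2,
                    "orbit_mean_x1": 0.5 * (orbit.sigma1 + orbit.max1),
                    "orbit_mean_x2": 0.5 * (orbit.sigma2 + orbit.max2),
                }
            )
    return pd.DataFrame(rows)


def sample_params(
    seed: int,
    n: int,
    filter_baseline: bool = False,
) -> list[tuple[ModelParams, TreatmentSchedule]]:
    """Seeded sampler of valid random parameter sets for property tests.

    Rates are drawn in (0.01, 1), capacities in (0.1, 2), epsilon in
    (0, 0.5), omega in (5, 100) and L in (0, omega).  With
    ``filter_baseline`` only sets satisfying the untreated cancer-wins
    condition are returned (rejection sampling).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[ModelParams, TreatmentSchedule]] = []
    while len(out) < n:
        p = ModelParams(
            alpha1=rng.uniform(0.01, 1.0),
            alpha2=rng.uniform(0.01, 1.0),
            K1=rng.uniform(0.1, 2.0),
            K2=rng.uniform(0.1, 2.0),
            beta1=rng.uniform(0.01, 1.0),
            beta2=rng.uniform(0.01, 1.0),
            epsilon=rng.uniform(1e-3, 0.5),
        )
        omega = rng.uniform(5.0, 100.0)
        sched = TreatmentSchedule(
            gamma=rng.uniform(0.0, 1.0),
            omega=omega,
            L=rng.uniform(1e-3, 1.0) * omega * 0.999 + 1e-6,
        )
        if filter_baseline and not conditions.check_baseline_cancer_wins(p).verdict:
            continue
        out.append((p, sched))
    return out
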