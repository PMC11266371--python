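"""Health-economic accounting: discounted costs, QALYs, ICERs, pricing.

Trajectories are converted to discounted cost components (diagnosis, disease
stage, drug), life years and QALYs. Accrual is at cycle start: membership at
the beginning of a year earns that year's full cost and utility (a half-cycle
correction is available as a switch). Incremental comparisons place the
result on the cost-effectiveness plane and apply the willingness-to-pay rule,
with the source convention in the southwest quadrant that an ICER at or above
the threshold favours the comparator. A value-based price search finds the
annual drug price at which the intervention's ICER equals the threshold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .decision_tree import (
    Amyloid,
    DiagnosticOutcome,
    PathwayId,
    evaluate_pathway,
)
from .fixtures import FixtureBundle
from .markov import Trajectory, run_cohort
from .parameters import ParameterSet
from .states import BASE_OF, EXT_STATES, HealthState, TUNNEL_STATES

__all__ = [
    "EconomicResult",
    "CEResult",
    "Quadrant",
    "Decision",
    "discount_factor",
    "accrue",
    "evaluate_strategy",
    "compute_icer",
    "compare_strategies",
    "price_threshold",
    "PriceThresholdError",
]


def discount_factor(rate: float, t: int) -> float:
    """Present-value factor (1 + rate)^(-t); cycle 0 is undiscounted."""
    if rate < 0 or t < 0:
        raise ValueError("rate and t must be non-negative")
    return (1.0 + rate) ** (-t)


@dataclass(frozen=True)
class EconomicResult:
    """Discounted lifetime results for one diagnostic strategy."""

    total_cost: float
    diagnosis_cost: float
    disease_cost: float
    dmt_cost: float
    life_years: float
    qalys: float
    time_in_state: dict[HealthState, float]

    def __post_init__(self) -> None:
        parts = self.diagnosis_cost + self.disease_cost + self.dmt_cost
        if abs(self.total_cost - parts) > 1e-6:
            raise ValueError("cost components do not sum to the total")


def _state_cost(params: ParameterSet, name: str) -> float:
    c = params.costs
    base = BASE_OF[name]
    return {
        HealthState.SCD: c.state_cost_scd_mci,
        HealthState.MCI: c.state_cost_scd_mci,
        HealthState.MILD: c.state_cost_mild,
        HealthState.MODERATE: c.state_cost_moderate,
        HealthState.SEVERE: c.state_cost_severe,
        HealthState.MILD_LTC: c.state_cost_mild_ltc,
        HealthState.MODERATE_LTC: c.state_cost_moderate_ltc,
        HealthState.SEVERE_LTC: c.state_cost_severe_ltc,
        HealthState.DEAD: 0.0,
    }[base]


def _state_utility(params: ParameterSet, name: str, amypos: bool) -> float:
    u = params.utilities
    base = BASE_OF[name]
    if base is HealthState.SCD:
        return u.u_scd_amypos if amypos else u.u_scd_amyneg
    if base is HealthState.MCI:
        return u.u_mci_amypos if amypos else u.u_mci_amyneg
    return {
        HealthState.MILD: u.u_mild,
        HealthState.MODERATE: u.u_moderate,
        HealthState.SEVERE: u.u_severe,
        HealthState.MILD_LTC: u.u_mild,
        HealthState.MODERATE_LTC: u.u_moderate,
        HealthState.SEVERE_LTC: u.u_severe,
        HealthState.DEAD: 0.0,
    }[base]


def accrue(
    trajectory: Trajectory,
    outcome: DiagnosticOutcome,
    params: ParameterSet,
) -> EconomicResult:
    """Convert a trajectory into discounted costs, life years and QALYs.

    Disease cost sums state occupancy times the annual stage cost (SCD costed
    as MCI; institutionalised stages at long-term-care cost); drug cost is the
    annual price times on-treatment (tunnel) occupancy; utilities split
    pre-dementia states by amyloid status and dementia states by stage only.
    The one-off diagnosis cost from the decision tree enters at cycle 0.
    """
    econ = params.econ
    horizon = trajectory.horizon
    occ = trajectory.occupancy  # (G, T+1, S)

    alive = np.array([1.0 if BASE_OF[s] is not HealthState.DEAD else 0.0
                      for s in EXT_STATES])
    tunnel = np.array([1.0 if s in TUNNEL_STATES else 0.0 for s in EXT_STATES])
    cost_vec = np.array([_state_cost(params, s) for s in EXT_STATES])
    util = np.stack(
        [
            [_state_utility(params, s, g.amyloid is Amyloid.POSITIVE)
             for s in EXT_STATES]
            for g in trajectory.groups
        ]
    )  # (G, S)

    if econ.half_cycle_correction:
        weight = 0.5 * (occ[:, :horizon, :] + occ[:, 1 : horizon + 1, :])
    else:
        weight = occ[:, :horizon, :]  # start-of-cycle accrual

    t = np.arange(horizon)
    disc_c = (1.0 + econ.discount_rate_costs) ** (-t)
    disc_e = (1.0 + econ.discount_rate_effects) ** (-t)

    per_cycle_disease = np.einsum("gts,s->t", weight, cost_vec)
    per_cycle_dmt = np.einsum("gts,s->t", weight, tunnel) * params.treatment.annual_cost
    per_cycle_ly = np.einsum("gts,s->t", weight, alive)
    per_cycle_qaly = np.einsum("gts,gs->t", weight, util)

    disease_cost = float(per_cycle_disease @ disc_c)
    dmt_cost = float(per_cycle_dmt @ disc_c)
    diagnosis = outcome.diagnosis_cost_per_person
    life_years = float(per_cycle_ly @ disc_e)
    qalys = float(per_cycle_qaly @ disc_e)

    base_occ = trajectory.base_state_occupancy().sum(axis=0)  # (T+1, 9)
    time_in_state = {
        s: float(base_occ[:horizon, i].sum()) for i, s in enumerate(HealthState)
    }

    return EconomicResult(
        total_cost=diagnosis + disease_cost + dmt_cost,
        diagnosis_cost=diagnosis,
        disease_cost=disease_cost,
        dmt_cost=dmt_cost,
        life_years=life_years,
        qalys=qalys,
        time_in_state=time_in_state,
    )


def evaluate_strategy(
    pathway: PathwayId, params: ParameterSet, fixtures: FixtureBundle
) -> EconomicResult:
    """Full pipeline for one pathway: decision tree -> cohort -> accounting."""
    outcome = evaluate_pathway(pathway, params)
    trajectory = run_cohort(outcome, params, fixtures)
    return accrue(trajectory, outcome, params)


class Quadrant(str, enum.Enum):
    NE = "NE"  # more costly, more effective
    SE = "SE"  # less costly, more effective (dominant)
    SW = "SW"  # less costly, less effective
    NW = "NW"  # more costly, less effective (dominated)


class Decision(str, enum.Enum):
    COST_EFFECTIVE = "cost_effective"
    NOT_COST_EFFECTIVE = "not_cost_effective"
    DOMINANT = "dominant"
    DOMINATED = "dominated"


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of an intervention against a reference."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    quadrant: Quadrant
    decision_at_wtp: Decision
    wtp: float


def compute_icer(
    reference: EconomicResult, intervention: EconomicResult, wtp: float
) -> CEResult:
    """Incremental cost, QALYs and ICER with the plane-quadrant decision.

    The ICER uses unrounded increments. In the southwest quadrant (cheaper
    but less effective) an ICER at or above the threshold favours the
    reference strategy.
    """
    dc = intervention.total_cost - reference.total_cost
    dq = intervention.qalys - reference.qalys

    if dq >= 0:
        quadrant = Quadrant.NE if dc >= 0 else Quadrant.SE
    else:
        quadrant = Quadrant.SW if dc < 0 else Quadrant.NW

    if dq == 0.0:
        icer = None
        if dc < 0:
            decision = Decision.DOMINANT
        elif dc > 0:
            decision = Decision.DOMINATED
        else:
            decision = Decision.COST_EFFECTIVE
    else:
        icer = dc / dq
        if quadrant is Quadrant.SE:
            decision = Decision.DOMINANT
        elif quadrant is Quadrant.NW:
            decision = Decision.DOMINATED
        elif quadrant is Quadrant.NE:
            decision = (
                Decision.COST_EFFECTIVE if icer <= wtp else Decision.NOT_COST_EFFECTIVE
            )
        else:  # SW: savings per QALY forgone at/above WTP favour the reference
            decision = (
                Decision.NOT_COST_EFFECTIVE if icer >= wtp else Decision.COST_EFFECTIVE
            )
    return CEResult(
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        quadrant=quadrant,
        decision_at_wtp=decision,
        wtp=wtp,
    )


def compare_strategies(
    reference: PathwayId,
    intervention: PathwayId,
    params: ParameterSet,
    fixtures: FixtureBundle,
    wtp: float | None = None,
) -> tuple[EconomicResult, EconomicResult, CEResult]:
    """Run both arms and compute the incremental result."""
    wtp = params.econ.wtp if wtp is None else wtp
    ref = evaluate_strategy(reference, params, fixtures)
    itv = evaluate_strategy(intervention, params, fixtures)
    return ref, itv, compute_icer(ref, itv, wtp)


class PriceThresholdError(RuntimeError):
    """No annual price solves ICER = WTP (no QALY gain to price)."""


def price_threshold(
    params: ParameterSet,
    fixtures: FixtureBundle,
    wtp: float | None = None,
    reference: PathwayId = PathwayId.SOC,
    intervention: PathwayId = PathwayId.BBM_PHC,
    tol: float = 1.0,
) -> float:
    """Annual drug price at which the intervention's ICER equals the WTP.

    The price enters the incremental cost linearly (through discounted
    on-treatment person-years), so the ICER is affine in price and the root
    is found from two evaluations, then verified to ``tol`` euros.
    """
    wtp = params.econ.wtp if wtp is None else wtp

    def icer_at(price: float) -> float:
        p = params.replace("treatment.annual_cost", price)
        _, _, ce = compare_strategies(reference, intervention, p, fixtures, wtp)
        if ce.delta_qaly <= 0:
            raise PriceThresholdError(
                "intervention gains no QALYs; ICER cannot reach the threshold "
                "by pricing"
            )
        return ce.icer  # type: ignore[return-value]

    i0 = icer_at(0.0)
    i1 = icer_at(1_000.0)
    slope = (i1 - i0) / 1_000.0
    if slope <= 0:
        raise PriceThresholdError("ICER is not increasing in price")
    if wtp < i0:
        return 0.0  # already at/above threshold with a free drug
    price = (wtp - i0) / slope
    # affine solve is exact up to float error; verify anyway
    if abs(icer_at(price) - wtp) > tol:  # pragma: no cover - numeric guard
        from scipy.optimize import brentq

        price = float(
            brentq(lambda x: icer_at(x) - wtp, 0.0, max(2 * price, 1e5), xtol=tol / 10)
        )
    return price
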