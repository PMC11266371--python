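"""Annual Markov cohort engine for post-diagnosis disease progression.

Each diagnostic group from the decision tree starts in its true state (SCD,
MCI or mild dementia) at the cohort start age and is propagated through
annual transition matrices over the model horizon. Pre-dementia progression
(SCD -> MCI -> mild) is amyloid-specific; the six clinical-dementia states
share one registry-style transition block regardless of amyloid status, with
regression allowed between dementia states but not out of MCI or mild.

Mortality is applied first each cycle as a competing risk: SCD and MCI die
at the general-population rate q(age); dementia states at
``1 - exp(-q(age) * HR(stage))``. Surviving mass is then distributed over
the conditional progression probabilities, which keeps every row stochastic.

Treated groups (biomarker-confirmed AD) enter treatment tunnel copies of MCI
and mild dementia. Treatment lasts at most ``max_duration`` (two) annual
cycles or until progression to moderate dementia, whichever comes first, and
multiplies the MCI -> mild and mild -> moderate progression probabilities by
``(1 - effect)`` for amyloid-positive patients only; amyloid-negative
(false-positive) patients occupy the tunnels — and accrue drug cost — with
no effect. Institutionalisation ends the tunnel early (the drug targets the
community-dwelling mild stage). There is no residual effect after the
tunnel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .decision_tree import Amyloid, DiagnosticGroup, DiagnosticOutcome, TrueState
from .fixtures import FixtureBundle
from .parameters import ParameterSet
from .states import BASE_OF, EXT_INDEX, EXT_STATES, HealthState

__all__ = [
    "Trajectory",
    "combine_mortality",
    "apply_treatment_effect",
    "build_transition_matrix",
    "run_cohort",
    "microsimulate",
]

N_EXT = len(EXT_STATES)
I_DEAD = EXT_INDEX["DEAD"]

ROW_TOL = 1e-9


def combine_mortality(q_age: float, hr: float) -> float:
    """Stage-adjusted annual death probability: 1 - exp(-q * HR).

    Treats the annual death probability as a rate when scaling by the hazard
    ratio, so HR = 1 gives 1 - exp(-q) (slightly below q) and large HRs
    saturate at 1.
    """
    if q_age < 0 or q_age > 1:
        raise ValueError("q_age must lie in [0, 1]")
    if hr < 0:
        raise ValueError("hr must be >= 0")
    return 1.0 - math.exp(-q_age * hr)


def apply_treatment_effect(base_progression: float, effect: float) -> float:
    """Reduce an annual progression probability by the treatment effect.

    The removed probability mass stays with the origin state.
    """
    if not 0.0 <= base_progression <= 1.0 or not 0.0 <= effect <= 1.0:
        raise ValueError("base_progression and effect must lie in [0, 1]")
    return base_progression * (1.0 - effect)


def _death_prob(state_name: str, q: float, fixtures: FixtureBundle) -> float:
    base = BASE_OF[state_name]
    if base in (HealthState.SCD, HealthState.MCI):
        return q
    if base is HealthState.DEAD:
        return 0.0
    return combine_mortality(q, fixtures.mortality_hrs.for_state(base))


def _tunnel_mortality_base(state_name: str) -> HealthState:
    # tunnels die at the rate of the stage they copy
    return BASE_OF[state_name]


def build_transition_matrix(
    group: DiagnosticGroup,
    age: float,
    params: ParameterSet,
    fixtures: FixtureBundle,
) -> np.ndarray:
    """One-year transition matrix on the extended state space for a group.

    The matrix depends on the group only through its amyloid status (choice
    of pre-dementia progression probabilities) and its effective treatment
    response (tunnel rows); the tunnel bookkeeping itself is encoded in the
    matrix, so the same matrix serves every cycle at a given age.
    """
    amypos = group.amyloid is Amyloid.POSITIVE
    nh = params.natural_history
    tr = params.treatment
    responder_frac = (
        tr.responder_fraction_amypos if amypos else tr.responder_fraction_amyneg
    )
    eff = tr.effect * responder_frac
    p_scd = nh.p_scd_to_mci_amypos if amypos else nh.p_scd_to_mci_amyneg
    p_mci = nh.p_mci_to_mild_amypos if amypos else nh.p_mci_to_mild_amyneg
    q = fixtures.life_table.q_at(age)

    M = np.zeros((N_EXT, N_EXT))

    def fill(row_state: str, cond: dict[str, float]) -> None:
        """Fill one row: death first, survivors follow `cond` (sums to 1)."""
        i = EXT_INDEX[row_state]
        pd_ = _death_prob(row_state, q, fixtures)
        M[i, I_DEAD] += pd_
        surv = 1.0 - pd_
        for dest, p in cond.items():
            M[i, EXT_INDEX[dest]] += surv * p

    # pre-dementia, untreated
    fill("SCD", {"MCI": p_scd, "SCD": 1.0 - p_scd})
    fill("MCI", {"MILD": p_mci, "MCI": 1.0 - p_mci})

    # dementia block, identical for both amyloid groups
    for s in ("MILD", "MODERATE", "SEVERE", "MILD_LTC", "MODERATE_LTC", "SEVERE_LTC"):
        row = fixtures.dementia_row(HealthState(s))
        fill(s, {dest: float(p) for dest, p in row.items() if p > 0.0})

    # treatment tunnels: same marginal structure, progression slowed by the
    # effective effect; destinations remapped to keep treatment-year memory
    p_mci_tx = apply_treatment_effect(p_mci, eff)
    fill("MCI_TX1", {"MILD_TX2": p_mci_tx, "MCI_TX2": 1.0 - p_mci_tx})
    fill("MCI_TX2", {"MILD": p_mci_tx, "MCI": 1.0 - p_mci_tx})

    mild_row = fixtures.dementia_row(HealthState.MILD)
    p_prog = apply_treatment_effect(float(mild_row["MODERATE"]), eff)
    p_inst = float(mild_row["MILD_LTC"])
    fill("MILD_TX1", {"MODERATE": p_prog, "MILD_LTC": p_inst,
                      "MILD_TX2": 1.0 - p_prog - p_inst})
    fill("MILD_TX2", {"MODERATE": p_prog, "MILD_LTC": p_inst,
                      "MILD": 1.0 - p_prog - p_inst})

    M[I_DEAD, I_DEAD] = 1.0

    sums = M.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > ROW_TOL):
        raise AssertionError(f"non-stochastic row(s): {sums}")
    return M


@dataclass
class Trajectory:
    """State occupancy per diagnostic group and cycle.

    ``occupancy[g, t, s]`` is the cohort fraction of group ``g`` in extended
    state ``s`` at the start of cycle ``t`` (t = 0 .. horizon).
    """

    occupancy: np.ndarray  # (n_groups, horizon + 1, N_EXT)
    groups: list[DiagnosticGroup]
    ages: np.ndarray
    state_names: tuple[str, ...] = EXT_STATES

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[1] - 1

    def total_occupancy(self) -> np.ndarray:
        """Occupancy summed over groups, shape (horizon + 1, N_EXT)."""
        return self.occupancy.sum(axis=0)

    def base_state_occupancy(self) -> np.ndarray:
        """Occupancy collapsed to the nine base states, tunnels folded in."""
        out = np.zeros((self.occupancy.shape[0], self.occupancy.shape[1], 9))
        base_idx = {s: i for i, s in enumerate(HealthState)}
        for j, name in enumerate(self.state_names):
            out[:, :, base_idx[BASE_OF[name]]] += self.occupancy[:, :, j]
        return out


def _start_index(group: DiagnosticGroup) -> int:
    if group.true_state is TrueState.SCD:
        return EXT_INDEX["SCD"]
    if group.true_state is TrueState.MCI:
        return EXT_INDEX["MCI_TX1"] if group.treated else EXT_INDEX["MCI"]
    return EXT_INDEX["MILD_TX1"] if group.treated else EXT_INDEX["MILD"]


def _group_matrix_key(group: DiagnosticGroup, params: ParameterSet) -> tuple:
    amypos = group.amyloid is Amyloid.POSITIVE
    frac = (
        params.treatment.responder_fraction_amypos
        if amypos
        else params.treatment.responder_fraction_amyneg
    )
    return (amypos, params.treatment.effect * frac)


def run_cohort(
    outcome: DiagnosticOutcome,
    params: ParameterSet,
    fixtures: FixtureBundle,
) -> Trajectory:
    """Deterministic cohort propagation of every diagnostic group.

    Each group starts with its decision-tree mass in its true state (inside
    the first tunnel year if treated) at the economic start age; ages advance
    one year per cycle.
    """
    horizon = params.econ.horizon
    start_age = params.econ.start_age
    groups = outcome.groups
    occ = np.zeros((len(groups), horizon + 1, N_EXT))
    ages = start_age + np.arange(horizon + 1, dtype=float)

    for g, group in enumerate(groups):
        occ[g, 0, _start_index(group)] = group.mass

    # matrices are shared between groups with the same amyloid status and
    # effective treatment response; cache them per cycle
    for t in range(horizon):
        age = float(ages[t])
        cache: dict[tuple, np.ndarray] = {}
        for g, group in enumerate(groups):
            if group.mass == 0.0 and occ[g, t].sum() == 0.0:
                continue
            key = _group_matrix_key(group, params)
            if key not in cache:
                cache[key] = build_transition_matrix(group, age, params, fixtures)
            occ[g, t + 1] = occ[g, t] @ cache[key]

    return Trajectory(occupancy=occ, groups=list(groups), ages=ages)


def microsimulate(
    outcome: DiagnosticOutcome,
    params: ParameterSet,
    fixtures: FixtureBundle,
    n_individuals: int,
    seed: int,
) -> Trajectory:
    """Individual-level Monte-Carlo estimate of the cohort trajectory.

    Simulates ``n_individuals`` annual paths with the same matrices as
    :func:`run_cohort` and returns occupancy fractions of the whole cohort
    (Monte-Carlo error ~ n^(-1/2)); deterministic given ``seed``. Serves as
    an independent check on the matrix propagation.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    horizon = params.econ.horizon
    groups = outcome.groups
    ages = params.econ.start_age + np.arange(horizon + 1, dtype=float)

    masses = np.array([g.mass for g in groups], dtype=float)
    counts = rng.multinomial(n_individuals, masses / masses.sum())
    occ = np.zeros((len(groups), horizon + 1, N_EXT))

    for g, (group, n_g) in enumerate(zip(groups, counts)):
        if n_g == 0:
            continue
        states = np.full(n_g, _start_index(group), dtype=np.int64)
        occ[g, 0, :] = np.bincount(states, minlength=N_EXT)
        for t in range(horizon):
            M = build_transition_matrix(group, float(ages[t]), params, fixtures)
            cum = np.cumsum(M, axis=1)
            u = rng.random(n_g)
            states = np.argmax(u[:, None] < cum[states], axis=1)
            occ[g, t + 1, :] = np.bincount(states, minlength=N_EXT)

    occ *= masses.sum() / n_individuals
    return Trajectory(occupancy=occ, groups=list(groups), ages=ages)
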