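"""Synthetic stand-ins for registry-derived model inputs.

The progression model needs three inputs that come from national registries
and are not published alongside the model parameters: an old-age life table,
the annual transition block between the six clinical-dementia states, and
mortality hazard ratios by dementia stage and care setting. This module
generates plausible synthetic versions of all three so the full pipeline
runs and can be tested without external data.

The synthetic fixtures deliberately do NOT reproduce any registry estimate;
every bundle records ``provenance = "synthetic"`` and that tag is carried
into reports. Users holding the real tables can load them from CSV files
with the same schemas via :meth:`FixtureBundle.from_csv_dir`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .states import DEMENTIA_STATES, HealthState

__all__ = [
    "LifeTable",
    "MortalityHRs",
    "FixtureBundle",
    "generate_life_table",
    "generate_dementia_transition_fixture",
    "generate_mortality_hr_fixture",
    "default_fixture_bundle",
    "F0_SEED",
]

#: Seed of the versioned default bundle "F0" used throughout the test suite.
F0_SEED = 74

#: Gompertz defaults for the synthetic life table (see generate_life_table).
GOMPERTZ_A = 2e-5
GOMPERTZ_B = 0.11


@dataclass(frozen=True)
class LifeTable:
    """Annual death probability q(age) for the general population."""

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.q):
            raise ValueError("ages and q must have equal length")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")

    def q_at(self, age: float) -> float:
        idx = np.searchsorted(self.ages, age)
        if idx >= len(self.ages) or self.ages[idx] != age:
            raise KeyError(f"age {age} outside life table range "
                           f"[{self.ages[0]}, {self.ages[-1]}]")
        return float(self.q[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q": self.q})


@dataclass(frozen=True)
class MortalityHRs:
    """Hazard ratios of death versus the general population, by dementia
    stage and care setting; SCD/MCI carry HR 1 by assumption. The scale is
    anchored at the very-mild-dementia excess hazard (HR 1.82)."""

    hr: dict[HealthState, float]
    anchor_very_mild: float = 1.82

    def __post_init__(self) -> None:
        missing = [s for s in DEMENTIA_STATES if s not in self.hr]
        if missing:
            raise ValueError(f"missing HR for stages: {missing}")
        for s, v in self.hr.items():
            if v < 1.0:
                raise ValueError(f"HR for {s.value} must be >= 1, got {v}")
        # severity-monotone within each care setting
        comm = [HealthState.MILD, HealthState.MODERATE, HealthState.SEVERE]
        inst = [HealthState.MILD_LTC, HealthState.MODERATE_LTC, HealthState.SEVERE_LTC]
        for seq in (comm, inst):
            vals = [self.hr[s] for s in seq]
            if not all(a <= b for a, b in zip(vals, vals[1:])):
                raise ValueError("HRs must be non-decreasing in severity")
        for c, i in zip(comm, inst):
            if self.hr[i] < self.hr[c]:
                raise ValueError("institutionalised HR must be >= community HR")

    def for_state(self, state: HealthState) -> float:
        if state in (HealthState.SCD, HealthState.MCI):
            return 1.0
        return self.hr[state]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, v in self.hr.items():
            setting = "institution" if s.value.endswith("_LTC") else "community"
            rows.append({"state": s.value, "setting": setting, "hr": v})
        return pd.DataFrame(rows)


def generate_life_table(
    a: float = GOMPERTZ_A,
    b: float = GOMPERTZ_B,
    ages: np.ndarray | range = range(65, 111),
) -> LifeTable:
    """Gompertz-style synthetic life table: q(age) = 1 - exp(-a e^(b age)).

    With the defaults (a = 2e-5, b = 0.11) q(65) is about 0.025 and mortality
    roughly doubles every 6.3 years — the familiar old-age mortality shape,
    not a fit to any national table. ``a = 0`` gives an immortal cohort.
    """
    if a < 0 or b < 0:
        raise ValueError("Gompertz parameters must be non-negative")
    ages_arr = np.asarray(list(ages), dtype=float)
    hazard = a * np.exp(b * ages_arr)
    q = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    return LifeTable(ages=ages_arr, q=q)


def generate_dementia_transition_fixture(
    seed: int = F0_SEED,
    progression_level: float = 0.25,
    institutionalisation_level: float = 0.08,
    regression_level: float = 0.02,
) -> pd.DataFrame:
    """Synthetic annual transition block over the six dementia states.

    Probabilities are conditional on surviving the year. Structure: forward
    progression mild -> moderate -> severe within a care setting, entry to
    long-term care from every community stage, small regression steps to the
    next-less-severe stage (allowed in moderate/severe but not out of mild),
    and no return from institution to community. Rates are jittered +-20%
    around the requested levels, deterministically from ``seed``.
    """
    for name, lvl in (
        ("progression_level", progression_level),
        ("institutionalisation_level", institutionalisation_level),
        ("regression_level", regression_level),
    ):
        if not 0.0 <= lvl <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    rng = np.random.default_rng(seed)

    def jitter(x: float) -> float:
        return float(x * rng.uniform(0.8, 1.2))

    S = [s.value for s in DEMENTIA_STATES]
    block = pd.DataFrame(0.0, index=S, columns=S)

    moves: dict[str, dict[str, float]] = {
        "MILD": {
            "MODERATE": jitter(progression_level),
            "MILD_LTC": jitter(institutionalisation_level),
        },
        "MODERATE": {
            "SEVERE": jitter(progression_level),
            "MILD": jitter(regression_level),
            "MODERATE_LTC": jitter(institutionalisation_level),
        },
        "SEVERE": {
            "MODERATE": jitter(regression_level),
            "SEVERE_LTC": jitter(2.0 * institutionalisation_level),
        },
        "MILD_LTC": {"MODERATE_LTC": jitter(progression_level)},
        "MODERATE_LTC": {
            "SEVERE_LTC": jitter(progression_level),
            "MILD_LTC": jitter(regression_level),
        },
        "SEVERE_LTC": {"MODERATE_LTC": jitter(regression_level)},
    }
    for frm, dests in moves.items():
        total = sum(dests.values())
        if total > 1.0:
            warnings.warn(
                f"transition levels for {frm} sum to {total:.3f} > 1; rescaling",
                stacklevel=2,
            )
            dests = {k: v / total for k, v in dests.items()}
            total = 1.0
        for to, p in dests.items():
            block.loc[frm, to] = p
        block.loc[frm, frm] = 1.0 - total
    return block


def generate_mortality_hr_fixture(
    base: float = 1.82, step: float = 1.4, institution_factor: float = 1.2
) -> MortalityHRs:
    """Severity-monotone hazard-ratio ladder anchored at the very-mild HR.

    Community HRs climb multiplicatively from the anchor (mild = base x step,
    moderate = mild x step, severe = moderate x step); institutionalised
    states carry an additional factor over their community counterpart.
    """
    if base < 1.0 or step < 1.0 or institution_factor < 1.0:
        raise ValueError("base, step and institution_factor must all be >= 1")
    mild = base * step
    moderate = mild * step
    severe = moderate * step
    hr = {
        HealthState.MILD: mild,
        HealthState.MODERATE: moderate,
        HealthState.SEVERE: severe,
        HealthState.MILD_LTC: mild * institution_factor,
        HealthState.MODERATE_LTC: moderate * institution_factor,
        HealthState.SEVERE_LTC: severe * institution_factor,
    }
    return MortalityHRs(hr=hr, anchor_very_mild=base)


@dataclass(frozen=True)
class FixtureBundle:
    """Life table + dementia transition block + mortality HRs, with
    provenance so synthetic inputs are never silently mistaken for registry
    estimates."""

    life_table: LifeTable
    dementia_transitions: pd.DataFrame
    mortality_hrs: MortalityHRs
    provenance: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        S = [s.value for s in DEMENTIA_STATES]
        block = self.dementia_transitions
        if list(block.index) != S or list(block.columns) != S:
            raise ValueError("dementia block must be indexed by the six dementia states")
        if np.any(block.to_numpy() < 0):
            raise ValueError("dementia transition probabilities must be >= 0")
        sums = block.to_numpy().sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("dementia transition rows must sum to 1")

    def dementia_row(self, state: HealthState) -> pd.Series:
        return self.dementia_transitions.loc[state.value]

    # -- CSV round trip ------------------------------------------------------

    def to_csv_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.life_table.to_frame().to_csv(out / "life_table.csv", index=False)
        long = self.dementia_transitions.stack().rename("probability").reset_index()
        long.columns = ["from_state", "to_state", "probability"]
        long.to_csv(out / "dementia_transitions.csv", index=False)
        self.mortality_hrs.to_frame().to_csv(out / "mortality_hrs.csv", index=False)
        (out / "PROVENANCE.txt").write_text(
            f"provenance: {self.provenance}\nseed: {self.seed}\n"
        )

    @classmethod
    def from_csv_dir(cls, in_dir: str | Path, provenance: str = "user-supplied") -> "FixtureBundle":
        p = Path(in_dir)
        lt = pd.read_csv(p / "life_table.csv")
        life = LifeTable(ages=lt["age"].to_numpy(float), q=lt["q"].to_numpy(float))
        long = pd.read_csv(p / "dementia_transitions.csv")
        S = [s.value for s in DEMENTIA_STATES]
        block = (
            long.pivot(index="from_state", columns="to_state", values="probability")
            .reindex(index=S, columns=S)
            .fillna(0.0)
            .rename_axis(index=None, columns=None)
        )
        hr_df = pd.read_csv(p / "mortality_hrs.csv")
        hrs = MortalityHRs(
            hr={HealthState(r.state): float(r.hr) for r in hr_df.itertuples()}
        )
        return cls(
            life_table=life,
            dementia_transitions=block,
            mortality_hrs=hrs,
            provenance=provenance,
        )


def default_fixture_bundle() -> FixtureBundle:
    """The versioned synthetic bundle "F0" used by default everywhere.

    Deterministic: repeated calls return bit-identical bundles.
    """
    return FixtureBundle(
        life_table=generate_life_table(),
        dementia_transitions=generate_dementia_transition_fixture(seed=F0_SEED),
        mortality_hrs=generate_mortality_hr_fixture(),
        provenance="synthetic",
        seed=F0_SEED,
    )
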