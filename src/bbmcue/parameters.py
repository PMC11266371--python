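"""Input-parameter registry for the diagnostic cost-utility model.

Every model input lives here: the cohort composition at primary-care entry,
amyloid-positivity prevalence by cognitive stage, diagnostic-test accuracies,
referral policy, natural-history transition probabilities, treatment
assumptions, unit costs (2022 euros) and health-state utilities, plus the
uncertainty distribution attached to each parameter for sensitivity analyses
(beta for probabilities and utilities, gamma for costs).

Two published sets of amyloid-prevalence figures circulate for the same
source meta-analysis (the rounded table values and the one-decimal prose
values); both are exposed as parameter "dialects" (``table1`` vs ``text``)
because downstream printed results are internally consistent only within a
dialect.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EconSettings",
    "PopulationInputs",
    "AccuracyInputs",
    "PolicyInputs",
    "NaturalHistoryInputs",
    "TreatmentInputs",
    "CostInputs",
    "UtilityInputs",
    "DistributionSpec",
    "ParameterSet",
    "ParameterValidationError",
    "load_parameters",
    "odds_to_probability",
    "cpi_adjust",
    "sample_distribution",
    "default_distributions",
]

SCHEMA_VERSION = 1

#: Bundled YAML reproducing the base case; loading it equals the defaults.
DEFAULT_CONFIG_PATH = Path(__file__).parent / "data" / "default_config.yaml"

#: Sum-to-one tolerance for cohort shares.
SHARE_TOL = 1e-9


class ParameterValidationError(ValueError):
    """A model input failed validation; the message names the field."""


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterValidationError(
            f"{name} must lie in [0, 1], got {value!r}"
        )


@dataclass(frozen=True)
class EconSettings:
    """Economic evaluation settings: horizon, cycle, discounting, WTP."""

    start_age: float = 65.0
    horizon: int = 30
    cycle_length: float = 1.0
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    wtp: float = 50_000.0
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ParameterValidationError("horizon must be >= 1")
        for name in ("discount_rate_costs", "discount_rate_effects"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ParameterValidationError(f"{name} must be in [0, 1)")
        if self.wtp <= 0:
            raise ParameterValidationError("wtp must be positive")
        if self.cycle_length != 1.0:
            raise ParameterValidationError("only annual cycles are supported")


@dataclass(frozen=True)
class PopulationInputs:
    """Cohort composition at model entry and amyloid prevalence by stage."""

    share_scd: float = 0.53
    share_mci: float = 0.30
    share_mild_dem: float = 0.17
    amyloid_prev_scd: float = 0.31
    amyloid_prev_mci: float = 0.548
    amyloid_prev_dem: float = 0.841

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_fraction(f.name, getattr(self, f.name))
        total = self.share_scd + self.share_mci + self.share_mild_dem
        if abs(total - 1.0) > SHARE_TOL:
            raise ParameterValidationError(
                f"cohort shares must sum to 1 (got {total!r})"
            )


@dataclass(frozen=True)
class AccuracyInputs:
    """Sensitivity/specificity of the blood and CSF amyloid tests."""

    bbm_sensitivity: float = 0.89
    bbm_specificity: float = 0.69
    csf_sensitivity: float = 0.91
    csf_specificity: float = 0.89

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_fraction(f.name, getattr(self, f.name))


@dataclass(frozen=True)
class PolicyInputs:
    """Referral policy: clinician-judgement rate in standard of care and
    the (assumed complete) referral of blood-test-positive patients."""

    soc_referral_rate: float = 0.52
    bbm_positive_referral_rate: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_fraction(f.name, getattr(self, f.name))


@dataclass(frozen=True)
class NaturalHistoryInputs:
    """Annual pre-dementia progression probabilities by amyloid status.

    The amyloid-negative probabilities derive from the amyloid-positive ones
    through a progression odds ratio (amyloid pathology raises the odds of
    conversion); the stored values keep the published rounding.
    """

    p_scd_to_mci_amypos: float = 0.41
    p_mci_to_mild_amypos: float = 0.22
    p_scd_to_mci_amyneg: float = 0.10
    p_mci_to_mild_amyneg: float = 0.05
    progression_odds_ratio: float = 5.89

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name != "progression_odds_ratio":
                _check_fraction(f.name, getattr(self, f.name))
        if self.progression_odds_ratio <= 0:
            raise ParameterValidationError("progression_odds_ratio must be > 0")
        # stored amyloid-negative values must be within rounding of the
        # odds-ratio conversion applied to the amyloid-positive values
        for pos, neg, name in (
            (self.p_scd_to_mci_amypos, self.p_scd_to_mci_amyneg, "p_scd_to_mci_amyneg"),
            (self.p_mci_to_mild_amypos, self.p_mci_to_mild_amyneg, "p_mci_to_mild_amyneg"),
        ):
            derived = odds_to_probability(self.progression_odds_ratio, pos)
            if abs(derived - neg) > 0.01:
                raise ParameterValidationError(
                    f"{name}={neg} inconsistent with odds-ratio conversion "
                    f"({derived:.4f} expected within 0.01)"
                )


@dataclass(frozen=True)
class TreatmentInputs:
    """Disease-modifying-treatment assumptions.

    ``effect`` is the fractional reduction of the annual progression
    probability out of MCI and mild dementia while on treatment; treatment
    runs for at most ``max_duration`` annual cycles or until progression to
    moderate dementia. Only amyloid-positive patients respond.
    """

    effect: float = 0.27
    max_duration: int = 2
    annual_cost: float = 5_000.0
    responder_fraction_amypos: float = 1.0
    responder_fraction_amyneg: float = 0.0

    def __post_init__(self) -> None:
        _check_fraction("effect", self.effect)
        _check_fraction("responder_fraction_amypos", self.responder_fraction_amypos)
        _check_fraction("responder_fraction_amyneg", self.responder_fraction_amyneg)
        if self.max_duration < 1:
            raise ParameterValidationError("max_duration must be >= 1")
        if self.annual_cost < 0:
            raise ParameterValidationError("annual_cost must be >= 0")


@dataclass(frozen=True)
class CostInputs:
    """Unit costs in 2022 euros.

    Diagnosis costs are one-off; state costs are annual and include long-term
    care (LTC) variants for the institutionalised dementia states. Subjective
    cognitive decline is costed as MCI.
    """

    phc_cost_scd: float = 959.0
    phc_cost_mci: float = 1_896.0
    phc_cost_dem: float = 1_896.0
    csf_exam_incl_mc_visit: float = 1_940.0
    mc_visit: float = 524.0
    bbm_test: float = 200.0
    state_cost_scd_mci: float = 9_180.0
    state_cost_mild: float = 27_014.0
    state_cost_moderate: float = 30_824.0
    state_cost_severe: float = 35_471.0
    state_cost_mild_ltc: float = 81_383.0
    state_cost_moderate_ltc: float = 66_849.0
    state_cost_severe_ltc: float = 66_977.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ParameterValidationError(f"{f.name} must be >= 0")
        if self.csf_exam_incl_mc_visit <= self.mc_visit:
            raise ParameterValidationError(
                "csf_exam_incl_mc_visit must exceed mc_visit"
            )


@dataclass(frozen=True)
class UtilityInputs:
    """Annual health-state utility weights (EQ-5D style, in [0, 1]).

    Pre-dementia utilities differ by amyloid status; dementia utilities by
    stage only. Institutionalised states reuse the community utility of
    their stage.
    """

    u_scd_amyneg: float = 0.87
    u_scd_amypos: float = 0.86
    u_mci_amyneg: float = 0.71
    u_mci_amypos: float = 0.81
    u_mild: float = 0.74
    u_moderate: float = 0.59
    u_severe: float = 0.36

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_fraction(f.name, getattr(self, f.name))


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty distribution of a parameter for sensitivity analyses.

    ``low``/``high`` are the 2.5%/97.5% interval bounds (either a published
    95% CI or mean ± 20%). Beta/gamma parameters are fitted by method of
    moments with sd = (high - low) / 3.92.
    """

    family: str  # "beta" | "gamma" | "fixed"
    mean: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ParameterValidationError(f"unknown family {self.family!r}")
        if self.family != "fixed":
            if self.low is None or self.high is None:
                raise ParameterValidationError(
                    f"{self.family} spec requires low/high bounds"
                )
            if not self.low <= self.mean <= self.high:
                raise ParameterValidationError(
                    f"interval [{self.low}, {self.high}] must bracket "
                    f"mean {self.mean}"
                )
        if self.family == "beta" and not (
            0.0 <= self.mean <= 1.0
            and (self.low is None or self.low >= 0.0)
            and (self.high is None or self.high <= 1.0)
        ):
            raise ParameterValidationError("beta spec requires values in [0, 1]")
        if self.family == "gamma" and self.mean < 0:
            raise ParameterValidationError("gamma spec requires mean >= 0")

    @property
    def sd(self) -> float:
        assert self.low is not None and self.high is not None
        return (self.high - self.low) / 3.92

    def fit(self) -> tuple[float, ...]:
        """Return the fitted distribution parameters (moment matching)."""
        if self.family == "fixed":
            return (self.mean,)
        m, v = self.mean, self.sd**2
        if v <= 0:
            raise ParameterValidationError("degenerate interval in non-fixed spec")
        if self.family == "beta":
            if v >= m * (1.0 - m):
                raise ParameterValidationError(
                    f"beta moments unfittable (mean {m}, sd {self.sd})"
                )
            nu = m * (1.0 - m) / v - 1.0
            return (m * nu, (1.0 - m) * nu)
        # gamma: shape k, scale theta
        return (m * m / v, v / m)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        p = self.fit()
        if self.family == "beta":
            return rng.beta(p[0], p[1], size=size)
        return rng.gamma(p[0], p[1], size=size)


def sample_distribution(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value from a parameter's uncertainty distribution."""
    return float(spec.sample(rng))


def odds_to_probability(odds_ratio: float, p_reference: float) -> float:
    """Convert a reference probability through an odds ratio.

    Returns the probability ``p`` whose odds are the reference odds divided
    by ``odds_ratio``: odds(p_reference) / odds(p) = odds_ratio. Used to
    derive amyloid-negative progression probabilities from amyloid-positive
    ones given the progression odds ratio of amyloid pathology.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if not 0.0 < p_reference < 1.0:
        raise ValueError("p_reference must be strictly inside (0, 1)")
    odds = p_reference / (1.0 - p_reference) / odds_ratio
    return odds / (1.0 + odds)


def cpi_adjust(cost: float, cpi_original: float, cpi_2022: float) -> float:
    """Inflate a cost from its original price year to 2022 via CPI indices."""
    if cpi_original <= 0 or cpi_2022 <= 0:
        raise ValueError("CPI indices must be positive")
    if cost < 0:
        raise ValueError("cost must be >= 0")
    return cost * cpi_2022 / cpi_original


# ---------------------------------------------------------------------------
# Parameter dialects and the full set

#: (MCI, dementia) amyloid prevalence per dialect; SCD prevalence is 0.31 in
#: both. "table1" carries the rounded tabulated values, "text" the one-decimal
#: prose values; printed downstream results mix the two, so both are exposed.
DIALECTS: dict[str, tuple[float, float]] = {
    "text": (0.548, 0.841),
    "table1": (0.555, 0.84),
}


def default_distributions(population: PopulationInputs) -> dict[str, DistributionSpec]:
    """Uncertainty specs for every parameter varied in sensitivity analyses.

    Keys are attribute paths into :class:`ParameterSet`. Parameters without a
    published interval are fixed and simply absent here.
    """
    b, g = "beta", "gamma"
    return {
        "population.share_mci": DistributionSpec(b, 0.30, 0.25, 0.35),
        "population.share_mild_dem": DistributionSpec(b, 0.17, 0.14, 0.20),
        "population.amyloid_prev_mci": DistributionSpec(
            b, population.amyloid_prev_mci, 0.51, 0.595
        ),
        "population.amyloid_prev_dem": DistributionSpec(
            b, population.amyloid_prev_dem, 0.775, 0.89
        ),
        "policy.soc_referral_rate": DistributionSpec(b, 0.52, 0.416, 0.624),
        "accuracy.bbm_sensitivity": DistributionSpec(b, 0.89, 0.80, 0.95),
        "accuracy.bbm_specificity": DistributionSpec(b, 0.69, 0.54, 0.81),
        "accuracy.csf_sensitivity": DistributionSpec(b, 0.91, 0.84, 0.96),
        "accuracy.csf_specificity": DistributionSpec(b, 0.89, 0.84, 0.94),
        "treatment.effect": DistributionSpec(b, 0.27, 0.22, 0.324),
        "utilities.u_scd_amyneg": DistributionSpec(b, 0.87, 0.86, 0.89),
        "utilities.u_scd_amypos": DistributionSpec(b, 0.86, 0.83, 0.89),
        "utilities.u_mci_amyneg": DistributionSpec(b, 0.71, 0.64, 0.78),
        "utilities.u_mci_amypos": DistributionSpec(b, 0.81, 0.77, 0.85),
        "utilities.u_mild": DistributionSpec(b, 0.74, 0.69, 0.79),
        "utilities.u_moderate": DistributionSpec(b, 0.59, 0.47, 0.71),
        "utilities.u_severe": DistributionSpec(b, 0.36, 0.18, 0.53),
        "costs.csf_exam_incl_mc_visit": DistributionSpec(g, 1_940.0, 1_552.0, 2_328.0),
        "costs.mc_visit": DistributionSpec(g, 524.0, 419.0, 629.0),
        "costs.bbm_test": DistributionSpec(g, 200.0, 100.0, 300.0),
        "costs.state_cost_scd_mci": DistributionSpec(g, 9_180.0, 7_344.0, 11_016.0),
        "costs.state_cost_mild": DistributionSpec(g, 27_014.0, 21_348.0, 32_681.0),
        "treatment.annual_cost": DistributionSpec(g, 5_000.0, 4_000.0, 6_000.0),
    }


@dataclass(frozen=True)
class ParameterSet:
    """The complete, validated set of model inputs."""

    econ: EconSettings = field(default_factory=EconSettings)
    population: PopulationInputs = field(default_factory=PopulationInputs)
    accuracy: AccuracyInputs = field(default_factory=AccuracyInputs)
    policy: PolicyInputs = field(default_factory=PolicyInputs)
    natural_history: NaturalHistoryInputs = field(default_factory=NaturalHistoryInputs)
    treatment: TreatmentInputs = field(default_factory=TreatmentInputs)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    dialect: str = "text"
    distributions: Mapping[str, DistributionSpec] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ParameterValidationError(f"unknown dialect {self.dialect!r}")
        if self.distributions is None:
            object.__setattr__(
                self, "distributions", default_distributions(self.population)
            )

    @classmethod
    def default(cls, dialect: str = "text", **overrides: Any) -> "ParameterSet":
        if dialect not in DIALECTS:
            raise ParameterValidationError(f"unknown dialect {dialect!r}")
        mci, dem = DIALECTS[dialect]
        pop = overrides.pop(
            "population",
            PopulationInputs(amyloid_prev_mci=mci, amyloid_prev_dem=dem),
        )
        return cls(population=pop, dialect=dialect, **overrides)

    # -- attribute-path access, used by the sensitivity analyses ------------

    def get(self, path: str) -> float:
        section, _, name = path.partition(".")
        return getattr(getattr(self, section), name)

    def replace(self, path: str, value: float) -> "ParameterSet":
        """Return a copy with one parameter (given as ``section.name``) replaced."""
        section, _, name = path.partition(".")
        block = getattr(self, section)
        new_block = dataclasses.replace(block, **{name: value})
        return dataclasses.replace(self, **{section: new_block})

    def replace_many(self, values: Mapping[str, float]) -> "ParameterSet":
        by_section: dict[str, dict[str, float]] = {}
        for path, value in values.items():
            section, _, name = path.partition(".")
            by_section.setdefault(section, {})[name] = value
        out = self
        for section, kwargs in by_section.items():
            block = dataclasses.replace(getattr(out, section), **kwargs)
            out = dataclasses.replace(out, **{section: block})
        return out

    def iter_uncertain(self) -> Iterator[tuple[str, DistributionSpec]]:
        for path, spec in self.distributions.items():
            if spec.family != "fixed":
                yield path, spec

    def to_frame(self) -> pd.DataFrame:
        """Resolved parameter table (name, value, family, low, high)."""
        rows = []
        for section in (
            "econ", "population", "accuracy", "policy",
            "natural_history", "treatment", "costs", "utilities",
        ):
            block = getattr(self, section)
            for f in fields(block):
                path = f"{section}.{f.name}"
                spec = self.distributions.get(path)
                rows.append(
                    {
                        "name": path,
                        "value": getattr(block, f.name),
                        "family": spec.family if spec else "fixed",
                        "low": spec.low if spec else None,
                        "high": spec.high if spec else None,
                    }
                )
        return pd.DataFrame(rows)


_SECTION_TYPES = {
    "econ": EconSettings,
    "population": PopulationInputs,
    "accuracy": AccuracyInputs,
    "policy": PolicyInputs,
    "natural_history": NaturalHistoryInputs,
    "treatment": TreatmentInputs,
    "costs": CostInputs,
    "utilities": UtilityInputs,
}


def load_parameters(config_source: str | Path | Mapping[str, Any] | None = None) -> ParameterSet:
    """Load a :class:`ParameterSet` from YAML (path, text or mapping).

    Keys omitted from the config fall back to the bundled defaults; unknown
    keys raise. A top-level ``dialect`` selects the amyloid-prevalence
    dialect before any explicit prevalence overrides are applied.
    """
    if config_source is None:
        data: dict[str, Any] = {}
    elif isinstance(config_source, Mapping):
        data = dict(config_source)
    else:
        p = Path(config_source)
        if p.exists():
            text = p.read_text()
        else:
            text = str(config_source)
        loaded = yaml.safe_load(io.StringIO(text))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParameterValidationError("config must be a mapping")
        data = loaded

    data.pop("schema", None)
    dialect = data.pop("dialect", "text")
    if dialect not in DIALECTS:
        raise ParameterValidationError(f"unknown dialect {dialect!r}")
    mci, dem = DIALECTS[dialect]

    sections: dict[str, Any] = {}
    for name, typ in _SECTION_TYPES.items():
        overrides = data.pop(name, {})
        if not isinstance(overrides, Mapping):
            raise ParameterValidationError(f"section {name!r} must be a mapping")
        known = {f.name for f in fields(typ)}
        unknown = set(overrides) - known
        if unknown:
            raise ParameterValidationError(
                f"unknown key(s) in section {name!r}: {sorted(unknown)}"
            )
        kwargs = dict(overrides)
        if name == "population":
            kwargs.setdefault("amyloid_prev_mci", mci)
            kwargs.setdefault("amyloid_prev_dem", dem)
        try:
            sections[name] = typ(**kwargs)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ParameterValidationError(str(exc)) from exc
    if data:
        raise ParameterValidationError(f"unknown top-level key(s): {sorted(data)}")
    return ParameterSet(dialect=dialect, **sections)
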