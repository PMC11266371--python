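"""Diagnostic decision tree for the three evaluation pathways.

A unit cohort of 65-year-olds with subjective cognitive complaints enters
primary care and is partitioned by true cognitive state (SCD / MCI / mild
dementia) and true amyloid status. Three pathways decide who reaches the
memory clinic and who receives a CSF amyloid examination:

* ``SOC`` — clinician judgement refers a fixed fraction of MCI/dementia
  patients; everyone referred gets CSF, whose result sets the diagnosis.
* ``BBM_PHC`` — MCI/dementia patients get a blood biomarker test at primary
  care; test-positives are all referred and get CSF.
* ``BBM_MC`` — referral as in SOC, but the memory clinic uses the blood test
  to triage: only blood-test-positives proceed to CSF.

SCD patients exit at primary care untested in every pathway (no intervention
exists at that stage), so amyloid-positive SCD is always a false negative.
A diagnosis of amyloid-positive AD requires a positive CSF result; CSF
accuracy is conditioned on true amyloid only, never on the blood-test result.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .parameters import CostInputs, ParameterSet

__all__ = [
    "PathwayId",
    "TrueState",
    "Amyloid",
    "Label",
    "DiagnosticGroup",
    "DiagnosticOutcome",
    "evaluate_pathway",
    "diagnosis_cost",
    "compare_pathways",
    "population_scale",
    "outcomes_table",
]


class PathwayId(str, enum.Enum):
    SOC = "SOC"
    BBM_PHC = "BBM_PHC"
    BBM_MC = "BBM_MC"


class TrueState(str, enum.Enum):
    SCD = "SCD"
    MCI = "MCI"
    MILD_DEM = "MILD_DEM"


class Amyloid(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class Label(str, enum.Enum):
    AD_DIAGNOSED = "AD_DIAGNOSED"  # biomarker-confirmed, receives treatment
    NOT_AD = "NOT_AD"


@dataclass(frozen=True)
class DiagnosticGroup:
    """One cell of the cohort partition with its downstream-relevant tags."""

    true_state: TrueState
    amyloid: Amyloid
    label: Label
    mass: float

    @property
    def treated(self) -> bool:
        return self.label is Label.AD_DIAGNOSED


@dataclass
class DiagnosticOutcome:
    """Decision-tree result for one pathway on the unit cohort."""

    pathway: PathwayId
    groups: list[DiagnosticGroup]
    frac_referred: float
    frac_csf: float
    frac_bbm_tested: float
    frac_tp: float
    frac_tn: float
    frac_fp: float
    frac_fn: float
    diagnosis_cost_per_person: float = 0.0
    cost_components: dict[str, float] = field(default_factory=dict)

    @property
    def state_masses(self) -> dict[TrueState, float]:
        out: dict[TrueState, float] = {s: 0.0 for s in TrueState}
        for g in self.groups:
            out[g.true_state] += g.mass
        return out


def _per_cell_probabilities(
    pathway: PathwayId, params: ParameterSet, state: TrueState, amypos: bool
) -> tuple[float, float, float, float]:
    """Return (P(referred), P(BBM tested), P(CSF), P(AD diagnosis)) for a cell."""
    if state is TrueState.SCD:
        return 0.0, 0.0, 0.0, 0.0
    acc = params.accuracy
    bbm_pos = acc.bbm_sensitivity if amypos else 1.0 - acc.bbm_specificity
    csf_pos = acc.csf_sensitivity if amypos else 1.0 - acc.csf_specificity
    soc_rate = params.policy.soc_referral_rate
    bbm_ref = params.policy.bbm_positive_referral_rate

    if pathway is PathwayId.SOC:
        referred = soc_rate
        bbm = 0.0
        csf = referred
    elif pathway is PathwayId.BBM_PHC:
        bbm = 1.0
        referred = bbm_pos * bbm_ref
        csf = referred
    elif pathway is PathwayId.BBM_MC:
        referred = soc_rate
        bbm = referred
        csf = referred * bbm_pos
    else:  # pragma: no cover
        raise ValueError(f"unknown pathway {pathway!r}")
    return referred, bbm, csf, csf * csf_pos


def evaluate_pathway(pathway: PathwayId, params: ParameterSet) -> DiagnosticOutcome:
    """Partition the unit cohort under one diagnostic pathway.

    Returns the ten-group partition (state x amyloid x final label; SCD can
    never be labelled AD) together with referral/CSF burden, the
    confusion-matrix fractions against true amyloid status, and the
    per-person diagnosis cost.
    """
    pathway = PathwayId(pathway)
    pop = params.population
    shares = {
        TrueState.SCD: pop.share_scd,
        TrueState.MCI: pop.share_mci,
        TrueState.MILD_DEM: pop.share_mild_dem,
    }
    prev = {
        TrueState.SCD: pop.amyloid_prev_scd,
        TrueState.MCI: pop.amyloid_prev_mci,
        TrueState.MILD_DEM: pop.amyloid_prev_dem,
    }

    groups: list[DiagnosticGroup] = []
    referred = csf = bbm_tested = tp = tn = fp = fn = 0.0
    for state in TrueState:
        for amy in (Amyloid.POSITIVE, Amyloid.NEGATIVE):
            amypos = amy is Amyloid.POSITIVE
            p_amy = prev[state] if amypos else 1.0 - prev[state]
            mass = shares[state] * p_amy
            p_ref, p_bbm, p_csf, p_diag = _per_cell_probabilities(
                pathway, params, state, amypos
            )
            referred += mass * p_ref
            bbm_tested += mass * p_bbm
            csf += mass * p_csf
            diagnosed = mass * p_diag
            if amypos:
                tp += diagnosed
                fn += mass - diagnosed
            else:
                fp += diagnosed
                tn += mass - diagnosed
            if state is not TrueState.SCD and p_diag > 0.0:
                groups.append(DiagnosticGroup(state, amy, Label.AD_DIAGNOSED, diagnosed))
            elif state is not TrueState.SCD:
                groups.append(DiagnosticGroup(state, amy, Label.AD_DIAGNOSED, 0.0))
            groups.append(DiagnosticGroup(state, amy, Label.NOT_AD, mass - diagnosed))

    outcome = DiagnosticOutcome(
        pathway=pathway,
        groups=groups,
        frac_referred=referred,
        frac_csf=csf,
        frac_bbm_tested=bbm_tested,
        frac_tp=tp,
        frac_tn=tn,
        frac_fp=fp,
        frac_fn=fn,
    )
    diagnosis_cost(pathway, outcome, params.costs)
    return outcome


def diagnosis_cost(
    pathway: PathwayId, outcome: DiagnosticOutcome, costs: CostInputs
) -> float:
    """Per-person diagnosis cost with its component breakdown.

    Primary-care work-up is incurred by everyone (by true state); the CSF
    examination price includes the memory-clinic consultation, so the BBM_MC
    pathway charges the plain clinic visit for referred patients and only the
    CSF top-up for those triaged into the examination.
    """
    pathway = PathwayId(pathway)
    if pathway is not outcome.pathway:
        raise ValueError(
            f"outcome was produced for {outcome.pathway.value}, not {pathway.value}"
        )
    masses = outcome.state_masses
    phc = (
        masses[TrueState.SCD] * costs.phc_cost_scd
        + masses[TrueState.MCI] * costs.phc_cost_mci
        + masses[TrueState.MILD_DEM] * costs.phc_cost_dem
    )
    bbm = outcome.frac_bbm_tested * costs.bbm_test
    if pathway is PathwayId.BBM_MC:
        mc_visit = outcome.frac_referred * costs.mc_visit
        csf = outcome.frac_csf * (costs.csf_exam_incl_mc_visit - costs.mc_visit)
    else:
        mc_visit = 0.0
        csf = outcome.frac_csf * costs.csf_exam_incl_mc_visit
    components = {"phc": phc, "bbm": bbm, "mc_visit": mc_visit, "csf": csf}
    outcome.cost_components = components
    outcome.diagnosis_cost_per_person = sum(components.values())
    return outcome.diagnosis_cost_per_person


_DIFF_FIELDS = (
    "frac_referred",
    "frac_csf",
    "frac_bbm_tested",
    "frac_tp",
    "frac_tn",
    "frac_fp",
    "frac_fn",
    "diagnosis_cost_per_person",
)


def compare_pathways(a: DiagnosticOutcome, b: DiagnosticOutcome) -> pd.Series:
    """Element-wise differences ``b - a`` of the intermediate outcomes."""
    diff = {name: getattr(b, name) - getattr(a, name) for name in _DIFF_FIELDS}
    for comp in ("phc", "bbm", "mc_visit", "csf"):
        diff[f"cost_{comp}"] = b.cost_components.get(comp, 0.0) - a.cost_components.get(
            comp, 0.0
        )
    return pd.Series(diff, name=f"{b.pathway.value} - {a.pathway.value}")


def population_scale(outcome_diff: Mapping[str, float] | pd.Series, n: int) -> pd.Series:
    """Scale per-person differences to a population of ``n`` people.

    Cohort fractions become head counts and per-person euros become total
    euros, e.g. a +0.08 referral difference over 10,000 people seeking
    evaluation is 800 additional referrals.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    return pd.Series(dict(outcome_diff), dtype=float) * n


def outcomes_table(a: DiagnosticOutcome, b: DiagnosticOutcome) -> pd.DataFrame:
    """Two-pathway comparison in the published table layout."""
    rows = {
        "Percentage referred to memory clinic": "frac_referred",
        "Percentage received CSF examination": "frac_csf",
        "Percentage of AD TP": "frac_tp",
        "Percentage of AD TN": "frac_tn",
        "Percentage of AD FP": "frac_fp",
        "Percentage of AD FN": "frac_fn",
        "Diagnosis cost": "diagnosis_cost_per_person",
    }
    data = {
        a.pathway.value: [getattr(a, attr) for attr in rows.values()],
        b.pathway.value: [getattr(b, attr) for attr in rows.values()],
    }
    df = pd.DataFrame(data, index=list(rows))
    df["Difference"] = df[b.pathway.value] - df[a.pathway.value]
    return df
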