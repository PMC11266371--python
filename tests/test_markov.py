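import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bbmcue.decision_tree import (
    Amyloid,
    DiagnosticGroup,
    DiagnosticOutcome,
    Label,
    PathwayId,
    TrueState,
    evaluate_pathway,
)
from bbmcue.fixtures import (
    FixtureBundle,
    generate_dementia_transition_fixture,
    generate_life_table,
    generate_mortality_hr_fixture,
)
from bbmcue.markov import (
    apply_treatment_effect,
    build_transition_matrix,
    combine_mortality,
    microsimulate,
    run_cohort,
)
from bbmcue.states import EXT_INDEX, EXT_STATES


def single_group_outcome(group: DiagnosticGroup) -> DiagnosticOutcome:
    return DiagnosticOutcome(
        pathway=PathwayId.SOC,
        groups=[group],
        frac_referred=0.0,
        frac_csf=0.0,
        frac_bbm_tested=0.0,
        frac_tp=0.0,
        frac_tn=0.0,
        frac_fp=0.0,
        frac_fn=1.0,
    )


def immortal_bundle(seed: int = 5) -> FixtureBundle:
    return FixtureBundle(
        life_table=generate_life_table(a=0.0),
        dementia_transitions=generate_dementia_transition_fixture(seed=seed),
        mortality_hrs=generate_mortality_hr_fixture(),
        seed=seed,
    )


UNTREATED_MCI_NEG = DiagnosticGroup(
    TrueState.MCI, Amyloid.NEGATIVE, Label.NOT_AD, 1.0
)
TREATED_MCI_POS = DiagnosticGroup(
    TrueState.MCI, Amyloid.POSITIVE, Label.AD_DIAGNOSED, 1.0
)


class TestCombineMortality:
    @pytest.mark.parametrize(
        "q, hr, expected",
        [(0.02, 1.0, 0.019801), (0.0, 5.0, 0.0), (0.01, 1.82, 0.018035)],
    )
    def test_rate_scaling_formula(self, q, hr, expected):
        assert combine_mortality(q, hr) == pytest.approx(expected, abs=1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            combine_mortality(-0.1, 1.0)
        with pytest.raises(ValueError):
            combine_mortality(0.1, -1.0)


class TestTreatmentEffect:
    @pytest.mark.parametrize(
        "base, effect, expected", [(0.22, 0.27, 0.1606), (0.22, 0.0, 0.22), (0.0, 0.27, 0.0)]
    )
    def test_multiplicative_reduction(self, base, effect, expected):
        assert apply_treatment_effect(base, effect) == pytest.approx(expected)


class TestTransitionMatrix:
    @given(
        age=st.integers(65, 94),
        seed=st.integers(0, 500),
        amypos=st.booleans(),
        treated=st.booleans(),
    )
    def test_rows_stochastic_and_dead_absorbing(self, age, seed, amypos, treated, params_text):
        fixtures = FixtureBundle(
            life_table=generate_life_table(),
            dementia_transitions=generate_dementia_transition_fixture(seed=seed),
            mortality_hrs=generate_mortality_hr_fixture(),
            seed=seed,
        )
        group = DiagnosticGroup(
            TrueState.MCI,
            Amyloid.POSITIVE if amypos else Amyloid.NEGATIVE,
            Label.AD_DIAGNOSED if treated else Label.NOT_AD,
            1.0,
        )
        M = build_transition_matrix(group, float(age), params_text, fixtures)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-9)
        assert (M >= 0).all()
        dead = EXT_INDEX["DEAD"]
        assert M[dead, dead] == 1.0
        assert M[dead].sum() == 1.0

    def test_competing_risk_scaling_of_progression(self, params_text, f0):
        M = build_transition_matrix(UNTREATED_MCI_NEG, 70.0, params_text, f0)
        q = f0.life_table.q_at(70.0)
        assert M[EXT_INDEX["MCI"], EXT_INDEX["MILD"]] == pytest.approx(
            0.05 * (1.0 - q), abs=1e-12
        )

    def test_tunnel_progression_carries_treatment_effect(self, params_text, f0):
        M = build_transition_matrix(TREATED_MCI_POS, 70.0, params_text, f0)
        q = f0.life_table.q_at(70.0)
        assert M[EXT_INDEX["MCI_TX1"], EXT_INDEX["MILD_TX2"]] == pytest.approx(
            0.22 * (1.0 - 0.27) * (1.0 - q), abs=1e-12
        )
        # amyloid-negative treated (false positive): no effect
        fp_group = DiagnosticGroup(TrueState.MCI, Amyloid.NEGATIVE, Label.AD_DIAGNOSED, 1.0)
        M2 = build_transition_matrix(fp_group, 70.0, params_text, f0)
        assert M2[EXT_INDEX["MCI_TX1"], EXT_INDEX["MILD_TX2"]] == pytest.approx(
            0.05 * (1.0 - q), abs=1e-12
        )

    def test_certain_death_empties_row(self, params_text, f0):
        import dataclasses

        lt = f0.life_table
        certain = dataclasses.replace(
            f0, life_table=type(lt)(ages=lt.ages, q=np.ones_like(lt.q))
        )
        M = build_transition_matrix(UNTREATED_MCI_NEG, 70.0, params_text, certain)
        assert M[EXT_INDEX["MCI"], EXT_INDEX["DEAD"]] == 1.0


class TestRunCohort:
    def test_mass_conserved_every_cycle(self, params_text, f0):
        outcome = evaluate_pathway(PathwayId.BBM_PHC, params_text)
        traj = run_cohort(outcome, params_text, f0)
        per_group = traj.occupancy.sum(axis=2)
        expected = np.tile(
            np.array([g.mass for g in outcome.groups])[:, None], (1, traj.horizon + 1)
        )
        np.testing.assert_allclose(per_group, expected, atol=1e-9)
        dead = traj.occupancy[:, :, EXT_INDEX["DEAD"]].sum(axis=0)
        assert np.all(np.diff(dead) >= -1e-12)

    def test_geometric_decay_in_two_state_chain(self, params_text):
        traj = run_cohort(
            single_group_outcome(UNTREATED_MCI_NEG), params_text, immortal_bundle()
        )
        mci = traj.occupancy[0, :, EXT_INDEX["MCI"]]
        np.testing.assert_allclose(mci, 0.95 ** np.arange(31), atol=1e-12)

    def test_treated_arm_stochastically_dominates(self, params_text, f0):
        treated = run_cohort(
            single_group_outcome(TREATED_MCI_POS), params_text, f0
        ).base_state_occupancy()[0]
        untreated_group = DiagnosticGroup(
            TrueState.MCI, Amyloid.POSITIVE, Label.NOT_AD, 1.0
        )
        untreated = run_cohort(
            single_group_outcome(untreated_group), params_text, f0
        ).base_state_occupancy()[0]
        # occupancy of mild-or-worse (incl. dead) never higher under treatment
        worse_t = treated[:, 2:].sum(axis=1)
        worse_u = untreated[:, 2:].sum(axis=1)
        assert np.all(worse_t <= worse_u + 1e-12)

    def test_null_treatment_equivalence(self, params_text, f0):
        null = params_text.replace("treatment.effect", 0.0)
        a = run_cohort(single_group_outcome(TREATED_MCI_POS), null, f0)
        b = run_cohort(
            single_group_outcome(
                DiagnosticGroup(TrueState.MCI, Amyloid.POSITIVE, Label.NOT_AD, 1.0)
            ),
            null,
            f0,
        )
        np.testing.assert_allclose(
            a.base_state_occupancy(), b.base_state_occupancy(), atol=1e-12
        )

    def test_nonresponder_fraction_nullifies_effect(self, params_text, f0):
        null_resp = params_text.replace("treatment.responder_fraction_amypos", 0.0)
        a = run_cohort(single_group_outcome(TREATED_MCI_POS), null_resp, f0)
        b = run_cohort(
            single_group_outcome(
                DiagnosticGroup(TrueState.MCI, Amyloid.POSITIVE, Label.NOT_AD, 1.0)
            ),
            null_resp,
            f0,
        )
        np.testing.assert_allclose(
            a.base_state_occupancy(), b.base_state_occupancy(), atol=1e-12
        )

    def test_higher_stage_hazard_kills_earlier(self, params_text):
        import dataclasses

        mild_start = DiagnosticGroup(TrueState.MILD_DEM, Amyloid.POSITIVE, Label.NOT_AD, 1.0)
        base = immortal_bundle()
        lt = generate_life_table()  # mortal
        low = dataclasses.replace(base, life_table=lt,
                                  mortality_hrs=generate_mortality_hr_fixture(step=1.0))
        high = dataclasses.replace(base, life_table=lt,
                                   mortality_hrs=generate_mortality_hr_fixture(step=1.6))
        d_low = run_cohort(single_group_outcome(mild_start), params_text, low)
        d_high = run_cohort(single_group_outcome(mild_start), params_text, high)
        dead_low = d_low.occupancy[0, :, EXT_INDEX["DEAD"]]
        dead_high = d_high.occupancy[0, :, EXT_INDEX["DEAD"]]
        assert np.all(dead_high[1:] >= dead_low[1:])
        assert dead_high[15] > dead_low[15]

    def test_age_beyond_life_table_rejected(self, params_text, f0):
        import dataclasses

        far = dataclasses.replace(
            params_text, econ=dataclasses.replace(params_text.econ, horizon=80)
        )
        with pytest.raises(KeyError):
            run_cohort(single_group_outcome(UNTREATED_MCI_NEG), far, f0)

    def test_median_survival_from_mild_dementia_plausible(self, params_text, f0):
        mild_start = DiagnosticGroup(TrueState.MILD_DEM, Amyloid.POSITIVE, Label.NOT_AD, 1.0)
        traj = run_cohort(single_group_outcome(mild_start), params_text, f0)
        alive = 1.0 - traj.occupancy[0, :, EXT_INDEX["DEAD"]]
        median = int(np.argmax(alive < 0.5))
        assert 3 <= median <= 10


class TestMicrosimulation:
    def test_same_seed_identical(self, params_text, f0):
        outcome = evaluate_pathway(PathwayId.SOC, params_text)
        a = microsimulate(outcome, params_text, f0, 500, seed=11)
        b = microsimulate(outcome, params_text, f0, 500, seed=11)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)

    def test_single_individual_is_indicator_path(self, params_text, f0):
        traj = microsimulate(
            single_group_outcome(UNTREATED_MCI_NEG), params_text, f0, 1, seed=2
        )
        sums = traj.occupancy.sum(axis=(0, 2))
        np.testing.assert_allclose(sums, 1.0)
        assert set(np.unique(traj.occupancy)) <= {0.0, 1.0}

    def test_converges_to_cohort_occupancy(self, params_text, f0):
        outcome = evaluate_pathway(PathwayId.BBM_PHC, params_text)
        cohort = run_cohort(outcome, params_text, f0).total_occupancy()
        micro = microsimulate(outcome, params_text, f0, 50_000, seed=3).total_occupancy()
        assert np.abs(micro - cohort).max() < 0.01
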