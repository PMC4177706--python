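import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olsim.model_core import (
    SCORE_MAX,
    SCORE_MIN,
    UNEARNED_AUTHORITY,
    AgentState,
    ConfigurationError,
    Motive,
    Role,
    StateError,
    Unit,
    UnitConfig,
    adoption_decision,
    announce_evidence,
    assess_announcer_credibility,
    assess_evidence,
    classify_motive,
    compute_credibility,
    credibility_doubt,
    determine_uncertainty,
    find_available_advisors,
    revise_belief,
    sample_attribute,
    seek_advice,
    update_visibility,
    visibility_threshold,
)

scores = st.floats(min_value=1.0, max_value=100.0, allow_nan=False)


def make_agent(agent_id=0, role=Role.STAFF_NURSE, prior=50.0, earned=50.0,
               motives=50.0):
    return AgentState(agent_id=agent_id, role=role, prior_belief=prior,
                      earned_authority=earned, motives=motives)


class TestSampleAttribute:
    def test_degenerate_sd_returns_mean(self, rng):
        assert sample_attribute(50.0, 0.0, rng) == 50.0

    def test_low_mean_clips_to_lower_bound(self):
        rng = np.random.default_rng(0)
        draws = [sample_attribute(1.0, 10.0, rng) for _ in range(500)]
        assert min(draws) == SCORE_MIN
        assert all(d >= SCORE_MIN for d in draws)

    def test_sample_mean_matches_normal_mean(self):
        # clipping is negligible at mean 65, sd 10
        rng = np.random.default_rng(7)
        draws = [sample_attribute(65.0, 10.0, rng) for _ in range(10_000)]
        assert abs(np.mean(draws) - 65.0) < 0.5

    @pytest.mark.parametrize("mean,sd", [(0.5, 10.0), (150.0, 10.0), (50.0, -1.0)])
    def test_invalid_parameters(self, mean, sd, rng):
        with pytest.raises(ConfigurationError):
            sample_attribute(mean, sd, rng)

    @given(mean=scores, sd=st.floats(min_value=0.0, max_value=50.0),
           seed=st.integers(min_value=0, max_value=2**31))
    @settings(max_examples=50)
    def test_always_within_score_bounds(self, mean, sd, seed):
        value = sample_attribute(mean, sd, np.random.default_rng(seed))
        assert SCORE_MIN <= value <= SCORE_MAX


class TestMotivesAndVisibility:
    def test_49_is_pragmatic(self):
        assert classify_motive(49.0) is Motive.PRAGMATIC

    def test_50_is_epistemic(self):
        assert classify_motive(50.0) is Motive.EPISTEMIC

    def test_88_is_epistemic(self):
        assert classify_motive(88.0) is Motive.EPISTEMIC

    def test_epistemic_threshold_is_70(self, default_config):
        assert visibility_threshold(88.0, default_config) == 70.0

    def test_pragmatic_threshold_is_30(self, default_config):
        assert visibility_threshold(30.0, default_config) == 30.0

    def test_boundary_motives_use_epistemic_threshold(self, default_config):
        assert visibility_threshold(50.0, default_config) == 70.0

    @pytest.mark.parametrize(
        "prior,motives,expected",
        [(75.0, 88.0, True), (70.0, 88.0, False), (35.0, 30.0, True)],
    )
    def test_update_visibility(self, prior, motives, expected, default_config):
        agent = make_agent(prior=prior, motives=motives)
        assert update_visibility(agent, default_config) is expected
        assert agent.visible is expected


class TestCredibility:
    def test_visible_weights_earned(self, default_config):
        agent = make_agent(earned=60.0)
        agent.visible = True
        assert compute_credibility(agent, default_config) == pytest.approx(58.0)

    def test_hidden_weights_unearned(self, default_config):
        agent = make_agent(earned=60.0)
        agent.visible = False
        assert compute_credibility(agent, default_config) == pytest.approx(52.0)

    def test_equal_components_ignore_weights(self, default_config):
        agent = make_agent(earned=50.0)
        for visible in (True, False):
            agent.visible = visible
            assert compute_credibility(agent, default_config) == pytest.approx(50.0)

    def test_unearned_authority_fixed_by_role(self):
        assert UNEARNED_AUTHORITY[Role.STAFF_NURSE] == 50.0
        assert UNEARNED_AUTHORITY[Role.EDUCATOR] == 80.0
        assert UNEARNED_AUTHORITY[Role.MANAGER] == 90.0
        for role in Role:
            agent = make_agent(role=role)
            assert agent.unearned_authority == UNEARNED_AUTHORITY[role]


class TestAssessments:
    def test_assess_evidence_examples(self):
        assert assess_evidence(60.0, 70.0) == 10.0
        assert assess_evidence(42.0, 42.0) == 0.0
        assert assess_evidence(1.0, 100.0) == 99.0

    def test_assess_credibility_examples(self):
        assert assess_announcer_credibility(58.0, 90.0) == 32.0
        assert assess_announcer_credibility(77.0, 77.0) == 0.0

    @given(a=scores, b=scores)
    def test_assessments_symmetric_nonnegative(self, a, b):
        assert assess_evidence(a, b) == assess_evidence(b, a) >= 0.0
        assert (
            assess_announcer_credibility(a, b)
            == assess_announcer_credibility(b, a)
            >= 0.0
        )

    def test_doubt_zero_when_source_meets_bar(self):
        assert credibility_doubt(50.0, 80.0, 65.0) == 0.0

    def test_doubt_measured_from_unit_bar(self):
        # own credibility below the bar: the bar still applies
        assert credibility_doubt(50.0, 40.0, 65.0) == 25.0

    def test_doubt_measured_from_own_standing_when_higher(self):
        assert credibility_doubt(85.0, 70.0, 65.0) == 15.0


class TestUncertaintyAndAdoption:
    def test_zero_differences_are_certain(self, default_config):
        assert determine_uncertainty(0.0, 0.0, default_config) is False

    def test_evidence_exceedance_triggers_uncertainty(self, default_config):
        assert determine_uncertainty(25.0, 0.0, default_config) is True

    def test_credibility_exceedance_triggers_uncertainty(self, default_config):
        assert determine_uncertainty(0.0, 25.0, default_config) is True

    def test_adoption_examples(self, default_config):
        assert adoption_decision(0.0, 0.0, default_config) is True
        assert adoption_decision(21.0, 0.0, default_config) is False
        assert adoption_decision(20.0, 20.0, default_config) is True

    @given(ae=st.floats(min_value=0, max_value=99), ac=st.floats(min_value=0, max_value=99))
    def test_adoption_complements_uncertainty(self, ae, ac):
        config = UnitConfig()
        assert adoption_decision(ae, ac, config) is not determine_uncertainty(
            ae, ac, config
        )


class TestReviseBelief:
    def test_fixed_point(self):
        for credibility in (1.0, 50.0, 100.0):
            assert revise_belief(60.0, 60.0, credibility) == 60.0

    def test_full_credibility_moves_to_evidence(self):
        assert revise_belief(50.0, 70.0, 100.0) == 70.0

    def test_half_credibility_moves_halfway(self):
        assert revise_belief(50.0, 70.0, 50.0) == 60.0

    @given(prior=scores, evidence=scores, credibility=scores)
    def test_result_between_prior_and_evidence(self, prior, evidence, credibility):
        new = revise_belief(prior, evidence, credibility)
        lo, hi = sorted((prior, evidence))
        assert lo - 1e-9 <= new <= hi + 1e-9
        assert SCORE_MIN <= new <= SCORE_MAX


class TestAnnounceEvidence:
    def test_single_agent_forced_choice(self, rng):
        unit = Unit(UnitConfig(n_staff=1, n_educators=0, n_managers=0), rng)
        state = announce_evidence(unit, rng)
        assert state.announcer_id == 0
        assert state.announcer_credibility == unit.agents[0].credibility

    def test_degenerate_evidence_draw(self, rng):
        unit = Unit(UnitConfig(mean_evidence=70.0, sd_evidence=0.0), rng)
        assert announce_evidence(unit, rng).announced_evidence == 70.0

    def test_announcer_counts_near_binomial_expectation(self):
        rng = np.random.default_rng(42)
        unit = Unit(UnitConfig(), rng)  # 106 agents
        counts = np.zeros(unit.n_agents, dtype=int)
        for _ in range(10_000):
            counts[announce_evidence(unit, rng).announcer_id] += 1
        assert np.all(np.abs(counts - 10_000 / 106) <= 30)

    def test_uniform_choice_chi_square(self):
        from scipy import stats

        rng = np.random.default_rng(2024)
        unit = Unit(UnitConfig(n_staff=20, n_educators=3, n_managers=1), rng)
        counts = np.zeros(unit.n_agents, dtype=int)
        for _ in range(12_000):
            counts[announce_evidence(unit, rng).announcer_id] += 1
        assert stats.chisquare(counts).pvalue > 0.01


class TestAdvisorsAndAdvice:
    def test_unattainable_threshold_gives_empty_set(self, small_unit_factory):
        unit = small_unit_factory(seed=3, credibility_threshold=100.0,
                                  mean_earned_authority=50.0)
        assert find_available_advisors(unit) == set()

    def test_all_hidden_gives_empty_set(self, rng):
        # epistemic unit with weak priors: nobody acts
        unit = Unit(
            UnitConfig(n_staff=10, n_educators=0, n_managers=0,
                       mean_prior_belief=20.0, mean_motives=90.0,
                       sd_attributes=1.0, credibility_threshold=1.0),
            rng,
        )
        assert not any(a.visible for a in unit.agents)
        assert find_available_advisors(unit) == set()

    def test_threshold_rule_is_exact(self, small_unit_factory):
        unit = small_unit_factory(seed=5)
        unit.agents[0].visible = True
        unit.agents[0].credibility = 66.0
        for agent in unit.agents[1:]:
            agent.visible = False
        assert find_available_advisors(
            unit, unit.config.replace(credibility_threshold=65.0)
        ) == {0}

    def test_empty_pool_leaves_seeker_untouched(self, small_unit_factory, rng):
        from olsim.model_core import GlobalState

        unit = small_unit_factory(seed=6)
        seeker = unit.agents[0]
        seeker.uncertain = True
        seeker.assessed_evidence = 30.0
        state = GlobalState(60.0, 1, 50.0, 0)
        assert seek_advice(seeker, set(), unit, state, rng) is None
        assert seeker.assessed_evidence == 30.0
        assert seeker.out_link_count == 0

    def test_self_only_pool_is_empty(self, small_unit_factory, rng):
        from olsim.model_core import GlobalState

        unit = small_unit_factory(seed=6)
        seeker = unit.agents[0]
        seeker.uncertain = True
        state = GlobalState(60.0, 1, 50.0, 0)
        assert seek_advice(seeker, {seeker.agent_id}, unit, state, rng) is None

    def test_single_advisor_forced_choice_and_reassessment(
        self, small_unit_factory, rng
    ):
        from olsim.model_core import GlobalState

        unit = small_unit_factory(seed=7)
        seeker, advisor = unit.agents[0], unit.agents[1]
        state = GlobalState(announced_evidence=80.0, announcer_id=5,
                           announcer_credibility=50.0, tick_index=0)
        advisor.prior_belief = 80.0  # matches the evidence exactly
        advisor.credibility = 70.0
        seeker.assessed_evidence = 40.0  # out of tolerance -> gets replaced
        seeker.credibility_doubt = 25.0
        seeker.uncertain = True
        link = seek_advice(seeker, {advisor.agent_id}, unit, state, rng)
        assert link is not None and link.advisor_id == advisor.agent_id
        assert seeker.assessed_evidence == 0.0
        assert seeker.revised_evidence_assessment is True
        assert seeker.out_link_count == 1
        assert advisor.gave_advice_count == 1

    def test_in_tolerance_assessment_not_replaced(self, small_unit_factory, rng):
        from olsim.model_core import GlobalState

        unit = small_unit_factory(seed=8)
        seeker, advisor = unit.agents[0], unit.agents[1]
        state = GlobalState(80.0, 5, 50.0, 0)
        seeker.assessed_evidence = 5.0  # fine already
        seeker.credibility_doubt = 30.0  # this is what drove uncertainty
        seeker.uncertain = True
        seek_advice(seeker, {advisor.agent_id}, unit, state, rng)
        assert seeker.assessed_evidence == 5.0
        assert seeker.revised_evidence_assessment is False
        assert seeker.revised_credibility_assessment is True


class TestTick:
    def test_generous_tolerances_mean_no_uncertainty(self, rng):
        config = UnitConfig(n_staff=20, evidence_tolerance=200.0,
                            credibility_tolerance=200.0)
        unit = Unit(config, rng)
        record = unit.tick(rng)
        assert record.need_advice == 0
        assert record.sought_advice == 0
        assert unit.links == []

    def test_identical_agents_at_evidence_all_adopt(self, rng):
        config = UnitConfig(
            n_staff=8, n_educators=0, n_managers=0,
            mean_prior_belief=60.0, mean_evidence=60.0,
            sd_attributes=0.0, sd_evidence=0.0,
            announcer_updates_self=True,
        )
        unit = Unit(config, rng)
        record = unit.tick(rng)
        assert record.revised_beliefs == 8
        assert all(a.new_belief == 60.0 for a in unit.agents)

    def test_announcer_does_not_seek_or_revise(self, rng):
        config = UnitConfig(n_staff=12, n_educators=0, n_managers=0,
                            mean_prior_belief=20.0, mean_evidence=90.0)
        unit = Unit(config, rng)
        unit.tick(rng)
        announcer = unit.agents[unit.global_state.announcer_id]
        assert announcer.out_link_count == 0
        assert announcer.revised_belief is False
        assert announcer.new_belief == announcer.prior_belief

    @pytest.mark.parametrize("seed", range(8))
    def test_count_identities(self, seed, small_unit_factory, rng):
        unit = small_unit_factory(seed=seed)
        record = unit.tick(np.random.default_rng(seed + 100))
        n = unit.n_agents
        assert record.visible + record.not_visible == n
        assert record.sought_advice <= record.need_advice
        assert sum(a.out_link_count for a in unit.agents) == sum(
            a.gave_advice_count for a in unit.agents
        )
        assert record.revised_via_evidence + record.revised_via_advice == (
            record.revised_beliefs
        )
        advisors = {a.agent_id for a in unit.agents if a.available}
        givers = {a.agent_id for a in unit.agents if a.gave_advice_count > 0}
        assert givers <= advisors
        assert advisors <= {a.agent_id for a in unit.agents if a.visible}

    def test_empty_unit_rejected(self):
        with pytest.raises(ConfigurationError):
            UnitConfig(n_staff=0, n_educators=0, n_managers=0)


class TestCommitAndReset:
    def test_commit_before_tick_is_state_error(self, small_unit_factory):
        unit = small_unit_factory(seed=1)
        with pytest.raises(StateError):
            unit.commit_and_reset()

    def test_unrevised_beliefs_bitwise_identical(self, rng):
        # tolerances force rejection of every announcement
        config = UnitConfig(n_staff=15, mean_prior_belief=20.0,
                            mean_evidence=90.0, evidence_tolerance=1.0,
                            credibility_tolerance=1.0)
        unit = Unit(config, rng)
        before = [a.prior_belief for a in unit.agents]
        record = unit.tick(rng)
        assert record.revised_beliefs == 0
        unit.commit_and_reset()
        assert [a.prior_belief for a in unit.agents] == before

    def test_revision_to_80_makes_epistemic_agent_visible(
        self, small_unit_factory, rng
    ):
        unit = small_unit_factory(seed=2)
        unit.tick(rng)
        agent = unit.agents[0]
        agent.motives = 88.0
        agent.revised_belief = True
        agent.new_belief = 80.0
        unit.commit_and_reset()
        assert agent.prior_belief == 80.0
        assert agent.visible is True

    def test_links_cleared_and_flags_reset(self, small_unit_factory):
        unit = small_unit_factory(seed=9, mean_prior_belief=30.0,
                                  mean_evidence=80.0)
        unit.tick(np.random.default_rng(9))
        unit.commit_and_reset()
        assert unit.links == []
        for a in unit.agents:
            assert a.out_link_count == 0 and a.gave_advice_count == 0
            assert not a.uncertain and not a.sought_advice
            assert not a.revised_belief
            assert a.new_belief == a.prior_belief


class TestBoundsInvariant:
    @pytest.mark.parametrize("seed", range(5))
    def test_scores_in_bounds_after_many_ticks(self, seed):
        rng = np.random.default_rng(seed)
        unit = Unit(UnitConfig(n_staff=12, n_educators=2, n_managers=1,
                               seed=seed), rng)
        for _ in range(10):
            unit.tick(rng)
            for a in unit.agents:
                for value in (a.prior_belief, a.credibility, a.new_belief):
                    assert SCORE_MIN <= value <= SCORE_MAX
            unit.commit_and_reset()


class TestAvailabilityMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_monotone(self, seed, small_unit_factory):
        unit = small_unit_factory(seed=seed)
        sizes = [
            len(find_available_advisors(unit, unit.config.replace(
                credibility_threshold=float(t))))
            for t in range(1, 101, 7)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestConvergence:
    def _uniform_unit(self, prior, evidence):
        config = UnitConfig(
            n_staff=10, n_educators=0, n_managers=0,
            mean_prior_belief=prior, mean_earned_authority=50.0,
            mean_evidence=evidence, sd_attributes=0.0, sd_evidence=0.0,
            evidence_tolerance=500.0, credibility_tolerance=500.0,
            announcer_updates_self=True,
        )
        rng = np.random.default_rng(0)
        return Unit(config, rng), rng

    def test_geometric_contraction_to_evidence(self):
        # identical staff agents: credibility pinned at 50 -> factor 0.5
        unit, rng = self._uniform_unit(prior=40.0, evidence=80.0)
        assert all(a.credibility == 50.0 for a in unit.agents)
        for t in range(1, 12):
            unit.tick(rng)
            unit.commit_and_reset()
            expected = 80.0 + (0.5 ** t) * (40.0 - 80.0)
            for a in unit.agents:
                assert a.prior_belief == pytest.approx(expected, abs=1e-9)

    def test_full_credibility_converges_in_one_tick(self):
        unit, rng = self._uniform_unit(prior=40.0, evidence=80.0)
        for a in unit.agents:
            a.credibility = 100.0
        unit.tick(rng)
        unit.commit_and_reset()
        # commit recomputes credibility, but beliefs already moved fully
        assert all(a.prior_belief == 80.0 for a in unit.agents)
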