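"""Domain types, effect conversions, bounds and joint imputation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cesize import (
    AssociationMatrix,
    AssociationScenario,
    DesignParams,
    JointCorrectionWarning,
    OutcomeSpec,
    Panel,
    correct_joint,
    frechet_bounds,
    impute_joint,
    or_to_rr,
    rr_to_or,
    select_re,
)

S = AssociationScenario


class TestEffectConversion:
    @pytest.mark.parametrize(
        ("rr", "p", "expected_or"),
        [
            (1.33, 0.023, 1.34),   # mortality row of the worked example
            (1.0, 0.3, 1.0),       # null effect is invariant
            (0.85, 0.092, 0.84),   # revascularization row
        ],
    )
    def test_rr_to_or_matches_published_conversions(self, rr, p, expected_or):
        assert rr_to_or(rr, p) == pytest.approx(expected_or, abs=0.005)

    def test_rr_to_or_exact_formula(self):
        assert rr_to_or(0.85, 0.092) == pytest.approx(0.8373, abs=1e-4)

    @pytest.mark.parametrize(
        ("odds_ratio", "p", "expected_rr"),
        [(1.34, 0.023, 1.33), (1.0, 0.5, 1.0)],
    )
    def test_or_to_rr_matches_published_conversions(self, odds_ratio, p, expected_rr):
        assert or_to_rr(odds_ratio, p) == pytest.approx(expected_rr, abs=0.005)

    @given(
        rr=st.floats(0.05, 3.0),
        p=st.floats(0.001, 0.3),
    )
    def test_round_trip_identity(self, rr, p):
        if rr * p >= 1.0:
            return
        assert or_to_rr(rr_to_or(rr, p), p) == pytest.approx(rr, rel=1e-10)

    @pytest.mark.parametrize(
        ("fn", "args"),
        [
            (rr_to_or, (0.5, 1.5)),     # control rate not a probability
            (rr_to_or, (-1.0, 0.1)),    # negative risk ratio
            (rr_to_or, (20.0, 0.5)),    # treatment rate above one
            (or_to_rr, (0.5, 0.0)),     # boundary control rate
            (or_to_rr, (0.0, 0.1)),     # zero odds ratio
        ],
    )
    def test_out_of_range_inputs_rejected(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


class TestFrechetBounds:
    @pytest.mark.parametrize(
        ("p_a", "p_b", "expected"),
        [
            (0.06, 0.10, (0.0, 0.06)),
            (0.6, 0.7, (0.3, 0.6)),
            (0.092, 0.0115, (0.0, 0.0115)),
        ],
    )
    def test_known_bounds(self, p_a, p_b, expected):
        lo, up = frechet_bounds(p_a, p_b)
        assert (lo, up) == pytest.approx(expected)

    @given(p_a=st.floats(0, 1), p_b=st.floats(0, 1))
    def test_low_never_exceeds_up(self, p_a, p_b):
        lo, up = frechet_bounds(p_a, p_b)
        assert 0.0 <= lo <= up <= 1.0

    def test_rejects_non_probabilities(self):
        with pytest.raises(ValueError):
            frechet_bounds(-0.1, 0.5)


MARGINAL_GRID = [0.001, 0.01, 0.06, 0.092, 0.25, 0.5, 0.75, 0.97]


class TestImputeJoint:
    @pytest.mark.parametrize(
        ("scenario", "p_a", "p_b", "expected"),
        [
            (S.NONE, 0.06, 0.10, 0.006),
            (S.HIGHEST, 0.092, 0.0115, 0.0115),
            # half-way between independence (0.001058) and the upper bound
            (S.MODERATE_POSITIVE, 0.092, 0.0115, 0.006279),
            # three quarters of the way toward the lower bound, here zero
            (S.STRONG_NEGATIVE, 0.092, 0.0115, 0.0002645),
        ],
    )
    def test_scenario_values(self, scenario, p_a, p_b, expected):
        assert impute_joint(p_a, p_b, scenario) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("p_a", MARGINAL_GRID)
    @pytest.mark.parametrize("p_b", MARGINAL_GRID)
    @pytest.mark.parametrize("scenario", list(S))
    def test_always_within_bounds(self, p_a, p_b, scenario):
        lo, up = frechet_bounds(p_a, p_b)
        assert lo - 1e-15 <= impute_joint(p_a, p_b, scenario) <= up + 1e-15

    @pytest.mark.parametrize("p_a", [0.05, 0.3, 0.9])
    @pytest.mark.parametrize("p_b", [0.02, 0.5])
    def test_monotone_in_scenario_strength(self, p_a, p_b):
        order = [S.LOWEST, S.STRONG_NEGATIVE, S.MODERATE_NEGATIVE, S.LOW_NEGATIVE,
                 S.NONE, S.LOW_POSITIVE, S.MODERATE_POSITIVE, S.STRONG_POSITIVE,
                 S.HIGHEST]
        joints = [impute_joint(p_a, p_b, s) for s in order]
        assert joints == sorted(joints)

    def test_independence_is_exact_product(self):
        assert impute_joint(0.123, 0.456, S.NONE) == 0.123 * 0.456

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            impute_joint(0.1, 0.2, "kind_of_positive")


class TestCorrectJoint:
    def test_out_of_bounds_replaced_by_product_with_warning(self):
        with pytest.warns(JointCorrectionWarning):
            assert correct_joint(0.06, 0.10, 0.08) == pytest.approx(0.006)

    def test_below_lower_bound_replaced(self):
        with pytest.warns(JointCorrectionWarning):
            assert correct_joint(0.6, 0.7, 0.1) == pytest.approx(0.42)

    def test_inside_bounds_untouched(self):
        assert correct_joint(0.06, 0.10, 0.05) == 0.05

    @given(
        p_a=st.floats(0.01, 0.99),
        p_b=st.floats(0.01, 0.99),
        j=st.floats(0.0, 1.0),
    )
    def test_idempotent(self, p_a, p_b, j):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", JointCorrectionWarning)
            once = correct_joint(p_a, p_b, j)
            assert correct_joint(p_a, p_b, once) == once


class TestPanelValidation:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            Panel(outcomes=[OutcomeSpec("a", 0.1, 0.5), OutcomeSpec("a", 0.2, 0.5)])

    def test_single_outcome_rejected(self):
        with pytest.raises(ValueError, match="2 to 10"):
            Panel(outcomes=[OutcomeSpec("a", 0.1, 0.5)])

    def test_eleven_outcomes_rejected(self):
        outs = [OutcomeSpec(f"o{i}", 0.1, 0.5) for i in range(11)]
        with pytest.raises(ValueError, match="2 to 10"):
            Panel(outcomes=outs)

    def test_two_relevant_flags_rejected(self):
        with pytest.raises(ValueError, match="relevant"):
            Panel(outcomes=[
                OutcomeSpec("a", 0.1, 0.5, is_relevant=True),
                OutcomeSpec("b", 0.2, 0.5, is_relevant=True),
            ])

    def test_treatment_rate_must_be_probability(self):
        with pytest.raises(ValueError, match="treatment rate"):
            OutcomeSpec("a", 0.6, 2.0)

    def test_design_alpha_beta_budget(self):
        with pytest.raises(ValueError):
            DesignParams(alpha=0.5, power=0.4)

    def test_association_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            AssociationMatrix({(1, 1): 0.1})

    def test_association_pair_normalised_to_upper_triangle(self):
        m = AssociationMatrix({(2, 0): 0.01})
        assert m.get(0, 2) == 0.01
        assert m.get(2, 0) == 0.01

    def test_missing_pair_defaults_to_independence(self):
        assert AssociationMatrix().get(0, 1) is AssociationScenario.NONE


class TestSelectRe:
    def test_lowest_ssr_outcome_wins_without_flag(self, ischemic_panel):
        # revascularization: common event, so fewest subjects needed
        idx = select_re(ischemic_panel)
        assert ischemic_panel.outcomes[idx].label == "CABG/Revascularization"

    def test_flag_overrides_ssr(self, bleeding_panel):
        idx = select_re(bleeding_panel)
        assert bleeding_panel.outcomes[idx].label == "Hematoma > 15 cm"

    def test_flag_breaks_tie_between_identical_outcomes(self):
        panel = Panel(outcomes=[
            OutcomeSpec("twin_a", 0.1, 0.5),
            OutcomeSpec("twin_b", 0.1, 0.5, is_relevant=True),
        ])
        assert select_re(panel) == 1
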