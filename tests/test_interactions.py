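"""Interaction calling: additive TSS null, multiplicative growth null,
planted-mechanism recovery, and relationship classes."""

import numpy as np
import pytest

from startshift.interactions import (
    ADDITIVE,
    EPISTASIS,
    EPISTATIC_TO_A,
    EPISTATIC_TO_B,
    EXACERBATING,
    MUTUALLY_SUPPRESSIVE,
    NO_INTERACTION,
    OTHER,
    SUPPRESSION_DIRECTIONAL,
    SUPPRESSION_MUTUAL,
    SYNTHETIC_LETHAL,
    SYNTHETIC_SICK,
    GenotypeTriple,
    GrowthInteractionCall,
    PairEvidence,
    call_growth_interaction,
    call_tss_interaction,
    classify_relationship,
    fitness_from_score,
    growth_expected_multiplicative,
    tss_expected_additive,
)
from startshift.quant import (
    TSSDistribution,
    classify_direction,
    relative_change,
    shift_index,
    ShiftProfile,
)
from startshift.scores import INVIABLE
from startshift.synthetic import ShiftModel, tilt_distribution


def profile_from_deltas(deltas, scheme, strain="mut", tolerance=0.05):
    deltas = np.asarray(deltas, dtype=float)
    deltas = deltas - deltas.mean()
    index = shift_index(deltas)
    return ShiftProfile(
        deltas=deltas,
        scheme=scheme,
        strain=strain,
        index=index,
        direction=classify_direction(index, tolerance),
        tolerance=tolerance,
    )


def binned_usage(promoter, scheme, theta):
    p = tilt_distribution(promoter, ShiftModel(theta))
    sums = np.zeros(scheme.K)
    for pos, w in zip(promoter.positions, p):
        sums[scheme.bin_of(pos)] += w
    return sums


@pytest.fixture(scope="module")
def ref_dist(promoter, scheme):
    return TSSDistribution(binned_usage(promoter, scheme, 0.0), scheme, strain="WT")


def theta_profile(promoter, scheme, ref_dist, theta, strain="mut"):
    mut = TSSDistribution(binned_usage(promoter, scheme, theta), scheme, strain=strain)
    return relative_change(mut, ref_dist, tolerance=0.05)


class TestTssExpectedAdditive:
    def test_zero_second_profile_reproduces_first_single(self, promoter, scheme, ref_dist):
        pa = theta_profile(promoter, scheme, ref_dist, -1.0, "a")
        pb = profile_from_deltas(np.zeros(6), scheme, "b")
        expected, clipped = tss_expected_additive(pa, pb, ref_dist)
        np.testing.assert_allclose(
            expected.fractions, ref_dist.fractions + pa.deltas, atol=1e-12
        )
        assert clipped == 0.0

    def test_opposite_profiles_cancel_to_reference(self, promoter, scheme, ref_dist):
        pa = theta_profile(promoter, scheme, ref_dist, -1.0, "a")
        pb = profile_from_deltas(-pa.deltas, scheme, "b")
        expected, clipped = tss_expected_additive(pa, pb, ref_dist)
        np.testing.assert_allclose(expected.fractions, ref_dist.fractions, atol=1e-12)
        assert clipped == 0.0

    def test_clipping_and_renormalization_hand_computed(self, scheme):
        ref = TSSDistribution(np.array([0.1, 0.3, 0.3, 0.1, 0.1, 0.1]), scheme)
        da = np.array([-0.08, 0.02, 0.02, 0.02, 0.01, 0.01])
        db = np.array([-0.08, 0.02, 0.02, 0.02, 0.01, 0.01])
        pa = profile_from_deltas(da, scheme, "a")
        pb = profile_from_deltas(db, scheme, "b")
        raw = ref.fractions + da + db          # bin 1: 0.1 - 0.16 = -0.06
        clipped_hand = 0.06
        exp_hand = np.clip(raw, 0, None)
        exp_hand = exp_hand / exp_hand.sum()
        expected, clipped = tss_expected_additive(pa, pb, ref)
        assert clipped == pytest.approx(clipped_hand)
        np.testing.assert_allclose(expected.fractions, exp_hand, atol=1e-12)
        assert expected.fractions.sum() == pytest.approx(1.0)


class TestCallTssInteraction:
    def make_triple(self, scheme, da, db, dab):
        return GenotypeTriple(
            a="A", b="B", ab="AB",
            profile_a=profile_from_deltas(da, scheme, "A"),
            profile_b=profile_from_deltas(db, scheme, "B"),
            profile_ab=profile_from_deltas(dab, scheme, "AB"),
        )

    def test_planted_mechanisms_recovered(self, promoter, scheme, ref_dist):
        """Factorial planted-truth recovery: mechanism x polarity x noise,
        200 seeds per cell; >=90% correct at delta-noise sd <= 0.01."""
        da = theta_profile(promoter, scheme, ref_dist, -1.0, "A").deltas
        table = {}
        cell_id = 0
        for polarity, theta_b in (("same", -1.0), ("opposite", 1.0)):
            db = theta_profile(promoter, scheme, ref_dist, theta_b, "B").deltas
            for mech, base in (("additive", da + db), ("epistatic_to_A", da)):
                for sd in (0.0, 0.01):
                    cell_id += 1
                    hits = 0
                    for child in np.random.SeedSequence(
                        77, spawn_key=(cell_id,)
                    ).spawn(200):
                        noise = np.random.default_rng(child).normal(0, sd, 6)
                        triple = self.make_triple(scheme, da, db, base + noise)
                        call = call_tss_interaction(triple, tolerance=0.15)
                        want = ADDITIVE if mech == "additive" else EPISTATIC_TO_A
                        hits += call.category == want
                    table[(polarity, mech, sd)] = hits / 200
        for cell, rate in sorted(table.items()):
            print(f"tss-call calibration {cell}: {rate:.1%}")
        assert all(rate >= 0.9 for rate in table.values())

    def test_sub1_style_exact_epistasis(self, promoter, scheme, ref_dist):
        # double's profile identical to the Pol II single's, interactor's not
        da = theta_profile(promoter, scheme, ref_dist, -0.8, "A").deltas
        db = theta_profile(promoter, scheme, ref_dist, 0.8, "B").deltas
        call = call_tss_interaction(self.make_triple(scheme, da, db, da), tolerance=0.15)
        assert call.category == EPISTATIC_TO_A
        assert call.d_a == pytest.approx(0.0)

    def test_opposite_singles_with_additive_double_mutually_suppressive(
        self, promoter, scheme, ref_dist
    ):
        da = theta_profile(promoter, scheme, ref_dist, -1.0, "A").deltas
        db = theta_profile(promoter, scheme, ref_dist, 1.0, "B").deltas
        call = call_tss_interaction(self.make_triple(scheme, da, db, da + db), tolerance=0.15)
        assert call.category == ADDITIVE
        assert call.polarity == MUTUALLY_SUPPRESSIVE

    def test_same_direction_additive_double_exacerbating(self, promoter, scheme, ref_dist):
        da = theta_profile(promoter, scheme, ref_dist, -0.6, "A").deltas
        db = theta_profile(promoter, scheme, ref_dist, -0.8, "B").deltas
        call = call_tss_interaction(self.make_triple(scheme, da, db, da + db), tolerance=0.15)
        assert call.category == ADDITIVE
        assert call.polarity == EXACERBATING

    def test_symmetric_under_swap(self, promoter, scheme, ref_dist):
        da = theta_profile(promoter, scheme, ref_dist, -0.8, "A").deltas
        db = theta_profile(promoter, scheme, ref_dist, 0.5, "B").deltas
        fwd = call_tss_interaction(self.make_triple(scheme, da, db, da), tolerance=0.15)
        rev = call_tss_interaction(self.make_triple(scheme, db, da, da), tolerance=0.15)
        assert fwd.category == EPISTATIC_TO_A and rev.category == EPISTATIC_TO_B
        assert fwd.d_additive == pytest.approx(rev.d_additive)

    def test_far_from_every_null_is_other(self, scheme):
        da = np.array([0.3, -0.3, 0, 0, 0, 0])
        db = np.array([0, 0, 0.3, -0.3, 0, 0])
        dab = np.array([0, 0, 0, 0, 0.4, -0.4])
        call = call_tss_interaction(self.make_triple(scheme, da, db, dab), tolerance=0.15)
        assert call.category == OTHER

    def test_exact_tie_resolves_to_additive(self, scheme):
        # deltaB = 0 makes the additive and epistatic-to-A nulls coincide
        da = np.array([0.2, -0.2, 0, 0, 0, 0])
        call = call_tss_interaction(
            self.make_triple(scheme, da, np.zeros(6), da), tolerance=0.15
        )
        assert call.d_additive == call.d_a
        assert call.category == ADDITIVE

    def test_missing_profile_rejected(self, scheme):
        triple = GenotypeTriple(a="A", b="B", ab="AB")
        with pytest.raises(ValueError, match="profile"):
            call_tss_interaction(triple)


class TestGrowthExpected:
    def test_wt_factor_identity(self):
        assert growth_expected_multiplicative(1.0, 0.37) == pytest.approx(0.37)

    def test_product_and_commutativity(self):
        assert growth_expected_multiplicative(0.8, 0.6) == pytest.approx(0.48)
        assert growth_expected_multiplicative(0.6, 0.8) == pytest.approx(0.48)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            growth_expected_multiplicative(1.2, 0.5)


class TestCallGrowthInteraction:
    def make(self, fa, fb, fab=None, inviable=False):
        return GenotypeTriple(
            a="A", b="B", ab="AB",
            fitness_a=fa, fitness_b=fb,
            fitness_ab=0.0 if inviable else fab,
            ab_inviable=inviable,
        )

    def test_exact_multiplicative_is_no_interaction(self):
        call = call_growth_interaction(self.make(0.6, 0.6, 0.36), tau=0.05)
        assert call.category == NO_INTERACTION
        assert call.expected == pytest.approx(0.36)

    def test_inviable_double_with_viable_expectation_is_lethal(self):
        call = call_growth_interaction(self.make(0.8, 0.8, inviable=True), tau=0.1)
        assert call.category == SYNTHETIC_LETHAL

    def test_below_expectation_is_sick(self):
        assert call_growth_interaction(self.make(0.8, 0.8, 0.2)).category == SYNTHETIC_SICK

    def test_double_better_than_both_singles_is_mutual_suppression(self):
        assert (
            call_growth_interaction(self.make(0.5, 0.5, 0.9)).category
            == SUPPRESSION_MUTUAL
        )

    def test_double_matching_one_single_is_epistasis(self):
        assert call_growth_interaction(self.make(0.8, 0.6, 0.8)).category == EPISTASIS

    def test_fitness_from_score_mapping(self):
        assert fitness_from_score(3) == (0.6, False)
        assert fitness_from_score(INVIABLE) == (0.0, True)

    def test_planted_epsilon_grid_recovery(self):
        """Category recovery >=90% per planted epsilon with score rounding;
        epsilon = 0 yields no_interaction in >=95% of runs."""
        from startshift.scores import INVIABLE as IV
        from startshift.synthetic import GrowthModel, simulate_growth_panel

        truth = {
            -2.0: {SYNTHETIC_SICK, SYNTHETIC_LETHAL},
            0.0: {NO_INTERACTION},
            1.0: {SUPPRESSION_MUTUAL, EPISTASIS, SUPPRESSION_DIRECTIONAL},
        }
        grid = (0.4, 0.6, 0.8)
        rates = {}
        for eps, accepted in truth.items():
            hits = 0
            rng = np.random.default_rng(314)
            for _ in range(200):
                fa, fb = rng.choice(grid), rng.choice(grid)
                model = GrowthModel(
                    fitness={"WT": {"default": 1.0}, "A": {"default": fa}, "B": {"default": fb}},
                    doubles={"AB": ("A", "B")},
                    epsilon={frozenset(("A", "B")): {"default": eps}},
                    wt="WT",
                    permissive_medium="YPD",
                )
                panel = simulate_growth_panel(
                    model, ["WT", "A", "B", "AB"], ["YPD"], seed=int(rng.integers(2**31))
                )
                fab, inviable = fitness_from_score(panel.score("AB", "YPD"))
                call = call_growth_interaction(
                    self.make(fa, fb, fab, inviable=inviable), tau=0.1
                )
                hits += call.category in accepted
            rates[eps] = hits / 200
            print(f"growth-call calibration eps={eps:+.0f}: {rates[eps]:.1%}")
        assert all(rate >= 0.9 for rate in rates.values())
        assert rates[0.0] >= 0.95


class TestClassifyRelationship:
    def growth(self, category):
        return GrowthInteractionCall(
            a="P", b="X", ab="PX", category=category, expected=0.5, observed=0.4, tau=0.1
        )

    def tss(self, category, d_a=0.3, polarity=MUTUALLY_SUPPRESSIVE):
        from startshift.interactions import TSSInteractionCall

        return TSSInteractionCall(
            a="P", b="X", ab="PX", category=category, polarity=polarity,
            d_additive=0.01, d_a=d_a, d_b=0.3, tolerance=0.15,
        )

    def own(self, scheme, index):
        deltas = np.zeros(6)
        deltas[0], deltas[-1] = -index / 5.0, index / 5.0
        return profile_from_deltas(deltas, scheme)

    def test_gtf_style_panel_is_class_one(self, scheme):
        panel = [
            PairEvidence("gof", tss=self.tss(ADDITIVE, polarity=EXACERBATING),
                         growth=self.growth(SYNTHETIC_SICK), pol2_class="gof"),
            PairEvidence("lof", tss=self.tss(ADDITIVE),
                         growth=self.growth(NO_INTERACTION), pol2_class="lof"),
        ]
        rc = classify_relationship("gtf", self.own(scheme, -1.0), panel)
        assert rc.cls == "I"

    def test_sub1_style_panel_is_class_two(self, scheme):
        panel = [
            PairEvidence("gof", tss=self.tss(EPISTATIC_TO_A, d_a=0.01),
                         growth=self.growth(EPISTASIS), pol2_class="gof"),
            PairEvidence("lof", tss=self.tss(ADDITIVE, polarity=EXACERBATING),
                         growth=self.growth(SYNTHETIC_SICK), pol2_class="lof"),
        ]
        rc = classify_relationship("sub1", self.own(scheme, 1.0), panel)
        assert rc.cls == "II"

    def test_interactor_style_panel_is_class_three(self, scheme):
        panel = [
            PairEvidence("gof", tss=self.tss(ADDITIVE, d_a=0.02),
                         growth=self.growth(SYNTHETIC_SICK)),
            PairEvidence("lof", tss=self.tss(ADDITIVE, d_a=0.03),
                         growth=self.growth(NO_INTERACTION)),
        ]
        rc = classify_relationship("dst1", self.own(scheme, 0.0), panel)
        assert rc.cls == "III"

    def test_empty_panel_rejected(self, scheme):
        with pytest.raises(ValueError, match="no TSS evidence"):
            classify_relationship("x", self.own(scheme, 0.0), [])

    def test_no_own_defect_with_modulation_is_unclassified(self, scheme):
        panel = [PairEvidence("gof", tss=self.tss(OTHER, d_a=0.4),
                              growth=self.growth(SYNTHETIC_SICK))]
        rc = classify_relationship("x", self.own(scheme, 0.0), panel)
        assert rc.cls == "unclassified"
        assert rc.evidence
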