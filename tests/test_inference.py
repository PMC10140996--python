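"""Strain typing, haplotype deduction, segregation tests, model selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from auricolor.core import (
    Color,
    DEFAULT_CANDIDATE_MODELS,
    DUPLICATE_RECESSIVE,
    SINGLE_LOCUS_A,
    HaplotypeClass,
    StrainType,
)
from auricolor.inference import (
    AmbiguousHaplotypeError,
    ClassificationRecord,
    ColorInheritance,
    InconsistentObservationsError,
    PopulationCounts,
    UnclassifiableError,
    chi_square_segregation,
    classify_color_type,
    classify_strain_type,
    deduce_tester_haplotype,
    estimate_recombination,
    infer_haplotype_class,
    select_model,
    solve_haplotype_class,
)
from auricolor.synth import StudyConfig, generate_study


def oracle_consistent_classes(observations):
    """Brute-force truth-table oracle, independent of the library path."""
    out = set()
    for cand in "AB Ab aB ab".split():
        ok = True
        for tester, color in observations:
            a = "A" in (cand[0], tester.value[0])
            b = "B" in (cand[1], tester.value[1])
            purple = a and b
            if purple != (color is Color.PURPLE):
                ok = False
                break
        if ok:
            out.add(HaplotypeClass(cand))
    return out


class TestClassification:
    def test_purple_testcross_is_p(self):
        rec = ClassificationRecord("s", testcross_color=Color.PURPLE)
        assert classify_color_type(rec) == "P"

    def test_white_testcross_is_w(self):
        rec = ClassificationRecord("s", testcross_color=Color.WHITE)
        assert classify_color_type(rec) == "W"

    def test_missing_testcross_unclassifiable(self):
        rec = ClassificationRecord("s", backcross_color=Color.WHITE)
        with pytest.raises(UnclassifiableError):
            classify_color_type(rec)

    def test_no_observation_at_all_rejected(self):
        with pytest.raises(ValueError):
            ClassificationRecord("s")

    @pytest.mark.parametrize(
        "pw,color,expected",
        [
            ("P", Color.PURPLE, StrainType.PD),
            ("P", Color.WHITE, StrainType.PR),
            ("W", Color.WHITE, StrainType.WD),
            ("W", Color.PURPLE, StrainType.WR),
        ],
    )
    def test_four_types(self, pw, color, expected):
        assert classify_strain_type(pw, {"t23": color}) is expected

    def test_disagreeing_testers_flagged_inconsistent(self):
        st_ = classify_strain_type(
            "P", {"t23": Color.PURPLE, "t51": Color.WHITE}
        )
        assert st_ is StrainType.INCONSISTENT

    def test_no_tester_observation_is_ambiguous(self):
        assert classify_strain_type("P", {"t23": None}) is StrainType.AMBIGUOUS


class TestHaplotypeInference:
    @pytest.mark.parametrize(
        "stype,expected",
        [
            (StrainType.PD, "AB"),
            (StrainType.PR, "aB"),
            (StrainType.WD, "ab"),
            (StrainType.WR, "Ab"),
        ],
    )
    def test_study_tester_assignment(self, stype, expected):
        assert infer_haplotype_class(stype).value == expected

    def test_not_a_lookup_other_testers_shift_solution(self):
        # swap tester roles: primary aB, recombinant Ab -> Pr must solve to Ab
        classes = {"primary": HaplotypeClass.aB, "recombinant": HaplotypeClass.Ab}
        assert infer_haplotype_class(StrainType.PR, classes) is HaplotypeClass.Ab

    def test_ambiguous_and_inconsistent_types_rejected(self):
        with pytest.raises(ValueError):
            infer_haplotype_class(StrainType.AMBIGUOUS)

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(list(HaplotypeClass)),
                st.sampled_from([Color.PURPLE, Color.WHITE]),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_solver_agrees_with_bruteforce_oracle(self, observations):
        assert set(
            solve_haplotype_class(observations, DUPLICATE_RECESSIVE)
        ) == oracle_consistent_classes(observations)


class TestTesterDeduction:
    def test_ab_strains_purple_only_with_fully_dominant_tester(self):
        got = deduce_tester_haplotype([(HaplotypeClass.ab, Color.PURPLE)])
        assert got is HaplotypeClass.AB

    def test_study_deduction_of_single_dominant_tester(self):
        # aB strains purple with the unknown tester, white with ab -> Ab
        got = deduce_tester_haplotype(
            [
                (HaplotypeClass.aB, Color.PURPLE),
                (HaplotypeClass.ab, Color.WHITE),
            ]
        )
        assert got is HaplotypeClass.Ab

    def test_uninformative_observations_report_candidates(self):
        with pytest.raises(AmbiguousHaplotypeError) as exc:
            deduce_tester_haplotype([(HaplotypeClass.ab, Color.WHITE)])
        assert exc.value.candidates == {
            HaplotypeClass.ab, HaplotypeClass.Ab, HaplotypeClass.aB
        }

    def test_contradiction_reported(self):
        with pytest.raises(InconsistentObservationsError):
            deduce_tester_haplotype(
                [
                    (HaplotypeClass.AB, Color.WHITE),
                ]
            )


class TestRecombinationEstimate:
    def test_printed_counts_give_377(self):
        est = estimate_recombination({"AB": 14, "aB": 7, "ab": 24, "Ab": 16})
        assert est.n_recombinant == 23 and est.n_total == 61
        assert est.r_hat == pytest.approx(23 / 61)
        assert est.r_hat == pytest.approx(0.377, abs=5e-4)

    def test_exact_ci_and_unlinked_verdict(self):
        est = estimate_recombination({"AB": 14, "aB": 7, "ab": 24, "Ab": 16})
        assert est.ci[0] == pytest.approx(0.2561, abs=1e-3)
        assert est.ci[1] == pytest.approx(0.5104, abs=1e-3)
        assert est.ci[0] <= est.r_hat <= est.ci[1]
        assert not est.linked  # r=0.5 not rejected at alpha=0.05

    def test_no_recombinants(self):
        est = estimate_recombination({"AB": 10, "ab": 10, "Ab": 0, "aB": 0})
        assert est.r_hat == 0.0 and est.linked

    def test_opposite_phase(self):
        est = estimate_recombination(
            {"AB": 2, "ab": 2, "Ab": 8, "aB": 8},
            parental_phase=("Ab", "aB"),
        )
        assert est.r_hat == pytest.approx(0.2)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            estimate_recombination({"AB": 0})

    def test_ci_coverage_under_simulation(self):
        # 200 mapping populations of n=61 at the true r; the exact 95% CI
        # must cover truth in at least 90% of runs
        r_true = 0.377
        rng = np.random.default_rng(2024)
        probs = [(1 - r_true) / 2, (1 - r_true) / 2, r_true / 2, r_true / 2]
        covered = 0
        for _ in range(200):
            ab, ab2, Ab, aB = rng.multinomial(61, probs)
            est = estimate_recombination(
                {"AB": ab, "ab": ab2, "Ab": Ab, "aB": aB}
            )
            if est.ci[0] <= r_true <= est.ci[1]:
                covered += 1
        assert covered >= 180


class TestChiSquare:
    def test_backcross_counts_consistent_with_3_1(self):
        res = chi_square_segregation([25, 8], (3, 1))
        assert res.chi2 == pytest.approx(0.010101, abs=1e-5)
        assert res.p == pytest.approx(0.9199, abs=1e-3)
        assert res.verdict == "consistent"

    def test_mating_type_distortion_detected(self):
        res = chi_square_segregation([54, 33], (1, 1))
        assert res.chi2 == pytest.approx(5.0690, abs=1e-3)
        assert res.p == pytest.approx(0.02436, abs=1e-4)
        assert res.distorted

    def test_exact_proportion_gives_zero(self):
        res = chi_square_segregation([30, 10], (3, 1))
        assert res.chi2 == 0.0 and res.verdict == "consistent"

    def test_yates_correction_flag(self):
        plain = chi_square_segregation([54, 33], (1, 1))
        corrected = chi_square_segregation([54, 33], (1, 1), yates=True)
        assert corrected.chi2 < plain.chi2

    def test_arity_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chi_square_segregation([1, 2, 3], (1, 1))

    def test_type_i_error_rate(self):
        # simulate true 1:1 draws (n=87) and check the alpha=0.05 rejection rate
        rng = np.random.default_rng(7)
        ks = rng.binomial(87, 0.5, size=5000)
        rejections = sum(
            chi_square_segregation([int(k), int(87 - k)], (1, 1)).distorted
            for k in ks
        )
        assert abs(rejections / 5000 - 0.05) <= 0.01


class TestSelectModel:
    def test_grid_counts_prefer_duplicate_recessive(self):
        pops = [
            PopulationCounts(
                design="f2_random_union",
                counts={Color.PURPLE: 9, Color.WHITE: 7},
            )
        ]
        fits = select_model(pops, DEFAULT_CANDIDATE_MODELS)
        assert fits[0].model.name == "duplicate_recessive"

    def test_simulated_single_locus_testcross_prefers_single_locus(self):
        # 200 progeny of a single-locus test-cross: ~1:1 on A only
        rng = np.random.default_rng(55)
        k = rng.binomial(200, 0.5)
        pops = [
            PopulationCounts(
                design="test_cross",
                counts={Color.PURPLE: int(k), Color.WHITE: int(200 - k)},
                tester=HaplotypeClass.ab,
            )
        ]
        fits = select_model(pops, [DUPLICATE_RECESSIVE, SINGLE_LOCUS_A])
        assert fits[0].model.name == "single_locus_A"

    def test_degenerate_all_white_flagged_poor(self):
        pops = [
            PopulationCounts(
                design="back_cross",
                counts={Color.PURPLE: 0, Color.WHITE: 50},
                tester=HaplotypeClass.ab,
            )
        ]
        fits = select_model(pops, [DUPLICATE_RECESSIVE, SINGLE_LOCUS_A])
        assert all(not f.adequate for f in fits)


class TestEndToEnd:
    def test_full_recovery_at_fruiting_rate_one(self, ideal_bundle):
        model = ColorInheritance.from_bundle(ideal_bundle)
        res = model.fit()
        truth = dict(
            zip(
                ideal_bundle.truth["strain_id"],
                ideal_bundle.truth["haplotype_class"],
            )
        )
        tab = res.strain_table
        assert tab["haplotype_class"].notna().all()
        assert all(
            truth[sid] == hc
            for sid, hc in zip(tab["strain_id"], tab["haplotype_class"])
        )

    def test_results_serialise(self, default_bundle):
        res = ColorInheritance.from_bundle(default_bundle).fit()
        d = res.to_dict()
        assert set(d) >= {
            "strains", "class_counts", "segregation_tests", "model_ranking",
        }
        assert "Colour-inheritance analysis" in res.summary()
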