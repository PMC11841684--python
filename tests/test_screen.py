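"""Modifier screen: grouping, divergence, filtering, segregation, ranking."""

import itertools

import numpy as np
import pytest

from ebsmod.cohort import GenotypeMatrix, Severity, VariantRecord, PredictorCall
from ebsmod.screen import (
    Pattern,
    ScreenConfig,
    aggregate_candidates,
    detect_divergence,
    filter_candidates,
    group_by_causative,
    population_carrier_scan,
    run_screen,
    test_cosegregation,
)
from ebsmod.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_population,
    variant_key_str,
)

from conftest import make_single_family_cohort


def exhaustive_segregation_p(carrier_flags, severe_flags):
    """Independent oracle: enumerate all severity relabelings preserving the
    severe count; p = fraction with discordance <= observed (no smoothing)."""
    n = len(carrier_flags)
    s = sum(severe_flags)
    carriers = {i for i, c in enumerate(carrier_flags) if c}

    def discordance(severe_set):
        return len(severe_set - carriers) + len(carriers - severe_set)

    d_obs = discordance({i for i, x in enumerate(severe_flags) if x})
    hits = total = 0
    for combo in itertools.combinations(range(n), s):
        total += 1
        hits += discordance(set(combo)) <= d_obs
    return hits / total


class TestGroupByCausative:
    def test_paper_fixture_groups(self, paper_cohort):
        cohort, _ = paper_cohort
        groups = group_by_causative(cohort)
        assert len(groups) == 3
        by_fams = {tuple(sorted(g.family_ids)): g for g in groups}
        founder = by_fams[("F3", "F4")]
        assert len(founder.patient_ids) == 10
        assert len(by_fams[("F1",)].patient_ids) == 5
        assert len(by_fams[("F2",)].patient_ids) == 5

    def test_singleton_cohort_yields_no_groups(self):
        cohort, _ = make_single_family_cohort([True], [True])
        # group has one affected patient only -> dropped
        assert group_by_causative(cohort) == []

    def test_matches_brute_force_enumeration(self):
        """Pairwise O(n^2) oracle over affected carriers of each causative key."""
        cohort, _ = simulate_cohort(SimulationConfig(seed=13, n_families=10))
        groups = group_by_causative(cohort)
        # oracle: scan every affected sample against every causative key
        need = {c.variant_key: c.inheritance.required_dosage for c in cohort.causative}
        oracle: dict = {}
        for key, nd in need.items():
            carriers = set()
            for ped in cohort.pedigrees:
                for m in ped.members:
                    if m.affected and cohort.genotypes.dosage(key, m.individual_id) >= nd:
                        carriers.add(m.individual_id)
            if len(carriers) >= 2:
                oracle[key] = carriers
        assert {g.causative_key: set(g.patient_ids) for g in groups} == oracle


class TestDetectDivergence:
    def test_paper_fixture_all_divergent_three_severe(self, paper_cohort):
        cohort, _ = paper_cohort
        calls = detect_divergence(group_by_causative(cohort), cohort)
        assert all(c.divergent for c in calls)
        severe_union = set().union(*[c.severe_ids for c in calls])
        assert severe_union == {"F1-III-1", "F2-II-6", "F4-II-2"}

    def test_all_mild_group_not_divergent(self):
        cohort, _ = make_single_family_cohort([True, False, True], [False, False, False])
        calls = detect_divergence(group_by_causative(cohort), cohort)
        assert len(calls) == 1 and not calls[0].divergent

    def test_severe_set_matches_planted_truth(self):
        cohort, truth = simulate_cohort(SimulationConfig(seed=21))
        calls = detect_divergence(group_by_causative(cohort), cohort)
        severe_union = set().union(*[set(c.severe_ids) for c in calls])
        assert severe_union == set(truth.affected_carrier_ids)


class TestFilterCandidates:
    def test_paper_fixture_filtering(self, paper_cohort):
        cohort, expected = paper_cohort
        kept = filter_candidates(cohort.variants, cohort.disease_genes, ScreenConfig())
        assert {v.key for v in kept} == expected["candidate_keys"]

    def test_common_variant_excluded(self):
        v = VariantRecord("1", 1, "A", "G", gene="X", population_af=0.2,
                          predictor_scores={p: PredictorCall.DELETERIOUS for p in "ABCDE"})
        assert filter_candidates([v], set(), ScreenConfig()) == []

    def test_missing_af_passes_with_predictor_consensus(self):
        v = VariantRecord("1", 1, "A", "G", gene="X", population_af=None,
                          predictor_scores={p: PredictorCall.DELETERIOUS for p in "ABC"})
        assert filter_candidates([v], set(), ScreenConfig()) == [v]

    def test_insufficient_predictor_consensus_excluded(self):
        scores = {
            "A": PredictorCall.DELETERIOUS,
            "B": PredictorCall.DELETERIOUS,
            "C": PredictorCall.TOLERATED,
        }
        v = VariantRecord("1", 1, "A", "G", gene="X", population_af=1e-5,
                          predictor_scores=scores)
        assert filter_candidates([v], set(), ScreenConfig()) == []


class TestCosegregation:
    def _seg(self, carriers, severe, config=None):
        cohort, cand_key = make_single_family_cohort(carriers, severe)
        calls = detect_divergence(group_by_causative(cohort), cohort)
        return test_cosegregation(cand_key, calls[0], cohort, config or ScreenConfig())

    def test_perfect_pattern_on_paper_family4_variant(self, paper_cohort):
        cohort, _ = paper_cohort
        calls = detect_divergence(group_by_causative(cohort), cohort)
        founder_call = next(c for c in calls if c.group.family_ids == {"F3", "F4"})
        res = test_cosegregation(
            ("1", 185995800, "C", "T"), founder_call, cohort, ScreenConfig()
        )
        assert res.pattern is Pattern.PERFECT

    def test_variant_in_every_member_carries_no_information(self):
        res = self._seg([True] * 5, [True, False, False, False, False])
        assert res.pattern is Pattern.NONE
        assert res.p_perm == 1.0

    def test_absent_variant(self):
        res = self._seg([False] * 4, [True, False, False, False])
        assert res.pattern is Pattern.NONE and res.p_perm == 1.0

    def test_permutation_matches_exhaustive_oracle(self):
        """5 affected, 1 severe, carrier set = {severe}: exact p = 1/5."""
        carriers = [True, False, False, False, False]
        severe = [True, False, False, False, False]
        exact = exhaustive_segregation_p(carriers, severe)
        assert exact == pytest.approx(1 / 5)
        res = self._seg(carriers, severe, ScreenConfig(permutations=10_000, seed=0))
        assert res.pattern is Pattern.PERFECT
        assert abs(res.p_perm - exact) < 2 * np.sqrt(exact * (1 - exact) / 10_000)

    @pytest.mark.parametrize(
        "carriers, severe",
        [
            ([True, True, False, False, False, False], [True, False, True, False, False, False]),
            ([True, True, True, False, False], [True, True, False, False, False]),
            ([True, False, False, False], [False, True, False, False]),
        ],
    )
    def test_partial_patterns_match_oracle(self, carriers, severe):
        exact = exhaustive_segregation_p(carriers, severe)
        res = self._seg(carriers, severe, ScreenConfig(permutations=20_000, seed=1))
        assert res.pattern is Pattern.PARTIAL
        sd = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(res.p_perm - exact) < max(3 * sd, 2e-3)

    def test_p_monotone_in_discordance(self):
        """A more discordant carrier pattern never gets a smaller p."""
        severe = [True, True, False, False, False, False]
        patterns = [
            [True, True, False, False, False, False],   # d = 0
            [True, False, False, False, False, False],  # d = 1
            [True, False, True, False, False, False],   # d = 2
            [False, False, True, True, False, False],   # d = 4
        ]
        ps = [
            self._seg(c, severe, ScreenConfig(permutations=5000, seed=2)).p_perm
            for c in patterns
        ]
        assert ps == sorted(ps)
        assert all(0 < p <= 1 for p in ps)


class TestAggregateAndScreen:
    def test_paper_fixture_reports_three_candidates_over_four_families(self, paper_cohort):
        cohort, expected = paper_cohort
        report = run_screen(cohort, ScreenConfig(seed=0))
        assert len(report.candidates) == expected["n_candidate_modifiers"] == 3
        assert {c.variant_key for c in report.candidates} == expected["candidate_keys"]
        assert all(c.gene == "HMCN1" for c in report.candidates)
        fams = set().union(
            *[s.group.family_ids for c in report.candidates for s in c.supporting_groups]
        )
        assert len(fams) == expected["n_supporting_families"] == 4

    def test_no_divergence_no_candidates(self):
        cohort, _ = make_single_family_cohort([True, False, True], [False, False, False])
        report = run_screen(cohort, ScreenConfig(seed=0))
        assert report.candidates == ()

    def test_planted_modifier_ranks_first(self):
        cohort, truth = simulate_cohort(SimulationConfig(seed=17))
        report = run_screen(cohort, ScreenConfig(seed=17))
        assert report.candidates[0].variant_key == truth.modifier_variant_key
        assert report.candidates[0].rank == 1

    def test_screen_invariant_to_row_and_sample_order(self):
        cohort, _ = simulate_cohort(SimulationConfig(seed=23, n_background_variants=40))
        rng = np.random.default_rng(0)
        vperm = rng.permutation(len(cohort.genotypes.variants))
        sperm = rng.permutation(len(cohort.genotypes.samples))
        shuffled = GenotypeMatrix(
            [cohort.genotypes.variants[i] for i in vperm],
            [cohort.genotypes.samples[j] for j in sperm],
            cohort.genotypes.dosages[np.ix_(vperm, sperm)],
        )
        import dataclasses

        reordered = dataclasses.replace(
            cohort,
            genotypes=shuffled,
            variants=tuple(cohort.variants[i] for i in vperm),
        )
        a = run_screen(cohort, ScreenConfig(seed=3))
        b = run_screen(reordered, ScreenConfig(seed=3))
        assert [(c.variant_key, c.rank, c.combined_p) for c in a.candidates] == [
            (c.variant_key, c.rank, c.combined_p) for c in b.candidates
        ]

    def test_report_serialization(self, paper_cohort, tmp_path):
        cohort, _ = paper_cohort
        report = run_screen(cohort, ScreenConfig(seed=0))
        paths = report.write(tmp_path / "report")
        assert paths["json"].exists()
        text = paths["candidates"].read_text()
        assert "HMCN1" in text


class TestPopulationCarrierScan:
    def test_small_panel_counts(self):
        key = ("1", 5, "C", "T")
        table = simulate_population(10, {variant_key_str(key): 0.0}, seed=0)
        table[variant_key_str(key)] = [1, 0, 0, 1, 0, 0, 0, 0, 0, 0]
        scan = population_carrier_scan([key], table)
        assert scan.counts[key] == 2
        assert scan.total_distinct_carriers == 2

    def test_unassayed_candidate_reported(self):
        table = simulate_population(10, {"1:5:C:T": 0.1}, seed=0)
        missing = ("9", 9, "A", "T")
        scan = population_carrier_scan([missing], table)
        assert scan.not_assayed == (missing,)
        assert scan.total_distinct_carriers == 0

    def test_carrier_count_matches_binomial_expectation(self):
        key = ("1", 5, "C", "T")
        af, n = 0.004, 8011
        table = simulate_population(n, {variant_key_str(key): af}, seed=7)
        scan = population_carrier_scan([key], table)
        p_carrier = 1 - (1 - af) ** 2
        mu = n * p_carrier
        assert abs(scan.counts[key] - mu) < 3 * np.sqrt(mu * (1 - p_carrier))
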