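"""Synthetic-data generators: determinism, Mendelian rules, planted truth."""

import numpy as np
import pytest

from ebsmod.cohort import (
    Inheritance,
    Severity,
    read_disease_genes,
    read_pedigrees,
    read_phenotypes,
    read_variants,
    validate_cohort,
)
from ebsmod.geometry import angle_series, read_pdb_trajectory, read_xyz_trajectory
from ebsmod.simulate import (
    MODIFIER_KEY,
    SimulationConfig,
    SimulationError,
    TrajectorySimSpec,
    read_causative_toml,
    simulate_cohort,
    simulate_pedigree,
    simulate_population,
    simulate_trajectory,
    variant_key_str,
    write_fixture,
)
from ebsmod.cohort import encode_paper_cohort


class TestSimulatePedigree:
    def test_fixed_children_range(self):
        cfg = SimulationConfig(children_per_family=(3, 3), seed=1)
        ped = simulate_pedigree(cfg, 0)
        assert len(ped.members) == 5
        assert sum(m.is_founder for m in ped.members) == 2

    def test_deterministic(self):
        cfg = SimulationConfig(seed=7)
        assert simulate_pedigree(cfg, 4) == simulate_pedigree(cfg, 4)

    def test_child_count_distribution(self):
        """Uniform sampler over [2,6]: counts in range, mean near midpoint."""
        cfg = SimulationConfig(children_per_family=(2, 6), seed=11, n_families=100)
        counts = [
            len(simulate_pedigree(cfg, i).members) - 2 for i in range(100)
        ]
        assert min(counts) >= 2 and max(counts) <= 6
        # uniform on {2..6}: mean 4, var 2; 3 SD band for the mean of 100
        assert abs(np.mean(counts) - 4.0) < 3 * np.sqrt(2.0 / 100)


class TestSimulateCohort:
    def test_degenerate_rates_severe_equals_modifier_carriers(self):
        cfg = SimulationConfig(seed=2, modifier_penetrance=1.0, phenocopy_rate=0.0)
        cohort, truth = simulate_cohort(cfg)
        severe = {
            m.individual_id
            for p in cohort.pedigrees
            for m in p.members
            if m.severity is Severity.SEVERE
        }
        assert severe == set(truth.affected_carrier_ids)
        assert severe  # planted families guarantee at least one severe

    def test_no_modifier_no_phenocopy_means_no_severe(self):
        cfg = SimulationConfig(seed=2, plant_modifier_in_k_families=0, phenocopy_rate=0.0)
        cohort, truth = simulate_cohort(cfg)
        assert truth.modifier_variant_key is None
        assert not any(
            m.severity is Severity.SEVERE for p in cohort.pedigrees for m in p.members
        )

    def test_recessive_model_affected_are_homozygous(self):
        cfg = SimulationConfig(seed=3, inheritance=Inheritance.RECESSIVE_HOM,
                               children_per_family=(4, 8))
        cohort, truth = simulate_cohort(cfg)
        for fam, key in truth.causal_keys.items():
            for m in cohort.pedigree(fam).members:
                if m.affected:
                    assert cohort.genotypes.dosage(key, m.individual_id) == 2

    def test_mendelian_consistency_all_variants(self):
        """Every child dosage must be attainable from its parents' dosages."""
        cfg = SimulationConfig(seed=4, n_background_variants=50)
        cohort, _ = simulate_cohort(cfg)
        attainable = {
            0: {0},
            1: {0, 1},
            2: {1},
        }  # alleles a parent of given dosage can transmit... per-parent sets
        for ped in cohort.pedigrees:
            for m in ped.members:
                if m.is_founder:
                    continue
                for key in cohort.genotypes.variants:
                    d = cohort.genotypes.dosage(key, m.individual_id)
                    fd = cohort.genotypes.dosage(key, m.father_id)
                    md = cohort.genotypes.dosage(key, m.mother_id)
                    possible = {a + b for a in attainable[fd] for b in attainable[md]}
                    assert d in possible

    def test_penetrance_conservation(self):
        """Severe fraction among affected modifier carriers matches the
        configured penetrance within 3 SD over >= 1000 carriers."""
        pen = 0.7
        n_severe = n_carrier = 0
        seed = 0
        while n_carrier < 1000:
            cfg = SimulationConfig(
                seed=seed, n_families=10, plant_modifier_in_k_families=10,
                modifier_penetrance=pen, children_per_family=(4, 8),
            )
            cohort, truth = simulate_cohort(cfg)
            for iid in truth.affected_carrier_ids:
                n_carrier += 1
                n_severe += cohort.individual(iid).severity is Severity.SEVERE
            seed += 1
        phat = n_severe / n_carrier
        assert abs(phat - pen) < 3 * np.sqrt(pen * (1 - pen) / n_carrier)

    def test_deterministic_in_seed(self):
        cfg = SimulationConfig(seed=9)
        a, ta = simulate_cohort(cfg)
        b, tb = simulate_cohort(cfg)
        assert a == b and ta == tb

    def test_infeasible_config_raises(self):
        cfg = SimulationConfig(
            seed=1, inheritance=Inheritance.RECESSIVE_HOM, children_per_family=(0, 0)
        )
        with pytest.raises(SimulationError, match="infeasible"):
            simulate_cohort(cfg)


class TestSimulatePopulation:
    def test_fixed_afs(self):
        t0 = simulate_population(50, {"1:1:A:G": 0.0}, seed=0)
        t1 = simulate_population(50, {"1:1:A:G": 1.0}, seed=0)
        assert (t0["1:1:A:G"] == 0).all()
        assert (t1["1:1:A:G"] == 2).all()

    def test_heterozygote_count_binomial(self):
        n, af = 8011, 0.0116
        table = simulate_population(n, {"1:5:C:T": af}, seed=42)
        hets = int((table["1:5:C:T"] == 1).sum())
        p_het = 2 * af * (1 - af)
        assert abs(hets - n * p_het) < 3 * np.sqrt(n * p_het * (1 - p_het))


class TestSimulateTrajectory:
    def test_rigid_noise_free_angle_exact(self):
        spec = TrajectorySimSpec(mode="rigid", angle_deg=150.0,
                                 noise_sigma_angstrom=0.0, n_frames=20)
        series = angle_series(simulate_trajectory(spec), spec.triplet)
        assert np.allclose(series.angles_deg, 150.0, atol=1e-9)

    def test_deterministic(self):
        spec = TrajectorySimSpec(mode="hinged", seed=5, n_frames=100)
        a = simulate_trajectory(spec)
        b = simulate_trajectory(spec)
        assert np.array_equal(a.coords, b.coords)

    def test_hinged_occupancy_matches_stationary_distribution(self):
        """Symmetric two-state chain: stationary occupancy 1/2; the variance
        of the empirical occupancy includes the chain autocorrelation
        (1+rho)/(1-rho) with rho = 1 - 2q."""
        q, n = 0.05, 10_000
        spec = TrajectorySimSpec(
            mode="hinged", angle_a_deg=150, angle_b_deg=90, switch_prob=q,
            noise_sigma_angstrom=0.0, n_frames=n, seed=8,
        )
        series = angle_series(simulate_trajectory(spec), spec.triplet)
        occ_a = np.mean(np.abs(series.angles_deg - 150) < 1)
        rho = 1 - 2 * q
        sd = np.sqrt(0.25 / n * (1 + rho) / (1 - rho))
        assert abs(occ_a - 0.5) < 3 * sd


class TestWriteFixture:
    def test_cohort_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_families=3, n_background_variants=20)
        cohort, _ = simulate_cohort(cfg)
        paths = write_fixture(cohort, tmp_path / "cohort")
        back = validate_cohort(
            read_pedigrees(paths["ped"]),
            *read_variants(paths["vcf"]),
            read_phenotypes(paths["phenotypes"]),
            read_causative_toml(paths["causative"]),
            read_disease_genes(paths["disease_genes"]),
        )
        assert {p.family_id for p in back.pedigrees} == {
            p.family_id for p in cohort.pedigrees
        }
        members = {m.individual_id: m for p in back.pedigrees for m in p.members}
        for p in cohort.pedigrees:
            for m in p.members:
                assert members[m.individual_id] == m
        for key in cohort.genotypes.variants:
            for s in cohort.genotypes.samples:
                assert back.genotypes.dosage(key, s) == cohort.genotypes.dosage(key, s)

    def test_trajectory_round_trip_within_format_precision(self, tmp_path):
        spec = TrajectorySimSpec(n_frames=8, seed=3)
        traj = simulate_trajectory(spec)
        paths = write_fixture(traj, tmp_path / "traj")
        for reader, path in ((read_pdb_trajectory, paths["pdb"]),
                             (read_xyz_trajectory, paths["xyz"])):
            back = reader(path)
            assert back.atoms == traj.atoms
            assert np.abs(back.coords - traj.coords).max() < 1e-3

    def test_paper_fixture_vcf_record_count(self, tmp_path):
        cohort, expected = encode_paper_cohort()
        paths = write_fixture(cohort, tmp_path / "paper")
        records, _ = read_variants(paths["vcf"])
        core = [r for r in records if r.gene in ("KRT14", "HMCN1")]
        assert len(core) == expected["n_causative_plus_modifier_records"] == 6
        assert len(records) > len(core)  # background records present

    def test_planted_modifier_key_str(self):
        assert variant_key_str(MODIFIER_KEY) == "1:186000000:G:A"
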