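"""Seeded generators for cohorts with planted digenic severity structure,
Hardy-Weinberg population panels, and rigid/hinged pseudo-atom trajectories.

The cohort generator emulates the screening substrate of a modifier-gene
study: families segregating a Mendelian causative allele (dominant
heterozygous or recessive homozygous), an optional heterozygous modifier
allele planted in a subset of families that raises severity among affected
carriers with configurable penetrance, and annotated rare background
variants.  All generators are pure functions of their configuration and
seed.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (
    CausativeAssignment,
    Cohort,
    CohortError,
    GenotypeMatrix,
    Individual,
    Inheritance,
    Pedigree,
    PredictorCall,
    Severity,
    Sex,
    VariantKey,
    VariantRecord,
    validate_cohort,
    write_disease_genes,
    write_pedigrees,
    write_phenotypes,
    write_variants,
)
from .geometry import DomainTriplet, Trajectory, write_pdb_trajectory, write_xyz_trajectory

PREDICTORS = ("GERP", "PROVEAN", "SIFT4G", "POLYPHEN2", "CADD")

MAX_RESAMPLE_ATTEMPTS = 1000


class SimulationError(RuntimeError):
    """Raised when a configuration cannot be satisfied within the resampling budget."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated modifier screen.

    Defaults mirror the motivating study design: a handful of multiplex
    families, a fully penetrant modifier planted in two of them, no
    phenocopies, and rare background variation with noisy predictor calls.
    """

    n_families: int = 8
    children_per_family: tuple[int, int] = (2, 5)
    inheritance: Inheritance = Inheritance.DOMINANT_HET
    plant_modifier_in_k_families: int = 2
    modifier_penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    n_background_variants: int = 200
    af_beta: tuple[float, float] = (0.2, 20.0)
    background_deleterious_fraction: float = 0.3
    predictor_error_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.plant_modifier_in_k_families > self.n_families:
            raise ValueError("cannot plant modifier in more families than exist")
        if self.plant_modifier_in_k_families < 0:
            raise ValueError("plant_modifier_in_k_families must be >= 0")
        lo, hi = self.children_per_family
        if not 0 <= lo <= hi:
            raise ValueError("children_per_family must be a non-negative (lo, hi) range")
        for name in (
            "modifier_penetrance",
            "phenocopy_rate",
            "predictor_error_rate",
            "background_deleterious_fraction",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {val}")


@dataclass(frozen=True)
class PlantedTruth:
    """Generator ground truth for parameter-recovery tests."""

    modifier_variant_key: VariantKey | None
    carrier_ids: frozenset[str]
    affected_carrier_ids: frozenset[str]
    causal_keys: Mapping[str, VariantKey] = field(default_factory=dict)


MODIFIER_KEY: VariantKey = ("1", 186000000, "G", "A")
MODIFIER_GENE = "MODG1"
CAUSAL_GENE = "KRT14"
DISEASE_GENES = frozenset({"KRT5", "KRT14"})


def _family_rng(seed: int, family_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, family_index, stream]))


def simulate_pedigree(config: SimulationConfig, family_index: int) -> Pedigree:
    """Two founders plus a sampled number of children, deterministic in
    (config.seed, family_index).  Affected status is assigned later from
    the gene-dropped genotypes."""
    rng = _family_rng(config.seed, family_index, 0)
    fid = f"SF{family_index + 1}"
    lo, hi = config.children_per_family
    n_children = int(rng.integers(lo, hi + 1))
    members = [
        Individual(f"{fid}-I-1", fid, sex=Sex.MALE),
        Individual(f"{fid}-I-2", fid, sex=Sex.FEMALE),
    ]
    for j in range(n_children):
        members.append(
            Individual(
                f"{fid}-II-{j + 1}",
                fid,
                father_id=f"{fid}-I-1",
                mother_id=f"{fid}-I-2",
                sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
            )
        )
    return Pedigree(fid, tuple(members))


def _drop_allele(
    ped: Pedigree, founder_dosages: dict[str, int], rng: np.random.Generator
) -> dict[str, int]:
    """Mendelian gene drop through a pedigree; founders fixed, children drawn."""
    dosages = dict(founder_dosages)
    # members are listed parents-first in generated pedigrees
    for m in ped.members:
        if m.individual_id in dosages:
            continue
        d = 0
        for pid in (m.father_id, m.mother_id):
            d += int(rng.random() < dosages[pid] / 2.0)
        dosages[m.individual_id] = d
    return dosages


def _drop_family(
    config: SimulationConfig,
    ped: Pedigree,
    planted: bool,
    rng: np.random.Generator,
) -> tuple[dict[str, int], dict[str, int]]:
    """Drop causal (and modifier) alleles until the family is informative:
    >= 2 affected, and for planted families at least one affected modifier
    carrier and one affected non-carrier."""
    founders = [m.individual_id for m in ped.members if m.is_founder]
    if config.inheritance is Inheritance.RECESSIVE_HOM:
        causal_founders = {founders[0]: 1, founders[1]: 1}
    else:
        causal_founders = {founders[0]: 1, founders[1]: 0}
    need = config.inheritance.required_dosage

    for _ in range(MAX_RESAMPLE_ATTEMPTS):
        causal = _drop_allele(ped, causal_founders, rng)
        affected = {iid for iid, d in causal.items() if d >= need}
        if len(affected) < 2:
            continue
        if not planted:
            return causal, {iid: 0 for iid in causal}
        mod_founder = founders[int(rng.integers(0, 2))]
        mod_founders = {f: (1 if f == mod_founder else 0) for f in founders}
        modifier = _drop_allele(ped, mod_founders, rng)
        carriers = {iid for iid in affected if modifier[iid] >= 1}
        if carriers and affected - carriers:
            return causal, modifier
    raise SimulationError(
        f"family {ped.family_id}: no informative gene drop in "
        f"{MAX_RESAMPLE_ATTEMPTS} attempts (config infeasible?)"
    )


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, PlantedTruth]:
    """Generate a pedigreed cohort with planted digenic severity structure.

    Each family segregates its own causative variant under the configured
    inheritance model; the first ``plant_modifier_in_k_families`` families
    additionally segregate one shared heterozygous modifier allele (rare,
    uniformly deleterious-predicted, in a gene outside the disease list).
    Severity among affected individuals is Bernoulli: ``modifier_penetrance``
    for modifier carriers, ``phenocopy_rate`` otherwise.  Background variants
    get allele frequencies from a Beta law, founder genotypes from
    Hardy-Weinberg, child genotypes by Mendelian transmission, and predictor
    calls flipped at ``predictor_error_rate``.
    """
    cohort_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 999]))

    all_deleterious = {p: PredictorCall.DELETERIOUS for p in PREDICTORS}
    pedigrees: list[Pedigree] = []
    causative: list[CausativeAssignment] = []
    causal_keys: dict[str, VariantKey] = {}
    dosage_by_sample: dict[str, dict[VariantKey, int]] = {}
    modifier_dosage: dict[str, int] = {}
    severity: dict[str, Severity] = {}

    variants: list[VariantRecord] = [
        VariantRecord(
            *MODIFIER_KEY,
            gene=MODIFIER_GENE,
            hgvs_c="c.100G>A",
            population_af=1e-4,
            predictor_scores=all_deleterious,
        )
    ]

    for i in range(config.n_families):
        ped = simulate_pedigree(config, i)
        planted = i < config.plant_modifier_in_k_families
        drop_rng = _family_rng(config.seed, i, 1)
        causal, modifier = _drop_family(config, ped, planted, drop_rng)

        key: VariantKey = ("17", 39742000 + i, "G", "A")
        causal_keys[ped.family_id] = key
        variants.append(
            VariantRecord(
                *key,
                gene=CAUSAL_GENE,
                hgvs_c=f"c.{100 + i}G>A",
                population_af=1e-5,
                predictor_scores=all_deleterious,
            )
        )
        causative.append(CausativeAssignment(ped.family_id, key, config.inheritance))

        need = config.inheritance.required_dosage
        sev_rng = _family_rng(config.seed, i, 2)
        new_members = []
        for m in ped.members:
            iid = m.individual_id
            dosage_by_sample[iid] = {key: causal[iid]}
            modifier_dosage[iid] = modifier[iid]
            affected = causal[iid] >= need
            sev = Severity.UNKNOWN
            if affected:
                p_severe = (
                    config.modifier_penetrance
                    if modifier[iid] >= 1
                    else config.phenocopy_rate
                )
                sev = Severity.SEVERE if sev_rng.random() < p_severe else Severity.MILD
            severity[iid] = sev
            new_members.append(replace(m, affected=affected, severity=Severity.UNKNOWN))
        pedigrees.append(Pedigree(ped.family_id, tuple(new_members)))

    # background variants: AFs from Beta, founders HWE, children Mendelian
    a, b = config.af_beta
    afs = cohort_rng.beta(a, b, size=config.n_background_variants)
    truly_deleterious = cohort_rng.random(config.n_background_variants) < (
        config.background_deleterious_fraction
    )
    background_keys: list[VariantKey] = []
    for j in range(config.n_background_variants):
        key = ("2", 1000 * (j + 1), "A", "G")
        background_keys.append(key)
        truth = PredictorCall.DELETERIOUS if truly_deleterious[j] else PredictorCall.TOLERATED
        flipped = {
            PredictorCall.DELETERIOUS: PredictorCall.TOLERATED,
            PredictorCall.TOLERATED: PredictorCall.DELETERIOUS,
        }
        calls = {
            p: (flipped[truth] if cohort_rng.random() < config.predictor_error_rate else truth)
            for p in PREDICTORS
        }
        variants.append(
            VariantRecord(
                *key,
                gene=f"BG{j:04d}",
                population_af=float(afs[j]),
                predictor_scores=calls,
            )
        )

    for i, ped in enumerate(pedigrees):
        bg_rng = _family_rng(config.seed, i, 3)
        founders = [m.individual_id for m in ped.members if m.is_founder]
        for j, key in enumerate(background_keys):
            founder_d = {f: int(bg_rng.binomial(2, afs[j])) for f in founders}
            drop = _drop_allele(ped, founder_d, bg_rng)
            for iid, d in drop.items():
                dosage_by_sample[iid][key] = d

    samples = [m.individual_id for p in pedigrees for m in p.members]
    keys = [v.key for v in variants]
    kidx = {k: i for i, k in enumerate(keys)}
    dosages = np.zeros((len(keys), len(samples)), dtype=np.int8)
    for s_i, s in enumerate(samples):
        dosages[kidx[MODIFIER_KEY], s_i] = min(modifier_dosage[s], 2)
        for k, d in dosage_by_sample[s].items():
            dosages[kidx[k], s_i] = d
    matrix = GenotypeMatrix(keys, samples, dosages)

    cohort = validate_cohort(
        pedigrees, variants, matrix, severity, causative, DISEASE_GENES
    )
    planted_any = config.plant_modifier_in_k_families > 0
    carriers = frozenset(s for s in samples if modifier_dosage[s] >= 1)
    affected_carriers = frozenset(
        s for s in carriers if cohort.individual(s).affected
    )
    truth = PlantedTruth(
        modifier_variant_key=MODIFIER_KEY if planted_any else None,
        carrier_ids=carriers if planted_any else frozenset(),
        affected_carrier_ids=affected_carriers if planted_any else frozenset(),
        causal_keys=causal_keys,
    )
    return cohort, truth


def simulate_population(
    n_individuals: int,
    variant_afs: Mapping[str, float],
    seed: int,
) -> pd.DataFrame:
    """Hardy-Weinberg population panel: independent genotypes per variant.

    ``variant_afs`` maps variant column labels (``chrom:pos:ref:alt``) to
    alt allele frequencies; returns an individuals x variants dosage table.
    """
    for k, af in variant_afs.items():
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"{k}: allele frequency {af} outside [0,1]")
    rng = np.random.default_rng(seed)
    data = {
        k: rng.binomial(2, af, size=n_individuals).astype(np.int8)
        for k, af in variant_afs.items()
    }
    index = [f"P{i + 1:06d}" for i in range(n_individuals)]
    return pd.DataFrame(data, index=index)


def variant_key_str(key: VariantKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


# ---------------------------------------------------------------------------
# coordinate trajectories
# ---------------------------------------------------------------------------


def default_triplet() -> DomainTriplet:
    return DomainTriplet(
        domain_ranges=((1, 30), (31, 60), (61, 90)),
        cys_pairs=((14, 16), (44, 46), (74, 76)),
    )


@dataclass(frozen=True)
class TrajectorySimSpec:
    """Pseudo-atom tandem-Ig trajectory: rigid (one commanded hinge angle) or
    hinged (two-state Markov chain between two angles), plus isotropic
    Gaussian coordinate noise."""

    triplet: DomainTriplet = field(default_factory=default_triplet)
    mode: str = "rigid"
    angle_deg: float = 150.0
    angle_a_deg: float = 150.0
    angle_b_deg: float = 90.0
    switch_prob: float = 0.05
    noise_sigma_angstrom: float = 1.0
    n_frames: int = 2000
    arm_length_angstrom: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("rigid", "hinged"):
            raise ValueError(f"mode must be rigid or hinged, got {self.mode!r}")
        for ang in (self.angle_deg, self.angle_a_deg, self.angle_b_deg):
            if not 0.0 < ang <= 180.0:
                raise ValueError(f"angle {ang} outside (0, 180]")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0,1]")
        if self.noise_sigma_angstrom < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _triplet_roster(triplet: DomainTriplet) -> list[tuple[int, str]]:
    atoms: list[tuple[int, str]] = []
    for (start, end), (c1, c2) in zip(triplet.domain_ranges, triplet.cys_pairs):
        atoms.append((start, "CA"))
        atoms.append((c1, "CA"))
        atoms.append((c1, "SG"))
        atoms.append((c2, "CA"))
        atoms.append((c2, "SG"))
        atoms.append((end, "CA"))
    return atoms


def _base_frame(triplet: DomainTriplet, angle_deg: float, arm: float) -> np.ndarray:
    """Noise-free coordinates whose CA-midpoint hinge angle is exactly
    ``angle_deg``: domain landmarks at m2=origin, m1 and m3 at distance
    ``arm`` separated by the commanded angle, atoms placed symmetrically
    about each landmark."""
    theta = np.radians(angle_deg)
    centers = np.array(
        [
            [-arm, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [-arm * np.cos(theta), arm * np.sin(theta), 0.0],
        ]
    )
    ca_off = np.array([0.0, 2.8, 0.0])
    sg_off = np.array([0.0, 0.0, 1.0])
    start_off = np.array([3.0, 3.0, 3.0])
    end_off = np.array([-3.0, -3.0, 3.0])
    rows = []
    for m in centers:
        rows.extend(
            [m + start_off, m + ca_off, m + sg_off, m - ca_off, m - sg_off, m + end_off]
        )
    return np.asarray(rows)


def simulate_trajectory(spec: TrajectorySimSpec) -> Trajectory:
    """Generate a pseudo-atom trajectory whose noise-free hinge angle equals
    the commanded angle in every frame (rigid) or follows a symmetric
    two-state Markov chain between two commanded angles (hinged)."""
    rng = np.random.default_rng(spec.seed)
    atoms = _triplet_roster(spec.triplet)
    if spec.mode == "rigid":
        commanded = np.full(spec.n_frames, spec.angle_deg)
    else:
        states = np.empty(spec.n_frames, dtype=int)
        states[0] = 0
        switches = rng.random(spec.n_frames - 1) < spec.switch_prob
        for t in range(1, spec.n_frames):
            states[t] = states[t - 1] ^ int(switches[t - 1])
        commanded = np.where(states == 0, spec.angle_a_deg, spec.angle_b_deg)
    coords = np.empty((spec.n_frames, len(atoms), 3))
    base_cache: dict[float, np.ndarray] = {}
    for t in range(spec.n_frames):
        ang = float(commanded[t])
        if ang not in base_cache:
            base_cache[ang] = _base_frame(spec.triplet, ang, spec.arm_length_angstrom)
        coords[t] = base_cache[ang]
    if spec.noise_sigma_angstrom > 0:
        coords += rng.normal(0.0, spec.noise_sigma_angstrom, size=coords.shape)
    return Trajectory(atoms=atoms, coords=coords)


# ---------------------------------------------------------------------------
# fixture writing and TOML configs
# ---------------------------------------------------------------------------


def write_cohort_fixture(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort in the package's PED / VCF / TSV / text dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": out / "cohort.ped",
        "vcf": out / "cohort.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "disease_genes": out / "disease_genes.txt",
        "causative": out / "causative.toml",
    }
    write_pedigrees(cohort.pedigrees, paths["ped"])
    write_variants(cohort.variants, cohort.genotypes, paths["vcf"])
    write_phenotypes(cohort.pedigrees, paths["phenotypes"])
    write_disease_genes(cohort.disease_genes, paths["disease_genes"])
    write_causative_toml(cohort.causative, paths["causative"])
    return paths


def write_trajectory_fixture(trajectory: Trajectory, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"pdb": out / "traj.pdb", "xyz": out / "traj.xyz"}
    write_pdb_trajectory(trajectory, paths["pdb"])
    write_xyz_trajectory(trajectory, paths["xyz"])
    return paths


def write_fixture(obj: Cohort | Trajectory, out_dir: str | Path) -> dict[str, Path]:
    if isinstance(obj, Cohort):
        return write_cohort_fixture(obj, out_dir)
    if isinstance(obj, Trajectory):
        return write_trajectory_fixture(obj, out_dir)
    raise TypeError(f"cannot write fixture for {type(obj).__name__}")


def write_causative_toml(
    causative: tuple[CausativeAssignment, ...] | list[CausativeAssignment],
    path: str | Path,
) -> None:
    blocks = []
    for c in causative:
        chrom, pos, ref, alt = c.variant_key
        blocks.append(
            "[[causative]]\n"
            f'family_id = "{c.family_id}"\n'
            f'chrom = "{chrom}"\n'
            f"pos = {pos}\n"
            f'ref = "{ref}"\n'
            f'alt = "{alt}"\n'
            f'inheritance = "{c.inheritance.value}"\n'
        )
    Path(path).write_text("\n".join(blocks))


def read_causative_toml(path: str | Path) -> list[CausativeAssignment]:
    data = tomllib.loads(Path(path).read_text())
    out = []
    for c in data.get("causative", []):
        out.append(
            CausativeAssignment(
                family_id=str(c["family_id"]),
                variant_key=(str(c["chrom"]), int(c["pos"]), str(c["ref"]), str(c["alt"])),
                inheritance=Inheritance(c["inheritance"]),
            )
        )
    if not out:
        raise CohortError(f"{path}: no [[causative]] tables")
    return out


def read_simulation_config(path: str | Path) -> SimulationConfig:
    data = tomllib.loads(Path(path).read_text())
    kwargs = dict(data)
    if "inheritance" in kwargs:
        kwargs["inheritance"] = Inheritance(kwargs["inheritance"])
    for tup in ("children_per_family", "af_beta"):
        if tup in kwargs:
            kwargs[tup] = tuple(kwargs[tup])
    return SimulationConfig(**kwargs)


def read_trajectory_spec(path: str | Path) -> TrajectorySimSpec:
    data = tomllib.loads(Path(path).read_text())
    kwargs = dict(data)
    if "triplet" in kwargs:
        t = kwargs["triplet"]
        kwargs["triplet"] = DomainTriplet(
            domain_ranges=tuple(tuple(r) for r in t["domain_ranges"]),
            cys_pairs=tuple(tuple(p) for p in t["cys_pairs"]),
        )
    return TrajectorySimSpec(**kwargs)
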