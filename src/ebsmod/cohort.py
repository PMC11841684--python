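"""Domain model for pedigreed disease cohorts.

A cohort couples family structure (PED), per-sample genotypes at annotated
variant sites (VCF), ordinal severity phenotypes (TSV) and a per-family
assignment of the Mendelian causative variant.  Individual ids are globally
unique across the cohort (the family id is carried separately), which lets
genotype matrices and phenotype maps key on the individual id alone.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: (chrom, pos, ref, alt) — the cohort-wide unique key of a variant.
VariantKey = tuple[str, int, str, str]

MISSING_DOSAGE = -1


class CohortError(ValueError):
    """Raised on malformed input files or cross-reference violations."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Severity(enum.IntEnum):
    UNKNOWN = 0
    MILD = 1
    SEVERE = 2


class PredictorCall(enum.Enum):
    DELETERIOUS = "D"
    TOLERATED = "T"
    MISSING = "."


class Inheritance(enum.Enum):
    DOMINANT_HET = "dominant_het"
    RECESSIVE_HOM = "recessive_hom"

    @property
    def required_dosage(self) -> int:
        return 1 if self is Inheritance.DOMINANT_HET else 2


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affected: bool = False
    severity: Severity = Severity.UNKNOWN

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise CohortError(
                f"{self.individual_id}: father/mother must both be present or both missing"
            )
        if self.severity is not Severity.UNKNOWN and not self.affected:
            raise CohortError(
                f"{self.individual_id}: severity {self.severity.name} on unaffected individual"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass(frozen=True)
class Pedigree:
    family_id: str
    members: tuple[Individual, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise CohortError(f"family {self.family_id}: empty pedigree")
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise CohortError(f"family {self.family_id}: duplicate individual ids")
        known = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in known:
                    raise CohortError(
                        f"family {self.family_id}: parent {pid} of "
                        f"{m.individual_id} not in pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            m.individual_id: {p for p in (m.father_id, m.mother_id) if p is not None}
            for m in self.members
        }
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            if state.get(node) == 1:
                raise CohortError(f"family {self.family_id}: pedigree cycle at {node}")
            if state.get(node) == 2:
                return
            state[node] = 1
            for p in parents[node]:
                visit(p)
            state[node] = 2

        for iid in parents:
            visit(iid)

    def member(self, individual_id: str) -> Individual:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        raise KeyError(individual_id)

    @property
    def affected_ids(self) -> tuple[str, ...]:
        return tuple(m.individual_id for m in self.members if m.affected)


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    hgvs_c: str = ""
    hgvs_p: str = ""
    population_af: float | None = None
    predictor_scores: Mapping[str, PredictorCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise CohortError(f"{self.chrom}:{self.pos} ref equals alt")
        if self.pos < 1:
            raise CohortError(f"{self.chrom}:{self.pos} non-positive position")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise CohortError(f"{self.chrom}:{self.pos} AF outside [0,1]")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_deleterious(self) -> int:
        return sum(
            1 for c in self.predictor_scores.values() if c is PredictorCall.DELETERIOUS
        )


class GenotypeMatrix:
    """Variants x samples alt-allele dosage matrix; -1 encodes a missing call."""

    def __init__(
        self,
        variants: Sequence[VariantKey],
        samples: Sequence[str],
        dosages: np.ndarray,
    ) -> None:
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (len(variants), len(samples)):
            raise CohortError(
                f"dosage matrix shape {dosages.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        bad = ~np.isin(dosages, (MISSING_DOSAGE, 0, 1, 2))
        if bad.any():
            raise CohortError("dosages must be in {0,1,2} or missing (-1)")
        if len(set(variants)) != len(variants):
            raise CohortError("duplicate variant keys")
        if len(set(samples)) != len(samples):
            raise CohortError("duplicate sample ids")
        self.variants = tuple(variants)
        self.samples = tuple(samples)
        self.dosages = dosages
        self._vidx = {k: i for i, k in enumerate(self.variants)}
        self._sidx = {s: i for i, s in enumerate(self.samples)}

    def dosage(self, key: VariantKey, sample: str) -> int:
        """Alt-allele dosage, or MISSING_DOSAGE (-1) if not called."""
        return int(self.dosages[self._vidx[key], self._sidx[sample]])

    def has_variant(self, key: VariantKey) -> bool:
        return key in self._vidx

    def row(self, key: VariantKey) -> np.ndarray:
        return self.dosages[self._vidx[key]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass(frozen=True)
class CausativeAssignment:
    family_id: str
    variant_key: VariantKey
    inheritance: Inheritance


@dataclass(frozen=True)
class Cohort:
    pedigrees: tuple[Pedigree, ...]
    variants: tuple[VariantRecord, ...]
    genotypes: GenotypeMatrix
    causative: tuple[CausativeAssignment, ...]
    disease_genes: frozenset[str]

    def pedigree(self, family_id: str) -> Pedigree:
        for p in self.pedigrees:
            if p.family_id == family_id:
                return p
        raise KeyError(family_id)

    def individual(self, individual_id: str) -> Individual:
        for p in self.pedigrees:
            for m in p.members:
                if m.individual_id == individual_id:
                    return m
        raise KeyError(individual_id)

    def variant(self, key: VariantKey) -> VariantRecord:
        for v in self.variants:
            if v.key == key:
                return v
        raise KeyError(key)

    @property
    def affected_ids(self) -> tuple[str, ...]:
        return tuple(i for p in self.pedigrees for i in p.affected_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_SEX_PED = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}


def read_pedigrees(ped_path: str | Path) -> list[Pedigree]:
    """Parse a 6-column whitespace-delimited PED file (FID IID PAT MAT SEX PHENO).

    PED phenotype 1 maps to unaffected, 2 to affected, 0/-9 to unknown
    (treated as unaffected with no severity).  Severity is never read from
    PED; it comes from the separate phenotype TSV.
    """
    rows: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6:
            raise CohortError(f"{ped_path}:{lineno}: expected 6 columns, got {len(fields)}")
        rows.append((lineno, fields))

    by_family: dict[str, list[tuple[int, list[str]]]] = {}
    for lineno, fields in rows:
        by_family.setdefault(fields[0], []).append((lineno, fields))

    pedigrees = []
    for fid, frows in by_family.items():
        seen: set[str] = set()
        members = []
        for lineno, (_, iid, pat, mat, sex, pheno) in frows:
            if iid in seen:
                raise CohortError(f"{ped_path}:{lineno}: duplicate individual {iid} in family {fid}")
            seen.add(iid)
            if sex not in _PED_SEX:
                raise CohortError(f"{ped_path}:{lineno}: bad sex code {sex!r}")
            if pheno not in ("0", "1", "2", "-9"):
                raise CohortError(f"{ped_path}:{lineno}: bad phenotype code {pheno!r}")
            members.append(
                Individual(
                    individual_id=iid,
                    family_id=fid,
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    sex=_PED_SEX[sex],
                    affected=(pheno == "2"),
                )
            )
        ids = {m.individual_id for m in members}
        for lineno, (_, iid, pat, mat, _, _) in frows:
            for pid in (pat, mat):
                if pid != "0" and pid not in ids:
                    raise CohortError(
                        f"{ped_path}:{lineno}: parent {pid} of {iid} absent from family {fid}"
                    )
        pedigrees.append(Pedigree(family_id=fid, members=tuple(members)))
    return pedigrees


def write_pedigrees(pedigrees: Iterable[Pedigree], ped_path: str | Path) -> None:
    lines = []
    for ped in pedigrees:
        for m in ped.members:
            lines.append(
                " ".join(
                    (
                        ped.family_id,
                        m.individual_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _SEX_PED[m.sex],
                        "2" if m.affected else "1",
                    )
                )
            )
    Path(ped_path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_phenotypes(tsv_path: str | Path) -> dict[str, Severity]:
    """Read the severity TSV (family_id, individual_id, severity in {0,1,2})."""
    text = Path(tsv_path).read_text().splitlines()
    if not text:
        raise CohortError(f"{tsv_path}: empty phenotype file")
    header = text[0].split("\t")
    try:
        fi = header.index("family_id")
        ii = header.index("individual_id")
        si = header.index("severity")
    except ValueError as exc:
        raise CohortError(f"{tsv_path}: missing required header column ({exc})") from None
    out: dict[str, Severity] = {}
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        sev = fields[si]
        if sev not in ("0", "1", "2"):
            raise CohortError(f"{tsv_path}:{lineno}: severity {sev!r} outside {{0,1,2}}")
        out[fields[ii]] = Severity(int(sev))
        _ = fields[fi]
    return out


def write_phenotypes(
    pedigrees: Iterable[Pedigree], tsv_path: str | Path
) -> None:
    lines = ["family_id\tindividual_id\tseverity"]
    for ped in pedigrees:
        for m in ped.members:
            lines.append(f"{ped.family_id}\t{m.individual_id}\t{int(m.severity)}")
    Path(tsv_path).write_text("\n".join(lines) + "\n")


def read_disease_genes(path: str | Path) -> frozenset[str]:
    return frozenset(
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    )


def write_disease_genes(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


_PREDICTOR_FROM_VCF = {
    "D": PredictorCall.DELETERIOUS,
    "T": PredictorCall.TOLERATED,
    ".": PredictorCall.MISSING,
}


def read_variants(vcf_path: str | Path) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read annotated variants + genotypes from a VCF 4.x file.

    INFO keys consumed: GENE, AF_POP, HGVS_C, HGVS_P and any PRED_<name> key
    with value D (deleterious) or T (tolerated).  Dosage is the alt-allele
    count of the GT field; ./. becomes missing.  Multiallelic records are
    rejected — normalize (split and left-align) upstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise CohortError(
                f"{var.CHROM}:{var.POS}: multiallelic record; split and "
                "left-align the VCF before loading"
            )
        gene = var.INFO.get("GENE")
        if gene is None:
            log.warning(
                "%s:%s has no GENE annotation; excluded from gene-aware filters",
                var.CHROM,
                var.POS,
            )
        af = var.INFO.get("AF_POP")
        preds = {}
        for key, val in var.INFO:
            if key.startswith("PRED_"):
                preds[key[5:]] = _PREDICTOR_FROM_VCF.get(str(val), PredictorCall.MISSING)
        records.append(
            VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0],
                gene=gene,
                hgvs_c=var.INFO.get("HGVS_C") or "",
                hgvs_p=var.INFO.get("HGVS_P") or "",
                population_af=float(af) if af is not None else None,
                predictor_scores=preds,
            )
        )
        row = np.full(len(samples), MISSING_DOSAGE, dtype=np.int8)
        for j, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == len(gt) - 1:  # fully called
                row[j] = sum(alleles)
        rows.append(row)
    vcf.close()
    dosages = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    matrix = GenotypeMatrix([r.key for r in records], samples, dosages)
    return records, matrix


_GT_FROM_DOSAGE = {MISSING_DOSAGE: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_variants(
    variants: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    vcf_path: str | Path,
) -> None:
    """Write the cohort VCF dialect read by :func:`read_variants`."""
    predictors = sorted({p for v in variants for p in v.predictor_scores})
    contigs = sorted({v.chrom for v in variants})
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=AF_POP,Number=1,Type=Float,Description="Population allele frequency">',
        '##INFO=<ID=HGVS_C,Number=1,Type=String,Description="HGVS cDNA">',
        '##INFO=<ID=HGVS_P,Number=1,Type=String,Description="HGVS protein">',
    ]
    for p in predictors:
        lines.append(
            f'##INFO=<ID=PRED_{p},Number=1,Type=String,Description="Predictor call D/T">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.samples)
    )
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    for i in order:
        v = variants[i]
        info = []
        if v.gene is not None:
            info.append(f"GENE={v.gene}")
        if v.population_af is not None:
            info.append(f"AF_POP={v.population_af:.6g}")
        if v.hgvs_c:
            info.append(f"HGVS_C={v.hgvs_c}")
        if v.hgvs_p:
            info.append(f"HGVS_P={v.hgvs_p}")
        for p, call in sorted(v.predictor_scores.items()):
            if call is not PredictorCall.MISSING:
                info.append(f"PRED_{p}={call.value}")
        gts = "\t".join(_GT_FROM_DOSAGE[int(d)] for d in genotypes.row(v.key))
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
            f"{';'.join(info) or '.'}\tGT\t{gts}"
        )
    Path(vcf_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_cohort(
    pedigrees: Sequence[Pedigree],
    variants: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    phenotypes: Mapping[str, Severity],
    causative: Sequence[CausativeAssignment],
    disease_genes: Iterable[str],
) -> Cohort:
    """Cross-reference all cohort components and attach severities.

    Checks: every genotyped sample belongs to exactly one pedigree; one
    causative assignment per family, keyed to a known variant; every affected
    family member with a genotype call carries the causative variant with the
    zygosity the inheritance model requires.
    """
    members: dict[str, Individual] = {}
    for ped in pedigrees:
        for m in ped.members:
            if m.individual_id in members:
                raise CohortError(f"individual id {m.individual_id} appears in two pedigrees")
            members[m.individual_id] = m

    for s in genotypes.samples:
        if s not in members:
            raise CohortError(f"genotyped sample {s} absent from all pedigrees")

    for iid in phenotypes:
        if iid not in members:
            log.warning("phenotype for unknown individual %s ignored", iid)

    fams = [c.family_id for c in causative]
    if len(set(fams)) != len(fams):
        raise CohortError("multiple causative assignments for one family")
    known_fams = {p.family_id for p in pedigrees}
    for c in causative:
        if c.family_id not in known_fams:
            raise CohortError(f"causative assignment for unknown family {c.family_id}")
        if not genotypes.has_variant(c.variant_key):
            raise CohortError(f"causative variant {c.variant_key} not genotyped")

    # attach severity, then verify zygosity per inheritance model
    new_pedigrees = []
    for ped in pedigrees:
        new_members = []
        for m in ped.members:
            sev = phenotypes.get(m.individual_id, Severity.UNKNOWN)
            if sev is not Severity.UNKNOWN and not m.affected:
                raise CohortError(
                    f"{m.individual_id}: severity {sev.name} but PED marks unaffected"
                )
            new_members.append(replace(m, severity=sev))
        new_pedigrees.append(Pedigree(ped.family_id, tuple(new_members)))

    by_fam = {p.family_id: p for p in new_pedigrees}
    for c in causative:
        need = c.inheritance.required_dosage
        for m in by_fam[c.family_id].members:
            if not m.affected or m.individual_id not in genotypes.samples:
                continue
            d = genotypes.dosage(c.variant_key, m.individual_id)
            if d == MISSING_DOSAGE:
                continue  # not called: non-informative
            if d < need:
                raise CohortError(
                    f"{m.individual_id}: affected but dosage {d} at causative "
                    f"{c.variant_key} under {c.inheritance.value}"
                )

    return Cohort(
        pedigrees=tuple(new_pedigrees),
        variants=tuple(variants),
        genotypes=genotypes,
        causative=tuple(causative),
        disease_genes=frozenset(disease_genes),
    )


# ---------------------------------------------------------------------------
# worked-example fixture
# ---------------------------------------------------------------------------

#: Genes with an established causal role in epidermolysis bullosa; candidates
#: in these genes are causative alleles, not modifiers.
EB_GENES = frozenset(
    {"KRT5", "KRT14", "PLEC", "DST", "EXPH5", "KLHL24", "CD151", "TGM5", "PKP1", "DSP", "JUP"}
)

_PREDICTORS = ("GERP", "PROVEAN", "SIFT4G", "POLYPHEN2", "CADD")
_ALL_DELETERIOUS = {p: PredictorCall.DELETERIOUS for p in _PREDICTORS}
_ALL_TOLERATED = {p: PredictorCall.TOLERATED for p in _PREDICTORS}

# Positions are synthetic placeholders on the genes' true chromosomes (KRT14 on
# 17q21.2, HMCN1 on 1q25); the source data identify variants by HGVS only.
KRT14_R125C: VariantKey = ("17", 39742500, "G", "A")
KRT14_E411DEL: VariantKey = ("17", 39740100, "CCTC", "C")
KRT14_R388H: VariantKey = ("17", 39740900, "C", "T")
HMCN1_A3969T: VariantKey = ("1", 185990500, "G", "A")
HMCN1_G2939S: VariantKey = ("1", 185942300, "G", "A")
HMCN1_H4084Y: VariantKey = ("1", 185995800, "C", "T")


def _fam(
    family_id: str,
    rows: list[tuple[str, str | None, str | None, Sex, bool, Severity]],
) -> Pedigree:
    members = tuple(
        Individual(
            individual_id=f"{family_id}-{iid}",
            family_id=family_id,
            father_id=f"{family_id}-{pat}" if pat else None,
            mother_id=f"{family_id}-{mat}" if mat else None,
            sex=sex,
            affected=aff,
            severity=sev,
        )
        for iid, pat, mat, sex, aff, sev in rows
    )
    return Pedigree(family_id, members)


def encode_paper_cohort() -> tuple[Cohort, dict]:
    """Build the four-family EBS worked-example cohort, deterministically.

    Four KRT14 families, 20 affected individuals in total.  Families 1 and 2
    segregate dominant heterozygous causative variants (p.Arg125Cys and
    p.Glu411del); families 3 and 4 are homozygous for the founder variant
    p.Arg388His and therefore share one causative key.  Exactly three
    individuals are severely affected (F1 III-1, F2 II-6, F4 II-2) and each
    carries one rare, uniformly deleterious-predicted heterozygous HMCN1
    variant found in no other cohort member.

    The published sources give member labels and totals but not full family
    trees; the trees here are minimal ones consistent with those labels,
    padded with mild affected members so the affected count is exactly 20.

    Returns the validated cohort plus a map of the outcome counts the screen
    is expected to reproduce.
    """
    M, F, U = Sex.MALE, Sex.FEMALE, Sex.UNKNOWN
    mild, sev, unk = Severity.MILD, Severity.SEVERE, Severity.UNKNOWN

    fam1 = _fam(
        "F1",
        [
            ("I-1", None, None, M, True, mild),
            ("I-2", None, None, F, False, unk),
            ("II-1", "I-1", "I-2", M, True, mild),
            ("II-2", "I-1", "I-2", F, True, mild),
            ("II-3", None, None, M, False, unk),
            ("III-1", "II-3", "II-2", F, True, sev),
            ("III-2", "II-3", "II-2", M, True, mild),
        ],
    )
    fam2 = _fam(
        "F2",
        [
            ("I-1", None, None, F, True, mild),
            ("I-2", None, None, M, False, unk),
            ("II-6", "I-2", "I-1", M, True, sev),
            ("II-7", None, None, F, False, unk),
            ("III-1", "II-6", "II-7", F, True, mild),
            ("III-3", "II-6", "II-7", M, True, mild),
            ("III-5", "II-6", "II-7", F, True, mild),
        ],
    )
    fam3 = _fam(
        "F3",
        [
            ("I-1", None, None, M, False, unk),
            ("I-2", None, None, F, False, unk),
            ("II-1", "I-1", "I-2", M, True, mild),
            ("II-2", "I-1", "I-2", F, True, mild),
            ("II-3", "I-1", "I-2", M, True, mild),
            ("II-4", "I-1", "I-2", F, True, mild),
            ("II-5", "I-1", "I-2", M, True, mild),
            ("II-6", "I-1", "I-2", F, True, mild),
        ],
    )
    fam4 = _fam(
        "F4",
        [
            ("I-1", None, None, M, False, unk),
            ("I-2", None, None, F, False, unk),
            ("II-1", "I-1", "I-2", F, True, mild),
            ("II-2", "I-1", "I-2", F, True, sev),
            ("II-3", "I-1", "I-2", M, True, mild),
            ("II-4", "I-1", "I-2", M, True, mild),
        ],
    )
    pedigrees = (fam1, fam2, fam3, fam4)

    variants = [
        VariantRecord(*KRT14_R125C, gene="KRT14", hgvs_c="c.373C>T", hgvs_p="p.Arg125Cys",
                      population_af=0.00001, predictor_scores=_ALL_DELETERIOUS),
        VariantRecord(*KRT14_E411DEL, gene="KRT14", hgvs_c="c.1231_1233delGAG",
                      hgvs_p="p.Glu411del", population_af=0.00001,
                      predictor_scores=_ALL_DELETERIOUS),
        VariantRecord(*KRT14_R388H, gene="KRT14", hgvs_c="c.1163G>A", hgvs_p="p.Arg388His",
                      population_af=0.00002, predictor_scores=_ALL_DELETERIOUS),
        VariantRecord(*HMCN1_A3969T, gene="HMCN1", hgvs_c="c.11905G>A", hgvs_p="p.Ala3969Thr",
                      population_af=0.0001, predictor_scores=_ALL_DELETERIOUS),
        VariantRecord(*HMCN1_G2939S, gene="HMCN1", hgvs_c="c.8815G>A", hgvs_p="p.Gly2939Ser",
                      population_af=0.0001, predictor_scores=_ALL_DELETERIOUS),
        VariantRecord(*HMCN1_H4084Y, gene="HMCN1", hgvs_c="c.12250C>T", hgvs_p="p.His4084Tyr",
                      population_af=0.0001, predictor_scores=_ALL_DELETERIOUS),
        # benign background records exercising the filters
        VariantRecord("2", 1000500, "A", "G", gene="BGA", population_af=0.21,
                      predictor_scores=_ALL_TOLERATED),
        VariantRecord("2", 2000500, "T", "C", gene="BGB", population_af=0.0004,
                      predictor_scores=_ALL_TOLERATED),
        VariantRecord("2", 3000500, "G", "T", gene="BGC", population_af=0.32,
                      predictor_scores=_ALL_DELETERIOUS),
    ]

    samples = [m.individual_id for p in pedigrees for m in p.members]
    keys = [v.key for v in variants]
    dosages = np.full((len(keys), len(samples)), MISSING_DOSAGE, dtype=np.int8)
    mat = GenotypeMatrix(keys, samples, dosages)

    def set_dosage(key: VariantKey, sample: str, d: int) -> None:
        dosages[keys.index(key), samples.index(sample)] = d

    causative = (
        CausativeAssignment("F1", KRT14_R125C, Inheritance.DOMINANT_HET),
        CausativeAssignment("F2", KRT14_E411DEL, Inheritance.DOMINANT_HET),
        CausativeAssignment("F3", KRT14_R388H, Inheritance.RECESSIVE_HOM),
        CausativeAssignment("F4", KRT14_R388H, Inheritance.RECESSIVE_HOM),
    )
    causative_by_fam = {c.family_id: c for c in causative}

    for ped in pedigrees:
        c = causative_by_fam[ped.family_id]
        for m in ped.members:
            if m.affected:
                set_dosage(c.variant_key, m.individual_id, c.inheritance.required_dosage)
                # affected individuals genotyped at every candidate site
                for hk in (HMCN1_A3969T, HMCN1_G2939S, HMCN1_H4084Y):
                    set_dosage(hk, m.individual_id, 0)
                for bk in [v.key for v in variants if v.gene and v.gene.startswith("BG")]:
                    set_dosage(bk, m.individual_id, 0)
            elif m.is_founder and c.inheritance is Inheritance.RECESSIVE_HOM:
                set_dosage(c.variant_key, m.individual_id, 1)  # obligate carrier

    # the three severe individuals each carry their family's HMCN1 variant het
    set_dosage(HMCN1_A3969T, "F1-III-1", 1)
    set_dosage(HMCN1_G2939S, "F2-II-6", 1)
    set_dosage(HMCN1_H4084Y, "F4-II-2", 1)
    # common background variants carried broadly among affected
    for s in samples:
        if s.endswith(("II-1", "III-1")):
            i = samples.index(s)
            if dosages[keys.index(("2", 1000500, "A", "G")), i] != MISSING_DOSAGE:
                set_dosage(("2", 1000500, "A", "G"), s, 1)
                set_dosage(("2", 3000500, "G", "T"), s, 1)

    phenotypes = {
        m.individual_id: m.severity for p in pedigrees for m in p.members
    }
    bare_pedigrees = [
        Pedigree(p.family_id, tuple(replace(m, severity=Severity.UNKNOWN) for m in p.members))
        for p in pedigrees
    ]
    cohort = validate_cohort(
        bare_pedigrees, variants, mat, phenotypes, causative, EB_GENES
    )
    expected = {
        "n_affected": 20,
        "n_severe": 3,
        "n_shared_variant_groups": 3,
        "n_candidate_modifiers": 3,
        "n_supporting_families": 4,
        "candidate_keys": {HMCN1_A3969T, HMCN1_G2939S, HMCN1_H4084Y},
        "candidate_gene": "HMCN1",
        "n_causative_plus_modifier_records": 6,
    }
    return cohort, expected
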