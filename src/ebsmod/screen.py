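"""Modifier-gene co-segregation screen over a pedigreed cohort.

The discovery chain mirrors how a clinical-genetics team hunts for severity
modifiers once the Mendelian cause is known: (1) pool affected patients who
share a causative allele — within a family or across families linked by a
founder variant; (2) keep the groups whose members diverge in severity;
(3) restrict attention to rare variants with a consensus of deleterious
predictor calls in genes outside the known disease-gene list; (4) for each
candidate and divergent group, ask whether carrier status separates severe
from mild patients, with a permutation p-value over severity relabelings;
(5) aggregate across groups (Fisher's combination) and rank.  A healthy
population panel can then be scanned for carriers of the surviving
candidates to gauge whether the allele is pathogenic on its own.
"""

from __future__ import annotations

import enum
import json
import logging
import tomllib
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    MISSING_DOSAGE,
    Cohort,
    PredictorCall,
    Severity,
    VariantKey,
    VariantRecord,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    af_max: float = 0.001
    predictor_min_deleterious: int = 3
    permutations: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.af_max <= 1.0:
            raise ValueError("af_max must be in (0,1]")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")


@dataclass(frozen=True)
class SharedVariantGroup:
    causative_key: VariantKey
    family_ids: frozenset[str]
    patient_ids: frozenset[str]


@dataclass(frozen=True)
class DivergenceCall:
    group: SharedVariantGroup
    severe_ids: frozenset[str]
    mild_ids: frozenset[str]

    @property
    def divergent(self) -> bool:
        return bool(self.severe_ids) and bool(self.mild_ids)


class Pattern(enum.Enum):
    PERFECT = "perfect"
    PARTIAL = "partial"
    NONE = "none"


@dataclass(frozen=True)
class SegregationResult:
    variant_key: VariantKey
    group: SharedVariantGroup
    pattern: Pattern
    p_perm: float


@dataclass(frozen=True)
class CandidateModifier:
    variant_key: VariantKey
    gene: str | None
    supporting_groups: tuple[SegregationResult, ...]
    combined_p: float
    rank: int


@dataclass(frozen=True)
class CarrierScan:
    counts: Mapping[VariantKey, int]
    not_assayed: tuple[VariantKey, ...]
    total_distinct_carriers: int
    panel_size: int


@dataclass(frozen=True)
class ScreenReport:
    groups: tuple[SharedVariantGroup, ...]
    divergence: tuple[DivergenceCall, ...]
    candidates: tuple[CandidateModifier, ...]
    segregation: tuple[SegregationResult, ...] = ()
    carrier_scan: CarrierScan | None = None

    def to_dict(self) -> dict:
        def key_str(k: VariantKey) -> str:
            return f"{k[0]}:{k[1]}:{k[2]}:{k[3]}"

        out: dict = {
            "groups": [
                {
                    "causative_key": key_str(g.causative_key),
                    "family_ids": sorted(g.family_ids),
                    "patient_ids": sorted(g.patient_ids),
                }
                for g in self.groups
            ],
            "divergence": [
                {
                    "causative_key": key_str(d.group.causative_key),
                    "severe_ids": sorted(d.severe_ids),
                    "mild_ids": sorted(d.mild_ids),
                    "divergent": d.divergent,
                }
                for d in self.divergence
            ],
            "candidates": [
                {
                    "variant_key": key_str(c.variant_key),
                    "gene": c.gene,
                    "combined_p": c.combined_p,
                    "rank": c.rank,
                    "supporting_groups": [
                        {
                            "causative_key": key_str(s.group.causative_key),
                            "pattern": s.pattern.value,
                            "p_perm": s.p_perm,
                        }
                        for s in c.supporting_groups
                    ],
                }
                for c in self.candidates
            ],
        }
        if self.carrier_scan is not None:
            out["carrier_scan"] = {
                "counts": {key_str(k): v for k, v in sorted(self.carrier_scan.counts.items())},
                "not_assayed": [key_str(k) for k in self.carrier_scan.not_assayed],
                "total_distinct_carriers": self.carrier_scan.total_distinct_carriers,
                "panel_size": self.carrier_scan.panel_size,
            }
        return out

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "json": out / "report.json",
            "candidates": out / "candidates.tsv",
            "groups": out / "groups.tsv",
        }
        paths["json"].write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        cand_rows = [
            {
                "rank": c.rank,
                "variant_key": f"{c.variant_key[0]}:{c.variant_key[1]}:"
                f"{c.variant_key[2]}:{c.variant_key[3]}",
                "gene": c.gene or "",
                "combined_p": c.combined_p,
                "n_supporting_groups": len(c.supporting_groups),
            }
            for c in self.candidates
        ]
        pd.DataFrame(
            cand_rows,
            columns=["rank", "variant_key", "gene", "combined_p", "n_supporting_groups"],
        ).to_csv(paths["candidates"], sep="\t", index=False)
        group_rows = [
            {
                "causative_key": f"{g.causative_key[0]}:{g.causative_key[1]}:"
                f"{g.causative_key[2]}:{g.causative_key[3]}",
                "families": ",".join(sorted(g.family_ids)),
                "n_patients": len(g.patient_ids),
            }
            for g in self.groups
        ]
        pd.DataFrame(
            group_rows, columns=["causative_key", "families", "n_patients"]
        ).to_csv(paths["groups"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def group_by_causative(cohort: Cohort) -> list[SharedVariantGroup]:
    """Pool affected carriers by shared causative variant key.

    One group per causative key carried (with the model-required zygosity and
    a non-missing genotype) by at least two affected patients; founder
    variants shared by several families yield one cross-family group.
    Singleton groups are dropped.
    """
    by_key: dict[VariantKey, dict] = {}
    for c in cohort.causative:
        entry = by_key.setdefault(
            c.variant_key, {"families": set(), "patients": set()}
        )
        entry["families"].add(c.family_id)
        need = c.inheritance.required_dosage
        for m in cohort.pedigree(c.family_id).members:
            if not m.affected or m.individual_id not in cohort.genotypes.samples:
                continue
            d = cohort.genotypes.dosage(c.variant_key, m.individual_id)
            if d != MISSING_DOSAGE and d >= need:
                entry["patients"].add(m.individual_id)
    groups = [
        SharedVariantGroup(
            causative_key=key,
            family_ids=frozenset(v["families"]),
            patient_ids=frozenset(v["patients"]),
        )
        for key, v in by_key.items()
        if len(v["patients"]) >= 2
    ]
    groups.sort(key=lambda g: g.causative_key)
    return groups


def detect_divergence(
    groups: Sequence[SharedVariantGroup], cohort: Cohort
) -> list[DivergenceCall]:
    """Partition each group's patients into severe and mild; individuals with
    unknown severity are excluded from both sets."""
    calls = []
    for g in groups:
        severe, mild = set(), set()
        for iid in g.patient_ids:
            sev = cohort.individual(iid).severity
            if sev is Severity.SEVERE:
                severe.add(iid)
            elif sev is Severity.MILD:
                mild.add(iid)
        calls.append(DivergenceCall(g, frozenset(severe), frozenset(mild)))
    return calls


def filter_candidates(
    variants: Iterable[VariantRecord],
    disease_genes: Iterable[str],
    config: ScreenConfig,
) -> list[VariantRecord]:
    """Rarity + predictor-consensus + non-disease-gene filter.

    Missing population AF passes the rarity filter with a warning (absence
    from the frequency databases is itself evidence of rarity); variants
    without a gene annotation are excluded from the gene-aware screen.
    """
    disease = set(disease_genes)
    kept = []
    for v in variants:
        if v.gene is None:
            log.warning("%s:%s has no gene annotation; skipped", v.chrom, v.pos)
            continue
        if v.gene in disease:
            continue
        if v.population_af is None:
            log.warning("%s:%s has no population AF; treated as rare", v.chrom, v.pos)
        elif v.population_af > config.af_max:
            continue
        if v.n_deleterious < config.predictor_min_deleterious:
            continue
        kept.append(v)
    return kept


def _test_rng(seed: int, variant_key: VariantKey, group_key: VariantKey) -> np.random.Generator:
    """Per-(variant, group) RNG stream, invariant to input ordering."""
    tag = zlib.crc32(f"{variant_key}|{group_key}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def test_cosegregation(
    variant_key: VariantKey,
    call: DivergenceCall,
    cohort: Cohort,
    config: ScreenConfig,
) -> SegregationResult:
    """Permutation test of carrier status against severity within one group.

    Members are the group's genotyped affected carriers of the causative
    allele with known severity and a non-missing call at the candidate site.
    The observed discordance is the number of severe non-carriers plus mild
    carriers; the p-value is the fraction of ``permutations`` random severity
    relabelings (preserving the severe count) at least as concordant,
    with add-one smoothing p = (b+1)/(B+1).  Because a relabeling only
    enters through the overlap between the severe set and the carrier set,
    relabelings are drawn as hypergeometric overlap counts — exactly the
    permutation distribution, at O(B) cost.
    """
    group = call.group
    members = sorted(call.severe_ids | call.mild_ids)
    carrier = []
    severe = []
    for iid in members:
        d = cohort.genotypes.dosage(variant_key, iid)
        if d == MISSING_DOSAGE:
            continue
        carrier.append(d >= 1)
        severe.append(iid in call.severe_ids)
    carrier_arr = np.asarray(carrier, dtype=bool)
    severe_arr = np.asarray(severe, dtype=bool)
    n = carrier_arr.size
    n_carriers = int(carrier_arr.sum())
    n_severe = int(severe_arr.sum())

    if n == 0 or n_carriers == 0:
        return SegregationResult(variant_key, group, Pattern.NONE, 1.0)
    if n_carriers == n:
        # carried by everyone: no severity information
        return SegregationResult(variant_key, group, Pattern.NONE, 1.0)

    k_obs = int((carrier_arr & severe_arr).sum())
    d_obs = (n_severe - k_obs) + (n_carriers - k_obs)
    if d_obs == 0:
        pattern = Pattern.PERFECT
    else:
        pattern = Pattern.PARTIAL

    rng = _test_rng(config.seed, variant_key, group.causative_key)
    B = config.permutations
    # overlap |severe' ∩ carriers| under random relabeling is hypergeometric
    k_perm = rng.hypergeometric(n_carriers, n - n_carriers, n_severe, size=B)
    b = int(np.count_nonzero(k_perm >= k_obs))
    p = (b + 1) / (B + 1)
    return SegregationResult(variant_key, group, pattern, float(p))


test_cosegregation.__test__ = False  # name collides with pytest collection


def aggregate_candidates(
    seg_results: Sequence[SegregationResult],
    cohort: Cohort,
    config: ScreenConfig,
) -> list[CandidateModifier]:
    """Keep variants with a perfect pattern in at least one divergent group;
    combine p-values across supporting groups by Fisher's method and rank
    deterministically (p, then gene, then key)."""
    by_variant: dict[VariantKey, list[SegregationResult]] = {}
    for r in seg_results:
        by_variant.setdefault(r.variant_key, []).append(r)

    raw = []
    for key, results in by_variant.items():
        supporting = tuple(
            sorted(
                (r for r in results if r.pattern is Pattern.PERFECT),
                key=lambda r: r.group.causative_key,
            )
        )
        if not supporting:
            continue
        pvals = [r.p_perm for r in supporting]
        if len(pvals) == 1:
            combined = pvals[0]
        else:
            combined = float(stats.combine_pvalues(pvals, method="fisher").pvalue)
        try:
            gene = cohort.variant(key).gene
        except KeyError:
            gene = None
        raw.append((combined, gene or "", key, supporting))

    raw.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        CandidateModifier(
            variant_key=key,
            gene=gene or None,
            supporting_groups=supporting,
            combined_p=combined,
            rank=i + 1,
        )
        for i, (combined, gene, key, supporting) in enumerate(raw)
    ]


def population_carrier_scan(
    candidate_keys: Sequence[VariantKey],
    population_table: pd.DataFrame,
) -> CarrierScan:
    """Count carriers (dosage >= 1) of each candidate in a population panel.

    Panel columns are ``chrom:pos:ref:alt`` labels; candidates absent from
    the panel are reported not-assayed and excluded from the distinct-carrier
    total.
    """
    counts: dict[VariantKey, int] = {}
    not_assayed = []
    carrier_any = np.zeros(len(population_table), dtype=bool)
    for key in candidate_keys:
        col = f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"
        if col not in population_table.columns:
            not_assayed.append(key)
            continue
        carriers = population_table[col].to_numpy() >= 1
        counts[key] = int(carriers.sum())
        carrier_any |= carriers
    return CarrierScan(
        counts=counts,
        not_assayed=tuple(not_assayed),
        total_distinct_carriers=int(carrier_any.sum()),
        panel_size=len(population_table),
    )


def run_screen(
    cohort: Cohort,
    config: ScreenConfig | None = None,
    population_table: pd.DataFrame | None = None,
) -> ScreenReport:
    """Full discovery chain: group → divergence → filter → co-segregation →
    aggregate, plus an optional population carrier scan of the candidates."""
    config = config or ScreenConfig()
    groups = group_by_causative(cohort)
    divergence = detect_divergence(groups, cohort)
    divergent = [d for d in divergence if d.divergent]
    if not divergent:
        log.warning("no divergent shared-variant groups (is severity data attached?)")

    causative_keys = {c.variant_key for c in cohort.causative}
    candidates_in = [
        v for v in filter_candidates(cohort.variants, cohort.disease_genes, config)
        if v.key not in causative_keys
    ]
    seg_results = [
        test_cosegregation(v.key, call, cohort, config)
        for call in divergent
        for v in candidates_in
    ]
    candidates = aggregate_candidates(seg_results, cohort, config)
    scan = None
    if population_table is not None:
        scan = population_carrier_scan([c.variant_key for c in candidates], population_table)
    return ScreenReport(
        groups=tuple(groups),
        divergence=tuple(divergence),
        candidates=tuple(candidates),
        segregation=tuple(seg_results),
        carrier_scan=scan,
    )


def read_screen_config(path: str | Path) -> ScreenConfig:
    data = tomllib.loads(Path(path).read_text())
    return ScreenConfig(**data)
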