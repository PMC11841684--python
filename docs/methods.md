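# Methods

## The modifier screen

### Problem and model

Epidermolysis bullosa simplex (EBS) families segregating the same causative
keratin variant — within one family or across families linked by a founder
allele — can differ sharply in severity, which suggests a second, modifying
locus. The screen formalises the standard clinical-genetics reasoning as a
pipeline over a `Cohort` (pedigrees + genotypes + ordinal severity +
per-family causative assignments + a disease-gene list):

1. **Shared-causative grouping.** One group per causative variant key
   carried, with the zygosity its inheritance model requires, by ≥ 2
   affected patients. Grouping is by variant key rather than by family so
   that founder variants (identical-by-descent across families) pool their
   carriers into one group. Singleton groups are dropped: a single patient
   cannot display divergence.
2. **Divergence detection.** Each group's patients are partitioned into
   severe and mild; patients with unknown severity are excluded from both
   sides. A group is divergent iff both sides are non-empty.
3. **Candidate filtering.** Keep variants with population allele frequency
   ≤ `af_max` (default 0.001; a missing AF passes with a logged warning —
   absence from frequency databases is itself evidence of rarity), at least
   `predictor_min_deleterious` (default 3) predictor calls of
   "deleterious", and a gene outside the disease-gene list (an input file,
   never hard-coded). Predictor scores are consumed as annotations; the
   package never runs prediction software.
4. **Co-segregation test.** For a candidate variant and a divergent group,
   the members are the group's genotyped affected carriers of the causative
   allele with known severity and a non-missing call at the candidate site.
   The observed discordance is
   `d = |severe non-carriers| + |mild carriers|`; `d = 0` with a
   non-trivial carrier set (neither empty nor everyone) is a *perfect*
   pattern. The p-value is the fraction of random severity relabelings
   (preserving the severe count) with discordance ≤ d, with add-one
   smoothing `p = (b + 1)/(B + 1)` so p is never 0. Because a relabeling
   enters the statistic only through the overlap `k = |severe ∩ carriers|`
   (d = s + c − 2k is strictly decreasing in k), relabelings are drawn as
   hypergeometric overlap counts — exactly the permutation distribution at
   O(B) cost per test. The test RNG stream is derived from the config seed
   plus a hash of the (variant, group) pair, so results are invariant to
   input row order.
5. **Aggregation.** A candidate is reported if it has a perfect pattern in
   at least one divergent group. Evidence across several supporting groups
   (independent families) is combined with Fisher's method; ranking breaks
   ties deterministically by (combined p, gene, variant key).
6. **Population carrier scan** (optional). Carriers (dosage ≥ 1) of each
   reported candidate are counted in a healthy population panel;
   candidates absent from the panel are reported not-assayed. A substantial
   healthy-carrier count argues the modifier is not independently causal.

Unaffected relatives never enter the segregation statistic: the evidence
the screen quantifies concerns severity *among affected* carriers.
Missing genotypes are non-informative (the individual is excluded from the
pattern, not treated as carrier or non-carrier). The stricter perfect
definition — present in every severe AND absent in every genotyped mild
member — is the default; partial patterns are reported but never ranked.

### Worked-example fixture

`encode_paper_cohort()` builds a four-family EBS cohort deterministically:
dominant heterozygous KRT14 p.Arg125Cys (family 1) and p.Glu411del
(family 2), recessive homozygous founder p.Arg388His shared by families 3
and 4; 20 affected individuals, of whom exactly three are severe; each
severe individual is the sole heterozygous carrier of one rare,
uniformly deleterious-predicted HMCN1 variant (p.Ala3969Thr, p.Gly2939Ser,
p.His4084Tyr). The published member labels constrain but do not determine
the full trees, so the fixture uses minimal trees consistent with the
labels, padded with mild affected members to per-family affected counts of
5 + 5 + 6 + 4; those per-family counts are a fixture convention, not a
claim about the source families. Chromosome positions are synthetic
placeholders on the genes' true chromosomes. Unaffected members carry
missing genotypes at candidate sites except the obligate-carrier founders
of the recessive families.

Running the screen on this fixture yields three candidate modifier
variants (all HMCN1), supported by four families, with the three severe
individuals flagged by divergence detection — the outcome counts of the
motivating study.

## Synthetic cohorts

`simulate_cohort` is the screen's test harness and defines the study
conditions:

- **Pedigrees**: two founders plus a uniform number of children in
  `children_per_family` (default 2–5), 8 families by default.
- **Causative allele**: per family, gene-dropped from a carrier founder
  (dominant het) or two carrier founders (recessive hom); affected status
  follows the zygosity rule. Families are redrawn (bounded rejection
  sampling, 1,000 attempts, then an error — never an infinite loop) until
  they carry ≥ 2 affected members, and planted families additionally until
  at least one affected member carries the modifier and one does not, so a
  planted family is informative about divergence.
- **Modifier allele**: one shared rare variant (AF 1e-4, all predictors
  deleterious, gene outside the disease list) heterozygous in one founder
  of each of the first `plant_modifier_in_k_families` families (default 2)
  and transmitted by gene drop. Carriers are heterozygous only; homozygous
  modifiers are out of scope.
- **Severity**: assigned only to affected individuals — severe with
  probability `modifier_penetrance` (default 1.0) for modifier carriers
  and `phenocopy_rate` (default 0.0) otherwise. The defaults encode the
  implicit model of the motivating four-family study, where every severe
  patient carried a modifier and no mild patient did; both rates are
  exposed because real modifiers will be neither fully penetrant nor
  phenocopy-free.
- **Background variants** (default 200): allele frequencies from
  Beta(0.2, 20) — a rare-skewed spectrum giving a usable mix of
  filter-passing and filter-failing variants — founder genotypes from
  Hardy–Weinberg, child genotypes by Mendelian transmission (so every
  child's dosage is attainable from its parents), a 30% truly-deleterious
  fraction, and per-predictor calls flipped with `predictor_error_rate`
  (default 0.05).

Null-calibration runs plant no modifier and use `phenocopy_rate = 0.3` so
that divergent groups exist at all; this is the intended way to produce
label noise without signal.

All generators are pure functions of (config, seed): per-family RNG
streams are spawned from `SeedSequence([seed, family_index, stream])`, so
cohorts are bit-stable and families independent.

What the generator does **not** emulate: linkage disequilibrium, realistic
site-frequency spectra, recombination, consanguinity loops, genotyping
error, or ascertainment bias. Passing tests therefore demonstrate the
pipeline's correctness and calibration under idealised Mendelian
transmission, not robustness to real-exome artefacts.

## Trajectory hinge-angle analysis

Tandem-Ig proteins (titin, hemicentin-1) are mechanically rigid when
consecutive Ig domains keep a near-straight mutual orientation. Each Ig
domain has a central disulfide bridge; for a three-domain construct the
per-frame **interdomain angle** is defined at the midpoint of the central
domain's bridging cysteine pair, between the vectors to the two flanking
domains' midpoints, via arccos of the clamped normalised dot product
(180° = fully extended). Midpoints use the cysteines' CA atoms by default
— robust to SG rotamer noise — with the SG variant behind a flag; the
choice of CA midpoints and of the vertex angle at the central bridge (as
opposed to a vector-axis angle) is this package's convention, since no
universal standard exists. `locate_disulfide_pairs` finds, per domain
range, the unique SG–SG pair within 2.3 Å (an S–S bond is ~2.05 Å) and
fails loudly on zero or ambiguous pairs. Frames with missing atoms are an
error, never silently skipped — silent frame-dropping biases
distributions.

The angle series is histogrammed over [0°, 180°] (2° bins, frequencies
summing to 1) and classified by Gaussian-mixture fits with 1 and 2
components (10 restarts, fixed seed). Two components are reported only if
BIC(1) − BIC(2) > 10 (the conventional "very strong evidence" threshold),
both weights ≥ 0.05, and the means are ≥ 2 pooled SDs apart; the weight
and separation guards suppress spurious splits on heavy-tailed unimodal
data. A constant series short-circuits to unimodal.

The trajectory simulator builds pseudo-atom frames whose noise-free
CA-midpoint angle equals a commanded angle exactly (domain landmarks at
40 Å arms — the scale of an Ig domain — with atoms placed symmetrically
about each landmark), plus isotropic Gaussian coordinate noise. Hinged
mode switches the commanded angle between two values by a symmetric
two-state Markov chain (default 150°/90°, switch probability 0.05 per
frame). Real molecular-dynamics trajectories are ingested through the
multi-model PDB reader (and an XYZ dialect whose atom labels carry
`NAME.RESID`); running MD itself is out of scope, so the rigid-vs-bimodal
contrast is validated on simulated trajectories: rigid 150° constructs
with up to 5 Å of coordinate noise classify unimodal, and hinged 150°/90°
constructs classify bimodal with component means recovered within 2°.
Analyses use 2,000-frame trajectories, ample for the mixture fit while
keeping replicate studies fast.

## Blister morphometry

The organotypic-skin readout is the fraction of basement-membrane-zone
(BMZ) contour length that is blistering. Input is an annotated trace — the
BMZ polyline (pixel or micron units; the fraction is dimensionless so
calibration is irrelevant) plus blister intervals in arclength
coordinates; automated segmentation from histology images is out of scope.
Overlapping intervals are merged before summing, so annotation overlap can
never inflate the fraction, and the value is invariant to collinear
re-parameterization of the polyline. Groups of fractions are compared with
a Welch two-sided t-test; group sizes of ~29 fields per arm (58 total)
give essentially full power at α = 0.005 for the effect sizes seen in
deficient-vs-control comparisons. Pooling fields across experiments is the
default reduction; per-model averaging can be done by the caller before
testing.

## Numerical and design notes

- Dosages are int8 with −1 as missing; VCF multiallelic records are
  rejected with instructions to split/left-align upstream, rather than
  silently decomposed.
- Severity lives in a separate TSV; PED column 6 encodes affected status
  only.
- Permutation p-values are in (0, 1] by construction and monotone in the
  observed discordance.
- Fisher's combination assumes supporting groups are independent, which
  holds when groups correspond to distinct families or founder clusters.
- `assess_bimodality` requires ≥ 50 frames; below that the mixture fit is
  meaningless and the call errors.
- Replicate studies (recovery, null calibration, bimodality
  discrimination) use 100 replicates and 2,000 permutations per test —
  sizes chosen to make Monte-Carlo error small relative to the margins
  being checked.

## Known limitations

- The screen has no formal linkage model (no LOD scores, kinship, or
  burden tests) — it is a filter-plus-permutation procedure, faithful to
  the discovery logic it encodes.
- Groups with many candidates are not corrected for multiple testing
  across variants; the permutation p is per-(variant, group) and the
  aggregation is deliberately simple.
- The perfect-pattern requirement makes the screen conservative under
  incomplete penetrance; lowering strictness requires changing the
  pattern definition, not a tuning knob.
- The geometry module analyses geometry only; it knows nothing of forces,
  energetics, or solvent.
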