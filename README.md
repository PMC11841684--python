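# ebsmod

Modifier-gene co-segregation screening for pedigreed disease cohorts, with
two companion analyses: interdomain hinge-angle statistics for tandem-Ig
coordinate trajectories, and blister-fraction morphometry for organotypic
skin sections.

## The problem

Epidermolysis bullosa simplex (EBS) is an inherited blistering disorder,
usually caused by variants in the basal keratins KRT5/KRT14. Families that
segregate the *same* causative keratin variant can nonetheless differ
sharply in severity, pointing to modifier genes. Given a cohort of
pedigrees, genotypes, and ordinal severity ratings, `ebsmod` automates the
discovery logic:

1. pool affected patients who share a causative variant (founder alleles
   pool across families);
2. keep the groups whose members diverge into severe and mild;
3. restrict to rare variants (population AF ≤ 0.001 by default) with a
   consensus of deleterious predictor calls in genes outside the known
   disease-gene list;
4. test each candidate for co-segregation with severity inside each
   divergent group: a *perfect* pattern is presence in every severe and
   absence in every genotyped mild patient, and the permutation p-value is
   the fraction of severity relabelings (severe count preserved) at least
   as concordant, smoothed as p = (b+1)/(B+1);
5. combine evidence across supporting families with Fisher's method and
   rank; optionally count carriers of the surviving candidates in a
   healthy population panel.

A seeded synthetic-data module generates cohorts with a planted modifier
(configurable penetrance and phenocopy rate), Hardy–Weinberg population
panels, and rigid/hinged pseudo-atom trajectories, so the whole pipeline is
testable end to end without any external data.

## Worked example

The built-in worked-example cohort encodes four EBS families (20 affected
patients, KRT14 causative variants, three severely affected individuals
each carrying one rare heterozygous HMCN1 variant):

```python
from ebsmod import encode_paper_cohort, run_screen, ScreenConfig

cohort, expected = encode_paper_cohort()
report = run_screen(cohort, ScreenConfig(seed=0))

print(len(cohort.affected_ids))          # 20 affected patients
print(len(report.groups))                # 3 shared-causative groups
for c in report.candidates:
    print(c.rank, c.gene, c.variant_key, round(c.combined_p, 3))
```

prints

```
20
3
1 HMCN1 ('1', 185995800, 'C', 'T') 0.101
2 HMCN1 ('1', 185990500, 'G', 'A') 0.199
3 HMCN1 ('1', 185942300, 'G', 'A') 0.202
```

— the three HMCN1 candidates, each supported by a perfect segregation
pattern in its family group; the founder group spanning families 3 and 4
has ten genotyped affected members, which is why its candidate
(p.His4084Tyr) earns the smallest permutation p. Across the three
candidates the supporting groups cover all four families.

The same screen runs from the shell over the standard file formats
(6-column PED, VCF with `GENE`/`AF_POP`/`PRED_*` INFO keys, severity TSV):

```bash
ebsmod simulate-cohort --seed 11 --out sim/
ebsmod screen --vcf sim/cohort.vcf --ped sim/cohort.ped \
    --pheno sim/phenotypes.tsv --causative sim/causative.toml \
    --disease-genes sim/disease_genes.txt --out report/
```

Trajectory and morphometry tools:

```bash
ebsmod simulate-trajectory --seed 2 --out traj.pdb
ebsmod angles --traj traj.pdb --domains domains.toml \
    --out angles.tsv --summary summary.json
ebsmod blister --traces traces.json --out blister.tsv
```

`angles` reports the per-frame interdomain angle of a tandem-Ig construct
(the vertex angle at the central domain's disulfide-bridge midpoint) and a
unimodal/bimodal verdict from a BIC-guarded Gaussian-mixture fit — rigid
tandems sit near 150°, destabilised hinges produce a second bent mode.

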