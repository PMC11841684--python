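import numpy as np
import pytest

from ebsmod.cohort import (
    CausativeAssignment,
    GenotypeMatrix,
    Individual,
    Inheritance,
    Pedigree,
    PredictorCall,
    Severity,
    Sex,
    VariantRecord,
    encode_paper_cohort,
    validate_cohort,
)


@pytest.fixture(scope="session")
def paper_cohort():
    cohort, expected = encode_paper_cohort()
    return cohort, expected


def make_single_family_cohort(carrier_flags, severe_flags, candidate_af=1e-4):
    """One-family cohort of len(flags) affected sibs plus unaffected founders.

    All affected carry a dominant causative variant; the candidate variant is
    carried by the sibs flagged in ``carrier_flags``; severity follows
    ``severe_flags``.  Used to exercise the segregation test on hand-built
    carrier/severity patterns.
    """
    assert len(carrier_flags) == len(severe_flags)
    n = len(carrier_flags)
    fid = "FX"
    members = [
        Individual(f"{fid}-I-1", fid, sex=Sex.MALE),
        Individual(f"{fid}-I-2", fid, sex=Sex.FEMALE),
    ]
    for j in range(n):
        members.append(
            Individual(
                f"{fid}-II-{j + 1}",
                fid,
                father_id=f"{fid}-I-1",
                mother_id=f"{fid}-I-2",
                sex=Sex.UNKNOWN,
                affected=True,
            )
        )
    ped = Pedigree(fid, tuple(members))

    deleterious = {p: PredictorCall.DELETERIOUS for p in ("A", "B", "C", "D", "E")}
    causal = VariantRecord(
        "17", 100, "G", "A", gene="KRT14", population_af=1e-5,
        predictor_scores=deleterious,
    )
    cand = VariantRecord(
        "1", 200, "C", "T", gene="CAND", population_af=candidate_af,
        predictor_scores=deleterious,
    )
    samples = [m.individual_id for m in ped.members]
    dosages = np.zeros((2, len(samples)), dtype=np.int8)
    for j, m in enumerate(ped.members):
        if m.affected:
            dosages[0, j] = 1
            dosages[1, j] = 1 if carrier_flags[j - 2] else 0
    matrix = GenotypeMatrix([causal.key, cand.key], samples, dosages)
    phenotypes = {
        f"{fid}-II-{j + 1}": (Severity.SEVERE if severe_flags[j] else Severity.MILD)
        for j in range(n)
    }
    causative = [CausativeAssignment(fid, causal.key, Inheritance.DOMINANT_HET)]
    cohort = validate_cohort(
        [ped], [causal, cand], matrix, phenotypes, causative, {"KRT5", "KRT14"}
    )
    return cohort, cand.key
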