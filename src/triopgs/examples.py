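"""Synthetic worked-example cohorts.

`composition_cohort` builds a cohort whose availability flags reproduce the
sample-composition margins of a typical clinical trio study: 367 probands in
complete trios (39 of them younger siblings in multi-proband families), 454
probands in incomplete trios, 36 unclassified because a provided parental
sample failed genotyping, and 328 trios surviving the
oldest-proband/same-array filters. The genotypes themselves are small
synthetic Mendelian trios; only the margins are fixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import MISSING, TrioCohort

N_COMPLETE_FAMILIES = 328
N_MULTI_PROBAND_EXTRA = 39
N_INCOMPLETE = 454
N_UNCLASSIFIED = 36
N_VARIANTS = 60
_AF = 0.3


def _transmit(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one transmitted allele per locus from a parent dosage vector."""
    het = parent == 1
    allele = np.where(parent == 2, 1, 0)
    allele[het] = rng.integers(0, 2, size=int(het.sum()))
    return allele


def composition_cohort(seed: int = 0) -> TrioCohort:
    """Cohort constructed to published-style trio-status margins."""
    rng = np.random.default_rng(seed)
    n_fam = N_COMPLETE_FAMILIES + N_INCOMPLETE + N_UNCLASSIFIED
    fam_ids = [f"F{i + 1:04d}" for i in range(n_fam)]

    # multi-proband families are the first N_MULTI_PROBAND_EXTRA complete ones
    ped_rows, phen_rows, avail_rows = [], [], []
    samples, dosage_rows = [], []

    def draw_parent() -> np.ndarray:
        return (rng.random((2, N_VARIANTS)) < _AF).sum(axis=0).astype(np.int16)

    for i, fam in enumerate(fam_ids):
        father, mother = f"{fam}_D", f"{fam}_M"
        f_dos, m_dos = draw_parent(), draw_parent()
        children = [f"{fam}_C1"]
        if i < N_MULTI_PROBAND_EXTRA:
            children.append(f"{fam}_C2")
        ped_rows.append((fam, father, "0", "0", 1, -9))
        ped_rows.append((fam, mother, "0", "0", 2, -9))
        samples.extend([father, mother])
        dosage_rows.extend([f_dos, m_dos])
        for k, child in enumerate(children):
            c_dos = (_transmit(f_dos, rng) + _transmit(m_dos, rng)).astype(np.int16)
            ped_rows.append((fam, child, father, mother, 0, 2))
            samples.append(child)
            dosage_rows.append(c_dos)
            # the first-listed child is the oldest
            phen_rows.append(
                {
                    "individual_id": child,
                    "family_id": fam,
                    "age": 12.0 - 2.0 * k,
                    "sex": 1,
                    "case": True,
                }
            )
        if i < N_COMPLETE_FAMILIES:
            avail = dict(father_dna=True, mother_dna=True,
                         father_genotyped=True, mother_genotyped=True)
        elif i < N_COMPLETE_FAMILIES + N_INCOMPLETE:
            # father most often the non-providing parent
            father_out = (i % 10) != 0
            avail = dict(father_dna=not father_out, mother_dna=father_out,
                         father_genotyped=not father_out, mother_genotyped=father_out)
        else:
            avail = dict(father_dna=True, mother_dna=True,
                         father_genotyped=False, mother_genotyped=True)
        avail_rows.append(
            {
                "family_id": fam, **avail,
                "child_genotyped": True,
                "father_array": "A1", "mother_array": "A1", "child_array": "A1",
            }
        )

    dosages = np.asarray(dosage_rows, dtype=np.int16)
    # parents without DNA or failed genotyping carry no usable genotypes
    avail_df = pd.DataFrame(avail_rows)
    ped_df = pd.DataFrame(
        ped_rows,
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
    )
    idx = {s: i for i, s in enumerate(samples)}
    for _, a in avail_df.iterrows():
        if not (a["father_dna"] and a["father_genotyped"]):
            dosages[idx[f"{a['family_id']}_D"]] = MISSING
        if not (a["mother_dna"] and a["mother_genotyped"]):
            dosages[idx[f"{a['family_id']}_M"]] = MISSING

    variants = pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(N_VARIANTS)],
            "chrom": "1",
            "pos": np.arange(1, N_VARIANTS + 1) * 5000,
            "ref": "A",
            "alt": "C",
            "af": _AF,
            "ld_block": np.arange(N_VARIANTS),
            "true_weight": 0.0,
            "gwas_beta": 0.0,
            "gwas_p": 1.0,
        }
    )
    return TrioCohort(
        variants=variants,
        samples=samples,
        dosages=dosages,
        pedigree=ped_df,
        phenotypes=pd.DataFrame(phen_rows),
        availability=avail_df,
        controls=[],
        meta={"seed": seed, "synthetic": "sample-composition margins fixture"},
    )


def composition_counts(cohort: TrioCohort) -> dict:
    """Run status classification + filters; return the composition counts."""
    from .qc import classify_trio_status, select_ptdt_trios

    statuses = classify_trio_status(cohort)
    children = cohort.children()[["family_id", "individual_id"]]
    merged = children.merge(statuses, on="family_id")
    counts = merged["status"].value_counts().to_dict()
    eligible = select_ptdt_trios(cohort, statuses)
    return {
        "complete_trio_probands": int(counts.get("complete", 0)),
        "incomplete_trio_probands": int(counts.get("incomplete", 0)),
        "unclassified_probands": int(counts.get("unclassified", 0)),
        "oldest_proband_exclusions": int(counts.get("complete", 0) - len(eligible)),
        "ptdt_eligible_trios": int(len(eligible)),
    }
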