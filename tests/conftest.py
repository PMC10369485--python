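import numpy as np
import pandas as pd
import pytest

from triopgs.cohort import TrioCohort
from triopgs.config import SimConfig
from triopgs.simulate import (
    ascertain,
    assign_phenotypes,
    simulate_missingness,
    simulate_trio_cohort,
    simulate_variants,
)


def make_variants(n=5, af=0.3, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "id": [f"rs{i + 1}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 1000,
            "ref": "A",
            "alt": "C",
            "af": af,
            "ld_block": np.arange(n),
            "true_weight": rng.normal(size=n),
            "gwas_beta": rng.normal(size=n),
            "gwas_p": rng.uniform(0.001, 1, size=n),
        }
    )


def make_trio_cohort(trio_dosages, variants=None, availability=True):
    """Hand-built cohort: trio_dosages maps family -> (child, father, mother)
    dosage vectors."""
    fams = list(trio_dosages)
    n_var = len(next(iter(trio_dosages.values()))[0])
    variants = variants if variants is not None else make_variants(n_var)
    samples, rows, ped = [], [], []
    for fam, (c, f, m) in trio_dosages.items():
        cid, fid, mid = f"{fam}_C1", f"{fam}_D", f"{fam}_M"
        ped.append((fam, fid, "0", "0", 1, -9))
        ped.append((fam, mid, "0", "0", 2, -9))
        ped.append((fam, cid, fid, mid, 0, 2))
        samples.extend([fid, mid, cid])
        rows.extend([f, m, c])
    avail = pd.DataFrame(
        {
            "family_id": fams,
            "father_dna": True, "mother_dna": True,
            "father_genotyped": True, "mother_genotyped": True,
            "child_genotyped": True,
            "father_array": "A1", "mother_array": "A1", "child_array": "A1",
        }
    ) if availability else pd.DataFrame()
    return TrioCohort(
        variants=variants,
        samples=samples,
        dosages=np.asarray(rows, dtype=np.int16),
        pedigree=pd.DataFrame(
            ped, columns=["family_id", "individual_id", "father_id", "mother_id",
                          "sex", "phenotype"],
        ),
        availability=avail,
    )


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_variants=200, n_ld_blocks=20, n_trio_families=80, n_controls=200,
        h2_direct=0.3, prevalence=0.05, seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    variants = simulate_variants(small_config)
    cohort = simulate_trio_cohort(small_config, variants)
    cohort = assign_phenotypes(cohort, small_config)
    cohort = ascertain(cohort, small_config)
    return simulate_missingness(cohort, small_config)
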