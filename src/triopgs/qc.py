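"""Trio-status classification, parentage checks and inclusion filters.

Families are partitioned exhaustively into:

* ``complete`` (coded 0): both parents provided DNA and were confirmed as
  the biological parents — regardless of whether both later passed
  genotyping QC;
* ``incomplete`` (coded 1): one or both parents did not provide DNA;
* ``unclassified``: both provided DNA but a genotyping failure (or a failed
  parentage check) prevented confirmation of biological parenthood.

Parentage is confirmed with a Mendelian-error-rate test: the fraction of
fully observed loci whose transmission is impossible. True trios without a
genotyping-error model have rate 0; an unrelated child produces errors at a
rate predictable from the allele frequencies under Hardy-Weinberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import MISSING, TrioCohort
from .pseudocontrols import mendelian_consistent

DEFAULT_MENDEL_THRESHOLD = 0.01
MIN_INFORMATIVE_LOCI = 50


class TrioStatus(Enum):
    COMPLETE = 0
    INCOMPLETE = 1
    UNCLASSIFIED = "unclassified"


@dataclass
class ParentageResult:
    family_id: str
    n_informative: int
    error_rate: float
    confirmed: Optional[bool]  # None = indeterminate

    @property
    def indeterminate(self) -> bool:
        return self.confirmed is None


def parentage_check(
    cohort: TrioCohort,
    family_id: str,
    threshold: float = DEFAULT_MENDEL_THRESHOLD,
    min_informative: int = MIN_INFORMATIVE_LOCI,
) -> ParentageResult:
    """Mendelian-error-rate parentage test for one trio."""
    child, father, mother = cohort.trio(family_id)
    c = cohort.dosage_of([child])[0]
    f = cohort.dosage_of([father])[0]
    m = cohort.dosage_of([mother])[0]
    observed = (c != MISSING) & (f != MISSING) & (m != MISSING)
    n_inf = int(observed.sum())
    if n_inf < min_informative:
        return ParentageResult(family_id, n_inf, float("nan"), None)
    errors = ~mendelian_consistent(f[observed], m[observed], c[observed])
    rate = float(errors.mean())
    return ParentageResult(family_id, n_inf, rate, rate <= threshold)


def expected_unrelated_error_rate(af: np.ndarray) -> float:
    """Analytic Mendelian-error rate for an unrelated 'child' under HWE.

    Enumerates the 3x3x3 genotype table with HWE weights at each allele
    frequency and averages the probability of an impossible triple. Serves
    as the power reference for the parentage test.
    """
    af = np.asarray(af, dtype=float)
    total = 0.0
    for p in af:
        q = 1.0 - p
        gp = np.array([q * q, 2 * p * q, p * p])  # P(dosage = 0,1,2)
        acc = 0.0
        for fd in range(3):
            for md in range(3):
                for cd in range(3):
                    if not mendelian_consistent(
                        np.array([fd]), np.array([md]), np.array([cd])
                    )[0]:
                        acc += gp[fd] * gp[md] * gp[cd]
        total += acc
    return total / len(af)


def classify_trio_status(
    cohort: TrioCohort,
    mendel_threshold: float = DEFAULT_MENDEL_THRESHOLD,
    run_parentage: bool = True,
) -> pd.DataFrame:
    """Assign every family a TrioStatus.

    Requires availability flags. A family is complete only if both parents
    provided DNA *and* parentage could be (and was) confirmed; genotyping
    failure of a provided sample blocks confirmation, leaving the family
    unclassified. Any parent without DNA makes the family incomplete.

    Returns a DataFrame with family_id, status, status_code (0 complete /
    1 incomplete / NaN unclassified) and the parentage error rate where
    computed.
    """
    fams = cohort.family_ids()
    avail = cohort.availability.set_index("family_id")
    missing_fams = [f for f in fams if f not in avail.index]
    if missing_fams:
        raise KeyError(f"families without availability rows: {missing_fams[:5]}")
    rows = []
    for f in fams:
        a = avail.loc[f]
        rate = np.nan
        if not (a["father_dna"] and a["mother_dna"]):
            status = TrioStatus.INCOMPLETE
        elif not (a["father_genotyped"] and a["mother_genotyped"] and a["child_genotyped"]):
            status = TrioStatus.UNCLASSIFIED
        elif run_parentage:
            pr = parentage_check(cohort, f, threshold=mendel_threshold)
            rate = pr.error_rate
            if pr.confirmed is True:
                status = TrioStatus.COMPLETE
            else:  # rejected or indeterminate: parenthood unconfirmed
                status = TrioStatus.UNCLASSIFIED
        else:
            status = TrioStatus.COMPLETE
        rows.append(
            {
                "family_id": f,
                "status": status.name.lower(),
                "status_code": status.value if status is not TrioStatus.UNCLASSIFIED else np.nan,
                "mendel_error_rate": rate,
            }
        )
    return pd.DataFrame(rows)


def select_ptdt_trios(cohort: TrioCohort, statuses: pd.DataFrame) -> pd.DataFrame:
    """Apply the transmission-analysis filters to complete trios.

    Keeps complete trios in which all three members passed genotyping QC and
    share one array, and retains only the oldest proband per family (age
    ties broken by lexicographic sample id for determinism).

    Returns a DataFrame with family_id, child_id, father_id, mother_id.
    """
    complete = set(statuses.loc[statuses["status"] == "complete", "family_id"])
    avail = cohort.availability.set_index("family_id")
    phen = cohort.phenotypes.set_index("individual_id") if len(cohort.phenotypes) else None
    rows = []
    children = cohort.children()
    for fam, grp in children.groupby("family_id", sort=False):
        if fam not in complete:
            continue
        a = avail.loc[fam]
        if not (a["father_genotyped"] and a["mother_genotyped"] and a["child_genotyped"]):
            continue
        if not (a["father_array"] == a["mother_array"] == a["child_array"]):
            continue
        cand = grp["individual_id"].tolist()
        if phen is not None:
            ages = {c: float(phen.loc[c, "age"]) if c in phen.index else -np.inf for c in cand}
            # oldest first; ties by id
            cand.sort(key=lambda c: (-ages[c], c))
        else:
            cand.sort()
        child = cand[0]
        row = grp[grp["individual_id"] == child].iloc[0]
        rows.append(
            {
                "family_id": fam,
                "child_id": child,
                "father_id": row["father_id"],
                "mother_id": row["mother_id"],
            }
        )
    return pd.DataFrame(rows, columns=["family_id", "child_id", "father_id", "mother_id"])
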