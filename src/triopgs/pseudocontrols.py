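"""Nontransmitted parental alleles (pseudo-controls) for complete trios.

At a biallelic locus the two parental alleles not transmitted to the child
form a composite pseudo-control dosage NT = father + mother - child. The
identity holds whenever at least one of the four possible allele
transmissions is consistent with the observed triple; inconsistent triples
are Mendelian errors and are nulled per locus.

Because every downstream use of the pseudo-control is an additive score,
the composite dosage satisfies the exact linearity
score(NT) = score(F) + score(M) - score(C) at fully observed loci.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import MISSING, TrioCohort

NT_SUFFIX = "_NT"


def mendelian_consistent(
    father: np.ndarray, mother: np.ndarray, child: np.ndarray
) -> np.ndarray:
    """Boolean mask of triples reachable by some allele transmission.

    A parent with dosage 0 can only transmit the reference allele, dosage 2
    only the alternate, dosage 1 either. The child dosage must decompose as
    one paternal plus one maternal transmitted allele.
    """
    f = np.asarray(father, dtype=np.int64)
    m = np.asarray(mother, dtype=np.int64)
    c = np.asarray(child, dtype=np.int64)
    pat_lo, pat_hi = (f >= 1).astype(np.int64) * (f == 2), (f >= 1).astype(np.int64)
    mat_lo, mat_hi = (m >= 1).astype(np.int64) * (m == 2), (m >= 1).astype(np.int64)
    lo = pat_lo + mat_lo  # minimal transmissible alt count
    hi = pat_hi + mat_hi  # maximal transmissible alt count
    return (c >= lo) & (c <= hi)


def nontransmitted_dosages(
    father: np.ndarray, mother: np.ndarray, child: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Composite nontransmitted dosage per locus for one trio.

    Returns ``(nt, mendel_error)`` where ``nt`` is F + M - C with the missing
    sentinel wherever any member is missing or the triple is Mendelian-
    inconsistent, and ``mendel_error`` flags the inconsistent loci.
    """
    f = np.asarray(father, dtype=np.int64)
    m = np.asarray(mother, dtype=np.int64)
    c = np.asarray(child, dtype=np.int64)
    observed = (f != MISSING) & (m != MISSING) & (c != MISSING)
    ok = np.zeros_like(observed)
    ok[observed] = mendelian_consistent(f[observed], m[observed], c[observed])
    error = observed & ~ok
    nt = np.full(f.shape, MISSING, dtype=np.int16)
    nt[ok] = (f[ok] + m[ok] - c[ok]).astype(np.int16)
    return nt, error


def build_nontransmitted_cohort(
    cohort: TrioCohort, eligible: pd.DataFrame | list
) -> tuple[TrioCohort, pd.DataFrame]:
    """Append one NT pseudo-sample per eligible trio.

    Parameters
    ----------
    cohort : TrioCohort
    eligible : DataFrame with columns family_id/child_id/father_id/mother_id
        (as produced by :func:`triopgs.qc.select_ptdt_trios`) or a list of
        family ids.

    Returns
    -------
    (extended cohort, per-variant Mendelian error report)
        NT samples carry the child id plus ``_NT``.
    """
    if isinstance(eligible, (list, tuple, set)):
        rows = [
            dict(zip(("child_id", "father_id", "mother_id"), cohort.trio(f)), family_id=f)
            for f in eligible
        ]
        eligible = pd.DataFrame(rows)
    if len(eligible) == 0:
        warnings.warn("no eligible trios: cohort returned without NT samples")
        report = pd.DataFrame(
            {"id": cohort.variants["id"], "mendel_errors": 0, "n_trios": 0}
        )
        return cohort, report

    nt_rows, nt_ids = [], []
    err_count = np.zeros(cohort.n_variants, dtype=np.int64)
    for _, t in eligible.iterrows():
        f = cohort.dosage_of([t["father_id"]])[0]
        m = cohort.dosage_of([t["mother_id"]])[0]
        c = cohort.dosage_of([t["child_id"]])[0]
        nt, err = nontransmitted_dosages(f, m, c)
        err_count += err
        nt_rows.append(nt)
        nt_ids.append(str(t["child_id"]) + NT_SUFFIX)

    ped_extra = pd.DataFrame(
        {
            "family_id": eligible["family_id"].to_numpy(),
            "individual_id": nt_ids,
            "father_id": "0",
            "mother_id": "0",
            "sex": 0,
            "phenotype": -9,
        }
    )
    extended = TrioCohort(
        variants=cohort.variants,
        samples=cohort.samples + nt_ids,
        dosages=np.vstack([cohort.dosages, np.asarray(nt_rows, dtype=np.int16)]),
        pedigree=pd.concat([cohort.pedigree, ped_extra], ignore_index=True),
        phenotypes=cohort.phenotypes,
        availability=cohort.availability,
        controls=cohort.controls,
        meta=dict(cohort.meta),
    )
    extended.meta["nt_samples"] = nt_ids
    report = pd.DataFrame(
        {
            "id": cohort.variants["id"].to_numpy(),
            "mendel_errors": err_count,
            "n_trios": len(eligible),
        }
    )
    return extended, report
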