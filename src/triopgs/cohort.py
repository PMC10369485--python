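"""In-memory containers: variant table and trio cohort.

Dosages count copies of the alternate allele (0/1/2) with ``MISSING`` (-1)
as the sentinel for no-calls. Pedigrees follow the FAM convention
(family, individual, father, mother, sex, phenotype) with "0" for unknown
parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

VARIANT_COLUMNS = [
    "id", "chrom", "pos", "ref", "alt", "af",
    "ld_block", "true_weight", "gwas_beta", "gwas_p",
]

PEDIGREE_COLUMNS = ["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"]

AVAILABILITY_COLUMNS = [
    "family_id",
    "father_dna", "mother_dna",
    "father_genotyped", "mother_genotyped", "child_genotyped",
    "father_array", "mother_array", "child_array",
]


def empty_variant_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in VARIANT_COLUMNS})


def validate_variant_table(variants: pd.DataFrame) -> None:
    """Check ordering and frequency invariants of a variant table."""
    if len(variants) == 0:
        return
    for chrom, grp in variants.groupby("chrom", sort=False):
        pos = np.asarray(grp["pos"], dtype=np.int64)
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"positions not strictly increasing on chrom {chrom}")
    af = np.asarray(variants["af"], dtype=float)
    if np.any((af <= 0) | (af >= 1)):
        raise ValueError("allele frequencies must lie in (0, 1)")


@dataclass
class TrioCohort:
    """Genotype dosages plus pedigree, phenotypes and availability flags.

    Attributes
    ----------
    variants : pandas.DataFrame
        One row per variant (see VARIANT_COLUMNS).
    samples : list of str
        Sample ids; row order of ``dosages``.
    dosages : ndarray of shape (n_samples, n_variants), dtype int16
        Alternate-allele counts, -1 for missing.
    pedigree : pandas.DataFrame
        FAM-style rows for every individual, founders included.
    phenotypes : pandas.DataFrame
        Per-child phenotype rows indexed by individual_id.
    availability : pandas.DataFrame
        Per-family DNA/genotyping/array flags (one row per family).
    controls : list of str
        Ids of the unscreened population control pool.
    """

    variants: pd.DataFrame
    samples: list[str]
    dosages: np.ndarray
    pedigree: pd.DataFrame
    phenotypes: pd.DataFrame = field(default_factory=pd.DataFrame)
    availability: pd.DataFrame = field(default_factory=pd.DataFrame)
    controls: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self._index = {s: i for i, s in enumerate(self.samples)}
        if len(self._index) != len(self.samples):
            raise ValueError("duplicate sample ids")

    # -- lookups ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def row(self, sample_id: str) -> int:
        try:
            return self._index[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in cohort") from None

    def dosage_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        idx = [self.row(s) for s in sample_ids]
        return self.dosages[idx]

    def children(self) -> pd.DataFrame:
        ped = self.pedigree
        return ped[(ped["father_id"] != "0") | (ped["mother_id"] != "0")]

    def founders(self) -> pd.DataFrame:
        ped = self.pedigree
        return ped[(ped["father_id"] == "0") & (ped["mother_id"] == "0")]

    def family_ids(self) -> list[str]:
        ids = self.children()["family_id"].unique().tolist()
        return ids

    def trio(self, family_id: str, child_id: Optional[str] = None) -> tuple[str, str, str]:
        """Return (child, father, mother) ids for a family.

        With multiple children the first pedigree row is used unless
        ``child_id`` is given.
        """
        fam = self.children()
        fam = fam[fam["family_id"] == family_id]
        if child_id is not None:
            fam = fam[fam["individual_id"] == child_id]
        if len(fam) == 0:
            raise KeyError(f"no child rows for family {family_id!r}")
        row = fam.iloc[0]
        return row["individual_id"], row["father_id"], row["mother_id"]

    def subset_samples(self, sample_ids: Iterable[str]) -> "TrioCohort":
        keep = list(sample_ids)
        keep_set = set(keep)
        ped = self.pedigree[self.pedigree["individual_id"].isin(keep_set)].reset_index(drop=True)
        phen = self.phenotypes
        if len(phen) and "individual_id" in phen.columns:
            phen = phen[phen["individual_id"].isin(keep_set)].reset_index(drop=True)
        fams = set(ped["family_id"])
        avail = self.availability
        if len(avail):
            avail = avail[avail["family_id"].isin(fams)].reset_index(drop=True)
        return TrioCohort(
            variants=self.variants,
            samples=keep,
            dosages=self.dosage_of(keep),
            pedigree=ped,
            phenotypes=phen,
            availability=avail,
            controls=[c for c in self.controls if c in keep_set],
            meta=dict(self.meta),
        )

    def check_mendelian_reachability(self) -> int:
        """Count loci x trios where the child dosage is unreachable.

        Used as a simulator invariant; returns the number of violations at
        fully observed loci.
        """
        from .pseudocontrols import mendelian_consistent

        bad = 0
        for fam in self.family_ids():
            for _, row in self.children()[self.children()["family_id"] == fam].iterrows():
                c = self.dosage_of([row["individual_id"]])[0]
                f = self.dosage_of([row["father_id"]])[0]
                m = self.dosage_of([row["mother_id"]])[0]
                obs = (c != MISSING) & (f != MISSING) & (m != MISSING)
                bad += int(np.sum(~mendelian_consistent(f[obs], m[obs], c[obs])))
        return bad
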