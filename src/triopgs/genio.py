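"""Reading and writing the pipeline's file formats.

Genotypes travel as GT-only VCF v4.2 (read through cyvcf2) or as PED/MAP
text; the pedigree as a FAM-style table; phenotypes, availability flags and
the variant table as tab-delimited text; GWAS summary statistics as a
tab-delimited table with required header names
``id chrom pos effect_allele other_allele beta p``.

Coordinates are 1-based as in VCF and dosages count the alternate allele.
Missing dosages are carried as the sentinel and never imputed at I/O time.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MISSING, TrioCohort, validate_variant_table

log = logging.getLogger(__name__)

GWAS_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p"]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


class ParseError(ValueError):
    """Malformed record in an input file (carries the line number)."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path, self.line_no = str(path), line_no


class ReferentialError(ValueError):
    """Pedigree id absent from the genotype data (or vice versa)."""


# ---------------------------------------------------------------------------
# cohort save/load
# ---------------------------------------------------------------------------

def save_cohort(cohort: TrioCohort, prefix: str | os.PathLike, fmt: str = "vcf") -> dict:
    """Write a cohort under a path prefix; returns the path map.

    Produces ``<prefix>.vcf`` or ``<prefix>.ped``/``.map``, plus sidecars
    ``.fam`` (pedigree), ``.variants.tsv``, ``.phenotypes.tsv``,
    ``.availability.tsv``, ``.controls.txt`` and ``.meta.json``.
    """
    if fmt not in ("vcf", "ped"):
        raise ValueError(f"unsupported format {fmt!r}")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    if fmt == "vcf":
        paths["genotypes"] = _write_vcf(cohort, prefix.with_suffix(".vcf"))
    else:
        paths["genotypes"] = _write_ped(cohort, prefix.with_suffix(".ped"))
        paths["map"] = _write_map(cohort, prefix.with_suffix(".map"))

    fam_path = prefix.with_suffix(".fam")
    cohort.pedigree.to_csv(fam_path, sep="\t", header=False, index=False)
    paths["pedigree"] = fam_path

    var_path = Path(str(prefix) + ".variants.tsv")
    cohort.variants.to_csv(var_path, sep="\t", index=False)
    paths["variants"] = var_path

    phen_path = Path(str(prefix) + ".phenotypes.tsv")
    cohort.phenotypes.to_csv(phen_path, sep="\t", index=False)
    paths["phenotypes"] = phen_path

    avail_path = Path(str(prefix) + ".availability.tsv")
    cohort.availability.to_csv(avail_path, sep="\t", index=False)
    paths["availability"] = avail_path

    ctrl_path = Path(str(prefix) + ".controls.txt")
    ctrl_path.write_text("".join(c + "\n" for c in cohort.controls))
    paths["controls"] = ctrl_path

    meta_path = Path(str(prefix) + ".meta.json")
    meta = {k: v for k, v in cohort.meta.items() if _json_safe(v)}
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    paths["meta"] = meta_path
    return paths


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def load_cohort(prefix: str | os.PathLike, fmt: str = "vcf") -> TrioCohort:
    """Read a cohort written by :func:`save_cohort` (round-trip inverse)."""
    if fmt not in ("vcf", "ped"):
        raise ValueError(f"unsupported format {fmt!r}")
    prefix = Path(prefix)
    var_path = Path(str(prefix) + ".variants.tsv")
    variants = pd.read_csv(var_path, sep="\t", dtype={"chrom": str}) if var_path.exists() else None

    if fmt == "vcf":
        samples, dosages, vcf_variants = _read_vcf(prefix.with_suffix(".vcf"))
        if variants is None:
            variants = vcf_variants
    else:
        if variants is None:
            raise FileNotFoundError(
                f"{var_path} required to orient PED alleles (no ref/alt in PED/MAP)"
            )
        samples, dosages = _read_ped(prefix.with_suffix(".ped"), variants)

    pedigree = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep="\t",
        header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
        dtype={"family_id": str, "individual_id": str, "father_id": str, "mother_id": str},
    )
    known = set(samples)
    for col in ("father_id", "mother_id"):
        bad = pedigree.loc[
            (pedigree[col] != "0") & ~pedigree[col].isin(set(pedigree["individual_id"])), col
        ]
        if len(bad):
            raise ReferentialError(f"pedigree references unknown {col}: {bad.iloc[0]!r}")
    absent = [s for s in pedigree["individual_id"] if s not in known]
    if absent:
        raise ReferentialError(f"pedigree ids absent from genotypes: {absent[:5]}")

    phen_path = Path(str(prefix) + ".phenotypes.tsv")
    phenotypes = (
        pd.read_csv(phen_path, sep="\t", dtype={"individual_id": str, "family_id": str})
        if phen_path.exists() and phen_path.stat().st_size > 1
        else pd.DataFrame()
    )
    avail_path = Path(str(prefix) + ".availability.tsv")
    availability = (
        pd.read_csv(avail_path, sep="\t", dtype={"family_id": str})
        if avail_path.exists() and avail_path.stat().st_size > 1
        else pd.DataFrame()
    )
    ctrl_path = Path(str(prefix) + ".controls.txt")
    controls = (
        [l for l in ctrl_path.read_text().splitlines() if l] if ctrl_path.exists() else []
    )
    meta_path = Path(str(prefix) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TrioCohort(
        variants=variants,
        samples=samples,
        dosages=dosages,
        pedigree=pedigree,
        phenotypes=phenotypes,
        availability=availability,
        controls=controls,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _write_vcf(cohort: TrioCohort, path: Path) -> Path:
    v = cohort.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(v["chrom"]) if len(v) else []:
            fh.write(f"##contig=<ID={chrom}>\n")
        if "seed" in cohort.meta:
            fh.write(f"##triopgs_seed={cohort.meta['seed']}\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        dos = cohort.dosages
        for j in range(len(v)):
            row = v.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(d)] for d in dos[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )
    return path


def _read_vcf(path: Path) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    from cyvcf2 import VCF

    if not Path(path).exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, recs = [], []
    # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
    remap = np.array([0, 1, MISSING, 2], dtype=np.int16)
    for rec in vcf:
        rows.append(remap[rec.gt_types])
        recs.append(
            {
                "id": rec.ID,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
            }
        )
    dosages = (
        np.asarray(rows, dtype=np.int16).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int16)
    )
    return samples, dosages, pd.DataFrame(recs, columns=["id", "chrom", "pos", "ref", "alt"])


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def _write_ped(cohort: TrioCohort, path: Path) -> Path:
    v = cohort.variants
    ped = cohort.pedigree.set_index("individual_id")
    with open(path, "w") as fh:
        for i, s in enumerate(cohort.samples):
            if s in ped.index:
                p = ped.loc[s]
                head = [p["family_id"], s, p["father_id"], p["mother_id"],
                        str(p["sex"]), str(p["phenotype"])]
            else:
                head = [s, s, "0", "0", "0", "-9"]
            alleles = []
            for j in range(len(v)):
                d = int(cohort.dosages[i, j])
                ref, alt = v.iloc[j]["ref"], v.iloc[j]["alt"]
                pair = {0: (ref, ref), 1: (ref, alt), 2: (alt, alt), MISSING: ("0", "0")}[d]
                alleles.extend(pair)
            fh.write(" ".join(head + alleles) + "\n")
    return path


def _write_map(cohort: TrioCohort, path: Path) -> Path:
    v = cohort.variants
    with open(path, "w") as fh:
        for j in range(len(v)):
            row = v.iloc[j]
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{int(row['pos'])}\n")
    return path


def _read_ped(path: Path, variants: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    n_var = len(variants)
    ref = variants["ref"].to_numpy()
    alt = variants["alt"].to_numpy()
    samples, rows = [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_var:
                raise ParseError(
                    path, line_no,
                    f"expected {6 + 2 * n_var} fields, found {len(parts)}",
                )
            samples.append(parts[1])
            alleles = np.array(parts[6:]).reshape(n_var, 2)
            dos = np.full(n_var, MISSING, dtype=np.int16)
            miss = (alleles == "0").any(axis=1)
            n_alt = (alleles == alt[:, None]).sum(axis=1)
            n_ref = (alleles == ref[:, None]).sum(axis=1)
            bad = ~miss & (n_alt + n_ref != 2)
            if bad.any():
                j = int(np.flatnonzero(bad)[0])
                raise ParseError(
                    path, line_no,
                    f"alleles {tuple(alleles[j])} do not match {ref[j]}/{alt[j]} "
                    f"at variant {variants.iloc[j]['id']}",
                )
            dos[~miss] = n_alt[~miss]
            rows.append(dos)
    dosages = (
        np.asarray(rows, dtype=np.int16)
        if rows
        else np.zeros((0, n_var), dtype=np.int16)
    )
    return samples, dosages


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def load_gwas(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tab-delimited GWAS summary table and validate its invariants."""
    gwas = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in GWAS_COLUMNS if c not in gwas.columns]
    if missing:
        raise ParseError(path, 1, f"missing required columns {missing}")
    p = gwas["p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("GWAS p-values must lie in (0, 1]")
    return gwas


def save_gwas(gwas: pd.DataFrame, path: str | os.PathLike) -> None:
    gwas.to_csv(path, sep="\t", index=False, columns=GWAS_COLUMNS)


def gwas_from_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Express a simulated variant table as a GWAS summary table.

    The effect allele is the alternate allele, matching the dosage scale.
    """
    return pd.DataFrame(
        {
            "id": variants["id"],
            "chrom": variants["chrom"],
            "pos": variants["pos"],
            "effect_allele": variants["alt"],
            "other_allele": variants["ref"],
            "beta": variants["gwas_beta"],
            "p": variants["gwas_p"],
        }
    )


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def align_effect_alleles(variants: pd.DataFrame, gwas: pd.DataFrame) -> pd.DataFrame:
    """Orient GWAS betas to the cohort's counted (alternate) allele.

    Matching is by variant id. When the effect allele equals the cohort's
    alternate allele the beta is kept; when it equals the reference allele
    the sign is flipped. Strand-ambiguous A/T and C/G variants are dropped,
    as are variants whose allele pair neither matches nor flips; dropped
    counts are logged.

    Aligning an already aligned table is a no-op (involution on the kept
    set).
    """
    merged = variants.merge(gwas, on="id", suffixes=("", "_gwas"))
    n_unshared = len(variants) - len(merged)
    keep, beta = [], []
    n_pal = n_irrec = 0
    for _, row in merged.iterrows():
        ref, alt = row["ref"], row["alt"]
        ea, oa = row["effect_allele"], row["other_allele"]
        if _palindromic(ref, alt) or _palindromic(ea, oa):
            n_pal += 1
            continue
        pair = {ea, oa}
        if ea == alt and oa == ref:
            beta.append(row["beta"])
        elif ea == ref and oa == alt:
            beta.append(-row["beta"])
        elif pair == {_COMPLEMENT[ref], _COMPLEMENT[alt]}:
            # opposite strand: orient by complemented match
            beta.append(row["beta"] if _COMPLEMENT[ea] == alt else -row["beta"])
        else:
            n_irrec += 1
            continue
        keep.append(row)
    if n_pal or n_irrec or n_unshared:
        log.info(
            "align_effect_alleles: dropped %d palindromic, %d irreconcilable, "
            "%d unshared variants", n_pal, n_irrec, n_unshared,
        )
    if not keep:
        return pd.DataFrame(columns=["id", "chrom", "pos", "beta", "p"])
    out = pd.DataFrame(keep)
    return pd.DataFrame(
        {
            "id": out["id"].to_numpy(),
            "chrom": out["chrom"].to_numpy(),
            "pos": out["pos"].to_numpy(),
            "beta": np.asarray(beta, dtype=float),
            "p": out["p"].to_numpy(dtype=float),
        }
    )
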