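"""Synthetic trio cohorts with known direct-genetic and genetic-nurture structure.

The generator follows a liability-threshold model. Founder haplotypes are
drawn at configured allele frequencies with blockwise-equicorrelated LD;
children inherit one parental haplotype per LD block. Child liability is

    L = a * G_child + b * (G_father + G_mother) / sqrt(2) + e * N(0,1)

where G are standardized true polygenic values, a = sqrt(h2_direct), b is
the genetic-nurture coefficient (it acts through the *full* parental
polygenic value, so the nontransmitted half carries effect), and e scales
the residual so Var(L) = 1. Cases exceed the analytic Gaussian threshold
set by the population prevalence. Clinically flavoured phenotypes (symptom
counts, IQ, SES binaries) are generated with fixed loadings on liability,
and trio incompleteness follows a logistic model on child severity and low
family SES.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MISSING, TrioCohort, empty_variant_table, validate_variant_table
from .config import ConfigurationError, SimConfig

_STAGES = {
    "variants": 0,
    "founders": 1,
    "transmission": 2,
    "phenotypes": 3,
    "ascertain": 4,
    "missingness": 5,
}


class AscertainmentError(RuntimeError):
    """Fewer case families were simulated than requested."""


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    """Stage-local generator derived deterministically from the root seed."""
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STAGES[stage],))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def simulate_variants(config: SimConfig) -> pd.DataFrame:
    """Draw a variant table with LD-block structure and noisy GWAS weights.

    The "discovery GWAS" effect estimate is the true per-allele weight plus
    Gaussian noise of SD ``gwas_noise_sd``; its p-value is the two-sided
    normal tail at z = beta_hat / gwas_noise_sd, so p decreases in |beta|.
    """
    if config.n_variants == 0:
        return empty_variant_table()
    rng = _rng(config, "variants")
    n = config.n_variants
    n_blocks = max(1, min(config.n_ld_blocks, n))
    block_ids = np.repeat(np.arange(n_blocks), _block_sizes(n, n_blocks))
    lo, hi = config.maf_range
    af = rng.uniform(lo, hi, size=n)
    pos = np.cumsum(rng.integers(2_000, 8_000, size=n))  # ~5 kb spacing
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n)
    # alternate allele differs from ref; palindromic pairs arise naturally
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    w = rng.normal(0.0, 1.0, size=n)
    beta_hat = w + rng.normal(0.0, config.gwas_noise_sd, size=n)
    se = max(config.gwas_noise_sd, 1e-12)
    p = 2.0 * stats.norm.sf(np.abs(beta_hat) / se)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    tab = pd.DataFrame(
        {
            "id": [f"rs{i + 1}" for i in range(n)],
            "chrom": "1",
            "pos": pos.astype(np.int64),
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "af": af,
            "ld_block": block_ids.astype(np.int64),
            "true_weight": w,
            "gwas_beta": beta_hat,
            "gwas_p": p,
        }
    )
    validate_variant_table(tab)
    return tab


def _block_sizes(n: int, n_blocks: int) -> np.ndarray:
    sizes = np.full(n_blocks, n // n_blocks, dtype=np.int64)
    sizes[: n % n_blocks] += 1
    return sizes


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _draw_haplotypes(
    rng: np.random.Generator, variants: pd.DataFrame, n_haps: int, r: float
) -> np.ndarray:
    """Draw haplotypes with one-factor equicorrelated latent LD per block.

    Within a block the latent Gaussians share correlation ``r``; the allele
    indicator thresholds the latent at the quantile of the allele frequency,
    preserving the marginal AF exactly.
    """
    af = np.asarray(variants["af"], dtype=float)
    blocks = np.asarray(variants["ld_block"], dtype=np.int64)
    thr = stats.norm.ppf(af)
    out = np.empty((n_haps, len(af)), dtype=np.uint8)
    sq_r, sq_1mr = math.sqrt(r), math.sqrt(1.0 - r)
    for b in np.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        shared = rng.normal(size=(n_haps, 1))
        z = sq_r * shared + sq_1mr * rng.normal(size=(n_haps, len(cols)))
        out[:, cols] = (z < thr[cols]).astype(np.uint8)
    return out


def simulate_trio_cohort(config: SimConfig, variants: pd.DataFrame) -> TrioCohort:
    """Simulate founder couples, Mendelian transmission, and a control pool.

    Returns the *base* (unascertained) cohort of ``config.base_families()``
    families plus ``config.n_controls`` unrelated controls drawn from the
    same founder distribution.
    """
    if len(variants) == 0:
        raise ValueError("variant table is empty")
    n_fam = config.base_families()
    rng_f = _rng(config, "founders")
    rng_t = _rng(config, "transmission")
    r = config.within_block_r

    fat_h = _draw_haplotypes(rng_f, variants, 2 * n_fam, r).reshape(n_fam, 2, -1)
    mot_h = _draw_haplotypes(rng_f, variants, 2 * n_fam, r).reshape(n_fam, 2, -1)
    ctrl_h = _draw_haplotypes(rng_f, variants, 2 * config.n_controls, r)
    ctrl_dos = (
        ctrl_h.reshape(config.n_controls, 2, -1).sum(axis=1).astype(np.int16)
        if config.n_controls
        else np.zeros((0, len(variants)), dtype=np.int16)
    )

    blocks = np.asarray(variants["ld_block"], dtype=np.int64)

    def transmit(parent_h: np.ndarray) -> np.ndarray:
        # one inherited haplotype per block (recombination-free blocks)
        choice = rng_t.integers(0, 2, size=(n_fam, blocks.max() + 1))
        choice_v = choice[:, blocks]  # (n_fam, n_variants)
        return np.where(choice_v == 0, parent_h[:, 0, :], parent_h[:, 1, :])

    child_dos = (transmit(fat_h) + transmit(mot_h)).astype(np.int16)

    multi = (
        rng_t.random(n_fam) < config.multi_proband_prob
        if config.multi_proband_prob > 0
        else np.zeros(n_fam, dtype=bool)
    )
    sib_dos = (transmit(fat_h) + transmit(mot_h)).astype(np.int16)[multi]

    fam_ids = [f"F{i + 1:05d}" for i in range(n_fam)]
    child_ids = [f"{f}_C1" for f in fam_ids]
    father_ids = [f"{f}_D" for f in fam_ids]
    mother_ids = [f"{f}_M" for f in fam_ids]
    sib_fams = [fam_ids[i] for i in np.flatnonzero(multi)]
    sib_ids = [f"{f}_C2" for f in sib_fams]
    ctrl_ids = [f"CTRL{i + 1:05d}" for i in range(config.n_controls)]

    samples = child_ids + sib_ids + father_ids + mother_ids + ctrl_ids
    dosages = np.vstack(
        [
            child_dos,
            sib_dos,
            fat_h.sum(axis=1).astype(np.int16),
            mot_h.sum(axis=1).astype(np.int16),
            ctrl_dos,
        ]
    )

    ped_rows = []
    for f, c, d, m in zip(fam_ids, child_ids, father_ids, mother_ids):
        ped_rows.append((f, d, "0", "0", 1, -9))
        ped_rows.append((f, m, "0", "0", 2, -9))
        ped_rows.append((f, c, d, m, 0, -9))
    for f, s in zip(sib_fams, sib_ids):
        ped_rows.append((f, s, f"{f}_D", f"{f}_M", 0, -9))
    for c in ctrl_ids:
        ped_rows.append((c, c, "0", "0", 0, -9))
    pedigree = pd.DataFrame(
        ped_rows,
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
    )

    availability = pd.DataFrame(
        {
            "family_id": fam_ids,
            "father_dna": True,
            "mother_dna": True,
            "father_genotyped": True,
            "mother_genotyped": True,
            "child_genotyped": True,
            "father_array": "A1",
            "mother_array": "A1",
            "child_array": "A1",
        }
    )

    return TrioCohort(
        variants=variants,
        samples=samples,
        dosages=dosages,
        pedigree=pedigree,
        phenotypes=pd.DataFrame(),
        availability=availability,
        controls=ctrl_ids,
        meta={"config": config.to_dict(), "seed": config.seed},
    )


def polygenic_values(cohort: TrioCohort, weights: np.ndarray | None = None) -> pd.Series:
    """True polygenic values for every sample, standardized on founders.

    Standardization uses the founder population (parents plus controls),
    whose marginal genotype distribution equals the population's.
    """
    w = np.asarray(weights if weights is not None else cohort.variants["true_weight"], float)
    dos = np.where(cohort.dosages == MISSING, 0, cohort.dosages).astype(float)
    g = dos @ w
    founders = set(cohort.founders()["individual_id"])
    mask = np.array([s in founders for s in cohort.samples])
    if mask.sum() < 2:
        mask = np.ones(len(g), dtype=bool)
    mu, sd = g[mask].mean(), g[mask].std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate polygenic values: zero founder SD")
    return pd.Series((g - mu) / sd, index=cohort.samples, name="G_std")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def assign_phenotypes(cohort: TrioCohort, config: SimConfig) -> TrioCohort:
    """Assign liabilities, case flags and correlated clinical phenotypes.

    Loadings of symptoms/IQ on liability are fixed generator constants chosen
    to mimic a clinically ascertained ADHD-like cohort (severity-linked
    hyperactive-impulsive and conduct symptoms, IQ below the population mean
    in cases); low SES is drawn independently of severity so the configured
    SES effect on missingness stays a clean conditional parameter.
    """
    if config.liability_noise_var < -1e-12:
        raise ConfigurationError("liability variance components exceed 1")
    rng = _rng(config, "phenotypes")
    g = polygenic_values(cohort)
    children = cohort.children()
    n = len(children)
    gc = g[children["individual_id"]].to_numpy()
    gf = g[children["father_id"]].to_numpy()
    gm = g[children["mother_id"]].to_numpy()

    a, b = config.direct_coef, config.b_nurture
    e = math.sqrt(max(config.liability_noise_var, 0.0))
    liab = a * gc + b * (gf + gm) / math.sqrt(2.0) + e * rng.normal(size=n)
    threshold = stats.norm.ppf(1.0 - config.prevalence) if config.prevalence < 1 else -np.inf
    case = liab > threshold

    sev = 0.6 * liab + 0.8 * rng.normal(size=n)
    hyper = np.clip(np.round(4.5 + 1.9 * (0.8 * sev + 0.6 * rng.normal(size=n))), 0, 9)
    inatt = np.clip(np.round(4.5 + 1.9 * (0.35 * liab + 0.937 * rng.normal(size=n))), 0, 9)
    conduct = np.clip(np.round(1.3 + 1.4 * (0.7 * sev + 0.714 * rng.normal(size=n))), 0, 9)
    iq = np.round(100.0 - 15.0 * (0.35 * liab + 0.937 * rng.normal(size=n)))
    age = np.clip(np.round(rng.normal(10.4, 2.8, size=n), 1), 5.0, 18.0)
    sex = np.where(rng.random(n) < 0.139, 2, 1)  # 2 = female
    low_ses = rng.random(n) < 0.45
    low_income = rng.random(n) < np.where(low_ses, 0.75, 0.40)

    phen = pd.DataFrame(
        {
            "individual_id": children["individual_id"].to_numpy(),
            "family_id": children["family_id"].to_numpy(),
            "liability": liab,
            "case": case,
            "age": age,
            "sex": sex,
            "inattentive_sym": inatt.astype(int),
            "hyperimp_sym": hyper.astype(int),
            "conduct_sym": conduct.astype(int),
            "iq": iq.astype(int),
            "severity": sev,
            "low_ses": low_ses.astype(int),
            "low_income": low_income.astype(int),
        }
    )
    ped = cohort.pedigree.copy()
    case_map = dict(zip(phen["individual_id"], np.where(case, 2, 1)))
    ped["phenotype"] = [case_map.get(i, -9) for i in ped["individual_id"]]
    out = TrioCohort(
        variants=cohort.variants,
        samples=cohort.samples,
        dosages=cohort.dosages,
        pedigree=ped,
        phenotypes=phen,
        availability=cohort.availability,
        controls=cohort.controls,
        meta=dict(cohort.meta),
    )
    out.meta["G_std"] = g
    return out


def ascertain(cohort: TrioCohort, config: SimConfig) -> TrioCohort:
    """Retain ``n_trio_families`` case families plus the unscreened controls.

    Families qualify when at least one child is a case; controls pass through
    without screening. Raises :class:`AscertainmentError` on shortfall.
    """
    if len(cohort.phenotypes) == 0:
        raise ValueError("phenotypes must be assigned before ascertainment")
    rng = _rng(config, "ascertain")
    phen = cohort.phenotypes
    case_fams = phen.loc[phen["case"], "family_id"].unique()
    if len(case_fams) < config.n_trio_families:
        raise AscertainmentError(
            f"only {len(case_fams)} case families simulated, "
            f"{config.n_trio_families} requested; increase n_base_families"
        )
    keep_fams = set(rng.choice(case_fams, size=config.n_trio_families, replace=False))
    ped = cohort.pedigree
    keep = ped.loc[ped["family_id"].isin(keep_fams), "individual_id"].tolist()
    keep += cohort.controls
    sub = cohort.subset_samples(keep)
    sub.meta = dict(cohort.meta)
    if "G_std" in cohort.meta:
        sub.meta["G_std"] = cohort.meta["G_std"][sub.samples]
    sub.meta["ascertained"] = True
    return sub


def simulate_missingness(cohort: TrioCohort, config: SimConfig) -> TrioCohort:
    """Draw parent-DNA availability from a logistic model on severity and SES.

    Family incompleteness has log-odds
    ``missing_intercept + missing_beta_severity * severity_z +
    missing_beta_ses * low_ses``; within incomplete families the father is
    the missing parent most of the time (clinical cohorts mostly lose
    fathers). A small fraction of provided samples fail genotyping.
    Genotypes of unavailable or failed parents are set to the missing
    sentinel.
    """
    rng = _rng(config, "missingness")
    phen = cohort.phenotypes
    if len(phen) == 0:
        raise ValueError("phenotypes required for missingness simulation")
    # oldest proband defines family severity
    oldest = phen.sort_values(["family_id", "age"], ascending=[True, False]).groupby(
        "family_id", sort=False
    ).head(1)
    sev = oldest["severity"].to_numpy()
    sev_z = (sev - sev.mean()) / sev.std(ddof=1) if sev.std(ddof=1) > 0 else sev * 0.0
    ses = oldest["low_ses"].to_numpy()
    logit = (
        config.missing_intercept
        + config.missing_beta_severity * sev_z
        + config.missing_beta_ses * ses
    )
    from scipy.special import expit

    p_inc = expit(logit)
    incomplete = rng.random(len(oldest)) < p_inc
    father_missing = incomplete & (rng.random(len(oldest)) < config.father_missing_frac)
    mother_missing = incomplete & (rng.random(len(oldest)) < config.mother_missing_frac)
    neither = incomplete & ~father_missing & ~mother_missing
    father_missing |= neither

    avail = cohort.availability.set_index("family_id").copy()
    fams = oldest["family_id"].to_numpy()
    avail.loc[fams, "father_dna"] = ~father_missing
    avail.loc[fams, "mother_dna"] = ~mother_missing
    fail_f = rng.random(len(oldest)) < config.genotyping_fail_rate
    fail_m = rng.random(len(oldest)) < config.genotyping_fail_rate
    avail.loc[fams, "father_genotyped"] = ~father_missing & ~fail_f
    avail.loc[fams, "mother_genotyped"] = ~mother_missing & ~fail_m

    dosages = cohort.dosages.copy()
    fam_to_idx = {f: i for i, f in enumerate(fams)}
    for _, row in cohort.founders().iterrows():
        f = row["family_id"]
        if f not in fam_to_idx:
            continue
        i = fam_to_idx[f]
        is_father = row["individual_id"].endswith("_D")
        geno_ok = (not father_missing[i] and not fail_f[i]) if is_father else (
            not mother_missing[i] and not fail_m[i]
        )
        if not geno_ok:
            dosages[cohort.row(row["individual_id"])] = MISSING

    out = TrioCohort(
        variants=cohort.variants,
        samples=cohort.samples,
        dosages=dosages,
        pedigree=cohort.pedigree,
        phenotypes=cohort.phenotypes,
        availability=avail.reset_index(),
        controls=cohort.controls,
        meta=dict(cohort.meta),
    )
    return out


def simulate_cohort(config: SimConfig, with_missingness: bool = True) -> TrioCohort:
    """Convenience wrapper: variants -> trios -> phenotypes -> ascertainment."""
    variants = simulate_variants(config)
    cohort = simulate_trio_cohort(config, variants)
    cohort = assign_phenotypes(cohort, config)
    cohort = ascertain(cohort, config)
    if with_missingness:
        cohort = simulate_missingness(cohort, config)
    return cohort
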