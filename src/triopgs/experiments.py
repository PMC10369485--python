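"""Replication-style synthetic experiments.

Each function runs one self-contained experiment on generated data and
returns summary numbers: null calibration of the transmission test,
discriminant validity of direct-effect versus genetic-nurture simulations,
parameter recovery for phenotype-dependent trio incompleteness, and the
sandwich-variance check against a cluster bootstrap. They are the package's
own end-to-end validation harness; the test suite and the acceptance script
both drive them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from .compare import gee_fit
from .config import PipelineConfig, SimConfig
from .pipeline import run_pipeline
from .ptdt import ptdt
from .simulate import simulate_trio_cohort, simulate_variants


def ptdt_null_calibration(
    n_sims: int = 1000,
    n_trios: int = 328,
    n_variants: int = 60,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the pTDT on unascertained trios.

    Each replicate simulates ``n_trios`` trios with Mendelian transmission
    (no ascertainment, so any weighting is a null score) and runs the
    one-sample test; returns the rejection rate at ``alpha``.
    """
    rejections = 0
    for s in range(n_sims):
        cfg = SimConfig(
            n_variants=n_variants, n_ld_blocks=max(1, n_variants // 10),
            n_base_families=n_trios, n_controls=0,
            seed=int((seed * 100_003 + s) % (2**31 - 1)),
        )
        v = simulate_variants(cfg)
        coh = simulate_trio_cohort(cfg, v)
        w = v["gwas_beta"].to_numpy()
        ch = coh.children()
        c = coh.dosage_of(ch["individual_id"]).astype(float) @ w
        f = coh.dosage_of(ch["father_id"]).astype(float) @ w
        m = coh.dosage_of(ch["mother_id"]).astype(float) @ w
        if ptdt(c, f, m).pvalue < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims,
            "n_trios": n_trios, "alpha": alpha}


def discriminant_experiment(
    mode: str,
    seed: int = 0,
    n_trio_families: int = 328,
    n_variants: int = 2000,
    n_controls: int = 2000,
) -> dict:
    """Full-pipeline run under a direct-effect or pure-nurture model.

    ``direct``  : h2_direct = 0.3, no nurture — expects overtransmission
                  (positive pTDT deviation) and nontransmitted scores at
                  control level.
    ``nurture`` : h2_direct = 0, nurture coefficient 0.55 — expects a null
                  pTDT but elevated nontransmitted scores versus controls.

    Case families are ascertained through the top-5% liability threshold;
    missingness is disabled so the full set of families reaches the
    transmission analysis.
    """
    if mode == "direct":
        h2, b = 0.3, 0.0
    elif mode == "nurture":
        h2, b = 0.0, 0.55
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cfg = PipelineConfig(
        sim=SimConfig(
            n_variants=n_variants, n_ld_blocks=max(1, n_variants // 10),
            n_trio_families=n_trio_families, n_controls=n_controls,
            h2_direct=h2, b_nurture=b, prevalence=0.05,
            missing_intercept=-1e9, genotyping_fail_rate=0.0,
            seed=seed,
        ),
        outdir="scratch/discriminant_" + mode,
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = run_pipeline(cfg)
    res = bundle["ptdt"]
    nt_tab = bundle["nt_vs_controls"].set_index("outcome")
    ci = res.conf_int()
    return {
        "mode": mode,
        "ptdt_mean_deviation": res.mean_deviation,
        "ptdt_se": res.se,
        "ptdt_p": res.pvalue,
        "ptdt_ci": ci,
        "n_trios": res.n,
        "nt_estimate": float(nt_tab.loc["nontransmitted", "estimate"]),
        "nt_se": float(nt_tab.loc["nontransmitted", "robust_se"]),
        "nt_p": float(nt_tab.loc["nontransmitted", "p"]),
        "proband_estimate": float(nt_tab.loc["proband", "estimate"]),
        "proband_p": float(nt_tab.loc["proband", "p"]),
    }


def ses_missingness_recovery(
    seed: int = 0,
    target_or: float = 2.35,
    n_trio_families: int = 6000,
) -> dict:
    """Recover the low-SES effect on trio incompleteness by GEE.

    Simulates an ascertained cohort whose incompleteness log-odds include
    ``log(target_or)`` for low family SES, then estimates that odds ratio
    with a cluster-robust logistic GEE adjusting for symptom severity.
    """
    from .simulate import ascertain, assign_phenotypes, simulate_missingness

    cfg = SimConfig(
        n_variants=60, n_ld_blocks=6, n_trio_families=n_trio_families,
        n_controls=0, prevalence=0.3, n_base_families=4 * n_trio_families,
        missing_beta_ses=float(np.log(target_or)),
        missing_beta_severity=float(np.log(1.3)), missing_intercept=-0.5,
        seed=seed,
    )
    v = simulate_variants(cfg)
    coh = simulate_missingness(
        ascertain(assign_phenotypes(simulate_trio_cohort(cfg, v), cfg), cfg), cfg)
    avail = coh.availability.set_index("family_id")
    phen = coh.phenotypes.set_index("family_id")
    inc = (~(avail["father_dna"] & avail["mother_dna"])).loc[phen.index]
    sev = phen["severity"]
    df = pd.DataFrame(
        {
            "inc": inc.astype(float).to_numpy(),
            "ses": phen["low_ses"].to_numpy(dtype=float),
            "sev": ((sev - sev.mean()) / sev.std(ddof=1)).to_numpy(),
            "fam": phen.index,
        }
    )
    res = gee_fit(df["inc"], df[["ses", "sev"]], df["fam"],
                  family="binomial", focal="ses")
    return {
        "odds_ratio": res.odds_ratio, "ci": (res.or_ci_low, res.or_ci_high),
        "target": target_or, "n_families": len(df),
    }


def two_by_two_example() -> dict:
    """Closed-form 2x2 check: 30/50 exposed cases vs 20/50 exposed controls.

    The saturated logistic MLE equals the sample odds ratio
    (30*30)/(20*20) = 2.25.
    """
    y = np.r_[np.ones(50), np.zeros(50)]
    x = np.r_[np.ones(30), np.zeros(20), np.ones(20), np.zeros(30)]
    res = gee_fit(pd.Series(y), pd.DataFrame({"x": x}), np.arange(100),
                  family="binomial")
    return {"odds_ratio": res.odds_ratio, "closed_form": (30 * 30) / (20 * 20)}


def gee_sandwich_vs_bootstrap(
    seed: int = 0,
    n_clusters: int = 500,
    cluster_size: int = 3,
    n_boot: int = 2000,
    true_or: float = 2.0,
    rho: float = 0.5,
) -> dict:
    """Sandwich SE versus a cluster-bootstrap SE on clustered logistic data.

    Outcomes are marginally exact logistic (Gaussian-copula correlation
    ``rho`` within clusters) with true odds ratio ``true_or``. The bootstrap
    refits an ordinary GLM per resample — valid because GEE point estimates
    under the independence working model coincide with GLM estimates.
    """
    rng = np.random.default_rng(seed)
    zc = np.repeat(rng.normal(size=n_clusters), cluster_size)
    e = rng.normal(size=n_clusters * cluster_size)
    v = norm.cdf(np.sqrt(rho) * zc + np.sqrt(1 - rho) * e)
    x = rng.integers(0, 2, n_clusters * cluster_size).astype(float)
    y = (v < expit(-0.5 + np.log(true_or) * x)).astype(float)
    cl = np.repeat(np.arange(n_clusters), cluster_size)
    res = gee_fit(pd.Series(y), pd.DataFrame({"x": x}), cl, family="binomial")

    X = sm.add_constant(pd.DataFrame({"x": x})).to_numpy()
    groups = [np.flatnonzero(cl == c) for c in range(n_clusters)]
    boots = []
    for _ in range(n_boot):
        pick = rng.integers(0, n_clusters, n_clusters)
        idx = np.concatenate([groups[c] for c in pick])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y[idx], X[idx], family=sm.families.Binomial()).fit()
        boots.append(fit.params[1])
    boot_se = float(np.std(boots, ddof=1))
    return {
        "estimate": res.estimate, "true_log_or": float(np.log(true_or)),
        "robust_se": res.robust_se, "bootstrap_se": boot_se,
        "se_ratio": res.robust_se / boot_se, "n_boot": n_boot,
    }
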