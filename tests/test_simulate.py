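"""Generator correctness: determinism, Mendelian structure, liability model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triopgs.config import ConfigurationError, SimConfig
from triopgs.pseudocontrols import mendelian_consistent
from triopgs.simulate import (
    AscertainmentError,
    ascertain,
    assign_phenotypes,
    polygenic_values,
    simulate_missingness,
    simulate_trio_cohort,
    simulate_variants,
)


def cfg(**kw):
    base = dict(n_variants=100, n_ld_blocks=10, n_trio_families=50,
                n_controls=50, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestSimulateVariants:
    def test_empty_table_for_zero_variants(self):
        tab = simulate_variants(cfg(n_variants=0))
        assert len(tab) == 0

    def test_same_seed_identical(self):
        a = simulate_variants(cfg(seed=9))
        b = simulate_variants(cfg(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(maf_range=(0.5, 0.05))
        with pytest.raises(ConfigurationError):
            cfg(maf_range=(0.0, 0.5))

    def test_af_distribution_matches_uniform_sampling(self):
        """10k simulated AFs agree with direct uniform resampling (KS)."""
        c = cfg(n_variants=10_000, n_ld_blocks=500, maf_range=(0.05, 0.5))
        af = simulate_variants(c)["af"].to_numpy()
        assert af.min() >= 0.05 and af.max() <= 0.5
        oracle = np.random.default_rng(123).uniform(0.05, 0.5, size=10_000)
        ks = stats.ks_2samp(af, oracle)
        assert ks.pvalue > 1e-4

    def test_gwas_p_decreasing_in_abs_beta(self):
        tab = simulate_variants(cfg(n_variants=500, n_ld_blocks=50))
        order = np.argsort(np.abs(tab["gwas_beta"]))
        p_sorted = tab["gwas_p"].to_numpy()[order]
        assert np.all(np.diff(p_sorted) <= 1e-15)

    def test_positions_strictly_increasing(self):
        tab = simulate_variants(cfg(n_variants=500, n_ld_blocks=50))
        assert np.all(np.diff(tab["pos"]) > 0)


class TestTrioCohort:
    def test_mendelian_consistency_exhaustive(self, small_cohort):
        assert small_cohort.check_mendelian_reachability() == 0

    def test_seeded_determinism_byte_identical(self):
        c = cfg(seed=5)
        v = simulate_variants(c)
        a = simulate_trio_cohort(c, v)
        b = simulate_trio_cohort(c, v)
        assert a.samples == b.samples
        assert np.array_equal(a.dosages, b.dosages)
        assert a.dosages.tobytes() == b.dosages.tobytes()

    def test_forced_transmission_from_homozygous_parents(self):
        c = cfg(n_variants=40, n_ld_blocks=4, n_base_families=300)
        v = simulate_variants(c)
        coh = simulate_trio_cohort(c, v)
        ch = coh.children()
        f = coh.dosage_of(ch["father_id"])
        m = coh.dosage_of(ch["mother_id"])
        child = coh.dosage_of(ch["individual_id"])
        both2 = (f == 2) & (m == 2)
        both0 = (f == 0) & (m == 0)
        assert both2.any() and both0.any()
        assert np.all(child[both2] == 2)
        assert np.all(child[both0] == 0)

    def test_mean_child_dosage_matches_midparent(self):
        """Monte-Carlo: across many trios the child mean equals the parental
        mean per locus within 3 SE (transmission is unbiased)."""
        c = cfg(n_variants=20, n_ld_blocks=2, n_base_families=50_000, seed=3)
        v = simulate_variants(c)
        coh = simulate_trio_cohort(c, v)
        ch = coh.children()
        child = coh.dosage_of(ch["individual_id"]).astype(float)
        mid = (coh.dosage_of(ch["father_id"]) + coh.dosage_of(ch["mother_id"])) / 2.0
        diff = child.mean(axis=0) - mid.mean(axis=0)
        se = (child - mid).std(axis=0, ddof=1) / np.sqrt(len(child))
        assert np.all(np.abs(diff) <= 3 * se + 1e-12)


class TestPhenotypes:
    def test_null_model_no_genotype_effect(self):
        c = cfg(h2_direct=0.0, b_nurture=0.0, n_base_families=5000, seed=2)
        v = simulate_variants(c)
        coh = assign_phenotypes(simulate_trio_cohort(c, v), c)
        g = polygenic_values(coh)
        gc = g[coh.phenotypes["individual_id"]].to_numpy()
        slope = np.polyfit(gc, coh.phenotypes["liability"], 1)[0]
        assert abs(slope) < 3.0 / np.sqrt(len(gc))

    def test_case_fraction_matches_prevalence(self):
        c = cfg(prevalence=0.05, n_base_families=20_000, seed=4)
        v = simulate_variants(c)
        coh = assign_phenotypes(simulate_trio_cohort(c, v), c)
        frac = coh.phenotypes["case"].mean()
        se = np.sqrt(0.05 * 0.95 / 20_000)
        assert abs(frac - 0.05) < 4 * se

    def test_h2_direct_recovered_at_scale(self):
        """corr^2(G_child, liability) ~ h2_direct at n = 100,000."""
        c = cfg(h2_direct=0.5, b_nurture=0.0, n_variants=100, n_ld_blocks=20,
                n_base_families=100_000, n_controls=0, seed=6)
        v = simulate_variants(c)
        coh = assign_phenotypes(simulate_trio_cohort(c, v), c)
        g = polygenic_values(coh)
        gc = g[coh.phenotypes["individual_id"]].to_numpy()
        r2 = np.corrcoef(gc, coh.phenotypes["liability"])[0, 1] ** 2
        se = 2 * np.sqrt(0.5) * (1 - 0.5) / np.sqrt(100_000)  # delta method
        assert abs(r2 - 0.5) < 5 * se

    def test_overfull_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(h2_direct=0.8, b_nurture=0.6)


class TestAscertainment:
    def test_all_retained_children_are_cases(self, small_cohort):
        phen = small_cohort.phenotypes
        assert bool(phen["case"].all())

    def test_shortfall_raises(self):
        c = cfg(n_trio_families=1000, n_base_families=200, seed=7)
        v = simulate_variants(c)
        coh = assign_phenotypes(simulate_trio_cohort(c, v), c)
        with pytest.raises(AscertainmentError):
            ascertain(coh, c)

    def test_prevalence_one_is_random_sampling(self):
        c = cfg(prevalence=1.0, n_base_families=100, n_trio_families=60, seed=8)
        v = simulate_variants(c)
        coh = assign_phenotypes(simulate_trio_cohort(c, v), c)
        sub = ascertain(coh, c)
        assert len(sub.family_ids()) == 60
        assert bool(sub.phenotypes["case"].all())

    def test_ascertained_polygenic_mean_elevated(self):
        c = cfg(h2_direct=0.5, n_base_families=3000, n_trio_families=100, seed=9)
        v = simulate_variants(c)
        coh = assign_phenotypes(simulate_trio_cohort(c, v), c)
        sub = ascertain(coh, c)
        g = sub.meta["G_std"]
        gc = g[sub.phenotypes["individual_id"]].to_numpy()
        assert gc.mean() > 0.5  # cases sit far above the population mean


class TestMissingness:
    def test_null_coefficients_give_phenotype_independence(self):
        c = cfg(missing_beta_severity=0.0, missing_beta_ses=0.0,
                missing_intercept=0.0, prevalence=0.3, n_base_families=8000,
                n_trio_families=2000, seed=10)
        v = simulate_variants(c)
        coh = simulate_missingness(
            ascertain(assign_phenotypes(simulate_trio_cohort(c, v), c), c), c)
        avail = coh.availability.set_index("family_id")
        phen = coh.phenotypes.set_index("family_id")
        inc = ~(avail["father_dna"] & avail["mother_dna"])
        r = np.corrcoef(inc.loc[phen.index].astype(float), phen["severity"])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(phen))

    def test_infinite_negative_intercept_all_complete(self):
        c = cfg(missing_intercept=-1e9, genotyping_fail_rate=0.0,
                n_base_families=2000, n_trio_families=100, seed=11)
        v = simulate_variants(c)
        coh = simulate_missingness(
            ascertain(assign_phenotypes(simulate_trio_cohort(c, v), c), c), c)
        avail = coh.availability
        assert bool((avail["father_dna"] & avail["mother_dna"]).all())

    def test_severity_raises_missingness(self):
        c = cfg(missing_beta_severity=1.0, missing_beta_ses=0.0,
                missing_intercept=-0.5, prevalence=0.3, n_base_families=16_000,
                n_trio_families=4000, seed=12)
        v = simulate_variants(c)
        coh = simulate_missingness(
            ascertain(assign_phenotypes(simulate_trio_cohort(c, v), c), c), c)
        avail = coh.availability.set_index("family_id")
        phen = coh.phenotypes.set_index("family_id")
        inc = ~(avail["father_dna"] & avail["mother_dna"])
        sev = phen["severity"]
        assert sev[inc.loc[phen.index]].mean() > sev[~inc.loc[phen.index]].mean()
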