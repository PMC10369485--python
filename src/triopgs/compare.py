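"""Group comparisons with cluster-robust GEE and BH-FDR.

Two comparison designs are supported, mirroring the trio-analysis layout:

* group-vs-controls contrasts of polygenic scores (probands, fathers,
  mothers and nontransmitted pseudo-samples each against the population
  control pool; identity link), and
* complete-vs-incomplete trio-status contrasts of clinical phenotypes and
  scores (logistic link; complete coded 0, incomplete coded 1, so OR > 1
  means "more of the variable in incomplete trios").

All fits use generalized estimating equations with an independence working
correlation — point estimates then coincide with the ordinary GLM solution —
and the cluster-aggregated sandwich estimator for standard errors, which
stays valid under within-family correlation. Wald 95% intervals use the
1.96 multiplier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z95 = 1.959963984540054

MIN_FATHER_GROUP = 20  # smaller father groups are skipped, not compared


class GeeFitError(RuntimeError):
    """Non-estimable GEE: separation, single cluster, or no variation."""


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeeResult:
    """One fitted GEE contrast: focal-term estimate with robust inference."""

    term: str
    outcome: str
    estimate: float
    robust_se: float
    ci_low: float
    ci_high: float
    pvalue: float
    family: str
    n_obs: int
    n_clusters: int
    odds_ratio: Optional[float] = None
    or_ci_low: Optional[float] = None
    or_ci_high: Optional[float] = None
    qvalue: Optional[float] = None
    params: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def to_row(self) -> dict:
        row = {
            "outcome": self.outcome,
            "term": self.term,
            "estimate": self.estimate,
            "robust_se": self.robust_se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.pvalue,
        }
        if self.family == "binomial":
            row.update(
                OR=self.odds_ratio, OR_ci_low=self.or_ci_low, OR_ci_high=self.or_ci_high
            )
        if self.qvalue is not None:
            row["q"] = self.qvalue
        return row


def gee_fit(
    outcome,
    predictors: pd.DataFrame,
    clusters,
    family: str = "binomial",
    focal: Optional[str] = None,
    outcome_name: str = "outcome",
) -> GeeResult:
    """Fit outcome ~ predictors by GEE with independence working correlation.

    ``clusters`` labels the sampling clusters (families); robust SEs use the
    sandwich aggregated over clusters. ``focal`` names the predictor column
    reported as the headline contrast (default: first column).
    """
    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(predictors.astype(float), has_constant="add")
    groups = pd.Series(clusters).astype(str).to_numpy()
    if len(np.unique(groups)) < 2:
        raise GeeFitError("at least 2 clusters required for the sandwich estimator")
    if family == "binomial":
        fam = sm.families.Binomial()
    elif family == "gaussian":
        fam = sm.families.Gaussian()
    else:
        raise ValueError(f"unsupported family {family!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(y, X, groups=groups, family=fam,
                       cov_struct=sm.cov_struct.Independence())
        try:
            res = model.fit()
        except Exception as exc:  # singular design, etc.
            raise GeeFitError(f"GEE fit failed: {exc}") from exc
    if family == "binomial" and np.any(np.abs(res.params.drop("const", errors="ignore")) > 15):
        raise GeeFitError("perfect separation suspected (diverging coefficients)")

    params = pd.DataFrame(
        {
            "estimate": res.params,
            "robust_se": res.bse,
            "ci_low": res.params - Z95 * res.bse,
            "ci_high": res.params + Z95 * res.bse,
            "p": res.pvalues,
        }
    )
    focal = focal or predictors.columns[0]
    row = params.loc[focal]
    result = GeeResult(
        term=focal,
        outcome=outcome_name,
        estimate=float(row["estimate"]),
        robust_se=float(row["robust_se"]),
        ci_low=float(row["ci_low"]),
        ci_high=float(row["ci_high"]),
        pvalue=float(row["p"]),
        family=family,
        n_obs=len(y),
        n_clusters=len(np.unique(groups)),
        params=params,
    )
    if family == "binomial":
        result.odds_ratio = float(np.exp(row["estimate"]))
        result.or_ci_low = float(np.exp(row["ci_low"]))
        result.or_ci_high = float(np.exp(row["ci_high"]))
    return result


class GroupComparison:
    """Model object for a block of GEE contrasts sharing one FDR family.

    Each contrast is either "outcome ~ focal + covariates" with a logistic
    link (trio-status designs) or a continuous score compared between a
    group and the controls (identity link). ``fit()`` runs every contrast
    and attaches BH-FDR q-values across the block when requested.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        contrasts: Sequence[tuple],
        cluster_col: str = "family_id",
        apply_fdr: bool = True,
    ):
        """``contrasts`` rows: (outcome_col, focal_col, covariate_cols, family)."""
        self.data = data
        self.contrasts = list(contrasts)
        self.cluster_col = cluster_col
        self.apply_fdr = apply_fdr

    def fit(self) -> "GroupComparisonResults":
        results, skipped = [], []
        for outcome, focal, covars, family in self.contrasts:
            cols = [outcome, focal, *covars, self.cluster_col]
            sub = self.data[cols].dropna()
            if sub[focal].nunique() < 2 or sub[outcome].nunique() < 2:
                skipped.append((outcome, focal, "no variation"))
                warnings.warn(f"skipping {outcome} ~ {focal}: no variation")
                continue
            try:
                res = gee_fit(
                    sub[outcome],
                    sub[[focal, *covars]],
                    sub[self.cluster_col],
                    family=family,
                    focal=focal,
                    outcome_name=outcome,
                )
            except GeeFitError as exc:
                skipped.append((outcome, focal, str(exc)))
                warnings.warn(f"skipping {outcome} ~ {focal}: {exc}")
                continue
            results.append(res)
        if self.apply_fdr and results:
            q = bh_fdr([r.pvalue for r in results])
            for r, qi in zip(results, q):
                r.qvalue = float(qi)
        return GroupComparisonResults(self, results, skipped)


@dataclass
class GroupComparisonResults:
    model: GroupComparison
    results: list[GeeResult]
    skipped: list[tuple]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.results])

    def summary(self) -> str:
        tab = self.to_frame()
        lines = ["Cluster-robust GEE comparisons", "=" * 34]
        if len(tab):
            lines.append(tab.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
        for outcome, focal, reason in self.skipped:
            lines.append(f"skipped {outcome} ~ {focal}: {reason}")
        return "\n".join(lines)


def trio_status_comparison(
    data: pd.DataFrame,
    phenotypes: Sequence[str],
    status_col: str = "status_code",
    covariates: Sequence[str] = ("age",),
    cluster_col: str = "family_id",
    apply_fdr: bool = True,
) -> GroupComparisonResults:
    """Compare complete (0) vs incomplete (1) trios on each phenotype.

    Logistic GEE of trio status on the phenotype with the listed covariates;
    OR > 1 means the variable is higher in incomplete trios. The phenotype
    used as a covariate is never contrasted against itself.
    """
    contrasts = [
        (status_col, ph, tuple(c for c in covariates if c != ph), "binomial")
        for ph in phenotypes
    ]
    return GroupComparison(data, contrasts, cluster_col, apply_fdr).fit()


def group_vs_control_comparison(
    scores: pd.Series,
    groups: dict[str, Sequence[str]],
    control_ids: Sequence[str],
    cluster_of: Optional[dict] = None,
    apply_fdr: bool = True,
    min_father_group: int = MIN_FATHER_GROUP,
) -> GroupComparisonResults:
    """Compare each sample group against the control pool on a score.

    ``groups`` maps group names (e.g. proband/father/mother/NT) to sample
    ids; controls form the reference level of an identity-link GEE.
    ``cluster_of`` maps trio-derived sample ids to family ids (controls
    cluster as themselves). A father group smaller than
    ``min_father_group`` is skipped rather than compared.
    """
    cluster_of = cluster_of or {}
    control_ids = list(control_ids)
    rows, contrasts = [], []
    frames = {}
    skipped = []
    for name, ids in groups.items():
        ids = list(ids)
        if name.lower().startswith("father") and len(ids) < min_father_group:
            skipped.append((name, "group", f"only {len(ids)} fathers; comparison skipped"))
            continue
        if len(ids) == 0:
            skipped.append((name, "group", "empty group"))
            continue
        all_ids = ids + control_ids
        df = pd.DataFrame(
            {
                "score": scores.reindex(all_ids).to_numpy(),
                "group": [1] * len(ids) + [0] * len(control_ids),
                "family_id": [cluster_of.get(s, s) for s in all_ids],
            }
        )
        frames[name] = df
        contrasts.append(("score", "group", (), "gaussian"))
    results = []
    for (name, df), contrast in zip(frames.items(), contrasts):
        outcome, focal, covars, family = contrast
        sub = df.dropna()
        try:
            res = gee_fit(
                sub[outcome], sub[[focal]], sub["family_id"],
                family=family, focal=focal, outcome_name=name,
            )
        except GeeFitError as exc:
            skipped.append((name, focal, str(exc)))
            continue
        results.append(res)
    if apply_fdr and results:
        q = bh_fdr([r.pvalue for r in results])
        for r, qi in zip(results, q):
            r.qvalue = float(qi)
    model = GroupComparison(pd.DataFrame(), [], apply_fdr=apply_fdr)
    return GroupComparisonResults(model, results, skipped)
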