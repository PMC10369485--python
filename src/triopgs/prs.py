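"""Polygenic risk scoring: LD clumping, multi-threshold scores, PRS-PCA,
ancestry PCs, control-referenced standardization and residualization.

The scoring chain mirrors standard clumping-and-thresholding practice:
greedily keep the most significant variant in each correlated neighbourhood,
sum beta-weighted dosages at several p-value thresholds, reduce the
threshold columns to their first principal component (PRS-PCA), and express
scores in control-population SD units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MISSING

__all__ = [
    "clump",
    "score_at_thresholds",
    "prs_pca",
    "ancestry_pcs",
    "standardize",
    "residualize",
]


def clump(
    aligned: pd.DataFrame,
    genotypes: np.ndarray,
    variant_pos: np.ndarray | None = None,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
) -> list[int]:
    """Greedy LD clumping; returns retained row indices of ``aligned``.

    Variants are visited by ascending p-value; each retained index variant
    removes every not-yet-retained variant within ``window_kb`` whose
    squared genotype correlation exceeds ``r2_threshold``. ``genotypes``
    holds the LD reference panel (samples x variants, columns matching
    ``aligned`` rows); missing dosages are mean-imputed for the correlation
    only. Monomorphic variants have undefined correlation, treated as r²=0.
    """
    n = len(aligned)
    if n == 0:
        return []
    pos = np.asarray(variant_pos if variant_pos is not None else aligned["pos"], dtype=float)
    chrom = np.asarray(aligned["chrom"].astype(str))
    pvals = np.asarray(aligned["p"], dtype=float)
    G = np.asarray(genotypes, dtype=float)
    if G.shape[1] != n:
        raise ValueError(f"genotype panel has {G.shape[1]} columns for {n} variants")
    G = G.copy()
    G[G == MISSING] = np.nan
    col_mean = np.nanmean(G, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(col_mean, inds[1])
    sd = G.std(axis=0)
    mono = sd == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic variants: r^2 treated as 0")
    Gz = (G - G.mean(axis=0)) / np.where(mono, 1.0, sd)
    Gz[:, mono] = 0.0

    window = window_kb * 1000.0
    order = np.lexsort((np.asarray(aligned["id"].astype(str)), pvals))
    removed = np.zeros(n, dtype=bool)
    retained: list[int] = []
    m = G.shape[0]
    for i in order:
        if removed[i]:
            continue
        retained.append(int(i))
        near = (
            (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
            & ~removed
        )
        near[i] = False
        idx = np.flatnonzero(near)
        if len(idx) == 0:
            continue
        r = (Gz[:, idx].T @ Gz[:, i]) / m
        removed[idx[r * r > r2_threshold]] = True
        removed[i] = True  # processed
    return sorted(retained)


def score_at_thresholds(
    genotypes: np.ndarray,
    aligned: pd.DataFrame,
    thresholds,
    retained: list[int] | None = None,
    control_af: np.ndarray | None = None,
    sample_ids=None,
) -> pd.DataFrame:
    """Additive scores per sample at each p-value threshold.

    score(s, t) = sum over retained variants with p <= t of
    beta * dosage(s, v); a missing dosage contributes 2 * control AF * beta
    (mean imputation on the control reference).
    """
    thresholds = list(thresholds)
    G = np.asarray(genotypes, dtype=float)
    idx = np.arange(len(aligned)) if retained is None else np.asarray(retained, dtype=int)
    beta = np.asarray(aligned["beta"], dtype=float)[idx]
    pvals = np.asarray(aligned["p"], dtype=float)[idx]
    sub = G[:, idx].copy()
    if control_af is not None:
        fill = 2.0 * np.asarray(control_af, dtype=float)[idx]
    else:
        masked = np.where(sub == MISSING, np.nan, sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fill = np.nanmean(masked, axis=0)
        fill = np.where(np.isnan(fill), 0.0, fill)
    miss = sub == MISSING
    if miss.any():
        sub[miss] = np.broadcast_to(fill, sub.shape)[miss]
    cols = {}
    for t in thresholds:
        sel = pvals <= t
        if not sel.any():
            warnings.warn(f"threshold {t}: no retained variants; zero column")
            cols[t] = np.zeros(G.shape[0])
        else:
            cols[t] = sub[:, sel] @ beta[sel]
    out = pd.DataFrame(cols)
    out.columns = [f"p_{t:g}" for t in thresholds]
    if sample_ids is not None:
        out.index = list(sample_ids)
    return out


@dataclass
class PrsPcaResult:
    """First principal component of the threshold-score matrix."""

    scores: pd.Series
    loadings: pd.Series
    explained_variance_ratio: float
    dropped_columns: list = field(default_factory=list)


def prs_pca(score_matrix: pd.DataFrame) -> PrsPcaResult:
    """PRS-PCA reduction: PC1 of the column-standardized score matrix.

    Zero-variance columns are dropped with a warning. The component sign is
    oriented so it correlates positively with the mean standardized column,
    making "higher score = higher aggregate liability" stable across runs.
    """
    if score_matrix.shape[0] < 2:
        raise ValueError("PRS-PCA needs at least 2 samples")
    X = score_matrix.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    drop = sd == 0
    dropped = list(score_matrix.columns[drop])
    if drop.all():
        raise ValueError("all threshold columns have zero variance")
    if drop.any():
        warnings.warn(f"dropping zero-variance score columns: {dropped}")
    keep_cols = score_matrix.columns[~drop]
    Xz = (X[:, ~drop] - X[:, ~drop].mean(axis=0)) / sd[~drop]
    # PC1 via SVD of the centered/standardized matrix
    U, S, Vt = np.linalg.svd(Xz, full_matrices=False)
    pc1 = U[:, 0] * S[0]
    loadings = Vt[0]
    mean_col = Xz.mean(axis=1)
    orient = np.corrcoef(pc1, mean_col)[0, 1] if np.std(mean_col) > 0 else 1.0
    if orient < 0:
        pc1, loadings = -pc1, -loadings
    evr = float(S[0] ** 2 / np.sum(S**2))
    return PrsPcaResult(
        scores=pd.Series(pc1, index=score_matrix.index, name="prs_pca"),
        loadings=pd.Series(loadings, index=keep_cols, name="loading"),
        explained_variance_ratio=evr,
        dropped_columns=dropped,
    )


def ancestry_pcs(
    genotypes: np.ndarray,
    founder_rows: np.ndarray,
    n_components: int = 10,
    sample_ids=None,
) -> pd.DataFrame:
    """Genotype principal components fit on founders, projected onto all.

    Founder dosages are centered and scaled (unit variance per variant);
    offspring are projected onto the founder loadings, avoiding the
    inflation that related samples cause in a joint PCA.
    """
    from sklearn.decomposition import PCA

    G = np.asarray(genotypes, dtype=float)
    founder_rows = np.asarray(founder_rows)
    if founder_rows.dtype == bool:
        founder_rows = np.flatnonzero(founder_rows)
    F = G[founder_rows]
    if F.shape[0] < n_components + 1:
        n_components = max(1, F.shape[0] - 1)
        warnings.warn(f"few founders: reducing to {n_components} components")
    Fm = np.where(F == MISSING, np.nan, F)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(Fm, axis=0)
        sd = np.nanstd(Fm, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    sd = np.where((sd == 0) | np.isnan(sd), 1.0, sd)

    def standardized(M):
        Mm = np.where(M == MISSING, np.nan, M.astype(float))
        Z = (Mm - mu) / sd
        return np.where(np.isnan(Z), 0.0, Z)

    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    pca.fit(standardized(F))
    coords = pca.transform(standardized(G))
    out = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(n_components)])
    if sample_ids is not None:
        out.index = list(sample_ids)
    return out


def standardize(scores: pd.Series, control_ids=None) -> pd.Series:
    """Express scores in control-population SD units.

    With ``control_ids`` given, subtract the control mean and divide by the
    control SD (so the control subset has mean 0, SD 1); otherwise z-score
    over all samples.
    """
    x = scores.astype(float)
    ref = x.loc[list(control_ids)] if control_ids is not None else x
    if len(ref) == 0:
        raise ValueError("empty control subset")
    sd = ref.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError("zero control SD: cannot standardize")
    return (x - ref.mean()) / sd


def residualize(scores: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """Least-squares residuals of the score on covariates plus intercept.

    Collinear covariate columns are handled by the minimum-norm solution
    (rank-deficient design triggers a warning); residuals are identical to
    dropping the redundant columns.
    """
    if len(covariates) != len(scores):
        raise ValueError("covariate rows do not match samples")
    X = np.column_stack(
        [np.ones(len(scores)), covariates.to_numpy(dtype=float)]
    )
    y = scores.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient covariates (rank {rank} < {X.shape[1]}); "
            "collinear columns contribute nothing to the fit"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ beta, index=scores.index, name=scores.name)
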