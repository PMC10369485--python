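"""Polygenic transmission disequilibrium test (pTDT).

For trio i with child score c_i and midparent score m_i = (f_i + mo_i)/2,
the pTDT deviation is

    d_i = (c_i - m_i) / SD({m_j})

i.e. the child's departure from the parental midpoint in units of the
midparent-distribution SD. Under Mendelian transmission and no selection,
E[c_i | parents] = m_i, so the deviations have mean zero regardless of the
score weights; ascertainment on a phenotype the score predicts shifts the
mean upward (overtransmission) or downward (undertransmission). The test
is a two-sided one-sample t test of mean(d) = 0 with n - 1 degrees of
freedom. The statistic is invariant to any affine transform applied to all
scores jointly, which is why scores enter on a shared raw scale and no
covariate residualization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateCohortError(ValueError):
    """Midparent scores have zero spread; deviations are undefined."""


class PTDT:
    """One-sample transmission test of child-vs-midparent polygenic scores.

    Parameters
    ----------
    child, father, mother : array-like
        Matched per-trio scores on a common (raw) scale. Trios with any
        missing member score are dropped listwise.
    name : str
        Label of the scored phenotype, carried into the summary.
    """

    def __init__(self, child, father, mother, name: str = "score"):
        c = np.asarray(child, dtype=float)
        f = np.asarray(father, dtype=float)
        m = np.asarray(mother, dtype=float)
        if not (c.shape == f.shape == m.shape) or c.ndim != 1:
            raise ValueError("child/father/mother must be matched 1-d arrays")
        keep = np.isfinite(c) & np.isfinite(f) & np.isfinite(m)
        self.n_dropped = int((~keep).sum())
        self.child, self.father, self.mother = c[keep], f[keep], m[keep]
        self.name = name
        if len(self.child) < 3:
            raise ValueError("pTDT needs at least 3 complete trios")

    @classmethod
    def from_dataframe(
        cls,
        scores: pd.Series,
        trios: pd.DataFrame,
        name: str = "score",
    ) -> "PTDT":
        """Build from a per-sample score Series and an eligible-trio table
        (columns child_id / father_id / mother_id)."""
        get = lambda col: scores.reindex(trios[col]).to_numpy()
        return cls(get("child_id"), get("father_id"), get("mother_id"), name=name)

    def fit(self) -> "PTDTResults":
        midparent = (self.father + self.mother) / 2.0
        sd_mid = midparent.std(ddof=1)
        if sd_mid == 0 or not np.isfinite(sd_mid):
            raise DegenerateCohortError("midparent SD is zero")
        dev = (self.child - midparent) / sd_mid
        n = len(dev)
        mean = float(dev.mean())
        sd_dev = dev.std(ddof=1)
        se = float(sd_dev / np.sqrt(n))
        if sd_dev == 0:
            return PTDTResults(
                model=self, deviations=dev, n=n, mean_deviation=mean,
                se=0.0, tstat=np.nan, pvalue=np.nan, degenerate=True,
            )
        t = mean / se
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
        return PTDTResults(
            model=self, deviations=dev, n=n, mean_deviation=mean,
            se=se, tstat=float(t), pvalue=p,
        )


@dataclass
class PTDTResults:
    """pTDT estimates: mean deviation, its SE, t statistic and p-value."""

    model: PTDT
    deviations: np.ndarray
    n: int
    mean_deviation: float
    se: float
    tstat: float
    pvalue: float
    degenerate: bool = field(default=False)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided t confidence interval for the mean deviation."""
        half = stats.t.ppf(1 - alpha / 2, df=self.n - 1) * self.se
        return (self.mean_deviation - half, self.mean_deviation + half)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.conf_int() if self.se > 0 else (np.nan, np.nan)
        return pd.DataFrame(
            [
                {
                    "phenotype": self.model.name,
                    "n_trios": self.n,
                    "mean_deviation": self.mean_deviation,
                    "se": self.se,
                    "ci_low": lo,
                    "ci_high": hi,
                    "t": self.tstat,
                    "p": self.pvalue,
                }
            ]
        )

    def summary(self) -> str:
        lo, hi = self.conf_int() if self.se > 0 else (np.nan, np.nan)
        lines = [
            "Polygenic Transmission Disequilibrium Test",
            "=" * 46,
            f"Score:                 {self.model.name}",
            f"Trios (dropped):       {self.n} ({self.model.n_dropped})",
            f"Mean deviation (SE):   {self.mean_deviation:.4f} ({self.se:.4f})",
            f"95% CI:                [{lo:.4f}, {hi:.4f}]",
            f"t ({self.n - 1} df):   {self.tstat:.3f}",
            f"two-sided p:           {self.pvalue:.3g}",
        ]
        if self.degenerate:
            lines.append("WARNING: zero deviation variance; p undefined")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Histogram of per-trio deviations with the mean marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.deviations, bins=30, color="steelblue", alpha=0.8)
        ax.axvline(0, color="k", lw=1)
        ax.axvline(self.mean_deviation, color="crimson", lw=2,
                   label=f"mean = {self.mean_deviation:.2f}")
        ax.set_xlabel("pTDT deviation (midparent SD units)")
        ax.set_ylabel("trios")
        ax.set_title(self.model.name)
        ax.legend()
        return ax


def ptdt(child, father, mother, name: str = "score") -> PTDTResults:
    """Functional shorthand for ``PTDT(...).fit()``."""
    return PTDT(child, father, mother, name=name).fit()


def ptdt_table(results: list[PTDTResults], apply_fdr: bool = True) -> pd.DataFrame:
    """Stack per-phenotype pTDT results; optionally add BH-FDR q-values."""
    tab = pd.concat([r.to_frame() for r in results], ignore_index=True)
    if apply_fdr and len(tab):
        from .compare import bh_fdr

        tab["q"] = bh_fdr(tab["p"].to_numpy())
    return tab
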