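"""NormFinder-style model-based stability analysis.

The input is a log-scale expression matrix y (genes x samples); by default
the pipeline feeds y = -Ct, which is log2 expression up to a per-gene
constant, or efficiency-corrected y = log2(Q). The model decomposes each
value into a gene effect, a sample effect, an optional (gene, group) bias
d_ig, and residual noise with gene-specific variance gamma^2_i.

Sample effects are removed by centering each sample (column) on its
across-gene mean, z[i,s] = y[i,s] - mean_i(y[i,s]). Centering mixes a
little of every gene's noise into every z row, so the naive within-group
sample variance v_ig of z is biased; the corrected estimator

    gamma2_ig = max(0, (v_ig - sum_k v_kg / (n (n-1))) / (1 - 2/n))

is mean-unbiased for gamma^2_ig under the model (n = number of genes; it
needs n >= 3, since the correction denominator vanishes at n = 2).

With sample groups (e.g. organs), the inter-group bias d_ig is the deviation
of gene i's group-g mean of z from its across-group average; these sum to
zero over groups by construction. Because d_hat is estimated from K_g samples
it is shrunk toward zero in proportion to its sampling noise,

    d_tilde_ig = d_hat_ig * tau2_i / (tau2_i + gamma2_ig / K_g),

where tau2_i is the (moment-estimated, floored) true inter-group variance of
gene i. The grouped stability value combines bias and noise additively,

    rho_i = mean_g( |d_tilde_ig| + sqrt(gamma2_ig / K_g) ),

and ungrouped stability is simply rho_i = sqrt(gamma2_i) with all samples as
one group. Lower rho means more stable; ranking is ascending in rho.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger("refstab")

__all__ = [
    "NormFinder",
    "sample_center",
    "intragroup_variances",
    "intergroup_variation",
    "stability_values",
]


def sample_center(y: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's across-gene mean; columns of the result sum to 0."""
    y = pd.DataFrame(y)
    if y.isna().to_numpy().any():
        raise ValueError("matrix must be complete (no missing values)")
    if y.shape[0] < 3:
        raise ValueError("centering-bias correction needs >=3 genes")
    return y - y.mean(axis=0)


def _group_columns(z: pd.DataFrame, groups) -> dict:
    """Map group label -> list of sample columns, preserving first appearance."""
    groups = pd.Series(groups, index=z.columns) if not isinstance(groups, pd.Series) else groups
    groups = groups.reindex(z.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    out: dict = {}
    for s, g in groups.items():
        out.setdefault(g, []).append(s)
    return out


def intragroup_variances(z: pd.DataFrame, groups) -> pd.DataFrame:
    """Bias-corrected residual variance gamma2 per (gene, group), floored at 0."""
    z = pd.DataFrame(z)
    n = z.shape[0]
    if n < 3:
        raise ValueError("intragroup variance needs >=3 genes (correction "
                         "denominator 1 - 2/n vanishes at n = 2)")
    cols = _group_columns(z, groups)
    out = {}
    for g, samples in cols.items():
        if len(samples) < 2:
            raise ValueError(f"group {g!r} has {len(samples)} sample(s); need >=2")
        v = z[samples].var(axis=1, ddof=1)
        corrected = (v - v.sum() / (n * (n - 1))) / (1.0 - 2.0 / n)
        floored = corrected.clip(lower=0.0)
        n_floor = int((corrected < 0).sum())
        if n_floor:
            logger.info("group %r: floored %d negative variance estimate(s)", g, n_floor)
        out[g] = floored
    return pd.DataFrame(out)


def intergroup_variation(
    z: pd.DataFrame, groups, gamma2: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Inter-group biases d_hat, shrunk d_tilde, and tau2 per gene.

    Returns (d_hat, d_tilde, tau2); d_hat rows sum to zero over groups.
    """
    z = pd.DataFrame(z)
    cols = _group_columns(z, groups)
    if len(cols) < 2:
        raise ValueError("inter-group variation needs >=2 groups (use ungrouped mode)")
    if gamma2 is None:
        gamma2 = intragroup_variances(z, groups)
    k = pd.Series({g: len(s) for g, s in cols.items()})
    means = pd.DataFrame({g: z[s].mean(axis=1) for g, s in cols.items()})
    d_hat = means.sub(means.mean(axis=1), axis=0)
    se2 = gamma2[d_hat.columns].div(k, axis=1)  # sampling variance of d_hat
    tau2 = (d_hat.var(axis=1, ddof=1) - se2.mean(axis=1)).clip(lower=0.0)
    denom = se2.add(tau2, axis=0).to_numpy()
    # shrink toward 0 by the signal fraction; 0/0 (no noise, no signal) -> 1
    factor = np.where(denom > 0, tau2.to_numpy()[:, None] / np.where(denom > 0, denom, 1.0), 1.0)
    d_tilde = d_hat * pd.DataFrame(factor, index=d_hat.index, columns=d_hat.columns)
    return d_hat, d_tilde, tau2.rename("tau2")


class NormFinder(BaseEstimator):
    """Model-based stability ranking (grouped or ungrouped).

    Attributes after :meth:`fit`
    ----------------------------
    genes_ : list of gene names.
    mode_ : "grouped" or "ungrouped".
    gamma2_ : DataFrame gene x group of floored residual-variance estimates
        (single column "all" in ungrouped mode).
    d_hat_, d_tilde_, tau2_ : inter-group bias terms (grouped mode only).
    stability_ : Series of rho values, lower = more stable.
    ranking_ : Series of integer ranks, ascending in rho, ties by input order.
    """

    def fit(self, X, y=None, groups=None):
        """Fit on a samples x genes log-scale matrix (e.g. -Ct).

        Parameters
        ----------
        X : DataFrame or ndarray, samples x genes.
        groups : array-like of per-sample labels, optional
            Omit (None) for ungrouped analysis.
        """
        X = pd.DataFrame(X)
        ymat = X.T  # genes x samples
        z = sample_center(ymat)
        self.genes_ = list(ymat.index)
        if groups is None:
            self.mode_ = "ungrouped"
            gamma2 = intragroup_variances(z, ["all"] * z.shape[1])
            self.gamma2_ = gamma2
            self.d_hat_ = self.d_tilde_ = self.tau2_ = None
            rho = np.sqrt(gamma2["all"])
        else:
            self.mode_ = "grouped"
            gamma2 = intragroup_variances(z, groups)
            d_hat, d_tilde, tau2 = intergroup_variation(z, groups, gamma2)
            self.gamma2_, self.d_hat_, self.d_tilde_, self.tau2_ = (
                gamma2, d_hat, d_tilde, tau2,
            )
            cols = _group_columns(z, groups)
            k = pd.Series({g: len(s) for g, s in cols.items()})
            se = np.sqrt(gamma2[d_tilde.columns].div(k, axis=1))
            rho = (d_tilde.abs() + se).mean(axis=1)
        self.stability_ = rho.rename("stability").loc[self.genes_]
        order = sorted(range(len(self.genes_)), key=lambda i: (self.stability_.iloc[i], i))
        ranks = pd.Series(0, index=self.genes_, name="rank")
        for r, i in enumerate(order, start=1):
            ranks.iloc[i] = r
        self.ranking_ = ranks
        return self


def stability_values(y: pd.DataFrame, groups=None) -> NormFinder:
    """Run the analysis on a gene x sample log-scale matrix (e.g. -Ct)."""
    return NormFinder().fit(pd.DataFrame(y).T, groups=groups)
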