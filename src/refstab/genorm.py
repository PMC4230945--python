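"""geNorm expression-stability analysis.

The method rests on the observation that the expression ratio of two ideal
reference genes is constant across samples. For each gene j it computes the
pairwise variation V[j,k] = SD over samples of log2(Q_j / Q_k) against every
other candidate k, and summarises stability as the M value, the mean of
V[j,k] over k != j. Genes are ranked by stepwise exclusion: the gene with
the highest M is removed and M recomputed, until the two most stable genes
remain (they share rank 1 — with only two genes left their M values are
equal by construction).

Relative quantities Q are derived from cycle thresholds via the
amplification efficiency E of each amplicon: Q = E^(minCt - Ct), so the
sample with the lowest Ct gets Q = 1 and Q halves per extra cycle at E = 2.

The number of reference genes worth using is chosen from the pairwise
variation series V(n/n+1) = SD over samples of log2(NF_n / NF_{n+1}), where
NF_n is the per-sample geometric mean of the n most stable genes' quantities.
The smallest n with V(n/n+1) below the cutoff (conventionally 0.15) is
recommended; adding a gene beyond that does not change normalization
appreciably.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .tables_io import CtTable

logger = logging.getLogger("refstab")

__all__ = [
    "GeNorm",
    "ct_to_quantity",
    "pairwise_stability",
    "m_values",
    "stepwise_ranking",
    "normalization_factor",
    "v_series",
]


def ct_to_quantity(ct: CtTable) -> pd.DataFrame:
    """Relative quantities Q = E^(minCt - Ct), gene x sample.

    The input must be replicate-collapsed. Genes with missing cells are
    dropped with a logged warning (the pairwise log-ratio matrix requires a
    complete table); a gene with no finite Ct at all raises.
    """
    mat = ct.sample_matrix()
    all_missing = mat.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(f"all-missing gene(s): {list(mat.index[all_missing])}")
    incomplete = mat.isna().any(axis=1)
    if incomplete.any():
        dropped = list(mat.index[incomplete])
        logger.warning("dropping %d gene(s) with missing Ct: %s", len(dropped), dropped)
        mat = mat.loc[~incomplete]
    eff = ct.efficiency.loc[mat.index]
    q = eff.to_numpy()[:, None] ** (mat.min(axis=1).to_numpy()[:, None] - mat.to_numpy())
    return pd.DataFrame(q, index=mat.index, columns=mat.columns)


def _check_quantities(q: pd.DataFrame) -> pd.DataFrame:
    q = pd.DataFrame(q)
    vals = q.to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals <= 0).any():
        raise ValueError("relative quantities must be finite and > 0")
    return q


def pairwise_stability(q: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene matrix of SD over samples of log2(Q_j / Q_k) (n-1 SD)."""
    q = _check_quantities(q)
    if q.shape[0] < 2 or q.shape[1] < 2:
        raise ValueError("need >=2 genes and >=2 samples")
    logq = np.log2(q.to_numpy(dtype=float))
    diff = logq[:, None, :] - logq[None, :, :]  # gene x gene x sample
    v = diff.std(axis=2, ddof=1)
    np.fill_diagonal(v, 0.0)
    return pd.DataFrame(v, index=q.index, columns=q.index)


def m_values(q: pd.DataFrame, active=None) -> pd.Series:
    """M_j = mean pairwise variation of gene j against the other active genes."""
    q = _check_quantities(q)
    active = list(q.index if active is None else active)
    if len(active) < 2:
        raise ValueError("M values need >=2 active genes")
    v = pairwise_stability(q.loc[active])
    n = len(active)
    m = v.sum(axis=1) / (n - 1)
    return m.rename("M")


def normalization_factor(q: pd.DataFrame, genes) -> pd.Series:
    """Per-sample normalization factor: geometric mean of the genes' quantities."""
    q = _check_quantities(q)
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise ValueError("empty gene set")
    nf = np.exp(np.log(q.loc[genes].to_numpy(dtype=float)).mean(axis=0))
    return pd.Series(nf, index=q.columns, name="NF")


class GeNorm(BaseEstimator):
    """geNorm stability ranking by stepwise exclusion.

    Parameters
    ----------
    cutoff : float, default 0.15
        Pairwise-variation threshold for recommending the number of
        reference genes.

    Attributes
    ----------
    genes_ : list
        Gene (feature) names seen during fit.
    pairwise_variation_ : DataFrame
        Full gene x gene log-ratio SD matrix (before any exclusion).
    exclusion_order_ : list of (gene, M)
        Genes in the order removed, with the M value that removed them.
    stability_order_ : list
        Genes from most to least stable: the final pair (input order)
        followed by the exclusions reversed.
    m_final_ : Series
        Each gene's M at the round it left the analysis (the final pair
        share the 2-gene M).
    most_stable_pair_ : tuple
        The last two genes standing.
    ranking_ : Series
        Integer ranks; the final pair share rank 1, the next gene is rank 3.
    v_series_ : DataFrame
        Columns n, v: V(n/n+1) for n = 2 .. G-1 (empty if G < 3).
    recommended_n_ : int or None
        Smallest n with V(n/n+1) < cutoff; None when never achieved.
    """

    def __init__(self, cutoff: float = 0.15):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        """Fit on a samples x genes matrix of relative quantities (> 0).

        Accepts a DataFrame (columns = gene names) or ndarray.
        """
        X = pd.DataFrame(X)
        q = _check_quantities(X.T)  # gene x sample, the method's orientation
        self._q_ = q
        if q.shape[0] < 2:
            raise ValueError("geNorm needs >=2 genes")
        if q.shape[1] < 2:
            raise ValueError("geNorm needs >=2 samples")
        self.genes_ = list(q.index)
        self.pairwise_variation_ = pairwise_stability(q)

        active = list(q.index)
        exclusion: list[tuple] = []
        m_final = {}
        while len(active) > 2:
            m = m_values(q, active)
            worst = None
            for g in active:  # ties -> exclude the later gene in input order
                if worst is None or m[g] >= m[worst]:
                    worst = g
            exclusion.append((worst, float(m[worst])))
            m_final[worst] = float(m[worst])
            active.remove(worst)
        m_pair = m_values(q, active)
        for g in active:
            m_final[g] = float(m_pair[g])

        self.exclusion_order_ = exclusion
        self.most_stable_pair_ = tuple(active)
        self.stability_order_ = active + [g for g, _ in reversed(exclusion)]
        self.m_final_ = pd.Series(m_final, name="M").loc[self.genes_]
        ranks = {g: 1 for g in active}
        for i, g in enumerate(self.stability_order_[2:], start=3):
            ranks[g] = i
        self.ranking_ = pd.Series(ranks, name="rank").loc[self.genes_]
        self.v_series_, self.recommended_n_ = v_series(
            q, self.stability_order_, self.cutoff
        )
        return self

    def normalization_factor(self, n: int = 2) -> pd.Series:
        """NF over the n most stable genes, on the fitted quantities."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "stability_order_")
        return normalization_factor(self._q_, self.stability_order_[:n])

    def fit_transform(self, X, y=None):  # pragma: no cover - convenience
        return self.fit(X).ranking_.to_numpy()


def stepwise_ranking(q: pd.DataFrame, cutoff: float = 0.15) -> GeNorm:
    """Run the full geNorm analysis on a gene x sample quantity matrix."""
    q = _check_quantities(q)
    if q.shape[0] < 3:
        raise ValueError("stepwise exclusion needs >=3 genes")
    return GeNorm(cutoff=cutoff).fit(q.T)


def v_series(
    q: pd.DataFrame, ranking, cutoff: float = 0.15
) -> tuple[pd.DataFrame, int | None]:
    """Pairwise variation V(n/n+1) for n = 2 .. G-1, genes added in stability order.

    Returns the series and the smallest n with V < cutoff (None if never).
    """
    q = _check_quantities(q)
    ranking = list(ranking)
    rows = []
    recommended = None
    for n in range(2, len(ranking)):
        nf_n = normalization_factor(q, ranking[:n])
        nf_n1 = normalization_factor(q, ranking[: n + 1])
        v = float(np.log2(nf_n.to_numpy() / nf_n1.to_numpy()).std(ddof=1))
        rows.append((n, v))
        if recommended is None and v < cutoff:
            recommended = n
    return pd.DataFrame(rows, columns=["n", "v"]), recommended
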