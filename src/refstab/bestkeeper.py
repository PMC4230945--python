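"""BestKeeper-style descriptive stability analysis on raw Ct values.

Per gene the method reports the arithmetic and geometric mean Ct, the range,
a dispersion measure SD, and CV = 100 * SD / mean. Following the original
tool's convention the default SD is the mean absolute deviation around the
arithmetic mean (a robust dispersion on the cycle scale); the classic n-1
standard deviation is available via ``sd_method="classic"``.

Candidates are additionally judged against the BestKeeper index — the
per-sample geometric mean of the candidate genes' Ct values — through the
Pearson correlation r (two-sided p from the t distribution with n-2 df).
A gene tracking the index tightly (r near 1) varies with overall template
load rather than on its own. The original spreadsheet handles at most 10
genes; that cap is kept as a configurable default.

Genes are ranked by (CV, SD) ascending: the most stable gene shows the
lowest dispersion of its cycle threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .tables_io import CtTable

logger = logging.getLogger("refstab")

__all__ = [
    "BestKeeper",
    "descriptive_stats",
    "bestkeeper_index",
    "index_correlations",
]


def _as_ct_matrix(ct) -> pd.DataFrame:
    if isinstance(ct, CtTable):
        return ct.sample_matrix()
    return pd.DataFrame(ct)


def descriptive_stats(ct, sd_method: str = "mad") -> pd.DataFrame:
    """Per-gene Ct descriptives: geo/arith mean, min, max, SD, CV%.

    ``ct`` is a collapsed CtTable or a gene x sample DataFrame; missing
    cells are dropped per gene with a logged count. SD is the mean absolute
    deviation (``"mad"``, the method's convention) or the n-1 standard
    deviation (``"classic"``).
    """
    if sd_method not in ("mad", "classic"):
        raise ValueError(f"sd_method must be 'mad' or 'classic', got {sd_method!r}")
    mat = _as_ct_matrix(ct)
    rows = []
    n_dropped = int(mat.isna().to_numpy().sum())
    if n_dropped:
        logger.info("descriptive_stats: ignoring %d missing Ct cell(s)", n_dropped)
    for gene in mat.index:
        x = mat.loc[gene].dropna().to_numpy(dtype=float)
        if x.size < 2:
            raise ValueError(f"gene {gene!r} has {x.size} observation(s); need >=2")
        if (x <= 0).any():
            raise ValueError(f"gene {gene!r} has non-positive Ct")
        ar = float(x.mean())
        sd = float(np.abs(x - ar).mean()) if sd_method == "mad" else float(x.std(ddof=1))
        rows.append(
            (gene, float(sps.gmean(x)), ar, float(x.min()), float(x.max()),
             sd, 100.0 * sd / ar)
        )
    return pd.DataFrame(
        rows, columns=["gene", "geo_mean", "ar_mean", "min", "max", "sd", "cv_pct"]
    ).set_index("gene")


def bestkeeper_index(ct, genes=None, cap: int = 10) -> pd.Series:
    """Per-sample index: geometric mean of the candidate genes' Ct values.

    Duplicated gene names are used once. More than ``cap`` genes raises,
    mirroring the original tool's 10-gene limit (raise the cap to lift it).
    """
    mat = _as_ct_matrix(ct)
    genes = list(dict.fromkeys(mat.index if genes is None else genes))
    if len(genes) < 2:
        raise ValueError("index needs >=2 genes")
    if cap is not None and len(genes) > cap:
        raise ValueError(
            f"{len(genes)} genes exceed the method's {cap}-gene limit; "
            "pre-select candidates or raise the cap"
        )
    sub = mat.loc[genes]
    if sub.isna().to_numpy().any():
        raise ValueError("index needs complete Ct rows for the chosen genes")
    return pd.Series(
        sps.gmean(sub.to_numpy(dtype=float), axis=0), index=mat.columns, name="index"
    )


def index_correlations(ct, index: pd.Series) -> pd.DataFrame:
    """Pearson r (and two-sided p, t with n-2 df) of each gene's Ct vs the index.

    Zero-variance genes get r = p = NaN with a logged reason.
    """
    mat = _as_ct_matrix(ct)
    index = pd.Series(index).reindex(mat.columns)
    if mat.shape[1] < 3:
        raise ValueError("correlations need >=3 samples")
    rows = []
    for gene in mat.index:
        x = mat.loc[gene].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(index.to_numpy(dtype=float))
        xv, iv = x[keep], index.to_numpy(dtype=float)[keep]
        if np.ptp(xv) == 0 or np.ptp(iv) == 0:
            logger.info("gene %r: zero variance, correlation undefined", gene)
            rows.append((gene, np.nan, np.nan))
            continue
        r, p = sps.pearsonr(xv, iv)
        rows.append((gene, float(r), float(p)))
    return pd.DataFrame(rows, columns=["gene", "r", "p"]).set_index("gene")


class BestKeeper(BaseEstimator):
    """Descriptive Ct-stability ranking with index correlations.

    Parameters
    ----------
    sd_method : {"mad", "classic"}
        Dispersion convention (mean absolute deviation by default).
    max_genes : int, default 10
        Cap on the number of genes entering the index.
    index_genes : list, optional
        Genes forming the index (default: all fitted genes).

    Attributes after :meth:`fit`
    ----------------------------
    stats_ : DataFrame per gene with geo_mean, ar_mean, min, max, sd,
        cv_pct, r, p and rank.
    index_ : Series, the per-sample BestKeeper index.
    ranking_ : Series of integer ranks by (CV, SD) ascending.
    """

    def __init__(self, sd_method: str = "mad", max_genes: int = 10, index_genes=None):
        self.sd_method = sd_method
        self.max_genes = max_genes
        self.index_genes = index_genes

    def fit(self, X, y=None):
        """Fit on a samples x genes matrix of (collapsed) Ct values."""
        mat = pd.DataFrame(X).T  # gene x sample
        if mat.shape[0] > self.max_genes:
            raise ValueError(
                f"{mat.shape[0]} genes exceed the method's {self.max_genes}-gene "
                "limit; pre-select candidates (e.g. by geNorm rank) or raise max_genes"
            )
        self.genes_ = list(mat.index)
        stats = descriptive_stats(mat, self.sd_method)
        self.index_ = bestkeeper_index(
            mat, self.index_genes, cap=self.max_genes
        )
        corr = index_correlations(mat, self.index_)
        stats = stats.join(corr)
        order = sorted(
            range(len(stats)),
            key=lambda i: (stats["cv_pct"].iloc[i], stats["sd"].iloc[i], i),
        )
        ranks = pd.Series(0, index=stats.index, name="rank")
        for r, i in enumerate(order, start=1):
            ranks.iloc[i] = r
        stats["rank"] = ranks
        self.stats_ = stats
        self.ranking_ = ranks
        return self
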