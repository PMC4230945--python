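"""Candidate reference-gene screening from a transcriptome abundance matrix.

A good qRT-PCR reference gene should be moderately expressed and flat across
conditions. Screening therefore combines:

* an abundance window — every group mean inside [low, high] RPKM
  (default 50–500), which removes both weakly expressed genes and
  rRNA-like genes with means in the thousands; and
* per-group dispersion thresholds — coefficient of variation
  CV = 100 * SD / mean and maximum fold change MFC = max / min computed per
  sample group (one organ across stages, or one stage across organs), with a
  gene passing a group when round(CV, 2) <= cv_max and round(MFC, 2) <= mfc_max.

The candidate set is the union of genes passing in at least ``min_groups``
groups. Known housekeeping genes can be tagged and exempted from the screen:
they are carried forward into downstream stability analysis regardless of
their dispersion, mirroring common practice of benchmarking novel candidates
against the traditional panel.

The module ships the published ginseng screening table (per-group mean, CV
and MFC for 10 housekeeping genes and the 10 novel candidates across
3 organs and 5 growth stages) as a fixture, loadable with :func:`load_ginseng_screening`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .tables_io import ExpressionTable

__all__ = [
    "GroupStats",
    "ScreeningReport",
    "group_stats",
    "abundance_filter",
    "screen_candidates",
    "load_ginseng_screening",
    "GINSENG_HOUSEKEEPING",
]

#: The traditional housekeeping panel of the ginseng study.
GINSENG_HOUSEKEEPING = (
    "ACT1", "GAPDH", "18SrRNA", "UBQ", "bTUB",
    "aTUB", "CYP", "eIF-5A", "F-box", "EF-1a",
)

STAT_COLUMNS = ["gene", "group", "mean", "sd", "cv_pct", "mfc"]


@dataclass(frozen=True)
class GroupStats:
    """Dispersion statistics of one gene within one sample group."""

    gene: str
    group: str
    mean: float
    sd: float
    cv_pct: float
    mfc: float


def _single_group_stats(values: np.ndarray, ddof: int = 1) -> tuple[float, float, float, float]:
    mean = float(values.mean())
    sd = float(values.std(ddof=ddof))
    return mean, sd, 100.0 * sd / mean, float(values.max() / values.min())


def group_stats(
    expr: ExpressionTable,
    grouping: str = "both",
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-(gene, group) mean, SD, CV% and MFC.

    Parameters
    ----------
    expr : ExpressionTable
        Abundance matrix bound to a sample design; all evaluated values must
        be strictly positive.
    grouping : {"both", "by_organ", "by_stage"}
        ``by_organ`` groups samples of one organ across stages, ``by_stage``
        one stage across organs; ``both`` concatenates the two margins (the
        full screening layout: 3 + 5 = 8 groups under a 3x5 design).
    ddof : int
        Delta degrees of freedom for the SD (1 = sample SD, the default).

    Returns
    -------
    pandas.DataFrame
        Columns gene, group, mean, sd, cv_pct, mfc; one row per (gene, group).
    """
    if grouping not in ("both", "by_organ", "by_stage"):
        raise ValueError(f"unknown grouping {grouping!r}")
    margins = {"by_organ": ["organ"], "by_stage": ["stage"], "both": ["organ", "stage"]}
    groups: dict[str, list[str]] = {}
    for margin in margins[grouping]:
        for level, samples in expr.design.groups(margin).items():
            groups[level] = samples
    rows = []
    for group, samples in groups.items():
        samples = [s for s in samples if s in expr.values.columns]
        if len(samples) < 2:
            raise ValueError(f"group {group!r} has <2 samples")
        sub = expr.values[samples]
        nonpos = sub <= 0
        if nonpos.to_numpy().any():
            stacked = nonpos.stack()
            gene, sample = stacked.index[int(np.argmax(stacked.to_numpy()))]
            raise ValueError(
                f"non-positive abundance at gene {gene!r}, sample {sample!r}: "
                "CV/MFC undefined"
            )
        for gene in expr.genes:
            mean, sd, cv, mfc = _single_group_stats(sub.loc[gene].to_numpy(float), ddof)
            rows.append((gene, group, mean, sd, cv, mfc))
    return pd.DataFrame(rows, columns=STAT_COLUMNS)


def abundance_filter(
    expr: ExpressionTable,
    window: tuple[float, float] = (50.0, 500.0),
    grouping: str = "both",
) -> list[str]:
    """Genes whose mean abundance in *every* group lies within the window."""
    low, high = window
    if not low < high:
        raise ValueError(f"window low must be < high, got {window}")
    if not expr.genes:
        return []
    stats = group_stats(expr, grouping)
    ok = stats.groupby("gene", sort=False)["mean"].agg(
        lambda m: bool(((m >= low) & (m <= high)).all())
    )
    return [g for g in expr.genes if ok[g]]


@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of the CV/MFC screen.

    Attributes
    ----------
    stats : pandas.DataFrame
        Per-(gene, group) statistics with a boolean ``passed`` column.
    candidates : list of str
        Non-housekeeping genes passing in >= min_groups groups, in first-seen
        order.
    passing_groups : dict
        gene -> list of groups in which the gene passed.
    housekeeping : list of str
        Genes exempted from the screen and carried forward.
    thresholds : dict
        The cv_max / mfc_max / min_groups / rounding_dp actually used.
    """

    stats: pd.DataFrame
    candidates: list
    passing_groups: dict
    housekeeping: list
    thresholds: dict

    @property
    def panel(self) -> list:
        """Housekeeping panel plus novel candidates: the qPCR validation set."""
        return list(self.housekeeping) + [
            g for g in self.candidates if g not in self.housekeeping
        ]


def screen_candidates(
    stats: pd.DataFrame,
    cv_max: float = 20.0,
    mfc_max: float = 1.50,
    min_groups: int = 1,
    rounding_dp: int = 2,
    housekeeping: tuple | list = (),
) -> ScreeningReport:
    """Apply CV/MFC thresholds to per-group statistics and form the candidate set.

    A (gene, group) passes iff ``round(cv, rounding_dp) <= cv_max`` and
    ``round(mfc, rounding_dp) <= mfc_max``; comparisons happen at printed
    precision because published tables round to two decimals and list
    borderline passers at exactly the threshold.
    """
    if stats.empty:
        raise ValueError("empty statistics table")
    missing = [c for c in ("gene", "group", "cv_pct", "mfc") if c not in stats.columns]
    if missing:
        raise ValueError(f"statistics table missing columns {missing}")
    out = stats.copy()
    out["passed"] = (out["cv_pct"].round(rounding_dp) <= cv_max) & (
        out["mfc"].round(rounding_dp) <= mfc_max
    )
    hk = [g for g in housekeeping if g in set(out["gene"])]
    passing: dict[str, list] = {}
    for gene, sub in out.groupby("gene", sort=False):
        passing[gene] = list(sub.loc[sub["passed"], "group"])
    candidates = [
        g for g in dict.fromkeys(out["gene"])
        if g not in set(hk) and len(passing[g]) >= min_groups
    ]
    return ScreeningReport(
        stats=out,
        candidates=candidates,
        passing_groups=passing,
        housekeeping=hk,
        thresholds={
            "cv_max": cv_max,
            "mfc_max": mfc_max,
            "min_groups": min_groups,
            "rounding_dp": rounding_dp,
        },
    )


def load_ginseng_screening() -> pd.DataFrame:
    """The packaged ginseng screening fixture (printed per-group CV/MFC values).

    Returns a DataFrame with columns gene, group, mean, cv_pct, mfc and a
    boolean ``housekeeping`` flag. Novel genes appear only in the groups
    where the published table lists them (i.e. where they passed the screen).
    """
    with resources.files("refstab.data").joinpath("ginseng_screening.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["housekeeping"] = df["housekeeping"].astype(bool)
    return df
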