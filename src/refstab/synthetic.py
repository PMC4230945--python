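"""Synthetic expression and Ct data with planted stability structure.

Every downstream stage of the package can be exercised against ground truth:
the generator plants, per gene, a baseline abundance (RPKM-like) and baseline
Ct, a gene-specific residual SD gamma on the log2 scale, and additive
organ/stage offsets (log2 units); per sample it adds a shared loading/RT
effect, and per well replicate noise on the Ct scale. Noise is Gaussian on
log2 (equivalently on Ct), the standard qPCR error model; optional
heavy-tail contamination mixes in occasional t-distributed residuals for
robustness checks.

The default design mirrors a 3-organ x 5-stage factorial with one biological
sample per cell and 3 technical replicates (15 samples, 45 wells per gene).
RPKM values are treated as library-normalized, so the shared per-sample
effect enters only the Ct table.

:func:`truth_ranking` converts the planted parameters into the expected
stability order — total instability gamma^2 + variance of the group offsets
across the design cells — which recovery tests compare against the rankings
the three analysis methods estimate from the simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import CtTable, ExpressionTable, SampleDesign

__all__ = [
    "SimTruth",
    "default_truth",
    "planted_outlier_truth",
    "simulate_expression",
    "simulate_ct",
    "truth_ranking",
]

ORGANS = ("root", "stem", "leaf")
STAGES = ("LP", "FS", "GFS", "RFS", "RGS")

#: The 20-gene panel of the ginseng study: 10 housekeeping + 10 novel.
PANEL_GENES = (
    "ACT1", "GAPDH", "18SrRNA", "UBQ", "bTUB",
    "aTUB", "CYP", "eIF-5A", "F-box", "EF-1a",
    "CDP", "6-PG", "30SRPS20", "60SRPL13", "V-ATP",
    "polIIa", "ARF", "QCR", "SAR1", "TCTP",
)


@dataclass(frozen=True)
class SimTruth:
    """Planted simulation parameters.

    All per-gene containers are pandas Series/DataFrames indexed by gene;
    offsets are DataFrames gene x level in log2 units. ``sample_effect_sd``
    models shared loading/RT variation (Ct scale), ``replicate_sd`` the
    technical well noise, and ``heavy_tail_frac`` the fraction of residuals
    drawn from a t(3) distribution instead of a normal.
    """

    genes: tuple
    baseline_ct: pd.Series
    baseline_rpkm: pd.Series
    gamma: pd.Series                # residual log2 SD per gene
    organ_offsets: pd.DataFrame     # gene x organ, log2
    stage_offsets: pd.DataFrame     # gene x stage, log2
    sample_effect_sd: float = 0.3
    replicate_sd: float = 0.15
    efficiency: pd.Series = None
    organs: tuple = ORGANS
    stages: tuple = STAGES
    n_replicates: int = 3
    heavy_tail_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.efficiency is None:
            object.__setattr__(
                self, "efficiency",
                pd.Series(2.0, index=list(self.genes), name="efficiency"),
            )
        if (self.gamma < 0).any() or self.sample_effect_sd < 0 or self.replicate_sd < 0:
            raise ValueError("planted SDs must be >= 0")
        eff = self.efficiency
        if ((eff <= 1.0) | (eff > 2.2)).any():
            raise ValueError("efficiency must be in (1, 2.2]")
        if not (self.organs and self.stages and self.n_replicates >= 1):
            raise ValueError("design must be nonempty")

    def design(self) -> SampleDesign:
        rows = [
            (f"{o}_{s}", o, s, 1) for o in self.organs for s in self.stages
        ]
        df = pd.DataFrame(rows, columns=["sample_id", "organ", "stage", "replicate"])
        return SampleDesign(df.set_index("sample_id"))


def _rng(truth: SimTruth, stream: int) -> np.random.Generator:
    return np.random.default_rng([truth.seed, stream])


def _residuals(rng, shape, heavy_tail_frac: float) -> np.ndarray:
    """Standard residuals, optionally contaminated with t(3) draws."""
    eps = rng.standard_normal(shape)
    if heavy_tail_frac > 0:
        mask = rng.random(shape) < heavy_tail_frac
        eps = np.where(mask, rng.standard_t(3, size=shape), eps)
    return eps


def _cell_offsets(truth: SimTruth) -> pd.DataFrame:
    """Gene x sample matrix of organ+stage offsets over the design grid."""
    design = truth.design()
    cols = {}
    for sid, row in design.table.iterrows():
        cols[sid] = (
            truth.organ_offsets[row["organ"]] + truth.stage_offsets[row["stage"]]
        )
    out = pd.DataFrame(cols, index=list(truth.genes))
    out.index.name = "gene"
    return out


def simulate_expression(truth: SimTruth) -> ExpressionTable:
    """RPKM-like matrix: baseline * 2^(group offsets + N(0, gamma)) per sample."""
    rng = _rng(truth, 1)
    offsets = _cell_offsets(truth)
    eps = _residuals(rng, offsets.shape, truth.heavy_tail_frac)
    log2v = (
        np.log2(truth.baseline_rpkm.to_numpy())[:, None]
        + offsets.to_numpy()
        + truth.gamma.to_numpy()[:, None] * eps
    )
    values = pd.DataFrame(2.0 ** log2v, index=offsets.index, columns=offsets.columns)
    return ExpressionTable(values, truth.design())


def simulate_ct(truth: SimTruth) -> CtTable:
    """Replicated Ct table.

    Ct[g, s, rep] = baselineCt_g - (offsets + sample effect + N(0, gamma_g))
    + N(0, replicate_sd): higher expression means earlier threshold crossing,
    so biological effects enter with a minus sign.
    """
    rng = _rng(truth, 2)
    offsets = _cell_offsets(truth)
    n_genes, n_samples = offsets.shape
    sample_eff = rng.normal(0.0, truth.sample_effect_sd, size=n_samples)
    eps = _residuals(rng, (n_genes, n_samples), truth.heavy_tail_frac)
    true_ct = (
        truth.baseline_ct.to_numpy()[:, None]
        - offsets.to_numpy()
        - sample_eff[None, :]
        - truth.gamma.to_numpy()[:, None] * eps
    )
    reps = truth.n_replicates
    wells = pd.MultiIndex.from_tuples(
        [(s, r) for s in offsets.columns for r in range(1, reps + 1)],
        names=["sample_id", "replicate"],
    )
    noise = rng.normal(0.0, truth.replicate_sd, size=(n_genes, n_samples * reps))
    ct = pd.DataFrame(
        np.repeat(true_ct, reps, axis=1) + noise, index=offsets.index, columns=wells
    )
    return CtTable(ct, truth.efficiency, truth.design())


def truth_ranking(truth: SimTruth) -> pd.DataFrame:
    """Expected stability order from the planted parameters.

    Instability = gamma^2 + population variance over the design cells of the
    summed organ+stage offsets. Equal instability yields shared (min) ranks,
    so a fully symmetric truth is declared a full tie.
    """
    offsets = _cell_offsets(truth)
    between = offsets.to_numpy().var(axis=1)  # population variance over cells
    instab = pd.Series(
        truth.gamma.to_numpy() ** 2 + between, index=offsets.index, name="instability"
    )
    rank = instab.rank(method="min").astype(int)
    out = pd.DataFrame({"instability": instab, "rank": rank})
    return out.sort_values(["instability"], kind="mergesort")


def _centered(rng, levels, sd, genes) -> pd.DataFrame:
    raw = rng.normal(0.0, sd, size=(len(genes), len(levels)))
    raw -= raw.mean(axis=1, keepdims=True)
    return pd.DataFrame(raw, index=list(genes), columns=list(levels))


def default_truth(seed: int = 0) -> SimTruth:
    """Study-like default truth: the 20-gene panel on a 3 x 5 x 3 design.

    Housekeeping genes get moderate residual SDs (0.25–0.6 log2) and
    noticeable organ/stage offsets, the rRNA-like gene is abundant and
    volatile, and the 10 novel genes are flat (SD 0.08–0.2, near-zero
    offsets) — the qualitative structure the screening stage is meant to
    detect.
    """
    rng = np.random.default_rng([seed, 0])
    genes = PANEL_GENES
    hk = set(PANEL_GENES[:10])

    baseline_ct, baseline_rpkm, gamma = {}, {}, {}
    for g in genes:
        if g == "18SrRNA":
            baseline_ct[g] = 15.1
            baseline_rpkm[g] = 2500.0
            gamma[g] = 0.9
        elif g == "bTUB":
            baseline_ct[g] = 26.4
            baseline_rpkm[g] = float(rng.uniform(90, 250))
            gamma[g] = float(rng.uniform(0.25, 0.6))
        elif g in hk:
            baseline_ct[g] = float(rng.uniform(19, 24))
            baseline_rpkm[g] = float(rng.uniform(90, 500))
            gamma[g] = float(rng.uniform(0.25, 0.6))
        else:
            baseline_ct[g] = float(rng.uniform(19, 24))
            baseline_rpkm[g] = float(rng.uniform(80, 200))
            gamma[g] = float(rng.uniform(0.08, 0.2))

    organ_off = _centered(rng, ORGANS, 0.0, genes)
    stage_off = _centered(rng, STAGES, 0.0, genes)
    for g in genes:
        sd = 0.35 if g in hk else 0.04
        organ_off.loc[g] = _centered(rng, ORGANS, sd, [g]).iloc[0]
        stage_off.loc[g] = _centered(rng, STAGES, sd, [g]).iloc[0]

    return SimTruth(
        genes=genes,
        baseline_ct=pd.Series(baseline_ct),
        baseline_rpkm=pd.Series(baseline_rpkm),
        gamma=pd.Series(gamma),
        organ_offsets=organ_off,
        stage_offsets=stage_off,
        seed=seed,
    )


def planted_outlier_truth(
    seed: int = 0,
    n_genes: int = 8,
    gamma_stable: float = 0.1,
    gamma_outlier: float = 0.8,
) -> SimTruth:
    """Truth with one clearly unstable gene (last in the panel).

    All genes share the design and baselines; the final gene's residual
    log2 SD is ``gamma_outlier`` (default 8x the others — a wide margin, so
    that even the raw-Ct dispersion ranking of BestKeeper, whose per-gene SD
    is inflated by the shared sample effect, separates the outlier at 15
    samples), no group offsets. The canonical recovery scenario for
    rank-last tests.
    """
    rng = np.random.default_rng([seed, 0])
    genes = tuple(f"g{i + 1}" for i in range(n_genes))
    gamma = pd.Series(gamma_stable, index=list(genes))
    gamma.iloc[-1] = gamma_outlier
    return SimTruth(
        genes=genes,
        baseline_ct=pd.Series(rng.uniform(19, 24, n_genes), index=list(genes)),
        baseline_rpkm=pd.Series(rng.uniform(80, 300, n_genes), index=list(genes)),
        gamma=gamma,
        organ_offsets=_centered(rng, ORGANS, 0.0, genes),
        stage_offsets=_centered(rng, STAGES, 0.0, genes),
        sample_effect_sd=0.3,
        replicate_sd=0.1,
        seed=seed,
    )
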