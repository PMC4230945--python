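"""Method comparison, rank aggregation and the end-to-end pipeline driver.

The three stability methods rarely agree exactly; a side-by-side rank table
per sample set (total, each organ, each stage) plus a geometric-mean rank
aggregate (RefFinder-style) turns their qualitative agreement into a single
final order. BestKeeper ranks may be missing for genes outside its capped
input; the aggregate uses whatever ranks are available.

:func:`run_pipeline` drives everything from a run configuration: optional
screening of an expression matrix, then geNorm, NormFinder and BestKeeper on
every sample set derived from the design, with reports written as TSV/JSON
plus a plain-text summary. Given the same configuration (and seed, when the
inputs are simulated) two runs produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import screening as _screening
from .bestkeeper import BestKeeper
from .genorm import GeNorm, ct_to_quantity
from .normfinder import NormFinder
from .tables_io import (
    CtTable,
    collapse_replicates,
    read_ct_table,
    read_expression_table,
)

logger = logging.getLogger("refstab")

__all__ = [
    "method_rank_table",
    "aggregate_ranks",
    "run_pipeline",
    "PipelineResult",
    "SampleSetResult",
]

METHOD_COLUMNS = ["genorm", "normfinder", "bestkeeper"]


def _ranks_of(obj) -> pd.Series:
    if obj is None:
        return None
    if isinstance(obj, pd.Series):
        return obj
    if hasattr(obj, "ranking_"):
        return obj.ranking_
    raise TypeError(f"cannot extract ranking from {type(obj).__name__}")


def method_rank_table(genorm, normfinder, bestkeeper=None) -> pd.DataFrame:
    """Per-gene rank triple; missing BestKeeper ranks become NaN.

    Accepts fitted estimators or rank Series. geNorm and NormFinder must
    cover the same gene universe; BestKeeper may cover a subset.
    """
    rg, rn, rb = _ranks_of(genorm), _ranks_of(normfinder), _ranks_of(bestkeeper)
    genes = list(rg.index)
    if set(genes) != set(rn.index):
        raise ValueError("geNorm and NormFinder were run on different gene sets")
    if rb is not None:
        stray = set(rb.index) - set(genes)
        if stray:
            raise ValueError(f"BestKeeper genes outside the universe: {sorted(stray)}")
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    table["genorm"] = rg.astype(float)
    table["normfinder"] = rn.reindex(genes).astype(float)
    table["bestkeeper"] = (
        rb.reindex(genes).astype(float) if rb is not None else np.nan
    )
    return table


def aggregate_ranks(table: pd.DataFrame, method: str = "geometric_mean") -> pd.DataFrame:
    """Aggregate available method ranks into a final order.

    ``geometric_mean`` (default) or ``mean`` of the non-missing ranks; ties
    broken by geNorm rank, then input order. Returns the table with
    ``aggregate`` and ``final_rank`` columns, sorted by final rank.
    """
    if table.empty:
        raise ValueError("empty rank table")
    if method not in ("geometric_mean", "mean"):
        raise ValueError(f"unknown aggregation {method!r}")
    vals = table[METHOD_COLUMNS]
    if vals.isna().all(axis=1).any():
        bad = list(table.index[vals.isna().all(axis=1)])
        raise ValueError(f"gene(s) with no rank from any method: {bad}")
    if method == "geometric_mean":
        agg = np.exp(np.log(vals).mean(axis=1, skipna=True))
    else:
        agg = vals.mean(axis=1, skipna=True)
    out = table.copy()
    out["aggregate"] = agg
    order = sorted(
        range(len(out)),
        key=lambda i: (out["aggregate"].iloc[i], out["genorm"].iloc[i], i),
    )
    final = pd.Series(0, index=out.index)
    for r, i in enumerate(order, start=1):
        final.iloc[i] = r
    out["final_rank"] = final
    return out.sort_values("final_rank", kind="mergesort")


@dataclass
class SampleSetResult:
    """Fitted methods and consensus for one sample set."""

    name: str
    samples: list
    genorm: GeNorm
    normfinder: NormFinder
    bestkeeper: BestKeeper
    ranking: pd.DataFrame  # aggregated rank table


@dataclass
class PipelineResult:
    """Everything a full run produced; :meth:`write` serializes it."""

    screening: object  # ScreeningReport or None
    sets: dict  # name -> SampleSetResult
    config: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary: dict = {"config": _jsonable(self.config), "sets": {}}
        if self.screening is not None:
            rep = self.screening
            rep.stats.to_csv(
                outdir / "screening.tsv", sep="\t", index=False,
                float_format="%.6g", lineterminator="\n",
            )
            summary["screening"] = {
                "candidates": list(rep.candidates),
                "housekeeping": list(rep.housekeeping),
                "thresholds": rep.thresholds,
            }
        for name, res in self.sets.items():
            g = res.genorm
            pd.DataFrame(
                {"M": g.m_final_.round(6), "rank": g.ranking_}
            ).rename_axis("gene").to_csv(
                outdir / f"{name}.genorm.tsv", sep="\t",
                float_format="%.6g", lineterminator="\n",
            )
            g.v_series_.to_csv(
                outdir / f"{name}.vseries.tsv", sep="\t", index=False,
                float_format="%.6g", lineterminator="\n",
            )
            nf = res.normfinder
            nf_out = pd.DataFrame(
                {"stability": nf.stability_.round(6), "rank": nf.ranking_}
            )
            if nf.mode_ == "grouped":
                for grp in nf.gamma2_.columns:
                    nf_out[f"gamma2_{grp}"] = nf.gamma2_[grp].round(6)
                    nf_out[f"d_hat_{grp}"] = nf.d_hat_[grp].round(6)
                    nf_out[f"d_tilde_{grp}"] = nf.d_tilde_[grp].round(6)
            nf_out.rename_axis("gene").to_csv(
                outdir / f"{name}.normfinder.tsv", sep="\t",
                float_format="%.6g", lineterminator="\n",
            )
            res.bestkeeper.stats_.round(6).rename_axis("gene").to_csv(
                outdir / f"{name}.bestkeeper.tsv", sep="\t",
                float_format="%.6g", lineterminator="\n",
            )
            res.ranking.round(6).to_csv(
                outdir / f"{name}.ranking.tsv", sep="\t",
                float_format="%.6g", lineterminator="\n",
            )
            summary["sets"][name] = {
                "n_samples": len(res.samples),
                "most_stable_pair": list(g.most_stable_pair_),
                "recommended_n": g.recommended_n_,
                "normfinder_top": nf.stability_.idxmin(),
                "normfinder_mode": nf.mode_,
                "bestkeeper_top": res.bestkeeper.ranking_.idxmin(),
                "consensus_top": res.ranking.index[0],
            }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        self._write_text_summary(outdir / "summary.txt")

    def _write_text_summary(self, path) -> None:
        """Plain-text gene x set table of G/N/B ranks."""
        lines = ["Stability ranking per sample set (G=geNorm, N=NormFinder, B=BestKeeper)", ""]
        names = list(self.sets)
        genes = list(self.sets[names[0]].ranking.sort_index().index) if names else []
        header = ["gene"] + [f"{n}(G/N/B)" for n in names]
        rows = []
        for gene in genes:
            cells = [gene]
            for n in names:
                t = self.sets[n].ranking
                if gene in t.index:
                    trip = [
                        "-" if pd.isna(t.loc[gene, m]) else str(int(t.loc[gene, m]))
                        for m in METHOD_COLUMNS
                    ]
                    cells.append("/".join(trip))
                else:
                    cells.append("-")
            rows.append(cells)
        widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
        for r in [header] + rows:
            lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)))
        Path(path).write_text("\n".join(lines) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _auto_groups(ct: CtTable, samples, policy: str):
    """Per-sample group labels for NormFinder, or None for ungrouped."""
    design = ct.design.table.loc[samples]
    candidates = {"organ": design["organ"], "stage": design["stage"]}
    if policy == "none":
        return None
    margins = [policy] if policy in candidates else ["organ", "stage"]
    for margin in margins:
        labels = candidates[margin]
        counts = labels.value_counts()
        if len(counts) >= 2 and (counts >= 2).all():
            return labels
    if policy in candidates:
        logger.warning(
            "groups=%r not usable for this sample set; falling back to ungrouped",
            policy,
        )
    return None


def run_pipeline(config) -> PipelineResult:
    """Execute screening plus the three stability methods on every sample set.

    ``config`` is a dict or a YAML/JSON file path with keys::

        expression: path (optional)   # RPKM-like matrix for screening
        ct: path                      # Ct matrix (wide or long)
        design: path                  # sample design table
        efficiency: path (optional)
        housekeeping: [gene, ...]     # exempted from the screen
        screening: {cv_max, mfc_max, min_groups, window}
        genorm: {cutoff}
        normfinder: {groups}          # auto | organ | stage | none
        bestkeeper: {max_genes, sd_method}
        collapse: mean | median
        seed: int                     # recorded for provenance

    Tables may also be passed directly under ``expression_table`` /
    ``ct_table`` (programmatic use). Any stage failure aborts with the stage
    name and cause.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    expr = config.get("expression_table")
    if expr is None and config.get("expression"):
        expr = stage(
            "read_expression",
            read_expression_table, config["expression"], config["design"],
        )
    report = None
    if expr is not None:
        opts = dict(config.get("screening") or {})
        window = tuple(opts.pop("window", (50.0, 500.0)))
        hk = list(config.get("housekeeping") or ())
        stats = stage("screening", _screening.group_stats, expr)
        in_window = stage("screening", _screening.abundance_filter, expr, window)
        keep = [g for g in expr.genes if g in set(in_window) or g in set(hk)]
        stats = stats[stats["gene"].isin(keep)]
        report = stage(
            "screening", _screening.screen_candidates, stats,
            housekeeping=hk, **opts,
        )

    ct = config.get("ct_table")
    if ct is None and config.get("ct"):
        ct = stage(
            "read_ct", read_ct_table,
            config["ct"], config["design"], config.get("efficiency"),
        )

    sets: dict[str, SampleSetResult] = {}
    if ct is not None:
        collapsed = stage(
            "collapse", collapse_replicates, ct, config.get("collapse", "mean")
        )
        gn_opts = dict(config.get("genorm") or {})
        bk_opts = dict(config.get("bestkeeper") or {})
        nf_policy = (config.get("normfinder") or {}).get("groups", "auto")
        for name, samples in ct.design.sample_sets().items():
            sub = collapsed.subset_samples(samples)
            q = stage(f"{name}:quantities", ct_to_quantity, sub)
            genorm = stage(f"{name}:genorm", GeNorm(**gn_opts).fit, q.T)
            groups = _auto_groups(sub, list(q.columns), nf_policy)
            y = -sub.sample_matrix().loc[q.index]  # log2 scale up to a constant
            normfinder = stage(
                f"{name}:normfinder", NormFinder().fit, y.T, groups=groups
            )
            cap = bk_opts.get("max_genes", 10)
            bk_genes = (
                list(q.index) if len(q.index) <= cap
                else genorm.stability_order_[:cap]
            )
            bk_mat = sub.sample_matrix().loc[bk_genes]
            bestkeeper = stage(
                f"{name}:bestkeeper", BestKeeper(**bk_opts).fit, bk_mat.T
            )
            table = stage(
                f"{name}:rank", method_rank_table, genorm, normfinder, bestkeeper
            )
            ranking = stage(f"{name}:rank", aggregate_ranks, table)
            sets[name] = SampleSetResult(
                name=name, samples=list(samples), genorm=genorm,
                normfinder=normfinder, bestkeeper=bestkeeper, ranking=ranking,
            )

    public = {
        k: v for k, v in config.items() if k not in ("expression_table", "ct_table")
    }
    return PipelineResult(screening=report, sets=sets, config=public)
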