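"""Input/output and validation for expression matrices, Ct tables and sample designs.

The containers here are thin, validated wrappers around pandas objects:

* :class:`SampleDesign` — maps each sample to an organ and a growth stage
  (a factorial design such as 3 organs x 5 stages).
* :class:`ExpressionTable` — gene x sample abundance matrix (RPKM-like units)
  bound to a design; input to candidate screening.
* :class:`CtTable` — gene x well cycle-threshold matrix with replicate
  structure and per-gene amplification efficiency; input to the stability
  methods.

Files are plain TSV/CSV. Ct tables are accepted in wide layout (columns
named ``sampleID.rep``) or long layout (columns gene, sample, replicate, ct).
Missing Ct values are stored as NaN, never as 0 or 40 — substituting a fixed
cycle number biases every downstream variance statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("refstab")

__all__ = [
    "SampleDesign",
    "ExpressionTable",
    "CtTable",
    "read_design",
    "read_expression_table",
    "write_expression_table",
    "read_ct_table",
    "write_ct_table",
    "collapse_replicates",
]

DESIGN_COLUMNS = ("sample_id", "organ", "stage", "replicate")


def _read_table(path) -> pd.DataFrame:
    """Read a TSV or CSV file, sniffing the delimiter from the header line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


@dataclass(frozen=True)
class SampleDesign:
    """Sample metadata: one row per sample with organ, stage and replicate.

    Parameters
    ----------
    table : pandas.DataFrame
        Indexed by sample_id, with columns ``organ``, ``stage`` and
        ``replicate`` (biological replicate number, >= 1).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id in design: {dups}")
        for col in ("organ", "stage", "replicate"):
            if col not in t.columns:
                raise ValueError(f"design table missing column {col!r}")
        rep = pd.to_numeric(t["replicate"], errors="coerce")
        if rep.isna().any() or (rep < 1).any():
            bad = t.index[rep.isna() | (rep < 1)].tolist()
            raise ValueError(f"replicate must be an integer >= 1; bad samples: {bad}")
        object.__setattr__(self, "table", t.assign(replicate=rep.astype(int)))
        if len(self.organs) < 2 and len(self.stages) < 2:
            raise ValueError(
                "design needs >=2 levels on at least one margin (organ or stage) "
                "for grouped analyses"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def organs(self) -> list[str]:
        return list(dict.fromkeys(self.table["organ"]))

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.table["stage"]))

    def groups(self, margin: str) -> dict[str, list[str]]:
        """Samples per level of one margin (``"organ"`` or ``"stage"``)."""
        if margin not in ("organ", "stage"):
            raise ValueError(f"margin must be 'organ' or 'stage', got {margin!r}")
        levels = self.organs if margin == "organ" else self.stages
        col = self.table[margin]
        return {lv: list(self.table.index[col == lv]) for lv in levels}

    def sample_sets(self) -> dict[str, list[str]]:
        """The analysis sample sets: total, then one per organ, one per stage.

        For a 3-organ x 5-stage design this yields the nine sets
        (total, 3 organs, 5 stages) on which each stability method is run.
        """
        sets: dict[str, list[str]] = {"total": self.samples}
        sets.update(self.groups("organ"))
        sets.update(self.groups("stage"))
        return sets


def read_design(path) -> SampleDesign:
    df = _read_table(path)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design file {path}: missing columns {missing}")
    return SampleDesign(df.set_index("sample_id")[["organ", "stage", "replicate"]])


def _numeric_matrix(df: pd.DataFrame, path, allow_empty: bool = False) -> pd.DataFrame:
    """First column = gene symbol, remaining columns numeric; report bad cells."""
    gene_col = df.columns[0]
    genes = df[gene_col]
    if genes.duplicated().any():
        rows = (genes.index[genes.duplicated()] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: duplicate gene symbol at row(s) {rows}")
    if len(df) == 0 and not allow_empty:
        raise ValueError(f"{path}: no genes (header only)")
    out = df.set_index(gene_col)
    for col in out.columns:
        vals = out[col].replace({"": np.nan, "NA": np.nan, "NaN": np.nan})
        num = pd.to_numeric(vals, errors="coerce")
        bad = vals.notna() & num.isna()
        if bad.any():
            gene = out.index[bad.argmax()]
            raise ValueError(
                f"{path}: non-numeric value {vals[bad].iloc[0]!r} at gene {gene!r}, "
                f"column {col!r}"
            )
        out[col] = num
    out.index.name = "gene"
    return out


@dataclass(frozen=True)
class ExpressionTable:
    """Gene x sample abundance matrix (RPKM-like) bound to a sample design."""

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        unknown = [s for s in v.columns if s not in self.design.samples]
        if unknown:
            raise ValueError(f"samples absent from design: {unknown}")
        if (v.to_numpy() < 0).any():
            gene, sample = _first_offender(v, v < 0)
            raise ValueError(f"negative abundance at gene {gene!r}, sample {sample!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def _first_offender(df: pd.DataFrame, mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    gene, col = stacked.index[stacked.argmax()]
    return gene, col


def read_expression_table(matrix_path, design_path) -> ExpressionTable:
    """Read an abundance matrix (first column gene, header sample_ids) + design."""
    design = read_design(design_path)
    values = _numeric_matrix(_read_table(matrix_path), matrix_path)
    if values.isna().any().any():
        gene, sample = _first_offender(values, values.isna())
        raise ValueError(
            f"{matrix_path}: missing abundance at gene {gene!r}, sample {sample!r}"
        )
    return ExpressionTable(values, design)


def write_expression_table(table: ExpressionTable, matrix_path, design_path=None) -> None:
    table.values.to_csv(matrix_path, sep="\t", lineterminator="\n")
    if design_path is not None:
        write_design(table.design, design_path)


def write_design(design: SampleDesign, path) -> None:
    design.table.rename_axis("sample_id").to_csv(path, sep="\t", lineterminator="\n")


@dataclass(frozen=True)
class CtTable:
    """Gene x well Ct matrix with replicate structure and per-gene efficiency.

    ``ct`` has a two-level column MultiIndex (sample_id, replicate); missing
    wells are NaN. ``efficiency`` is the per-gene amplification factor E in
    (1, 2.2], 2.0 meaning perfect doubling per cycle.
    """

    ct: pd.DataFrame
    efficiency: pd.Series = None
    design: SampleDesign = None

    def __post_init__(self):
        ct = self.ct
        if not isinstance(ct.columns, pd.MultiIndex) or ct.columns.nlevels != 2:
            raise ValueError("ct columns must be a (sample_id, replicate) MultiIndex")
        if ct.columns.has_duplicates:
            dups = ct.columns[ct.columns.duplicated()].tolist()
            raise ValueError(f"duplicate (gene, well) assignments: wells {dups}")
        if ct.index.has_duplicates:
            raise ValueError("duplicate gene symbols in Ct matrix")
        vals = ct.to_numpy(dtype=float)
        bad = np.isfinite(vals) & ((vals <= 0) | (vals >= 50))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            g, (s, rep) = ct.index[i], ct.columns[j]
            raise ValueError(
                f"Ct outside (0, 50) at gene {g!r}, sample {s!r}, replicate {rep}"
            )
        if self.efficiency is None:
            object.__setattr__(
                self, "efficiency", pd.Series(2.0, index=ct.index, name="efficiency")
            )
        eff = self.efficiency.reindex(ct.index).fillna(2.0)
        if ((eff <= 1.0) | (eff > 2.2)).any():
            bad_genes = eff.index[(eff <= 1.0) | (eff > 2.2)].tolist()
            raise ValueError(f"efficiency must be in (1, 2.2]; bad genes: {bad_genes}")
        object.__setattr__(self, "efficiency", eff.rename("efficiency"))
        if self.design is not None:
            unknown = [
                s for s in ct.columns.get_level_values(0).unique()
                if s not in self.design.samples
            ]
            if unknown:
                raise ValueError(f"samples absent from design: {unknown}")

    @property
    def genes(self) -> list[str]:
        return list(self.ct.index)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.ct.columns.get_level_values(0)))

    @property
    def is_collapsed(self) -> bool:
        counts = self.ct.columns.get_level_values(0).value_counts()
        return bool((counts == 1).all())

    def sample_matrix(self) -> pd.DataFrame:
        """Gene x sample matrix; requires one well per sample (collapsed)."""
        if not self.is_collapsed:
            raise ValueError(
                "Ct table has multiple replicates per sample; "
                "collapse_replicates() first"
            )
        out = self.ct.copy()
        out.columns = out.columns.get_level_values(0)
        return out

    def subset_samples(self, samples: list[str]) -> "CtTable":
        cols = [c for c in self.ct.columns if c[0] in set(samples)]
        return CtTable(self.ct[cols], self.efficiency, self.design)


def _wells_from_wide(columns) -> pd.MultiIndex:
    """Parse wide Ct headers 'sampleID.rep' into (sample, replicate) tuples."""
    wells = []
    for col in columns:
        if "." in col:
            sample, rep = col.rsplit(".", 1)
            if rep.isdigit():
                wells.append((sample, int(rep)))
                continue
        wells.append((col, 1))
    return pd.MultiIndex.from_tuples(wells, names=["sample_id", "replicate"])


def _read_efficiency(path) -> pd.Series:
    df = _read_table(path)
    for col in ("gene", "efficiency"):
        if col not in df.columns:
            raise ValueError(f"efficiency file {path}: missing column {col!r}")
    eff = pd.to_numeric(df.set_index("gene")["efficiency"], errors="coerce")
    if eff.isna().any():
        raise ValueError(f"efficiency file {path}: non-numeric efficiency")
    return eff


def read_ct_table(matrix_path, design_path, efficiency_path=None) -> CtTable:
    """Read a Ct table (wide 'sampleID.rep' columns, or long format) + design.

    Genes missing from the efficiency file (or the whole file when absent)
    default to E = 2.0.
    """
    design = read_design(design_path)
    raw = _read_table(matrix_path)
    lower = {c.lower(): c for c in raw.columns}
    if {"gene", "sample", "replicate", "ct"} <= set(lower):
        long = raw.rename(columns={lower[k]: k for k in ("gene", "sample", "replicate", "ct")})
        long["replicate"] = pd.to_numeric(long["replicate"], errors="raise").astype(int)
        long["ct"] = pd.to_numeric(
            long["ct"].replace({"": np.nan, "NA": np.nan}), errors="raise"
        )
        dup = long.duplicated(subset=["gene", "sample", "replicate"])
        if dup.any():
            row = long[dup].iloc[0]
            raise ValueError(
                f"{matrix_path}: duplicate well (gene {row['gene']!r}, "
                f"sample {row['sample']!r}, replicate {row['replicate']})"
            )
        ct = long.pivot(index="gene", columns=["sample", "replicate"], values="ct")
        ct = ct.reindex(index=list(dict.fromkeys(long["gene"])))
        ct.columns = ct.columns.set_names(["sample_id", "replicate"])
        ct.index.name = "gene"
    else:
        mat = _numeric_matrix(raw, matrix_path)
        ct = mat.copy()
        ct.columns = _wells_from_wide(mat.columns)
    eff = _read_efficiency(efficiency_path) if efficiency_path else None
    return CtTable(ct, eff, design)


def write_ct_table(ct: CtTable, matrix_path, design_path=None, efficiency_path=None) -> None:
    out = ct.ct.copy()
    out.columns = [f"{s}.{r}" for s, r in out.columns]
    out.to_csv(matrix_path, sep="\t", lineterminator="\n")
    if design_path is not None and ct.design is not None:
        write_design(ct.design, design_path)
    if efficiency_path is not None:
        ct.efficiency.rename_axis("gene").to_csv(
            efficiency_path, sep="\t", lineterminator="\n"
        )


def collapse_replicates(ct: CtTable, method: str = "mean") -> CtTable:
    """Collapse technical replicates to one Ct per (gene, sample).

    Missingness propagates: a (gene, sample) cell with no finite replicate
    stays missing. Idempotent — collapsing a collapsed table is the identity.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"method must be 'mean' or 'median', got {method!r}")
    grouped = ct.ct.T.groupby(level=0, sort=False)
    collapsed = (grouped.mean() if method == "mean" else grouped.median()).T
    collapsed = collapsed[list(dict.fromkeys(ct.ct.columns.get_level_values(0)))]
    collapsed.columns = pd.MultiIndex.from_tuples(
        [(s, 1) for s in collapsed.columns], names=["sample_id", "replicate"]
    )
    return CtTable(collapsed, ct.efficiency, ct.design)
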