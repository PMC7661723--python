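"""Count-matrix and sample-design I/O.

Counts are gene-by-sample integer matrices read from headered TSV/CSV with
the gene identifier in the first column. The design table maps each sample
to a biological group, an optional induction time point (hours), and a
replicate number. Groups play one of four roles in the analysis — target
state (e.g. ESC), start state (naive fibroblast), control state
(GFP-transduced fibroblast), and response (OSKM-transduced) — the mapping
from role to group label lives in the run configuration, not here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("sample", "group", "time_h", "replicate")


@dataclass
class SampleDesign:
    """Per-sample metadata: group label, time point (h, NaN if none), replicate."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(DESIGN_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"design missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["sample"] = t["sample"].astype(str)
        t["group"] = t["group"].astype(str)
        t["time_h"] = pd.to_numeric(t["time_h"], errors="coerce")
        t["replicate"] = pd.to_numeric(t["replicate"], errors="coerce").astype("Int64")
        dup = t["sample"][t["sample"].duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate sample ids in design: {sorted(dup)}")
        self.table = t.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def samples_of(self, group: str, time_h: float | None = None) -> list[str]:
        """Sample ids of ``group``, optionally restricted to one time point."""
        mask = self.table["group"] == group
        if time_h is not None:
            mask &= self.table["time_h"] == time_h
        return list(self.table.loc[mask, "sample"])

    def time_points(self, group: str) -> list[float]:
        t = self.table.loc[self.table["group"] == group, "time_h"].dropna().unique()
        return sorted(float(x) for x in t)


@dataclass
class CountMatrix:
    """Integer gene-by-sample count matrix with its sample design attached."""

    counts: pd.DataFrame = field(repr=False)
    design: SampleDesign = None

    def __post_init__(self) -> None:
        c = self.counts
        dup_g = c.index[c.index.duplicated()].unique()
        if len(dup_g):
            raise ValueError(f"duplicate gene ids: {sorted(map(str, dup_g))}")
        dup_s = c.columns[c.columns.duplicated()].unique()
        if len(dup_s):
            raise ValueError(f"duplicate sample ids: {sorted(map(str, dup_s))}")
        arr = c.to_numpy()
        bad = ~(np.isfinite(arr) & (arr >= 0) & (arr == np.round(arr)))
        if bad.any():
            gi, si = np.argwhere(bad)[0]
            raise ValueError(
                f"counts must be non-negative integers; offending entry at "
                f"gene {c.index[gi]!r}, sample {c.columns[si]!r}: {arr[gi, si]!r}"
            )
        self.counts = c.astype(np.int64)
        if self.design is not None:
            missing = [s for s in c.columns if s not in set(self.design.samples)]
            if missing:
                raise ValueError(f"samples missing from design: {missing}")
            extra = [s for s in self.design.samples if s not in set(c.columns)]
            if extra:
                raise ValueError(f"design samples absent from matrix: {extra}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        present = [g for g in genes if g in self.counts.index]
        return CountMatrix(self.counts.loc[present], self.design)


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized counts; ``values = counts / size_factors``."""

    values: pd.DataFrame = field(repr=False)
    size_factors: pd.Series = field(repr=False)
    design: SampleDesign = None

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            bad = self.size_factors[self.size_factors <= 0]
            raise ValueError(f"size factors must be positive: {dict(bad)}")
        if list(self.values.columns) != list(self.size_factors.index):
            raise ValueError("size factor index does not match sample columns")

    def group_means(self, group: str, time_h: float | None = None) -> pd.Series:
        samples = self.design.samples_of(group, time_h)
        return self.values[samples].mean(axis=1)

    def group_values(self, group: str, time_h: float | None = None) -> pd.DataFrame:
        return self.values[self.design.samples_of(group, time_h)]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_design(path: str | Path) -> SampleDesign:
    t = _read_table(path)
    if "time_h" not in t.columns:
        t["time_h"] = np.nan
    if "replicate" not in t.columns:
        t["replicate"] = range(1, len(t) + 1)
    return SampleDesign(t)


def read_counts(matrix_path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a count matrix and its design; validate them jointly.

    The full genome matrix is accepted — genes outside the TF catalog are
    retained here because normalization runs on the whole matrix before any
    TF subsetting.
    """
    design = read_design(design_path)
    raw = _read_table(matrix_path)
    gene_col = raw.columns[0]
    counts = raw.set_index(gene_col)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    # case-insensitive fallback for sample-name matching
    if set(counts.columns) != set(design.samples):
        folded = {s.lower(): s for s in design.samples}
        if set(c.lower() for c in counts.columns) == set(folded):
            warnings.warn("sample names matched case-insensitively", stacklevel=2)
            counts.columns = [folded[c.lower()] for c in counts.columns]
    return CountMatrix(counts, design)


def write_counts(
    cm: CountMatrix, matrix_path: str | Path, design_path: str | Path
) -> None:
    out = cm.counts.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(matrix_path, sep="\t", index=False)
    cm.design.table.to_csv(design_path, sep="\t", index=False)


def log2_matrix(norm: NormalizedMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Element-wise ``log2(normalized + pseudocount)`` for heat-map export.

    Visualization only — statistical testing always runs on the count scale.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    return np.log2(norm.values + pseudocount)
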