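"""Fold-change screening of label-free protein abundance tables.

Compares protein abundances between low- and high-density sample groups:
per-sample normalisation, high/low group-mean fold changes, and a
symmetric fold-change threshold screen (strictly greater than ``t``-fold
up, strictly less than ``1/t``-fold down).  No per-protein significance
testing is performed — with three samples per group the screen is a
fold-magnitude filter, not an inference procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ProteinTable", "DiffResult", "normalise", "fold_changes",
           "differential_list"]

_GROUPS = ("low", "high")


@dataclass(frozen=True)
class ProteinTable:
    """Protein x sample abundance matrix with a low/high group label per
    sample.  Missing values are NaN; abundances are nonnegative."""

    abundance: pd.DataFrame  # index: protein IDs, columns: sample IDs
    group: pd.Series  # sample ID -> "low" | "high"

    def __post_init__(self) -> None:
        ab = self.abundance
        if ab.index.duplicated().any():
            raise ValueError("duplicate protein IDs")
        if not set(self.group.unique()).issubset(_GROUPS):
            raise ValueError("group labels must be 'low' or 'high'")
        if set(self.group.index) != set(ab.columns):
            raise ValueError("group labels must cover exactly the sample columns")
        for g in _GROUPS:
            if (self.group == g).sum() < 1:
                raise ValueError(f"need at least one sample in group {g!r}")
        if (ab.to_numpy(dtype=float, na_value=np.nan) < 0).any():
            raise ValueError("abundances must be nonnegative")

    @property
    def proteins(self) -> list[str]:
        return list(self.abundance.index)

    def samples(self, group: str) -> pd.DataFrame:
        return self.abundance.loc[:, self.group[self.group == group].index]


@dataclass(frozen=True)
class DiffResult:
    """Per-protein fold changes (high/low) with threshold screen lists."""

    fold_change: pd.Series  # protein -> fold (NaN where undefined)
    direction: pd.Series  # protein -> "up" | "down" | "unchanged"
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)  # undefined folds

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("a protein cannot be both up and down")


def normalise(table: ProteinTable, method: str = "total_sum") -> ProteinTable:
    """Per-sample abundance normalisation.

    ``total_sum`` rescales every sample to the mean column sum;
    ``median_ratio`` rescales by the median of per-protein ratios to the
    first sample (a reference-sample size factor); ``none`` returns the
    table unchanged.
    """
    ab = table.abundance
    if method == "none":
        return table
    col_sums = ab.sum(axis=0, skipna=True)
    if (col_sums == 0).any():
        raise ValueError("cannot normalise a sample whose abundances are all zero")
    if method == "total_sum":
        scaled = ab.div(col_sums, axis=1) * col_sums.mean()
    elif method == "median_ratio":
        ref = ab.iloc[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = ab.div(ref.where(ref > 0), axis=0)
        factors = ratios.median(axis=0, skipna=True)
        if factors.isna().any() or (factors <= 0).any():
            raise ValueError("median-ratio factors undefined for some sample")
        scaled = ab.div(factors, axis=1)
    else:
        raise ValueError(f"unknown normalisation method {method!r}")
    return ProteinTable(abundance=scaled, group=table.group)


def fold_changes(table: ProteinTable) -> DiffResult:
    """High/low ratio of group-mean abundances per protein.

    Proteins with an all-missing group or a zero low-group mean get a NaN
    fold and are listed in ``flagged`` rather than silently dropped.
    """
    low = table.samples("low").mean(axis=1, skipna=True)
    high = table.samples("high").mean(axis=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = high / low
    fold = fold.where((low > 0) & high.notna() & low.notna())
    flagged = list(fold.index[fold.isna()])
    direction = pd.Series("unchanged", index=fold.index)
    return DiffResult(fold_change=fold, direction=direction, flagged=flagged)


def differential_list(result: DiffResult, threshold: float = 2.0) -> DiffResult:
    """Screen fold changes at a symmetric threshold (strict inequalities).

    Up-regulated: fold > threshold; down-regulated: fold < 1/threshold;
    a fold exactly at the boundary stays unchanged.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    fold = result.fold_change
    up = fold > threshold
    down = fold < 1.0 / threshold
    direction = pd.Series(
        np.where(up, "up", np.where(down, "down", "unchanged")), index=fold.index
    )
    return DiffResult(
        fold_change=fold,
        direction=direction,
        up=list(fold.index[up.fillna(False)]),
        down=list(fold.index[down.fillna(False)]),
        flagged=list(result.flagged),
    )


def read_protein_table(abundance_tsv, groups_tsv) -> ProteinTable:
    """Load a protein x sample TSV plus a (sample, group) TSV."""
    ab = pd.read_csv(abundance_tsv, sep="\t", index_col=0)
    grp = pd.read_csv(groups_tsv, sep="\t", index_col=0).iloc[:, 0]
    return ProteinTable(abundance=ab, group=grp)


def write_diff_result(result: DiffResult, path) -> None:
    """Write (protein, fold_change, direction) as TSV."""
    out = pd.DataFrame(
        {"fold_change": result.fold_change, "direction": result.direction}
    )
    out.to_csv(path, sep="\t", index_label="protein")
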