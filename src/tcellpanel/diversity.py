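"""TCR repertoire clonality statistics for clone-count tables.

Works on TRB clone tables (AIRR rearrangement TSVs or minimal clone_id/count
tables): Shannon-Weiner diversity H = -sum p_i ln p_i, its normalized form
H / ln R (Pielou evenness, in [0, 1]), and the fraction of reads captured by
the N most abundant clones. No rarefaction or depth correction is applied;
comparisons across populations sequenced at very different depths should be
interpreted with that caveat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CloneTable",
    "read_clone_table",
    "shannon_index",
    "normalized_shannon",
    "top_n_fraction",
]


@dataclass
class CloneTable:
    """Clone identities with read counts for one T cell population."""

    clone_ids: list[str]
    counts: np.ndarray
    population_label: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.clone_ids) != len(self.counts):
            raise ValueError("clone_ids and counts must have equal length")
        if len(self.counts) == 0:
            raise ValueError("clone table is empty")
        if (self.counts < 1).any():
            bad = int(np.argmax(self.counts < 1))
            raise ValueError(
                f"clone {self.clone_ids[bad]!r} has non-positive count {int(self.counts[bad])}"
            )
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise ValueError("clone_ids must be unique")

    @property
    def n_clones(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def read_clone_table(path, population_label: str | None = None) -> CloneTable:
    """Read a clone table from an AIRR rearrangement TSV or a two-column file.

    AIRR convention: clone identity is (v_call, junction_aa) when both columns
    are present (else the one available), count is ``duplicate_count``. A
    minimal table uses ``clone_id`` and ``count``. Rows with identical clone
    identity are summed; zero or negative counts are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"clone table {path} is empty")
    cols = set(df.columns)
    if {"clone_id", "count"} <= cols:
        id_series = df["clone_id"].astype(str)
        counts = df["count"]
    else:
        id_cols = [c for c in ("v_call", "junction_aa") if c in cols]
        if not id_cols:
            raise ValueError("clone table needs clone_id or v_call/junction_aa columns")
        if "duplicate_count" not in cols:
            raise ValueError("AIRR clone table missing the duplicate_count column")
        id_series = df[id_cols].astype(str).agg("|".join, axis=1)
        counts = df["duplicate_count"]
    counts = pd.to_numeric(counts, errors="raise")
    if (counts < 1).any():
        row = int(counts[counts < 1].index[0])
        raise ValueError(f"clone table row {row}: count must be a positive integer")
    agg = counts.groupby(id_series, sort=True).sum()
    return CloneTable(
        clone_ids=list(agg.index), counts=agg.to_numpy(), population_label=population_label
    )


def shannon_index(table: CloneTable) -> float:
    """Shannon-Weiner diversity H = -sum p_i ln p_i (natural log)."""
    p = table.frequencies
    return float(-(p * np.log(p)).sum())


def normalized_shannon(table: CloneTable) -> float:
    """Normalized Shannon-Weiner index (evenness): H / ln R, with R the
    number of unique clones; 0 by convention for a single-clone table."""
    if table.n_clones == 1:
        return 0.0
    return shannon_index(table) / math.log(table.n_clones)


def top_n_fraction(table: CloneTable, n: int = 10) -> float:
    """Fraction of all reads carried by the n most abundant clones.

    Ties at the inclusion boundary are broken by clone_id lexicographic order
    for determinism; returns 1.0 when the table has at most n clones.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if table.n_clones <= n:
        return 1.0
    order = sorted(range(table.n_clones), key=lambda i: (-table.counts[i], table.clone_ids[i]))
    top = sum(int(table.counts[i]) for i in order[:n])
    return top / table.total


def diversity_table(tables: list[CloneTable], top_n: int = 10) -> pd.DataFrame:
    """Per-population summary: clone richness R, Shannon H, evenness, top-N fraction."""
    rows = []
    for t in tables:
        rows.append(
            {
                "population_label": t.population_label,
                "R": t.n_clones,
                "H": shannon_index(t),
                "normalized_H": normalized_shannon(t),
                f"top{top_n}_fraction": top_n_fraction(t, top_n),
            }
        )
    return pd.DataFrame(rows)
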