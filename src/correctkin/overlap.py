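"""Typed-marker bookkeeping: per-sample typed counts, minimum-marker
filtering and the pairwise overlapping-marker-fraction matrix.

The overlap fraction f_ij divides the count of markers typed in BOTH members
of a pair by the full panel size M (all loaded markers after any autosome
restriction) — not by the post-MAF-pruned marker count used inside the
kinship estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset


class EmptyCohortError(ValueError):
    """All samples were removed by a filter."""


@dataclass
class OverlapMatrix:
    """Pairwise overlapping-marker counts and fractions.

    ``counts[i, j]`` is the number of markers typed in both samples i and j;
    the diagonal holds per-sample typed counts. ``fraction = counts / M``.
    """

    sample_ids: list
    panel_size: int
    counts: np.ndarray  # (n, n) int64

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.sample_ids)
        if self.counts.shape != (n, n):
            raise ValueError("overlap counts shape does not match sample count")

    @property
    def fraction(self) -> np.ndarray:
        return self.counts / float(self.panel_size)

    @property
    def typed_counts(self) -> np.ndarray:
        return np.diag(self.counts).copy()

    def pair(self, i: int, j: int):
        """(n_ij, f_ij) for a sample index pair."""
        n = int(self.counts[i, j])
        return n, n / float(self.panel_size)


def overlap_matrix(ds: GenotypeDataset) -> OverlapMatrix:
    """Pairwise overlapping-marker counts; MISSING is the only untyped state."""
    if ds.n_samples == 0 or ds.n_markers == 0:
        raise ValueError("overlap_matrix requires a non-empty dataset")
    typed = ds.typed_mask().astype(np.float64)
    counts = np.rint(typed @ typed.T).astype(np.int64)
    return OverlapMatrix(ds.sample_ids, ds.n_markers, counts)


def filter_min_markers(ds: GenotypeDataset, min_typed: int = 100_000):
    """Remove samples typed at fewer than ``min_typed`` markers (inclusive
    boundary: a sample typed at exactly ``min_typed`` is retained).

    Returns ``(filtered_dataset, report)`` where the report lists every
    sample with its typed count and whether it was removed.
    """
    if min_typed < 0:
        raise ValueError("min_typed must be >= 0")
    typed = ds.typed_counts()
    removed = typed < min_typed
    report = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "typed_count": typed,
            "removed": removed,
        }
    )
    if removed.all():
        raise EmptyCohortError(
            f"all {ds.n_samples} samples fall below min_typed={min_typed}"
        )
    kept = np.flatnonzero(~removed)
    return ds.subset_samples(kept), report


def write_overlap_tsv(om: OverlapMatrix, fraction_path: str, counts_path: str | None = None):
    """Square tab-separated matrices with a sample-id header row/column."""
    frac = pd.DataFrame(om.fraction, index=om.sample_ids, columns=om.sample_ids)
    frac.to_csv(fraction_path, sep="\t", float_format="%.10g")
    if counts_path is not None:
        cnt = pd.DataFrame(om.counts, index=om.sample_ids, columns=om.sample_ids)
        cnt.to_csv(counts_path, sep="\t")


def read_overlap_tsv(counts_path: str, panel_size: int) -> OverlapMatrix:
    cnt = pd.read_csv(counts_path, sep="\t", index_col=0)
    return OverlapMatrix(list(cnt.columns), panel_size, cnt.to_numpy())
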