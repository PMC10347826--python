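"""Rank abundance curves, the abundant/rare cutoff and the rarity-gradient windows.

A rank abundance curve (RAC) orders the OTUs of one size fraction by total
read count; the rarity gradient is explored through overlapping windows of
5000 ranks stepping by 2500, with an end-anchored final window of the last
2500 ranks, mirroring the published worked example (N = 71,380 -> last two
windows of 3880 and 2500 OTUs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import EmptyInputError, InsufficientDataError, ParameterError
from .io_formats import OtuTable
from .phylo import _pearson


@dataclass
class RankAbundanceCurve:
    """OTUs of one size fraction ranked by total reads (rank 1 = most abundant)."""

    fraction: str
    otu_ids: list[str]
    total_reads: np.ndarray

    def __post_init__(self) -> None:
        self.total_reads = np.asarray(self.total_reads, dtype=np.int64)
        if len(self.otu_ids) != len(self.total_reads):
            raise EmptyInputError("otu_ids and total_reads length mismatch")
        if np.any(np.diff(self.total_reads) > 0):
            raise EmptyInputError("total_reads must be non-increasing in rank")

    @property
    def n(self) -> int:
        return len(self.otu_ids)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, self.n + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": self.ranks,
            "otu_id": self.otu_ids,
            "total_reads": self.total_reads,
            "fraction": self.fraction,
        })


@dataclass
class RacWindow:
    """A contiguous rank interval of the RAC (1-based, inclusive)."""

    label: str
    start_rank: int
    end_rank: int
    otu_ids: list[str] = field(default_factory=list)

    @property
    def n_otus(self) -> int:
        return self.end_rank - self.start_rank + 1

    def with_otus(self, rac: RankAbundanceCurve) -> "RacWindow":
        return RacWindow(self.label, self.start_rank, self.end_rank,
                         rac.otu_ids[self.start_rank - 1: self.end_rank])


def filter_low_evidence_otus(
    table: OtuTable, min_samples: int = 2, min_reads: int = 3,
    require_both: bool = True,
) -> tuple[OtuTable, pd.DataFrame]:
    """Drop putative-artefact OTUs with too few occurrences AND too few reads.

    An OTU is removed iff (occurrence < min_samples) and (total reads <
    min_reads); set ``require_both=False`` for the OR variant used by some
    singleton-removal protocols.  Returns the filtered table and a report of
    removed OTUs.
    """
    occ = table.occurrence()
    tot = table.total_reads()
    low_occ = occ < min_samples
    low_reads = tot < min_reads
    removed = (low_occ & low_reads) if require_both else (low_occ | low_reads)
    keep_ids = [o for o, r in zip(table.otu_ids, removed) if not r]
    report = pd.DataFrame({
        "otu_id": np.asarray(table.otu_ids)[removed],
        "occurrence": occ[removed],
        "total_reads": tot[removed],
    })
    return table.subset_otus(keep_ids), report


def build_rac(table: OtuTable, fraction: str) -> RankAbundanceCurve:
    """RAC from total reads over all samples of ``fraction``.

    Zero-read OTUs are dropped before ranking; ties broken by lexicographic
    OTU id so the ranking (and every downstream window) is deterministic.
    """
    sub = table.samples_of_fraction(fraction)
    if sub.n_samples == 0:
        raise EmptyInputError(f"no samples in fraction {fraction!r}")
    totals = sub.total_reads()
    keep = totals > 0
    ids = np.asarray(sub.otu_ids, dtype=object)[keep]
    tot = totals[keep]
    order = np.lexsort((ids, -tot))  # descending reads, ascending id on ties
    return RankAbundanceCurve(fraction, list(ids[order]), tot[order])


def make_rac_windows(n_otus: int, window: int = 5000, step: int = 2500) -> list[RacWindow]:
    """Sliding rank windows over a RAC of ``n_otus`` OTUs.

    Grid windows [s+1, min(s+window, N)] for s = 0, step, 2*step, ... are
    kept while the (possibly truncated) window holds more than ``step``
    ranks; a final end-anchored window of the last ``step`` ranks is then
    appended.  Truncated grid windows are labeled by their nominal mid-grid
    rank (start + step), full windows and the final window by their end rank.
    """
    if n_otus <= 0:
        raise EmptyInputError("n_otus must be positive")
    if window < step:
        raise ParameterError(f"window ({window}) must be >= step ({step})")
    if n_otus <= step:
        return [RacWindow(str(n_otus), 1, n_otus)]
    out: list[RacWindow] = []
    s = 0
    while n_otus - s > step:
        end = min(s + window, n_otus)
        label = str(end) if end == s + window else str(s + step)
        out.append(RacWindow(label, s + 1, end))
        s += step
    out.append(RacWindow(str(n_otus), n_otus - step + 1, n_otus))
    return out


def windows_frame(windows: list[RacWindow]) -> pd.DataFrame:
    return pd.DataFrame({
        "label": [w.label for w in windows],
        "start_rank": [w.start_rank for w in windows],
        "end_rank": [w.end_rank for w in windows],
        "n_otus": [w.n_otus for w in windows],
    })


def _bray_curtis_condensed(rel: np.ndarray) -> np.ndarray:
    return pdist(rel, metric="braycurtis")


def find_abundant_cutoff(
    table: OtuTable,
    rac: RankAbundanceCurve,
    correlation_threshold: float = 0.95,
    n_grid: int = 50,
) -> tuple[int, pd.DataFrame]:
    """Multivariate abundant/rare cutoff on the RAC.

    For candidate head sizes k on a geometric grid, the sample-by-sample
    Bray-Curtis matrix of the top-k OTUs is correlated (Pearson over pairs,
    i.e. a Mantel statistic) with the full-table Bray-Curtis matrix;
    ``k_abundant`` is the smallest grid k whose correlation reaches the
    threshold.  Samples emptied by truncation are dropped pairwise.
    """
    sub = table.samples_of_fraction(rac.fraction)
    sub = sub.subset_otus(rac.otu_ids)
    if sub.n_samples < 3:
        raise InsufficientDataError("need >= 3 samples for the multivariate cutoff")
    n = rac.n
    grid = np.unique(np.rint(np.geomspace(1, n, n_grid)).astype(int))
    full_rel = sub.relative_abundance()
    nonempty_full = sub.sample_sums() > 0
    rows = []
    k_abundant = None
    for k in grid:
        head = sub.counts[:, :k]
        keep = (head.sum(axis=1) > 0) & nonempty_full
        if keep.sum() < 3:
            rows.append({"k": int(k), "n_samples": int(keep.sum()),
                         "correlation": np.nan})
            continue
        sums = head[keep].sum(axis=1, keepdims=True).astype(float)
        rel_k = head[keep] / sums
        d_k = _bray_curtis_condensed(rel_k)
        d_full = _bray_curtis_condensed(full_rel[keep])
        if np.array_equal(d_k, d_full):
            r = 1.0
        elif d_k.std() > 0 and d_full.std() > 0:
            r = _pearson(d_k, d_full)
        else:
            r = np.nan
        rows.append({"k": int(k), "n_samples": int(keep.sum()), "correlation": r})
        if k_abundant is None and np.isfinite(r) and r >= correlation_threshold:
            k_abundant = int(k)
    diagnostics = pd.DataFrame(rows)
    if k_abundant is None:
        if diagnostics["correlation"].dropna().empty:
            raise InsufficientDataError("no candidate k retained >= 3 samples")
        k_abundant = int(n)
    return k_abundant, diagnostics


def subset_by_window(table: OtuTable, window: RacWindow) -> tuple[OtuTable, int]:
    """Restrict the table to a window's OTUs, dropping emptied samples.

    Returns (subset table, retained sample count); the retained count is
    what gets annotated per window in the process summaries.
    """
    if not window.otu_ids:
        raise EmptyInputError(f"window {window.label} carries no OTU ids")
    sub = table.subset_otus([o for o in window.otu_ids if o in set(table.otu_ids)])
    if sub.n_otus == 0:
        raise EmptyInputError(f"window {window.label} shares no OTUs with the table")
    keep = sub.sample_sums() > 0
    sub = sub.subset_samples([s for s, ok in zip(sub.sample_ids, keep) if ok])
    return sub, sub.n_samples
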