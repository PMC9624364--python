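"""Adaptor trimming, read-to-precursor assignment and class profiles.

Assignment re-implements an ungapped, sense-strand, best-hit policy with at
most two mismatches (the classic ``bowtie -v 2 --best`` behaviour) as a
native vectorized scanner: references here are a few hundred short
precursors, so an exhaustive window scan is fast and dependency-free.
Among hits with the minimal mismatch count, ties are broken by a fixed
class priority, then smallest start, then lexicographic precursor id, so
assignment is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MIN_INSERT = 15

#: Default multimapper tie-break order; classes absent from the list rank
#: after it, alphabetically.
DEFAULT_CLASS_PRIORITY = (
    "miRNA", "tRNA", "rRNA", "snoRNA", "snRNA", "mtRNA", "ra-ncRNA",
)

SIZE_RANGE = np.arange(15, 37)  # insert-length histogram support, nt


@dataclass(frozen=True)
class TrimResult:
    insert: str
    trimmed: bool  # leading adaptor found and removed?


def trim_adaptor(
    sequence: str,
    adaptor: str,
    max_mismatches: int = 1,
    recurrence_prefix: int = 5,
    search_from: int = DEFAULT_MIN_INSERT,
) -> TrimResult:
    """Strip the leading adaptor and any trailing adaptor-derived padding.

    If the read's leading ``len(adaptor)`` nt match the adaptor with at most
    one mismatch the remainder is returned; otherwise the read is returned
    unchanged with ``trimmed=False``.  Padding is removed at the first
    recurrence of the adaptor prefix (first ``recurrence_prefix`` nt) at or
    beyond ``search_from`` — inserts shorter than that are discarded
    downstream anyway, and restricting the search keeps chance prefix
    occurrences inside genuine inserts from truncating them.
    """
    k = len(adaptor)
    if len(sequence) < k:
        raise ValueError(f"read shorter ({len(sequence)} nt) than adaptor ({k} nt)")
    lead_mm = sum(a != b for a, b in zip(sequence[:k], adaptor))
    if lead_mm > max_mismatches:
        return TrimResult(sequence, trimmed=False)
    insert = sequence[k:]
    pos = insert.find(adaptor[:recurrence_prefix], search_from)
    if pos != -1:
        insert = insert[:pos]
    return TrimResult(insert, trimmed=True)


@dataclass(frozen=True)
class ReadAssignment:
    """A read's best placement on a precursor (0-based half-open)."""

    read_id: str
    precursor_id: str
    ncrna_class: str
    start: int
    end: int
    mismatches: int

    @property
    def insert_length(self) -> int:
        return self.end - self.start


def class_priority_rank(classes: Iterable[str],
                        priority: tuple[str, ...] = DEFAULT_CLASS_PRIORITY
                        ) -> dict[str, int]:
    """Rank map implementing priority order then alphabetical for the rest."""
    listed = {c: i for i, c in enumerate(priority)}
    rest = sorted(c for c in set(classes) if c not in listed)
    rank = dict(listed)
    for j, c in enumerate(rest):
        rank[c] = len(priority) + j
    return rank


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class PrecursorIndex:
    """Vectorized ungapped scanner over a precursor reference.

    Windows of each query length are materialized lazily (one uint8 matrix
    per length, cached) so that a query costs a single vectorized mismatch
    count over every admissible placement in the reference.
    """

    def __init__(
        self,
        sequences: dict[str, str],
        annotation: pd.DataFrame,
        max_mismatches: int = DEFAULT_MAX_MISMATCHES,
        class_priority: tuple[str, ...] = DEFAULT_CLASS_PRIORITY,
    ) -> None:
        if not sequences:
            raise ValueError("empty precursor reference")
        missing = [p for p in sequences if p not in annotation.index]
        if missing:
            raise ValueError(f"precursors missing from annotation: {missing[:5]}")
        self.max_mismatches = max_mismatches
        self.precursor_ids = sorted(sequences)
        self.sequences = {p: sequences[p] for p in self.precursor_ids}
        self.classes = {p: annotation.loc[p, "class"] for p in self.precursor_ids}
        self.lengths = {p: len(sequences[p]) for p in self.precursor_ids}
        self._rank = class_priority_rank(set(self.classes.values()), class_priority)
        self._encoded = [_encode(self.sequences[p]) for p in self.precursor_ids]
        self._window_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._assign_cache: dict[str, Optional[tuple[int, int, int]]] = {}

    def _windows(self, L: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(windows[n,L], precursor_index[n], start[n]) for query length L."""
        if L not in self._window_cache:
            mats, pidx, starts = [], [], []
            for i, enc in enumerate(self._encoded):
                n = len(enc) - L + 1
                if n <= 0:
                    continue
                mats.append(np.lib.stride_tricks.sliding_window_view(enc, L))
                pidx.append(np.full(n, i, dtype=np.int32))
                starts.append(np.arange(n, dtype=np.int32))
            if mats:
                self._window_cache[L] = (
                    np.ascontiguousarray(np.concatenate(mats)),
                    np.concatenate(pidx),
                    np.concatenate(starts),
                )
            else:
                self._window_cache[L] = (
                    np.empty((0, L), dtype=np.uint8),
                    np.empty(0, dtype=np.int32),
                    np.empty(0, dtype=np.int32),
                )
        return self._window_cache[L]

    def _best_hit(self, insert: str) -> Optional[tuple[int, int, int]]:
        """(precursor_index, start, mismatches) of the best placement."""
        if insert in self._assign_cache:
            return self._assign_cache[insert]
        L = len(insert)
        windows, pidx, starts = self._windows(L)
        best: Optional[tuple[int, int, int]] = None
        if len(windows):
            mism = np.count_nonzero(windows != _encode(insert), axis=1)
            m = int(mism.min())
            if m <= self.max_mismatches:
                cand = np.flatnonzero(mism == m)
                # minimal mismatches, then class priority, start, precursor id
                best_i = min(
                    cand,
                    key=lambda i: (
                        self._rank[self.classes[self.precursor_ids[pidx[i]]]],
                        starts[i],
                        self.precursor_ids[pidx[i]],
                    ),
                )
                best = (int(pidx[best_i]), int(starts[best_i]), m)
        self._assign_cache[insert] = best
        return best

    def assign(self, read_id: str, insert: str) -> Optional[ReadAssignment]:
        """Best-hit assignment of one insert, or None if no placement has
        <= max_mismatches mismatches anywhere in the reference."""
        if len(insert) < 1:
            return None
        hit = self._best_hit(insert)
        if hit is None:
            return None
        pi, start, mm = hit
        pid = self.precursor_ids[pi]
        return ReadAssignment(
            read_id=read_id,
            precursor_id=pid,
            ncrna_class=self.classes[pid],
            start=start,
            end=start + len(insert),
            mismatches=mm,
        )


def assign_read(
    read_id: str,
    insert: str,
    index: PrecursorIndex,
    min_insert: int = DEFAULT_MIN_INSERT,
) -> Optional[ReadAssignment]:
    """Assign one trimmed insert; inserts shorter than ``min_insert`` are
    rejected (returned as None) per the length floor."""
    if len(insert) < min_insert:
        return None
    return index.assign(read_id, insert)


def assignments_to_frame(
    assignments: Iterable[tuple[ReadAssignment, str]]
) -> pd.DataFrame:
    """Tabulate (assignment, insert sequence) pairs."""
    rows = [
        {
            "read_id": a.read_id,
            "precursor_id": a.precursor_id,
            "class": a.ncrna_class,
            "start": a.start,
            "end": a.end,
            "mismatches": a.mismatches,
            "insert_length": a.insert_length,
            "insert": seq,
        }
        for a, seq in assignments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "precursor_id", "class", "start", "end",
            "mismatches", "insert_length", "insert",
        ],
    )


# ---------------------------------------------------------------------------
# Per-pool class profiles


@dataclass
class ClassProfile:
    """Composition, GC and size profile of one pool's assigned reads."""

    pool_id: str
    fractions: pd.Series          # class -> fraction of 1 over assigned reads
    gc: pd.Series                 # class -> pooled GC fraction of bases
    size_counts: pd.DataFrame     # class x insert length (15-36) counts
    size_summary: pd.DataFrame    # class x (min, q1, median, q3, max)
    n_reads: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.fractions.index:
            s = self.size_summary.loc[cls]
            rows.append(
                {
                    "pool": self.pool_id,
                    "class": cls,
                    "fraction": self.fractions[cls],
                    "mean_gc": self.gc[cls],
                    "size_min": s["min"],
                    "size_q1": s["q1"],
                    "size_median": s["median"],
                    "size_q3": s["q3"],
                    "size_max": s["max"],
                    "n_reads": int(self.size_counts.loc[cls].sum()),
                }
            )
        return pd.DataFrame(rows)


def class_profile(assignments: pd.DataFrame, pool_id: str = "pool") -> ClassProfile:
    """Per-class read fractions (of 1), pooled GC and size distributions.

    Fractions are class counts over total assigned reads and always sum to
    one; GC pools G+C bases over all of a class's inserts.
    """
    if assignments.empty:
        raise ValueError("class_profile requires at least one assigned read")
    fractions = (
        assignments["class"].value_counts(normalize=True).sort_index()
    )
    gc = assignments.groupby("class")["insert"].apply(
        lambda s: sum(seq.count("G") + seq.count("C") for seq in s)
        / sum(len(seq) for seq in s)
    ).sort_index()
    size_counts = pd.DataFrame(
        0, index=fractions.index, columns=SIZE_RANGE, dtype=int
    )
    for cls, sub in assignments.groupby("class"):
        counts = sub["insert_length"].value_counts()
        for length, n in counts.items():
            if length in size_counts.columns:
                size_counts.loc[cls, length] = int(n)
    summary_rows = {}
    for cls, sub in assignments.groupby("class"):
        v = sub["insert_length"].to_numpy()
        summary_rows[cls] = {
            "min": float(v.min()),
            "q1": float(np.percentile(v, 25)),
            "median": float(np.percentile(v, 50)),
            "q3": float(np.percentile(v, 75)),
            "max": float(v.max()),
        }
    size_summary = pd.DataFrame(summary_rows).T.sort_index()
    return ClassProfile(
        pool_id=pool_id,
        fractions=fractions,
        gc=gc,
        size_counts=size_counts,
        size_summary=size_summary,
        n_reads=len(assignments),
    )


def mapping_rate(n_raw: int, n_assigned: int) -> float:
    """Percentage of raw reads that were assigned to a precursor."""
    if n_raw == 0:
        raise ValueError("mapping rate undefined for zero raw reads")
    if not 0 <= n_assigned <= n_raw:
        raise ValueError("assigned count must be between 0 and the raw count")
    return 100.0 * n_assigned / n_raw
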