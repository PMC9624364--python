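"""End-to-end orchestration: raw reads -> assignments -> profiles/fragments."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from . import read_assign
from .read_assign import (
    PrecursorIndex,
    ReadAssignment,
    assignments_to_frame,
    trim_adaptor,
    mapping_rate,
)


@dataclass
class ClassifyStats:
    """Bookkeeping of a classification run."""

    n_raw: int = 0
    n_untrimmed: int = 0
    n_too_short: int = 0
    n_assigned: int = 0
    n_unassigned: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def mapping_rate_pct(self) -> float:
        return mapping_rate(self.n_raw, self.n_assigned)


def classify_reads(
    reads: Iterable[tuple[str, str, Optional[str]]],
    index: PrecursorIndex,
    adaptor: Optional[str],
    min_insert: int = read_assign.DEFAULT_MIN_INSERT,
) -> tuple[pd.DataFrame, ClassifyStats]:
    """Trim (when an adaptor is given) and assign a stream of reads.

    Untrimmed reads (no leading adaptor match) are still submitted to
    assignment as-is; inserts shorter than ``min_insert`` are discarded and
    counted.  Returns the assignment table plus run statistics.
    """
    stats = ClassifyStats()
    collected: list[tuple[ReadAssignment, str]] = []
    for read_id, seq, _qual in reads:
        stats.n_raw += 1
        if adaptor:
            result = trim_adaptor(seq, adaptor, search_from=min_insert)
            if not result.trimmed:
                stats.n_untrimmed += 1
            insert = result.insert
        else:
            insert = seq
        if len(insert) < min_insert:
            stats.n_too_short += 1
            continue
        assignment = index.assign(read_id, insert)
        if assignment is None:
            stats.n_unassigned += 1
        else:
            stats.n_assigned += 1
            collected.append((assignment, insert))
    return assignments_to_frame(collected), stats
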