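"""ncRF identification and quantification.

A read is a non-coding RNA fragment (ncRF) when its insert is at most 27 nt;
reads of 29 nt or longer count as precursor-length (full ncRNA) reads; the
28-nt gap left by those two definitions belongs to neither set and is
tallied separately.  Only precursors with at least five mapped reads enter
the analysis.  On top of that partition this module computes 5'/3' end
categories, 10-bin positional distributions, fragment-to-precursor
enrichment ratios (per precursor and per family, e.g. tRNA isoacceptor),
and library-size prorating against a designated reference pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

MAX_FRAGMENT_LENGTH = 27   # nt; longest read still called an ncRF
MIN_PRECURSOR_READ = 29    # nt; shortest read counted as full-length ncRNA
DEFAULT_END_TOLERANCE = 2  # nt window for 5'/3' end calls
DEFAULT_MIN_READS = 5      # per-precursor inclusion filter

#: Field names for the fragment pool of each ncRNA class.
FRAGMENT_LABELS = {"tRNA": "tRF", "rRNA": "rRF", "snoRNA": "snoRF",
                   "snRNA": "snRF", "miRNA": "miRF"}


def fragment_label(ncrna_class: str) -> str:
    return FRAGMENT_LABELS.get(ncrna_class, f"{ncrna_class}-RF")


@dataclass
class FragmentSet:
    """Filtered ncRF calls of one pool.

    per_precursor   one row per qualifying precursor (>= min_reads mapped):
                    end-category counts, fragment/precursor-read totals
    fragment_reads  the individual fragment reads with their end category
    """

    pool_id: str
    per_precursor: pd.DataFrame
    fragment_reads: pd.DataFrame
    end_tolerance: int
    min_reads: int
    n_gap28_total: int = 0

    @property
    def class_totals(self) -> pd.Series:
        """Total fragment reads per ncRNA class (tRF, rRF, ...)."""
        if self.per_precursor.empty:
            return pd.Series(dtype=int)
        return self.per_precursor.groupby("class")["n_fragment"].sum().sort_index()

    def size_distribution(self) -> pd.DataFrame:
        """Class x fragment-length (15-27 nt) count table."""
        lengths = np.arange(15, MAX_FRAGMENT_LENGTH + 1)
        classes = sorted(self.fragment_reads["class"].unique()) if not self.fragment_reads.empty else []
        out = pd.DataFrame(0, index=classes, columns=lengths, dtype=int)
        for cls, sub in self.fragment_reads.groupby("class"):
            for length, n in sub["insert_length"].value_counts().items():
                if length in out.columns:
                    out.loc[cls, length] = int(n)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = self.per_precursor.reset_index()
        df.insert(0, "pool", self.pool_id)
        return df


def _end_category(start: int, end: int, precursor_length: int, tol: int) -> str:
    # 5' wins when a short precursor makes both criteria hold
    if start <= tol:
        return "5prime"
    if precursor_length - end <= tol:
        return "3prime"
    return "internal"


def call_fragments(
    assignments: pd.DataFrame,
    precursor_lengths: Mapping[str, int] | pd.Series,
    annotation: pd.DataFrame,
    end_tolerance: int = DEFAULT_END_TOLERANCE,
    min_reads: int = DEFAULT_MIN_READS,
    pool_id: str = "pool",
) -> FragmentSet:
    """Identify ncRFs and build per-precursor end/count tables.

    A read is an ncRF iff its insert is <= 27 nt; >= 29 nt reads are
    precursor reads; 28-nt reads fall in neither bucket.  End category is
    5' when the start lies within ``end_tolerance`` of the precursor's 5'
    terminus, 3' when the end lies within it of the 3' terminus (5' wins if
    both), internal otherwise.  Precursors with fewer than ``min_reads``
    total mapped reads are dropped entirely.
    """
    if end_tolerance < 0:
        raise ValueError("end_tolerance must be non-negative")
    if isinstance(precursor_lengths, pd.Series):
        precursor_lengths = precursor_lengths.to_dict()

    work = assignments.copy()
    totals = work.groupby("precursor_id").size()
    keep = totals[totals >= min_reads].index
    work = work[work["precursor_id"].isin(keep)]

    n_gap28_total = int((work["insert_length"] == MIN_PRECURSOR_READ - 1).sum())

    is_frag = work["insert_length"] <= MAX_FRAGMENT_LENGTH
    frags = work[is_frag].copy()
    if not frags.empty:
        frags["end_category"] = [
            _end_category(s, e, precursor_lengths[p], end_tolerance)
            for s, e, p in zip(frags["start"], frags["end"], frags["precursor_id"])
        ]
    else:
        frags["end_category"] = pd.Series(dtype=str)

    rows = []
    for pid, sub in work.groupby("precursor_id"):
        fsub = frags[frags["precursor_id"] == pid]
        cats = fsub["end_category"].value_counts()
        rows.append(
            {
                "precursor_id": pid,
                "class": annotation.loc[pid, "class"],
                "family": annotation.loc[pid, "family"]
                if "family" in annotation.columns else pid,
                "n_5prime": int(cats.get("5prime", 0)),
                "n_3prime": int(cats.get("3prime", 0)),
                "n_internal": int(cats.get("internal", 0)),
                "n_fragment": int(len(fsub)),
                "n_precursor": int((sub["insert_length"] >= MIN_PRECURSOR_READ).sum()),
                "n_gap28": int((sub["insert_length"] == MIN_PRECURSOR_READ - 1).sum()),
                "n_total": int(len(sub)),
            }
        )
    per_precursor = pd.DataFrame(
        rows,
        columns=[
            "precursor_id", "class", "family", "n_5prime", "n_3prime",
            "n_internal", "n_fragment", "n_precursor", "n_gap28", "n_total",
        ],
    ).set_index("precursor_id")
    return FragmentSet(
        pool_id=pool_id,
        per_precursor=per_precursor,
        fragment_reads=frags,
        end_tolerance=end_tolerance,
        min_reads=min_reads,
        n_gap28_total=n_gap28_total,
    )


# ---------------------------------------------------------------------------
# Positional bin distributions


@dataclass
class BinDistribution:
    """10-bin positional fragment distribution for one ncRNA class."""

    ncrna_class: str
    proportions: np.ndarray  # length 10, sums to 1 unless empty
    n_fragments: int

    @property
    def empty(self) -> bool:
        return self.n_fragments == 0


def _bin_of(start: int, length: int, n_bins: int) -> int:
    # bin b covers [floor(b*L/n), floor((b+1)*L/n))
    edges = (np.arange(1, n_bins + 1) * length) // n_bins
    return int(np.searchsorted(edges, start, side="right"))


def bin_distribution(
    fragment_reads: pd.DataFrame,
    precursor_lengths: Mapping[str, int] | pd.Series,
    n_bins: int = 10,
    method: str = "start",
) -> dict[str, BinDistribution]:
    """Positional distribution of fragment reads over 10 equal precursor bins.

    Each precursor is split into ``n_bins`` equal-length bins; with
    ``method="start"`` (default) a read is counted once, in the bin holding
    its start position; ``method="coverage"`` instead spreads each read over
    the bins it covers in proportion to the overlap.  Counts are normalized
    within each ncRNA class; a class with zero fragments gets an all-zero
    distribution flagged empty rather than an error.
    """
    if method not in ("start", "coverage"):
        raise ValueError(f"unknown binning method {method!r}")
    if isinstance(precursor_lengths, pd.Series):
        precursor_lengths = precursor_lengths.to_dict()
    out: dict[str, BinDistribution] = {}
    for cls, sub in fragment_reads.groupby("class"):
        counts = np.zeros(n_bins)
        for start, end, pid in zip(sub["start"], sub["end"], sub["precursor_id"]):
            L = precursor_lengths[pid]
            if method == "start":
                counts[_bin_of(start, L, n_bins)] += 1.0
            else:
                edges = np.concatenate([[0], (np.arange(1, n_bins + 1) * L) // n_bins])
                overlap = np.maximum(
                    0, np.minimum(end, edges[1:]) - np.maximum(start, edges[:-1])
                )
                counts += overlap / (end - start)
        total = counts.sum()
        out[cls] = BinDistribution(
            ncrna_class=cls,
            proportions=counts / total if total > 0 else counts,
            n_fragments=int(len(sub)),
        )
    return out


def bins_to_frame(distributions: dict[str, BinDistribution],
                  pool_id: str = "pool") -> pd.DataFrame:
    rows = []
    for cls in sorted(distributions):
        d = distributions[cls]
        row = {"pool": pool_id, "class": cls}
        row.update({f"bin_{i + 1}": d.proportions[i] for i in range(len(d.proportions))})
        row["n_fragments"] = d.n_fragments
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Enrichment: fragments per full-length precursor read


def enrichment(fragset: FragmentSet, by: str = "precursor") -> pd.DataFrame:
    """Fragment-to-precursor enrichment ratios.

    ratio = n_fragment (reads <= 27 nt) / n_precursor (reads >= 29 nt); a
    ratio of 1 means one fragment per full-length read.  With
    ``by="family"`` numerators and denominators are summed over precursors
    sharing a family key (e.g. all GlyGCC tRNA copies) before dividing.
    Rows with a zero denominator are retained with ``ratio_defined=False``
    and a missing ratio.
    """
    if by not in ("precursor", "family"):
        raise ValueError(f"unknown aggregation {by!r}")
    tab = fragset.per_precursor
    if tab.empty:
        return pd.DataFrame(
            columns=["pool", "precursor_id", "class", "family",
                     "n_fragment", "n_precursor", "ratio", "ratio_defined"]
        )
    if by == "precursor":
        out = tab.reset_index()[
            ["precursor_id", "class", "family", "n_fragment", "n_precursor"]
        ].copy()
    else:
        grouped = (
            tab.groupby(["family", "class"])[["n_fragment", "n_precursor"]]
            .sum()
            .reset_index()
        )
        grouped["precursor_id"] = grouped["family"]
        out = grouped[["precursor_id", "class", "family", "n_fragment", "n_precursor"]]
    out = out.copy()
    out["ratio_defined"] = out["n_precursor"] > 0
    out["ratio"] = np.where(
        out["ratio_defined"], out["n_fragment"] / out["n_precursor"].replace(0, np.nan), np.nan
    )
    out.insert(0, "pool", fragset.pool_id)
    return out.sort_values(["class", "precursor_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cross-pool prorating


def prorate(
    tables: dict[str, pd.Series | pd.DataFrame],
    pool_totals: Mapping[str, int],
    reference_pool: str,
    numeric_columns: Optional[list[str]] = None,
) -> dict[str, pd.Series | pd.DataFrame]:
    """Rescale per-pool count tables to the reference pool's library size.

    Each pool's counts are multiplied by
    ``pool_totals[reference_pool] / pool_totals[pool]`` so that all pools
    are expressed at the reference's sequencing depth; the reference pool
    itself is unchanged (factor exactly 1).  ``pool_totals`` is normally
    total assigned reads; pass fragment totals to prorate by ncRF counts
    instead.
    """
    if reference_pool not in pool_totals:
        raise ValueError(f"reference pool {reference_pool!r} missing from totals")
    ref_total = pool_totals[reference_pool]
    out: dict[str, pd.Series | pd.DataFrame] = {}
    for pool, table in tables.items():
        if pool not in pool_totals:
            raise ValueError(f"pool {pool!r} missing from totals")
        if pool_totals[pool] == 0:
            raise ValueError(f"pool {pool!r} has zero assigned reads")
        factor = 1.0 if pool == reference_pool else ref_total / pool_totals[pool]
        scaled = table.copy()
        if isinstance(scaled, pd.DataFrame):
            cols = numeric_columns or scaled.select_dtypes("number").columns
            scaled[cols] = scaled[cols] * factor
        else:
            scaled = scaled * factor
        out[pool] = scaled
    return out


# ---------------------------------------------------------------------------
# 5' vs 3' end-bias summaries


@dataclass
class EndFractionSummary:
    per_class: pd.DataFrame       # class x (frac_5prime, frac_3prime, n_end)
    per_precursor: pd.DataFrame   # precursor x the same
    excluded_classes: list[str] = field(default_factory=list)


def end_fraction_summary(fragset: FragmentSet) -> EndFractionSummary:
    """Fraction of 5' vs 3' fragments per class and per precursor.

    Internal fragments are excluded from the denominator; classes (or
    precursors) whose fragments are all internal are excluded and flagged.
    """
    tab = fragset.per_precursor
    excluded: list[str] = []

    def _summarize(grouped: pd.DataFrame) -> pd.DataFrame:
        n_end = grouped["n_5prime"] + grouped["n_3prime"]
        ok = n_end > 0
        out = pd.DataFrame(
            {
                "frac_5prime": grouped.loc[ok, "n_5prime"] / n_end[ok],
                "frac_3prime": grouped.loc[ok, "n_3prime"] / n_end[ok],
                "n_end": n_end[ok].astype(int),
            }
        )
        return out

    if tab.empty:
        empty = pd.DataFrame(columns=["frac_5prime", "frac_3prime", "n_end"])
        return EndFractionSummary(empty, empty.copy(), [])

    by_class = tab.groupby("class")[["n_5prime", "n_3prime"]].sum()
    per_class = _summarize(by_class)
    excluded = sorted(set(by_class.index) - set(per_class.index))
    per_precursor = _summarize(tab[["n_5prime", "n_3prime"]])
    return EndFractionSummary(per_class, per_precursor, excluded)
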