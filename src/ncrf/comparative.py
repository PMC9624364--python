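"""Cross-group comparison, target filtering, FDR correction and Venn sets.

Target-prediction (miRDB-style) and pathway-annotation (DAVID-chart-style)
results are consumed as plain tables — the web services themselves are
never queried.  The Benjamini-Hochberg step-up correction is implemented
directly; the strict cutoffs (prediction score > 80, adjusted p < 0.05)
match the selection rules the tables were designed for.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .smallrna_io import logger

FLAG_UP = "up"
FLAG_DOWN = "down"
FLAG_SAME = "="
FLAG_APPEARED = "appeared"
FLAG_DISAPPEARED = "disappeared"
FLAG_MISSING = "missing"

DEFAULT_MIN_REL_CHANGE = 0.1
DEFAULT_SCORE_CUTOFF = 80.0
DEFAULT_ALPHA = 0.05


def change_flag(ct: Optional[float], sr: Optional[float],
                min_rel_change: float = DEFAULT_MIN_REL_CHANGE) -> str:
    """Qualitative change flag for one control-vs-exposed cell.

    "appeared"/"disappeared" require a true zero on one side; otherwise the
    flag is up/down when the relative change |sr-ct|/ct reaches
    ``min_rel_change``, "=" below it, "missing" when either value is absent.
    """
    if ct is None or sr is None or pd.isna(ct) or pd.isna(sr):
        return FLAG_MISSING
    if ct == 0 and sr > 0:
        return FLAG_APPEARED
    if sr == 0 and ct > 0:
        return FLAG_DISAPPEARED
    if ct == 0 and sr == 0:
        return FLAG_SAME
    rel = (sr - ct) / ct
    if rel >= min_rel_change:
        return FLAG_UP
    if rel <= -min_rel_change:
        return FLAG_DOWN
    return FLAG_SAME


def compare_groups(
    ct_values: Mapping[str, float] | pd.Series,
    sr_values: Mapping[str, float] | pd.Series,
    region: str,
    sex: str,
    metric: str,
    min_rel_change: float = DEFAULT_MIN_REL_CHANGE,
) -> pd.DataFrame:
    """Summary-table rows comparing control (Ct) and exposed (SR) values.

    ``ct_values``/``sr_values`` map items (a class, precursor or family) to
    the metric's value in that group; items present on only one side are
    emitted with a "missing" flag.  Values are carried verbatim into the
    table alongside the flag and the threshold used.
    """
    ct = pd.Series(ct_values, dtype=float)
    sr = pd.Series(sr_values, dtype=float)
    items = sorted(set(ct.index) | set(sr.index))
    rows = []
    for item in items:
        c = ct.get(item)
        s = sr.get(item)
        rows.append(
            {
                "region": region,
                "sex": sex,
                "metric": metric,
                "item": item,
                "ct_value": c,
                "sr_value": s,
                "flag": change_flag(c, s, min_rel_change),
                "threshold": min_rel_change,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Target-prediction filtering


def filter_targets(
    predictions: pd.DataFrame,
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> set[str]:
    """Unique predicted target genes with score strictly above the cutoff.

    Expects columns ``gene_symbol`` and ``score`` (``fragment_id`` optional).
    Rows with scores outside [0, 100] are rejected with a warning; gene
    symbols are deduplicated case-insensitively (reported upper-cased).
    """
    if predictions.empty:
        return set()
    scores = predictions["score"].astype(float)
    bad = (scores < 0) | (scores > 100) | scores.isna()
    if bad.any():
        logger.warning("rejecting %d prediction rows with scores outside [0, 100]",
                       int(bad.sum()))
    kept = predictions[~bad & (scores > score_cutoff)]
    return {g.upper() for g in kept["gene_symbol"].astype(str)}


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up correction


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone), in the
    input order: adj_i = min_{k: p_(k) >= p_i} m * p_(k) / k, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def filter_pathways(
    records: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Pathway terms significant after BH correction (adjusted p strictly
    below ``alpha``).

    Expects a ``term`` column and either an ``adjusted_p`` column or a raw
    ``p_value`` column from which adjusted values are computed.  Returns the
    retained rows with the ``adjusted_p`` column filled in.
    """
    if records.empty:
        out = records.copy()
        if "adjusted_p" not in out.columns:
            out["adjusted_p"] = pd.Series(dtype=float)
        return out
    out = records.copy()
    if "adjusted_p" not in out.columns or out["adjusted_p"].isna().any():
        out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    if ((out["adjusted_p"] < out.get("p_value", out["adjusted_p"])) - 1e-15).any() and \
       "p_value" in out.columns and (out["adjusted_p"] + 1e-12 < out["p_value"]).any():
        raise ValueError("adjusted p-values below raw p-values")
    return out[out["adjusted_p"] < alpha].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Venn overlaps


@dataclass
class VennResult:
    """Disjoint-region decomposition of 2-4 named sets."""

    set_names: tuple[str, ...]
    regions: dict[frozenset[str], set[str]]  # member names per exclusive region

    @property
    def counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def count(self, *names: str) -> int:
        """Size of the exclusive region belonging to exactly these sets."""
        return len(self.regions.get(frozenset(names), set()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(1, len(self.set_names) + 1):
            for combo in combinations(self.set_names, r):
                key = frozenset(combo)
                members = sorted(self.regions.get(key, set()))
                rows.append(
                    {
                        "region": "&".join(combo),
                        "n_sets": r,
                        "count": len(members),
                        "members": ",".join(members),
                    }
                )
        return pd.DataFrame(rows)


def venn(sets: Mapping[str, Iterable]) -> VennResult:
    """Exclusive-region counts and memberships for 2-4 named sets.

    Every element of the union lands in exactly one region (the combination
    of sets containing it), so the disjoint region counts sum to the size
    of the union.
    """
    names = tuple(sets.keys())
    if not 2 <= len(names) <= 4:
        raise ValueError("venn supports between 2 and 4 sets")
    materialized = {name: set(sets[name]) for name in names}
    regions: dict[frozenset[str], set[str]] = {}
    universe = set().union(*materialized.values())
    for element in universe:
        key = frozenset(n for n in names if element in materialized[n])
        regions.setdefault(key, set()).add(element)
    return VennResult(set_names=names, regions=regions)
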