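"""Synthetic precursor references and fragment-processed read libraries.

The generator emulates the structure of a rodent-brain small-RNA study:
36-nt single-end raw reads consisting of a 7-nt adaptor followed by a 29-nt
insert; inserts are either a full-length 29-nt precursor prefix or a
processed fragment of 15-27 nt cut from a precursor terminus (5'-anchored
or 3'-terminal, controlled per class by an end bias).  Library composition
is dominated by miRNA (~80%) with a ~11% repeat-associated component, and
every read carries a ground-truth record so the whole pipeline can be
verified by parameter recovery.

Reads shorter than 36 nt after adaptor+insert are 3'-padded with the
adaptor sequence repeated from its start; the trimmer removes padding by
spotting that adaptor-prefix recurrence, while ground truth records the
true insert length directly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .smallrna_io import CLASS_VOCABULARY, write_fasta, write_annotation, write_fastq, logger

BASES = np.array(list("ACGT"))
READ_LENGTH = 36
INSERT_FULL_LENGTH = 29  # full-length ncRNA insert, nt
FRAGMENT_MIN, FRAGMENT_MAX = 15, 27
DEFAULT_ADAPTOR = "TGGAATT"  # 7 nt

#: tRNA isoacceptor family names used to label synthetic tRNA precursors.
TRNA_FAMILIES = ("GlyGCC", "GluCTC", "LysCTT", "HisGTG", "ValCAC")
SNORNA_FAMILIES = ("snoRA3", "snoRD22", "snoRA52", "snoRD113")


@dataclass
class ClassModel:
    """Per-class generative settings.

    weight            proportion of reads drawn from this class
    precursor_length  (min, max) precursor length range, nt
    frag_len_mode     mode of the fragment length distribution, nt
    frag_len_sd       spread of the (discretized normal) length distribution
    full_length_prob  probability a read is a full 29-nt precursor prefix
    end_bias          probability a fragment is 5'-anchored (else 3'-terminal)
    gc                expected GC fraction of precursor sequences
    """

    weight: float
    precursor_length: tuple[int, int]
    frag_len_mode: int = 22
    frag_len_sd: float = 1.5
    full_length_prob: float = 0.4
    end_bias: float = 0.7
    gc: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.precursor_length
        if hi < lo or lo < INSERT_FULL_LENGTH:
            raise ValueError(
                f"precursor length range {self.precursor_length} invalid: "
                f"must be non-empty and >= {INSERT_FULL_LENGTH} nt"
            )
        for name, p in (
            ("weight", self.weight),
            ("full_length_prob", self.full_length_prob),
            ("end_bias", self.end_bias),
            ("gc", self.gc),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not FRAGMENT_MIN <= self.frag_len_mode <= FRAGMENT_MAX:
            raise ValueError(
                f"frag_len_mode {self.frag_len_mode} outside "
                f"[{FRAGMENT_MIN}, {FRAGMENT_MAX}]"
            )

    def fragment_length_pmf(self, mode_shift: int = 0) -> np.ndarray:
        """Discretized normal over [15, 27], truncated and renormalized."""
        mode = int(np.clip(self.frag_len_mode + mode_shift, FRAGMENT_MIN, FRAGMENT_MAX))
        lengths = np.arange(FRAGMENT_MIN, FRAGMENT_MAX + 1)
        w = np.exp(-((lengths - mode) ** 2) / (2.0 * self.frag_len_sd**2))
        return w / w.sum()


@dataclass
class GroupEffect:
    """Multiplicative/additive shifts applied for one (region, sex, treatment).

    class_weight_mult  per-class factor on the class weights (renormalized)
    end_bias_mult      per-class factor on the 5' cleavage probability
                       (clipped to [0, 1])
    length_shift       per-class integer shift of the fragment length mode
    gc_shift           per-class additive shift of precursor GC (reference
                       generation only)
    """

    class_weight_mult: dict[str, float] = field(default_factory=dict)
    end_bias_mult: dict[str, float] = field(default_factory=dict)
    length_shift: dict[str, int] = field(default_factory=dict)
    gc_shift: dict[str, float] = field(default_factory=dict)


def default_class_models() -> dict[str, ClassModel]:
    """Baseline composition: ~80% miRNA, ~11% repeat-associated, the rest
    split over tRNA/rRNA/snoRNA/snRNA, with length modes near 22 nt."""
    return {
        "miRNA": ClassModel(0.80, (60, 90), 22, 1.2, 0.50, 0.80, 0.48),
        "ra-ncRNA": ClassModel(0.11, (80, 200), 22, 2.0, 0.40, 0.50, 0.42),
        "tRNA": ClassModel(0.04, (70, 95), 21, 1.5, 0.10, 1.00, 0.55),
        "rRNA": ClassModel(0.02, (100, 160), 21, 2.0, 0.40, 0.60, 0.52),
        "snoRNA": ClassModel(0.015, (60, 150), 22, 2.0, 0.30, 0.50, 0.45),
        "snRNA": ClassModel(0.015, (90, 150), 22, 1.5, 0.30, 1.00, 0.47),
    }


@dataclass
class SimulationParams:
    seed: int = 0
    n_reads: int = 50_000
    classes: dict[str, ClassModel] = field(default_factory=default_class_models)
    adaptor: str = DEFAULT_ADAPTOR
    n_precursors_per_class: int = 20
    internal_fragment_rate: float = 0.0
    group_effects: dict[tuple[str, str, str], GroupEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.adaptor) != 7:
            raise ValueError("adaptor must be exactly 7 nt")
        if not self.classes:
            raise ValueError("class set must be non-empty")
        if self.n_precursors_per_class < 1:
            raise ValueError("n_precursors_per_class must be >= 1")
        total = sum(m.weight for m in self.classes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class weights sum to {total}, expected 1")
        if not 0.0 <= self.internal_fragment_rate <= 1.0:
            raise ValueError("internal_fragment_rate outside [0, 1]")
        for label in self.classes:
            if label not in CLASS_VOCABULARY:
                raise ValueError(f"unknown ncRNA class {label!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        classes = {
            label: ClassModel(
                weight=cfg["weight"],
                precursor_length=tuple(cfg["precursor_length"]),
                frag_len_mode=cfg.get("frag_len_mode", 22),
                frag_len_sd=cfg.get("frag_len_sd", 1.5),
                full_length_prob=cfg.get("full_length_prob", 0.4),
                end_bias=cfg.get("end_bias", 0.7),
                gc=cfg.get("gc", 0.5),
            )
            for label, cfg in raw.get("classes", {}).items()
        } or default_class_models()
        effects = {}
        for key, eff in raw.get("group_effects", {}).items():
            group = tuple(key.split("_"))  # "FC_M_SR" style keys
            effects[group] = GroupEffect(
                class_weight_mult=eff.get("class_weight_mult", {}),
                end_bias_mult=eff.get("end_bias_mult", {}),
                length_shift=eff.get("length_shift", {}),
                gc_shift=eff.get("gc_shift", {}),
            )
        return cls(
            seed=raw.get("seed", 0),
            n_reads=raw.get("n_reads", 50_000),
            classes=classes,
            adaptor=raw.get("adaptor", DEFAULT_ADAPTOR),
            n_precursors_per_class=raw.get("n_precursors_per_class", 20),
            internal_fragment_rate=raw.get("internal_fragment_rate", 0.0),
            group_effects=effects,
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "seed": self.seed,
            "n_reads": self.n_reads,
            "adaptor": self.adaptor,
            "n_precursors_per_class": self.n_precursors_per_class,
            "internal_fragment_rate": self.internal_fragment_rate,
            "classes": {
                label: {
                    "weight": m.weight,
                    "precursor_length": list(m.precursor_length),
                    "frag_len_mode": m.frag_len_mode,
                    "frag_len_sd": m.frag_len_sd,
                    "full_length_prob": m.full_length_prob,
                    "end_bias": m.end_bias,
                    "gc": m.gc,
                }
                for label, m in self.classes.items()
            },
            "group_effects": {
                "_".join(group): asdict(eff)
                for group, eff in self.group_effects.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Reference generation


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    # per-base: G/C with prob gc split evenly, A/T otherwise
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=probs)])


def _family_for(cls: str, index: int) -> str:
    if cls == "tRNA":
        return TRNA_FAMILIES[index % len(TRNA_FAMILIES)]
    if cls == "snoRNA":
        return SNORNA_FAMILIES[index % len(SNORNA_FAMILIES)]
    return f"{cls}-{index + 1:04d}"


def make_reference(
    params: SimulationParams,
    group: Optional[tuple[str, str, str]] = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate the precursor reference and its annotation table.

    Returns ``(sequences, annotation)`` where sequences map unique
    precursor ids to random sequences hitting each class's GC target in
    expectation, and the annotation frame (indexed by precursor_id) carries
    ``class``, ``family`` and ``length`` columns.  Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    effect = params.group_effects.get(group) if group else None
    sequences: dict[str, str] = {}
    rows = []
    for cls in sorted(params.classes):
        model = params.classes[cls]
        lo, hi = model.precursor_length
        gc = model.gc + (effect.gc_shift.get(cls, 0.0) if effect else 0.0)
        gc = float(np.clip(gc, 0.0, 1.0))
        for i in range(params.n_precursors_per_class):
            pid = f"{cls}-{i + 1:04d}"
            length = int(rng.integers(lo, hi + 1))
            sequences[pid] = _random_sequence(rng, length, gc)
            rows.append(
                {"precursor_id": pid, "class": cls,
                 "family": _family_for(cls, i), "length": length}
            )
    annot = pd.DataFrame(rows).set_index("precursor_id")
    return sequences, annot


# ---------------------------------------------------------------------------
# Read simulation


def _group_seed(seed: int, group: Optional[tuple[str, str, str]]) -> list[int]:
    if group is None:
        return [seed]
    return [seed, zlib.crc32("_".join(group).encode()) & 0x7FFFFFFF]


def simulate_sample(
    params: SimulationParams,
    sequences: dict[str, str],
    annot: pd.DataFrame,
    group: Optional[tuple[str, str, str]] = None,
    sample_id: str = "sample",
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate one library: raw 36-nt reads plus their ground truth.

    Each raw read is ``adaptor + insert`` padded to exactly 36 nt with the
    adaptor repeated from its start.  The insert is either the precursor's
    first 29 nt (with the class's full-length probability) or a terminal
    fragment of 15-27 nt whose end is chosen by the class's 5' bias.  The
    read's class is drawn from the group-adjusted class weights.

    Returns ``(reads, ground_truth)`` where reads are
    ``(read_id, sequence, quality)`` triples and ground truth has one row
    per read: origin precursor, class, end category (5prime/3prime/full/
    internal) and true insert length.
    """
    rng = np.random.default_rng(_group_seed(params.seed, group))
    effect = params.group_effects.get(group) if group is not None else None
    if group is not None and group not in params.group_effects and params.group_effects:
        logger.warning("group %s not in group_effects; using baseline parameters", group)

    classes = sorted(params.classes)
    weights = np.array([params.classes[c].weight for c in classes], dtype=float)
    if effect:
        weights = weights * np.array(
            [effect.class_weight_mult.get(c, 1.0) for c in classes]
        )
        weights = weights / weights.sum()

    by_class = {
        cls: annot.index[annot["class"] == cls].to_numpy() for cls in classes
    }
    for cls in classes:
        if len(by_class[cls]) == 0:
            raise ValueError(f"reference has no precursors of class {cls!r}")

    pad_source = params.adaptor * 6  # long enough for any padding need
    quality = "I" * READ_LENGTH

    class_draws = rng.choice(len(classes), size=params.n_reads, p=weights)
    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    for i in range(params.n_reads):
        cls = classes[class_draws[i]]
        model = params.classes[cls]
        pid = by_class[cls][rng.integers(len(by_class[cls]))]
        seq = sequences[pid]
        end_bias = model.end_bias * (effect.end_bias_mult.get(cls, 1.0) if effect else 1.0)
        end_bias = float(np.clip(end_bias, 0.0, 1.0))

        if rng.random() < model.full_length_prob:
            insert = seq[:INSERT_FULL_LENGTH]
            origin_end = "full"
            length = INSERT_FULL_LENGTH
        else:
            pmf = model.fragment_length_pmf(
                effect.length_shift.get(cls, 0) if effect else 0
            )
            length = int(FRAGMENT_MIN + rng.choice(len(pmf), p=pmf))
            if rng.random() < params.internal_fragment_rate:
                start = int(rng.integers(1, len(seq) - length))
                insert = seq[start : start + length]
                origin_end = "internal"
            elif rng.random() < end_bias:
                insert = seq[:length]
                origin_end = "5prime"
            else:
                insert = seq[len(seq) - length :]
                origin_end = "3prime"

        raw = params.adaptor + insert
        if len(raw) < READ_LENGTH:
            raw += pad_source[: READ_LENGTH - len(raw)]
        raw = raw[:READ_LENGTH]
        read_id = f"{sample_id}:{i}"
        reads.append((read_id, raw, quality))
        truth_rows.append(
            {
                "read_id": read_id,
                "precursor_id": pid,
                "class": cls,
                "origin_end": origin_end,
                "insert_length": length,
            }
        )

    truth = pd.DataFrame(truth_rows)
    return reads, truth


def realized_composition(truth: pd.DataFrame) -> pd.Series:
    """Realized class proportions of a simulated sample (ground truth)."""
    return truth["class"].value_counts(normalize=True).sort_index()


def realized_end_bias(truth: pd.DataFrame) -> pd.Series:
    """Realized per-class 5' fraction among terminal fragments."""
    frags = truth[truth["origin_end"].isin(["5prime", "3prime"])]
    return (
        frags.groupby("class")["origin_end"]
        .apply(lambda s: (s == "5prime").mean())
        .sort_index()
    )


def realized_enrichment(truth: pd.DataFrame) -> pd.DataFrame:
    """Realized per-precursor fragment/full-length emission counts."""
    g = truth.groupby("precursor_id")["origin_end"]
    out = pd.DataFrame(
        {
            "n_fragment_true": g.apply(lambda s: s.isin(["5prime", "3prime", "internal"]).sum()),
            "n_full_true": g.apply(lambda s: (s == "full").sum()),
        }
    )
    out["ratio_true"] = out["n_fragment_true"] / out["n_full_true"].replace(0, np.nan)
    return out


# ---------------------------------------------------------------------------
# Synthetic downstream-analysis tables (miRDB/DAVID-shaped fixtures)


def make_target_table(
    rng: np.random.Generator,
    n_fragments: int = 20,
    genes_per_fragment: int = 15,
    universe_size: int = 400,
) -> pd.DataFrame:
    """Fabricate a miRDB-style target-prediction table.

    Scores are uniform over [40, 100] so the >80 cutoff bites; gene symbols
    are drawn from a synthetic universe with replacement so duplicates occur.
    """
    rows = []
    for f in range(n_fragments):
        genes = rng.integers(0, universe_size, size=genes_per_fragment)
        scores = rng.uniform(40, 100, size=genes_per_fragment)
        for g, s in zip(genes, scores):
            rows.append(
                {"fragment_id": f"ncRF-{f + 1:03d}", "gene_symbol": f"Gene{g:04d}",
                 "score": float(s)}
            )
    return pd.DataFrame(rows)


def make_pathway_table(
    rng: np.random.Generator,
    n_terms: int = 40,
    frac_signal: float = 0.25,
    universe_size: int = 400,
) -> pd.DataFrame:
    """Fabricate a DAVID-chart-style pathway table with raw p-values.

    A ``frac_signal`` share of terms get small (Beta(1, 80)) p-values, the
    rest uniform, giving a spectrum where BH retains some but not all terms.
    """
    n_signal = int(round(n_terms * frac_signal))
    p = np.concatenate(
        [rng.beta(1, 80, size=n_signal), rng.uniform(size=n_terms - n_signal)]
    )
    rows = []
    for i in range(n_terms):
        genes = sorted({f"Gene{g:04d}" for g in rng.integers(0, universe_size, size=8)})
        rows.append(
            {"term": f"PATH:{i + 1:04d}", "genes": ",".join(genes),
             "p_value": float(p[i])}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Convenience: write a full simulated dataset to disk


def write_simulation(
    params: SimulationParams,
    out_dir: str | Path,
    groups: Optional[list[tuple[str, str, str]]] = None,
) -> dict[str, Path]:
    """Generate reference + one FASTQ/ground-truth pair per group.

    With ``groups=None`` a single baseline sample named "sample" is written.
    Returns the paths written, keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sequences, annot = make_reference(params)
    paths: dict[str, Path] = {
        "reference": out_dir / "reference.fa",
        "annotation": out_dir / "annotation.tsv",
    }
    write_fasta(sequences, paths["reference"])
    write_annotation(annot, paths["annotation"])
    for group in groups if groups is not None else [None]:
        name = "_".join(group) if group else "sample"
        reads, truth = simulate_sample(params, sequences, annot, group, sample_id=name)
        fq = out_dir / f"{name}.fastq"
        gt = out_dir / f"{name}.ground_truth.tsv"
        write_fastq(reads, fq)
        truth.to_csv(gt, sep="\t", index=False)
        paths[f"reads:{name}"] = fq
        paths[f"truth:{name}"] = gt
    return paths
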