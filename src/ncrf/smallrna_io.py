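"""Readers and writers for the formats the pipeline touches.

Sequence formats (FASTA/FASTQ, optionally gzipped) are handled through
Bio.SeqIO; tabular results through pandas.  All tables use tab separation,
deterministic column order and 6-decimal floats so that reruns are
byte-identical.

Coordinates in every table are 0-based half-open; lengths are in nt.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("ncrf")

#: Closed (but extensible) vocabulary of ncRNA classes.  Labels outside the
#: vocabulary are accepted under "other" with a warning.
CLASS_VOCABULARY: tuple[str, ...] = (
    "miRNA",
    "tRNA",
    "rRNA",
    "snoRNA",
    "snRNA",
    "ra-ncRNA",
    "mtRNA",
    "lincRNA",
    "antisense",
    "sense-intronic",
    "processed-transcript",
    "sRNA",
    "other",
)

REGIONS = ("FC", "HIP", "CER")
SEXES = ("M", "F")
TREATMENTS = ("Ct", "SR")

FLOAT_FORMAT = "%.6f"


class MalformedRecordError(ValueError):
    """A sequence record could not be parsed; names the file and ordinal."""


def _open_maybe_gzip(path: str | Path) -> io.TextIOBase:
    """Open text, transparently decompressing gzip (detected by magic bytes)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _sniff_format(handle: io.TextIOBase) -> str:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise MalformedRecordError(
        "cannot auto-detect format: file starts with neither '>' (FASTA) nor '@' (FASTQ)"
    )


def read_reads(path: str | Path) -> Iterator[tuple[str, str, Optional[str]]]:
    """Stream reads from a FASTA or FASTQ file (gzip ok, auto-detected).

    Yields ``(read_id, sequence, quality-or-None)``.  Sequences are
    uppercased and U is converted to T.  A malformed record raises
    :class:`MalformedRecordError` naming the file and record ordinal rather
    than being dropped silently.
    """
    path = Path(path)
    handle = _open_maybe_gzip(path)
    fmt = _sniff_format(handle)
    ordinal = 0
    try:
        for rec in SeqIO.parse(handle, fmt):
            ordinal += 1
            seq = str(rec.seq).upper().replace("U", "T")
            qual = None
            if fmt == "fastq":
                quals = rec.letter_annotations.get("phred_quality")
                qual = "".join(chr(q + 33) for q in quals) if quals is not None else None
            yield rec.id, seq, qual
    except ValueError as exc:
        raise MalformedRecordError(
            f"{path}: malformed record at ordinal {ordinal + 1}: {exc}"
        ) from exc
    finally:
        handle.close()


def write_fastq(
    reads: Iterable[tuple[str, str, Optional[str]]], path: str | Path
) -> int:
    """Write 4-line FASTQ (Phred+33).  Missing qualities become 'I' (Q40)."""
    n = 0
    with open(path, "wt") as fh:
        for read_id, seq, qual in reads:
            if qual is None:
                qual = "I" * len(seq)
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a precursor reference FASTA into an ordered ``{id: sequence}`` map."""
    out: dict[str, str] = {}
    handle = _open_maybe_gzip(path)
    with handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in out:
                raise MalformedRecordError(f"{path}: duplicate precursor id {rec.id!r}")
            out[rec.id] = str(rec.seq).upper().replace("U", "T")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Annotation table


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the precursor annotation TSV.

    Expected columns: ``precursor_id``, ``class``; an optional ``family``
    column carries aggregation keys (tRNA isoacceptors such as GlyGCC,
    snoRNA family ids).  Unknown class labels are mapped to "other" with a
    warning.  Returns a DataFrame indexed by ``precursor_id``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "precursor_id" not in df.columns or "class" not in df.columns:
        raise MalformedRecordError(
            f"{path}: annotation table needs 'precursor_id' and 'class' columns"
        )
    if df["precursor_id"].duplicated().any():
        dup = df.loc[df["precursor_id"].duplicated(), "precursor_id"].iloc[0]
        raise MalformedRecordError(f"{path}: duplicate precursor_id {dup!r}")
    unknown = ~df["class"].isin(CLASS_VOCABULARY)
    if unknown.any():
        labels = sorted(df.loc[unknown, "class"].unique())
        logger.warning("unknown ncRNA class labels %s mapped to 'other'", labels)
        df.loc[unknown, "class"] = "other"
    if "family" not in df.columns:
        df["family"] = df["precursor_id"]
    df["family"] = df["family"].fillna(df["precursor_id"])
    return df.set_index("precursor_id")


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample sheet and pooling


@dataclass
class Sample:
    """One sequencing library and its experimental coordinates."""

    sample_id: str
    files: list[str]
    region: str
    sex: str
    treatment: str
    pool_group: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region {self.region!r} not in {REGIONS}")
        if self.sex not in SEXES:
            raise ValueError(f"sex {self.sex!r} not in {SEXES}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment {self.treatment!r} not in {TREATMENTS}")


@dataclass
class SampleSheet:
    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        samples = [
            Sample(
                sample_id=row["sample_id"],
                files=row["files"].split(","),
                region=row["region"],
                sex=row["sex"],
                treatment=row["treatment"],
                pool_group=row["pool_group"],
            )
            for _, row in df.iterrows()
        ]
        return cls(samples)


def pool_samples(
    sheet: SampleSheet,
    read_source=read_reads,
) -> dict[str, list[tuple[str, str, Optional[str]]]]:
    """Concatenate biological repeats sharing a ``pool_group``.

    Repeats pooled together must agree on region, sex and treatment; mixing
    (e.g. Ct with SR) is an error.  The pooled read count is the sum of the
    member counts.  ``read_source`` maps a file path to a read stream and
    exists so tests can pool in-memory reads.
    """
    pools: dict[str, list[tuple[str, str, Optional[str]]]] = {}
    keys: dict[str, tuple[str, str, str]] = {}
    for sample in sheet.samples:
        key = (sample.region, sample.sex, sample.treatment)
        if sample.pool_group in keys and keys[sample.pool_group] != key:
            raise ValueError(
                f"pool_group {sample.pool_group!r} mixes conditions "
                f"{keys[sample.pool_group]} and {key}"
            )
        keys[sample.pool_group] = key
        bucket = pools.setdefault(sample.pool_group, [])
        for path in sample.files:
            bucket.extend(read_source(path))
    return pools


# ---------------------------------------------------------------------------
# Result tables

#: Canonical column order per result kind; files are written one per kind.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "class_profile": [
        "pool", "class", "fraction", "mean_gc",
        "size_min", "size_q1", "size_median", "size_q3", "size_max", "n_reads",
    ],
    "fragments": [
        "pool", "precursor_id", "class", "family",
        "n_5prime", "n_3prime", "n_internal", "n_fragment", "n_precursor", "n_gap28",
        "n_total",
    ],
    "bins": ["pool", "class"] + [f"bin_{i}" for i in range(1, 11)] + ["n_fragments"],
    "enrichment": [
        "pool", "precursor_id", "class", "family", "n_fragment", "n_precursor",
        "ratio", "ratio_defined",
    ],
    "comparison": [
        "region", "sex", "metric", "item", "ct_value", "sr_value", "flag",
        "threshold",
    ],
}


def write_tables(results: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write result DataFrames as TSVs with fixed column order and 6-dp floats.

    ``results`` maps a table kind (key of :data:`TABLE_SCHEMAS`) to a frame.
    An empty frame still produces a header-only file.  Reruns on identical
    inputs give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for kind, df in results.items():
        if kind not in TABLE_SCHEMAS:
            raise ValueError(f"unknown result kind {kind!r}")
        cols = TABLE_SCHEMAS[kind]
        frame = df.copy()
        for col in cols:
            if col not in frame.columns:
                frame[col] = pd.Series(dtype=object)
        frame = frame[cols]
        path = out_dir / f"{kind}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written.append(path)
    return written


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
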