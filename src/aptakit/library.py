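"""Reading SELEX pools and turning raw reads into insert count tables.

A Cell-SELEX library member is ``forward_constant + random region +
reverse_constant``.  Only the random region carries information, so the
first analysis step is to locate the constant flanks in each sequencing
read (in either orientation), cut out the insert, and tally identical
inserts into a per-pool count table.

Coordinates are 0-based half-open internally; anything written for human
consumption is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "LibraryDesign",
    "ReadBatch",
    "PoolTable",
    "Rejection",
    "ParseError",
    "DEFAULT_LIBRARY",
    "reverse_complement",
    "parse_reads",
    "extract_insert",
    "count_pool",
    "write_pool_table",
    "read_pool_table",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGT")
READ_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class LibraryDesign:
    """Fixed-region layout of the selection library.

    Parameters
    ----------
    forward_constant : str
        5' constant (primer-binding) region, in library orientation.
    reverse_constant : str
        3' constant region, in library orientation.
    random_length : int
        Length of the randomized insert between the constant regions.
    reverse_primer : str
        Reverse PCR primer; must equal the reverse complement of
        ``reverse_constant``.
    """

    forward_constant: str
    reverse_constant: str
    random_length: int
    reverse_primer: str

    def __post_init__(self) -> None:
        for name in ("forward_constant", "reverse_constant", "reverse_primer"):
            seq = getattr(self, name)
            if not seq or not DNA_ALPHABET.issuperset(seq):
                raise ValueError(f"{name} must be a non-empty A/C/G/T string")
        if self.random_length <= 0:
            raise ValueError("random_length must be positive")
        if self.reverse_primer != reverse_complement(self.reverse_constant):
            raise ValueError(
                "reverse_primer is not the reverse complement of reverse_constant"
            )

    @property
    def read_length(self) -> int:
        """Length of a full-length library member."""
        return len(self.forward_constant) + self.random_length + len(self.reverse_constant)


#: The library used throughout: 20-nt constant flanks around a 36-nt random core.
DEFAULT_LIBRARY = LibraryDesign(
    forward_constant="GTTCGTGGTGTGCTGGATGT",
    reverse_constant="TGACACATCCAGCAGCACGA",
    random_length=36,
    reverse_primer="TCGTGCTGCTGGATGTGTCA",
)


@dataclass
class ReadBatch:
    """An ordered collection of sequencing reads from one pool."""

    records: list[tuple[str, str, str | None]]
    source_label: str = ""

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate read identifiers within batch")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str, str | None]]:
        return iter(self.records)


@dataclass(frozen=True)
class Rejection:
    """Why a read did not yield a countable insert.

    ``reason`` is one of ``no_forward``, ``no_reverse``,
    ``bad_insert_length``, ``bad_alphabet``, ``ambiguous_insert``.
    """

    reason: str

    def __bool__(self) -> bool:
        return False


@dataclass
class PoolTable:
    """Per-pool unique-insert counts, optionally depth-normalized.

    ``counts`` maps each 36-nt insert to its read count; ``rpm`` (reads
    per million) is attached by :func:`aptakit.enrichment.normalize_rpm`.
    """

    pool_id: tuple[int, str]
    counts: dict[str, int]
    total_reads: int
    unmatched_reads: int
    rpm: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.total_reads != sum(self.counts.values()):
            raise ValueError("total_reads must equal the sum of counts")

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    @property
    def n_input_reads(self) -> int:
        return self.total_reads + self.unmatched_reads


# ---------------------------------------------------------------------------
# Read parsing
# ---------------------------------------------------------------------------

def parse_reads(path: str | Path, format: str, source_label: str = "") -> ReadBatch:
    """Parse a FASTA or FASTQ file into a :class:`ReadBatch`.

    Order is preserved; FASTQ quality strings are retained.  An empty
    file yields an empty batch.  Malformed records raise
    :class:`ParseError` naming the offending record.
    """
    path = Path(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    records: list[tuple[str, str, str | None]] = []
    with open(path, encoding="utf-8") as handle:
        if format == "fasta":
            for title, seq in SimpleFastaParser(handle):
                records.append((title.split()[0] if title else title, seq.upper(), None))
        else:
            try:
                for title, seq, qual in FastqGeneralIterator(handle):
                    if len(seq) != len(qual):
                        raise ParseError(
                            f"{path}: record {len(records) + 1} "
                            f"(near line {4 * len(records) + 1}): sequence and "
                            f"quality lengths differ"
                        )
                    records.append((title.split()[0], seq.upper(), qual))
            except ValueError as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(
                    f"{path}: record {len(records) + 1} "
                    f"(near line {4 * len(records) + 1}): {exc}"
                ) from exc
    return ReadBatch(records=records, source_label=source_label or path.stem)


# ---------------------------------------------------------------------------
# Insert extraction
# ---------------------------------------------------------------------------

def _find_approx(haystack: str, needle: str, max_mismatch: int) -> int:
    """Leftmost start of ``needle`` in ``haystack`` with <= max_mismatch
    substitutions, or -1."""
    if max_mismatch == 0:
        return haystack.find(needle)
    n, m = len(haystack), len(needle)
    for start in range(n - m + 1):
        mm = 0
        window = haystack[start : start + m]
        for a, b in zip(window, needle):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return start
    return -1


_REASON_RANK = {
    "no_forward": 0,
    "no_reverse": 1,
    "bad_insert_length": 2,
    "ambiguous_insert": 3,
}


def _extract_oriented(read: str, design: LibraryDesign, max_mismatch: int) -> str | Rejection:
    fwd_at = _find_approx(read, design.forward_constant, max_mismatch)
    if fwd_at < 0:
        return Rejection("no_forward")
    insert_start = fwd_at + len(design.forward_constant)
    rev_at = _find_approx(read[insert_start:], design.reverse_constant, max_mismatch)
    if rev_at < 0:
        return Rejection("no_reverse")
    insert = read[insert_start : insert_start + rev_at]
    if len(insert) != design.random_length:
        return Rejection("bad_insert_length")
    if "N" in insert:
        return Rejection("ambiguous_insert")
    return insert


def extract_insert(
    read: str, design: LibraryDesign, max_mismatch: int = 0
) -> str | Rejection:
    """Locate the constant flanks in ``read`` (either orientation) and
    return the random-region insert in library orientation.

    Each constant region may carry up to ``max_mismatch`` substitutions.
    Failures return a :class:`Rejection` (falsy) rather than raising;
    when both orientations fail, the reason from the orientation that
    progressed furthest is reported.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    read = read.upper()
    if not READ_ALPHABET.issuperset(read):
        return Rejection("bad_alphabet")
    fwd = _extract_oriented(read, design, max_mismatch)
    if not isinstance(fwd, Rejection):
        return fwd
    rev = _extract_oriented(reverse_complement(read), design, max_mismatch)
    if not isinstance(rev, Rejection):
        return rev
    return fwd if _REASON_RANK[fwd.reason] >= _REASON_RANK[rev.reason] else rev


def count_pool(
    batch: ReadBatch,
    design: LibraryDesign,
    max_mismatch: int = 0,
    pool_id: tuple[int, str] | None = None,
) -> PoolTable:
    """Tally identical inserts across a read batch.

    Conservation holds by construction: counted reads plus unmatched
    reads equal the number of input records.
    """
    counts: dict[str, int] = {}
    unmatched = 0
    for _, seq, _ in batch:
        insert = extract_insert(seq, design, max_mismatch)
        if isinstance(insert, Rejection):
            unmatched += 1
        else:
            counts[insert] = counts.get(insert, 0) + 1
    return PoolTable(
        pool_id=pool_id or (0, batch.source_label),
        counts=counts,
        total_reads=len(batch) - unmatched,
        unmatched_reads=unmatched,
    )


# ---------------------------------------------------------------------------
# TSV persistence
# ---------------------------------------------------------------------------

def write_pool_table(table: PoolTable, path: str | Path) -> None:
    """Write a count table as TSV (``sequence\\tcount[\\trpm]``), sorted by
    descending count then sequence."""
    rows = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["sequence", "count"])
    if table.rpm is not None:
        df["rpm"] = [table.rpm[s] for s in df["sequence"]]
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(f"# pool_round={table.pool_id[0]}\tpool_arm={table.pool_id[1]}\t"
                     f"unmatched_reads={table.unmatched_reads}\n")
        df.to_csv(handle, sep="\t", index=False)


def read_pool_table(path: str | Path) -> PoolTable:
    """Inverse of :func:`write_pool_table`."""
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
        meta = dict(
            item.split("=", 1) for item in header.lstrip("# ").rstrip("\n").split("\t")
        )
        try:
            df = pd.read_csv(handle, sep="\t")
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise ParseError(f"{path}: malformed pool table: {exc}") from exc
    required = {"sequence", "count"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if len(df) and (df["count"] < 0).any():
        raise ParseError(f"{path}: negative count")
    counts = dict(zip(df["sequence"].astype(str), df["count"].astype(int)))
    rpm = None
    if "rpm" in df.columns:
        rpm = dict(zip(df["sequence"].astype(str), df["rpm"].astype(float)))
    return PoolTable(
        pool_id=(int(meta.get("pool_round", 0)), meta.get("pool_arm", "")),
        counts=counts,
        total_reads=int(df["count"].sum()) if len(df) else 0,
        unmatched_reads=int(meta.get("unmatched_reads", 0)),
        rpm=rpm,
    )
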