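"""Demultiplexing and barcode counting for indexed single-end reads.

Each sequencing read carries an 8-base sample index (identifying cell
line / passage / replicate) and an shRNA-specific barcode, both at fixed
0-based half-open offsets within the read. Index matching is exact;
barcode matching tolerates one mismatch, with exact matches taking
precedence and ties at the minimal distance treated as ambiguous and
discarded (impossible on a barcode set with minimum Hamming distance 3).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .manifest import LibraryManifest, hamming

__all__ = [
    "SampleKey",
    "ReadLayout",
    "CountMatrix",
    "BarcodeMatcher",
    "AMBIGUOUS",
    "QuantError",
    "read_fastq_sequences",
    "load_index_table",
    "write_index_table",
    "demultiplex",
    "match_barcode",
    "count_barcodes",
    "count_reads",
]

UNMATCHED_ROW = "__unmatched__"
AMBIGUOUS_ROW = "__ambiguous__"

_NUCLEOTIDES = frozenset("ACGT")


class QuantError(ValueError):
    """Raised on invalid index tables or layout configuration."""


class _Ambiguous:
    """Sentinel: read barcode tied between two library barcodes."""

    def __repr__(self) -> str:  # pragma: no cover
        return "AMBIGUOUS"


AMBIGUOUS = _Ambiguous()


@dataclass(frozen=True, order=True)
class SampleKey:
    """One sequencing sample: a cell line at a passage, one replicate."""

    cell_line: str
    passage: int
    replicate: str
    index_seq: str

    def __post_init__(self) -> None:
        if len(self.index_seq) != 8 or set(self.index_seq) - _NUCLEOTIDES:
            raise QuantError(
                f"index_seq {self.index_seq!r} must be 8 bases over A/C/G/T"
            )
        if self.passage < 0:
            raise QuantError(f"negative passage {self.passage}")

    @property
    def label(self) -> str:
        return f"{self.cell_line}|p{self.passage}|{self.replicate}"

    @classmethod
    def from_label(cls, label: str, index_seq: str = "A" * 8) -> "SampleKey":
        cell_line, p, replicate = label.split("|")
        return cls(cell_line, int(p.lstrip("p")), replicate, index_seq)


@dataclass(frozen=True)
class ReadLayout:
    """0-based half-open offsets of the index and barcode within a read."""

    index_start: int = 0
    index_length: int = 8
    barcode_start: int = 8

    def __post_init__(self) -> None:
        if self.index_start < 0 or self.barcode_start < 0:
            raise QuantError("offsets must be non-negative")


@dataclass
class CountMatrix:
    """Integer read counts, shRNA x sample, plus per-sample unassigned reads.

    ``values`` is indexed by shRNA id (rows) and :class:`SampleKey`
    labels (columns); ``unassigned`` has rows ``unmatched`` and
    ``ambiguous`` with the same columns.
    """

    values: pd.DataFrame
    samples: list[SampleKey]
    unassigned: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise QuantError("negative counts")
        labels = [s.label for s in self.samples]
        if list(self.values.columns) != labels:
            raise QuantError("column labels do not match sample keys")
        if len(set(labels)) != len(labels):
            raise QuantError("duplicate sample keys")

    @property
    def shrna_ids(self) -> list[str]:
        return list(self.values.index)

    def column_totals(self) -> pd.Series:
        """Assigned + unassigned reads per sample."""
        return self.values.sum(axis=0) + self.unassigned.sum(axis=0)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        out = pd.concat(
            [
                self.values,
                self.unassigned.rename(
                    index={"unmatched": UNMATCHED_ROW, "ambiguous": AMBIGUOUS_ROW}
                ),
            ]
        )
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            meta = ";".join(s.index_seq for s in self.samples)
            fh.write(f"# index_seqs={meta}\n")
            out.to_csv(fh, sep="\t", index_label="shrna_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        index_seqs: list[str] | None = None
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# index_seqs="):
                    index_seqs = line.strip().split("=", 1)[1].split(";")
        df = pd.read_csv(path, sep="\t", comment="#", index_col="shrna_id")
        special = [r for r in (UNMATCHED_ROW, AMBIGUOUS_ROW) if r in df.index]
        unassigned = df.loc[special].rename(
            index={UNMATCHED_ROW: "unmatched", AMBIGUOUS_ROW: "ambiguous"}
        )
        values = df.drop(index=special).astype(np.int64)
        for row in ("unmatched", "ambiguous"):
            if row not in unassigned.index:
                unassigned.loc[row] = 0
        if index_seqs is None:
            index_seqs = ["A" * 8] * len(df.columns)
        samples = [
            SampleKey.from_label(lab, seq)
            for lab, seq in zip(df.columns, index_seqs)
        ]
        return cls(values, samples, unassigned.astype(np.int64))


def read_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences (uppercase strings) from plain or gzipped FASTQ."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield str(rec.seq).upper()


def load_index_table(path: str | Path) -> list[SampleKey]:
    """Read a tab-delimited index table (cell_line, passage, replicate, index_seq)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ("cell_line", "passage", "replicate", "index_seq")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise QuantError(f"index table {path}: missing column(s) {missing}")
    keys = [
        SampleKey(r.cell_line, int(r.passage), str(r.replicate), r.index_seq)
        for r in df.itertuples(index=False)
    ]
    _check_index_table(keys)
    return keys


def write_index_table(keys: Iterable[SampleKey], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cell_line": k.cell_line,
                "passage": k.passage,
                "replicate": k.replicate,
                "index_seq": k.index_seq,
            }
            for k in keys
        ]
    ).to_csv(path, sep="\t", index=False)


def _check_index_table(keys: list[SampleKey]) -> None:
    seqs = [k.index_seq for k in keys]
    if len(set(seqs)) != len(seqs):
        dup = next(s for s in seqs if seqs.count(s) > 1)
        raise QuantError(f"duplicate index sequence {dup!r} in index table")
    meta = [(k.cell_line, k.passage, k.replicate) for k in keys]
    if len(set(meta)) != len(meta):
        raise QuantError("duplicate (cell_line, passage, replicate) in index table")


def demultiplex(
    reads: Iterable[str],
    index_table: list[SampleKey],
    layout: ReadLayout = ReadLayout(),
) -> tuple[dict[SampleKey, list[str]], int]:
    """Split reads by exact sample-index match.

    Returns per-sample read lists plus the count of unindexed reads
    (no exact match, or read too short to contain the index window).
    """
    _check_index_table(index_table)
    lookup = {k.index_seq: k for k in index_table}
    streams: dict[SampleKey, list[str]] = {k: [] for k in index_table}
    unindexed = 0
    lo, hi = layout.index_start, layout.index_start + layout.index_length
    for seq in reads:
        key = lookup.get(seq[lo:hi]) if len(seq) >= hi else None
        if key is None:
            unindexed += 1
        else:
            streams[key].append(seq)
    return streams, unindexed


class BarcodeMatcher:
    """Barcode lookup with an exact index and a precomputed 1-neighbour index.

    For the default single-mismatch tolerance, every Hamming-1 neighbour
    of every library barcode is tabulated once (collisions marked
    ambiguous), so matching is O(1) per read. Larger tolerances fall
    back to a linear scan.
    """

    def __init__(self, manifest: LibraryManifest, max_mismatch: int = 1) -> None:
        if max_mismatch < 0:
            raise QuantError("max_mismatch must be >= 0")
        self.max_mismatch = max_mismatch
        self.barcode_length = manifest.barcode_length
        self._exact = manifest.barcode_to_id()
        self._one_off: dict[str, object] = {}
        if max_mismatch >= 1:
            for bc, sid in self._exact.items():
                for variant in _hamming1_neighbours(bc):
                    prev = self._one_off.get(variant)
                    if prev is None:
                        self._one_off[variant] = sid
                    elif prev != sid:
                        self._one_off[variant] = AMBIGUOUS
        self._barcodes = list(self._exact)

    def match(self, window: str):
        window = window[: self.barcode_length]
        if len(window) < self.barcode_length:
            return None
        hit = self._exact.get(window)
        if hit is not None:
            return hit
        if self.max_mismatch == 0:
            return None
        if self.max_mismatch == 1:
            return self._one_off.get(window)
        # linear scan for the unusual >1 tolerance
        best_d, best, tied = self.max_mismatch + 1, None, False
        for bc in self._barcodes:
            d = hamming(window, bc)
            if d < best_d:
                best_d, best, tied = d, self._exact[bc], False
            elif d == best_d:
                tied = True
        if best_d > self.max_mismatch:
            return None
        return AMBIGUOUS if tied else best


def _hamming1_neighbours(barcode: str) -> Iterator[str]:
    for i, base in enumerate(barcode):
        for other in "ACGT":
            if other != base:
                yield barcode[:i] + other + barcode[i + 1 :]


def match_barcode(
    read_window: str, manifest: LibraryManifest, max_mismatch: int = 1
):
    """Resolve a read window to an shRNA id, ``None`` (unmatched), or AMBIGUOUS.

    Exact matches take precedence; a unique barcode within Hamming
    distance ``max_mismatch`` wins; a tie at the minimal distance
    returns the :data:`AMBIGUOUS` sentinel.
    """
    return BarcodeMatcher(manifest, max_mismatch).match(read_window)


def count_barcodes(
    streams: Mapping[SampleKey, Iterable[str]],
    manifest: LibraryManifest,
    layout: ReadLayout = ReadLayout(),
    max_mismatch: int = 1,
) -> CountMatrix:
    """Count barcode-resolved reads per shRNA per sample.

    Unmatched and ambiguous reads accumulate in the matrix's
    ``unassigned`` block, so per-sample totals are conserved.
    """
    matcher = BarcodeMatcher(manifest, max_mismatch)
    samples = list(streams)  # preserves index-table order from demultiplex
    ids = manifest.shrna_ids
    values = pd.DataFrame(
        0, index=ids, columns=[s.label for s in samples], dtype=np.int64
    )
    unassigned = pd.DataFrame(
        0, index=["unmatched", "ambiguous"], columns=values.columns, dtype=np.int64
    )
    lo = layout.barcode_start
    hi = lo + manifest.barcode_length
    for key in samples:
        col = values[key.label].to_dict()
        n_unmatched = n_ambig = 0
        for seq in streams[key]:
            hit = matcher.match(seq[lo:hi])
            if hit is None:
                n_unmatched += 1
            elif hit is AMBIGUOUS:
                n_ambig += 1
            else:
                col[hit] += 1
        values[key.label] = pd.Series(col)
        unassigned.loc["unmatched", key.label] = n_unmatched
        unassigned.loc["ambiguous", key.label] = n_ambig
    return CountMatrix(values, samples, unassigned)


def count_reads(
    fastq: str | Path,
    manifest: LibraryManifest,
    index_table: list[SampleKey],
    layout: ReadLayout = ReadLayout(),
    max_mismatch: int = 1,
) -> tuple[CountMatrix, int]:
    """FASTQ -> demultiplex -> count. Returns the matrix and the unindexed count."""
    streams, unindexed = demultiplex(read_fastq_sequences(fastq), index_table, layout)
    return count_barcodes(streams, manifest, layout, max_mismatch), unindexed
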