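"""Data model and validation for a focused shRNA library design.

A library manifest is a tab-delimited table with one row per hairpin:
an opaque shRNA identifier, the target gene symbol, the sequencing
barcode that tags the hairpin, and optionally the 19-nt hairpin sense
sequence and the predicted duplex free energy (kcal/mol).

Barcodes must be unique and of a single common length; pairwise Hamming
distance >= 3 additionally guarantees that single-mismatch barcode
assignment (see :mod:`conescreen.quant`) can never misassign a read.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "HairpinRecord",
    "LibraryManifest",
    "ManifestError",
    "load_manifest",
    "write_manifest",
    "composition_summary",
    "validate_distances",
    "hamming",
    "PUBLISHED_COMPOSITION",
]

_NUCLEOTIDES = frozenset("ACGT")
HAIRPIN_LENGTH = 19

# Free-energy window used when the library was designed; duplexes outside
# it draw a warning (design-time rule, not a hard constraint on input data).
DG_WINDOW = (-32.0, -28.0)

#: Library composition of the published focused screen: number of genes
#: (value) carrying a given number of hairpins (key).
PUBLISHED_COMPOSITION: Mapping[int, int] = {6: 209, 5: 1, 4: 1, 3: 2, 2: 2, 1: 1}

REQUIRED_COLUMNS = ("shrna_id", "gene", "barcode")
OPTIONAL_COLUMNS = ("hairpin", "duplex_dg")


class ManifestError(ValueError):
    """Raised when a manifest violates a structural invariant."""


@dataclass(frozen=True)
class HairpinRecord:
    """One shRNA: identifier, target gene, barcode, optional hairpin/ΔG."""

    shrna_id: str
    gene: str
    barcode: str
    hairpin: str | None = None
    duplex_dg: float | None = None

    def __post_init__(self) -> None:
        if not self.shrna_id:
            raise ManifestError("empty shrna_id")
        if not self.gene:
            raise ManifestError(f"record {self.shrna_id!r} has no gene")
        if not self.barcode or set(self.barcode) - _NUCLEOTIDES:
            raise ManifestError(
                f"record {self.shrna_id!r}: barcode {self.barcode!r} is not a "
                "non-empty string over A/C/G/T"
            )
        if self.hairpin is not None:
            if set(self.hairpin) - _NUCLEOTIDES:
                raise ManifestError(
                    f"record {self.shrna_id!r}: hairpin contains non-ACGT characters"
                )
            if len(self.hairpin) != HAIRPIN_LENGTH:
                raise ManifestError(
                    f"record {self.shrna_id!r}: hairpin length "
                    f"{len(self.hairpin)} != {HAIRPIN_LENGTH}"
                )
        if self.duplex_dg is not None:
            dg = float(self.duplex_dg)
            if dg != dg or dg in (float("inf"), float("-inf")):
                raise ManifestError(f"record {self.shrna_id!r}: non-finite duplex_dg")


@dataclass
class LibraryManifest:
    """Ordered collection of hairpin records with unique same-length barcodes."""

    records: list[HairpinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r.barcode) for r in self.records}
        if len(lengths) > 1:
            raise ManifestError(f"mixed barcode lengths: {sorted(lengths)}")
        seen_bc: dict[str, int] = {}
        seen_id: dict[str, int] = {}
        for i, r in enumerate(self.records):
            if r.barcode in seen_bc:
                raise ManifestError(
                    f"duplicate barcode {r.barcode!r} in rows "
                    f"{seen_bc[r.barcode]} and {i} "
                    f"({self.records[seen_bc[r.barcode]].shrna_id!r}, {r.shrna_id!r})"
                )
            if r.shrna_id in seen_id:
                raise ManifestError(
                    f"duplicate shrna_id {r.shrna_id!r} in rows "
                    f"{seen_id[r.shrna_id]} and {i}"
                )
            seen_bc[r.barcode] = i
            seen_id[r.shrna_id] = i
        self._warn_dg()

    def _warn_dg(self) -> None:
        lo, hi = DG_WINDOW
        out = [
            r.shrna_id
            for r in self.records
            if r.duplex_dg is not None and not (lo <= r.duplex_dg <= hi)
        ]
        if out:
            warnings.warn(
                f"{len(out)} hairpin(s) with duplex ΔG outside [{lo}, {hi}] "
                f"kcal/mol (first: {out[0]!r})",
                stacklevel=3,
            )

    @property
    def barcode_length(self) -> int:
        if not self.records:
            raise ManifestError("empty manifest has no barcode length")
        return len(self.records[0].barcode)

    @property
    def shrna_ids(self) -> list[str]:
        return [r.shrna_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        """Distinct gene symbols in first-appearance order."""
        return list(dict.fromkeys(r.gene for r in self.records))

    def barcode_to_id(self) -> dict[str, str]:
        return {r.barcode: r.shrna_id for r in self.records}

    def gene_of(self) -> dict[str, str]:
        return {r.shrna_id: r.gene for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, LibraryManifest) and self.records == other.records

    def validate_total(self, expected_total: int) -> None:
        """Check the hairpin count against a user-declared expectation."""
        if len(self.records) != expected_total:
            raise ManifestError(
                f"manifest has {len(self.records)} hairpins, expected {expected_total}"
            )


def load_manifest(path: str | Path) -> LibraryManifest:
    """Read a tab-delimited manifest with a header row.

    Required columns: ``shrna_id``, ``gene``, ``barcode``; optional:
    ``hairpin``, ``duplex_dg``. Column order is free; row order is
    preserved. Structural violations (duplicate or mixed-length
    barcodes, missing columns) raise :class:`ManifestError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path}: missing column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        hairpin = getattr(row, "hairpin", None)
        if isinstance(hairpin, float) or hairpin in (None, "", "nan"):
            hairpin = None
        dg = getattr(row, "duplex_dg", None)
        dg = None if dg is None or (isinstance(dg, float) and dg != dg) or dg == "" else float(dg)
        records.append(
            HairpinRecord(
                shrna_id=str(row.shrna_id),
                gene=str(row.gene),
                barcode=str(row.barcode),
                hairpin=hairpin,
                duplex_dg=dg,
            )
        )
    return LibraryManifest(records)


def write_manifest(manifest: LibraryManifest, path: str | Path) -> None:
    """Write a manifest as a tab-delimited table (inverse of load_manifest)."""
    rows = []
    for r in manifest.records:
        rows.append(
            {
                "shrna_id": r.shrna_id,
                "gene": r.gene,
                "barcode": r.barcode,
                "hairpin": "" if r.hairpin is None else r.hairpin,
                "duplex_dg": "" if r.duplex_dg is None else repr(r.duplex_dg),
            }
        )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def composition_summary(manifest: LibraryManifest) -> dict[int, int]:
    """Map hairpins-per-gene count -> number of genes with that count."""
    per_gene: dict[str, int] = {}
    for r in manifest.records:
        per_gene[r.gene] = per_gene.get(r.gene, 0) + 1
    out: dict[int, int] = {}
    for n in per_gene.values():
        out[n] = out.get(n, 0) + 1
    return out


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def validate_distances(
    manifest: LibraryManifest, min_hamming: int = 3
) -> list[tuple[str, str, int]]:
    """Report barcode pairs closer than ``min_hamming``.

    Returns ``(shrna_id_a, shrna_id_b, distance)`` tuples; an empty
    report means every pairwise distance is >= ``min_hamming``, which
    for ``min_hamming=3`` makes single-mismatch assignment unambiguous.
    """
    offending = []
    for a, b in itertools.combinations(manifest.records, 2):
        d = hamming(a.barcode, b.barcode)
        if d < min_hamming:
            offending.append((a.shrna_id, b.shrna_id, d))
    return offending


def write_distance_report(
    report: Iterable[tuple[str, str, int]], path: str | Path
) -> None:
    pd.DataFrame(report, columns=["shrna_id_a", "shrna_id_b", "hamming"]).to_csv(
        path, sep="\t", index=False
    )
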