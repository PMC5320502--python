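"""Synthetic pooled-screen generator for end-to-end testing.

Emulates the statistical structure of a focused shRNA dropout screen:
a manifest of barcoded hairpins (six per gene by default), a panel of
cell lines (four cancer plus one normal reference) passaged five times
in duplicate, and negative-binomial barcode counts whose expectation
drifts log-linearly with passage at a gene- and line-specific rate.
Reads can be rendered back to FASTQ (index + barcode at fixed offsets)
with an optional per-base substitution error, giving a full round-trip
check of the quantification stage.

Defaults mirror the screen the model was built for: 6 hairpins/gene,
5 passages, 2 replicates, cell lines BJ-hTERT (normal), MDA-MB-231,
HCT116, PC3 and HT1080, and a mean depth of ~2,357 reads per hairpin
per sample (3e6 reads over 1,273 hairpins). Replicate variability that
grows after passage 3 — seen in the real screen — is modelled as
log-normal jitter on the NB mean, off by default so calibration tests
run on clean data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .manifest import (
    HairpinRecord,
    LibraryManifest,
    HAIRPIN_LENGTH,
    hamming,
)
from .quant import CountMatrix, ReadLayout, SampleKey

__all__ = [
    "SimulationError",
    "SimulationDesign",
    "GroundTruth",
    "simulate_manifest",
    "make_index_table",
    "simulate_screen_counts",
    "simulate_fastq",
]

DEFAULT_CELL_LINES = ("MDA-MB-231", "HCT116", "PC3", "HT1080", "BJ-hTERT")
DEFAULT_NORMAL_LINE = "BJ-hTERT"
#: 3e6 reads per sample over 1,273 hairpins.
DEFAULT_DEPTH = 3_000_000 / 1_273


class SimulationError(ValueError):
    pass


@dataclass
class SimulationDesign:
    """Screen layout and noise model for the count simulator.

    ``slopes`` maps (gene, cell_line) to the log-linear drift per
    passage; unlisted pairs default to 0 (no depletion). ``dispersion``
    is the negative-binomial size parameter (variance = m + m^2/size);
    ``late_passage_inflation`` >= 1 multiplies replicate log-scale
    jitter for passages > 3 (1 = off).
    """

    n_genes: int = 20
    hairpins_per_gene: int = 6
    passages: int = 5
    replicates: int = 2
    cell_lines: Sequence[str] = DEFAULT_CELL_LINES
    normal_line: str = DEFAULT_NORMAL_LINE
    depth: float = DEFAULT_DEPTH
    dispersion: float = 10.0
    late_passage_inflation: float = 1.0
    baseline_log_sd: float = 0.5
    slopes: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.normal_line not in self.cell_lines:
            raise SimulationError(
                f"normal line {self.normal_line!r} not among cell lines"
            )
        if sum(1 for c in self.cell_lines if c == self.normal_line) != 1:
            raise SimulationError("exactly one normal line required")
        for name, val in (
            ("n_genes", self.n_genes),
            ("hairpins_per_gene", self.hairpins_per_gene),
            ("passages", self.passages),
            ("replicates", self.replicates),
            ("depth", self.depth),
            ("dispersion", self.dispersion),
        ):
            if val <= 0:
                raise SimulationError(f"{name} must be positive, got {val}")
        if self.late_passage_inflation < 1:
            raise SimulationError("late_passage_inflation must be >= 1")


@dataclass
class GroundTruth:
    """Generating parameters retained for recovery tests."""

    slopes: pd.DataFrame  # genes x cell lines, drift per passage
    baselines: pd.Series  # per-hairpin expected reads at passage 0

    def in_region(self, gene: str, cancer_line: str, normal_line: str) -> bool:
        b11 = float(self.slopes.loc[gene, cancer_line])
        b21 = float(self.slopes.loc[gene, normal_line])
        return b11 < 0 and b11 < b21 < -b11


def _random_barcodes(
    n: int, length: int, min_hamming: int, rng: np.random.Generator
) -> list[str]:
    """Rejection-sample barcodes with enforced pairwise Hamming distance.

    Errors out after a bounded run of consecutive rejections, which
    also catches sphere-packing-infeasible requests.
    """
    if min_hamming > length:
        raise SimulationError(
            f"min_hamming {min_hamming} exceeds barcode length {length}"
        )
    bases = np.array(list("ACGT"))
    accepted: list[str] = []
    failures, max_failures = 0, max(1000, 200 * n)
    while len(accepted) < n:
        cand = "".join(bases[rng.integers(0, 4, size=length)])
        if all(hamming(cand, b) >= min_hamming for b in accepted):
            accepted.append(cand)
            failures = 0
        else:
            failures += 1
            if failures > max_failures:
                raise SimulationError(
                    f"cannot place {n} barcodes of length {length} at "
                    f"min Hamming distance {min_hamming} "
                    f"(stuck after {len(accepted)})"
                )
    return accepted


def simulate_manifest(
    n_genes: int,
    hairpins_per_gene: int = 6,
    barcode_length: int = 16,
    min_hamming: int = 3,
    seed: int = 0,
    composition: Mapping[int, int] | None = None,
) -> LibraryManifest:
    """Random library manifest with distance-separated barcodes.

    ``composition`` (hairpins-per-gene -> number of genes) overrides
    the uniform ``n_genes`` x ``hairpins_per_gene`` design and lets the
    published mixed composition be reconstructed exactly.
    """
    rng = np.random.default_rng(seed)
    if composition is not None:
        gene_sizes = [k for k, g in sorted(composition.items()) for _ in range(g)]
    else:
        gene_sizes = [hairpins_per_gene] * n_genes
    total = sum(gene_sizes)
    barcodes = _random_barcodes(total, barcode_length, min_hamming, rng)
    bases = np.array(list("ACGT"))
    records, b = [], 0
    width = max(4, len(str(len(gene_sizes))))
    for gi, size in enumerate(gene_sizes):
        gene = f"GENE{gi:0{width}d}"
        for hi in range(size):
            hairpin = "".join(bases[rng.integers(0, 4, size=HAIRPIN_LENGTH)])
            records.append(
                HairpinRecord(
                    shrna_id=f"{gene}_sh{hi + 1}",
                    gene=gene,
                    barcode=barcodes[b],
                    hairpin=hairpin,
                    duplex_dg=float(rng.uniform(-32.0, -28.0)),
                )
            )
            b += 1
    return LibraryManifest(records)


def make_index_table(
    design: SimulationDesign, seed: int = 0
) -> list[SampleKey]:
    """One 8-base index per (cell line, passage, replicate), distance >= 3."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1D]))
    n = len(design.cell_lines) * design.passages * design.replicates
    seqs = _random_barcodes(n, 8, 3, rng)
    keys, i = [], 0
    for line in design.cell_lines:
        for p in range(1, design.passages + 1):
            for r in range(1, design.replicates + 1):
                keys.append(SampleKey(line, p, f"r{r}", seqs[i]))
                i += 1
    return keys


def default_hit_slopes(
    manifest: LibraryManifest,
    design: SimulationDesign,
    n_hits: int,
    cancer_slope: float = -0.3,
    normal_slope: float = 0.0,
) -> dict[tuple[str, str], float]:
    """Slope map marking the first ``n_hits`` genes as pan-cancer hits."""
    slopes: dict[tuple[str, str], float] = {}
    for gene in manifest.genes[:n_hits]:
        for line in design.cell_lines:
            slopes[(gene, line)] = (
                normal_slope if line == design.normal_line else cancer_slope
            )
    return slopes


def simulate_screen_counts(
    manifest: LibraryManifest,
    design: SimulationDesign,
    seed: int = 0,
) -> tuple[CountMatrix, GroundTruth]:
    """Draw negative-binomial barcode counts for the whole screen.

    Expected reads of hairpin h in line l at passage t are
    baseline_h * exp(slope_{gene(h), l} * t); replicates are
    independent draws. For t > 3 with ``late_passage_inflation`` > 1,
    the mean picks up multiplicative log-normal jitter with sigma =
    ln(inflation) per replicate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    ids = manifest.shrna_ids
    genes = [r.gene for r in manifest.records]
    baselines = design.depth * np.exp(
        rng.normal(0.0, design.baseline_log_sd, size=len(ids))
        - design.baseline_log_sd**2 / 2
    )
    slope_df = pd.DataFrame(
        0.0, index=manifest.genes, columns=list(design.cell_lines)
    )
    for (gene, line), s in design.slopes.items():
        slope_df.loc[gene, line] = s

    index_table = make_index_table(design, seed)
    values = {}
    size = design.dispersion
    jitter_sd = math.log(design.late_passage_inflation)
    gene_slope = np.empty(len(ids))
    for key in index_table:
        for i, g in enumerate(genes):
            gene_slope[i] = slope_df.loc[g, key.cell_line]
        mean = baselines * np.exp(gene_slope * key.passage)
        if key.passage > 3 and jitter_sd > 0:
            mean = mean * np.exp(rng.normal(0.0, jitter_sd, size=mean.size))
        # NB with mean m, size k: p = k / (k + m)
        p = size / (size + mean)
        values[key.label] = rng.negative_binomial(size, p)
    df = pd.DataFrame(values, index=ids, dtype=np.int64)
    unassigned = pd.DataFrame(
        0, index=["unmatched", "ambiguous"], columns=df.columns, dtype=np.int64
    )
    truth = GroundTruth(slope_df, pd.Series(baselines, index=ids))
    return CountMatrix(df, index_table, unassigned), truth


def simulate_fastq(
    counts: CountMatrix,
    manifest: LibraryManifest,
    path: str | Path,
    layout: ReadLayout = ReadLayout(),
    error_rate: float = 0.0,
    read_length: int = 50,
    seed: int = 0,
) -> int:
    """Render a count matrix to single-end FASTQ reads; returns reads written.

    Each read is the sample index at ``layout.index_start`` and the
    hairpin barcode at ``layout.barcode_start``, padded with random
    bases to ``read_length``; substitution errors are applied uniformly
    at ``error_rate`` per base over the whole read. Exactly
    ``counts[s, k]`` reads are emitted per (hairpin, sample) — the
    exact inverse of quantification at error_rate 0.
    """
    if not 0 <= error_rate < 1:
        raise SimulationError(f"error_rate {error_rate} outside [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA]))
    bases = np.array(list("ACGT"))
    barcode_of = {r.shrna_id: r.barcode for r in manifest.records}
    min_len = max(
        layout.index_start + layout.index_length,
        layout.barcode_start + manifest.barcode_length,
    )
    if read_length < min_len:
        raise SimulationError(
            f"read_length {read_length} shorter than layout span {min_len}"
        )
    n_written = 0
    with open(path, "w") as fh:
        for key in counts.samples:
            col = counts.values[key.label]
            for sid, n in col.items():
                n = int(n)
                if n == 0:
                    continue
                template = np.frombuffer(
                    ("N" * read_length).encode(), dtype="S1"
                ).astype("U1")
                template[:] = bases[rng.integers(0, 4, size=read_length)]
                template[
                    layout.index_start : layout.index_start + layout.index_length
                ] = list(key.index_seq)
                template[
                    layout.barcode_start : layout.barcode_start
                    + manifest.barcode_length
                ] = list(barcode_of[sid])
                block = np.tile(template, (n, 1))
                if error_rate > 0:
                    hit = rng.random(block.shape) < error_rate
                    n_err = int(hit.sum())
                    if n_err:
                        # substitute with a uniformly different base
                        shift = rng.integers(1, 4, size=n_err)
                        code = {"A": 0, "C": 1, "G": 2, "T": 3}
                        orig = np.array([code[c] for c in block[hit]])
                        block[hit] = bases[(orig + shift) % 4]
                qual = "I" * read_length
                for j in range(n):
                    fh.write(
                        f"@sim_{key.label}_{sid}_{n_written + j}\n"
                        f"{''.join(block[j])}\n+\n{qual}\n"
                    )
                n_written += n
    return n_written
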