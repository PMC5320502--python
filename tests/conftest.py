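import numpy as np
import pytest

from conescreen import (
    GeneObservations,
    HairpinRecord,
    LibraryManifest,
    SimulationDesign,
    simulate_manifest,
    simulate_screen_counts,
)


@pytest.fixture
def tiny_manifest() -> LibraryManifest:
    """Four hairpins over two genes, barcodes at pairwise distance >= 3."""
    return LibraryManifest(
        [
            HairpinRecord("A_sh1", "A", "AAAACCCC"),
            HairpinRecord("A_sh2", "A", "CCCCGGGG"),
            HairpinRecord("B_sh1", "B", "GGGGTTTT"),
            HairpinRecord("B_sh2", "B", "TTTTAAAA"),
        ]
    )


@pytest.fixture(scope="session")
def sim_manifest() -> LibraryManifest:
    return simulate_manifest(n_genes=8, hairpins_per_gene=6, barcode_length=16, seed=42)


@pytest.fixture(scope="session")
def sim_screen(sim_manifest):
    """Small screen: first two genes deplete in all cancer lines."""
    lines = ("MDA-MB-231", "HCT116", "PC3", "HT1080", "BJ-hTERT")
    slopes = {
        (g, l): -0.4
        for g in sim_manifest.genes[:2]
        for l in lines
        if l != "BJ-hTERT"
    }
    design = SimulationDesign(n_genes=8, cell_lines=lines, slopes=slopes)
    counts, truth = simulate_screen_counts(sim_manifest, design, seed=7)
    return design, counts, truth


def make_cone_obs(
    rng: np.random.Generator,
    b11: float,
    b21: float,
    n_per_passage: int = 12,
    passages: int = 5,
    sigma: float = 1.0,
    gene: str = "G",
) -> GeneObservations:
    """Gaussian observations around two exact lines (n = n_per_passage x passages)."""
    x = np.repeat(np.arange(1, passages + 1, dtype=float), n_per_passage)
    y1 = 10.0 + b11 * x + rng.normal(0, sigma, x.size)
    y2 = 10.0 + b21 * x + rng.normal(0, sigma, x.size)
    return GeneObservations(gene, y1, x, y2, x, cell_line="tumor")
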