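"""Shared fixtures: toy reference sequences, a three-exon gene on each
strand, and a small simulated cohort."""

from __future__ import annotations

import numpy as np
import pytest

from indelkit.model import AnalysisConfig, TranscriptModel
from indelkit.normalize import DictReference
from indelkit.simulate import SimulationConfig, simulate_dataset


def random_sequence(rng: np.random.Generator, length: int, repeat_prob: float = 0.15) -> str:
    """Random DNA with interspersed homopolymer / dinucleotide tracts."""
    out = []
    bases = "ACGT"
    while len(out) < length:
        if rng.random() < repeat_prob:
            unit = "".join(rng.choice(list(bases), size=int(rng.integers(1, 3))))
            out.extend((unit * 10)[: int(rng.integers(4, 13))])
        else:
            out.append(bases[int(rng.integers(0, 4))])
    return "".join(out[:length])


@pytest.fixture(scope="session")
def annot_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def toy_locus() -> tuple[DictReference, TranscriptModel]:
    """Forward-strand 3-exon coding gene in a 3 kb contig.

    Geometry: exon1 1001-1160 (UTR 1001-1060, CDS from 1061), intron1
    1161-1360, exon2 1361-1480 (all CDS), intron2 1481-1700, exon3
    1701-1900 (CDS to 1790, UTR 1791-1900).  CDS length = 100+120+90 = 310?
    -- adjusted below so it is a multiple of 3 with start/stop stamped.
    """
    rng = np.random.default_rng(12345)
    seq = list(random_sequence(rng, 3000, repeat_prob=0.1))
    exons = ((1001, 1160), (1361, 1480), (1701, 1900))
    cds_start, cds_end = 1061, 1789  # 100 + 120 + 89 = 309 bases -> 103 codons
    tx = TranscriptModel(
        transcript_id="toy_tx",
        gene_id="toy_gene",
        chrom="chrT",
        strand="+",
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )
    # stamp a clean ORF: ATG + non-stop codons + TAA
    stops = {"TAA", "TAG", "TGA"}
    non_stop = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in stops]
    n_codons = 309 // 3
    orf = "ATG" + "".join(
        non_stop[int(i)] for i in rng.integers(0, len(non_stop), size=n_codons - 2)
    ) + "TAA"
    k = 0
    for s, e in tx.cds_intervals():
        for p in range(s, e + 1):
            seq[p - 1] = orf[k]
            k += 1
    return DictReference({"chrT": "".join(seq)}), tx


@pytest.fixture(scope="session")
def small_dataset():
    """Small end-to-end simulated dataset (30 samples, 20 genes)."""
    cfg = SimulationConfig(
        rng_seed=42, n_samples=30, n_familial=6, n_genes=20, variants_per_gene=8,
        validation_panel_sizes={},
    )
    return simulate_dataset(cfg)
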