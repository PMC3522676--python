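"""Synthetic exome-cohort generator with recorded ground truth.

Emulates the statistical structure of a patient-exome indel call set:

* indel lengths 1-15 bp on a short-skewed (truncated geometric) distribution,
  with nothing above 15 bp;
* a provenance mix of already-described, newly-released-only and novel
  variants, where database copies of described variants are written with
  start positions right-shifted by up to ``db_jitter_max`` bp relative to
  the left-aligned call (historical databases predate left-alignment);
* a frequency spectrum in which novel variants concentrate at low
  frequencies while described variants reach higher frequencies;
* consequence categories hit by construction: variants are placed inside
  category-specific safe windows derived from an independently painted
  base-to-category feature map, and codon-aware placement produces STOP and
  in-frame coding variants.

Every generated variant is left-alignment stable (placements that a
left-shift would move are redrawn), so the recorded truth is exact by
construction rather than by running the annotator.  The feature map doubles
as the annotation oracle in tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import classify_frequency
from .consequence import revcomp
from .model import (
    AnalysisConfig,
    CohortCallSet,
    Consequence,
    FrequencyClass,
    Genotype,
    NormalizedIndel,
    Provenance,
    SampleCall,
    TranscriptModel,
    VariantDatabase,
)
from .normalize import DictReference, left_align
from . import io as ikio

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


class UnsatisfiableTargetError(ValueError):
    """A configured target mix or geometry cannot be realised."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort shape of the study design this package is
    built around: 173 diploid exomes of which 33 are familial cases, indel
    lengths 1-15 bp skewed short, database start positions right-shifted by
    0-10 bp, novel variants concentrated at low frequency, and a Sanger
    validation panel of 82 common and 78 private variants with
    per-frequency-class confirmation rates of 66/82 and 75/78.
    """

    rng_seed: int = 0
    n_samples: int = 173
    n_familial: int = 33
    n_genes: int = 60
    variants_per_gene: int = 10
    contig: str = "chr1"
    contig_length: int | None = None  # auto from geometry when None

    # gene geometry (bp)
    exon_count_range: tuple[int, int] = (2, 4)
    cds_exon_len_range: tuple[int, int] = (90, 180)
    intron_len_range: tuple[int, int] = (80, 400)
    utr_len_range: tuple[int, int] = (40, 120)
    intergenic_bp: int = 12000

    # indel lengths: truncated geometric on 1..15, most mass below 6 bp
    indel_len_p: float = 0.45
    max_indel_len: int = 15
    insertion_prob: float = 0.5

    # repeat tracts (left-alignment ambiguity)
    repeat_density: float = 0.001  # tract starts per bp
    repeat_tract_len_range: tuple[int, int] = (6, 12)

    provenance_mix: dict = field(
        default_factory=lambda: {
            Provenance.KNOWN_DB: 0.60,
            Provenance.NEWLY_RELEASED_ONLY: 0.10,
            Provenance.NOVEL: 0.30,
        }
    )
    # frequency-class mix per provenance class: described variants sit at
    # higher frequencies, novel ones are mostly rare/private
    freq_class_mix: dict = field(
        default_factory=lambda: {
            Provenance.KNOWN_DB: {
                FrequencyClass.COMMON: 0.90,
                FrequencyClass.RARE: 0.07,
                FrequencyClass.PRIVATE: 0.03,
            },
            Provenance.NEWLY_RELEASED_ONLY: {
                FrequencyClass.COMMON: 0.60,
                FrequencyClass.RARE: 0.25,
                FrequencyClass.PRIVATE: 0.15,
            },
            Provenance.NOVEL: {
                FrequencyClass.COMMON: 0.27,
                FrequencyClass.RARE: 0.23,
                FrequencyClass.PRIVATE: 0.50,
            },
        }
    )
    consequence_weights: dict = field(
        default_factory=lambda: {
            Consequence.INTRONIC: 0.63,
            Consequence.SPLICE_SITE: 0.10,
            Consequence.FRAMESHIFT_CODING: 0.09,
            Consequence.NON_SYNONYMOUS_CODING: 0.07,
            Consequence.THREE_PRIME_UTR: 0.05,
            Consequence.FIVE_PRIME_UTR: 0.025,
            Consequence.OTHER: 0.02,
            Consequence.ESSENTIAL_SPLICE_SITE: 0.01,
            Consequence.STOP: 0.005,
        }
    )

    common_freq_threshold: float = 0.05
    db_jitter_min: int = 0
    db_jitter_max: int = 10
    min_variant_spacing: int = 40

    validation_panel_sizes: dict = field(
        default_factory=lambda: {
            FrequencyClass.COMMON: 82,
            FrequencyClass.PRIVATE: 78,
        }
    )
    validation_tp_rates: dict = field(
        default_factory=lambda: {
            FrequencyClass.COMMON: 66 / 82,
            FrequencyClass.RARE: 0.90,
            FrequencyClass.PRIVATE: 75 / 78,
        }
    )

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0 or self.variants_per_gene <= 0:
            raise UnsatisfiableTargetError("counts must be positive")
        if not 0 <= self.n_familial <= self.n_samples:
            raise UnsatisfiableTargetError("n_familial out of range")
        if abs(sum(self.provenance_mix.values()) - 1) > 1e-9:
            raise UnsatisfiableTargetError("provenance_mix must sum to 1")
        for prov, mix in self.freq_class_mix.items():
            if abs(sum(mix.values()) - 1) > 1e-9:
                raise UnsatisfiableTargetError(f"freq_class_mix[{prov}] must sum to 1")
        if abs(sum(self.consequence_weights.values()) - 1) > 1e-9:
            raise UnsatisfiableTargetError("consequence_weights must sum to 1")
        # with 2N alleles, two carriers already give frequency 2/(2N): the
        # RARE class (non-private, freq < threshold) needs 2/(2N) < threshold
        min_nonprivate_freq = 2 / (2 * self.n_samples)
        rare_requested = any(
            mix.get(FrequencyClass.RARE, 0) > 0 for mix in self.freq_class_mix.values()
        )
        if rare_requested and min_nonprivate_freq >= self.common_freq_threshold:
            raise UnsatisfiableTargetError(
                f"RARE class unreachable with n_samples={self.n_samples}: two "
                f"carriers already give frequency {min_nonprivate_freq:.3f} >= "
                f"threshold {self.common_freq_threshold}; set the RARE "
                "proportions to 0 or enlarge the cohort"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(1, self.n_samples + 1)]

    @property
    def sample_labels(self) -> dict[str, str]:
        ids = self.sample_ids
        return {
            s: ("familial" if i < self.n_familial else "sporadic")
            for i, s in enumerate(ids)
        }


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, stage])


def _max_gene_span(config: SimulationConfig) -> int:
    n_ex = config.exon_count_range[1]
    return (
        n_ex * config.cds_exon_len_range[1]
        + (n_ex - 1) * config.intron_len_range[1]
        + 2 * config.utr_len_range[1]
    )


# ---------------------------------------------------------------------------
# reference


def generate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[tuple[str, int, int, str]]]:
    """Random contig with interspersed homopolymer/dinucleotide tracts.

    Returns (contigs, tracts) where each tract is (chrom, start, end, unit)
    in 1-based closed coordinates.  Deterministic for a given seed.
    """
    rng = _stage_rng(config, 1)
    length = config.contig_length
    if length is None:
        length = config.n_genes * (_max_gene_span(config) + config.intergenic_bp) + config.intergenic_bp
    seq = rng.choice(_BASES, size=length)
    tracts: list[tuple[str, int, int, str]] = []
    if config.repeat_density > 0:
        n_tracts = rng.binomial(length, config.repeat_density)
        starts = np.sort(rng.integers(1, max(2, length - 30), size=n_tracts))
        for s in starts:
            tract_len = int(rng.integers(*config.repeat_tract_len_range, endpoint=True))
            unit = "".join(rng.choice(_BASES, size=int(rng.integers(1, 3))))
            tract = (unit * (tract_len // len(unit) + 1))[:tract_len]
            end = min(int(s) + tract_len - 1, length)
            seq[s - 1 : end] = list(tract[: end - int(s) + 1])
            tracts.append((config.contig, int(s), end, unit))
    return {config.contig: "".join(seq)}, tracts


# ---------------------------------------------------------------------------
# gene models and the independent feature map


def _paint_feature_map(
    tx: TranscriptModel, config: AnalysisConfig
) -> dict[int, Consequence]:
    """Base -> category a 1 bp deletion at that base receives.

    Painted in increasing precedence (OTHER < INTRONIC < UTR < SPLICE_SITE
    < coding < ESSENTIAL_SPLICE_SITE), so later layers overwrite earlier
    ones; built purely from interval arithmetic, independently of the
    annotator's decision procedure.
    """
    fmap: dict[int, Consequence] = {}
    flank = config.upstream_downstream_bp
    for p in range(max(1, tx.start - flank), tx.end + flank + 1):
        fmap[p] = Consequence.OTHER
    for s, e in tx.introns:
        for p in range(s, e + 1):
            fmap[p] = Consequence.INTRONIC
    cds = set()
    for s, e in tx.cds_intervals():
        cds.update(range(s, e + 1))
    for s, e in tx.exons:
        for p in range(s, e + 1):
            if p in cds:
                continue
            if tx.strand == "+":
                cat = (
                    Consequence.FIVE_PRIME_UTR
                    if p < tx.cds_start
                    else Consequence.THREE_PRIME_UTR
                )
            else:
                cat = (
                    Consequence.THREE_PRIME_UTR
                    if p < tx.cds_start
                    else Consequence.FIVE_PRIME_UTR
                )
            fmap[p] = cat
    ess = config.essential_splice_intron_bp
    sri = config.splice_region_intron_bp
    sre = config.splice_region_exon_bp
    for s, e in tx.introns:
        for p in list(range(s + ess, s + sri)) + list(range(e - sri + 1, e - ess + 1)):
            if s <= p <= e:
                fmap[p] = Consequence.SPLICE_SITE
        for p in list(range(s - sre, s)) + list(range(e + 1, e + 1 + sre)):
            if tx.start <= p <= tx.end and p not in cds:
                fmap[p] = Consequence.SPLICE_SITE
    for p in cds:
        fmap[p] = Consequence.FRAMESHIFT_CODING
    for s, e in tx.introns:
        for p in list(range(s, s + ess)) + list(range(e - ess + 1, e + 1)):
            fmap[p] = Consequence.ESSENTIAL_SPLICE_SITE
    return fmap


def generate_gene_models(
    reference: dict[str, str],
    config: SimulationConfig,
    annot_config: AnalysisConfig | None = None,
) -> tuple[dict[str, str], list[TranscriptModel], dict[str, dict[int, Consequence]]]:
    """Place non-overlapping multi-exon genes and stamp their coding
    sequence into the contig.

    Every CDS starts with ATG, ends with a stop codon, contains no internal
    stop, and has length a multiple of 3; splice dinucleotides (GT/AG) are
    stamped strand-aware at intron edges.  Returns the updated contigs, the
    transcript models, and per-transcript base-to-category feature maps.
    """
    annot_config = annot_config or AnalysisConfig()
    rng = _stage_rng(config, 2)
    chrom = config.contig
    seq = list(reference[chrom])
    transcripts: list[TranscriptModel] = []
    feature_maps: dict[str, dict[int, Consequence]] = {}

    cursor = config.intergenic_bp
    for g in range(config.n_genes):
        n_ex = int(rng.integers(*config.exon_count_range, endpoint=True))
        cds_lens = [
            int(rng.integers(*config.cds_exon_len_range, endpoint=True))
            for _ in range(n_ex)
        ]
        excess = sum(cds_lens) % 3
        cds_lens[-1] -= excess
        u5 = int(rng.integers(*config.utr_len_range, endpoint=True))
        u3 = int(rng.integers(*config.utr_len_range, endpoint=True))
        introns = [
            int(rng.integers(*config.intron_len_range, endpoint=True))
            for _ in range(n_ex - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        left_utr, right_utr = (u5, u3) if strand == "+" else (u3, u5)

        exon_lens = list(cds_lens)
        exon_lens[0] += left_utr
        exon_lens[-1] += right_utr
        start = cursor + 1
        exons = []
        p = start
        for i, el in enumerate(exon_lens):
            exons.append((p, p + el - 1))
            p += el
            if i < n_ex - 1:
                p += introns[i]
        end = exons[-1][1]
        if end + config.intergenic_bp > len(seq):
            raise UnsatisfiableTargetError(
                f"gene {g} does not fit: contig too short ({len(seq)} bp)"
            )
        cds_start = start + left_utr
        cds_end = end - right_utr
        tx = TranscriptModel(
            transcript_id=f"tx{g:04d}",
            gene_id=f"gene{g:04d}",
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            cds_start=cds_start,
            cds_end=cds_end,
        )

        # stamp CDS: ATG + non-stop codons + stop, in transcript orientation
        pieces = tx.cds_intervals()
        total = sum(e - s + 1 for s, e in pieces)
        n_codons = total // 3
        body = [
            _NON_STOP_CODONS[int(i)]
            for i in rng.integers(0, len(_NON_STOP_CODONS), size=n_codons - 2)
        ]
        desired = "ATG" + "".join(body) + _STOPS[int(rng.integers(0, 3))]
        genomic = desired if strand == "+" else revcomp(desired)
        k = 0
        for s, e in pieces:
            for pos in range(s, e + 1):
                seq[pos - 1] = genomic[k]
                k += 1
        # splice dinucleotides at intron edges (donor GT / acceptor AG)
        for s, e in tx.introns:
            if strand == "+":
                seq[s - 1 : s + 1] = ["G", "T"]
                seq[e - 2 : e] = ["A", "G"]
            else:
                seq[s - 1 : s + 1] = ["C", "T"]
                seq[e - 2 : e] = ["A", "C"]

        transcripts.append(tx)
        feature_maps[tx.transcript_id] = _paint_feature_map(tx, annot_config)
        cursor = end + config.intergenic_bp

    return {chrom: "".join(seq)}, transcripts, feature_maps


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class SimulatedCohort:
    cohort: CohortCallSet
    known_db: VariantDatabase
    newly_released_db: VariantDatabase
    truth: pd.DataFrame


def _draw_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    while True:
        l = int(rng.geometric(config.indel_len_p))
        if l <= config.max_indel_len:
            return l


def _cds_maps(tx: TranscriptModel) -> tuple[dict[int, int], dict[int, int]]:
    """genomic->CDS index and its inverse, transcript orientation."""
    g2c: dict[int, int] = {}
    i = 0
    for s, e in tx.cds_intervals():
        for g in range(s, e + 1):
            g2c[g] = i
            i += 1
    if tx.strand == "-":
        n = i
        g2c = {g: n - 1 - j for g, j in g2c.items()}
    c2g = {j: g for g, j in g2c.items()}
    return g2c, c2g


def _place_variant(
    rng: np.random.Generator,
    tx: TranscriptModel,
    fmap: dict[int, Consequence],
    category: Consequence,
    config: SimulationConfig,
    reference: DictReference,
    used: list[int],
) -> NormalizedIndel | None:
    """One placement attempt for the target category; None on failure."""
    cat_positions = [p for p, c in fmap.items() if c is category]
    if not cat_positions:
        return None

    if category in (Consequence.NON_SYNONYMOUS_CODING, Consequence.STOP):
        g2c, c2g = _cds_maps(tx)
        n_codons = len(g2c) // 3
        if category is Consequence.STOP:
            j = int(rng.integers(1, n_codons - 1))  # internal codon boundary
            ci = 3 * j
            g_hi = c2g[ci]
            g_lo = c2g[ci - 1]
            if abs(g_hi - g_lo) != 1:
                return None  # boundary falls on an intron
            pos = min(g_lo, g_hi)
            stop = _STOPS[int(rng.integers(0, 3))]
            alt = stop if tx.strand == "+" else revcomp(stop)
            variant = NormalizedIndel(tx.chrom, pos, "", alt)
        else:
            insert = rng.random() < config.insertion_prob
            k = min(4, max(1, round(_draw_length(rng, config) / 3)))
            if insert:
                j = int(rng.integers(1, n_codons - 1))
                ci = 3 * j
                g_hi, g_lo = c2g[ci], c2g[ci - 1]
                if abs(g_hi - g_lo) != 1:
                    return None
                pos = min(g_lo, g_hi)
                codons = "".join(
                    _NON_STOP_CODONS[int(i)]
                    for i in rng.integers(0, len(_NON_STOP_CODONS), size=k)
                )
                alt = codons if tx.strand == "+" else revcomp(codons)
                variant = NormalizedIndel(tx.chrom, pos, "", alt)
            else:
                if n_codons - 2 <= k:
                    return None
                j = int(rng.integers(1, n_codons - 1 - k))  # skip start & stop
                idxs = [c2g[i] for i in range(3 * j, 3 * j + 3 * k)]
                lo, hi = min(idxs), max(idxs)
                if hi - lo != 3 * k - 1:
                    return None  # spans an intron
                ref_seq = reference.fetch(tx.chrom, lo, hi)
                variant = NormalizedIndel(tx.chrom, lo, ref_seq, "")
    else:
        insert = (
            rng.random() < config.insertion_prob
            and category is not Consequence.ESSENTIAL_SPLICE_SITE
        )
        if category is Consequence.ESSENTIAL_SPLICE_SITE:
            length = int(rng.integers(1, 3))
        elif category is Consequence.FRAMESHIFT_CODING:
            while True:
                length = _draw_length(rng, config)
                if length % 3 != 0:
                    break
        else:
            length = _draw_length(rng, config)
        anchor = int(cat_positions[int(rng.integers(0, len(cat_positions)))])
        if insert:
            # insertion between anchor and anchor+1: both sides in-category
            if fmap.get(anchor + 1) is not category:
                return None
            alt = "".join(rng.choice(_BASES, size=length))
            variant = NormalizedIndel(tx.chrom, anchor, "", alt)
        else:
            if any(fmap.get(anchor + i) is not category for i in range(length)):
                return None
            ref_seq = reference.fetch(tx.chrom, anchor, anchor + length - 1)
            variant = NormalizedIndel(tx.chrom, anchor, ref_seq, "")

    # left-alignment stability: the recorded truth assumes the placement is
    # already canonical
    if left_align(variant, reference) != variant:
        return None
    if variant.pos < 2:
        return None
    lo, hi = variant.footprint
    span_lo, span_hi = min(lo, variant.pos), max(hi, variant.pos + 1)
    i = np.searchsorted(used, span_lo - config.min_variant_spacing)
    j = np.searchsorted(used, span_hi + config.min_variant_spacing)
    if i != j:
        return None  # too close to an existing variant
    return variant


def _draw_genotypes(
    rng: np.random.Generator,
    freq_class: FrequencyClass,
    config: SimulationConfig,
    max_tries: int = 500,
) -> np.ndarray:
    """Per-sample alt-allele dosages (0/1/2) realising the target class."""
    n = config.n_samples
    thr = config.common_freq_threshold
    if freq_class is FrequencyClass.PRIVATE:
        dosage = np.zeros(n, dtype=int)
        dosage[int(rng.integers(0, n))] = 1
        return dosage
    for _ in range(max_tries):
        if freq_class is FrequencyClass.COMMON:
            f = rng.uniform(thr, 0.35)
        else:
            f = rng.uniform(1.0 / (2 * n), thr)
        dosage = rng.binomial(2, f, size=n)
        carriers = int((dosage > 0).sum())
        realized = dosage.sum() / (2 * n)
        if carriers < 2:
            continue
        if freq_class is FrequencyClass.COMMON and realized >= thr:
            return dosage
        if freq_class is FrequencyClass.RARE and realized < thr:
            return dosage
    raise UnsatisfiableTargetError(
        f"could not realise frequency class {freq_class} with n={n}"
    )


def generate_cohort(
    reference: dict[str, str],
    transcripts: Sequence[TranscriptModel],
    feature_maps: Mapping[str, Mapping[int, Consequence]],
    config: SimulationConfig,
) -> SimulatedCohort:
    """Place variants, draw genotypes, and build the jittered databases.

    Database copies of KNOWN / NEWLY_RELEASED variants keep the call's
    allele sequences but sit ``db_jitter_min..db_jitter_max`` bp downstream
    (right-shifted, un-normalized representations).  The truth table records
    provenance, frequency class, consequence and the database offset per
    variant.
    """
    rng = _stage_rng(config, 3)
    ref = DictReference(reference)
    sample_ids = config.sample_ids
    weights = {c: w for c, w in config.consequence_weights.items() if w > 0}
    cats = list(weights)
    cat_p = np.array([weights[c] for c in cats], dtype=float)
    cat_p /= cat_p.sum()
    provs = list(config.provenance_mix)
    prov_p = np.array([config.provenance_mix[p] for p in provs], dtype=float)

    used_positions: list[int] = []
    calls: list[SampleCall] = []
    known_records: list[NormalizedIndel] = []
    newly_records: list[NormalizedIndel] = []
    truth_rows = []

    for tx in transcripts:
        fmap = feature_maps[tx.transcript_id]
        for _ in range(config.variants_per_gene):
            variant = None
            category = None
            for _attempt in range(300):
                category = cats[int(rng.choice(len(cats), p=cat_p))]
                variant = _place_variant(
                    rng, tx, fmap, category, config, ref, used_positions
                )
                if variant is not None:
                    break
            if variant is None:
                raise UnsatisfiableTargetError(
                    f"could not place a variant in {tx.transcript_id} "
                    f"(last target {category})"
                )
            lo, hi = variant.footprint
            for p in sorted({min(lo, variant.pos), max(hi, variant.pos + 1)}):
                used_positions.insert(int(np.searchsorted(used_positions, p)), p)

            prov = provs[int(rng.choice(len(provs), p=prov_p))]
            fmix = config.freq_class_mix[prov]
            fcs = list(fmix)
            fc = fcs[int(rng.choice(len(fcs), p=np.array([fmix[c] for c in fcs])))]
            dosage = _draw_genotypes(rng, fc, config)
            carriers = int((dosage > 0).sum())
            freq = dosage.sum() / (2 * config.n_samples)
            realized_fc = classify_frequency(carriers, freq, config.common_freq_threshold)
            for i in np.flatnonzero(dosage):
                calls.append(
                    SampleCall(
                        sample_ids[int(i)],
                        variant,
                        Genotype.HET if dosage[i] == 1 else Genotype.HOM_ALT,
                    )
                )

            offset = None
            if prov is not Provenance.NOVEL:
                offset = int(
                    rng.integers(config.db_jitter_min, config.db_jitter_max, endpoint=True)
                )
                shifted = NormalizedIndel(
                    variant.chrom, variant.pos + offset, variant.ref_seq, variant.alt_seq
                )
                (known_records if prov is Provenance.KNOWN_DB else newly_records).append(
                    shifted
                )
            truth_rows.append(
                {
                    "chrom": variant.chrom,
                    "pos": variant.pos,
                    "ref_seq": variant.ref_seq,
                    "alt_seq": variant.alt_seq,
                    "length": variant.length,
                    "gene": tx.gene_id,
                    "transcript": tx.transcript_id,
                    "consequence": category.name,
                    "provenance": prov.value,
                    "freq_class": realized_fc.value,
                    "freq": freq,
                    "carrier_count": carriers,
                    "allele_count": int(dosage.sum()),
                    "db_offset": offset,
                }
            )

    cohort = CohortCallSet(samples=config.sample_labels, calls=calls)
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(
        cohort=cohort,
        known_db=VariantDatabase("known", known_records),
        newly_released_db=VariantDatabase("newly_released", newly_records),
        truth=truth,
    )


def generate_validation_panel(
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Sanger-style validation panel with one carrier and one reference
    sample per variant.

    Carrier confirmation outcomes are Bernoulli at the per-frequency-class
    true-positive rates; reference samples always confirm negative (no
    false negatives), matching the validation design being emulated.
    """
    rng = _stage_rng(config, 4)
    rows = []
    for fc, size in config.validation_panel_sizes.items():
        pool = truth[truth["freq_class"] == fc.value]
        if len(pool) < size:
            raise UnsatisfiableTargetError(
                f"validation panel for {fc.value} needs {size} variants, "
                f"only {len(pool)} generated"
            )
        pick = pool.iloc[rng.choice(len(pool), size=size, replace=False)]
        rate = config.validation_tp_rates[fc]
        for _, row in pick.iterrows():
            rows.append(
                {
                    "chrom": row["chrom"],
                    "pos": row["pos"],
                    "ref_seq": row["ref_seq"],
                    "alt_seq": row["alt_seq"],
                    "freq_class": fc.value,
                    "carrier_confirmed": "yes" if rng.random() < rate else "no",
                    "reference_confirmed": "yes",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: dict[str, str]
    tracts: list[tuple[str, int, int, str]]
    transcripts: list[TranscriptModel]
    feature_maps: dict[str, dict[int, Consequence]]
    cohort: CohortCallSet
    known_db: VariantDatabase
    newly_released_db: VariantDatabase
    truth: pd.DataFrame
    validation: pd.DataFrame

    def capture_regions(self) -> list[tuple[str, int, int]]:
        """BED intervals (0-based half-open) covering gene loci +- margin."""
        margin = AnalysisConfig().upstream_downstream_bp + 100
        return [
            (tx.chrom, max(0, tx.start - margin - 1), tx.end + margin)
            for tx in self.transcripts
        ]


def simulate_dataset(
    config: SimulationConfig,
    annot_config: AnalysisConfig | None = None,
) -> SimulatedDataset:
    reference, tracts = generate_reference(config)
    reference, transcripts, feature_maps = generate_gene_models(
        reference, config, annot_config
    )
    sim = generate_cohort(reference, transcripts, feature_maps, config)
    validation = generate_validation_panel(sim.truth, config)
    return SimulatedDataset(
        config=config,
        reference=reference,
        tracts=tracts,
        transcripts=transcripts,
        feature_maps=feature_maps,
        cohort=sim.cohort,
        known_db=sim.known_db,
        newly_released_db=sim.newly_released_db,
        truth=sim.truth,
        validation=validation,
    )


def _vcf_record(variant: NormalizedIndel, reference: DictReference) -> tuple[str, int, str, str]:
    """Anchor-free indel -> (chrom, POS, REF, ALT) in VCF convention."""
    if variant.ref_seq == "":
        anchor = reference.fetch(variant.chrom, variant.pos, variant.pos)
        return (variant.chrom, variant.pos, anchor, anchor + variant.alt_seq)
    anchor = reference.fetch(variant.chrom, variant.pos - 1, variant.pos - 1)
    return (
        variant.chrom,
        variant.pos - 1,
        anchor + variant.ref_seq,
        anchor + variant.alt_seq,
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA, GFF3, per-sample VCFs, database VCFs, BED, truth and
    validation TSVs plus a manifest; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = DictReference(dataset.reference)
    contig_lengths = {c: len(s) for c, s in dataset.reference.items()}
    paths: dict[str, Path] = {}

    paths["fasta"] = out / "reference.fa"
    ikio.write_fasta(paths["fasta"], dataset.reference)

    paths["gff3"] = out / "genes.gff3"
    write_gff3(dataset.transcripts, paths["gff3"])

    paths["bed"] = out / "capture.bed"
    with open(paths["bed"], "w") as fh:
        for chrom, start, end in dataset.capture_regions():
            fh.write(f"{chrom}\t{start}\t{end}\n")

    vcf_dir = out / "calls"
    vcf_dir.mkdir(exist_ok=True)
    by_sample: dict[str, list[SampleCall]] = {}
    for call in dataset.cohort.calls:
        by_sample.setdefault(call.sample_id, []).append(call)
    vcf_paths = []
    for sample in dataset.cohort.samples:
        records = []
        genotypes = {}
        for i, call in enumerate(by_sample.get(sample, [])):
            records.append(_vcf_record(call.variant, ref))
            genotypes[i] = {
                sample: (0, 1) if call.genotype is Genotype.HET else (1, 1)
            }
        p = vcf_dir / f"{sample}.vcf"
        ikio.write_vcf(p, contig_lengths, records, genotypes, samples=[sample])
        vcf_paths.append(p)
    paths["calls_dir"] = vcf_dir

    for name, db in (
        ("known", dataset.known_db),
        ("newly_released", dataset.newly_released_db),
    ):
        recs = [_vcf_record(v, ref) for v in db]
        p = out / f"db_{name}.vcf"
        ikio.write_vcf(p, contig_lengths, recs)
        paths[f"db_{name}"] = p

    paths["truth"] = out / "truth.tsv"
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["validation"] = out / "validation.tsv"
    dataset.validation.to_csv(paths["validation"], sep="\t", index=False)

    paths["manifest"] = out / "manifest.json"
    cfg = dataclasses.asdict(dataset.config)
    manifest = {
        "seed": dataset.config.rng_seed,
        "config": {k: _jsonable(v) for k, v in cfg.items()},
        "n_variants": int(len(dataset.truth)),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths


def _jsonable(v):
    if isinstance(v, dict):
        return {getattr(k, "value", getattr(k, "name", str(k))): _jsonable(x) for k, x in v.items()}
    if isinstance(v, tuple):
        return list(v)
    return v


def write_gff3(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in transcripts:
            gid, tid = tx.gene_id, tx.transcript_id
            fh.write(
                f"{tx.chrom}\tindelkit\tgene\t{tx.start}\t{tx.end}\t.\t{tx.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{tx.chrom}\tindelkit\tmRNA\t{tx.start}\t{tx.end}\t.\t{tx.strand}\t.\tID={tid};Parent={gid}\n"
            )
            for i, (s, e) in enumerate(tx.exons, 1):
                fh.write(
                    f"{tx.chrom}\tindelkit\texon\t{s}\t{e}\t.\t{tx.strand}\t.\tID={tid}.exon{i};Parent={tid}\n"
                )
            pieces = tx.cds_intervals()
            ordered = pieces if tx.strand == "+" else tuple(reversed(pieces))
            phase = 0
            for i, (s, e) in enumerate(ordered, 1):
                fh.write(
                    f"{tx.chrom}\tindelkit\tCDS\t{s}\t{e}\t.\t{tx.strand}\t{phase}\tID={tid}.cds{i};Parent={tid}\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            if tx.is_coding:
                for s, e in tx.exons:
                    for lo, hi, side in (
                        (s, min(e, tx.cds_start - 1), "left"),
                        (max(s, tx.cds_end + 1), e, "right"),
                    ):
                        if lo > hi:
                            continue
                        if side == "left":
                            feat = (
                                "five_prime_UTR" if tx.strand == "+" else "three_prime_UTR"
                            )
                        else:
                            feat = (
                                "three_prime_UTR" if tx.strand == "+" else "five_prime_UTR"
                            )
                        fh.write(
                            f"{tx.chrom}\tindelkit\t{feat}\t{lo}\t{hi}\t.\t{tx.strand}\t.\tID={tid}.{feat}.{lo};Parent={tid}\n"
                        )
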