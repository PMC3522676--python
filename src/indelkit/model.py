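"""Core domain types for exome INDEL characterisation.

Coordinate conventions
----------------------
All positions are 1-based and anchor-free: ``ref_seq``/``alt_seq`` never
include the padding base that VCF prepends to indel alleles.  For a deletion,
``pos`` is the first deleted reference base; for an insertion, ``pos`` is the
reference base immediately 5' of the insertion point (the inserted sequence
sits between ``pos`` and ``pos + 1``).  Conversion to and from VCF and BED
conventions happens exactly once, at the I/O boundary (:mod:`indelkit.io`).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from typing import Iterable, Iterator, Mapping, Sequence


class IndelKind(str, Enum):
    INSERTION = "insertion"
    DELETION = "deletion"
    COMPLEX = "complex"


@dataclass(frozen=True, order=True)
class NormalizedIndel:
    """A single insertion/deletion in anchor-free 1-based coordinates.

    ``length`` is signed: positive for insertions, negative for deletions,
    ``len(alt_seq) - len(ref_seq)`` in general.
    """

    chrom: str
    pos: int
    ref_seq: str
    alt_seq: str

    def __post_init__(self) -> None:
        if self.ref_seq == "" and self.alt_seq == "":
            raise ValueError("indel must have a non-empty ref or alt sequence")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")

    @property
    def kind(self) -> IndelKind:
        if self.ref_seq == "":
            return IndelKind.INSERTION
        if self.alt_seq == "":
            return IndelKind.DELETION
        return IndelKind.COMPLEX

    @property
    def length(self) -> int:
        return len(self.alt_seq) - len(self.ref_seq)

    @property
    def allele_seq(self) -> str:
        """The indel's own sequence: inserted bases, or deleted bases."""
        return self.alt_seq if self.ref_seq == "" else self.ref_seq

    @property
    def footprint(self) -> tuple[int, int]:
        """1-based closed interval of reference bases consumed.

        For pure insertions the footprint is empty; the returned interval is
        ``(pos + 1, pos)`` (end < start) so that overlap arithmetic treats it
        as a zero-width point between ``pos`` and ``pos + 1``.
        """
        if self.ref_seq == "":
            return (self.pos + 1, self.pos)
        return (self.pos, self.pos + len(self.ref_seq) - 1)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_seq, self.alt_seq)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.pos}:{self.ref_seq or '-'}>{self.alt_seq or '-'}"


class Genotype(str, Enum):
    """Carrier states only; non-carriers are simply absent from a call set."""

    HET = "het"
    HOM_ALT = "hom_alt"

    @property
    def allele_count(self) -> int:
        return 1 if self is Genotype.HET else 2


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    variant: NormalizedIndel
    genotype: Genotype


@dataclass
class CohortCallSet:
    """Per-sample carrier calls for a cohort.

    ``samples`` maps every sample id to its cohort-subgroup label (for this
    study design: ``"familial"`` or ``"sporadic"``); samples with no calls
    still count toward ``n_samples`` and hence toward allele frequencies.
    """

    samples: dict[str, str]
    calls: list[SampleCall] = field(default_factory=list)
    skipped_non_indel: int = 0
    skipped_bad_ploidy: int = 0
    missing_genotypes: int = 0

    def __post_init__(self) -> None:
        seen: set[tuple[str, tuple]] = set()
        for call in self.calls:
            if call.sample_id not in self.samples:
                raise ValueError(f"call for unknown sample {call.sample_id!r}")
            k = (call.sample_id, call.variant.key)
            if k in seen:
                raise ValueError(f"duplicate call {k}")
            seen.add(k)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def variants(self) -> list[NormalizedIndel]:
        """Distinct variants, ordered by (chrom, pos, ref, alt)."""
        return sorted({c.variant for c in self.calls})

    def calls_by_variant(self) -> dict[NormalizedIndel, list[SampleCall]]:
        out: dict[NormalizedIndel, list[SampleCall]] = {}
        for call in self.calls:
            out.setdefault(call.variant, []).append(call)
        return out

    def subset_samples(self, keep: Iterable[str]) -> "CohortCallSet":
        keep = set(keep)
        unknown = keep - set(self.samples)
        if unknown:
            raise ValueError(f"unknown samples: {sorted(unknown)}")
        return CohortCallSet(
            samples={s: g for s, g in self.samples.items() if s in keep},
            calls=[c for c in self.calls if c.sample_id in keep],
        )

    def exclude_subgroup(self, label: str) -> "CohortCallSet":
        keep = [s for s, g in self.samples.items() if g != label]
        if not keep:
            raise ValueError(f"excluding subgroup {label!r} empties the cohort")
        return self.subset_samples(keep)

    def map_variants(self, fn) -> "CohortCallSet":
        """Return a copy with ``fn`` applied to every call's variant."""
        cache: dict[NormalizedIndel, NormalizedIndel] = {}
        new_calls = []
        for c in self.calls:
            if c.variant not in cache:
                cache[c.variant] = fn(c.variant)
            new_calls.append(SampleCall(c.sample_id, cache[c.variant], c.genotype))
        return CohortCallSet(
            samples=dict(self.samples),
            calls=new_calls,
            skipped_non_indel=self.skipped_non_indel,
            skipped_bad_ploidy=self.skipped_bad_ploidy,
            missing_genotypes=self.missing_genotypes,
        )


class VariantDatabase:
    """Position-indexed collection of known indels.

    Records are kept per-chromosome in position-sorted order; ``query`` is a
    bisect range scan, equivalent to (and tested against) a linear scan.
    """

    def __init__(self, name: str, records: Iterable[NormalizedIndel] = ()) -> None:
        self.name = name
        self._by_chrom: dict[str, list[NormalizedIndel]] = {}
        self._pos_index: dict[str, list[int]] = {}
        by_chrom: dict[str, list[NormalizedIndel]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: (r.pos, r.ref_seq, r.alt_seq))
            self._by_chrom[chrom] = recs
            self._pos_index[chrom] = [r.pos for r in recs]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self) -> Iterator[NormalizedIndel]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def query(self, chrom: str, lo: int, hi: int) -> list[NormalizedIndel]:
        """All records with ``lo <= pos <= hi`` on ``chrom``, position-sorted."""
        recs = self._by_chrom.get(chrom)
        if not recs:
            return []
        positions = self._pos_index[chrom]
        i = bisect.bisect_left(positions, lo)
        j = bisect.bisect_right(positions, hi)
        return recs[i:j]


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered exon chain with optional CDS bounds.

    Exons are 1-based closed genomic intervals sorted by coordinate
    regardless of strand.  ``cds_start``/``cds_end`` are genomic bounds
    (``cds_start <= cds_end``); both are ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"malformed exon ({s}, {e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must both be set or both None")
        if self.cds_start is not None:
            if self.cds_start > self.cds_end:
                raise ValueError("cds_start > cds_end")
            if not self._covered(self.cds_start) or not self._covered(self.cds_end):
                raise ValueError("CDS bounds must lie within the exon union")

    def _covered(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, 1-based closed."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exon pieces inside [cds_start, cds_end], genomic order."""
        if not self.is_coding:
            return ()
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                out.append((lo, hi))
        return tuple(out)


class Consequence(IntEnum):
    """The ten consequence categories, ordered by decreasing severity.

    The integer value is the severity rank (lower = more severe), so
    ``min(...)`` picks the most severe category.
    """

    STOP = 0
    FRAMESHIFT_CODING = 1
    ESSENTIAL_SPLICE_SITE = 2
    COMPLEX_INDEL = 3
    NON_SYNONYMOUS_CODING = 4
    SPLICE_SITE = 5
    FIVE_PRIME_UTR = 6
    THREE_PRIME_UTR = 7
    INTRONIC = 8
    OTHER = 9


@dataclass(frozen=True)
class ConsequenceCall:
    variant: NormalizedIndel
    transcript_id: str
    category: Consequence


class Provenance(str, Enum):
    """Whether a called variant was already described somewhere."""

    KNOWN_DB = "KNOWN_DB"
    NEWLY_RELEASED_ONLY = "NEWLY_RELEASED_ONLY"
    NOVEL = "NOVEL"


class FrequencyClass(str, Enum):
    COMMON = "COMMON"
    RARE = "RARE"
    PRIVATE = "PRIVATE"


@dataclass
class AnalysisConfig:
    """Thresholds for the whole pipeline.

    match_window_bp
        half-width (bp) of the start-position window used when deciding
        whether a call is already described in a database.
    distance_window_bp
        extended half-width used only for distance profiling.
    common_freq_threshold
        non-reference allele frequency at or above which a variant is COMMON.
    essential_splice_intron_bp
        intronic bases at each intron end that form the essential splice site
        (donor GT / acceptor AG).
    splice_region_intron_bp / splice_region_exon_bp
        extent of the weaker splice-region class into the intron and exon.
    upstream_downstream_bp
        flank around a transcript within which a variant is still reported
        (category OTHER).
    """

    match_window_bp: int = 10
    distance_window_bp: int = 100
    common_freq_threshold: float = 0.05
    max_indel_len: int = 15
    essential_splice_intron_bp: int = 2
    splice_region_intron_bp: int = 8
    splice_region_exon_bp: int = 3
    upstream_downstream_bp: int = 5000
    p_adjust_method: str = "fdr_bh"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "match_window_bp",
            "distance_window_bp",
            "max_indel_len",
            "essential_splice_intron_bp",
            "splice_region_intron_bp",
            "splice_region_exon_bp",
            "upstream_downstream_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.common_freq_threshold < 1.0:
            raise ValueError("common_freq_threshold must be in (0, 1)")
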