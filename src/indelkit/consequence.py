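"""Transcript-model consequence annotation for small indels.

Reconstructs legacy-style consequence semantics against local gene models:
the essential splice site is the two intronic bases at each intron edge
(donor GT / acceptor AG), the splice region extends 3-8 bp into the intron
and 3 bp into the exon, and an in-frame coding indel is called
NON_SYNONYMOUS_CODING (the historical term predating "inframe insertion /
deletion").  All extents are configurable via :class:`AnalysisConfig`.

Decision order per (variant, transcript) pair, first hit wins:

1. ESSENTIAL_SPLICE_SITE — footprint touches an intron-edge base;
2. COMPLEX_INDEL — footprint spans an exon-intron boundary not already
   caught by the splice class;
3. coding — footprint touches CDS: FRAMESHIFT_CODING when the signed length
   is not a multiple of 3, STOP when an in-frame edit gains a premature stop
   codon or loses the terminal one, otherwise NON_SYNONYMOUS_CODING;
4. SPLICE_SITE — footprint in the weaker splice region;
5. FIVE_PRIME_UTR / THREE_PRIME_UTR — exonic UTR overlap, strand-aware;
6. INTRONIC;
7. OTHER — inside the transcript flank, or overlapping a non-coding
   transcript;
8. no call.

Insertions have an empty reference footprint and are assigned by insertion
point: strictly between two exonic bases they are exonic; exactly at an
exon/intron junction they go to the intron side, preserving the annotated
junction sequence on the exon side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .model import (
    AnalysisConfig,
    Consequence,
    ConsequenceCall,
    IndelKind,
    NormalizedIndel,
    TranscriptModel,
)

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _span_positions(intervals: Iterable[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for s, e in intervals:
        out.update(range(s, e + 1))
    return out


class _TranscriptFeatures:
    """Per-transcript base-level feature sets used by the decision rules."""

    def __init__(self, tx: TranscriptModel, config: AnalysisConfig) -> None:
        self.tx = tx
        ess = config.essential_splice_intron_bp
        sri = config.splice_region_intron_bp
        sre = config.splice_region_exon_bp

        self.exonic = _span_positions(tx.exons)
        self.intronic = _span_positions(tx.introns)
        self.essential: set[int] = set()
        self.splice_region: set[int] = set()
        for s, e in tx.introns:
            self.essential.update(range(s, min(s + ess, e + 1)))
            self.essential.update(range(max(e - ess + 1, s), e + 1))
            self.splice_region.update(range(s + ess, min(s + sri, e + 1)))
            self.splice_region.update(range(max(e - sri + 1, s), e - ess + 1))
            # exonic side of each junction
            self.splice_region.update(range(s - sre, s))
            self.splice_region.update(range(e + 1, e + 1 + sre))
        self.splice_region &= self.exonic | self.intronic
        self.splice_region -= self.essential

        self.cds = _span_positions(tx.cds_intervals())
        utr = self.exonic - self.cds if tx.is_coding else set()
        if tx.is_coding:
            before = {p for p in utr if p < tx.cds_start}
            after = {p for p in utr if p > tx.cds_end}
            self.utr5 = before if tx.strand == "+" else after
            self.utr3 = after if tx.strand == "+" else before
        else:
            self.utr5 = set()
            self.utr3 = set()

        # spliced CDS in transcript orientation with genomic->CDS index map
        self._cds_index: dict[int, int] = {}
        self.cds_seq: str | None = None


def _footprint_positions(variant: NormalizedIndel, feats: _TranscriptFeatures) -> set[int]:
    """Reference bases the variant is attributed to.

    Deletions (and complex indels) own their deleted bases.  An insertion
    between p and p+1 owns both flanking bases unless the pair straddles an
    exon/intron junction, in which case only the intron-side base counts.
    """
    if variant.kind is not IndelKind.INSERTION:
        lo, hi = variant.footprint
        return set(range(lo, hi + 1))
    p = variant.pos
    left_exonic = p in feats.exonic
    right_exonic = (p + 1) in feats.exonic
    left_intronic = p in feats.intronic
    right_intronic = (p + 1) in feats.intronic
    if left_exonic and right_intronic:
        return {p + 1}
    if left_intronic and right_exonic:
        return {p}
    return {p, p + 1}


def _build_cds_seq(feats: _TranscriptFeatures, reference) -> None:
    tx = feats.tx
    pieces = tx.cds_intervals()
    seq = "".join(reference.fetch(tx.chrom, s, e) for s, e in pieces)
    idx = 0
    for s, e in pieces:
        for g in range(s, e + 1):
            feats._cds_index[g] = idx
            idx += 1
    if tx.strand == "-":
        seq = revcomp(seq)
        n = idx
        feats._cds_index = {g: n - 1 - i for g, i in feats._cds_index.items()}
    feats.cds_seq = seq


def _edited_cds(variant: NormalizedIndel, feats: _TranscriptFeatures, reference) -> str | None:
    """Apply an in-frame, fully CDS-contained edit in transcript space.

    Returns None when the edit is not representable (partially outside the
    CDS), in which case the caller falls back to NON_SYNONYMOUS_CODING.
    """
    if feats.cds_seq is None:
        _build_cds_seq(feats, reference)
    cds = feats.cds_seq
    idx = feats._cds_index
    tx = feats.tx
    alt = variant.alt_seq if tx.strand == "+" else revcomp(variant.alt_seq)

    if variant.kind is IndelKind.INSERTION:
        p, q = variant.pos, variant.pos + 1
        if p not in idx or q not in idx:
            return None
        cut = max(idx[p], idx[q])  # insertion point in transcript coordinates
        if abs(idx[p] - idx[q]) != 1:
            return None
        return cds[:cut] + alt + cds[cut:]

    lo, hi = variant.footprint
    if any(g not in idx for g in range(lo, hi + 1)):
        return None
    tx_indices = sorted(idx[g] for g in range(lo, hi + 1))
    if tx_indices != list(range(tx_indices[0], tx_indices[-1] + 1)):
        return None
    a, b = tx_indices[0], tx_indices[-1]
    return cds[:a] + alt + cds[b + 1 :]


def _codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def _stop_effect(ref_cds: str, edited: str) -> bool:
    """True when the edit gains a premature stop or loses the terminal stop."""
    ref_codons = _codons(ref_cds)
    new_codons = _codons(edited)
    if not ref_codons or not new_codons:
        return False
    ref_premature = any(c in _STOP_CODONS for c in ref_codons[:-1])
    new_premature = any(c in _STOP_CODONS for c in new_codons[:-1])
    if new_premature and not ref_premature:
        return True
    if ref_codons[-1] in _STOP_CODONS and new_codons[-1] not in _STOP_CODONS:
        return True
    return False


def annotate(
    variant: NormalizedIndel,
    transcript: TranscriptModel,
    config: AnalysisConfig | None = None,
    reference=None,
) -> ConsequenceCall | None:
    """Assign one consequence category to a (variant, transcript) pair.

    ``reference`` is only needed for the STOP gain/loss check on in-frame
    coding variants; without it such variants fall back to
    NON_SYNONYMOUS_CODING.  Returns None when the variant does not touch the
    transcript or its configured flank.
    """
    config = config or AnalysisConfig()
    if variant.chrom != transcript.chrom:
        return None
    feats = _TranscriptFeatures(transcript, config)
    category = _classify(variant, feats, config, reference)
    if category is None:
        return None
    return ConsequenceCall(variant, transcript.transcript_id, category)


def _classify(
    variant: NormalizedIndel,
    feats: _TranscriptFeatures,
    config: AnalysisConfig,
    reference,
) -> Consequence | None:
    tx = feats.tx
    fp = _footprint_positions(variant, feats)
    in_transcript = any(tx.start <= p <= tx.end for p in fp)

    if not tx.is_coding:
        if in_transcript or _in_flank(fp, tx, config):
            return Consequence.OTHER
        return None

    if fp & feats.essential:
        return Consequence.ESSENTIAL_SPLICE_SITE
    if (fp & feats.exonic) and (fp & feats.intronic):
        return Consequence.COMPLEX_INDEL
    if fp & feats.cds:
        if variant.length % 3 != 0:
            return Consequence.FRAMESHIFT_CODING
        if reference is not None and fp <= feats.cds:
            edited = _edited_cds(variant, feats, reference)
            if edited is not None and feats.cds_seq is not None:
                if _stop_effect(feats.cds_seq, edited):
                    return Consequence.STOP
        return Consequence.NON_SYNONYMOUS_CODING
    if fp & feats.splice_region:
        return Consequence.SPLICE_SITE
    if fp & feats.utr5:
        return Consequence.FIVE_PRIME_UTR
    if fp & feats.utr3:
        return Consequence.THREE_PRIME_UTR
    if fp & feats.intronic:
        return Consequence.INTRONIC
    if _in_flank(fp, tx, config):
        return Consequence.OTHER
    return None


def _in_flank(fp: set[int], tx: TranscriptModel, config: AnalysisConfig) -> bool:
    d = config.upstream_downstream_bp
    return any(tx.start - d <= p <= tx.end + d for p in fp)


def most_severe(calls: Sequence[ConsequenceCall]) -> Consequence:
    """Highest-severity category across transcripts for one variant."""
    if not calls:
        raise ValueError("most_severe of an empty call list")
    return min(c.category for c in calls)


def is_lof(category: Consequence) -> bool:
    """Loss-of-function per the usual frame/stop/essential-splice definition."""
    return category in (
        Consequence.STOP,
        Consequence.FRAMESHIFT_CODING,
        Consequence.ESSENTIAL_SPLICE_SITE,
    )


class ConsequenceAnnotator:
    """Annotates variants against a set of transcripts.

    Transcripts are indexed by flank-extended span in an interval tree;
    per-transcript feature sets are built lazily and cached, so sweeping
    many variants over the same gene models stays cheap.
    """

    def __init__(
        self,
        transcripts: Iterable[TranscriptModel],
        config: AnalysisConfig | None = None,
        reference=None,
    ) -> None:
        self.config = config or AnalysisConfig()
        self.reference = reference
        self._trees: dict[str, IntervalTree] = {}
        self._features: dict[str, _TranscriptFeatures] = {}
        d = self.config.upstream_downstream_bp
        for tx in transcripts:
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            # interval tree is half-open; store [start-d, end+d] inclusive
            tree.addi(max(0, tx.start - d), tx.end + d + 1, tx)

    def _feats(self, tx: TranscriptModel) -> _TranscriptFeatures:
        if tx.transcript_id not in self._features:
            self._features[tx.transcript_id] = _TranscriptFeatures(tx, self.config)
        return self._features[tx.transcript_id]

    def annotate(self, variant: NormalizedIndel) -> list[ConsequenceCall]:
        tree = self._trees.get(variant.chrom)
        if tree is None:
            return []
        lo, hi = variant.footprint
        if lo > hi:  # insertion: probe the insertion point
            lo, hi = variant.pos, variant.pos + 1
        calls = []
        for iv in sorted(tree.overlap(lo, hi + 1), key=lambda iv: iv.data.transcript_id):
            tx: TranscriptModel = iv.data
            cat = _classify(variant, self._feats(tx), self.config, self.reference)
            if cat is not None:
                calls.append(ConsequenceCall(variant, tx.transcript_id, cat))
        return calls

    def most_severe_category(self, variant: NormalizedIndel) -> Consequence | None:
        calls = self.annotate(variant)
        return most_severe(calls) if calls else None
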