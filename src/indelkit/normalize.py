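"""Left-alignment of indels against a reference sequence.

An indel sitting in a repeat tract has many equivalent representations; the
canonical one used throughout this package (and produced by realignment-based
callers) is the representation with the lowest start coordinate that yields
the same alternative haplotype.  The shift algorithm is the standard left
rotation: while the last base of the allele equals the reference base
immediately 5' of the current position, rotate the allele right by one and
step the position down.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Protocol

from .model import IndelKind, NormalizedIndel


class ReferenceAccessor(Protocol):
    """Anything that can hand back reference bases, 1-based inclusive."""

    def fetch(self, chrom: str, start: int, end: int) -> str: ...


class DictReference:
    """In-memory reference; handy for simulation and tests."""

    def __init__(self, seqs: dict[str, str]) -> None:
        self._seqs = {c: s.upper() for c, s in seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq):
            raise IndexError(f"{chrom}:{start}-{end} outside contig of length {len(seq)}")
        return seq[start - 1 : end]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def contigs(self) -> dict[str, str]:
        return dict(self._seqs)


class FastaReference:
    """1-based inclusive fetch over an indexed FASTA (pyfaidx-backed)."""

    def __init__(self, path: str) -> None:
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fa[chrom][start - 1 : end])


class ReferenceMismatchError(ValueError):
    """Deleted bases recorded on the indel disagree with the reference."""


def left_align(indel: NormalizedIndel, reference: ReferenceAccessor) -> NormalizedIndel:
    """Reposition a pure insertion/deletion as far 5' as possible.

    The returned indel yields an alternative haplotype identical to the
    input's.  Complex indels (both alleles non-empty) are returned unchanged.
    Deletions are checked against the reference first; a disagreement raises
    :class:`ReferenceMismatchError`.
    """
    kind = indel.kind
    if kind is IndelKind.COMPLEX:
        return indel

    allele = indel.allele_seq
    pos = indel.pos
    if kind is IndelKind.DELETION:
        ref_here = reference.fetch(indel.chrom, pos, pos + len(allele) - 1)
        if ref_here != allele:
            raise ReferenceMismatchError(
                f"deletion at {indel.chrom}:{pos} records {allele!r} "
                f"but reference has {ref_here!r}"
            )
        # anchor base for the comparison is the one 5' of the footprint
        while pos > 1 and reference.fetch(indel.chrom, pos - 1, pos - 1) == allele[-1]:
            allele = reference.fetch(indel.chrom, pos - 1, pos - 1) + allele[:-1]
            pos -= 1
        return NormalizedIndel(indel.chrom, pos, allele, "")

    # insertion: sits between pos and pos+1; can shift while the last inserted
    # base equals the reference base at pos (rotation preserves the haplotype)
    while pos > 0 and reference.fetch(indel.chrom, pos, pos) == allele[-1]:
        allele = reference.fetch(indel.chrom, pos, pos) + allele[:-1]
        pos -= 1
    return NormalizedIndel(indel.chrom, pos, "", allele)


def is_left_aligned(indel: NormalizedIndel, reference: ReferenceAccessor) -> bool:
    return left_align(indel, reference) == indel


def apply_to_reference(
    indel: NormalizedIndel, reference: ReferenceAccessor, lo: int, hi: int
) -> str:
    """Alternative haplotype over the 1-based window [lo, hi].

    The indel's footprint must lie inside the window (for insertions, the
    insertion point).
    """
    if indel.kind is IndelKind.INSERTION:
        if not (lo <= indel.pos + 1 and indel.pos <= hi):
            raise ValueError("insertion point outside window")
        left = reference.fetch(indel.chrom, lo, indel.pos) if indel.pos >= lo else ""
        right = reference.fetch(indel.chrom, indel.pos + 1, hi)
        return left + indel.alt_seq + right
    f_lo, f_hi = indel.footprint
    if f_lo < lo or f_hi > hi:
        raise ValueError("footprint outside window")
    left = reference.fetch(indel.chrom, lo, f_lo - 1) if f_lo > lo else ""
    right = reference.fetch(indel.chrom, f_hi + 1, hi) if f_hi < hi else ""
    return left + indel.alt_seq + right


def equivalent(
    a: NormalizedIndel,
    b: NormalizedIndel,
    reference: ReferenceAccessor,
    margin: int = 30,
) -> bool:
    """True iff the two indels yield identical haplotypes.

    Compared over a shared window covering both footprints plus ``margin``
    bases on each side (clipped at the contig start).
    """
    if a.chrom != b.chrom:
        return False
    if a.length != b.length:
        return False
    lo = max(1, min(a.footprint[0], b.footprint[0]) - margin)
    hi = max(a.footprint[1], b.footprint[1], a.pos + 1, b.pos + 1) + margin
    try:
        return apply_to_reference(a, reference, lo, hi) == apply_to_reference(
            b, reference, lo, hi
        )
    except IndexError:
        # window ran off the contig end: retry clipped
        hi = max(a.footprint[1], b.footprint[1], a.pos + 1, b.pos + 1)
        return apply_to_reference(a, reference, lo, hi) == apply_to_reference(
            b, reference, lo, hi
        )
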