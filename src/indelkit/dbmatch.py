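"""Windowed identity matching of called indels against variant databases.

A called indel counts as "already described" if a database entry of the same
signed length lies within a small window around its (left-aligned) start
position; priority goes to entries with the same length and sequence, then
same length, then merely the nearest entry.  Historical databases predate
left-alignment conventions, so described entries tend to sit downstream
(higher coordinates) of the left-aligned call — ties on distance are broken
toward the 5' candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .model import NormalizedIndel, Provenance, VariantDatabase
from .normalize import ReferenceAccessor, is_left_aligned


class MatchTier(IntEnum):
    """Match quality, ordered best-first; the int is the rule rank."""

    EXACT_ALLELE = 0
    SAME_LENGTH_AND_SEQUENCE_IN_WINDOW = 1
    SAME_LENGTH_IN_WINDOW = 2
    NEAREST_IN_WINDOW = 3
    UNMATCHED = 4


#: Worst tier that still counts as "described" for provenance purposes:
#: a nearby indel of a *different* length marks a described region, not a
#: described variant, so NEAREST_IN_WINDOW never confers known status.
DEFAULT_KNOWN_TIER = MatchTier.SAME_LENGTH_IN_WINDOW


@dataclass(frozen=True)
class MatchResult:
    query: NormalizedIndel
    db_name: str
    tier: MatchTier
    matched: NormalizedIndel | None = None
    signed_distance: int | None = None

    def __post_init__(self) -> None:
        if (self.tier is MatchTier.UNMATCHED) != (self.matched is None):
            raise ValueError("matched record present iff tier != UNMATCHED")


def _candidate_key(query: NormalizedIndel, rec: NormalizedIndel):
    """Sort key implementing |distance| minimisation with 5'-then-sequence
    tie-breaks."""
    d = rec.pos - query.pos
    return (abs(d), 0 if d < 0 else 1, rec.ref_seq, rec.alt_seq)


def match_variant(
    query: NormalizedIndel,
    db: VariantDatabase,
    window_bp: int = 10,
    reference: ReferenceAccessor | None = None,
) -> MatchResult:
    """Match one left-aligned call against a database.

    Rules, applied in order over the candidates within ``pos ± window_bp``:

    1. exact allele: same position, same ref/alt sequences;
    2. same signed length and same allele sequence, closest;
    3. same signed length, closest;
    4. any indel, closest;

    else unmatched.  Ties on |distance| resolve toward the 5' candidate, then
    lexicographically by allele sequence.  If ``reference`` is given the
    query is checked to be left-aligned (contract of the matching rules).
    """
    if reference is not None and not is_left_aligned(query, reference):
        raise ValueError(f"query {query} is not left-aligned")

    candidates = db.query(query.chrom, query.pos - window_bp, query.pos + window_bp)
    if not candidates:
        return MatchResult(query, db.name, MatchTier.UNMATCHED)

    exact = [
        r
        for r in candidates
        if r.pos == query.pos
        and r.ref_seq == query.ref_seq
        and r.alt_seq == query.alt_seq
    ]
    if exact:
        return MatchResult(query, db.name, MatchTier.EXACT_ALLELE, exact[0], 0)

    same_len = [r for r in candidates if r.length == query.length]
    same_len_seq = [
        r
        for r in same_len
        if r.ref_seq == query.ref_seq and r.alt_seq == query.alt_seq
    ]
    for tier, pool in (
        (MatchTier.SAME_LENGTH_AND_SEQUENCE_IN_WINDOW, same_len_seq),
        (MatchTier.SAME_LENGTH_IN_WINDOW, same_len),
        (MatchTier.NEAREST_IN_WINDOW, candidates),
    ):
        if pool:
            best = min(pool, key=lambda r: _candidate_key(query, r))
            return MatchResult(query, db.name, tier, best, best.pos - query.pos)
    raise AssertionError("unreachable: candidates was non-empty")


def classify_provenance(
    query: NormalizedIndel,
    known_db: VariantDatabase,
    newly_released_db: VariantDatabase,
    window_bp: int = 10,
    known_tier: MatchTier = DEFAULT_KNOWN_TIER,
) -> Provenance:
    """Partition a call into KNOWN_DB / NEWLY_RELEASED_ONLY / NOVEL.

    The primary database takes priority: a call described in both databases
    is KNOWN_DB.  A match qualifies only at ``known_tier`` or better.
    """
    if match_variant(query, known_db, window_bp).tier <= known_tier:
        return Provenance.KNOWN_DB
    if match_variant(query, newly_released_db, window_bp).tier <= known_tier:
        return Provenance.NEWLY_RELEASED_ONLY
    return Provenance.NOVEL


def distance_profile(
    queries: Iterable[NormalizedIndel],
    db: VariantDatabase,
    extended_window_bp: int = 100,
) -> list[int]:
    """Signed start-position distances to the closest described entry.

    For each query with at least one database hit within the extended
    window, the closest hit of identical signed length is chosen if one
    exists, otherwise the closest hit of any length; queries with no hit are
    omitted.  Distances are ``matched.pos - query.pos``.
    """
    out: list[int] = []
    for q in queries:
        hits = db.query(q.chrom, q.pos - extended_window_bp, q.pos + extended_window_bp)
        if not hits:
            continue
        same_len = [r for r in hits if r.length == q.length]
        pool = same_len if same_len else hits
        best = min(pool, key=lambda r: _candidate_key(q, r))
        out.append(best.pos - q.pos)
    return out


@dataclass(frozen=True)
class SizeCorrelation:
    r_squared: float
    p_value: float
    n: int


def size_correlation(
    pairs: Sequence[tuple[int, int]],
) -> dict[str, SizeCorrelation]:
    """Squared Pearson correlation of called vs database indel length.

    Pairs are (called signed length, matched database signed length);
    insertions (positive) and deletions (negative) are tested as separate
    strata on absolute lengths.  A stratum with fewer than 3 pairs, or with
    zero variance in either margin, is absent from the result.
    """
    out: dict[str, SizeCorrelation] = {}
    arr = np.asarray(pairs, dtype=float)
    for name, mask in (
        ("insertions", arr[:, 0] > 0 if len(arr) else np.array([], bool)),
        ("deletions", arr[:, 0] < 0 if len(arr) else np.array([], bool)),
    ):
        sub = np.abs(arr[mask])
        if len(sub) < 3:
            continue
        if np.ptp(sub[:, 0]) == 0 or np.ptp(sub[:, 1]) == 0:
            continue  # degenerate margin: correlation undefined
        res = stats.pearsonr(sub[:, 0], sub[:, 1])
        out[name] = SizeCorrelation(res.statistic**2, res.pvalue, len(sub))
    return out
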