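"""Coordinate sorting and PCR-duplicate flagging.

Duplicate detection follows the usual 5'-unclipped-coordinate
convention: a read pair's key is the pair of (contig, 5' unclipped
position, orientation) tuples of its two primary alignments, so that
soft clipping cannot hide duplicates.  Within a duplicate group the
highest pair-score pair stays unflagged; ties break on read id.
"""

from __future__ import annotations

from dataclasses import dataclass

from rapidseq.mapper import (FLAG_DUPLICATE, FLAG_FIRST, AlignmentRecord)
from rapidseq.reference import ReferenceGenome


@dataclass
class SortedAlignmentSet:
    """Records totally ordered by (contig header order, position,
    orientation), with duplicate flags applied."""

    records: list[AlignmentRecord]
    contig_order: list[str]
    n_duplicate_pairs: int = 0


def _five_prime_key(rec: AlignmentRecord) -> tuple:
    if rec.is_reverse:
        return (rec.contig, rec.unclipped_end(), "-")
    return (rec.contig, rec.unclipped_start(), "+")


def sort_and_mark_duplicates(records: list[AlignmentRecord],
                             ref: ReferenceGenome,
                             mark: bool = True) -> SortedAlignmentSet:
    """Sort by reference coordinate and optionally flag PCR duplicates.

    Sorting is a permutation of the input (no records created or lost);
    unmapped reads sort at their mate's coordinate, where the mapper
    placed them.  Flagging is idempotent: pre-existing duplicate flags
    are cleared and recomputed.
    """
    order = {name: i for i, name in enumerate(ref.names)}
    n_dup = 0
    if mark:
        for rec in records:
            rec.flag &= ~FLAG_DUPLICATE
        groups: dict[tuple, list[tuple[AlignmentRecord, AlignmentRecord]]] = {}
        by_name: dict[str, dict[bool, AlignmentRecord]] = {}
        for rec in records:
            if rec.is_unmapped or rec.is_supplementary:
                continue
            by_name.setdefault(rec.qname, {})[bool(rec.flag & FLAG_FIRST)] = rec
        for qname, mates in by_name.items():
            if len(mates) != 2:
                continue
            r1, r2 = mates[True], mates[False]
            if r1.is_unmapped or r2.is_unmapped:
                continue
            key = tuple(sorted([_five_prime_key(r1), _five_prime_key(r2)],
                               key=lambda t: (order.get(t[0], 1 << 30), t[1], t[2])))
            groups.setdefault(key, []).append((r1, r2))
        for key, pairs in groups.items():
            if len(pairs) < 2:
                continue
            pairs.sort(key=lambda p: (-p[0].pair_score, p[0].qname))
            for r1, r2 in pairs[1:]:
                r1.flag |= FLAG_DUPLICATE
                r2.flag |= FLAG_DUPLICATE
                n_dup += 1

    def sort_key(rec: AlignmentRecord) -> tuple:
        contig_rank = order.get(rec.contig, 1 << 30) if rec.contig else 1 << 30
        return (contig_rank, rec.pos, 1 if rec.is_reverse else 0, rec.qname)

    ordered = sorted(records, key=sort_key)
    return SortedAlignmentSet(ordered, ref.names, n_dup)
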