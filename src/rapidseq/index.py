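"""Hash-table genome index with dynamic seed extension.

The mapper anchors reads by exact-matching fixed-length seeds against a
hash table built from the forward strand of the reference.  Seeds whose
primary form (default 21 nt) occurs at more than ``max_hits`` reference
locations are not stored as (useless) long hit lists; instead the table
holds an EXTEND record instructing the query to lengthen the seed
symmetrically with flanking read bases and re-query, iteratively, until
the extended seed is specific enough.  Extension is capped at
``max_ext_per_side`` nt per side; a seed that is still too frequent at
the cap is marked high-frequency and returns no hits.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

from rapidseq.reference import ReferenceGenome, revcomp

FORWARD = "+"
REVERSE = "-"

_INDEX_FORMAT_VERSION = 1


@dataclass(frozen=True)
class IndexParams:
    """Seeding parameters.

    With the defaults the maximum extended seed length is
    ``primary_seed_len + 2 * max_ext_per_side`` = 21 + 2*64 = 149 nt.
    """

    primary_seed_len: int = 21
    max_hits: int = 16
    max_ext_per_side: int = 64
    ext_increment: int = 3
    seed_stride: int = 2

    def __post_init__(self) -> None:
        for name in ("primary_seed_len", "max_hits", "max_ext_per_side",
                     "ext_increment", "seed_stride"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def max_seed_len(self) -> int:
        return self.primary_seed_len + 2 * self.max_ext_per_side


@dataclass(frozen=True)
class SeedHit:
    """Exact occurrence of a (possibly extended) seed on the reference.

    ``position`` is the 0-based forward-strand start of the *primary*
    seed portion; ``orientation`` records whether the read seed matched
    directly or via its reverse complement.
    """

    contig: str
    position: int
    orientation: str = FORWARD


@dataclass(frozen=True)
class ExtendRecord:
    """Directive to join ``ext_left``/``ext_right`` extra read bases onto
    the seed (cumulative totals, in nt) and re-query."""

    ext_left: int
    ext_right: int
    parent_key: object


class HighFrequency:
    """Marker: seed remained above ``max_hits`` at maximum extension."""

    def __repr__(self) -> str:  # pragma: no cover
        return "HighFrequency()"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HighFrequency)

    def __hash__(self) -> int:
        return hash("HighFrequency")


HIGH_FREQUENCY = HighFrequency()


@dataclass
class HashIndex:
    """Seed-key -> (hit list | ExtendRecord | HighFrequency) table.

    Primary keys are the seed strings themselves; extended keys are
    ``(parent_key, cum_left, cum_right, extended_seed_string)`` tuples so
    that each extension step hashes the additional bases together with an
    identifier of the pre-extended seed.
    """

    params: IndexParams
    table: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(
                {"version": _INDEX_FORMAT_VERSION, "params": self.params,
                 "table": self.table},
                fh, protocol=pickle.HIGHEST_PROTOCOL)

    @classmethod
    def load(cls, path: str) -> "HashIndex":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != _INDEX_FORMAT_VERSION:
            raise ValueError("unsupported index format version")
        return cls(params=payload["params"], table=payload["table"])


def _extended_key(parent_key: object, cum_left: int, cum_right: int,
                  ext_seq: str) -> tuple:
    return (parent_key, cum_left, cum_right, ext_seq)


def build_index(ref: ReferenceGenome, params: IndexParams | None = None) -> HashIndex:
    """Index every forward-strand primary seed of the reference.

    Seeds containing N are skipped.  Keys with more than ``max_hits``
    occurrences receive an :class:`ExtendRecord` chain; occurrences whose
    extension window would run off the contig cannot be disambiguated and
    are dropped from deeper levels.
    """
    if params is None:
        params = IndexParams()
    if len(ref) == 0:
        raise ValueError("empty reference")
    k = params.primary_seed_len

    occurrences: dict[str, list[tuple[str, int]]] = {}
    for name, seq in ref.contigs.items():
        if len(seq) < k:
            warnings.warn(f"contig {name!r} shorter than primary seed length; skipped")
            continue
        for pos in range(len(seq) - k + 1):
            seed = seq[pos:pos + k]
            if "N" in seed:
                continue
            occurrences.setdefault(seed, []).append((name, pos))

    idx = HashIndex(params=params)
    table = idx.table
    for seed, occs in occurrences.items():
        if len(occs) <= params.max_hits:
            table[seed] = [SeedHit(c, p) for c, p in occs]
        else:
            _extend(idx, ref, seed, occs, 0, 0)
    return idx


def _extend(idx: HashIndex, ref: ReferenceGenome, key: object,
            occs: list[tuple[str, int]], cum_left: int, cum_right: int) -> None:
    """Recursively install EXTEND records until each group is specific or
    the per-side cap is reached."""
    params = idx.params
    k = params.primary_seed_len
    if cum_left >= params.max_ext_per_side and cum_right >= params.max_ext_per_side:
        idx.table[key] = HIGH_FREQUENCY
        return
    dl = min(params.ext_increment, params.max_ext_per_side - cum_left)
    dr = min(params.ext_increment, params.max_ext_per_side - cum_right)
    new_left, new_right = cum_left + dl, cum_right + dr
    idx.table[key] = ExtendRecord(ext_left=new_left, ext_right=new_right,
                                  parent_key=key)

    groups: dict[str, list[tuple[str, int]]] = {}
    for contig, pos in occs:
        start = pos - new_left
        end = pos + k + new_right
        seq = ref.contigs[contig]
        if start < 0 or end > len(seq):
            continue  # extension runs off the contig; occurrence dropped
        ext = seq[start:end]
        if "N" in ext:
            continue
        groups.setdefault(ext, []).append((contig, pos))

    for ext_seq, group in groups.items():
        gkey = _extended_key(key, new_left, new_right, ext_seq)
        if len(group) <= params.max_hits:
            idx.table[gkey] = [SeedHit(c, p) for c, p in group]
        else:
            _extend(idx, ref, gkey, group, new_left, new_right)


def _query_oriented(idx: HashIndex, seq: str, offset: int) -> list[SeedHit] | HighFrequency | None:
    """Follow the EXTEND chain for the seed of ``seq`` at ``offset``.

    Returns ``None`` when the primary seed is absent from the table, a
    hit list otherwise, or HIGH_FREQUENCY when either the chain bottoms
    out at the cap or the read lacks the flanking bases an extension
    step requires.
    """
    params = idx.params
    k = params.primary_seed_len
    seed = seq[offset:offset + k]
    entry = idx.table.get(seed)
    key: object = seed
    while True:
        if entry is None:
            return None
        if isinstance(entry, HighFrequency):
            return HIGH_FREQUENCY
        if isinstance(entry, list):
            return entry
        # ExtendRecord: join cumulative flanking read bases and re-query.
        rec: ExtendRecord = entry
        start = offset - rec.ext_left
        end = offset + k + rec.ext_right
        if start < 0 or end > len(seq):
            return HIGH_FREQUENCY  # read too short to disambiguate
        ext_seq = seq[start:end]
        if "N" in ext_seq:
            return None
        key = _extended_key(key, rec.ext_left, rec.ext_right, ext_seq)
        entry = idx.table.get(key)


def query_seed(idx: HashIndex, read_seq: str, offset: int,
               ref: ReferenceGenome | None = None) -> list[SeedHit] | HighFrequency:
    """Look up the read seed at ``offset`` on both strands.

    Forward hits report the stored forward-strand positions; the reverse
    complement of the seed is queried too, its hits reported with
    reverse-complement orientation (position still the forward-strand
    start of the matching reference seed).  ``ref`` is accepted for
    interface symmetry but not needed: all extension bases come from the
    read.
    """
    params = idx.params
    k = params.primary_seed_len
    if offset + k > len(read_seq):
        raise ValueError("seed extends past read end")
    seed = read_seq[offset:offset + k]
    if "N" in seed:
        return []

    hits: list[SeedHit] = []
    fwd = _query_oriented(idx, read_seq, offset)
    if isinstance(fwd, HighFrequency):
        return HIGH_FREQUENCY
    if fwd:
        hits.extend(fwd)

    rc_read = revcomp(read_seq)
    rc_offset = len(read_seq) - offset - k
    rev = _query_oriented(idx, rc_read, rc_offset)
    if isinstance(rev, HighFrequency):
        return HIGH_FREQUENCY
    if rev:
        hits.extend(SeedHit(h.contig, h.position, REVERSE) for h in rev)
    return hits
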