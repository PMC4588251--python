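"""Mapper: seeding, chaining, pairing/rescue, MAPQ, and a round-trip
placement check on simulated error-free reads."""

import numpy as np
import pytest

from rapidseq.align import cigar_read_len, encode
from rapidseq.index import FORWARD, REVERSE, IndexParams, SeedHit, build_index
from rapidseq.mapper import (FLAG_FIRST, FLAG_REVERSE, FLAG_SUPPLEMENTARY,
                             InsertModel, MapperParams, Read, RescueParams,
                             SeedChain, build_chains, compute_mapq,
                             extract_seeds, finalize_pair, hamming_scan,
                             map_read_pairs, pairing_penalty, rescue_scan,
                             Candidate)
from rapidseq.reference import ReferenceGenome, revcomp
from rapidseq.simeval import SimConfig, simulate_reads

from conftest import make_read, make_seq


# ---------------------------------------------------------------------------
# Seed extraction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("read_len,expected", [(101, 41), (21, 1), (20, 0)])
def test_seed_counts_at_even_offsets(read_len, expected):
    read = make_read(make_seq(read_len, seed=read_len))
    seeds = extract_seeds(read, IndexParams())
    assert len(seeds) == expected
    assert all(off % 2 == 0 for off, _ in seeds)


def test_seeds_containing_n_are_omitted():
    seq = make_seq(40, seed=1)
    seq = seq[:10] + "N" + seq[11:]
    seeds = extract_seeds(make_read(seq), IndexParams())
    assert all("N" not in s for _, s in seeds)
    assert len(seeds) < 10  # several offsets span the N


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def test_same_diagonal_hits_merge_into_one_chain():
    hits = [(0, SeedHit("c", 100)), (2, SeedHit("c", 102)),
            (10, SeedHit("c", 110))]
    chains = build_chains(hits, seed_len=21)
    assert len(chains) == 1
    chain = chains[0]
    assert (chain.read_start, chain.read_end) == (0, 31)
    assert chain.diagonal == 100


def test_short_chain_dominated_by_4x_longer_overlapping_chain():
    # long chain spans read [0, 85): length 85 >= 4 * 21
    long_hits = [(off, SeedHit("c", 1000 + off)) for off in range(0, 66, 2)]
    short_hits = [(10, SeedHit("c", 5010))]
    chains = build_chains(long_hits + short_hits, seed_len=21)
    diagonals = {c.diagonal for c in chains}
    assert 1000 in diagonals and 5000 not in diagonals


def test_disjoint_read_spans_both_kept():
    a = [(0, SeedHit("c", 100))]
    b = [(60, SeedHit("c", 5060))]
    chains = build_chains(a + b, seed_len=21)
    assert len(chains) == 2


# ---------------------------------------------------------------------------
# Pairing penalty and rescue
# ---------------------------------------------------------------------------

def test_insert_at_model_mean_has_zero_penalty():
    model = InsertModel(350, 50)
    assert pairing_penalty(350, model, MapperParams()) == 0


def test_penalty_grows_with_deviation_and_caps():
    model = InsertModel(350, 50)
    params = MapperParams()
    p1 = pairing_penalty(400, model, params)
    p2 = pairing_penalty(600, model, params)
    assert 0 < p1 < p2 <= params.pair_pen_cap
    assert pairing_penalty(100000, model, params) == params.pair_pen_cap


def brute_force_hamming(window: str, kmer: str, max_d: int) -> list[int]:
    out = []
    for i in range(len(window) - len(kmer) + 1):
        d = sum(a != b for a, b in zip(window[i:i + len(kmer)], kmer))
        if d <= max_d:
            out.append(i)
    return out


@pytest.mark.parametrize("seed", range(10))
def test_hamming_scan_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    window = make_seq(200, seed=seed)
    kmer = list(window[50:74])
    for _ in range(int(rng.integers(0, 4))):   # plant up to 3 mismatches
        kmer[int(rng.integers(0, 24))] = "ACGT"[int(rng.integers(0, 4))]
    kmer = "".join(kmer)
    got = hamming_scan(encode(window), encode(kmer), 3)
    assert got == brute_force_hamming(window, kmer, 3)


def test_rescue_finds_mate_with_two_mismatches():
    ref = ReferenceGenome({"c": make_seq(2000, seed=3)})
    seq = ref.contigs["c"]
    # anchor forward at 500; true mate reverse, fragment 350
    mate_ref = seq[500 + 350 - 101:500 + 350]
    mutated = list(mate_ref)
    mutated[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[5]]
    mutated[15] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[15]]
    mate_oriented = "".join(mutated)    # reference-oriented mate sequence
    anchor = Candidate("c", FORWARD, 500, [("M", 101)], 212)
    mate_codes = {FORWARD: encode(mate_oriented),
                  REVERSE: encode(mate_oriented)}
    cands = rescue_scan(anchor, mate_codes, ref, InsertModel(350, 50),
                        RescueParams(), MapperParams())
    assert any(c.pos == 500 + 350 - 101 for c in cands)


def test_rescue_rejects_mate_beyond_hamming_limit():
    ref = ReferenceGenome({"c": make_seq(2000, seed=4)})
    random_mate = make_seq(101, seed=99)  # unrelated sequence
    anchor = Candidate("c", FORWARD, 500, [("M", 101)], 212)
    mate_codes = {FORWARD: encode(random_mate), REVERSE: encode(random_mate)}
    cands = rescue_scan(anchor, mate_codes, ref, InsertModel(350, 50),
                        RescueParams(), MapperParams())
    assert cands == []


# ---------------------------------------------------------------------------
# MAPQ
# ---------------------------------------------------------------------------

def test_equal_best_and_second_best_gives_mapq_zero():
    assert compute_mapq([200, 200], 200, 101, MapperParams()) == 0


def test_single_candidate_gets_cap():
    assert compute_mapq([200], 200, 101, MapperParams()) == 60


def test_mapq_monotone_in_score_margin():
    params = MapperParams()
    prev = -1
    for s2 in range(200, 0, -10):
        q = compute_mapq([200, s2], 200, 101, params)
        assert q >= prev
        prev = q
    assert 0 <= prev <= 60


def test_near_second_best_candidates_reduce_mapq():
    params = MapperParams()
    lone = compute_mapq([200, 150], 200, 101, params)
    crowded = compute_mapq([200, 150, 150, 149, 148], 200, 101, params)
    assert crowded < lone


# ---------------------------------------------------------------------------
# Pair finalization
# ---------------------------------------------------------------------------

def test_no_candidates_yields_two_unmapped_records():
    r1, r2 = make_read(make_seq(30, seed=1), "p"), make_read(make_seq(30, seed=2), "p")
    recs = finalize_pair(r1, r2, [], [], InsertModel(), MapperParams())
    assert len(recs) == 2 and all(r.is_unmapped for r in recs)


def test_chimeric_read_emits_supplementary_records():
    """A read whose halves come from two contigs gets one primary and
    at least one (at most three) supplementary alignment."""
    c1, c2 = make_seq(3000, seed=10), make_seq(3000, seed=11)
    ref = ReferenceGenome({"A": c1, "B": c2})
    idx = build_index(ref)
    chimera = c1[1000:1050] + c2[2000:2051]
    mate = revcomp(c1[1250:1351])
    pairs = [(make_read(chimera, "q"), make_read(mate, "q"))]
    records = map_read_pairs(pairs, idx, ref, insert_model=InsertModel(350, 50))
    first = [r for r in records if r.flag & FLAG_FIRST]
    sups = [r for r in first if r.is_supplementary]
    assert 1 <= len(sups) <= 3
    contigs = {r.contig for r in first}
    assert contigs == {"A", "B"}


# ---------------------------------------------------------------------------
# Round trip on simulated reads
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def roundtrip_run():
    ref = ReferenceGenome({"chr1": make_seq(20000, seed=21)})
    cfg = SimConfig(genome_length=20000, coverage=30, base_error_rate=0.0,
                    snv_rate=0.0, indel_rate=0.0, seed=21)
    pairs = simulate_reads({"chr1": (ref.contigs["chr1"],)}, cfg,
                           np.random.default_rng(22), genome_length=20000)
    idx = build_index(ref)
    records = map_read_pairs(pairs, idx, ref)
    return pairs, records


def test_error_free_reads_map_to_their_origin(roundtrip_run):
    """>= 99.9% of error-free reads from a unique-sequence genome are
    placed at their true origin with correct orientation."""
    pairs, records = roundtrip_run
    truth = {}
    for r1, r2 in pairs:
        _, _, _, start, insert, _ = r1.id.split("_")
        start, insert = int(start), int(insert)
        truth[(r1.id, True)] = (start, FORWARD)
        truth[(r1.id, False)] = (start + insert - 101, REVERSE)
    n = correct = 0
    for rec in records:
        if rec.is_supplementary:
            continue
        n += 1
        pos, orient = truth[(rec.qname, bool(rec.flag & FLAG_FIRST))]
        got_orient = REVERSE if rec.is_reverse else FORWARD
        if not rec.is_unmapped and rec.pos == pos and got_orient == orient:
            correct += 1
    assert n == 2 * len(pairs)
    assert correct / n >= 0.999


def test_cigar_consumes_read_exactly(roundtrip_run):
    _, records = roundtrip_run
    for rec in records:
        if not rec.is_unmapped:
            assert cigar_read_len(rec.cigar) == len(rec.seq)


def test_proper_pairs_have_symmetric_tlen(roundtrip_run):
    _, records = roundtrip_run
    by_name = {}
    for rec in records:
        if not rec.is_supplementary:
            by_name.setdefault(rec.qname, []).append(rec)
    for recs in list(by_name.values())[:200]:
        if len(recs) == 2 and not any(r.is_unmapped for r in recs):
            assert recs[0].tlen == -recs[1].tlen != 0
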