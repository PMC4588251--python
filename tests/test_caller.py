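"""Variant caller stages: region detection arithmetic, De Bruijn
assembly, event extraction, and Bayesian genotyping vs brute force."""

import itertools
import math

import numpy as np
import pytest

from rapidseq.align import encode
from rapidseq.caller import (ActiveRegion, CallerParams, Haplotype, RegionRead,
                             assemble_haplotypes, call_variants, detect_regions,
                             diplotype_posteriors, genotype_region,
                             haplotype_events)
from rapidseq.hmm import pair_hmm
from rapidseq.mapper import FLAG_PAIRED, AlignmentRecord
from rapidseq.pipeline import run_pipeline
from rapidseq.reference import ReferenceGenome
from rapidseq.simeval import SimConfig, simulate_reads, simulate_truth

from conftest import make_seq


def simple_record(name: str, contig: str, pos: int, seq: str,
                  mapq: int = 60) -> AlignmentRecord:
    return AlignmentRecord(name, FLAG_PAIRED, contig, pos, mapq,
                           [("M", len(seq))], seq,
                           np.full(len(seq), 30, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Region detection
# ---------------------------------------------------------------------------

@pytest.fixture
def flat_ref():
    return ReferenceGenome({"c": make_seq(1000, seed=2)})


def tile_reads(ref_seq: str, contig: str, depth: int, read_len: int = 60,
               mutate=None) -> list[AlignmentRecord]:
    """Evenly tiled error-free reads; ``mutate(seq, start)`` may edit
    each read sequence."""
    records = []
    step = max(1, read_len * 2 // depth)
    i = 0
    for start in range(0, len(ref_seq) - read_len + 1, step):
        for k in range(max(1, depth * step // (2 * read_len))):
            seq = ref_seq[start:start + read_len]
            if mutate:
                seq = mutate(seq, start)
            records.append(simple_record(f"t{i}", contig, start, seq))
            i += 1
    return records


def test_reference_identical_pileup_has_no_active_regions(flat_ref):
    seq = flat_ref.contigs["c"]
    records = tile_reads(seq, "c", depth=40)
    assert detect_regions(records, flat_ref, CallerParams()) == []


def test_column_with_30pct_nonref_becomes_active(flat_ref):
    seq = flat_ref.contigs["c"]
    alt = "A" if seq[500] != "A" else "T"
    state = {"n": 0}

    def mutate(read_seq, start):
        if start <= 500 < start + len(read_seq):
            state["n"] += 1
            if state["n"] % 10 < 3:  # 30% of covering reads carry the alt
                off = 500 - start
                return read_seq[:off] + alt + read_seq[off + 1:]
        return read_seq

    records = tile_reads(seq, "c", depth=40, mutate=mutate)
    regions = detect_regions(records, flat_ref, CallerParams())
    assert len(regions) == 1
    region = regions[0]
    assert region.start <= 500 < region.end
    # padded by base_pad on each side of the single active column
    assert region.end - region.start == pytest.approx(101, abs=3)


def test_low_depth_columns_not_callable(flat_ref):
    seq = flat_ref.contigs["c"]
    alt = "A" if seq[500] != "A" else "T"

    def mutate(read_seq, start):
        if start <= 500 < start + len(read_seq):
            off = 500 - start
            return read_seq[:off] + alt + read_seq[off + 1:]
        return read_seq

    # depth ~2 everywhere: below min_depth 4
    few = tile_reads(seq, "c", depth=2, mutate=mutate)[:6]
    regions = detect_regions(few, flat_ref, CallerParams(min_depth=4))
    assert all(not (r.start <= 500 < r.end) for r in regions)


def test_indel_evidence_widens_padding(flat_ref):
    seq = flat_ref.contigs["c"]
    records = []
    for i, start in enumerate(range(380, 480, 4)):
        # reads with a 3-nt deletion at 500
        left = 500 - start
        seq_read = seq[start:500] + seq[503:503 + 60 - left]
        cigar = [("M", left), ("D", 3), ("M", 60 - left)]
        records.append(AlignmentRecord(f"d{i}", FLAG_PAIRED, "c", start, 60,
                                       cigar, seq_read,
                                       np.full(60, 30, dtype=np.uint8)))
    regions = detect_regions(records, flat_ref, CallerParams())
    assert regions and regions[0].has_indel
    params = CallerParams()
    assert regions[0].end - regions[0].start >= 2 * params.indel_pad


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def test_reference_reads_assemble_to_reference_only():
    ref_seg = make_seq(150, seed=3)
    reads = [ref_seg[i:i + 60] for i in range(0, 90, 5)]
    haps = assemble_haplotypes(reads, ref_seg, CallerParams())
    assert [h.sequence for h in haps] == [ref_seg]


def test_heterozygous_snv_gives_exactly_two_haplotypes():
    ref_seg = make_seq(150, seed=4)
    alt_seg = ref_seg[:75] + ("A" if ref_seg[75] != "A" else "C") + ref_seg[76:]
    reads = []
    for i in range(0, 90, 5):
        reads.append(ref_seg[i:i + 60])
        reads.append(alt_seg[i:i + 60])
    haps = assemble_haplotypes(reads, ref_seg, CallerParams())
    assert len(haps) == 2
    assert {h.sequence for h in haps} == {ref_seg, alt_seg}


def test_tandem_repeat_forces_longer_kmers():
    """A repeat that makes the k=10 backbone cyclic is assembled after
    the schedule moves to a longer k."""
    unit = make_seq(12, seed=5)
    ref_seg = make_seq(40, seed=6) + unit * 3 + make_seq(40, seed=7)
    reads = [ref_seg[i:i + 60] for i in range(0, len(ref_seg) - 60, 4)]
    backbone10 = [ref_seg[i:i + 10] for i in range(len(ref_seg) - 9)]
    assert len(set(backbone10)) < len(backbone10)  # k=10 is degenerate
    haps = assemble_haplotypes(reads, ref_seg, CallerParams())
    assert any(h.sequence == ref_seg for h in haps)


def test_haplotype_cap_prefers_heavy_paths():
    ref_seg = make_seq(200, seed=8)
    params = CallerParams(max_haplotypes=2)
    # two SNV sites -> up to 4 combinations; cap keeps the heaviest 2
    alt1 = ref_seg[:50] + "A" + ref_seg[51:]
    alt2 = ref_seg[:150] + "A" + ref_seg[151:]
    reads = []
    for i in range(0, 140, 4):
        reads.append(alt1[i:i + 60])
        reads.append(ref_seg[i:i + 60])
    for i in range(100, 140, 4):
        reads.append(alt2[i:i + 60])
    haps = assemble_haplotypes(reads, ref_seg, params)
    assert len(haps) <= params.max_haplotypes + 1  # reference always kept


# ---------------------------------------------------------------------------
# Event extraction
# ---------------------------------------------------------------------------

def test_reference_haplotype_has_no_events():
    ref_seg = make_seq(100, seed=9)
    assert haplotype_events(Haplotype(ref_seg, 1), ref_seg, "c", 0, ref_seg) == []


def test_substitution_event_at_offset():
    contig_seq = make_seq(300, seed=10)
    ref_seg = contig_seq[100:200]
    hap = ref_seg[:40] + ("A" if ref_seg[40] != "A" else "C") + ref_seg[41:]
    events = haplotype_events(Haplotype(hap, 1), ref_seg, "c", 100, contig_seq)
    assert len(events) == 1
    ev = events[0]
    assert ev.position == 140 and ev.type == "SNV" and ev.alt == hap[40]


def test_deletion_in_homopolymer_left_normalized():
    flank_l = make_seq(50, seed=11).rstrip("A")
    flank_r = make_seq(50, seed=12).lstrip("A")
    contig_seq = flank_l + "AAAAAA" + flank_r
    run_start = len(flank_l)
    ref_seg = contig_seq
    # delete the *last* 3 As; leftmost representation anchors before the run
    hap = contig_seq[:run_start + 3] + contig_seq[run_start + 6:]
    events = haplotype_events(Haplotype(hap, 1), ref_seg, "c", 0, contig_seq)
    assert len(events) == 1
    ev = events[0]
    assert ev.type == "deletion" and ev.size == 3
    assert ev.position == run_start - 1  # anchored on the base before the run


# ---------------------------------------------------------------------------
# Genotyping
# ---------------------------------------------------------------------------

def brute_force_posteriors(per_allele: np.ndarray, theta: float):
    combos = list(itertools.combinations_with_replacement(
        range(per_allele.shape[1]), 2))
    priors = [(1 - theta) if c == (0, 0) else theta / (len(combos) - 1)
              for c in combos]
    joint = []
    for (a1, a2), prior in zip(combos, priors):
        p = prior
        for row in per_allele:
            p *= 0.5 * math.exp(row[a1]) + 0.5 * math.exp(row[a2])
        joint.append(p)
    total = sum(joint)
    return combos, [p / total for p in joint]


@pytest.mark.parametrize("seed", range(5))
def test_diplotype_posteriors_match_brute_force_and_normalize(seed):
    rng = np.random.default_rng(seed)
    per_allele = np.log(rng.random((8, 3)) * 0.9 + 1e-3)
    combos, post = diplotype_posteriors(per_allele, theta=0.001)
    bf_combos, bf_post = brute_force_posteriors(per_allele, 0.001)
    assert combos == bf_combos
    assert np.allclose(post, bf_post, atol=1e-12)
    assert abs(post.sum() - 1.0) < 1e-9


def test_heterozygous_site_called_against_bayes_oracle():
    """15 alt / 16 ref high-quality reads at a SNV: the het diplotype
    wins and its posterior matches a direct Bayes computation over the
    three diplotypes using the same P(r|H) values."""
    ref = ReferenceGenome({"c": make_seq(400, seed=13)})
    contig_seq = ref.contigs["c"]
    region = ActiveRegion("c", 100, 300)
    ref_seg = contig_seq[100:300]
    alt_base = "A" if contig_seq[200] != "A" else "G"
    alt_seg = ref_seg[:100] + alt_base + ref_seg[101:]
    params = CallerParams()

    haps = [Haplotype(ref_seg, 10), Haplotype(alt_seg, 10)]
    for h in haps:
        h.events = haplotype_events(h, ref_seg, "c", 100, contig_seq)
    reads = []
    for i in range(16):
        s = 150 + (i % 8)
        reads.append(RegionRead(encode(contig_seq[s:s + 80]),
                                np.full(80, 30, np.uint8), 60, (s, s + 80)))
    alt_contig = contig_seq[:200] + alt_base + contig_seq[201:]
    for i in range(15):
        s = 150 + (i % 8)
        reads.append(RegionRead(encode(alt_contig[s:s + 80]),
                                np.full(80, 30, np.uint8), 60, (s, s + 80)))

    calls = genotype_region(region, haps, reads, ref, params)
    assert len(calls) == 1
    call = calls[0]
    assert call.genotype == (0, 1) and call.alts == [alt_base]
    assert call.depth == 31

    # oracle: same likelihoods, explicit Bayes over {rr, ra, aa}
    per_allele = np.empty((31, 2))
    for i, read in enumerate(reads):
        per_allele[i, 0] = pair_hmm(read.codes, read.quals, 60,
                                    encode(ref_seg), params.hmm)
        per_allele[i, 1] = pair_hmm(read.codes, read.quals, 60,
                                    encode(alt_seg), params.hmm)
    combos, post = brute_force_posteriors(per_allele, params.theta)
    assert combos[int(np.argmax(post))] == (0, 1)
    err = 1 - max(post)
    expected_gq = 99 if err <= 0 else min(99, round(-10 * math.log10(err)))
    assert call.gq == expected_gq


def test_all_reference_reads_give_no_call():
    ref = ReferenceGenome({"c": make_seq(400, seed=14)})
    contig_seq = ref.contigs["c"]
    region = ActiveRegion("c", 100, 300)
    ref_seg = contig_seq[100:300]
    haps = [Haplotype(ref_seg, 10)]
    haps[0].events = []
    reads = [RegionRead(encode(contig_seq[150:230]),
                        np.full(80, 30, np.uint8), 60, (150, 230))]
    assert genotype_region(region, haps, reads, ref, CallerParams()) == []


# ---------------------------------------------------------------------------
# End-to-end properties
# ---------------------------------------------------------------------------

def test_calls_invariant_to_read_input_order():
    cfg = SimConfig(genome_length=15000, coverage=30, seed=17)
    ref, dip = simulate_truth(cfg)
    pairs = simulate_reads(dip.haplotypes, cfg, np.random.default_rng(18),
                           genome_length=ref.total_length())
    calls_a = run_pipeline(ref, pairs)
    rng = np.random.default_rng(0)
    shuffled = list(pairs)
    rng.shuffle(shuffled)
    calls_b = run_pipeline(ref, shuffled)
    key = lambda c: (c.contig, c.position, c.ref, tuple(c.alts), c.genotype)
    assert sorted(map(key, calls_a)) == sorted(map(key, calls_b))
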