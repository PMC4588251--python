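"""Synthetic diploid genomes, paired reads with known truth, and
call-set concordance evaluation.

The generator emulates the study conditions of a rapid short-read WGS
experiment at desk scale: a random reference, a diploid sample with
SNVs planted at ~1/1,000 nt and indels at ~1/8,000 nt (geometric sizes,
mean 3, capped at 470 nt to span the largest events a short-read
pipeline is expected to recover), 2 x 101 nt paired reads with an
empirical-style Normal(350, 50) insert distribution, i.i.d. base errors
and a constant Q30 quality profile.  Every run is fully determined by
the seed.

Variants are not planted within ``edge_margin`` nt of contig ends:
paired-end coverage necessarily ramps down over roughly one insert
length at the ends of a linear molecule, an effect that is negligible
genome-wide at chromosome scale but would dominate the error budget of
a 250-kb toy contig.

Concordance follows the usual truth-set comparison: records are
matched on (contig, pos, ref, alt) after left-normalization on the
shared reference; variant-call specificity uses confident-region
non-variant positions (genome length minus truth count) as its
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rapidseq.align import encode
from rapidseq.mapper import Read
from rapidseq.reference import ReferenceGenome
from rapidseq.variants import VariantCall, VariantEvent, normalize_variant

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 250_000
    contig_count: int = 1
    snv_rate: float = 0.001
    indel_rate: float = 1.25e-4
    indel_mean: float = 3.0          # geometric size distribution
    indel_max: int = 470
    read_length: int = 101
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    coverage: float = 40.0
    base_error_rate: float = 0.002
    base_quality: int = 30
    quality_decay: float = 0.0       # linear 3' quality decay per base
    edge_margin: int = 400           # no variants planted this close to contig ends
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.snv_rate, self.indel_rate, self.base_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass(frozen=True)
class TruthRecord:
    event: VariantEvent
    genotype: tuple[int, int]      # (0,1) het or (1,1) hom-alt

    def key(self) -> tuple:
        ev = self.event
        return (ev.contig, ev.position, ev.ref, ev.alt)


@dataclass
class TruthSet:
    """Planted diplotypes; the confident region is the whole genome."""

    records: list[TruthRecord]
    confident_length: int

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Diplome:
    """One diploid sample: reference plus two haplotype sequences."""

    haplotypes: dict[str, tuple[str, str]]   # contig -> (hap A, hap B)
    truth: TruthSet


# ---------------------------------------------------------------------------
# Truth simulation
# ---------------------------------------------------------------------------

def _random_reference(cfg: SimConfig, rng: np.random.Generator) -> ReferenceGenome:
    per = cfg.genome_length // cfg.contig_count
    contigs = {}
    for i in range(cfg.contig_count):
        n = per if i < cfg.contig_count - 1 else cfg.genome_length - per * (cfg.contig_count - 1)
        codes = rng.integers(0, 4, size=n)
        contigs[f"chr{i + 1}"] = bytes(_CODE_TO_BASE[codes]).decode()
    return ReferenceGenome(contigs)


def _draw_events(ref: ReferenceGenome, cfg: SimConfig,
                 rng: np.random.Generator) -> list[VariantEvent]:
    """Per-site Bernoulli draws; events conflicting with an already
    accepted indel's footprint (plus a small normalization buffer) are
    re-drawn by omission."""
    bases = "ACGT"
    events: list[VariantEvent] = []
    p_geom = 1.0 / cfg.indel_mean
    for contig, seq in ref.contigs.items():
        n = len(seq)
        lo, hi = cfg.edge_margin, n - cfg.edge_margin
        if hi <= lo:
            continue
        site_rate = cfg.snv_rate + cfg.indel_rate
        if site_rate == 0:
            continue
        positions = np.nonzero(rng.random(hi - lo) < site_rate)[0] + lo
        # exclusive end of the last accepted event's footprint (plus
        # buffer); events whose normalized representation would reach
        # back into it are dropped, so sites never overlap
        last_end = -1
        for pos in positions:
            pos = int(pos)
            if pos < last_end:
                continue
            is_indel = rng.random() < cfg.indel_rate / site_rate
            refbase = seq[pos]
            if not is_indel:
                alt = bases[(bases.index(refbase) + rng.integers(1, 4)) % 4]
                events.append(VariantEvent(contig, pos, refbase, alt))
                last_end = pos + 1
                continue
            size = int(min(cfg.indel_max, rng.geometric(p_geom)))
            if rng.random() < 0.5:  # insertion
                ins = "".join(bases[c] for c in rng.integers(0, 4, size=size))
                p, r, a = normalize_variant(seq, pos, refbase, refbase + ins)
            else:                   # deletion
                if pos + 1 + size >= hi:
                    continue
                p, r, a = normalize_variant(seq, pos, seq[pos:pos + 1 + size], refbase)
            if p < last_end + 2:
                continue  # left-normalization collided with the previous site
            events.append(VariantEvent(contig, p, r, a))
            last_end = pos + size + 12  # indel footprint plus buffer
    return events


def _apply_events(seq: str, events: list[tuple[VariantEvent, bool]]) -> str:
    """Apply the flagged events (sorted by position) to one contig."""
    parts = []
    cursor = 0
    for ev, keep in sorted(events, key=lambda t: t[0].position):
        if not keep:
            continue
        parts.append(seq[cursor:ev.position])
        parts.append(ev.alt)
        cursor = ev.position + len(ev.ref)
    parts.append(seq[cursor:])
    return "".join(parts)


def _sample_diplome(ref: ReferenceGenome, cfg: SimConfig,
                    rng: np.random.Generator
                    ) -> tuple[Diplome, dict[str, list[tuple[VariantEvent, bool, bool]]]]:
    """Draw one diploid sample; also return per-haplotype event flags
    (event, on haplotype A, on haplotype B) for trio transmission."""
    events = _draw_events(ref, cfg, rng)
    records: list[TruthRecord] = []
    flags: dict[str, list[tuple[VariantEvent, bool, bool]]] = {c: [] for c in ref.contigs}
    for ev in events:
        hom = bool(rng.random() < 0.5)
        on_a = hom or bool(rng.random() < 0.5)
        on_b = hom or not on_a
        records.append(TruthRecord(ev, (1, 1) if hom else (0, 1)))
        flags[ev.contig].append((ev, on_a, on_b))
    haplotypes = {}
    for contig, seq in ref.contigs.items():
        evs = flags[contig]
        hap_a = _apply_events(seq, [(e, a) for e, a, _ in evs])
        hap_b = _apply_events(seq, [(e, b) for e, _, b in evs])
        haplotypes[contig] = (hap_a, hap_b)
    truth = TruthSet(sorted(records, key=lambda r: r.key()),
                     confident_length=ref.total_length())
    return Diplome(haplotypes, truth), flags


def simulate_truth(cfg: SimConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[ReferenceGenome, Diplome]:
    """Generate a reference and a diploid sample with planted variants.

    Events are drawn per site at the configured rates; genotypes are
    het or hom-alt with equal probability, het alleles assigned to a
    random haplotype.  Seeded runs are byte-identical.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ref = _random_reference(cfg, rng)
    diplome, _ = _sample_diplome(ref, cfg, rng)
    return ref, diplome


@dataclass
class TrioTruth:
    mother: Diplome
    father: Diplome
    child: Diplome
    de_novo: list[TruthRecord]


def simulate_trio(cfg: SimConfig, n_de_novo: int = 1,
                  rng: np.random.Generator | None = None
                  ) -> tuple[ReferenceGenome, TrioTruth]:
    """Mother and father simulated independently on one reference; the
    child inherits one haplotype from each (Mendelian transmission) plus
    optional de novo SNVs on the maternal haplotype."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ref = _random_reference(cfg, rng)
    mother, mflags = _sample_diplome(ref, cfg, rng)
    father, fflags = _sample_diplome(ref, cfg, rng)

    mi = int(rng.integers(0, 2))  # transmitted maternal haplotype (0=A)
    fi = int(rng.integers(0, 2))

    def transmitted(flags, which: int) -> dict[str, list[VariantEvent]]:
        out: dict[str, list[VariantEvent]] = {c: [] for c in ref.contigs}
        for contig, evs in flags.items():
            for ev, on_a, on_b in evs:
                if (on_a, on_b)[which]:
                    out[contig].append(ev)
        return out

    maternal = transmitted(mflags, mi)
    paternal = transmitted(fflags, fi)

    # de novo SNVs on the maternal-origin haplotype, clear of other events
    de_novo: list[TruthRecord] = []
    contig0 = list(ref.contigs)[0]
    seq0 = ref.contigs[contig0]
    occupied = {ev.position for evs in (maternal, paternal)
                for ev in evs[contig0]}
    attempts = 0
    while len(de_novo) < n_de_novo and attempts < 100 * (n_de_novo + 1):
        attempts += 1
        pos = int(rng.integers(cfg.edge_margin, len(seq0) - cfg.edge_margin))
        if any(abs(pos - p) < 15 for p in occupied):
            continue
        refbase = seq0[pos]
        alt = "ACGT"[("ACGT".index(refbase) + int(rng.integers(1, 4))) % 4]
        ev = VariantEvent(contig0, pos, refbase, alt)
        de_novo.append(TruthRecord(ev, (0, 1)))
        maternal[contig0].append(ev)
        occupied.add(pos)

    child_haps = {}
    for contig, seq in ref.contigs.items():
        hap_m = _apply_events(seq, [(e, True) for e in maternal[contig]])
        hap_p = _apply_events(seq, [(e, True) for e in paternal[contig]])
        child_haps[contig] = (hap_m, hap_p)

    child_records = []
    mset = {(ev.contig, ev.position, ev.ref, ev.alt)
            for evs in maternal.values() for ev in evs}
    pset = {(ev.contig, ev.position, ev.ref, ev.alt)
            for evs in paternal.values() for ev in evs}
    for key in sorted(mset | pset):
        gt = (1, 1) if (key in mset and key in pset) else (0, 1)
        child_records.append(TruthRecord(VariantEvent(*key), gt))
    child = Diplome(child_haps, TruthSet(child_records, ref.total_length()))
    return ref, TrioTruth(mother, father, child, de_novo)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(haplotypes: dict[str, tuple[str, ...]], cfg: SimConfig,
                   rng: np.random.Generator | None = None,
                   genome_length: int | None = None) -> list[tuple[Read, Read]]:
    """Paired 2 x ``read_length`` reads at the configured coverage.

    Pair count = round(coverage * genome_length / (2 * read_length));
    fragments are drawn uniformly from a random haplotype with insert
    ~ Normal(mean, sd) truncated at twice the read length; base errors
    are i.i.d. at ``base_error_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if genome_length is None:
        genome_length = sum(len(h[0]) for h in haplotypes.values())
    L = cfg.read_length
    n_pairs = round(cfg.coverage * genome_length / (2 * L))

    contigs = list(haplotypes)
    hap_codes: list[tuple[str, np.ndarray]] = []
    for contig in contigs:
        for hap in haplotypes[contig]:
            hap_codes.append((contig, encode(hap)))
    weights = np.array([len(c) for _, c in hap_codes], dtype=float)
    weights /= weights.sum()

    quals = np.full(L, cfg.base_quality, dtype=np.uint8)
    if cfg.quality_decay > 0:
        quals = np.maximum(
            2, cfg.base_quality - (np.arange(L) * cfg.quality_decay)).astype(np.uint8)

    hap_idx = rng.choice(len(hap_codes), size=n_pairs, p=weights)
    inserts = np.maximum(2 * L, np.rint(
        rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs))).astype(np.int64)

    pairs: list[tuple[Read, Read]] = []
    for i in range(n_pairs):
        contig, codes = hap_codes[hap_idx[i]]
        insert = int(min(inserts[i], len(codes)))
        start = int(rng.integers(0, len(codes) - insert + 1))
        frag1 = codes[start:start + L].copy()
        frag2 = codes[start + insert - L:start + insert].copy()
        frag2 = 3 - frag2[::-1]  # reverse complement in 2-bit space
        for frag in (frag1, frag2):
            errs = np.nonzero(rng.random(L) < cfg.base_error_rate)[0]
            if len(errs):
                frag[errs] = (frag[errs] + rng.integers(1, 4, size=len(errs))) % 4
        name = f"sim_{i}_{contig}_{start}_{insert}_h{hap_idx[i]}"
        pairs.append((Read(name, bytes(_CODE_TO_BASE[frag1]).decode(), quals.copy()),
                      Read(name, bytes(_CODE_TO_BASE[frag2]).decode(), quals.copy())))
    return pairs


def write_fastq(pairs: list[tuple[Read, Read]], path1: str, path2: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    for path, idx in ((path1, 0), (path2, 1)):
        records = []
        for pair in pairs:
            read = pair[idx]
            rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in read.base_qualities]
            records.append(rec)
        SeqIO.write(records, path, "fastq")


def read_fastq_pairs(path1: str, path2: str) -> list[tuple[Read, Read]]:
    from Bio import SeqIO
    out = []
    for r1, r2 in zip(SeqIO.parse(path1, "fastq"), SeqIO.parse(path2, "fastq")):
        out.append((
            Read(r1.id, str(r1.seq).upper(),
                 np.array(r1.letter_annotations["phred_quality"], dtype=np.uint8)),
            Read(r2.id, str(r2.seq).upper(),
                 np.array(r2.letter_annotations["phred_quality"], dtype=np.uint8))))
    return out


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    tp: int
    fp: int
    fn: int
    genotype_tp: int
    confident_length: int

    @property
    def sensitivity(self) -> float:
        total = self.tp + self.fn
        return self.tp / total if total else 0.0

    @property
    def specificity(self) -> float:
        nonvariant = self.confident_length - (self.tp + self.fn)
        return 1.0 - self.fp / nonvariant if nonvariant > 0 else 1.0

    @property
    def genotype_sensitivity(self) -> float:
        total = self.tp + self.fn
        return self.genotype_tp / total if total else 0.0

    @property
    def genotype_specificity(self) -> float:
        # any call at a non-variant site is a genotype error there
        nonvariant = self.confident_length - (self.tp + self.fn)
        return 1.0 - self.fp / nonvariant if nonvariant > 0 else 1.0

    def to_tsv(self) -> str:
        lines = [
            "# specificity denominator: confident-region non-variant positions"
            " (genome length - truth count)",
            "metric\tvalue",
            f"TP\t{self.tp}",
            f"FP\t{self.fp}",
            f"FN\t{self.fn}",
            f"sensitivity\t{self.sensitivity:.6f}",
            f"specificity\t{self.specificity:.6f}",
            f"genotype_sensitivity\t{self.genotype_sensitivity:.6f}",
            f"genotype_specificity\t{self.genotype_specificity:.6f}",
        ]
        return "\n".join(lines) + "\n"


def _decompose(call: VariantCall, ref: ReferenceGenome) -> list[tuple[tuple, int]]:
    """Split a (possibly multi-allelic) call into normalized
    (contig, pos, ref, alt) allele keys with their genotype copy count."""
    seq = ref.contigs[call.contig]
    out = []
    for ai, alt in enumerate(call.alts, start=1):
        copies = sum(1 for g in call.genotype if g == ai)
        if copies == 0:
            continue
        p, r, a = normalize_variant(seq, call.position, call.ref, alt)
        out.append(((call.contig, p, r, a), copies))
    return out


def evaluate_concordance(calls: list[VariantCall], truth: TruthSet,
                         ref: ReferenceGenome) -> ConcordanceReport:
    """Allele-exact concordance after left-normalization on the shared
    reference.  Genotype-level truth match additionally requires the
    exact diplotype (copy number of the alt allele)."""
    truth_by_key = {rec.key(): rec for rec in truth.records}
    call_alleles: dict[tuple, int] = {}
    for call in calls:
        for key, copies in _decompose(call, ref):
            call_alleles[key] = max(call_alleles.get(key, 0), copies)

    tp = gt_tp = fp = 0
    for key, copies in call_alleles.items():
        rec = truth_by_key.get(key)
        if rec is None:
            fp += 1
            continue
        tp += 1
        truth_copies = sum(1 for g in rec.genotype if g == 1)
        if copies == truth_copies:
            gt_tp += 1
    fn = len(truth.records) - tp
    return ConcordanceReport(tp, fp, fn, gt_tp, truth.confident_length)


def truth_to_calls(truth: TruthSet) -> list[VariantCall]:
    """Represent a truth set as a call list (for evaluator round trips
    and VCF export)."""
    calls = []
    for rec in truth.records:
        ev = rec.event
        calls.append(VariantCall(ev.contig, ev.position, ev.ref, [ev.alt],
                                 rec.genotype, 99.0, 99, 0, [0, 0]))
    return calls
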