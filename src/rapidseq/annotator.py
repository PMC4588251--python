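"""Variant consequence prediction and ACMG-style categorization.

Each variant is evaluated against transcript geometry (exons, CDS,
splice boundaries) and assigned the most severe consequence across
overlapping transcripts, then mapped to a pathogenicity category:

* **1** - previously reported disease-causing (warehouse knowledge);
* **2** - expected pathogenic by consequence type: loss of initiation,
  premature stop, stop disruption, frameshifting indel, splice
  disruption (intronic positions +/-1,2 of an exon boundary);
* **3** - potentially causal variants of unknown significance:
  non-synonymous substitutions, in-frame indels, polypyrimidine-tract
  (acceptor -3..-20) and exonic splice-region changes;
* **4** - probably not causative: synonymous without a cryptic-splice
  motif, intronic >20 nt from any boundary, or common in unaffected
  individuals (MAF >= 2% by default);
* **5** - known benign.

Allele frequencies come from a local variant-warehouse table
(variant -> allele count / sample count), with
MAF = allele count / (2 * sample count).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from rapidseq.reference import ReferenceGenome
from rapidseq.variants import VariantCall, VariantEvent

# consequence labels, most severe first
SEVERITY_ORDER = [
    "loss_of_initiation",
    "premature_stop",
    "stop_disruption",
    "frameshift_indel",
    "splice_disruption",
    "nonsynonymous",
    "inframe_indel",
    "polypyrimidine_tract",
    "splice_region_exonic",
    "synonymous",
    "deep_intronic",
    "other",
    "intergenic",
]
_SEVERITY = {c: i for i, c in enumerate(SEVERITY_ORDER)}

CATEGORY_2 = {"loss_of_initiation", "premature_stop", "stop_disruption",
              "frameshift_indel", "splice_disruption"}
CATEGORY_3 = {"nonsynonymous", "inframe_indel", "polypyrimidine_tract",
              "splice_region_exonic"}

KNOWN_DISEASE = "disease-causing"
KNOWN_BENIGN = "benign"
NOVEL = "novel"

DEEP_INTRONIC_DISTANCE = 20   # ">20 nt from the intron/exon boundary"
SPLICE_REGION_EXONIC_NT = 3
COMMON_MAF_THRESHOLD = 0.02


@dataclass
class Transcript:
    id: str
    gene: str
    contig: str
    strand: str                      # '+' or '-'
    exons: list[tuple[int, int]]     # genomic, 0-based half-open, sorted
    cds: tuple[int, int] | None      # genomic interval

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in {self.id}")
        if self.cds is not None:
            lo, hi = self.cds
            if not (self.exons[0][0] <= lo and hi <= self.exons[-1][1]):
                raise ValueError(f"CDS outside exon span in {self.id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_exon_slices(self) -> list[tuple[int, int]]:
        if self.cds is None:
            return []
        lo, hi = self.cds
        out = []
        for s, e in self.exons:
            a, b = max(s, lo), min(e, hi)
            if a < b:
                out.append((a, b))
        return out

    def cds_sequence(self, ref: ReferenceGenome) -> str:
        seq = "".join(ref.contigs[self.contig][a:b] for a, b in self.cds_exon_slices())
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def genomic_to_cds(self, pos: int) -> int | None:
        """CDS offset (0-based, strand-aware) of a genomic position."""
        slices = self.cds_exon_slices()
        if not slices:
            return None
        off = 0
        for a, b in slices:
            if a <= pos < b:
                fwd = off + (pos - a)
                if self.strand == "+":
                    return fwd
                total = sum(e - s for s, e in slices)
                return total - fwd - 1
            off += b - a
        return None


@dataclass
class GeneModel:
    transcripts: list[Transcript]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for tx in self.transcripts:
            self._trees.setdefault(tx.contig, IntervalTree()).addi(
                tx.start, max(tx.end, tx.start + 1), tx)

    def overlapping(self, contig: str, start: int, end: int) -> list[Transcript]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, max(end, start + 1))),
                      key=lambda t: t.id)

    @classmethod
    def from_bed12(cls, path: str | Path) -> "GeneModel":
        """BED12 gene models; the name field may be ``GENE:TRANSCRIPT``
        (else the gene name equals the transcript name)."""
        txs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5]
                thick_s, thick_e = int(f[6]), int(f[7])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
                gene, _, tx_id = name.partition(":")
                if not tx_id:
                    gene = tx_id = name
                cds = (thick_s, thick_e) if thick_e > thick_s else None
                txs.append(Transcript(tx_id, gene, chrom, strand, exons, cds))
        return cls(txs)


# ---------------------------------------------------------------------------
# Consequence prediction
# ---------------------------------------------------------------------------

def _intron_context(tx: Transcript, pos: int) -> tuple[int, int] | None:
    """(donor_offset, acceptor_offset), both 1-based distances into the
    intron from the transcript's 5' (donor) and 3' (acceptor) splice
    sites, or None if ``pos`` is not intronic for this transcript."""
    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        if e1 <= pos < s2:
            if tx.strand == "+":
                return (pos - e1 + 1, s2 - pos)
            return (s2 - pos, pos - e1 + 1)
    return None


def _exonic_near_splice(tx: Transcript, pos: int) -> bool:
    for i, (s, e) in enumerate(tx.exons):
        if s <= pos < e:
            near = False
            if i > 0 and pos - s < SPLICE_REGION_EXONIC_NT:
                near = True
            if i < len(tx.exons) - 1 and e - pos <= SPLICE_REGION_EXONIC_NT:
                near = True
            return near
    return False


def _creates_splice_motif(ref: ReferenceGenome, v: VariantEvent) -> bool:
    """Crude cryptic-splice check for synonymous SNVs: does the alt
    sequence create a GT or AG dinucleotide within 3 nt that the
    reference lacks?"""
    seq = ref.contigs[v.contig]
    lo = max(0, v.position - 3)
    hi = min(len(seq), v.position + len(v.ref) + 3)
    before = seq[lo:hi]
    after = seq[lo:v.position] + v.alt + seq[v.position + len(v.ref):hi]
    for motif in ("GT", "AG"):
        if after.count(motif) > before.count(motif):
            return True
    return False


def _snv_coding_consequence(tx: Transcript, v: VariantEvent,
                            ref: ReferenceGenome) -> str | None:
    cds_off = tx.genomic_to_cds(v.position)
    if cds_off is None:
        return None
    cds = tx.cds_sequence(ref)
    codon_i = cds_off // 3
    frame = cds_off % 3
    codon = cds[codon_i * 3:codon_i * 3 + 3]
    if len(codon) < 3:
        return "other"
    base = v.alt if tx.strand == "+" else str(Seq(v.alt).reverse_complement())
    alt_codon = codon[:frame] + base + codon[frame + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if codon_i == 0 and aa_alt != aa_ref:
        return "loss_of_initiation"
    if aa_alt == "*" and aa_ref != "*":
        return "premature_stop"
    if aa_ref == "*" and aa_alt != "*":
        return "stop_disruption"
    if aa_ref == aa_alt:
        return "synonymous"
    return "nonsynonymous"


def _transcript_consequence(tx: Transcript, v: VariantEvent,
                            ref: ReferenceGenome) -> tuple[str, bool]:
    """(consequence, cryptic_splice_flag) for one transcript."""
    is_indel = v.type != "SNV"
    # affected genomic footprint: for anchored indels the anchor base is
    # unchanged, the edit happens after it
    lo = v.position + (1 if is_indel else 0)
    hi = max(v.position + len(v.ref), lo + 1)
    if hi <= tx.start or lo >= tx.end:
        return "intergenic", False

    positions = range(lo, hi)
    # splice disruption: any affected base at intronic +/-1,2
    contexts = [(_intron_context(tx, p), p) for p in positions]
    for ctx, _ in contexts:
        if ctx and min(ctx) <= 2:
            return "splice_disruption", False

    exonic = [p for p in positions if any(s <= p < e for s, e in tx.exons)]
    if exonic:
        if is_indel:
            in_cds = tx.cds is not None and any(
                tx.genomic_to_cds(p) is not None for p in exonic)
            if in_cds:
                return ("frameshift_indel" if v.size % 3 else "inframe_indel"), False
            if any(_exonic_near_splice(tx, p) for p in exonic):
                return "splice_region_exonic", False
            return "other", False
        cons = _snv_coding_consequence(tx, v, ref)
        if cons == "synonymous":
            return cons, _creates_splice_motif(ref, v)
        if cons is not None and cons != "other":
            return cons, False
        if _exonic_near_splice(tx, v.position):
            return "splice_region_exonic", False
        return "other", False

    # purely intronic
    intron = [ctx for ctx, _ in contexts if ctx is not None]
    if intron:
        donor = min(ctx[0] for ctx in intron)
        acceptor = min(ctx[1] for ctx in intron)
        if 3 <= acceptor <= DEEP_INTRONIC_DISTANCE:
            return "polypyrimidine_tract", False
        if min(donor, acceptor) > DEEP_INTRONIC_DISTANCE:
            return "deep_intronic", False
        return "other", False
    return "other", False


def predict_consequence(v: VariantEvent, gm: GeneModel,
                        ref: ReferenceGenome) -> tuple[str, bool]:
    """Most severe consequence across overlapping transcripts, plus a
    cryptic-splice flag relevant only for synonymous variants."""
    lo = v.position
    hi = v.position + len(v.ref)
    txs = gm.overlapping(v.contig, lo, hi)
    if not txs:
        return "intergenic", False
    best, best_flag = "intergenic", False
    for tx in txs:
        cons, flag = _transcript_consequence(tx, v, ref)
        if _SEVERITY[cons] < _SEVERITY[best]:
            best, best_flag = cons, flag
    return best, best_flag


def assign_category(consequence: str, known_status: str, maf: float,
                    cryptic_splice: bool = False,
                    common_threshold: float = COMMON_MAF_THRESHOLD) -> int:
    """ACMG-style category 1-5; known status wins over consequence."""
    if known_status == KNOWN_DISEASE:
        return 1
    if known_status == KNOWN_BENIGN:
        return 5
    if maf >= common_threshold:
        return 4
    if consequence in CATEGORY_2:
        return 2
    if consequence in CATEGORY_3:
        return 3
    if consequence == "synonymous" and cryptic_splice:
        return 3
    return 4


# ---------------------------------------------------------------------------
# Variant warehouse
# ---------------------------------------------------------------------------

@dataclass
class VariantWarehouse:
    """Local cohort table: variant key -> (allele count, sample count),
    with known disease-causing / benign sets."""

    table: dict[tuple, tuple[int, int]] = field(default_factory=dict)
    disease_causing: set[tuple] = field(default_factory=set)
    benign: set[tuple] = field(default_factory=set)

    def maf(self, v: VariantEvent) -> float:
        entry = self.table.get((v.contig, v.position, v.ref, v.alt))
        if entry is None:
            return 0.0
        ac, ns = entry
        return ac / (2 * ns) if ns else 0.0

    def known_status(self, v: VariantEvent) -> str:
        key = (v.contig, v.position, v.ref, v.alt)
        if key in self.disease_causing:
            return KNOWN_DISEASE
        if key in self.benign:
            return KNOWN_BENIGN
        return NOVEL

    def contains(self, v: VariantEvent) -> bool:
        return (v.contig, v.position, v.ref, v.alt) in self.table

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantWarehouse":
        """Columns: contig, pos (1-based), ref, alt, allele_count,
        sample_count, status (optional: disease-causing|benign)."""
        df = pd.read_csv(path, sep="\t", dtype={"contig": str})
        wh = cls()
        for row in df.itertuples(index=False):
            key = (row.contig, int(row.pos) - 1, row.ref, row.alt)
            wh.table[key] = (int(row.allele_count), int(row.sample_count))
            status = getattr(row, "status", NOVEL)
            if status == KNOWN_DISEASE:
                wh.disease_causing.add(key)
            elif status == KNOWN_BENIGN:
                wh.benign.add(key)
        return wh


# ---------------------------------------------------------------------------
# Annotation driver
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedVariant:
    event: VariantEvent
    genotype: tuple[int, int]
    gq: int
    allele_depths: list[int]
    consequence: str
    category: int
    maf: float
    known_status: str
    genes: list[str]

    def to_dict(self) -> dict:
        ev = self.event
        return {
            "contig": ev.contig, "pos": ev.position + 1,
            "ref": ev.ref, "alt": ev.alt,
            "genotype": "/".join(str(g) for g in self.genotype),
            "gq": self.gq, "allele_depths": self.allele_depths,
            "consequence": self.consequence, "category": self.category,
            "maf": self.maf, "known_status": self.known_status,
            "genes": self.genes,
        }


def annotate_calls(calls: list[VariantCall], gm: GeneModel,
                   warehouse: VariantWarehouse,
                   ref: ReferenceGenome) -> list[AnnotatedVariant]:
    out = []
    for call in calls:
        for ai, alt in enumerate(call.alts, start=1):
            if ai not in call.genotype:
                continue
            ev = VariantEvent(call.contig, call.position, call.ref, alt)
            cons, cryptic = predict_consequence(ev, gm, ref)
            maf = warehouse.maf(ev)
            status = warehouse.known_status(ev)
            cat = assign_category(cons, status, maf, cryptic)
            genes = sorted({tx.gene for tx in gm.overlapping(
                ev.contig, ev.position, ev.position + len(ev.ref))})
            gt = tuple(1 if g == ai else 0 for g in call.genotype) \
                if len(call.alts) > 1 else call.genotype
            out.append(AnnotatedVariant(ev, tuple(sorted(gt)), call.gq,
                                        call.allele_depths, cons, cat, maf,
                                        status, genes))
    return out


def write_annotation_json(annos: list[AnnotatedVariant], path: str | Path,
                          sample: str = "SAMPLE") -> None:
    doc = {"sample": sample, "variants": [a.to_dict() for a in annos]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_annotation_json(path: str | Path) -> list[AnnotatedVariant]:
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for d in doc["variants"]:
        gt = tuple(int(x) for x in d["genotype"].split("/"))
        out.append(AnnotatedVariant(
            VariantEvent(d["contig"], d["pos"] - 1, d["ref"], d["alt"]),
            gt, d["gq"], d.get("allele_depths", []), d["consequence"],
            d["category"], d["maf"], d["known_status"], d.get("genes", [])))
    return out
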