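"""Variant events, left-normalization, and VCF I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pysam

from rapidseq.reference import ReferenceGenome

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"

#: largest indel the caller will represent (ref or alt allele length)
MAX_INDEL_LEN = 470


@dataclass(frozen=True, order=True)
class VariantEvent:
    """A left-normalized small variant in VCF-style representation:
    ``position`` is 0-based, and indel alleles share a leading anchor
    base."""

    contig: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")

    @property
    def type(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return SNV
        return INSERTION if len(self.alt) > len(self.ref) else DELETION

    @property
    def size(self) -> int:
        return abs(len(self.alt) - len(self.ref))


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Drop shared suffix then shared prefix bases (keeping at least one
    base in each allele); returns the parsimonious representation."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(contig_seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-normalize an allele pair against the contig sequence.

    The standard left-alignment algorithm: while both alleles end with
    the same base, truncate it (extending leftward with the preceding
    reference base whenever an allele would become empty), then strip
    any shared leading bases beyond the anchor.
    """
    if not ref or not alt:
        raise ValueError("alleles must be non-empty")
    while True:
        changed = False
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            last = ref[-1]
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 0:
                    # cannot extend left past the contig start; undo
                    ref, alt = ref + last, alt + last
                    break
                prev = contig_seq[pos - 1]
                ref, alt, pos = prev + ref, prev + alt, pos - 1
            changed = True
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
            changed = True
        if not changed:
            break
    return pos, ref, alt


@dataclass
class VariantCall:
    """A called site: winning diplotype plus per-site qualities."""

    contig: str
    position: int            # 0-based
    ref: str
    alts: list[str]          # ALT alleles in VCF order
    genotype: tuple[int, int]  # allele indexes, 0 = REF
    qual: float
    gq: int
    depth: int
    allele_depths: list[int]   # per allele, REF first

    def key(self) -> tuple:
        return (self.contig, self.position, self.ref, tuple(sorted(self.alts)))


def write_vcf(calls: list[VariantCall], ref: ReferenceGenome,
              path: str | Path, sample: str = "SAMPLE") -> None:
    header = pysam.VariantHeader()
    header.add_meta("source", "rapidseq")
    for name, length in ref.lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Total read depth at the site")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allele depths")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (list(ref.names).index(c.contig),
                                                 c.position)):
            rec = vcf.new_record(
                contig=call.contig, start=call.position,
                stop=call.position + len(call.ref),
                alleles=[call.ref] + list(call.alts),
                qual=round(call.qual, 2), filter="PASS")
            rec.info["DP"] = call.depth
            rec.samples[sample]["GT"] = call.genotype
            rec.samples[sample].phased = False
            rec.samples[sample]["AD"] = call.allele_depths
            rec.samples[sample]["DP"] = call.depth
            rec.samples[sample]["GQ"] = call.gq
            vcf.write(rec)


def read_vcf(path: str | Path) -> list[VariantCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0] if list(vcf.header.samples) else None
        for rec in vcf:
            if sample is not None:
                fmt = rec.samples[sample]
                gt = tuple(a if a is not None else 0 for a in (fmt.get("GT") or (0, 0)))
                gq = int(fmt.get("GQ") or 0)
                ad = [x for x in (fmt.get("AD") or []) if x is not None]
                dp = int(fmt.get("DP") or 0)
            else:  # pragma: no cover - sites-only VCF
                gt, gq, ad, dp = (0, 0), 0, [], 0
            calls.append(VariantCall(
                contig=rec.contig, position=rec.start, ref=rec.ref,
                alts=list(rec.alts or []), genotype=gt,
                qual=float(rec.qual or 0), gq=gq, depth=dp,
                allele_depths=[int(x) for x in ad]))
    return calls
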