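"""Consequence prediction and category assignment on a constructed toy
gene, including the plus/minus strand mirror property."""

import itertools

import pytest
from Bio.Seq import Seq

from rapidseq.annotator import (CATEGORY_2, CATEGORY_3, COMMON_MAF_THRESHOLD,
                                KNOWN_BENIGN, KNOWN_DISEASE, NOVEL,
                                SEVERITY_ORDER, GeneModel, Transcript,
                                VariantWarehouse, annotate_calls,
                                assign_category, predict_consequence,
                                read_annotation_json, write_annotation_json)
from rapidseq.reference import ReferenceGenome, revcomp
from rapidseq.variants import VariantCall, VariantEvent

from conftest import make_seq


def build_toy_gene():
    """Two-exon plus-strand gene with known codons.

    exon1 [100, 160), intron [160, 240), exon2 [240, 320); CDS
    [130, 280): 30 nt in exon 1 (codons 0-9), 40... the CDS length is
    30 + 40 = 70 -> pad exon2 CDS to 42 so length 72 (divisible by 3).
    """
    L = 500
    seq = list(make_seq(L, seed=42))
    exon1 = (100, 160)
    exon2 = (240, 320)
    cds = (130, 172 + 130 - 30)  # placeholder, fixed below
    # CDS: [130,160) in exon1 (30 nt) + [240,282) in exon2 (42 nt) = 72 nt
    cds = (130, 282)
    codons = ("ATG" + "AAA" * 9          # exon1: start + 9 Lys codons
              + "AAA" * 13 + "TAA")      # exon2: 13 Lys + stop
    assert len(codons) == 72
    seq[130:160] = codons[:30]
    seq[240:282] = codons[30:]
    # make sure no stray ATG/stop confusion in the remaining exon2 UTR
    seq = "".join(seq)
    tx = Transcript("TX1", "GENE1", "chr1", "+", [exon1, exon2], cds)
    ref = ReferenceGenome({"chr1": seq})
    return ref, GeneModel([tx]), tx


@pytest.fixture(scope="module")
def toy_gene():
    return build_toy_gene()


def ev(pos, ref_allele, alt):
    return VariantEvent("chr1", pos, ref_allele, alt)


def test_synonymous_lys_codon(toy_gene):
    ref, gm, _ = toy_gene
    # codon 1 is AAA (Lys) at [133,136); AAA->AAG stays Lys
    cons, _ = predict_consequence(ev(135, "A", "G"), gm, ref)
    assert cons == "synonymous"


def test_nonsynonymous_substitution(toy_gene):
    ref, gm, _ = toy_gene
    # AAA->ACA (Lys->Thr) at codon 2, middle base
    cons, _ = predict_consequence(ev(137, "A", "C"), gm, ref)
    assert cons == "nonsynonymous"


def test_premature_stop(toy_gene):
    ref, gm, _ = toy_gene
    # AAA->TAA at codon 3 first base
    cons, _ = predict_consequence(ev(139, "A", "T"), gm, ref)
    assert cons == "premature_stop"


def test_loss_of_initiation(toy_gene):
    ref, gm, _ = toy_gene
    cons, _ = predict_consequence(ev(130, "A", "C"), gm, ref)  # ATG -> CTG
    assert cons == "loss_of_initiation"


def test_stop_disruption(toy_gene):
    ref, gm, _ = toy_gene
    # stop codon TAA at [279,282); TAA->CAA
    cons, _ = predict_consequence(ev(279, "T", "C"), gm, ref)
    assert cons == "stop_disruption"


def test_acceptor_minus_2_is_splice_disruption(toy_gene):
    ref, gm, _ = toy_gene
    # intron [160,240); acceptor side is position 238 (-2) and 239 (-1)
    seq = ref.contigs["chr1"]
    cons, _ = predict_consequence(ev(238, seq[238], "G" if seq[238] != "G" else "C"),
                                  gm, ref)
    assert cons == "splice_disruption"


def test_donor_plus_1_is_splice_disruption(toy_gene):
    ref, gm, _ = toy_gene
    seq = ref.contigs["chr1"]
    cons, _ = predict_consequence(ev(160, seq[160], "G" if seq[160] != "G" else "C"),
                                  gm, ref)
    assert cons == "splice_disruption"


def test_acceptor_minus_3_is_polypyrimidine_tract(toy_gene):
    ref, gm, _ = toy_gene
    seq = ref.contigs["chr1"]
    cons, _ = predict_consequence(ev(237, seq[237], "A" if seq[237] != "A" else "C"),
                                  gm, ref)
    assert cons == "polypyrimidine_tract"


def test_intron_25nt_from_boundary_is_deep_intronic(toy_gene):
    ref, gm, _ = toy_gene
    seq = ref.contigs["chr1"]
    pos = 160 + 24  # 25th intron base from the donor, >20 from both ends
    assert 240 - pos > 20
    cons, _ = predict_consequence(ev(pos, seq[pos], "A" if seq[pos] != "A" else "C"),
                                  gm, ref)
    assert cons == "deep_intronic"


def test_frameshift_and_inframe_indels(toy_gene):
    ref, gm, _ = toy_gene
    seq = ref.contigs["chr1"]
    # 1-nt insertion inside the CDS
    cons, _ = predict_consequence(ev(140, seq[140], seq[140] + "A"), gm, ref)
    assert cons == "frameshift_indel"
    cons, _ = predict_consequence(ev(140, seq[140:143], seq[140]), gm, ref)
    assert cons == "frameshift_indel"  # 2-nt deletion
    cons, _ = predict_consequence(ev(139, seq[139:143], seq[139]), gm, ref)
    assert cons == "inframe_indel"


def test_variant_off_all_transcripts_is_intergenic(toy_gene):
    ref, gm, _ = toy_gene
    seq = ref.contigs["chr1"]
    cons, _ = predict_consequence(ev(450, seq[450], "A" if seq[450] != "A" else "C"),
                                  gm, ref)
    assert cons == "intergenic"


# ---------------------------------------------------------------------------
# Category assignment
# ---------------------------------------------------------------------------

def test_known_disease_causing_missense_is_category_1():
    assert assign_category("nonsynonymous", KNOWN_DISEASE, 0.0) == 1


def test_known_benign_wins_over_consequence():
    assert assign_category("frameshift_indel", KNOWN_BENIGN, 0.0) == 5


def test_novel_frameshift_is_category_2():
    assert assign_category("frameshift_indel", NOVEL, 0.0) == 2


def test_polypyrimidine_is_category_3():
    assert assign_category("polypyrimidine_tract", NOVEL, 0.0) == 3


def test_common_variant_is_category_4():
    assert assign_category("nonsynonymous", NOVEL, 0.05) == 4


def test_synonymous_with_cryptic_splice_flag_is_category_3():
    assert assign_category("synonymous", NOVEL, 0.0, cryptic_splice=True) == 3
    assert assign_category("synonymous", NOVEL, 0.0, cryptic_splice=False) == 4


def test_category_rule_table_is_complete_and_consistent():
    """Exhaustive cross-product: every consequence maps to exactly one
    category, consistent with the rule table."""
    for cons, status, maf, cryptic in itertools.product(
            SEVERITY_ORDER, (KNOWN_DISEASE, KNOWN_BENIGN, NOVEL),
            (0.0, 0.001, COMMON_MAF_THRESHOLD, 0.5), (False, True)):
        cat = assign_category(cons, status, maf, cryptic)
        assert cat in (1, 2, 3, 4, 5)
        if status == KNOWN_DISEASE:
            assert cat == 1
        elif status == KNOWN_BENIGN:
            assert cat == 5
        elif maf >= COMMON_MAF_THRESHOLD:
            assert cat == 4
        elif cons in CATEGORY_2:
            assert cat == 2
        elif cons in CATEGORY_3 or (cons == "synonymous" and cryptic):
            assert cat == 3
        else:
            assert cat == 4


# ---------------------------------------------------------------------------
# Strand mirror property
# ---------------------------------------------------------------------------

def test_minus_strand_mirror_gives_identical_consequences(toy_gene):
    ref, gm, tx = toy_gene
    seq = ref.contigs["chr1"]
    L = len(seq)
    mirror_seq = revcomp(seq)
    mirror_exons = [(L - e, L - s) for s, e in reversed(tx.exons)]
    mirror_cds = (L - tx.cds[1], L - tx.cds[0])
    mirror_tx = Transcript("TX1m", "GENE1", "chr1", "-", mirror_exons, mirror_cds)
    mirror_ref = ReferenceGenome({"chr1": mirror_seq})
    mirror_gm = GeneModel([mirror_tx])

    probe_positions = [130, 135, 137, 139, 160, 161, 184, 237, 238, 300, 450]
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for pos in probe_positions:
        base = seq[pos]
        alt = "A" if base != "A" else "G"
        plus_cons, _ = predict_consequence(ev(pos, base, alt), gm, ref)
        mpos = L - 1 - pos
        minus_cons, _ = predict_consequence(
            VariantEvent("chr1", mpos, comp[base], comp[alt]),
            mirror_gm, mirror_ref)
        assert minus_cons == plus_cons, f"position {pos}"


# ---------------------------------------------------------------------------
# Warehouse and JSON round trip
# ---------------------------------------------------------------------------

def test_warehouse_maf_and_status(tmp_path):
    path = tmp_path / "wh.tsv"
    path.write_text(
        "contig\tpos\tref\talt\tallele_count\tsample_count\tstatus\n"
        "chr1\t101\tA\tT\t39\t3900\tnovel\n"
        "chr1\t201\tG\tC\t2\t3900\tdisease-causing\n")
    wh = VariantWarehouse.from_tsv(path)
    assert wh.maf(VariantEvent("chr1", 100, "A", "T")) == pytest.approx(39 / 7800)
    assert wh.known_status(VariantEvent("chr1", 200, "G", "C")) == KNOWN_DISEASE
    assert wh.maf(VariantEvent("chr1", 300, "A", "T")) == 0.0
    assert not wh.contains(VariantEvent("chr1", 300, "A", "T"))


def test_annotation_json_round_trip(tmp_path, toy_gene):
    ref, gm, _ = toy_gene
    seq = ref.contigs["chr1"]
    calls = [VariantCall("chr1", 137, seq[137], ["C"], (0, 1), 60.0, 55, 30,
                         [14, 16])]
    annos = annotate_calls(calls, gm, VariantWarehouse(), ref)
    assert len(annos) == 1
    assert annos[0].consequence == "nonsynonymous"
    assert annos[0].category == 3
    assert annos[0].genes == ["GENE1"]
    path = tmp_path / "anno.json"
    write_annotation_json(annos, path)
    loaded = read_annotation_json(path)
    assert loaded[0].event == annos[0].event
    assert loaded[0].category == 3 and loaded[0].genotype == (0, 1)


def test_bed12_gene_model_round_trip(tmp_path, toy_gene):
    _, gm, tx = toy_gene
    bed = tmp_path / "genes.bed"
    sizes = ",".join(str(e - s) for s, e in tx.exons)
    starts = ",".join(str(s - tx.start) for s, e in tx.exons)
    bed.write_text(f"chr1\t{tx.start}\t{tx.end}\tGENE1:TX1\t0\t+\t"
                   f"{tx.cds[0]}\t{tx.cds[1]}\t0\t{len(tx.exons)}\t{sizes}\t{starts}\n")
    loaded = GeneModel.from_bed12(bed)
    ltx = loaded.transcripts[0]
    assert ltx.exons == tx.exons and ltx.cds == tx.cds
    assert ltx.gene == "GENE1" and ltx.id == "TX1" and ltx.strand == "+"
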