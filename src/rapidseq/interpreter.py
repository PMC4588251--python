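"""Phenotype-driven differential diagnosis and trio variant filtering.

Two cooperating pieces:

* a match-count differential: diseases annotated with HPO terms and
  causative genes are ranked by how many of the patient's entered terms
  they match (at least one match required), ties alphabetical;
* a dynamic variant filter over an annotated trio: pathogenicity
  category, allele frequency (or cohort uniqueness), and monogenic
  inheritance patterns (de novo, recessive including compound
  heterozygous and X-linked hemizygous, dominant, mitochondrial) are
  applied, and surviving genes are ranked against the differential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from rapidseq.annotator import AnnotatedVariant, VariantWarehouse
from rapidseq.variants import VariantEvent

GQ_MIN_DE_NOVO = 30
MT_CONTIGS = {"MT", "chrM", "chrMT", "M"}
X_CONTIGS = {"X", "chrX"}

DE_NOVO = "de_novo"
RECESSIVE = "recessive"
DOMINANT = "dominant"
X_LINKED = "x_linked"
MITOCHONDRIAL = "mitochondrial"
UNRESOLVED = "unresolved"


@dataclass
class Disease:
    id: str
    name: str
    terms: set[str]
    genes: set[str]
    inheritance: set[str] = field(default_factory=set)


@dataclass
class DiseaseAnnotationTable:
    diseases: list[Disease]

    def __post_init__(self) -> None:
        # diagnoses without known causative genes are uninformative for
        # genome filtering and are removed
        self.diseases = [d for d in self.diseases if d.genes and d.terms]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiseaseAnnotationTable":
        """Columns: disease_id, name, hpo_terms, genes, inheritance
        (semicolon-separated lists)."""
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        diseases = []
        for row in df.itertuples(index=False):
            diseases.append(Disease(
                id=row.disease_id, name=row.name,
                terms={t for t in row.hpo_terms.split(";") if t},
                genes={g for g in row.genes.split(";") if g},
                inheritance={m for m in getattr(row, "inheritance", "").split(";") if m}))
        return cls(diseases)


@dataclass
class PatientPhenotype:
    terms: set[str]

    @classmethod
    def from_file(cls, path: str | Path) -> "PatientPhenotype":
        with open(path) as fh:
            return cls({line.strip() for line in fh if line.strip()})


def build_differential(pheno: PatientPhenotype, table: DiseaseAnnotationTable,
                       max_diseases: int | None = None
                       ) -> tuple[list[tuple[str, int]], set[str]]:
    """Diseases matching at least one entered feature, ranked by the
    number of matching terms (descending; ties alphabetical by disease
    id), plus the union of their causative genes."""
    if not pheno.terms:
        raise ValueError("at least one patient term is required")
    scored = []
    for d in table.diseases:
        n = len(pheno.terms & d.terms)
        if n >= 1:
            scored.append((d.id, n))
    scored.sort(key=lambda t: (-t[1], t[0]))
    if max_diseases is not None:
        scored = scored[:max_diseases]
    listed = {d_id for d_id, _ in scored}
    genes = set()
    for d in table.diseases:
        if d.id in listed:
            genes |= d.genes
    return scored, genes


# ---------------------------------------------------------------------------
# Trio genotypes and inheritance
# ---------------------------------------------------------------------------

PROBAND, MOTHER, FATHER = "proband", "mother", "father"


@dataclass
class TrioVariant:
    """One annotated variant with genotypes across the trio (members
    lacking the call are homozygous reference unless marked missing)."""

    annotation: AnnotatedVariant
    genotypes: dict[str, tuple[int, int] | None]
    gq: dict[str, int]

    @property
    def event(self) -> VariantEvent:
        return self.annotation.event

    def carries(self, member: str) -> bool:
        gt = self.genotypes.get(member)
        return gt is not None and any(g > 0 for g in gt)

    def hom_alt(self, member: str) -> bool:
        gt = self.genotypes.get(member)
        return gt is not None and all(g > 0 for g in gt)


@dataclass
class TrioGenotypes:
    variants: list[TrioVariant]
    proband_sex: str = "unknown"     # 'male' | 'female' | 'unknown'
    affected: dict[str, bool] = field(default_factory=lambda: {
        PROBAND: True, MOTHER: False, FATHER: False})


def build_trio(proband: list[AnnotatedVariant],
               mother: list[AnnotatedVariant],
               father: list[AnnotatedVariant],
               proband_sex: str = "unknown",
               parents_called: bool = True) -> TrioGenotypes:
    """Join three annotated call sets on variant identity.  Proband-only
    variants are kept; a parent without the call is taken as hom-ref
    when ``parents_called`` (whole-genome calling genotypes reference
    positions too), else marked missing."""
    def index(annos):
        return {(a.event.contig, a.event.position, a.event.ref, a.event.alt): a
                for a in annos}
    pi, mi, fi = index(proband), index(mother), index(father)
    default = (0, 0) if parents_called else None
    variants = []
    for key in sorted(pi):
        a = pi[key]
        m = mi.get(key)
        f = fi.get(key)
        variants.append(TrioVariant(
            annotation=a,
            genotypes={PROBAND: a.genotype,
                       MOTHER: m.genotype if m else default,
                       FATHER: f.genotype if f else default},
            gq={PROBAND: a.gq,
                MOTHER: m.gq if m else (99 if parents_called else 0),
                FATHER: f.gq if f else (99 if parents_called else 0)}))
    return TrioGenotypes(variants)


def variant_inheritance(tv: TrioVariant, proband_sex: str,
                        gq_min: int = GQ_MIN_DE_NOVO) -> set[str]:
    """Single-variant inheritance labels (compound heterozygosity is a
    gene-level pattern, handled in :func:`infer_inheritance`)."""
    labels: set[str] = set()
    gt_p = tv.genotypes.get(PROBAND)
    gt_m = tv.genotypes.get(MOTHER)
    gt_f = tv.genotypes.get(FATHER)
    if gt_p is None or not tv.carries(PROBAND):
        return labels
    contig = tv.event.contig
    if contig in MT_CONTIGS:
        labels.add(MITOCHONDRIAL)
    if gt_m is None or gt_f is None:
        labels.add(UNRESOLVED)
    else:
        parents_ref = not any(g > 0 for g in gt_m) and not any(g > 0 for g in gt_f)
        if (parents_ref and tv.gq[PROBAND] >= gq_min
                and tv.gq[MOTHER] >= gq_min and tv.gq[FATHER] >= gq_min):
            labels.add(DE_NOVO)
    if tv.hom_alt(PROBAND):
        carriers = (gt_m is None or tv.carries(MOTHER)) and \
                   (gt_f is None or tv.carries(FATHER))
        if carriers:
            labels.add(RECESSIVE)
    elif contig in X_CONTIGS and proband_sex == "male":
        # X in a male: heterozygous call is effectively hemizygous
        labels.add(RECESSIVE)
        labels.add(X_LINKED)
    if not tv.hom_alt(PROBAND):
        labels.add(DOMINANT)   # affected-only model; see filter for de novo tie-in
    if contig in X_CONTIGS:
        labels.add(X_LINKED)
    return labels


def _parental_origin(tv: TrioVariant) -> str | None:
    """'maternal' / 'paternal' when exactly one parent carries a het
    variant; None when phase cannot be established."""
    m, f = tv.carries(MOTHER), tv.carries(FATHER)
    if m and not f:
        return "maternal"
    if f and not m:
        return "paternal"
    return None


def infer_inheritance(variants_in_gene: list[TrioVariant],
                      proband_sex: str = "unknown",
                      gq_min: int = GQ_MIN_DE_NOVO) -> dict[str, list[TrioVariant]]:
    """Gene-level inheritance patterns -> supporting variants.

    Recessive support is homozygous-with-carrier-parents, X hemizygous
    in a male, or a compound heterozygote: two or more heterozygous
    variants with at least one inherited from each parent (in trans).
    """
    patterns: dict[str, list[TrioVariant]] = {}
    het = [tv for tv in variants_in_gene
           if tv.carries(PROBAND) and not tv.hom_alt(PROBAND)]
    for tv in variants_in_gene:
        for label in variant_inheritance(tv, proband_sex, gq_min):
            patterns.setdefault(label, []).append(tv)
    maternal = [tv for tv in het if _parental_origin(tv) == "maternal"]
    paternal = [tv for tv in het if _parental_origin(tv) == "paternal"]
    if maternal and paternal:
        patterns.setdefault(RECESSIVE, [])
        for tv in maternal + paternal:
            if tv not in patterns[RECESSIVE]:
                patterns[RECESSIVE].append(tv)
    return patterns


# ---------------------------------------------------------------------------
# Filtering and ranking
# ---------------------------------------------------------------------------

UNIQUE = "unique"


@dataclass(frozen=True)
class FilterSpec:
    """Typical interpretation settings: ACMG categories 1-3, a MAF
    ceiling of 1%, 0.5%, 0.1% or cohort uniqueness, and an inheritance
    mode."""

    categories: frozenset[int] = frozenset({1, 2, 3})
    maf_max: float | str = 0.01      # strict upper bound, or "unique"
    inheritance: str = "any"
    gene_list: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.maf_max != UNIQUE and not (0.0 < float(self.maf_max) <= 1.0):
            raise ValueError("maf_max must be in (0, 1] or 'unique'")


@dataclass
class CandidateDiagnosis:
    gene: str
    variants: list[TrioVariant]
    inheritance: str
    diseases: list[tuple[str, int]]   # (disease id, differential rank)

    @property
    def best_rank(self) -> int:
        return min((rank for _, rank in self.diseases), default=1 << 30)


def _passes_static(tv: TrioVariant, spec: FilterSpec,
                   warehouse: VariantWarehouse | None) -> bool:
    a = tv.annotation
    if a.category not in spec.categories:
        return False
    if spec.maf_max == UNIQUE:
        if warehouse is None:
            raise ValueError("uniqueness filtering requires a warehouse")
        if warehouse.contains(a.event):
            return False
    elif not (a.maf < float(spec.maf_max)):
        return False
    return True


def filter_and_rank(trio: TrioGenotypes, spec: FilterSpec,
                    differential: list[tuple[str, int]],
                    table: DiseaseAnnotationTable,
                    warehouse: VariantWarehouse | None = None
                    ) -> list[CandidateDiagnosis]:
    """Apply category/MAF/inheritance filters, group survivors by gene,
    and rank candidates: genes on the differential first (by best
    disease rank), then by most pathogenic category; deterministic
    ordering throughout."""
    rank_of: dict[str, int] = {d: i for i, (d, _) in enumerate(differential)}
    gene_diseases: dict[str, list[tuple[str, int]]] = {}
    for d in table.diseases:
        if d.id in rank_of:
            for g in d.genes:
                gene_diseases.setdefault(g, []).append((d.id, rank_of[d.id]))

    by_gene: dict[str, list[TrioVariant]] = {}
    for tv in trio.variants:
        if not tv.carries(PROBAND):
            continue
        if not _passes_static(tv, spec, warehouse):
            continue
        for gene in tv.annotation.genes:
            if spec.gene_list is not None and gene not in spec.gene_list:
                continue
            by_gene.setdefault(gene, []).append(tv)

    parent_affected = trio.affected.get(MOTHER) or trio.affected.get(FATHER)
    candidates = []
    for gene, tvs in sorted(by_gene.items()):
        patterns = infer_inheritance(tvs, trio.proband_sex)
        if spec.inheritance == "any":
            matched = {lab: v for lab, v in patterns.items() if v and lab != UNRESOLVED}
        else:
            matched = {}
            support = patterns.get(spec.inheritance, [])
            if spec.inheritance == RECESSIVE:
                hom = [tv for tv in support if tv.hom_alt(PROBAND)]
                hemi = [tv for tv in support
                        if tv.event.contig in X_CONTIGS and trio.proband_sex == "male"]
                comp = [tv for tv in support if not tv.hom_alt(PROBAND)
                        and tv.event.contig not in X_CONTIGS]
                # compound het needs both parental origins among the hets
                origins = {_parental_origin(tv) for tv in comp}
                if not hom and not hemi and not ({"maternal", "paternal"} <= origins):
                    support = []
            if spec.inheritance == DOMINANT and not parent_affected:
                # unaffected parents: dominant candidates must be de novo
                support = [tv for tv in support if tv in patterns.get(DE_NOVO, [])]
            if support:
                matched = {spec.inheritance: support}
        if not matched:
            continue
        label = spec.inheritance if spec.inheritance != "any" else \
            sorted(matched)[0]
        variants = sorted({id(tv): tv for vs in matched.values() for tv in vs}.values(),
                          key=lambda tv: (tv.event.contig, tv.event.position))
        candidates.append(CandidateDiagnosis(
            gene=gene, variants=variants, inheritance=label,
            diseases=sorted(gene_diseases.get(gene, []), key=lambda t: t[1])))

    candidates.sort(key=lambda c: (
        0 if c.diseases else 1,
        c.best_rank,
        min(tv.annotation.category for tv in c.variants),
        c.gene))
    return candidates


def report_tsv(candidates: list[CandidateDiagnosis]) -> str:
    lines = ["gene\tinheritance\tn_variants\tvariants\tdiseases"]
    for c in candidates:
        vs = ",".join(f"{tv.event.contig}:{tv.event.position + 1}"
                      f"{tv.event.ref}>{tv.event.alt}" for tv in c.variants)
        ds = ",".join(d for d, _ in c.diseases) or "-"
        lines.append(f"{c.gene}\t{c.inheritance}\t{len(c.variants)}\t{vs}\t{ds}")
    return "\n".join(lines) + "\n"
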