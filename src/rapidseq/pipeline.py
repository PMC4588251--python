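"""End-to-end convenience drivers: simulate -> index -> map -> sort/dedup
-> call -> evaluate."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from rapidseq.caller import CallerParams, call_variants
from rapidseq.dupsort import sort_and_mark_duplicates
from rapidseq.index import IndexParams, build_index
from rapidseq.mapper import InsertModel, MapperParams, Read, map_read_pairs
from rapidseq.reference import ReferenceGenome
from rapidseq.simeval import (ConcordanceReport, SimConfig, evaluate_concordance,
                              simulate_reads, simulate_truth)
from rapidseq.variants import VariantCall

logger = logging.getLogger(__name__)


def run_pipeline(ref: ReferenceGenome, pairs: list[tuple[Read, Read]],
                 index_params: IndexParams | None = None,
                 mapper_params: MapperParams | None = None,
                 caller_params: CallerParams | None = None,
                 insert_model: InsertModel | None = None) -> list[VariantCall]:
    """Map pairs against ``ref``, sort and flag duplicates, and call
    variants; returns the call list."""
    idx = build_index(ref, index_params or IndexParams())
    records = map_read_pairs(pairs, idx, ref, mapper_params,
                             insert_model=insert_model)
    sorted_set = sort_and_mark_duplicates(records, ref)
    return call_variants(sorted_set.records, ref, caller_params or CallerParams())


def simulate_and_call(cfg: SimConfig,
                      reads_seed: int | None = None
                      ) -> tuple[ConcordanceReport, list[VariantCall]]:
    """Full simulated experiment at the configured coverage; returns the
    concordance report against the planted truth and the raw calls."""
    ref, diplome = simulate_truth(cfg)
    reads_rng = np.random.default_rng(cfg.seed + 1 if reads_seed is None
                                      else reads_seed)
    pairs = simulate_reads(diplome.haplotypes, cfg, reads_rng,
                           genome_length=ref.total_length())
    calls = run_pipeline(ref, pairs)  # insert model fitted from the data
    report = evaluate_concordance(calls, diplome.truth, ref)
    logger.info("coverage %.0fx: sensitivity %.4f specificity %.6f (TP %d FP %d FN %d)",
                cfg.coverage, report.sensitivity, report.specificity,
                report.tp, report.fp, report.fn)
    return report, calls
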