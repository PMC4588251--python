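"""SAM reading/writing for the in-memory alignment records (via pysam)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam

from rapidseq.mapper import AlignmentRecord
from rapidseq.reference import ReferenceGenome

_OP_TO_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4}
_CODE_TO_OP = "MIDNSHP=X"


def write_sam(records: list[AlignmentRecord], ref: ReferenceGenome,
              path: str | Path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref.lengths.items()],
        "PG": [{"ID": "rapidseq", "PN": "rapidseq"}],
    }
    name_to_tid = {name: i for i, name in enumerate(ref.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.qname
            a.flag = rec.flag
            a.reference_id = name_to_tid.get(rec.contig, -1) if rec.contig else -1
            a.reference_start = rec.pos if rec.contig else -1
            a.mapping_quality = rec.mapq
            if rec.cigar:
                a.cigartuples = [(_OP_TO_CODE[op], n) for op, n in rec.cigar]
            a.query_sequence = rec.seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in rec.quals))
            a.next_reference_id = name_to_tid.get(rec.rnext, -1) if rec.rnext else -1
            a.next_reference_start = rec.pnext if rec.rnext else -1
            a.template_length = rec.tlen
            a.set_tag("AS", int(rec.score))
            a.set_tag("ps", int(rec.pair_score))
            out.write(a)


def read_sam(path: str | Path) -> tuple[list[AlignmentRecord], ReferenceGenome | None]:
    """Load SAM records; the reference itself is not reconstructed, only
    the contig names/lengths (sequences must come from the FASTA)."""
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam:
            cigar = [( _CODE_TO_OP[code], n) for code, n in (a.cigartuples or [])]
            quals = np.array(a.query_qualities or [0] * len(a.query_sequence or ""),
                             dtype=np.uint8)
            rec = AlignmentRecord(
                qname=a.query_name, flag=a.flag,
                contig=a.reference_name, pos=max(0, a.reference_start),
                mapq=a.mapping_quality, cigar=cigar,
                seq=a.query_sequence or "", quals=quals,
                rnext=a.next_reference_name, pnext=max(0, a.next_reference_start),
                tlen=a.template_length,
                score=int(a.get_tag("AS")) if a.has_tag("AS") else 0,
                pair_score=int(a.get_tag("ps")) if a.has_tag("ps") else 0)
            records.append(rec)
    return records, None
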