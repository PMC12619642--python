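"""AIRR Rearrangement TSV input/output and MSA threading.

Queries arrive as AIRR Rearrangement rows carrying a pairwise alignment
against their best-matching germline allele (``v_sequence_alignment`` /
``v_germline_alignment`` plus 1-based ungapped germline coordinates).
Threading re-expresses the query in the reference MSA's column space using
that existing alignment, so no re-alignment against the database is needed:
each germline-ungapped position maps through the assigned allele's
gap structure to an MSA column.  Query insertions (germline-side gaps) are
dropped — they are not modeled — and MSA columns never touched by the
alignment are set to 'N' (emission probability 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    MalformedRecordError,
    SchemaError,
    UnknownAlleleError,
)
from .reference_db import ReferenceMSA, normalize_sequence

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


def required_columns(segment: str = "v") -> list[str]:
    s = _norm_segment(segment)
    return [
        "sequence_id",
        f"{s}_call",
        f"{s}_sequence_alignment",
        f"{s}_germline_alignment",
        f"{s}_germline_start",
        f"{s}_germline_end",
    ]


def _norm_segment(segment: str) -> str:
    s = segment.lower()
    if s not in ("v", "j"):
        raise SchemaError(f"segment must be 'V' or 'J', got {segment!r}")
    return s


@dataclass
class AirrRecord:
    """One AIRR Rearrangement row; all input columns are passed through."""

    sequence_id: str
    row: dict

    def get(self, column: str, default: str = "") -> str:
        v = self.row.get(column, default)
        return "" if v is None else str(v)

    def call(self, segment: str = "v") -> str:
        return self.get(f"{_norm_segment(segment)}_call")

    def first_allele(self, segment: str = "v") -> str:
        return self.call(segment).split(",")[0].strip()

    def alignment_strings(self, segment: str = "v") -> tuple[str, str]:
        s = _norm_segment(segment)
        return (
            self.get(f"{s}_sequence_alignment"),
            self.get(f"{s}_germline_alignment"),
        )

    def germline_start(self, segment: str = "v") -> int:
        return int(float(self.get(f"{_norm_segment(segment)}_germline_start")))

    def germline_end(self, segment: str = "v") -> int:
        return int(float(self.get(f"{_norm_segment(segment)}_germline_end")))

    def is_complete(self, segment: str = "v") -> bool:
        """True when every required field is present, non-empty and parseable."""
        for col in required_columns(segment):
            if not self.get(col):
                return False
        try:
            start, end = self.germline_start(segment), self.germline_end(segment)
        except (TypeError, ValueError):
            return False
        if not (1 <= start <= end):
            return False
        seq_aln, germ_aln = self.alignment_strings(segment)
        return len(seq_aln) == len(germ_aln)


@dataclass
class ThreadedQuery:
    """A query re-expressed in MSA column coordinates over {A,C,G,T,-,N}."""

    sequence_id: str
    columns: str
    assigned_allele: str
    n_insertions_dropped: int
    dfr: int


def read_airr_table(path: str | Path, segment: str = "v") -> pd.DataFrame:
    """Read an AIRR TSV, validating that the required header columns exist."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required_columns(segment) if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required AIRR columns: {', '.join(missing)}"
        )
    return df


def read_airr(
    path: str | Path, segment: str = "v", *, skip_invalid: bool = True
) -> list[AirrRecord]:
    """Read AIRR records in file order.

    With ``skip_invalid`` (default), rows missing any required field are
    skipped and the skip count logged; with ``skip_invalid=False`` every row
    is returned and the caller classifies incomplete ones.
    """
    df = read_airr_table(path, segment)
    records, skipped = [], 0
    for row in df.to_dict(orient="records"):
        rec = AirrRecord(sequence_id=str(row.get("sequence_id", "")), row=row)
        if skip_invalid and not rec.is_complete(segment):
            skipped += 1
            continue
        records.append(rec)
    if skipped:
        logger.warning(
            "%s: skipped %d row(s) with missing or malformed required fields",
            path,
            skipped,
        )
    return records


def _pairwise_mismatches(a: str, b: str) -> int:
    if len(a) != len(b):
        raise MalformedRecordError(
            f"alignment strings differ in length ({len(a)} vs {len(b)})"
        )
    return sum(
        1
        for x, y in zip(a.upper(), b.upper())
        if x in _ACGT and y in _ACGT and x != y
    )


def compute_dfr(record: AirrRecord, segment: str = "v") -> int:
    """Differences from reference: mismatches in the record's own pairwise
    alignment where both sides are unambiguous nucleotides.  Gap and N
    columns never count.  Symmetric in the two alignment strings."""
    seq_aln, germ_aln = record.alignment_strings(segment)
    return _pairwise_mismatches(seq_aln, germ_aln)


def thread_query(
    record: AirrRecord, msa: ReferenceMSA, segment: str = "v"
) -> ThreadedQuery:
    """Thread a query onto the reference MSA via its existing AIRR alignment.

    Walks the pairwise alignment; germline-ungapped positions (counted from
    ``v_germline_start``) map through the assigned allele's
    ``ungapped_to_column`` table.  Query insertions are dropped and counted;
    query deletions place '-'; uncovered MSA columns stay 'N'.
    """
    allele = record.first_allele(segment)
    if allele not in msa:
        raise UnknownAlleleError(
            f"record {record.sequence_id!r}: allele {allele!r} is not in the "
            "reference database"
        )
    seq_aln, germ_aln = record.alignment_strings(segment)
    if len(seq_aln) != len(germ_aln):
        raise MalformedRecordError(
            f"record {record.sequence_id!r}: alignment strings differ in length"
        )
    seq_aln = normalize_sequence(seq_aln, context="sequence_alignment")
    germ_aln = normalize_sequence(germ_aln, context="germline_alignment")
    start = record.germline_start(segment)
    if start < 1:
        raise MalformedRecordError(
            f"record {record.sequence_id!r}: germline_start must be >= 1"
        )
    mapping = msa.ungapped_to_column[allele]
    cols = ["N"] * msa.L
    written = bytearray(msa.L)
    p = start - 1  # ungapped germline positions consumed so far
    n_ins = 0
    for qc, gc in zip(seq_aln, germ_aln):
        if gc == "-":
            if qc == "-":
                continue
            n_ins += 1  # query insertion relative to germline: not modeled
            continue
        p += 1
        if p > len(mapping):
            raise MalformedRecordError(
                f"record {record.sequence_id!r}: alignment runs past the end "
                f"of allele {allele!r} ({p} > {len(mapping)})"
            )
        col = int(mapping[p - 1])
        if written[col - 1]:
            raise MalformedRecordError(
                f"record {record.sequence_id!r}: germline position written "
                f"twice (MSA column {col})"
            )
        written[col - 1] = 1
        cols[col - 1] = "-" if qc == "-" else qc
    return ThreadedQuery(
        sequence_id=record.sequence_id,
        columns="".join(cols),
        assigned_allele=allele,
        n_insertions_dropped=n_ins,
        dfr=_pairwise_mismatches(seq_aln, germ_aln),
    )


def _format_probability(p: float | None) -> str:
    return "" if p is None else f"{p:.10g}"


def write_airr_with_calls(
    records: Sequence[AirrRecord],
    calls: Sequence,
    path: str | Path,
    *,
    input_columns: Sequence[str] | None = None,
) -> None:
    """Write input rows plus appended call columns as a deterministic TSV.

    Appends ``chimera_probability`` and ``chimeric`` (T/F); when any call
    carries a Viterbi result, also ``chimeric_alignments`` (reference names
    in path order, '/'-separated) and ``recombination_breakpoints``
    (1-based MSA columns, comma-separated).
    """
    records = list(records)
    calls = list(calls)
    if len(records) != len(calls):
        raise AlignmentError(
            f"{len(records)} records vs {len(calls)} calls"
        )
    for rec, call in zip(records, calls):
        if rec.sequence_id != call.sequence_id:
            raise AlignmentError(
                f"record/call id mismatch: {rec.sequence_id!r} vs "
                f"{call.sequence_id!r}"
            )
    if input_columns is None:
        input_columns = list(records[0].row.keys()) if records else []
    input_columns = list(input_columns)
    with_viterbi = any(getattr(c, "viterbi", None) is not None for c in calls)
    header = input_columns + ["chimera_probability", "chimeric"]
    if with_viterbi:
        header += ["chimeric_alignments", "recombination_breakpoints"]
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for rec, call in zip(records, calls):
            fields = [rec.get(c) for c in input_columns]
            fields.append(_format_probability(call.chimera_probability))
            fields.append("T" if call.chimeric else "F")
            if with_viterbi:
                vit = getattr(call, "viterbi", None)
                if vit is None:
                    fields += ["", ""]
                else:
                    fields.append("/".join(vit.path_refs))
                    fields.append(",".join(str(e[2]) for e in vit.events))
            fh.write("\t".join(fields) + "\n")
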