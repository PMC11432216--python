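"""Reading and writing peptide datasets (FASTA sequences + labels table).

A dataset is a FASTA file of sequences plus a delimited table (CSV or TSV)
with one row per record id carrying the binary label and any extra numeric
pass-through columns.  The two files are joined on id; any mismatch is a
hard error naming the offending ids.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .featurize import PeptideRecord


class DatasetError(ValueError):
    """Inconsistent dataset files (duplicate or mismatched ids)."""


def write_dataset(records: Sequence[PeptideRecord], fasta_path: str | Path,
                  labels_path: str | Path) -> None:
    """Write records as FASTA + labels CSV (id,label,extras...)."""
    fasta_path, labels_path = Path(fasta_path), Path(labels_path)
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DatasetError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(fasta_path), "fasta",
    )
    extra_names: list[str] = []
    for rec in records:
        for name in rec.extras:
            if name not in extra_names:
                extra_names.append(name)
    with open(labels_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label", *extra_names])
        for rec in records:
            writer.writerow(
                [rec.id, rec.label,
                 *(repr(float(rec.extras.get(n, 0.0))) for n in extra_names)])


def read_dataset(fasta_path: str | Path,
                 labels_path: str | Path) -> list[PeptideRecord]:
    """Read FASTA + labels table back into records.

    Sequences are uppercased and whitespace-stripped on read.  The label
    table may be comma- or tab-delimited.  Every FASTA id must appear in the
    label table and vice versa.
    """
    sequences: dict[str, str] = {}
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        if seq_rec.id in sequences:
            raise DatasetError(f"duplicate FASTA id {seq_rec.id!r}")
        sequences[seq_rec.id] = str(seq_rec.seq)

    with open(labels_path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if sample.count("\t") > sample.count(",") else ","
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or "id" not in reader.fieldnames \
                or "label" not in reader.fieldnames:
            raise DatasetError("labels table needs 'id' and 'label' columns")
        extra_names = [c for c in reader.fieldnames if c not in ("id", "label")]
        rows = {row["id"]: row for row in reader}

    missing_labels = sorted(set(sequences) - set(rows))
    missing_seqs = sorted(set(rows) - set(sequences))
    if missing_labels or missing_seqs:
        raise DatasetError(
            f"id mismatch between files: missing from labels {missing_labels}"
            f", missing from FASTA {missing_seqs}")

    records = []
    for rid, seq in sequences.items():
        row = rows[rid]
        extras = {n: float(row[n]) for n in extra_names if row[n] != ""}
        records.append(PeptideRecord(id=rid, sequence=seq,
                                     label=int(row["label"]), extras=extras))
    return records


def record_ids(records: Iterable[PeptideRecord]) -> list[str]:
    return [r.id for r in records]
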