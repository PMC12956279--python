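"""File-format boundary: FASTA, Vienna two-line structures, CSV schemas, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structure import DnaSequence, FoldResult, parse_dotbracket

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vienna",
    "write_vienna",
    "read_ct_table",
    "read_titration_table",
    "read_growth_table",
    "read_decay_table",
    "read_gel_table",
    "write_json_report",
]


def read_fasta(path) -> list[DnaSequence]:
    return [
        DnaSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, seqs: Iterable[DnaSequence]) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_vienna(path) -> list[tuple[DnaSequence, frozenset]]:
    """Read Vienna-style records: a '>' header, the sequence line, the dot-bracket line."""
    out = []
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if lines[i].startswith(">"):
            name, seq_line, db_line = lines[i][1:].split()[0], lines[i + 1], lines[i + 2]
            i += 3
        else:
            name, seq_line, db_line = f"seq{len(out)}", lines[i], lines[i + 1]
            i += 2
        if len(db_line) != len(seq_line):
            raise ValueError(f"structure length mismatch for record {name!r}")
        out.append((DnaSequence(id=name, residues=seq_line.upper()), parse_dotbracket(db_line)))
    return out


def write_vienna(path, folds: Iterable[FoldResult]) -> None:
    with open(path, "w") as fh:
        for fold in folds:
            fh.write(f">{fold.sequence.id}\n{fold.sequence.residues}\n{fold.dotbracket}\n")


def read_ct_table(path) -> pd.DataFrame:
    """CT table: sample,condition,primer_set,replicate,ct."""
    return pd.read_csv(path)


def read_titration_table(path) -> pd.DataFrame:
    """Titration table: construct,bt_nominal_uM,At_uM,fluorescence."""
    return pd.read_csv(path)


def read_growth_table(path) -> pd.DataFrame:
    """Growth table: time_min,od600."""
    return pd.read_csv(path)


def read_decay_table(path) -> pd.DataFrame:
    """Decay table: time_min,fold_change."""
    return pd.read_csv(path)


def read_gel_table(path) -> pd.DataFrame:
    """Gel table: label,intensity,length_nt."""
    return pd.read_csv(path)


def write_json_report(path, report: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
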