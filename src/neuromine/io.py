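"""FASTA / TSV round-trip helpers shared by the pipeline and CLI."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; descriptions after the first token dropped."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, entries: list[tuple[str, str]], width: int = 60) -> None:
    """Write sequences wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in entries]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
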