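"""FASTA / plain-text input and output."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import Candidate, TargetTranscript, emit_t7_template

__all__ = [
    "read_target",
    "write_candidates_fasta",
    "write_t7_templates_fasta",
]


def read_target(path, record_id: Optional[str] = None) -> TargetTranscript:
    """Read the target from a FASTA or plain-text sequence file.

    For multi-record FASTA the first record is used unless ``record_id``
    selects another.  Plain-text files (no '>' header) are read as a single
    anonymous sequence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"target file not found: {path}")
    text = path.read_text()
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        if record_id is None:
            rec = records[0]
        else:
            matches = [r for r in records if r.id == record_id]
            if not matches:
                raise ValueError(f"record {record_id!r} not found in {path}")
            rec = matches[0]
        return TargetTranscript.from_string(rec.id, str(rec.seq))
    return TargetTranscript.from_string(path.stem, "".join(text.split()))


def write_candidates_fasta(candidates: Sequence[Candidate], path) -> None:
    records = [
        SeqRecord(Seq(c.ribozyme_seq), id=c.name,
                  description=f"site={c.cutsite.index} triplet={c.cutsite.triplet} "
                              f"arms={c.arm1_len}/{c.arm3_len} rank={c.rank}")
        for c in candidates
    ]
    SeqIO.write(records, str(path), "fasta")


def write_t7_templates_fasta(candidates: Sequence[Candidate], path) -> None:
    """Sense and antisense DNA template strands for every candidate."""
    records = []
    for c in candidates:
        sense, antisense = emit_t7_template(c.ribozyme_seq)
        records.append(SeqRecord(Seq(sense), id=f"{c.name}_sense",
                                 description="T7 template sense strand"))
        records.append(SeqRecord(Seq(antisense), id=f"{c.name}_antisense",
                                 description="T7 template antisense strand"))
    SeqIO.write(records, str(path), "fasta")
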