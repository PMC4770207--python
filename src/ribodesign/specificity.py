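"""Off-target assessment against a reference transcriptome.

The query is the target region around a cut-site spanning the maximal
possible arm footprint (arm_max + 3 + arm_max nt, clipped at sequence
ends).  Every reference transcript is scanned — sense strand only, since
transcripts are directional — for ungapped local matches; each match is
weighted by its matched-pair fraction, so a perfect match contributes
exactly 1.  In ``cleavage_only`` mode a hit counts toward the score only if
the aligned position still presents a cleavable NUH motif (U at the U
position, A/C/U at the H position); in ``annealing_and_cleavage`` mode all
hits count.  Predicted-RNA records (accessions starting XM/XR) are reported
but excluded from the score.

A score of exactly 1 therefore means the query matches nothing but the one
intended cut-site; higher values flag potential off-target activity and the
measure is minimized during ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .model import CutSite, DesignParams, TargetTranscript, normalize_rna

__all__ = [
    "DEFAULT_MIN_WEIGHT",
    "OffTargetHit",
    "SpecificityResult",
    "build_query",
    "specificity_score",
]

#: Minimum matched-pair fraction for a window to count as a hit; the
#: high-sensitivity analogue of a permissive alignment threshold.
DEFAULT_MIN_WEIGHT = 0.75


@dataclass(frozen=True)
class OffTargetHit:
    accession: str
    position: int          # 0-based offset of the query alignment
    matched_pairs: int
    weight: float          # matched_pairs / query_length, in (0, 1]
    cleavable: bool        # NUH still present at the aligned cut position
    predicted_record: bool  # accession starts with XM or XR


@dataclass
class SpecificityResult:
    score: float
    hits: list = field(default_factory=list)


def build_query(target: TargetTranscript, site: CutSite,
                params: DesignParams) -> tuple[str, int]:
    """Target window of arm_max + 3 + arm_max nt centered on the triplet,
    clipped at sequence ends.

    Returns ``(query, site_offset)`` where ``site_offset`` is the position
    of the triplet's N within the query.
    """
    start = max(0, site.index - params.arm_max)
    end = min(len(target), site.index + 3 + params.arm_max)
    return target.sequence[start:end], site.index - start


def _iter_records(transcriptome) -> Iterable[tuple[str, str]]:
    if isinstance(transcriptome, (str, Path)):
        from Bio import SeqIO

        path = Path(transcriptome)
        if not path.exists():
            raise FileNotFoundError(f"transcriptome not found: {path}")
        for rec in SeqIO.parse(str(path), "fasta"):
            yield rec.id, str(rec.seq)
    else:
        for item in transcriptome:
            if hasattr(item, "seq"):  # Bio.SeqRecord
                yield item.id, str(item.seq)
            else:
                yield item  # (accession, sequence)


def _scan_record(ref: str, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match counts for every ungapped alignment offset of the query."""
    enc = np.frombuffer(ref.encode(), dtype=np.uint8)
    qlen = len(query)
    n_offsets = len(enc) - qlen + 1
    if n_offsets <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc, qlen)
    matches = (windows == query).sum(axis=1)
    return np.arange(n_offsets), matches


def specificity_score(query: str, site_offset: int,
                      transcriptome: Union[str, Path, Iterable],
                      mode: str = "cleavage_only",
                      min_weight: float = DEFAULT_MIN_WEIGHT) -> SpecificityResult:
    """Weighted off-target count of ``query`` against a reference.

    ``transcriptome`` may be a multi-FASTA path or an iterable of
    ``(accession, sequence)`` pairs / SeqRecords.  The accession is the
    first whitespace-delimited header token; XM/XR prefixes (case
    insensitive) mark predicted records.
    """
    if not (0.0 < min_weight <= 1.0):
        raise ValueError("min_weight must be in (0, 1]")
    if mode not in ("cleavage_only", "annealing_and_cleavage"):
        raise ValueError(f"unknown specificity mode {mode!r}")
    query = normalize_rna(query)
    if not (0 <= site_offset <= len(query) - 3):
        raise ValueError("site_offset must place the triplet inside the query")
    q_enc = np.frombuffer(query.encode(), dtype=np.uint8)
    qlen = len(query)
    hits: list[OffTargetHit] = []
    score = 0.0
    n_records = 0
    for accession, raw_seq in _iter_records(transcriptome):
        n_records += 1
        ref = normalize_rna(raw_seq)
        offsets, matches = _scan_record(ref, q_enc)
        threshold = min_weight * qlen - 1e-9
        for off in offsets[matches >= threshold]:
            off = int(off)
            m = int(matches[off])
            u_pos = off + site_offset + 1
            h_pos = off + site_offset + 2
            cleavable = ref[u_pos] == "U" and ref[h_pos] in "ACU"
            predicted = accession.upper().startswith(("XM", "XR"))
            hit = OffTargetHit(
                accession=accession, position=off, matched_pairs=m,
                weight=m / qlen, cleavable=cleavable,
                predicted_record=predicted,
            )
            hits.append(hit)
            if predicted:
                continue
            if mode == "cleavage_only" and not cleavable:
                continue
            score += hit.weight
    if n_records == 0:
        warnings.warn("empty reference transcriptome: specificity score is 0",
                      stacklevel=2)
    return SpecificityResult(score=score, hits=hits)
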