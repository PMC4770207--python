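"""Synthetic transcripts, ensemble fixtures and published-ribozyme fixtures.

Everything the test-bench needs to exercise the design pipeline offline:

* :func:`make_transcript` plants exact NUH triplets at exact positions in a
  random background guaranteed free of accidental occurrences of the
  requested triplet types (rejection sampling with a bounded repair loop).
* :func:`make_ensemble_fixture` writes hand-specified ensembles in the
  "dotbracket TAB weight" fixture format consumed by the fixture folding
  backend.
* :func:`yz_fixture_set` returns four experimentally validated anti-PABPN1
  hammerhead ribozymes (Yz144/Yz363/Yz437/Yz867) with their arm/core
  decomposition and a reconstructed target context for assembly round-trip
  tests.  The contexts are synthetic reconstructions: each is the reverse
  complement of the printed arms around an assumed GUC triplet (the target
  mRNA itself is not part of the fixture set).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .folding import FixtureFoldingBackend
from .model import (MINIMAL_CORE_SEQ, Candidate, TargetTranscript, is_nuh,
                    normalize_rna, revcomp, rna_to_dna)

__all__ = [
    "make_transcript",
    "make_ensemble_fixture",
    "designed_candidate_fold",
    "YzFixture",
    "yz_fixture_set",
]

_BASES = np.array(list("ACGU"))


def make_transcript(length: int,
                    planted_sites: Sequence[tuple[str, int]] = (),
                    seed: int = 0,
                    min_margin: int = 0,
                    gc_bias: float = 0.5,
                    id: str = "synthetic",
                    max_repair_rounds: int = 200) -> TargetTranscript:
    """Random transcript with the requested triplets at exact positions and
    no accidental occurrences of those triplet types anywhere else.

    ``min_margin`` additionally requires every planted triplet to sit at
    least that many bases from both sequence ends (so full-length arms fit).
    ``gc_bias`` is the total G+C probability of the background.  The repair
    loop mutates accidental occurrences at positions outside the planted
    triplets; if the constraints cannot be satisfied (e.g. accidental motifs
    wedged between adjacent planted sites) a RuntimeError is raised rather
    than silently relaxing them.  Deterministic per seed.
    """
    if length < 1:
        raise ValueError("length must be positive")
    planted = [(t.upper().replace("T", "U"), int(p)) for t, p in planted_sites]
    for triplet, pos in planted:
        if not is_nuh(triplet):
            raise ValueError(f"planted triplet {triplet!r} is not NUH")
        if pos < min_margin or pos + 3 + min_margin > length:
            raise ValueError(
                f"planted site at {pos} violates margin {min_margin}"
            )
    positions = sorted(p for _, p in planted)
    for a, b in zip(positions, positions[1:]):
        if b - a < 3:
            raise ValueError("planted sites overlap")

    rng = np.random.default_rng(seed)
    p_gc = gc_bias / 2.0
    p_au = (1.0 - gc_bias) / 2.0
    seq = rng.choice(_BASES, size=length, p=[p_au, p_gc, p_gc, p_au])
    planted_cover = set()
    planted_index = set()
    for triplet, pos in planted:
        seq[pos:pos + 3] = list(triplet)
        planted_index.add(pos)
        planted_cover.update(range(pos, pos + 3))

    types = {t for t, _ in planted}
    for _ in range(max_repair_rounds):
        s = "".join(seq)
        accidental = [
            i for i in range(length - 2)
            if s[i:i + 3] in types and i not in planted_index
        ]
        if not accidental:
            return TargetTranscript(id=id, sequence=s)
        for i in accidental:
            mutable = [p for p in (i, i + 1, i + 2) if p not in planted_cover]
            if not mutable:
                raise RuntimeError(
                    f"accidental {s[i:i+3]} at {i} overlaps planted sites "
                    "on all positions; constraints unsatisfiable"
                )
            p = mutable[rng.integers(len(mutable))]
            choices = [b for b in "ACGU" if b != seq[p]]
            seq[p] = choices[rng.integers(3)]
    raise RuntimeError(
        f"could not remove accidental triplets in {max_repair_rounds} rounds"
    )


def make_ensemble_fixture(seq: str, structures: Sequence[tuple[str, float]],
                          path) -> Path:
    """Validate and write an ensemble fixture file for ``seq``.

    One "dotbracket<TAB>weight" line per structure; weights must lie in
    [0, 1] and sum to at most 1; every dot-bracket must be balanced and
    match the sequence length.
    """
    backend = FixtureFoldingBackend()
    backend.register(seq, structures)  # raises on any malformed input
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# ensemble fixture for {seq}\n")
        for db, w in structures:
            fh.write(f"{db}\t{w}\n")
    return path


def designed_candidate_fold(cand: Candidate) -> str:
    """The intended fold of an assembled candidate: open arms, core folded
    as designed (helix II formed, conserved boxes unpaired)."""
    return ("." * cand.arm1_len
            + cand.core.designed_fold
            + "." * cand.arm3_len)


@dataclass(frozen=True)
class YzFixture:
    """One published anti-PABPN1 ribozyme with a reconstructed context."""

    name: str
    dna: str              # sequence as printed (DNA alphabet)
    rna: str
    arm1: str             # stem I arm, 5' of the core
    arm3: str             # stem III arm, 3' of the core
    core: str
    triplet: str          # assumed cut-site triplet of the reconstruction
    target_context: str   # synthetic: revcomp(arm3) + triplet + revcomp(arm1)
    cut_index: int        # position of the triplet's N in target_context


_YZ_PRINTED = {
    "Yz144": "CAGGCTCCAGTTTAACCTCACTGATGAGTCGCTGAAATGCGACGAAACTCCAGGCC",
    "Yz363": "TCTTCCTCCATCTAATCCCTCTGATGAGTCGCTGAAATGCGACGAAACTCGAGCTTTGATA",
    "Yz437": "GCATTGCCTGGTAAAGGTGCTGATGAGTCGCTGAAATGCGACGAAACTCATATTCATCT",
    "Yz867": "CCGGCCCTAACTGTACTGATGAGTCGCTGAAATGCGACGAAACGCGACCC",
}


def yz_fixture_set(triplet: str = "GUC") -> list[YzFixture]:
    """The four validated ribozymes with arm/core split and reconstructed
    target contexts for assembly round-trip tests."""
    out = []
    for name, dna in _YZ_PRINTED.items():
        rna = normalize_rna(dna)
        idx = rna.find(MINIMAL_CORE_SEQ)
        if idx < 0 or rna.find(MINIMAL_CORE_SEQ, idx + 1) >= 0:
            raise AssertionError(f"{name}: core constant not unique")
        arm1 = rna[:idx]
        arm3 = rna[idx + len(MINIMAL_CORE_SEQ):]
        context = revcomp(arm3) + triplet + revcomp(arm1)
        out.append(YzFixture(
            name=name, dna=rna_to_dna(rna), rna=rna, arm1=arm1, arm3=arm3,
            core=MINIMAL_CORE_SEQ, triplet=triplet,
            target_context=context, cut_index=len(arm3),
        ))
    return out
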