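"""Domain model for trans-cleaving hammerhead ribozyme design.

A trans-acting hammerhead ribozyme (hhRz) is a small catalytic RNA built from
three largely independent parts: two substrate-binding arms (stems I and III)
flanking a conserved catalytic core that carries the invariant CUGANGA and
GAAA boxes plus the stem II hairpin.  The substrate must present an NUH
triplet (N any base, U uridine, H = A/C/U); cleavage occurs immediately 3' of
the H.

Coordinate conventions used throughout the package: 0-based, half-open.  For
a cut-site whose N sits at ``index``, the scissile bond lies between
``index + 2`` (the H) and ``index + 3``, so ``cut_pos = index + 3``.

Arm geometry follows the classic trans-hammerhead layout: the ribozyme reads

    5'-[arm 1 / stem I]-CORE-[arm 3 / stem III]-3'

where arm 1 anneals to the target segment immediately 3' of the cleavage
site, ``target[cut_pos : cut_pos + arm1_len]``, and arm 3 anneals to the
segment ending immediately 5' of the N, ``target[index - arm3_len : index]``.
The N and U of the triplet are paired by the core's terminal ``...GAAAC``
(C opposite N, A opposite U) and the H is left unpaired.  This geometry
exactly reproduces published hammerhead constructs from their target
contexts (see the fixture round-trip tests).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "RNA_ALPHABET",
    "MINIMAL_CORE_SEQ",
    "MINIMAL_CORE_FOLD",
    "T7_PROMOTER",
    "normalize_rna",
    "revcomp",
    "rna_to_dna",
    "dna_revcomp",
    "is_nuh",
    "TargetTranscript",
    "Environment",
    "DesignParams",
    "CutSite",
    "CoreTemplate",
    "QualityVector",
    "Candidate",
    "find_cut_sites",
    "enumerate_candidates",
    "assemble_ribozyme",
    "emit_t7_template",
]

RNA_ALPHABET = frozenset("ACGU")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Catalytic core shared by the minimal-model designs: the CUGAUGA box, the
#: stem II hairpin (GUCG paired with CGAC around a 10-nt loop) and the
#: GAAAC tail whose terminal A,C pair the U,N of the target's NUH triplet.
MINIMAL_CORE_SEQ = "CUGAUGAGUCGCUGAAAUGCGACGAAAC"

#: Designed secondary structure of the minimal core: conserved boxes
#: unpaired, stem II formed.
MINIMAL_CORE_FOLD = ".......((((........))))....."

#: Class III phi-like T7 promoter plus the GCG leader used for run-off
#: transcription; transcription initiates at the G of ...TATAG.
T7_PROMOTER = "TAATACGACTCACTATAGCG"


def normalize_rna(sequence: str) -> str:
    """Normalize a DNA/RNA sequence to the uppercase RNA alphabet.

    T is converted to U; characters outside {A, C, G, U, T} (including IUPAC
    ambiguity codes) are rejected.
    """
    seq = sequence.strip().upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(
            f"sequence contains non-ACGU/T characters: {sorted(bad)!r} "
            "(IUPAC ambiguity codes are not supported)"
        )
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA sequence."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def dna_revcomp(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def is_nuh(triplet: str) -> bool:
    """True iff ``triplet`` is a valid NUH cleavage motif (H != G)."""
    return (
        len(triplet) == 3
        and triplet[0] in RNA_ALPHABET
        and triplet[1] == "U"
        and triplet[2] in "ACU"
    )


@dataclass(frozen=True)
class TargetTranscript:
    """The RNA to be cleaved, stored in the normalized RNA alphabet."""

    id: str
    sequence: str
    source_alphabet: str = "RNA"

    @classmethod
    def from_string(cls, id: str, sequence: str) -> "TargetTranscript":
        raw = sequence.strip().upper()
        alphabet = "DNA" if "T" in raw else "RNA"
        return cls(id=id, sequence=normalize_rna(raw), source_alphabet=alphabet)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("target sequence must be non-empty")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"target sequence not normalized RNA: {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Environment:
    """Physicochemical context of the intended application.

    temperature in deg C; Na+ and Mg2+ in mM; oligomer concentration in nM.
    ``context`` is "in_vitro" or "in_vivo"; an in vivo run requires a
    reference transcriptome for the off-target search.
    """

    temperature: float = 37.0
    na_mM: float = 100.0
    mg_mM: float = 0.1
    oligo_nM: float = 500.0
    context: str = "in_vitro"
    transcriptome_path: Optional[str] = None

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.temperature):
            raise ValueError("temperature must be finite")
        for name in ("na_mM", "mg_mM", "oligo_nM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.context not in ("in_vitro", "in_vivo"):
            raise ValueError("context must be 'in_vitro' or 'in_vivo'")
        if self.context == "in_vivo" and self.transcriptome_path is None:
            raise ValueError("in_vivo context requires a transcriptome_path")

    @property
    def kelvin(self) -> float:
        return self.temperature + 273.15


@dataclass(frozen=True)
class DesignParams:
    """User-tunable design-space parameters."""

    cut_triplets: frozenset = frozenset({"GUC"})
    arm_min: int = 3
    arm_max: int = 10
    model: str = "minimal"
    t7: bool = False
    specificity_mode: str = "cleavage_only"

    def __post_init__(self) -> None:
        object.__setattr__(self, "cut_triplets", frozenset(self.cut_triplets))
        if not (1 <= self.arm_min <= self.arm_max):
            raise ValueError("require 1 <= arm_min <= arm_max")
        for t in self.cut_triplets:
            if not is_nuh(t):
                raise ValueError(f"invalid NUH triplet: {t!r}")
        if self.model not in ("minimal", "extended"):
            raise ValueError("model must be 'minimal' or 'extended'")
        if self.specificity_mode not in ("cleavage_only", "annealing_and_cleavage"):
            raise ValueError(
                "specificity_mode must be 'cleavage_only' or 'annealing_and_cleavage'"
            )


@dataclass(frozen=True)
class CutSite:
    """One NUH occurrence on the target.

    ``index`` is the 0-based position of the N; cleavage occurs between
    ``cut_pos - 1`` and ``cut_pos`` with ``cut_pos = index + 3``.
    """

    index: int
    triplet: str

    @property
    def cut_pos(self) -> int:
        return self.index + 3


@dataclass(frozen=True)
class CoreTemplate:
    """The constant catalytic segment placed between the two arms.

    ``designed_fold`` is the intended secondary structure of the core in
    dot-bracket form (conserved boxes unpaired, stem II paired); it defines
    both the helix II pair set excluded from structure scoring and the
    positions that must stay unpaired for the core to be intact.
    """

    model: str = "minimal"
    core_seq: str = MINIMAL_CORE_SEQ
    designed_fold: str = MINIMAL_CORE_FOLD

    def __post_init__(self) -> None:
        if "CUGAUGA" not in self.core_seq or "GAAA" not in self.core_seq:
            raise ValueError("core must contain the conserved CUGAUGA and GAAA boxes")
        if len(self.designed_fold) != len(self.core_seq):
            raise ValueError("designed_fold length must match core_seq")
        depth = 0
        for ch in self.designed_fold:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced designed_fold")
            elif ch != ".":
                raise ValueError(f"bad designed_fold character {ch!r}")
        if depth != 0:
            raise ValueError("unbalanced designed_fold")

    @classmethod
    def for_model(cls, model: str, core_seq: Optional[str] = None,
                  designed_fold: Optional[str] = None) -> "CoreTemplate":
        """Core template for a run.

        The minimal core is fixed; the extended model's additional stem II /
        loop nucleotides are supplied via ``core_seq``/``designed_fold`` and
        fall back to the minimal core when not given.
        """
        if core_seq is None:
            return cls(model=model)
        if designed_fold is None:
            raise ValueError("custom core_seq requires designed_fold")
        return cls(model=model, core_seq=core_seq, designed_fold=designed_fold)

    @property
    def helix_ii_pairs(self) -> tuple:
        """Stem II pairs of the designed fold, core-relative, i < j."""
        stack: list = []
        pairs = []
        for pos, ch in enumerate(self.designed_fold):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                pairs.append((stack.pop(), pos))
        return tuple(sorted(pairs))

    @property
    def unpaired_positions(self) -> tuple:
        """Core-relative positions that must be single-stranded."""
        return tuple(p for p, ch in enumerate(self.designed_fold) if ch == ".")


@dataclass
class QualityVector:
    """Per-candidate quality measures, filled in as the pipeline advances.

    Raw measures are all "lower is better" except the arm Tms, which are
    reported as-is (the user judges them directly).  ``normalized`` and
    ``adjusted`` hold the min-max scaled forms for the detrimental measures.
    """

    tm_arm1: Optional[float] = None
    tm_arm3: Optional[float] = None
    structure_qf: Optional[float] = None
    inaccessibility: Optional[float] = None
    dg_disruption: Optional[float] = None
    specificity: Optional[float] = None
    normalized: dict = field(default_factory=dict)
    adjusted: dict = field(default_factory=dict)


@dataclass
class Candidate:
    """One ribozyme design against one cut-site."""

    cutsite: CutSite
    arm1_len: int
    arm3_len: int
    ribozyme_seq: str
    core: CoreTemplate
    quality: QualityVector = field(default_factory=QualityVector)
    rank: Optional[int] = None

    @property
    def core_offset(self) -> int:
        """Position of the core within ``ribozyme_seq``."""
        return self.arm1_len

    @property
    def arm1_seq(self) -> str:
        return self.ribozyme_seq[: self.arm1_len]

    @property
    def arm3_seq(self) -> str:
        return self.ribozyme_seq[self.arm1_len + len(self.core.core_seq):]

    @property
    def name(self) -> str:
        return f"Rz{self.cutsite.index}_{self.arm1_len}x{self.arm3_len}"


def find_cut_sites(target: TargetTranscript,
                   triplets: Iterable[str]) -> list[CutSite]:
    """All occurrences of the requested NUH triplets, sorted by position.

    Overlapping occurrences are allowed; the scan is a plain deterministic
    sweep over every position.
    """
    tripset = set(triplets)
    for t in tripset:
        if not is_nuh(t):
            raise ValueError(f"invalid NUH triplet: {t!r}")
    seq = target.sequence
    sites = [
        CutSite(index=i, triplet=seq[i:i + 3])
        for i in range(len(seq) - 2)
        if seq[i:i + 3] in tripset
    ]
    return sites


def assemble_ribozyme(target: TargetTranscript, site: CutSite,
                      arm1_len: int, arm3_len: int,
                      core: CoreTemplate) -> str:
    """Assemble the ribozyme sequence for one cut-site and arm-length pair.

    Arm 1 (stem I) is the reverse complement of the target segment starting
    at the cleavage position; arm 3 (stem III) is the reverse complement of
    the segment ending immediately 5' of the N of the triplet.  Raises if
    either arm would run off a sequence end.
    """
    seq = target.sequence
    if site.index < 0 or seq[site.index:site.index + 3] != site.triplet:
        raise ValueError("cut-site does not match target sequence")
    if site.index - arm3_len < 0:
        raise ValueError(
            f"arm 3 of length {arm3_len} runs off the 5' end at site {site.index}"
        )
    if site.cut_pos + arm1_len > len(seq):
        raise ValueError(
            f"arm 1 of length {arm1_len} runs off the 3' end at site {site.index}"
        )
    arm1 = revcomp(seq[site.cut_pos: site.cut_pos + arm1_len])
    arm3 = revcomp(seq[site.index - arm3_len: site.index])
    return arm1 + core.core_seq + arm3


def enumerate_candidates(target: TargetTranscript, sites: Sequence[CutSite],
                         params: DesignParams,
                         core: Optional[CoreTemplate] = None) -> list[Candidate]:
    """One candidate per (site, arm1_len, arm3_len) combination that fits.

    For a site far enough from both sequence ends this yields
    ``(arm_max - arm_min + 1)**2`` candidates; sites near an end keep only
    the length combinations whose arms stay inside the target.
    """
    if core is None:
        core = CoreTemplate.for_model(params.model)
    seq_len = len(target)
    out: list[Candidate] = []
    lengths = range(params.arm_min, params.arm_max + 1)
    for site in sites:
        for a1, a3 in itertools.product(lengths, lengths):
            if site.index - a3 < 0 or site.cut_pos + a1 > seq_len:
                continue
            rz = assemble_ribozyme(target, site, a1, a3, core)
            out.append(Candidate(cutsite=site, arm1_len=a1, arm3_len=a3,
                                 ribozyme_seq=rz, core=core))
    return out


def emit_t7_template(ribozyme_seq: str) -> tuple[str, str]:
    """DNA template strands for T7 run-off transcription of a ribozyme.

    The sense strand is the promoter-plus-GCG-leader followed by the DNA
    form of the ribozyme (the transcript therefore begins with G as T7
    requires); the antisense strand is its reverse complement.
    """
    sense = T7_PROMOTER + rna_to_dna(ribozyme_seq)
    return sense, dna_revcomp(sense)
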