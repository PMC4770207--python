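"""Target-side accessibility scores.

Two complementary measures of how much target self-structure competes with
ribozyme binding, both computed over the target's 10-structure ensemble
(folded once per run and reused by every candidate):

* *cut-site inaccessibility* (per candidate): the ensemble-weighted sum of
  the Kelvin melting temperatures of double-stranded stretches that
  intersect the candidate's arm-binding window — the same stretch scoring
  used for ribozyme structure quality.  0 means the window is free of
  structure in every weighted conformation.

* *disruption energy* dG_disruption (per cut-site): the ensemble-weighted
  free-energy cost (kcal/mol) of melting every base-pair stack with at
  least one partner inside a fixed 23-nt window around the cut-site (the
  maximal arm footprint, 10 + 3 + 10 at default arm lengths).

Both are >= 0, lower is better, and both are linear in the ensemble
weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .folding import (EnsembleStructure, double_stranded_stretches,
                      pairs_from_dotbracket, stretch_tm_kelvin)
from .model import Candidate, CutSite, Environment, TargetTranscript
from .thermo import NNParameterSet, default_nn_table

__all__ = [
    "DISRUPTION_FLANK",
    "SiteWindow",
    "AccessibilityScores",
    "binding_window",
    "disruption_window",
    "cutsite_inaccessibility",
    "disruption_energy",
]

#: Flank width on each side of the NUH triplet for the disruption-energy
#: window: 10 + 3 + 10 = 23 nt, the maximal default arm footprint.
DISRUPTION_FLANK = 10


@dataclass(frozen=True)
class SiteWindow:
    """Half-open target window [start, end) spanning the arm binding sites
    around a cut-site; always contains the NUH triplet, clipped at ends."""

    site: CutSite
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class AccessibilityScores:
    inaccessibility: float  # Kelvin-sum units, per candidate
    dg_disruption: float    # kcal/mol, per cut-site


def binding_window(target: TargetTranscript, cand: Candidate) -> SiteWindow:
    """The region a candidate's arms (plus the triplet) must invade:
    [index - arm3_len, cut_pos + arm1_len), clipped at sequence ends."""
    site = cand.cutsite
    return SiteWindow(
        site=site,
        start=max(0, site.index - cand.arm3_len),
        end=min(len(target), site.cut_pos + cand.arm1_len),
    )


def disruption_window(target: TargetTranscript, site: CutSite,
                      flank: int = DISRUPTION_FLANK) -> SiteWindow:
    """Fixed 23-nt (at default flank) window for dG_disruption, aligned so
    the NUH triplet is interior; clipped at sequence ends."""
    return SiteWindow(
        site=site,
        start=max(0, site.index - flank),
        end=min(len(target), site.index + 3 + flank),
    )


def cutsite_inaccessibility(target: TargetTranscript, cand: Candidate,
                            ensemble: Sequence[EnsembleStructure],
                            env: Environment,
                            nn: Optional[NNParameterSet] = None) -> float:
    """Ensemble-weighted Kelvin-sum of target stretches overlapping the
    candidate's binding window (lower = more accessible)."""
    window = binding_window(target, cand)
    total = 0.0
    for s in ensemble:
        pairs = pairs_from_dotbracket(s.dotbracket)
        contribution = 0.0
        for stretch in double_stranded_stretches(pairs):
            if any(i in window or j in window for i, j in stretch):
                contribution += stretch_tm_kelvin(stretch, target.sequence,
                                                  env, nn)
        total += s.f_s * contribution
    return total


def disruption_energy(target: TargetTranscript, site: CutSite,
                      ensemble: Sequence[EnsembleStructure],
                      env: Environment,
                      nn: Optional[NNParameterSet] = None,
                      flank: int = DISRUPTION_FLANK) -> float:
    """Ensemble-weighted free-energy cost (kcal/mol) of melting local target
    structure across the cut-site window.

    Per structure, the cost is minus the summed stabilizing free energies of
    base-pair stacks having at least one partner inside the window (melting
    the window necessarily breaks those pairs), floored at 0.  Stack
    energies come from the same nearest-neighbor table used for annealing
    temperatures, looked up from the 5'-side dinucleotide; this is an
    approximate relative score, not absolute folding energetics.
    """
    if nn is None:
        nn = default_nn_table()
    window = disruption_window(target, site, flank)
    seq = target.sequence
    total = 0.0
    for s in ensemble:
        pairs = set(pairs_from_dotbracket(s.dotbracket))
        dg = 0.0
        for i, j in pairs:
            if (i + 1, j - 1) not in pairs:
                continue  # not the outer pair of a stack
            if any(p in window for p in (i, i + 1, j - 1, j)):
                dg += nn.stack_dg(seq[i:i + 2], env.kelvin)
        cost = max(0.0, -dg)
        total += s.f_s * cost
    return total
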