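"""Nearest-neighbor annealing-temperature model and the candidate Tm filter.

The ribozyme-target duplex is RNA:RNA, so the default parameter set is the
Xia et al. (1998) Watson-Crick stacking table (1 M NaCl reference), shipped
as a plain-text data file so an alternative table (e.g. a DNA/RNA hybrid
set) can be swapped in.

The melting temperature of an arm annealed to its perfect complement is

    Tm(K) = 1000 * dH / (dS + R * ln(C / 4))

with dH the summed stack + initiation + terminal-AU enthalpy (kcal/mol), dS
the corresponding entropy (cal/mol/K), R = 1.9872 cal/mol/K and C the total
oligomer concentration (the /4 factor applies to non-self-complementary
duplexes at equal strand concentrations).  Salt is handled by the standard
logarithmic correction relative to the 1 M table reference,

    Tm += 16.6 * log10(M_eff),   M_eff = [Na+] + 120 * sqrt([Mg2+])  (mM -> M)

folding Mg2+ in as an effective monovalent contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from .model import Candidate, Environment, revcomp

__all__ = [
    "GAS_CONSTANT",
    "KELVIN",
    "NNParameterSet",
    "load_nn_table",
    "duplex_tm",
    "duplex_tm_kelvin",
    "candidate_tm",
    "tm_filter",
    "TM_WINDOW_BELOW",
    "TM_WINDOW_ABOVE",
]

GAS_CONSTANT = 1.9872  # cal / (mol K)
KELVIN = 273.15

#: Acceptance window for each arm's Tm relative to the environment
#: temperature: [T - 5, T + 60] deg C.
TM_WINDOW_BELOW = 5.0
TM_WINDOW_ABOVE = 60.0


@dataclass(frozen=True)
class NNParameterSet:
    """Dinucleotide stack dH/dS table plus initiation and terminal terms."""

    name: str
    stacks_dh: dict  # 5'->3' dinucleotide -> kcal/mol
    stacks_ds: dict  # 5'->3' dinucleotide -> cal/(mol K)
    init_dh: float
    init_ds: float
    term_au_dh: float
    term_au_ds: float
    salt_coefficient: float = 16.6
    mg_equivalence: float = 120.0

    def stack(self, dinuc: str) -> tuple[float, float]:
        """(dH, dS) for a stack, canonicalizing reverse-complement synonyms."""
        if dinuc in self.stacks_dh:
            return self.stacks_dh[dinuc], self.stacks_ds[dinuc]
        alt = revcomp(dinuc)
        if alt in self.stacks_dh:
            return self.stacks_dh[alt], self.stacks_ds[alt]
        raise KeyError(f"no stack parameters for {dinuc!r}")

    def stack_dg(self, dinuc: str, temp_kelvin: float) -> float:
        """Stack free energy dG = dH - T*dS at ``temp_kelvin``, kcal/mol."""
        dh, ds = self.stack(dinuc)
        return dh - temp_kelvin * ds / 1000.0


def load_nn_table(path: Optional[str] = None) -> NNParameterSet:
    """Load an NN parameter table from a tab-separated file.

    Defaults to the packaged RNA/RNA (Xia 1998) table.  The file format is
    three columns (stack, dH, dS); INIT and TERM_AU rows hold the duplex
    initiation and per-terminal-AU-pair terms.
    """
    if path is None:
        source = resources.files("ribodesign.data") / "rna_nn_xia1998.tsv"
        text = source.read_text()
        name = "rna_xia1998"
    else:
        text = Path(path).read_text()
        name = Path(path).stem
    stacks_dh: dict = {}
    stacks_ds: dict = {}
    special = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("stack\t"):
            continue
        key, dh, ds = line.split("\t")
        if key in ("INIT", "TERM_AU"):
            special[key] = (float(dh), float(ds))
        else:
            stacks_dh[key] = float(dh)
            stacks_ds[key] = float(ds)
    covered = set()
    for k in stacks_dh:
        covered.add(k)
        covered.add(revcomp(k))
    missing = {a + b for a in "ACGU" for b in "ACGU"} - covered
    if missing:
        raise ValueError(f"NN table does not cover stacks: {sorted(missing)}")
    return NNParameterSet(
        name=name,
        stacks_dh=stacks_dh,
        stacks_ds=stacks_ds,
        init_dh=special["INIT"][0],
        init_ds=special["INIT"][1],
        term_au_dh=special["TERM_AU"][0],
        term_au_ds=special["TERM_AU"][1],
    )


_DEFAULT_TABLE: Optional[NNParameterSet] = None


def default_nn_table() -> NNParameterSet:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_nn_table()
    return _DEFAULT_TABLE


def _effective_monovalent(env: Environment, params: NNParameterSet) -> float:
    """Effective monovalent cation concentration in mol/L."""
    return (env.na_mM + params.mg_equivalence * math.sqrt(env.mg_mM)) / 1000.0


def duplex_tm_kelvin(seq: str, env: Environment,
                     params: Optional[NNParameterSet] = None) -> float:
    """Salt-corrected melting temperature, in Kelvin, of ``seq`` annealed to
    its perfect RNA complement.

    Sequences shorter than 2 nt are outside the nearest-neighbor model and
    get a -inf sentinel (they are never acceptable arms).  Raises on empty
    input.
    """
    if not seq:
        raise ValueError("cannot compute Tm of an empty sequence")
    if params is None:
        params = default_nn_table()
    if len(seq) < 2:
        return float("-inf")
    dh = params.init_dh
    ds = params.init_ds
    for i in range(len(seq) - 1):
        sdh, sds = params.stack(seq[i:i + 2])
        dh += sdh
        ds += sds
    for terminal in (seq[0], seq[-1]):
        if terminal in "AU":
            dh += params.term_au_dh
            ds += params.term_au_ds
    conc = env.oligo_nM * 1e-9
    if conc <= 0:
        raise ValueError("oligomer concentration must be > 0 for Tm")
    tm = 1000.0 * dh / (ds + GAS_CONSTANT * math.log(conc / 4.0))
    m_eff = _effective_monovalent(env, params)
    if m_eff <= 0:
        raise ValueError("need Na+ or Mg2+ > 0 for the salt correction")
    tm += params.salt_coefficient * math.log10(m_eff)
    return tm


def duplex_tm(seq: str, env: Environment,
              params: Optional[NNParameterSet] = None) -> float:
    """As :func:`duplex_tm_kelvin` but in deg C."""
    tm_k = duplex_tm_kelvin(seq, env, params)
    return tm_k if tm_k == float("-inf") else tm_k - KELVIN


def candidate_tm(cand: Candidate, env: Environment,
                 params: Optional[NNParameterSet] = None) -> tuple[float, float]:
    """Per-arm annealing temperatures (deg C) of a candidate's two arms,
    each against its perfect-complement target segment."""
    return (duplex_tm(cand.arm1_seq, env, params),
            duplex_tm(cand.arm3_seq, env, params))


def tm_filter(cand: Candidate, env: Environment, strict: bool = False) -> bool:
    """Keep a candidate iff each arm's Tm lies in [T-5, T+60] deg C around
    the environment temperature.

    A single arm below the window is rescued when the other arm's excess
    compensates, i.e. the mean of the two arm Tms lies in the window;
    ``strict`` disables the rescue.  Requires :func:`candidate_tm` results
    stored on the candidate's quality vector.
    """
    tm1 = cand.quality.tm_arm1
    tm3 = cand.quality.tm_arm3
    if tm1 is None or tm3 is None:
        raise ValueError("candidate_tm must be computed before tm_filter")
    lo = env.temperature - TM_WINDOW_BELOW
    hi = env.temperature + TM_WINDOW_ABOVE
    in1 = lo <= tm1 <= hi
    in3 = lo <= tm3 <= hi
    if in1 and in3:
        return True
    if strict:
        return False
    # rescue: an arm below the window is compensated when the mean of the
    # two arm Tms still lies in the window
    if tm1 < lo or tm3 < lo:
        mean = (tm1 + tm3) / 2.0
        return lo <= mean <= hi
    return False
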