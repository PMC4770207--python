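"""Secondary-structure ensembles and the ribozyme structure-quality score.

The ensemble provider is a pluggable contract modeled on statistical
Boltzmann-sampling folders: given a sequence it returns up to
``n_structures`` (default 10) dot-bracket structures, each carrying a
probability weight ``f_s`` in [0, 1] with the weights summing to at most 1.
Three backends are provided:

* :class:`MockFoldingBackend` — a seeded stochastic-traceback maximum-pairing
  sampler (Nussinov-style dynamic program).  Fully offline and
  bit-reproducible; the default for tests and deterministic runs.
* :class:`ViennaFoldingBackend` — an adapter over the ViennaRNA python
  bindings using deterministic sub-optimal enumeration with Boltzmann
  weights relative to the ensemble free energy.
* :class:`FixtureFoldingBackend` — replays hand-written ensembles from
  fixture files ("dotbracket TAB weight" lines).

A candidate's structure quality is the ensemble-weighted sum

    Q_f = sum_s f_s * Q_s

where Q_s is the sum, over all continuous double-stranded stretches that are
not the designed helix II, of the stretch melting temperatures in Kelvin
(Kelvin so that no signed-temperature cancellation can occur), plus a flat
penalty of 50 when the catalytic core is not intact in that structure.  A
stretch may absorb at most one 1x1 internal mismatch.  Lower Q_f is better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np

from .model import Candidate, Environment
from .thermo import NNParameterSet, duplex_tm_kelvin

__all__ = [
    "CORE_PENALTY",
    "BackendUnavailableError",
    "EnsembleStructure",
    "StructureQuality",
    "FoldingBackend",
    "MockFoldingBackend",
    "ViennaFoldingBackend",
    "FixtureFoldingBackend",
    "fold_ensemble",
    "pairs_from_dotbracket",
    "partner_array",
    "double_stranded_stretches",
    "stretch_tm_kelvin",
    "core_intact",
    "structure_quality",
]

#: Penalty, on the Kelvin-sum scale of Q_s, for a structure in which the
#: catalytic core is disrupted (a conserved base paired, or helix II absent).
CORE_PENALTY = 50.0

_CAN_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
             ("G", "U"), ("U", "G")}


class BackendUnavailableError(RuntimeError):
    """Raised when an external folding engine is selected but not present."""


@dataclass(frozen=True)
class EnsembleStructure:
    """One predicted secondary structure with its ensemble probability."""

    dotbracket: str
    f_s: float

    def __post_init__(self) -> None:
        pairs_from_dotbracket(self.dotbracket)  # validates
        if not (0.0 <= self.f_s <= 1.0):
            raise ValueError(f"f_s must be in [0, 1], got {self.f_s}")


@dataclass(frozen=True)
class StructureQuality:
    """Per-structure scores Q_s, their weighted sum Q_f, and per-structure
    core-intactness flags."""

    q_s: tuple
    q_f: float
    core_intact: tuple


def pairs_from_dotbracket(dotbracket: str) -> list[tuple[int, int]]:
    """Base pairs (i, j), i < j, from a dot-bracket string.

    Raises on unbalanced or non-bracket characters; crossing (pseudoknotted)
    pairs cannot be expressed in plain dot-bracket and are thus excluded by
    construction.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def partner_array(dotbracket: str) -> np.ndarray:
    """Partner index per position (-1 where unpaired)."""
    partner = np.full(len(dotbracket), -1, dtype=np.int64)
    for i, j in pairs_from_dotbracket(dotbracket):
        partner[i] = j
        partner[j] = i
    return partner


def double_stranded_stretches(pairs: Sequence[tuple[int, int]],
                              max_mismatch: int = 1) -> list[list[tuple[int, int]]]:
    """Decompose a pair set into maximal continuous double-stranded stretches.

    Consecutive stacked pairs ((i, j), (i+1, j-1)) belong to one stretch; two
    helices separated by a single 1x1 internal loop (one unpaired base on
    each side) are merged into one stretch, at most ``max_mismatch`` times
    per stretch.  Larger loops and bulges split stretches.
    """
    if not pairs:
        return []
    paired = set()
    for i, j in pairs:
        paired.add(i)
        paired.add(j)
    ordered = sorted(pairs)
    stretches: list[list[tuple[int, int]]] = []
    current = [ordered[0]]
    mismatches = 0
    for p in ordered[1:]:
        pi, pj = current[-1]
        i, j = p
        if i == pi + 1 and j == pj - 1:
            current.append(p)
        elif (i == pi + 2 and j == pj - 2
              and mismatches < max_mismatch
              and pi + 1 not in paired and pj - 1 not in paired):
            current.append(p)
            mismatches += 1
        else:
            stretches.append(current)
            current = [p]
            mismatches = 0
    stretches.append(current)
    return stretches


def stretch_tm_kelvin(stretch: Sequence[tuple[int, int]], seq: str,
                      env: Environment,
                      nn: Optional[NNParameterSet] = None) -> float:
    """Melting temperature, in Kelvin, of one double-stranded stretch.

    Computed with the nearest-neighbor routine on the stretch's paired bases
    (5'-side strand, mismatched bases skipped), treating the partner as the
    perfect complement; stretches of fewer than two pairs are outside the
    model and contribute 0.
    """
    if len(stretch) < 2:
        return 0.0
    side = "".join(seq[i] for i, _ in stretch)
    # floored at 0 K: a nominally sub-zero-Kelvin Tm means the stretch never
    # holds together and contributes nothing, and keeps Q_s >= 0
    return max(0.0, duplex_tm_kelvin(side, env, nn))


class FoldingBackend(Protocol):
    """Contract: deterministic ensemble of up to n_structures structures."""

    name: str
    n_structures: int

    def fold(self, seq: str, seed: int) -> list[EnsembleStructure]: ...


class MockFoldingBackend:
    """Seeded stochastic-traceback maximum-pairing sampler.

    A Nussinov-style dynamic program computes the maximum number of nested
    base pairs (Watson-Crick + GU wobble, minimum hairpin loop of
    ``min_loop`` unpaired bases); structures are then drawn by stochastic
    traceback where each decomposition branch is taken with probability
    proportional to exp(beta * pairs), so near-maximally paired structures
    dominate the sample.  The ensemble is the ``n_structures`` most frequent
    distinct structures, weighted by their sample frequencies (weights
    therefore sum to <= 1).  Identical (sequence, seed) inputs give
    bit-identical ensembles.

    This emulates the *shape* of a Boltzmann-ensemble folder for testing and
    deterministic pipelines; it is not a thermodynamic model (see the
    methods note).  Intended for sequences up to a few hundred nt.
    """

    name = "mock"

    def __init__(self, n_structures: int = 10, n_samples: int = 400,
                 beta: float = 2.0, min_loop: int = 3) -> None:
        self.n_structures = n_structures
        self.n_samples = n_samples
        self.beta = beta
        self.min_loop = min_loop

    def _dp(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        n = len(seq)
        enc = np.frombuffer(seq.encode(), dtype=np.uint8)
        pairable = np.zeros((n, n), dtype=bool)
        for a, b in _CAN_PAIR:
            pairable |= (enc[:, None] == ord(a)) & (enc[None, :] == ord(b))
        # N[i, j]: max pairs in the half-open interval seq[i:j]
        table = np.zeros((n + 1, n + 1), dtype=np.int32)
        for span in range(self.min_loop + 2, n + 1):
            for i in range(n - span + 1):
                j = i + span
                last = j - 1
                best = table[i, j - 1]
                hi = j - self.min_loop - 1  # k in [i, hi)
                if hi > i:
                    ks = np.nonzero(pairable[i:hi, last])[0]
                    if ks.size:
                        ks = ks + i
                        vals = table[i, ks] + table[ks + 1, last] + 1
                        best = max(best, int(vals.max()))
                table[i, j] = best
        return table, pairable

    def _sample(self, n: int, table: np.ndarray, pairable: np.ndarray,
                rng: np.random.Generator) -> str:
        struct = ["."] * n
        stack = [(0, n)]
        while stack:
            i, j = stack.pop()
            if j - i < self.min_loop + 2:
                continue
            last = j - 1
            hi = j - self.min_loop - 1
            ks = np.nonzero(pairable[i:hi, last])[0] + i if hi > i else np.empty(0, int)
            scores = [table[i, j - 1]]
            if len(ks):
                scores.extend(table[i, ks] + table[ks + 1, last] + 1)
            scores = np.asarray(scores, dtype=float)
            w = np.exp(self.beta * (scores - scores.max()))
            choice = rng.choice(len(w), p=w / w.sum())
            if choice == 0:
                stack.append((i, j - 1))
            else:
                k = int(ks[choice - 1])
                struct[k] = "("
                struct[last] = ")"
                stack.append((i, k))
                stack.append((k + 1, last))
        return "".join(struct)

    def fold(self, seq: str, seed: int) -> list[EnsembleStructure]:
        if not seq:
            raise ValueError("cannot fold an empty sequence")
        n = len(seq)
        table, pairable = self._dp(seq)
        if table[0, n] == 0:
            return [EnsembleStructure("." * n, 1.0)]
        rng = np.random.default_rng(seed)
        counts: dict[str, int] = {}
        for _ in range(self.n_samples):
            s = self._sample(n, table, pairable, rng)
            counts[s] = counts.get(s, 0) + 1
        top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        top = top[: self.n_structures]
        return [EnsembleStructure(s, c / self.n_samples) for s, c in top]


class ViennaFoldingBackend:
    """Ensemble provider backed by the ViennaRNA partition-function engine.

    Uses deterministic sub-optimal enumeration within ``energy_range_kcal``
    of the minimum free energy and weights each returned structure by its
    Boltzmann probability exp((G_ensemble - E_s)/RT), so weights lie in
    [0, 1] and sum to at most 1.  The enumeration is deterministic, which
    satisfies the reproducibility contract for any seed.
    """

    name = "vienna"

    def __init__(self, n_structures: int = 10,
                 energy_range_kcal: float = 3.0,
                 temperature: float = 37.0) -> None:
        self.n_structures = n_structures
        self.energy_range_kcal = energy_range_kcal
        self.temperature = temperature

    def fold(self, seq: str, seed: int = 0) -> list[EnsembleStructure]:
        try:
            import RNA  # ViennaRNA python bindings
        except ImportError as exc:  # pragma: no cover - present in env
            raise BackendUnavailableError(
                "ViennaRNA python bindings are not installed; "
                "use the mock backend instead"
            ) from exc
        md = RNA.md()
        md.temperature = self.temperature
        md.uniq_ML = 1
        fc = RNA.fold_compound(seq, md)
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        _, g_ensemble = fc.pf()
        sols = fc.subopt(int(round(self.energy_range_kcal * 100)))
        sols = [s for s in sols if s.structure is not None]
        sols.sort(key=lambda s: (s.energy, s.structure))
        rt = 0.0019872 * (273.15 + self.temperature)
        out = []
        for s in sols[: self.n_structures]:
            f_s = math.exp((g_ensemble - s.energy) / rt)
            out.append(EnsembleStructure(s.structure, min(f_s, 1.0)))
        return out


class FixtureFoldingBackend:
    """Replays pre-defined ensembles, keyed by sequence.

    Ensembles can be registered directly or loaded from fixture files with
    one "dotbracket<TAB>weight" line per structure.
    """

    name = "fixture"

    def __init__(self, n_structures: int = 10) -> None:
        self.n_structures = n_structures
        self._ensembles: dict[str, list[EnsembleStructure]] = {}

    def register(self, seq: str,
                 structures: Sequence[tuple[str, float]]) -> None:
        ens = [EnsembleStructure(db, w) for db, w in structures]
        for s in ens:
            if len(s.dotbracket) != len(seq):
                raise ValueError("structure length does not match sequence")
        total = sum(s.f_s for s in ens)
        if total > 1.0 + 1e-9:
            raise ValueError(f"ensemble weights sum to {total} > 1")
        self._ensembles[seq] = ens

    def register_file(self, seq: str, path: str) -> None:
        structures = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                db, w = line.split("\t")
                structures.append((db, float(w)))
        self.register(seq, structures)

    def fold(self, seq: str, seed: int = 0) -> list[EnsembleStructure]:
        try:
            return list(self._ensembles[seq][: self.n_structures])
        except KeyError:
            raise KeyError(
                f"no fixture ensemble registered for sequence {seq[:30]}..."
            ) from None


def fold_ensemble(seq: str, backend: FoldingBackend,
                  seed: int) -> list[EnsembleStructure]:
    """Fold ``seq`` with ``backend`` and validate the ensemble contract."""
    ensemble = backend.fold(seq, seed)
    if not ensemble:
        raise ValueError(f"backend {backend.name!r} returned an empty ensemble")
    for s in ensemble:
        if len(s.dotbracket) != len(seq):
            raise ValueError("ensemble structure length != sequence length")
    total = sum(s.f_s for s in ensemble)
    if total > 1.0 + 1e-6:
        raise ValueError(f"ensemble weights sum to {total} > 1")
    return ensemble


def core_intact(cand: Candidate, structure: EnsembleStructure) -> bool:
    """True iff the catalytic core folds as designed in ``structure``:
    every conserved/unpaired core position is single-stranded and every
    designed helix II pair is present."""
    if len(structure.dotbracket) != len(cand.ribozyme_seq):
        raise ValueError("structure length does not match ribozyme length")
    partner = partner_array(structure.dotbracket)
    off = cand.core_offset
    for rel in cand.core.unpaired_positions:
        if partner[off + rel] != -1:
            return False
    for i, j in cand.core.helix_ii_pairs:
        if partner[off + i] != off + j:
            return False
    return True


def structure_quality(cand: Candidate,
                      ensemble: Sequence[EnsembleStructure],
                      env: Environment,
                      nn: Optional[NNParameterSet] = None) -> StructureQuality:
    """Ensemble-weighted structure quality of a candidate (lower is better).

    Per structure, Q_s sums the Kelvin melting temperatures of all
    double-stranded stretches other than the designed helix II, allowing one
    1x1 mismatch per stretch, and adds the flat 50-degree penalty when the
    core is not intact; Q_f weights the Q_s by the ensemble probabilities.
    """
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    off = cand.core_offset
    helix_abs = {(i + off, j + off) for i, j in cand.core.helix_ii_pairs}
    q_s_list = []
    intact_list = []
    for s in ensemble:
        pairs = pairs_from_dotbracket(s.dotbracket)
        extraneous = [p for p in pairs if p not in helix_abs]
        q_s = sum(
            stretch_tm_kelvin(st, cand.ribozyme_seq, env, nn)
            for st in double_stranded_stretches(extraneous)
        )
        intact = core_intact(cand, s)
        if not intact:
            q_s += CORE_PENALTY
        q_s_list.append(q_s)
        intact_list.append(intact)
    q_f = sum(s.f_s * q for s, q in zip(ensemble, q_s_list))
    return StructureQuality(q_s=tuple(q_s_list), q_f=q_f,
                            core_intact=tuple(intact_list))
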