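"""Measure normalization and multi-objective Pareto ranking.

Raw quality measures live on incommensurable scales (Kelvin sums,
kcal/mol, weighted hit counts), so for reporting each detrimental measure
M is min-max scaled over the surviving candidate set,

    M_normalized = (M_original - M_min) / (M_max - M_min)
    M_adjusted   = 1 - M_normalized

so that 1 is always the best observed value and 0 the worst.  Arm melting
temperatures and specificity are reported raw — users judge those
directly.

Ranking is successive non-dominated sorting: candidate a dominates b iff a
is no worse on every objective and strictly better on at least one; front 1
is the non-dominated set, which is removed, and the process iterates.  All
rank-1 candidates are optimal trade-offs among the objectives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import Candidate

__all__ = [
    "NORMALIZED_MEASURES",
    "DEFAULT_OBJECTIVES",
    "RankedSet",
    "DesignReport",
    "normalize_measures",
    "dominates",
    "pareto_rank",
    "build_report",
]

#: Measures that receive min-max normalization / adjustment.
NORMALIZED_MEASURES = ("structure_qf", "inaccessibility", "dg_disruption")

#: Objectives entering dominance, all minimized on the raw scale.  Arm Tms
#: are excluded (already filtered; judged directly by the user); specificity
#: is appended, raw, for in vivo runs.
DEFAULT_OBJECTIVES = (
    ("structure_qf", "min"),
    ("inaccessibility", "min"),
    ("dg_disruption", "min"),
)


@dataclass
class RankedSet:
    candidates: list
    objectives: tuple


@dataclass
class DesignReport:
    """Ranked, sortable design table plus the run metadata that produced it."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        """UTF-8 TSV with a '#'-prefixed metadata header."""
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            for key in sorted(self.meta):
                fh.write(f"# {key}: {self.meta[key]}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.4f")

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)


def normalize_measures(candidates: Sequence[Candidate],
                       measure_names: Sequence[str] = NORMALIZED_MEASURES) -> None:
    """Min-max normalize and adjust each measure over the candidate set.

    When all candidates share one value the measure carries no
    discriminating information: everything maps to normalized 0 / adjusted
    1 rather than penalizing the set.
    """
    if not candidates:
        raise ValueError("need at least one candidate to normalize")
    for name in measure_names:
        values = [getattr(c.quality, name) for c in candidates]
        if any(v is None for v in values):
            raise ValueError(f"measure {name!r} missing on some candidates")
        vmin, vmax = min(values), max(values)
        span = vmax - vmin
        for c, v in zip(candidates, values):
            norm = 0.0 if span == 0 else (v - vmin) / span
            c.quality.normalized[name] = norm
            c.quality.adjusted[name] = 1.0 - norm


def _objective_matrix(candidates: Sequence[Candidate],
                      objectives: Sequence[tuple]) -> np.ndarray:
    cols = []
    for name, direction in objectives:
        vals = np.asarray([getattr(c.quality, name) for c in candidates],
                          dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"objective {name!r} has non-finite values")
        cols.append(vals if direction == "min" else -vals)
    return np.column_stack(cols)


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff objective vector ``a`` dominates ``b`` (all minimized)."""
    return bool(np.all(a <= b) and np.any(a < b))


def pareto_rank(candidates: Sequence[Candidate],
                objectives: Sequence[tuple] = DEFAULT_OBJECTIVES) -> RankedSet:
    """Assign Pareto-front ranks (1 = non-dominated) by successive
    non-dominated sorting.

    Candidates with identical objective vectors are mutually non-dominating
    and share a rank.  The returned ordering is deterministic: by rank,
    then target position, then arm lengths.
    """
    cands = list(candidates)
    if not cands:
        return RankedSet(candidates=[], objectives=tuple(objectives))
    mat = _objective_matrix(cands, objectives)
    n = len(cands)
    # dom[j, i]: candidate j dominates candidate i
    le = (mat[:, None, :] <= mat[None, :, :]).all(axis=-1)
    lt = (mat[:, None, :] < mat[None, :, :]).any(axis=-1)
    dom = le & lt
    remaining = np.ones(n, dtype=bool)
    rank = 1
    while remaining.any():
        idx = np.nonzero(remaining)[0]
        front = idx[~dom[np.ix_(idx, idx)].any(axis=0)]
        for i in front:
            cands[i].rank = rank
        remaining[front] = False
        rank += 1
    ordered = sorted(
        cands,
        key=lambda c: (c.rank, c.cutsite.index, c.arm1_len, c.arm3_len),
    )
    return RankedSet(candidates=ordered, objectives=tuple(objectives))


def build_report(ranked: RankedSet, run_meta: Optional[dict] = None,
                 in_vivo: bool = False) -> DesignReport:
    """Assemble the ranked design table.

    Cut-sites are numbered from 0 in order of position; accessibility_1 is
    the adjusted cut-site (in)accessibility and accessibility_2 the adjusted
    disruption energy, both on a 0 (worst) to 1 (best) scale, as is the
    ribozyme shape column.  The off-target column is populated only for in
    vivo runs and marked NA otherwise.
    """
    meta = dict(run_meta or {})
    positions = sorted({c.cutsite.index for c in ranked.candidates})
    site_number = {pos: k for k, pos in enumerate(positions)}
    rows = []
    for c in ranked.candidates:
        q = c.quality
        rows.append({
            "cut_site": site_number[c.cutsite.index],
            "position": c.cutsite.index,
            "triplet": c.cutsite.triplet,
            "arm1_len": c.arm1_len,
            "arm3_len": c.arm3_len,
            "ribozyme": c.ribozyme_seq,
            "tm_arm1_C": q.tm_arm1,
            "tm_arm3_C": q.tm_arm3,
            "shape": q.adjusted.get("structure_qf"),
            "accessibility_1": q.adjusted.get("inaccessibility"),
            "accessibility_2": q.adjusted.get("dg_disruption"),
            "structure_qf_raw": q.structure_qf,
            "inaccessibility_raw": q.inaccessibility,
            "dg_disruption_raw": q.dg_disruption,
            "offtarget_hits": q.specificity if in_vivo else "NA",
            "rank": c.rank,
        })
    columns = ["cut_site", "position", "triplet", "arm1_len", "arm3_len",
               "ribozyme", "tm_arm1_C", "tm_arm3_C", "shape",
               "accessibility_1", "accessibility_2", "structure_qf_raw",
               "inaccessibility_raw", "dg_disruption_raw",
               "offtarget_hits", "rank"]
    table = pd.DataFrame(rows, columns=columns)
    return DesignReport(table=table, meta=meta)
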