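"""End-to-end design orchestration.

``run_design`` executes the full procedure: cut-site discovery, candidate
enumeration and assembly, the annealing-temperature filter, ribozyme
structure scoring, target accessibility scoring (the target is folded once
per run and reused), off-target assessment for in vivo runs, measure
normalization, Pareto ranking, and report assembly.  Per-stage candidate
counts are logged; with the mock backend the run manifest (config + seed)
fully determines every output byte.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .accessibility import cutsite_inaccessibility, disruption_energy
from .folding import (FoldingBackend, MockFoldingBackend,
                      ViennaFoldingBackend, fold_ensemble, structure_quality)
from .io import read_target, write_candidates_fasta, write_t7_templates_fasta
from .model import (Candidate, CoreTemplate, DesignParams, Environment,
                    TargetTranscript, enumerate_candidates, find_cut_sites)
from .ranking import (DEFAULT_OBJECTIVES, DesignReport, build_report,
                      normalize_measures, pareto_rank)
from .specificity import DEFAULT_MIN_WEIGHT, build_query, specificity_score
from .thermo import candidate_tm, default_nn_table, tm_filter

__all__ = ["RunConfig", "PipelineError", "run_design", "make_backend"]

logger = logging.getLogger("ribodesign")


class PipelineError(RuntimeError):
    """A design stage failed (e.g. every candidate was filtered out)."""


@dataclass
class RunConfig:
    """Fully serializable description of one design run."""

    target_path: Optional[str] = None
    record_id: Optional[str] = None
    env: Environment = field(default_factory=Environment)
    params: DesignParams = field(default_factory=DesignParams)
    backend: str = "mock"
    n_structures: int = 10
    seed: int = 0
    strict_tm: bool = False
    min_weight: float = DEFAULT_MIN_WEIGHT
    out_dir: Optional[str] = None

    def to_manifest(self) -> dict:
        data = asdict(self)
        data["params"]["cut_triplets"] = sorted(self.params.cut_triplets)
        data["version"] = __version__
        data["nn_table"] = default_nn_table().name
        return data


def make_backend(config: RunConfig) -> FoldingBackend:
    if config.backend == "mock":
        return MockFoldingBackend(n_structures=config.n_structures)
    if config.backend == "vienna":
        return ViennaFoldingBackend(n_structures=config.n_structures,
                                    temperature=config.env.temperature)
    raise ValueError(f"unknown folding backend {config.backend!r}")


def _child_seed(seed: int, ordinal: int) -> int:
    return (seed * 1000003 + ordinal + 1) % (2 ** 31)


def run_design(config: RunConfig,
               target: Optional[TargetTranscript] = None,
               backend: Optional[FoldingBackend] = None) -> DesignReport:
    """Run the whole design procedure and (optionally) write the outputs.

    ``target`` and ``backend`` may be passed directly to bypass file input
    and backend construction (used heavily by the test-bench with fixture
    backends).  Raises :class:`PipelineError` when no candidate survives
    the annealing-temperature filter.
    """
    if target is None:
        if config.target_path is None:
            raise ValueError("either config.target_path or target is required")
        target = read_target(config.target_path, config.record_id)
    if backend is None:
        backend = make_backend(config)
    env, params = config.env, config.params
    core = CoreTemplate.for_model(params.model)
    nn = default_nn_table()
    in_vivo = env.context == "in_vivo"

    sites = find_cut_sites(target, params.cut_triplets)
    logger.info("stage cut-sites: %d sites", len(sites))
    candidates = enumerate_candidates(target, sites, params, core)
    logger.info("stage enumeration: %d candidates", len(candidates))

    survivors: list[Candidate] = []
    for cand in candidates:
        cand.quality.tm_arm1, cand.quality.tm_arm3 = candidate_tm(cand, env, nn)
        if tm_filter(cand, env, strict=config.strict_tm):
            survivors.append(cand)
    logger.info("stage tm-filter: %d candidates kept", len(survivors))
    if not survivors:
        raise PipelineError(
            "no candidates survived the annealing-temperature filter"
        )

    for ordinal, cand in enumerate(survivors):
        ens = fold_ensemble(cand.ribozyme_seq, backend,
                            _child_seed(config.seed, ordinal))
        cand.quality.structure_qf = structure_quality(cand, ens, env, nn).q_f
    logger.info("stage ribozyme structure: scored %d candidates", len(survivors))

    target_ensemble = fold_ensemble(target.sequence, backend, config.seed)
    dg_by_site: dict[int, float] = {}
    for cand in survivors:
        cand.quality.inaccessibility = cutsite_inaccessibility(
            target, cand, target_ensemble, env, nn)
        idx = cand.cutsite.index
        if idx not in dg_by_site:
            dg_by_site[idx] = disruption_energy(
                target, cand.cutsite, target_ensemble, env, nn,
                flank=params.arm_max)
        cand.quality.dg_disruption = dg_by_site[idx]
    logger.info("stage accessibility: %d sites, %d candidates",
                len(dg_by_site), len(survivors))

    all_hits = []
    if in_vivo:
        score_by_site: dict[int, float] = {}
        for cand in survivors:
            idx = cand.cutsite.index
            if idx not in score_by_site:
                query, offset = build_query(target, cand.cutsite, params)
                result = specificity_score(
                    query, offset, env.transcriptome_path,
                    mode=params.specificity_mode,
                    min_weight=config.min_weight)
                score_by_site[idx] = result.score
                all_hits.extend((idx, h) for h in result.hits)
            cand.quality.specificity = score_by_site[idx]
        logger.info("stage specificity: %d sites scored", len(score_by_site))
    else:
        logger.info("stage specificity: skipped (in vitro run)")

    normalize_measures(survivors)
    objectives = list(DEFAULT_OBJECTIVES)
    if in_vivo:
        objectives.append(("specificity", "min"))
    ranked = pareto_rank(survivors, objectives)
    logger.info("stage ranking: %d fronts",
                max(c.rank for c in ranked.candidates))

    meta = {
        "tool": f"ribodesign {__version__}",
        "target": target.id,
        "target_length": len(target),
        "triplets": ",".join(sorted(params.cut_triplets)),
        "arm_range": f"{params.arm_min}-{params.arm_max}",
        "model": params.model,
        "environment": f"{env.temperature}C Na={env.na_mM}mM "
                       f"Mg={env.mg_mM}mM oligo={env.oligo_nM}nM",
        "context": env.context,
        "backend": backend.name,
        "n_structures": backend.n_structures,
        "seed": config.seed,
        "objectives": ";".join(f"{n}:{d}" for n, d in objectives),
    }
    report = build_report(ranked, meta, in_vivo=in_vivo)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_tsv(out / "report.tsv")
        write_candidates_fasta(ranked.candidates, out / "candidates.fasta")
        if params.t7:
            write_t7_templates_fasta(ranked.candidates,
                                     out / "t7_templates.fasta")
        if in_vivo:
            with open(out / "offtarget_hits.tsv", "w") as fh:
                fh.write("site_index\taccession\tposition\tweight\t"
                         "cleavable\tpredicted_record\n")
                for idx, h in all_hits:
                    fh.write(f"{idx}\t{h.accession}\t{h.position}\t"
                             f"{h.weight:.4f}\t{h.cleavable}\t"
                             f"{h.predicted_record}\n")
        import yaml

        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(config.to_manifest(), fh, sort_keys=True)
        logger.info("outputs written to %s", out)
    return report
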