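# ribodesign

Automated design and multi-objective ranking of **trans-cleaving hammerhead
ribozymes** (hhRz) — small catalytic RNAs that anneal to a substrate RNA via
two hybridizing arms and cleave it immediately 3′ of an NUH triplet
(N ∈ {A,C,G,U}, U, H ∈ {A,C,U}). Given a target transcript and a description
of the intended environment, the package enumerates every candidate ribozyme,
scores each on annealing temperature, ribozyme structure, target-site
accessibility and (for in vivo use) off-target specificity, and ranks the
survivors into Pareto-optimal fronts so a user can pick the best trade-off
for their application. It is aimed at molecular biologists planning gene
knock-down or RNA-cutting experiments, in vitro or in cells.

## The design procedure

1. **Cut-site discovery.** Every occurrence of the user-selected NUH
   triplets (default GUC) on the target is a potential cleavage site.
2. **Candidate enumeration.** For each site, one candidate per arm-length
   combination (default 3–10 nt per arm), so an interior site contributes
   (arm range)² candidates. Each candidate is `arm1 + core + arm3`, with
   the arms reverse-complementary to the target around the site and the
   constant catalytic core `CUGAUGAGUCGCUGAAAUGCGACGAAAC` (conserved
   CUGAUGA/GAAA boxes plus the stem II hairpin) between them.
3. **Annealing-temperature filter.** Per-arm nearest-neighbor RNA:RNA
   melting temperatures (salt-corrected); an arm must fall within
   [T−5 °C, T+60 °C] of the environment temperature, with a rescue rule
   when the other arm compensates.
4. **Ribozyme structure** (*shape*). Each candidate is folded into a
   10-structure probability-weighted ensemble; per structure, Q_s sums the
   Kelvin melting temperatures of all extraneous double-stranded stretches
   (helix II excluded, one 1×1 mismatch allowed per stretch), plus a flat
   penalty of 50 whenever the catalytic core is disrupted. The ensemble
   score is Q_f = Σ f_s·Q_s (lower = better).
5. **Target accessibility.** The target is folded once per run;
   *cut-site inaccessibility* (per candidate) sums stretch melting
   temperatures overlapping the arm-binding window, and the *disruption
   energy* ΔG_disruption (per site) is the ensemble-weighted free-energy
   cost of melting all base-pair stacks touching a 23-nt window around the
   site.
6. **Specificity** (in vivo only). The 23-nt region around the site is
   scanned against a reference transcriptome; each ungapped local match is
   weighted by its matched-pair fraction (perfect match = 1). A score of
   exactly 1 means the candidate hits nothing but its intended site.
7. **Normalization and Pareto ranking.** Detrimental measures are min–max
   scaled (M_norm = (M−M_min)/(M_max−M_min), M_adj = 1−M_norm) and the raw
   measures enter successive non-dominated sorting; all rank-1 candidates
   are optimal trade-offs.

Folding backends are pluggable: a deterministic, seeded mock sampler (the
default, bit-reproducible and offline) and an adapter over the ViennaRNA
partition-function engine. See `docs/methods.md` for model details and
limitations.

## Worked example

```bash
ribodesign design --target demo.fasta --arm-min 6 --arm-max 8 \
    --temp 4 --na 1000 --mg 0 --seed 1 --out demo_out
```

For a 120-nt synthetic transcript with two GUC sites this prints
`ranked 18 candidates -> demo_out/report.tsv` (2 sites × 3² arm
combinations, nothing lost to the Tm window at 4 °C / 1 M Na⁺), and the
report begins:

```
cut_site  position  triplet  arm1_len  arm3_len  ribozyme                                       tm_arm1_C  tm_arm3_C  shape   accessibility_1  accessibility_2  ...  rank
0         40        GUC      7         6         AUGCCCGCUGAUGAGUCGCUGAAAUGCGACGAAACCUGAGG      42.6116    25.7578    0.9696  0.3052           0.0000           ...  1
0         40        GUC      8         8         UAUGCCCGCUGAUGAGUCGCUGAAAUGCGACGAAACCUGAGGGC   48.0035    55.7434    1.0000  0.0000           0.0000           ...  1
1         80        GUC      7         6         GUGGAGCCUGAUGAGUCGCUGAAAUGCGACGAAACUACAAC      44.2908    -0.0169    0.5446  1.0000           1.0000           ...  1
```

Reading a row: `cut_site` numbers the distinct sites from 0 along the
target; `tm_arm*_C` are the per-arm annealing temperatures; `shape`,
`accessibility_1` (cut-site openness) and `accessibility_2` (disruption
energy) are adjusted to a 0 (worst) – 1 (best) scale over this candidate
set; `rank` is the Pareto front (1 = no other candidate beats this one on
every measure simultaneously). Raw measure columns and, for in vivo runs,
the weighted off-target count are also included; the table is plain TSV and
can be sorted on any column. `--t7` additionally writes sense/antisense DNA
template strands carrying the T7 promoter + GCG leader for run-off
transcription.

The library surface mirrors the pipeline (`find_cut_sites`,
`enumerate_candidates`, `assemble_ribozyme`, `candidate_tm`,
`fold_ensemble`, `structure_quality`, `cutsite_inaccessibility`,
`disruption_energy`, `specificity_score`, `pareto_rank`, `run_design`) for
programmatic use.

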