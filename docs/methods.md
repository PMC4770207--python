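# Methods

This note records the models behind each scoring stage, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
test-bench does and does not establish about real targets.

## Sequence model and coordinates

All sequences are normalized to the RNA alphabet (T→U, case folded); IUPAC
ambiguity codes are rejected outright rather than expanded, since a
degenerate target would make every downstream score ill-defined.
Coordinates are 0-based and half-open everywhere. For an NUH triplet whose
N sits at `index`, cleavage occurs 3′ of the H, i.e. between `index+2` and
`index+3` (`cut_pos = index+3`).

### Hammerhead geometry

A candidate reads `5′-[arm1/stem I]-core-[arm3/stem III]-3′`. Arm 1 is the
reverse complement of `target[cut_pos : cut_pos+arm1_len]`; arm 3 is the
reverse complement of `target[index−arm3_len : index]`, ending immediately
5′ of the N. The N and U of the triplet are paired by the core's terminal
`…GAAAC` (C opposite N, A opposite U — the classic trans-hammerhead
arrangement) and the H is left unpaired. This geometry was chosen because
it exactly reproduces four experimentally validated anti-PABPN1 ribozymes
(Yz144/Yz363/Yz437/Yz867, shipped as fixtures) from their reconstructed
target contexts; the alternative reading in which stem III ends 5′ of the
H cannot reproduce them. The fixture contexts themselves are synthetic:
the reverse complements of the printed arms around an assumed GUC triplet
(the H is not recoverable from a ribozyme sequence, and GUC is the
canonical, most cleavable triplet).

The minimal-model core is fixed to
`CUGAUGAGUCGCUGAAAUGCGACGAAAC` with designed fold
`.......((((........)))).....` — conserved boxes unpaired, stem II =
GUCG/CGAC. It is the maximal common substring of the four validated
ribozymes. The extended model (tertiary-interaction stem II/loop variants)
is supported as a user-supplied `CoreTemplate` override (sequence +
designed fold); absent an override it falls back to the minimal core, since
no single extended sequence is canonical.

Sites closer than `arm_min` to an end are kept but generate only the
arm-length combinations that fit; the (arm range)²·sites candidate count is
therefore exact for interior sites and an upper bound near the ends.

## Annealing temperatures

Arm↔target duplexes are RNA:RNA, so the default parameter set is the Xia
et al. (1998) Watson–Crick nearest-neighbor ΔH/ΔS table (1 M NaCl
reference), shipped as a documented plain-text file (`--nn-table`-style
override via `load_nn_table`). For an arm annealed to its perfect
complement:

    Tm(K) = 1000·ΔH / (ΔS + R·ln(C/4)) ,  R = 1.9872 cal/mol/K

with initiation and per-terminal-AU terms included and C the oligomer
concentration (default 500 nM — a typical assay scale; configurable).
Salt enters as the standard logarithmic correction
`+16.6·log10(M_eff)` with `M_eff = [Na+] + 120·√[Mg2+]` (mM → M), folding
Mg²⁺ in as an effective monovalent contribution. Arms shorter than 2 nt
are outside the NN model and get a −∞ sentinel, so they can never pass the
filter. Kelvin↔Celsius conversions use the exact 273.15 offset.

The acceptance window keeps a candidate iff each arm Tm lies in
[T−5 °C, T+60 °C] around the environment temperature; a single arm below
the window is rescued when the mean of the two arm Tms still lies in the
window (the compensation is stated only qualitatively in the literature;
the mean rule is the simplest symmetric reading, and `--strict-arm-window`
disables it). Note that on this physical Tm scale short (3–5 nt) arms melt
far below 37 °C at submicromolar concentrations, so physiological-
temperature runs genuinely favor longer arms; small worked examples in the
tests use cold/high-salt environments so that arithmetic — not the filter —
determines their candidate counts.

## Structure quality (Q_f)

Per structure, all base pairs except the designed helix II are decomposed
into maximal continuous double-stranded stretches: consecutive stacked
pairs extend a stretch, and two helices separated by exactly one unpaired
base on each side (a 1×1 internal loop) merge, at most once per stretch;
bulges and larger loops split. Each stretch contributes its NN melting
temperature **in Kelvin** (summing in Kelvin avoids sign cancellation
between stable and marginal stretches); a stretch of fewer than 2 pairs is
outside the NN model and contributes 0, and a nominally sub-zero-Kelvin
stretch is floored at 0, keeping Q_s ≥ 0 and monotone under stretch
removal. A flat 50 (same Kelvin-sum scale) is added when the core is not
intact — i.e. when any conserved core position is paired or any designed
helix II pair is missing. Q_f = Σ f_s·Q_s over the ensemble.

Stretch Tm and stack energies are looked up from the 5′-side dinucleotide
assuming a Watson–Crick partner; GU wobble pairs emitted by a folding
backend are thereby approximated by their WC-complement stack. All
structure-derived scores are approximate *relative* measures used to rank
candidates against each other, not absolute thermodynamics.

## Target accessibility

The target is folded once per run (long-RNA folding dominates run time)
and the 10-structure ensemble reused by all candidates. *Cut-site
inaccessibility* (per candidate) sums, per structure, the Kelvin Tm of
every stretch with at least one partner inside the candidate's binding
window `[index−arm3_len, cut_pos+arm1_len)`, weighted by f_s — the same
stretch machinery as Q_f, applied to the target. *Disruption energy* (per
cut-site) uses a fixed window of `arm_max + 3 + arm_max` nt (23 nt at the
default arm_max 10) aligned so the triplet is interior and clipped at the
ends; per structure the cost is −Σ ΔG of base-pair stacks with ≥ 1 partner
in the window (ΔG = ΔH − T·ΔS from the same NN table at the environment
temperature), floored at 0, then ensemble-weighted. Stacks straddling the
window edge count fully: melting the window necessarily breaks them. Both
scores are ≥ 0, zero iff the window is structure-free in every weighted
conformation, and linear in the ensemble weights.

## Specificity

The query is the target window spanning the maximal arm footprint around
the site. Matching is exact, ungapped and sense-strand only (transcripts
are directional; ribozyme arms anneal contiguously, so gapped alignment
would not model annealing). Every alignment offset of every reference
record is scored by matched-pair fraction via a vectorized sliding-window
comparison — an exhaustive scan rather than a seeded heuristic, because at
the default acceptance threshold (0.75 on a 23-nt query, i.e. up to 5
mismatches) a pigeonhole seed would be 3 nt and filter nothing, while the
exhaustive scan is exact by construction and fast at transcriptome scales
used here. Hits at weight ≥ `min_weight` are reported; a hit counts toward
the score unless its accession starts with XM/XR (predicted records —
reported but never counted) or, in `cleavage_only` mode, the aligned cut
position no longer presents U at the U position and A/C/U at the H
position. In vitro runs skip the stage entirely and the report column is
NA.

## Folding backends

* **mock** (default): a Nussinov-style maximum-pairing dynamic program
  (WC + GU pairs, minimum hairpin loop 3) with stochastic traceback; each
  decomposition branch is drawn with probability ∝ exp(β·pairs), β = 2, so
  near-maximally paired structures dominate. 400 samples are drawn, the 10
  most frequent distinct structures form the ensemble and their sample
  frequencies the weights (hence Σ f_s ≤ 1). Identical (sequence, seed)
  give bit-identical ensembles, which is what makes whole-pipeline runs
  byte-reproducible. It is a *shape* emulator of a Boltzmann folder, not a
  thermodynamic model, and is O(n³); intended for sequences up to a few
  hundred nt (all shipped tests and the acceptance script keep targets at
  32–3000 nt with folding only on ≤ 120-nt sequences).
* **vienna**: the ViennaRNA partition-function engine; structures come
  from deterministic sub-optimal enumeration within 3 kcal/mol of the MFE
  and each is weighted by its true Boltzmann probability
  exp((G_ensemble−E_s)/RT). Deterministic regardless of seed. This is the
  backend to use for real targets.
* **fixture**: replays hand-written ensembles ("dotbracket TAB weight"
  files) for exact-value tests.

The ensemble size defaults to 10 structures, mirroring common
Boltzmann-sampling folders' reporting convention; scorers consume whatever
the backend returns, and an ensemble may legitimately be smaller when the
sequence admits fewer distinct structures (e.g. an unpairable homopolymer
has exactly one).

## Normalization, ranking, report

Min–max normalization is per measure over the surviving candidate set;
when all candidates share a value the measure is uninformative and maps to
adjusted 1 for everyone rather than penalizing arbitrarily. Dominance uses
the raw minimized measures {Q_f, inaccessibility, ΔG_disruption}
(+ specificity, raw, for in vivo runs); min–max scaling is strictly
monotone, so using raw values changes nothing in the ranking while keeping
the dominance relation independent of the candidate set. Arm Tms are
excluded from dominance — they were already filtered and users judge them
directly. Identical objective vectors are mutually non-dominating and
share a rank; output ordering is deterministic (rank, then position, then
arm lengths), so reports are byte-identical across repeated seeded runs.

## Synthetic data

`make_transcript` draws an i.i.d. background (configurable GC content,
default uniform) and plants exact triplets at exact positions, then
repairs any accidental occurrence of the *requested* triplet types by
point mutation outside the planted triplets, raising rather than relaxing
constraints when impossible. It emulates only what the pipeline consumes —
motif placement and local sequence context. It does **not** emulate real
transcript features: codon structure, repeat content, UTR composition
biases, or realistic secondary-structure landscapes. Consequently, green
tests demonstrate the correctness of the enumeration/scoring/ranking
machinery and its determinism, not that any particular designed ribozyme
will cleave a biological target; for real designs the vienna backend and a
real transcriptome should be used, and wet-lab validation remains the
arbiter.

## Degenerate inputs and tie-breaks

Empty candidate sets after filtering abort the run with a nonzero exit; an
empty reference transcriptome warns and scores 0 (a score of 0 is
otherwise impossible, since the target itself always matches when
present); windows are clipped at sequence ends; overlapping cut-sites are
all kept; ties in sampling frequency in the mock backend break on the
structure string, and report ordering ties break on (position, arm1,
arm3) — all deterministic.

## Known limitations

* No dangling-end, coaxial-stacking or loop-sequence terms anywhere; NN
  Watson–Crick stacks only.
* ΔG_disruption ignores the compensating hybridization energy of the
  ribozyme (no RNAup-style ΔG_total); it is the melting-cost term only.
* The mock backend's weights are sampling frequencies, not Boltzmann
  probabilities.
* Extended-model tertiary interactions are represented only through a
  user-supplied core template, not scored specially.
* Specificity treats the transcriptome as a flat FASTA; no expression
  weighting or splice-isoform awareness.
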