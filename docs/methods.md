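# Methods

## The problem and the model

Class I MHC molecules present peptides of 8–10 residues in a closed groove.
A bulky lysine adduct such as an isolevuglandin (IsoLG) pyrrole can only be
tolerated where the modified side chain has somewhere to go — solvent-exposed,
TCR-facing positions — while pocket-buried positions cannot accommodate it.
`adductscan` encodes that structural intuition directly rather than running
all-atom refinement: each allele carries a per-position *groove exposure*
profile `e_i ∈ [0, 1]` (1 = fully exposed), and the surrogate score of a
peptide–MHC complex is

    score = Σ_i [ −PSSM(i, aa_i) + penalty_i ]
    penalty_i = κ · w_s · (1 − e_i)            for an adduct of species s at i
              (+ c · #{receptor pseudo-atoms within r of residue i}, optional)

with lower scores more favorable, matching the convention that binders have
lower energies than nonbinders. The adduction statistic is

    ΔScore(i) = score(adducted at i) − score(unadducted) = penalty_i ,

so ΔScore ≥ 0 always, with equality exactly at fully exposed, clash-free
positions. This makes every downstream analysis (per-position aggregation,
group comparisons, the screening funnel) exactly testable at desk scale. The
surrogate deliberately replaces ensemble all-atom refinement; a backend
registry accepts external scorers that return a single scalar per complex,
and the `n_models`/`top_k` arguments of `score_complex` exist for interface
parity with ensemble backends (the surrogate is deterministic, so they are
no-ops by construction).

What the surrogate does *not* model: side-chain rotamers, backbone
flexibility, adduct stereochemistry, and any absolute energy scale. Passing
tests therefore demonstrate the pipeline's logic and statistics, not absolute
energetics of real complexes.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `penalty_scale` κ | 10.0 | score cost of unit-bulk adduct at a fully buried position (unitless surrogate energy) |
| `bulk_weight` w_s | 1.0 per species | relative bulk of an adduct chemotype |
| `clash_radius` / `clash_weight` | 2.5 Å / 1.0 | optional clash term; off by default so worked examples stay closed-form |
| PSSM pseudocount α | 1.0 (Laplace) | column frequency = (count + α)/(n + 20α) |
| log-odds floor | −20 bits | keeps α→0 zero-frequency cells finite while dominating any realistic score |
| background size | 100 000 | i.i.d. uniform-composition peptides for percentile ranks |
| strong-binder rank | ≤ 0.5 percentile | stand-in for an external predictor's unstated "strong binder" default; configurable |
| binder IC50 threshold | ≤ 500 nM inclusive | binary binder call |
| fold threshold | > 4 (strict) | target-tissue overexpression, denominator = max over non-target tissues (the conservative tissue-enrichment convention; mean optional) |
| favorable call | τ = 0, m = 2 | a position is favorable if ≥ m peptides show ΔScore ≤ τ ("no score increase"); "multiple peptides" is not pinned down in the source protocol, so m = 2, the minimal reading, is the default and both knobs are exposed |
| HLA panel | freq > 0.05, top 10 per population | the two published selection criteria disagree (top-10 vs > 5 %); both are applied and both are configurable |

Default allele profiles (H-2Db: 9-mers, anchors P5/P9, exposed P4/P6/P7;
H-2Kb: 8-mers, anchors P5/P8, uniformly low non-anchor exposure) are
configuration defaults chosen to reflect the known anchor spacing and the
restrictive behaviour of H-2Kb; they are fully overridable via the allele
TSV and are not measured accessibilities.

## Chemistry

Masses are monoisotopic, computed from a shipped element table (overridable
by YAML): peptide mass = Σ residue masses + H2O (+ C2H2O if N-terminally
acetylated) + Σ adduct deltas; precursor m/z = (M + z·1.00727646688)/z.
N-terminal acetylation is a peptide-level flag because synthesis acetylates
uniformly to block N-terminal adduction. The four IsoLG-lysine chemotypes
ship with *placeholder* elemental deltas derived from the IsoLG (C20H32O4) +
lysine condensation series — pyrrole C20H28O2 (−2 H2O), lactam C20H28O3
(pyrrole + O), anhydropyrrole C20H26O, anhydrolactam C20H26O2 — because no
authoritative per-chemotype composition is bundled; real work should supply
a chemistry config. All mass assertions in the tests are checked against an
independent elemental-composition oracle, not literature values.

## Template selection and threading

Same-length templates are scored by ungapped position-wise BLOSUM62 and the
argmax returned, ties broken by lexicographically smallest template id.
Gapless scoring is a design decision: equal-length MHC-I peptides occupy the
groove end-to-end, so alignment columns correspond positionally.
Mixed-length threading is out of scope. The PDB reader honours a minimal
dialect (ATOM records; peptide chain id configurable, default "C"); entries
with missing CA records, altlocs or insertion codes are skipped per entry
with a logged reason. Threading copies the template backbone verbatim and
swaps the sequence — deterministic by construction.

## Statistics

`compare_groups` computes the Mann–Whitney U (A-over-B pairs, ties ½).
For both groups ≤ 8 it enumerates all C(n_A+n_B, n_A) labelings exactly;
otherwise it uses the tie-corrected normal approximation with a 0.5
continuity correction. Two-sided p doubles the smaller tail, capped at 1
(tail-doubling, not mid-p — the simplest exact convention, fixed so results
are reproducible). Anchor positions are excluded when the ΔScore table is
built, upstream of aggregation, since anchor adduction abolishes binding
rather than probing accommodation. Multi-lysine peptides contribute one row
per (peptide, position) pair and are pooled.

## Synthetic data and what passing tests show

The generators are pure functions of (spec, seed); a single integer seed
drives named sub-streams so adding a generator never perturbs existing
fixtures. Defaults encode the study conditions: 9-mers, anchors {5, 9},
favorable positions {4, 6, 7} at exposure 1.0 (≤ 0.4 elsewhere, 0.1 at
anchors), epitope sets of 200 binders + 200 nonbinders with
log10(IC50) = a − b·score + N(0, 0.3) calibrated so binders centre at 50 nM
and nonbinders at 5000 nM against the 500 nM threshold, planted motif
sharpness 0.8 (a strong but not degenerate single-consensus motif), proteomes
of 8 proteins of length 60 with 3 planted candidates at 8-fold kidney
overexpression against the 4-fold screening threshold, and background
proteins ≤ 2-fold.

`gen_proteome` guarantees its truth list by construction: each attempt is
audited by running the actual screening predicates, and is resampled
(bounded rejection sampling, expected ≈ 1 attempt) unless the funnel
recovers exactly the planted candidates *and* a wide margin separates them
in percentile rank (planted ≤ 0.1, all other surviving k-mers ≥ 5.0) so that
recovery does not hinge on the particular background sample. Background
proteins always fail the expression filter, which is one of the allowed
failure modes for background material and keeps the zero-false-positive
guarantee unconditional.

The generators do not emulate real tissue-expression covariance, real
immunopeptidome length distributions, or realistic amino-acid composition
(backgrounds are uniform by design, keeping the percentile-rank calibration
assumption-free). Recovery results on synthetic data therefore validate the
pipeline's correctness and statistical behaviour, not its yield on real
proteomes.

## Numerical and edge-case choices

- Peptide positions are 1-based everywhere (P1…P9 convention).
- Expression fold with a zero denominator counts as infinite (pass) when the
  target level is positive; proteins missing the target-tissue row are
  excluded with a warning, never silently.
- Deduplication keeps the first occurrence ordered by (protein id, offset).
- Candidate TSVs are written with fixed float formatting so identical runs
  are byte-identical.
- Sub-seeds derived from a master seed stay below 2^31.
- Problem sizes in the test suite and acceptance script (100 seeds for the
  statistical properties, 50 random template libraries, 1000 random peptides
  for the mass identities) were chosen as the package's own desk-scale study
  conditions; each completes in seconds on one CPU.
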