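# Methods

This note documents the models and procedures `slscreen` implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic studies do and do not demonstrate.

## Constraint-based simulation substrate

All growth predictions come from flux balance analysis (FBA): maximize flux
through the biomass reaction subject to steady-state mass balance
(S·v = 0) and flux bounds, in mmol·gDW⁻¹·h⁻¹ (growth in h⁻¹).  COBRApy with
the GLPK backend does the solving; the package's own contract layer fixes
the behaviours the screen depends on:

* **Degenerate optima.**  FBA optima are usually non-unique in the flux
  vector; only the objective *value* is unique.  Every downstream decision
  (lethality, safety) therefore uses objective values only.  The single
  place a flux vector is consulted — candidate narrowing in the SL search —
  is sound under any optimal vertex (see below), and candidates are always
  re-verified by a full knockout solve.
* **Knockouts.**  Deleting a gene set turns a reaction off exactly when its
  GPR boolean rule (AND = complex, OR = isozymes; case-insensitive, no
  negation) evaluates false with the deleted genes set to false; the
  reaction's bounds are then forced to (0, 0).  An infeasible mutant is
  reported as growth 0.  Deleting more genes can never raise the optimum
  (the feasible region only shrinks); this monotonicity is property-tested.
* **Tolerances.**  Growth-rate comparisons use an absolute tolerance of
  1e−6; the lethality and safety thresholds sit at ratios (50%, 10%) where
  LP round-off must not flip verdicts, so "reduction > 0.5" is implemented
  as `reduction > 0.5 + 1e−6` and "reduction < 0.1" as
  `reduction < 0.1 − 1e−6`.  Fixtures engineered to land exactly on a
  threshold are classified as non-lethal / non-safe, matching the strict
  inequalities of the criteria.
* **I/O.**  SBML Level 3 with the FBC package is the interchange format; a
  plain-JSON dialect (`{"metabolites", "reactions": [{"id", "stoich",
  "lb", "ub", "gpr"}], "genes", "objective"}`) serves deterministic,
  human-readable fixtures.  Round trips preserve stoichiometry, bounds and
  GPR semantics (tree equality up to AND/OR commutativity).

An independent LP oracle (scipy HiGHS built directly from the
stoichiometric matrix) cross-checks the FBA optimum in the test suite, so
no solver is ever checked against itself.

## Expression discretization (zFPKM)

Per sample: zeros are excluded (log2(0) is undefined; an exact FPKM of 0 is
unambiguous inexpression and scores −1 directly), a Gaussian kernel density
with Silverman bandwidth is evaluated on a 512-point grid spanning the
log2(FPKM > 0) range ± 1, and the *main peak* is the global density maximum
(ties broken toward larger log2-FPKM, since the expression peak dominates
real RNA-seq).  The expression curve (amplitude, μ, σ) is least-squares
fitted to the grid points at or right of the peak; the implied symmetric
curve is subtracted, negative residuals are clipped at 0, and the
inexpression curve is fitted to the residual.

Two conditions must hold for the inexpression curve to be accepted: the
residual must carry ≥ 1% of the total density mass, and the fitted mean
must lie at least 2σ left of the expression mean.  The second condition is
needed because even a perfectly unimodal Gaussian sample leaves a small
KDE-vs-Gaussian mismatch residual near the peak that a curve fit will
happily chase; without the separation requirement such samples acquire a
spurious inexpression curve and a wildly wrong lower threshold.  When the
curve is absent the lower threshold falls back to the −3 zFPKM floor.

Scoring: zFPKM > 0 → +1; zFPKM < max(zFPKM(μᵢ), −3) → −1; otherwise 0.
Both comparisons are strict, so values exactly at a threshold are
*unknown*.  The consensus over samples is a fraction-threshold vote
(defaults 0.9 and 0.9, configurable in [0.5, 1]): a gene is +1/−1 only if
at least that fraction of samples agrees, else 0.

**What the consensus can and cannot call.**  Because the expression
threshold is the fitted peak mean, roughly half of the genuinely expressed
genes in any one sample sit below it and score 0.  When expression levels
are drawn independently per sample (as the bundled simulator does), active
genes therefore almost never reach a 0.9 consensus of +1 and land on 0 —
which is exactly as much as the downstream stage needs, since the context
builder constrains only −1 calls and treats 0 and +1 identically
(unconstrained).  Inactive genes, by contrast, score −1 in essentially
every sample and are called reliably.  Recovery is accordingly measured on
the definite (non-zero) consensus calls, where it exceeds 95% by a wide
margin.  Real data, with persistent per-gene expression levels across
samples, would also yield stable +1 calls; the i.i.d. simulator is the
harsher case for the +1 side and the realistic one for the −1 side that
drives model construction.

## Context-specific model extraction

Consensus scores map to reactions through the GPR tree with AND → min and
OR → max of child scores; reactions without gene association score 0.
Reactions scored −1 get bounds (0, 0); scores 0 and +1 keep base bounds —
only evidence of *inactivity* constrains the model, unknown status never
does, because aggressively removing unknown reactions would reshape the SL
structure on no evidence.  Blocked reactions (FVA min = max = 0 with no
objective floor) are flagged and excluded from statistics but physically
retained with zero feasible flux, keeping reaction indexing stable across
contexts; pruning them is verified not to change the wild-type optimum.  A
context whose restricted model cannot sustain biomass is a hard error — all
reduction fractions divide by the context's own wild-type growth.

## Synthetic-lethal enumeration

Definitions: lethal = reduction strictly above the threshold (default 0.5);
SL set = minimal lethal set; orders 1 (essential genes) through 4
(quadruples).  The search walks the subset lattice depth-first with two
pruning rules:

1. a lethal set is never extended (its supersets are non-minimal);
2. a non-lethal mutant is only extended by genes whose GPRs touch a
   reaction carrying nonzero flux in a minimum-ℓ1-norm optimal flux
   distribution (parsimonious FBA at 100% of the mutant optimum) of that
   mutant.

Rule 2 is sound because deleting any gene set disjoint from that support
leaves the current optimal flux vector feasible, so the optimum — and hence
lethality — cannot change; any lethal extension must contain at least one
support gene, and the support is recomputed at every node, so the recursion
reaches every minimal lethal set regardless of which optimal vertex the
solver returned.  Support membership never *decides* anything: lethality
and minimality are always established by full knockout solves, with growths
memoized per gene set.  An exhaustive enumerator (guarded at 30 genes)
implements the same definitions independently; set-equality of the two
routes is asserted over a 20-network randomized suite at orders 2–4, and
every reported set is re-audited for minimality post hoc.

Output is deduplicated, canonically sorted, and invariant to gene ordering
of the input model.  Reaction-level deletions and orders above 4 are out of
scope.

## Strict-selectivity screen

A candidate passes when its cancer reduction exceeds 50% and its reduction
in *every* protected non-tumor model is below 10%, both strict, each
against that model's own wild type.  Genes absent from a protected model
are no-ops there (their reactions do not exist to disable).  The matched
non-tumor tissue of the cancer is simply the first protected model in the
configured order; no special-casing.  Rejected candidates keep their
failing tissue and per-tissue reductions in the record, which is what the
incremental protection curve (per-order survivor counts after protecting
the first k tissues — non-increasing in k by construction) and the
per-order percentage summaries are built from.  Percentages are rounded
half away from zero to one decimal.  Final verdicts are invariant to the
protected-tissue ordering (property-tested).

## Synthetic data

**Toy networks.**  Biomass consumes one unit of each precursor metabolite;
each precursor is fed by parallel capacity-bounded source paths gated by an
AND over one or more genes, with optional core genes AND-ed into every path
and an optional biomass cap.  Growth under any deletion equals
min-over-precursors of surviving capacity, capped — pure arithmetic, no LP
— so every generated network carries an exact brute-force catalog of its
minimal lethal sets per order, computed independently of the simulation
route under test.  Default random networks stay ≤ 25 genes and ≤ 40
reactions so that order-4 exhaustive enumeration remains a seconds-scale
oracle.

**Expression.**  log2-FPKM is drawn per gene and sample from a
two-component Gaussian mixture — expressed N(4, 1.5²), non-expressed
N(−4, 1²), 30 samples per context by default — with draws below
mean − 3 s.d. of the non-expressed component floored to exact zeros to
emulate undetected genes.  These defaults put the two density peaks ~8
log2-units apart at comparable heights, the regime the zFPKM decomposition
assumes.  The simulator has no per-gene random effects, no library-size or
batch variation, and no dosage compensation; passing recovery tests shows
the decomposition and thresholding logic are correct, not that any
particular real dataset would discretize cleanly.

**Paired contexts.**  Per-context activity masks over the network genes
(padded with a few hundred background genes so density fitting sees
realistic support) define one cancer and several non-tumor expression
matrices.  The designed ground-truth SSDTs implied by the masks are
computed by the capacity oracle, so the full pipeline — discretize, build,
enumerate, screen — can be validated end to end against sets it has never
been told.  The bundled demonstration study couples six precursors so that
selective targets exist at orders 1–4, some lethal candidates fail at the
first protected tissue and one fails only at the second, exercising the
protection curve; two of its path families are sized to land exactly on the
50% boundary under triple deletion, exercising threshold strictness in
vivo.

## Problem sizes and determinism

The shipped studies use toy networks of ≤ 25 genes, 30 samples and 400–500
background genes per expression matrix, 20 networks in the search-oracle
suite and 50 fixtures in the protection-curve suite — sizes at which the
exhaustive oracles themselves stay in the seconds range while still
covering orders 2–4 and every pruning rule.  All generators are pure
functions of spec + seed; the pipeline writes a manifest with a config hash
and reruns byte-identically.

## Known limitations

* Steady-state FBA inherits its usual assumptions: no kinetics, no
  regulation, no enzyme capacity or thermodynamic constraints; loopless and
  parsimonious variants are not user-facing features.
* Knockouts are gene-level only; reaction-level lethality and minimal cut
  set formulations are out of scope.
* The consensus vote is one of several reasonable cross-sample aggregation
  rules; the fractions are exposed so users can match other conventions.
* Genome-scale inputs (a human reconstruction plus real tumor RNA-seq,
  including curation of the exchange medium) are supported by the
  interfaces but not bundled, and results at that scale depend on model
  and medium curation choices this package deliberately does not make.
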