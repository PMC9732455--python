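# Methods

`molforge` implements the computational core of an AI-assisted hit-to-lead
campaign at desk scale: given a hit compound, (1) infer likely protein
targets from a ligand-similarity network, (2) train a SMILES language model
and bias it toward the hit's chemotype by transfer learning, (3) triage the
generated molecules by synthetic feasibility, lead-likeness, structural
alerts and novelty, and (4) score downstream artifacts — kinase-panel
docking tables and alchemical free-energy samples — that in a real campaign
come from docking engines and molecular dynamics. This note records the
models, the parameters that matter, and the design decisions taken where the
underlying procedures are commonly left unspecified.

## Reverse target prediction

A bipartite protein–ligand interaction network (ids + ligand SMILES) stands
in for curated bioactivity databases. A query compound is compared to every
network ligand under six fingerprint families — path-based (maxPath 7),
MACCS 166-key, atom-pair, topological-torsion, radius-2 circular, and
radius-2 circular with pharmacophoric feature invariants — and six bit-vector
similarity measures (Tanimoto, Dice, Cosine, Sokal, Kulczynski,
McConnaughey). Hashed fingerprints default to 2048 bits; lengths, radius and
path depth are configuration, since common practice rather than any single
published value fixes them.

Per fingerprint, a ligand's similarity score is the **sum of the six
measures** (≤ 6 for identical molecules; McConnaughey can contribute down to
−1). The alternative — averaging, or keeping the 36 values separate — would
not change rankings; summing preserves all 36 values while keeping one
number per fingerprint. The `top_k` most similar ligands (default 100)
propagate their scores to every protein they bind. Within each fingerprint,
proteins are sorted by propagated score and assigned integer rank values
N..1 (best to worst); the normalized rank score is

    rank score = rank value / Σ rank values ,

which sums to 1 within a fingerprint by construction. A protein's total R is
the sum of its six rank scores, and the modified total rank score is
R̃ = R / Rmax ∈ (0, 1]; exactly one protein attains R̃ = 1 when Rmax is
unique. Ties in propagated scores receive distinct consecutive rank values
with a lexicographic protein-id tie-break (logged); averaging tied ranks
would break the integer structure that makes the per-fingerprint scores sum
to 1.

Validation is by planted-target recovery: synthetic networks (10 proteins ×
5 ligands) in which one protein's ligands are single-substituent
perturbations of the query and all others carry unrelated-scaffold decoys.
The planted protein reaches R̃ = 1 in 50/50 seeded trials. This establishes
that the scoring machinery concentrates rank mass correctly; it does not
establish performance on real bioactivity data, where ligand promiscuity and
assay noise blur the planted/decoy distinction.

## SMILES language model

A character-level LSTM (default 2 layers × 256 hidden units, 64-d token
embedding) is trained with teacher forcing to predict the next SMILES token;
two-letter elements, bracket atoms and `%nn` ring closures are single
tokens, so tokenize→detokenize is the identity on any string. The network,
backpropagation through time and the Adam optimizer (lr 2e-3, batch 32,
global-norm gradient clip 5, forget-gate bias +1) are implemented directly
over NumPy in float32. All randomness flows through seeded generators:
training, sampling and checkpoint round-trips are exactly reproducible.

Transfer learning continues training on a small focused set at a reduced
rate (1e-3, no held-out split); its contract is that the focused set's mean
per-token log-likelihood strictly increases, and its observable effect is
that samples shift toward the focused chemotype (measured as mean
nearest-analog circular Tanimoto).

Sampling draws tokens autoregressively at temperature T (default 1.0),
stopping at END or `max_length` (default 100 tokens). Generation quality is
reported MOSES-style on canonical SMILES: validity (parseable fraction),
uniqueness (unique canonical / valid), novelty (unique valid outside the
training set / unique valid), internal diversity (1 − mean pairwise circular
Tanimoto, subsampled at 500), and Bemis–Murcko scaffold overlap with a
reference set. Undefined metrics (zero valid samples) are reported as null.

The synthetic training corpus enumerates 5 two-site drug-like scaffolds
(benzanilide, diaryl urea, sulfonanilide, piperazine benzamide,
2-anilinopyrimidine) × 12 substituents — 500 molecules by default. At this
scale the default model reaches ≈78% valid SMILES after 20 epochs.
That figure is a learning-sanity benchmark of the architecture on a narrow,
regular chemical language; it says nothing about the validity achievable
with database-scale pretraining, and conversely the corpus's regularity
makes high uniqueness unattainable (the model legitimately re-generates the
small template space).

## RAFSF synthetic feasibility

Molecules are cleaved at BRICS bonds (optionally also exocyclic amide C–N
bonds, off by default); fragments are canonicalized with attachment points
reduced to plain `[*]` by default (erasing BRICS environment labels coarsens
matching and enlarges the effective space; configurable). A fragment space
counts, over a reference corpus, how many molecules contain each fragment
and each broken-bond type; it serializes to a self-describing TSV whose
header records the exact rule set.

Scoring maps each fragment/bond count to a rarity penalty
p = 1 − log10(1+count)/log10(1+Cmax) (p = 1 if absent), where Cmax is the
table's maximum count, and aggregates by **max**:

    RAFSF = 1 + 9 · max p   ∈ [1, 10].

The max encodes that a compound is only as synthesizable as its hardest
piece: any absent fragment forces 10, and 1 requires every piece to be as
common as the commonest piece of the space. The aggregation is a pluggable
strategy (mean or percentile aggregation can be substituted) because the
field has no canonical mapping from fragment frequency to a 1–10 scale.
Monotonicity holds piecewise: lowering a fragment's count never lowers the
score while the calibration count Cmax is unchanged; lowering the *maximal*
count rescales all penalties.

## Lead-like funnel

Filters: closed-interval property windows (defaults MW 200–600 Da, logP
−1..6); structural alerts (default: RDKit's built-in public PAINS A/B/C
catalog, with user-supplied named-SMARTS files supported); novelty (fail iff
the canonical SMILES is a known active); RAFSF feasibility (default cutoff
6.0); and toxicity plug-ins under a minimal contract (callable: SMILES →
{pass, score}), shipped with a pass-everything null plug-in so the funnel's
shape is preserved when no external models are wired in. The overall verdict
is the conjunction of enabled filters; disabled filters are recorded as
not-evaluated rather than passed. Enabling an additional filter can only
shrink the survivor set, and the funnel is idempotent on its survivors.

## Kinase-panel selectivity

Raw per-kinase docking scores (kcal/mol, lower = more favorable) are min–max
rescaled to [0, 1] per compound across the panel (order-preserving; the most
favorable score maps to 0; panels without two distinct values are rejected
as degenerate). The selectivity score is the fraction of kinases with
rescaled score **strictly** below the threshold (default 0.5) — a score
exactly at the threshold does not count. Min–max is one choice of
order-preserving rescaling; the score is invariant under any monotone
rescaling that fixes which kinases fall below the threshold, which is why
the strategy is isolated behind a replaceable function.

## BAR free-energy estimation

For each λ-window pair, forward and backward potential-energy-difference
samples (ΔU = U_j − U_i, kcal/mol; β in 1/(kcal/mol)) enter the Bennett
acceptance-ratio self-consistency condition

    ⟨1/(1+exp(β(ΔU−ΔG)))⟩_i = ⟨1/(1+exp(β(−ΔU+ΔG)))⟩_j .

The left side increases and the right side decreases in ΔG, so the residual
has a unique root, found by bracket expansion around the midpoint of the
sample means plus Brent's method (default tolerance 1e-8 kcal/mol). Because
a root formally exists even for disjoint distributions, the solver
additionally rejects solutions whose mean Fermi acceptance has saturated
(< 1e-12 or > 1−1e-12): such windows carry no statistical information and
the remedy is more, closer λ states. Uncertainty is a seeded (block)
bootstrap standard error (default 200 resamples).

The default λ schedule turns off electrostatics over 5 uniform states
(0, 0.25, 0.5, 0.75, 1) and van der Waals interactions over 16 states
(0, 0.05, 0.1, …, 0.95, 1; dense near full coupling) — 21 λ states, i.e. 19
window pairs per decoupling leg. A leg total is the sum of window ΔGs, and
the binding estimate combines two legs as

    ΔG_bind = ΔG_water − ΔG_complex + restraint correction,

with the sign convention written into every output (negative = favorable).
The restraint correction is an explicit user-supplied field rather than an
estimate, since restraint protocols vary and silently guessing one is worse
than requiring it.

The estimator is validated against a Crooks-consistent Gaussian oracle:
forward ΔU ~ N(ΔG + βσ²/2, σ²) and backward ΔU ~ N(ΔG − βσ²/2, σ²) satisfy
the Crooks relation exactly, so BAR must recover the planted ΔG. Across
ΔG ∈ {−2, 0, 3} and σ² ∈ {0.5, 2} at n = 10⁵ the estimate lands within 3
bootstrap standard errors (observed max ≈ 1.6 SE). Exact checks: symmetric
samples give ΔG = 0, swapping ensembles negates the estimate, and scaling
all energies together with 1/β scales the estimate.

## Numerical and degenerate-input conventions

* All-zero fingerprints: the five [0,1] similarity measures return 0;
  McConnaughey raises (it is 0/0). In batch network scoring an undefined
  McConnaughey term contributes 0 so that one torsion-free ligand cannot
  poison a whole scoring run.
* Similarity is computed on binary vectors; count information is discarded
  at fingerprint generation.
* Rank-value ties and drug-selection ties break lexicographically (ids), so
  all orderings are total and runs are reproducible.
* Sampling never emits PAD/BEGIN; rows that have emitted END keep consuming
  one random draw per step so that results do not depend on which other
  sequences finished earlier.
* Property windows are closed intervals; boundary values pass.
* Checkpoints store weights + vocabulary + config; optimizer state is not
  checkpointed (reloaded models sample identically; fine-tuning restarts
  Adam).

## Problem sizes

Defaults used throughout tests and the acceptance script: 500-molecule
corpus, 20 pretraining epochs, 1000 samples; 50 planted-target networks of
10×5; 1000-molecule RAFSF sets; 10⁵ BAR samples per window. These sizes are
chosen so a complete run takes about a minute on one CPU core while leaving
every statistical check far from its decision boundary.

## Known limitations

* The synthetic corpus is a narrow, regular chemical language; metrics on it
  (validity, uniqueness, novelty) are sanity benchmarks, not estimates of
  performance under database-scale pretraining.
* The toxicity stage is a contract, not a model; the null plug-in passes
  everything.
* Docking, MD, and QM stages are consumed as tabular inputs only; the
  package neither runs nor replaces them.
* RAFSF's frequency→score mapping is this package's documented choice; other
  implementations of the same idea need not agree numerically.
* The bundled reference table ships only structures printed in this
  documentation; external database records (e.g. the ChEMBL ligand used in
  the MACCS-Tanimoto worked example) must be supplied by the user.
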