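# Methods

## Model and assumptions

`pocketvote` rests on one premise: proteins that share a fold tend to bind
ligands at equivalent sites, so ligands observed in solved structures can be
carried onto a model of a related protein by rigid superposition, and the
consensus of many transferred ligands localises the binding site. The
pipeline is purely geometric — no energetics, no chemistry beyond van der
Waals radii — and is therefore exactly as good as the superpositions and the
contact criterion that feed it.

## Superposition and the TM-score gate

Correspondences between model and template residues come from a global
sequence alignment (BLOSUM62, affine gaps, open −11 / extend −1). This is a
deliberate simplification: a full sequence-independent structure alignment
is out of scope, and for templates similar enough to pass the downstream
TM-score gate, sequence alignment recovers essentially the same residue
pairing. A user-supplied two-column correspondence file bypasses the
alignment entirely.

The rigid fit is an iterative Kabsch superposition: fit on the current pair
set, reject pairs whose Cα–Cα distance exceeds a cutoff annealed linearly
from 8 Å to 4 Å over at most 10 iterations, stop early when the pair set is
stable at the final cutoff. Fewer than 3 surviving pairs aborts the template
(logged, skipped). The TM-score is computed over **all** correspondence
pairs under the final transform and normalised by the **target model
length** (the fixed-target convention; with one model against many
templates this makes scores comparable across templates). Templates score
into the pipeline iff TM ≥ 0.4, boundary inclusive.

## Contacts, clustering, voting

* Contact: d(a,b) ≤ r_vdw(a) + r_vdw(b) + 0.5 Å. The radius set is Bondi's
  (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, ZN 1.39, MG 1.73, CA 2.31,
  FE 2.05, …) with 1.70 Å for anything unlisted. The "one radius plus
  tolerance" reading of the criterion is available as a config switch
  (`sum_radii=false`), but the two-radius sum is the default: it is the
  physically standard heavy-atom contact definition.
* Clustering: single-linkage agglomeration halted at the contact threshold,
  which is exactly the connected components of the ligand contact graph;
  implemented via `scipy.sparse.csgraph`, with a brute-force transitive
  closure kept in the test suite as an independent oracle.
* Pocket: the largest cluster. Ties (rare, but possible on symmetric decoys)
  break by more voting residues, then smaller mean distance of ligand
  centroids to the model centroid, then input order.
* Voting: residue r is a binding residue iff it contacts at least
  max(2, ⌈0.25·N⌉) of the N pocket ligands, counting all heavy atoms
  (backbone included; hydrogens ignored). For N = 1 the literal "≥ 2
  ligands" rule can never fire, so the requirement degrades to contact with
  the single ligand and the prediction is flagged low-confidence.

## Ligand relevance and typing

Crystallisation additives and solvent (HOH, DOD, GOL, EDO, PEG, MPD, PG4,
ACT, DMS, FMT, TRS, BME, MES, EPE, SO4, PO4, NO3) are excluded by default;
the list is configurable because "biologically relevant" is ultimately a
judgement call. Waters are never ligands. Typing is by residue name: a
curated ion set (single-atom metals/halides), a nucleotide/cofactor set
(ATP…NAD, FAD, FMN, mono-nucleotides), peptide for all-standard-residue
chains of ≤ 20 residues appearing in a template alongside a longer protein
chain, and Organic otherwise. The four classes are exhaustive and mutually
exclusive by construction.

## Propensities

The per-residue propensity of binding ligand type t is

    p_t(r) = model_quality × |{ligands of type t in the pocket contacting r}| / N

clipped to [0,1]; the global pocket propensity is the fraction of pocket
ligands of each type. These contact-fraction forms are this package's own
definition: they guarantee the [0,1] range, exact zeros for types absent
from the pocket, and an upper bound at the global model-quality score, which
are the properties downstream consumers rely on. They are not claimed to
reproduce any externally published propensity values.

## Assessment metrics

MCC is the standard Matthews correlation over binding/non-binding residue
classification with the residue universe equal to the model's standard
residues; any zero factor in the denominator gives 0. BDT is a symmetric
distance-kernel score,

    BDT(P,O) = [Σ_{p∈P} κ(d(p,O)) + Σ_{o∈O} κ(d(o,P))] / (|P|+|O|),
    κ(d) = 1/(1+(d/d₀)²), d₀ = 3.9 Å,

on Cα–Cα distances; it is 1 iff the sets are identical, 0 when exactly one
is empty, 1 when both are, and decays smoothly for near-miss predictions
(d₀ equals the C–C contact threshold, so "one contact shell away" costs
half credit). This is this package's formulation of a distance-aware
binding-site score; published BDT values from other implementations are not
numerically comparable.

## Quality features and regressor

Per template, over the predicted residues:

* **BDTalign** — mean κ(‖Cα(r) − Cα(r′)‖) over correspondence-equivalent
  pairs; predicted residues without an equivalent contribute 0.
* **Identity** — fraction whose 3D-equivalent template residue (nearest
  superposed template Cα within 3.9 Å) has the same amino-acid type.
* **Rescaled BLOSUM62** — mean (s − s_min)/(s_max − s_min) over the same 3D
  pairs, s_min = −4, s_max = 11. Note this feature is < 1 even for an
  identical site unless every residue is tryptophan — diagonal BLOSUM
  entries rescale below 1 (H↔H gives 0.8) — so a "perfect" feature vector
  in practice has blosum ≈ 0.6–0.9, not 1.
* **ERLD** — mean κ(|d(r → pocket ligands) − d(r′ → template ligands)|),
  comparing each residue's heavy-atom distance to its ligands with its
  equivalent's.
* **Model quality** — the caller-supplied global score (an external model
  quality assessor is out of scope, so this is an input; the CLI default is
  0.5 with a warning).

Features aggregate across gated templates by a ligand-count-weighted mean
(templates contributing more pocket ligands dominate the prediction, so
they dominate its assessment); templates contributing nothing to the pocket
get weight 0.

The regressor is two feed-forward networks (5 inputs, 8 logistic hidden
units, 1 output), one trained on true MCC, one on true BDT, fitted with
scikit-learn's L-BFGS solver at a fixed seed (deterministic weights). The
output unit is linear with clipping to [0,1] rather than sigmoidal: with
targets already in [0,1] and this little data, the clipped-linear head
trains more reliably and the distinction is immaterial after clipping.
Prediction uses an in-repo forward pass over the stored weights (verified
against scikit-learn in the tests), so the packaged JSON weights are
self-contained. The shipped default weights were trained on a 2,000-example
synthetic corpus at seed 7.

Ranking of alternative predictions sorts by mean(predicted MCC, predicted
BDT), ties by the model-quality feature, then stably.

## Synthetic data: what it emulates and what it does not

The generator emulates the *geometry* of the problem, nothing else: an
idealized α-helical backbone (2.3 Å radius, 1.5 Å rise, 100°/residue, with
sketched N/C/O positions) whose Cα trace is self-avoiding (> 3.5 Å);
templates that are rigidly moved, Gaussian-noised (σ per coordinate),
optionally mutated copies of the target carrying one planted ligand each
(ZN ion, 3-carbon organic, 4-atom nucleotide stand-in, or di-glycine
peptide); decoy templates plant their ligand at a distant surface site. The
planted ground truth is *defined* as what the voting rule returns on the
noiseless ligands in the model frame, so noise-free recovery is exact by
construction and every departure from it is attributable to the pipeline
stage under stress.

What it does not emulate: real fold diversity (templates are derived from
the target, so the sequence-alignment correspondence is nearly trivial at
low mutation rates), side-chain packing, realistic ligand chemistry, or
partial-coverage templates. Passing tests therefore demonstrate the
correctness of the algorithmic machinery and its degradation behaviour
under noise — not benchmark performance on real structures.

Random streams: each scenario spawns named substreams (residue names,
template plan, template noise, corpus draws) from one root seed in a fixed
order, so individual products are reproducible independently.

The QA training corpus draws model noise from {0, 0.5, 1, 1.5, 2, 3} Å,
template noise from {0, 0.5, 1, 2, 3} Å and mutation rates from
{0, 0.1, 0.2, 0.4}, with the model-quality input computed as the TM-score
of the degraded model against its noise-free original; this spreads true
MCC/BDT over the full [0, 1] range. The multi-model ranking benchmark uses
10 models per target with noise in [0, 2.5] Å and an *observed* model
quality carrying Gaussian error (sd 0.15) — an imperfect external quality
estimator is exactly the situation in which feature-based re-ranking can
help.

## Problem sizes and numerical choices

Default study conditions: chain length 60, 8 templates, one ligand per
template, pocket anchored at residues {10, 13, 14} with the ligand site
placed ~3.3 Å off the nearest anchor Cα. The test suite and the acceptance
script use 200 random instances for each oracle-equivalence check, 20 seeds
for known-answer recovery, a 5-point noise grid {0, 0.5, 1, 2, 4} Å, a
2,000-example QA corpus (80/20 train/test), and 20 ranking runs of 10
models — sizes chosen so the full reproduction stays in the minutes range
on a single core while keeping every check statistically unambiguous.

Numerical conventions: alternate locations keep the highest-occupancy
conformer (ties: first in file); TM-score d₀ is floored at 0.5 Å;
zero-denominator MCC is 0; empty-versus-nonempty BDT is 0 and
empty-versus-empty 1; ligand residues are renumbered onto one chain by the
PDB writer so re-reading never merges distinct ligands; all writers are
byte-deterministic for identical inputs.

## Known limitations

* Correspondence by sequence alignment fails for analogous folds with
  divergent sequences — precisely where a structure aligner would shine;
  the user-supplied correspondence file is the escape hatch.
* One binding site per target: the largest cluster wins; all clusters are
  reported in the JSON manifest but only the pocket is scored.
* Propensity and BDT formulas are this package's own definitions (see
  above); compare trends, not absolute values, against other tools.
* The packaged regressor weights are only as general as the synthetic
  corpus; retrain with `train_regressor` on domain-specific data for real
  applications.
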