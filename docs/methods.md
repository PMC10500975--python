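# Methods

`ssrbm` analyses fixed-length amino-acid stretches at the boundaries of
secondary-structure elements with an ensemble of restricted Boltzmann
machines (RBMs), consolidates the ensemble into a consensus model, and
reads interpretable structure — sequence modes and an effective
hydrophobicity axis — off the learned parameters. This note records the
model, the numerical choices, and what the synthetic benchmarks do and do
not establish.

## Data model

A stretch is the first or last Γ residues (default Γ = 5) of a maximal
run of DSSP code `H` (α-helix) or `E` (β-strand). Runs shorter than Γ are
discarded; runs of exactly Γ contribute the same residues to the start
and end datasets. Only the strict codes `H` and `E` are used: 3₁₀/π
helices (`G`, `I`), bridges (`B`) and turns/bends are treated as
non-element states, which is the conservative reading of "α-helix" and
"β-sheet". Chain breaks and chain changes terminate runs, so no stretch
spans a discontinuity. Lowercase DSSP letters (disulfide-bonded
cysteines) map to `C`; any other non-canonical residue causes the stretch
to be dropped and counted.

Each stretch is one-hot encoded with spin values: residue position γ
occupies a block of 20 visible sites (alphabetical residue order
`A,C,D,…,Y`, fixed package-wide), with +1 at the residue's index and −1
elsewhere, giving N_v = 20Γ spins per sample. Datasets are split 80/20
into training and validation sets by a seeded uniform partition.

## The spin RBM

Visible spins v ∈ {±1}^{N_v} (constrained to the one-hot manifold) and
hidden spins h ∈ {±1}^{N_h} interact through

    E(v, h) = − a·v − b·h − vᵀ W h,      p(v, h) ∝ e^{−E(v,h)}.

Conditionals factorise: p(h_j = +1 | v) = e^{u_j} / (2 cosh u_j) with
u_j = b_j + Σ_i w_ij v_i, and given h each block picks residue k with
probability softmax over the block of 2 φ_k, where φ = a + W h is the
local field. The factor 2 arises because moving the block's +1 from site
l to site k changes the energy by 2φ_l − 2φ_k; the −1 background
contributes a constant that cancels in the softmax.

Exact quantities used throughout:

* free energy F(v) = −a·v − Σ_j log 2 cosh u_j (hidden layer marginalised
  analytically), stable via log 2cosh x = |x| + log1p e^{−2|x|};
* pseudo-log-likelihood (PLL): per position, the exact conditional of the
  observed residue given all others, obtained by renormalising e^{−F}
  over the 20 candidate residues of that block. Reported in nats per
  sample (sum over Γ positions). Because the hidden layer marginalises
  analytically this is exact for any N_h;
* partition function and generation: for N_h ≤ 12 the hidden layer is
  enumerated (2^{N_h} states), giving the exact log Z on the one-hot
  manifold and exact ancestral sampling (draw h from its marginal, then
  blocks) with no burn-in.

## Training

Gradients are estimated by CD-n (default n = 1) or persistent CD-n:
block-Gibbs alternation with categorical visible updates that never leave
the one-hot manifold. Data-side hidden statistics use the exact
expectation tanh u (Rao–Blackwellised); the model side uses the chain
state after n sweeps. Three standard stabilisers are on by default:

* **centering**: v and tanh u enter the weight gradient as deviations
  from offsets (data mean for v, an EMA for tanh u), with compensated
  bias gradients. Without it, every hidden unit initially chases the data
  mean and the units collapse onto one direction;
* **visible-bias warm start** at the empirical log-odds, so the bias —
  not the couplings — models the single-site marginals from epoch 0;
* **weight decay** (10⁻⁴, couplings only), letting redundant duplicated
  units shrink and re-differentiate.

The optimiser is stochastic gradient ascent with momentum 0.9,
learning rate 0.2 decaying exponentially to 0.02 over 50 epochs
(batch 128). Adam is available (`TrainConfig(optimizer="adam")`) but is
not the default: on planted-mode benchmarks its per-coordinate rescaling
flattens the weak curvature that separates near-degenerate "mixed"
solutions (hidden units learning linear mixtures of the true modes) from
the well-separated optimum, and a substantial fraction of runs stall
there regardless of schedule.

Those mixed solutions are genuine local maxima of the exact likelihood —
they persist even with an exactly enumerated negative phase — sitting
roughly one nat (per sample, Γ = 5) below the separated optimum. `train`
therefore races three weight initialisations for 15 epochs and completes
only the candidate with the best validation PLL. The PLL gap makes this
selection essentially error-free, and determinism is preserved (candidate
seeds derive from the configured seed).

Per-epoch PLL monitoring uses a deterministic subsample (default 2048
samples) to keep ensemble scans cheap; all PLLs reported by the
complexity scan are exact over the full train/validation sets.

## Ensemble consolidation

R independent realizations (default 30; scans in this package's
benchmarks use 10) differ in weight initialisation and in their own
80/20 split; realization r derives both from seed + r. All R·N_h hidden
units are pooled and compared by Euclidean distance between weight
vectors. Because the model is invariant under the gauge flip
(h_j, w_{·j}, b_j) → −(h_j, w_{·j}, b_j), distances are sign-aligned by
default: d(w, w′) = min(‖w − w′‖, ‖w + w′‖). Without alignment each mode
appears as two antipodal clusters.

Units are grouped by DBSCAN on the precomputed distances
(min_samples = max(3, R/3); eps defaults to the knee of the sorted
k-nearest-neighbour distance curve, located as the point furthest from
the chord — both overridable). Unassigned units are noise. Groups are
renumbered by decreasing size. The average RBM (aRBM) takes, per group,
the mean of member weights and hidden biases after orienting each member
toward the group's largest-norm member; the visible bias averages over
all realizations. Diverged realizations are dropped, not retrained.

The complexity scan trains an ensemble at each candidate N_h and reports
group count, noise fraction and mean exact PLLs. The recommended N_h is
the largest value whose group count equals N_h with noise at or below a
threshold (default 0.1, a strict reading of "noise still tiny"): the most
complex model the whole ensemble still agrees on.

## Interpretation

With N_h units the aRBM has 2^{N_h} hidden states. Their frequencies are
dataset-averaged posteriors f_s = ⟨Π_j p(h_j = s_j | v)⟩_data (the model
prior p(h) is reported alongside; the posterior is primary). Each state
induces a 20×Γ column-stochastic residue table via the block softmax.
States are ranked by decreasing frequency (ties broken by lexicographic
state order, +1 first) and labelled S1, S2, …. The f-weighted mixture of
state tables should reproduce the empirical single-position frequencies
of the data; the comparison metric is per-position total variation
distance. The two-site-correlation matrix (Pearson correlations of the
one-hot indicators) is provided as the standard-statistics baseline the
decomposition is meant to improve on.

## Effective hydrophobicity

For each group, the N_v weight vector is reshaped to a 20×Γ matrix (rows:
amino acids; columns: positions) and a PCA is run with amino acids as the
20 observations and positions as variables (column-centered). PC1
captures how strongly a residue commits to one side of the polar/nonpolar
alternation. Since the component sign is arbitrary, PC1 is oriented to
correlate positively with a reference hydrophobicity scale and the
Pearson r is reported (the orientation and raw sign are retained). When
the per-member matrices of a group are supplied, the reported explained
variances are the means of the members' own explained-variance fractions.
The shipped default scale is the Fauchère–Pliška (1983) octanol/water
side-chain partition scale (π values, unitless; Trp highest, Arg/Lys
lowest); any two-column residue/value TSV can replace it.

## Synthetic generators and what the benchmarks show

The planted-RBM generator builds hidden units from balanced residue
dichotomies: the primary polar/hydrophobic split
(H = `ACFGILMVWY`, P = `DEHKNPQRST`; Tyr hydrophobic, Pro polar, with the
two ambiguous residues Ala and Gly placed on the hydrophobic side so each
class has exactly 10 members) and an orthogonal secondary split used for
the third/fourth units so the planted weight vectors are linearly
independent. Default units: primary split at odd positions (helix-like
period 2), primary at even positions, secondary at all positions
(strand-like period 1), each with amplitude c (default 1.0). Balanced
classes make each mode gauge-symmetric; hidden biases are then set by an
enumerated fixed point so the units' prior activations hit slightly
asymmetric targets (0.62/0.45/0.55/0.48), giving bistable modes with a
unique frequency ranking. Sampling is exact. A simpler mode-mixture
generator draws a mode per sample and residues independently per
position from explicit tables; two antiphase amphiphilic tables give the
minimal generator with between-position class correlations.

The headline benchmark plants K = 3 modes at c = 1.0, Γ = 5, draws
50 000 sequences, trains ensembles of R = 10 at N_h = 1…4 and requires:
one group per hidden unit up to N_h = 3, rising noise at N_h = 4, a
validation-PLL plateau at N_h = 3, and |Pearson r| ≥ 0.9 between aligned
group weights and the planted units. These sizes keep the full scan
within a few minutes on one CPU while leaving comfortable statistical
margins (observed correlations are ≥ 0.99 and noise ≤ 7%).

The generators emulate the *latent-mode* structure the method assumes —
position-specific biases, amphiphilic alternation, a handful of modes —
but not other features of real boundary data: residue-frequency skew
beyond the planted biases, length variation of elements, dataset overlap
between start/end sets of short elements, or phylogenetic redundancy.
Passing the benchmarks therefore demonstrates that the machinery
(training, consolidation, decomposition, PCA readout) recovers planted
structure of realistic geometry; it does not by itself validate the
biological conclusions drawn from any particular corpus.

## Numerical conventions and degenerate inputs

* Positions are 0-based internally, 1-based in external tables.
* Model files are JSON with row-major weight lists; stretch tables and
  all outputs are TSV.
* `block_probs`/softmax subtract the per-block maximum; `expit`/log1p
  forms guard all sigmoids and log-coshes.
* Empty batches, empty datasets, < 2 samples for splits/correlations,
  non-simplex mixture inputs, unknown groups and eps ≤ 0 raise
  `ValueError`; non-finite parameters during training raise
  `TrainingDivergedError`.
* DBSCAN on identical units (all-zero distances) yields a single group;
  an all-noise clustering makes `build_arbm` fail loudly.
* PCA on an all-rows-equal matrix is flagged degenerate with zero scores
  rather than raising, so per-group loops can continue.

## Known limitations

* CD-1 with the default stabilisers is tuned for the N_h ≤ ~6,
  Γ = 5 regime this package targets; very large hidden layers would need
  PCD with more chains and a smaller learning rate.
* Exact generation and state decomposition require N_h ≤ 12; no annealed
  importance sampling is provided for larger models.
* The knee heuristic for eps is scale-free but jittery for very small
  ensembles (R·N_h ≲ 8 units); pass an explicit eps there.
* DSSP parsing supports the classic column format only (mmCIF-era DSSP
  can be exported to it); STRIDE is out of scope.
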