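# Methods

## The model

For each mutated gene *g* with *M* mutated patients and *N* connected
genes, xshadow places a small Bayesian network over four latent layers and
the observed expression:

```
P(D) · ∏_m P(F_m | D) · ∏_{m,n} P(G_{m,n} | F_m, H_n) · p(y_{m,n} | G_{m,n})
```

* **D ∈ {0,1}** — does this gene's mutations, as a class, perturb
  expression?  Prior θ_D, shared across genes.
* **F_m ∈ {0,1}** — is the *m*-th patient's mutation functional?
  P(F=1|D) with θ_{F=1|D=1} ≥ θ_{F=1|D=0} (identifiability).
* **G_{m,n} ∈ {down, neutral, up}** — the latent regulation state of
  connected gene *n* in patient *m*.  Under F=0 the null table θ_{G|F=0}
  applies; under F=1 the table θ_{G|F=1,H_n} oriented by the neighbour's
  fixed response direction H_n ∈ {down, up}.
* **y_{m,n}** — observed log2 expression, emitted by the per-gene
  three-component Student's-t mixture (component densities only; the
  state probabilities come from the CPDs).

In cis mode N = 1 and the single "neighbour" is the gene itself.  An edge
weight w ∈ [0,1] from the influence graph enters as a convex mixture
`w·θ_{G|F=1,H} + (1−w)·θ_{G|F=0}`: a fully trusted edge applies the
dysregulated table, an untrusted edge reduces the neighbour to noise.
This mixing is treated as an exact latent edge-real/null indicator in the
M-step, so learning remains a true EM.

Fixing H makes each gene's network a tree, so sum-product message passing
gives exact marginals P(D), P(F_m), P(G_{m,n}) in O(M·N).  All messages
live in log space (a gene may have thousands of neighbours).  H_n is
estimated once, before EM, as the direction with the larger mean off-line
responsibility across mutated patients (ties break to up), and is held
fixed; an exhaustive-enumeration oracle cross-checks the message passing
on small instances in the test suite.

## Learning

The θs are shared across all mutated genes in one analysis and fitted by
EM: the E-step runs exact inference per gene; the M-step is a ratio of
pooled expected counts with a 0.5 pseudo-count on every cell (a
Beta(1.5,1.5)/Dirichlet(1.5) smoothing prior).  Because of the smoothing,
the quantity EM provably never decreases is the penalised objective
(log marginal likelihood + log prior); `EMTrace` records both it and the
raw likelihood.  Genes with fewer than 2 mutations contribute no pooling
signal; they are excluded from fitting and scored with the final θ.

Two guards keep the latent labels meaningful:

* **Identifiability swaps.**  If θ_{F=1|D=1} < θ_{F=1|D=0} the D labels
  are swapped (an exact model symmetry).  If the H=up table is less
  up-skewed than the H=down table (compared by up-minus-down asymmetry,
  robust to near-ties), the two tables are swapped.
* **Null anchoring.**  The cohort's non-mutated patients are known F=0
  observations of the null regulation distribution.  Their per-leaf
  component densities enter the likelihood as F=0 leaves and their
  responsibilities feed the θ_{G|F=0} expected counts.  Without this, the
  F channel slowly absorbs patients with ordinary expression tails and
  the learned null over-concentrates, corrupting downstream calls.

Defaults: θ_D = 0.5, θ_{F=1|D=1} = 0.8, θ_{F=1|D=0} = 0.1,
θ_{G|F=0} = (0.1, 0.8, 0.1), θ_{G|F=1,up} = (0.05, 0.45, 0.5) (mirrored
for down); convergence at relative objective change < 1e-5 or 100
iterations.  Genes are reported at P(D) ≥ 0.8 and mutations at
P(F) ≥ 0.5.

## Emission mixtures

Each gene's expression across the cohort is a 3-component location-scale
Student's-t mixture (down / neutral / up).  Unconstrained mixture EM is
unusable here: on a unimodal column it carves the bulk into three
overlapping pieces, labelling ordinary patients dysregulated.  Fitting is
therefore hierarchical:

1. a single Student's t is fitted to the column (robust bulk model);
2. an **anchored** 3-component EM runs with the flank locations kept at
   least 1.5 neutral scales away from the neutral location (the clamp is
   the constrained argmax of the M-step objective, so EM stays monotone);
   ν per component by bounded optimisation over [2, 100] (continuous in
   the per-gene route, a fixed grid in the vectorised batch route);
3. the mixture is kept only if it beats the single t by its BIC margin
   (8 extra parameters); otherwise the column **collapses** to a
   neutral-dominant mixture — neutral = the single-t fit, flanks at the
   canonical ±2σ offsets with nominal weight 0.01.

Initialisation is deterministic (10th/50th/90th percentile locations
pushed out to the separation floor, MAD scale, weights 0.15/0.7/0.15),
so fits are reproducible without seeds.  Columns with < 30 observations
fall back to a single neutral component with a warning; constant columns
are an error.  Scale floor 1e-3.

The collapsed form matters: a column with no detectable mixture structure
still registers strong tail values as possible dysregulation (±2σ), but
its bulk is firmly neutral.  Under heavy-tailed data this leaves a known
limitation — single patients with several coincidental same-direction
outliers across a *small* neighbour set can reach moderate P(F); the
effect shrinks rapidly as neighbour sets grow (see Permutation analysis).

## Preprocessing

* **Expressed-gene filter.**  The 90th percentile of each gene's log2
  expression summarises its overall expression (robust to deletions in a
  minority of tumours).  Tukey-fence outliers are removed and assigned
  posterior 1 (high side) or 0 (low side); a two-component Gaussian
  mixture fitted to the rest gives each gene the posterior of the
  higher-mean component; genes with posterior ≥ 0.8 count as expressed.
  If a one-component fit has the better BIC the filter is inert (all
  non-low-outlier genes pass): a unimodal percentile distribution carries
  no evidence of an unexpressed class.  Needs ≥ 50 genes.
* **Copy-number cis compensation** (trans mode).  Expression is regressed
  on the gene's own log2 copy-number with a GP
  (squared-exponential + white noise); hyperparameters maximise the log
  marginal likelihood with restarts from ℓ ∈ {0.5, 1, 2}×SD(x); the
  residuals y − posterior mean carry the trans signal.  Constant copy
  number degenerates to centred expression.
* **Graph conditioning.**  Edges below weight 0.4 are dropped.  Per
  mutated gene (≥ 3 mutated patients), each neighbour is Welch-t-tested
  for differential expression between mutated and non-mutated patients
  with BH correction at 0.05; if any neighbour passes, the neighbour set
  shrinks to the passers at weight 1, otherwise the original weighted set
  is kept.  An optional cross-cohort mode combines per-cohort p-values by
  Fisher's method at FDR 0.05.  Non-expressed genes are removed both as
  mutated genes and as neighbours.

## Driver annotation

Per gene: N_g total mutations, n_loss loss-of-function events (nonsense,
stop-gain, frameshift indel, splice site) and n_rec hotspot events
(missense or in-frame indels recurring ≥ 2 times at the same codon within
the same class; events without codon positions never count).  Each count
is modelled as a two-component binomial mixture over (n, N) — a high-rate
driver component and a low-rate background — fitted by EM (init
p = (0.3, 0.02), ω = (0.1, 0.9), 0.5 pseudo-counts, components ordered
p1 > p2).  P(TSG) (from n_loss) and P(OCG) (from n_rec) are the
posteriors of the high-rate component; labels are called at ≥ 0.2.
The TSG and OCG mixtures are fitted independently on the same gene
universe.  Pairs collapsed to the `complex` class count toward N_g only.

## Simulation benchmark

`simulate_dataset` samples ancestrally from the model itself:
D ~ Bernoulli(fraction_D1); F | D; H ~ uniform{down,up} per neighbour;
G | F, H; and y = baseline + offset(G) + σ·t_ν noise, with the component
offsets ±δ·SD where SD = σ·sqrt(ν/(ν−2)).  Defaults define the headline
study conditions: 200 mutated genes (half impactful), M = 30 mutated
patients from a 200-patient cohort, N = 20 connected genes per gene,
δ = 1.5 (poorly discriminative emissions), θ_{F=1|D=1} = 0.85,
θ_{F=1|D=0} = 0.10, P(G in the H direction | F=1) = 0.5, 5% non-neutral
tails under F=0.  Free choices made once: cohort size 200 (a typical
tumour-type cohort), ν = 5 (robust heavy-tailed expression noise),
baselines ~ U(6,10) log2 units, edge weight 1.  Optional extras emulate
two features of real data: `phenocopy_fraction` flips a fraction of
non-mutated patients to mutated-like expression, and
`n_background_genes` adds unregulated expressed genes (the bulk of a
real transcriptome).

The benchmark pipeline is the full stack — batch emission fits, H
estimation, EM to convergence, exact inference — and reports rank-based
AUROC of P(D) against true D (per gene) and of P(F) against true F
(pooled mutations), averaged over 10 seeded replicates.  What passing
shows: the implementation recovers its own generative process at the
stated noise level.  What it does not show: robustness to model
misspecification (real expression is not a clean t mixture, real networks
are noisy, mutations are not exchangeable within a gene).

## Permutation analysis

Four schemes destroy specific parts of the mutation-expression link while
never touching the expression matrix: `sample` (switch patient names),
`gene` (switch gene names), `network` (redraw each mutated gene's
neighbour set, preserving its size and weights, from the gene universe),
and `all` (all three).  Scoring follows the standard permutation
protocol: the θs learned on the real cohort are held fixed and only the
inputs are shuffled (`fit_and_score(params=...)`).  Refitting EM per
permutation answers a different question and, on pure-null data, drifts
along a near-flat likelihood ridge to an uninformative fixed point.  The
permutation FDR at a threshold is mean permuted calls / real calls,
clipped to [0,1].

The null-suppression check runs at regulon scale (N = 50 neighbours,
4000 background genes): with small neighbour sets and heavy-tailed
emissions, a patient with a handful of coincidental same-direction
outliers is genuinely likelihood-favoured, and no faithful implementation
can push such calls below a few percent; with dozens of neighbours,
chance alignment cannot scale and permuted calls collapse.

## Post hoc statistics

* **Dip test.**  Hartigan's dip — the sup-distance between the empirical
  CDF and the closest unimodal CDF — computed from scratch by the
  greatest-convex-minorant / least-concave-majorant algorithm with
  iterative modal-interval narrowing (ties collapse into weights; an
  equally spaced grid attains the exact minimum 1/(2n)).  P-values are
  Monte-Carlo against uniform(0,1) samples of the same n (≥ 2000 draws,
  seeded, cached per sample size, +1 continuity correction).  Used to ask
  whether a gene's per-patient P(F) values split into responder /
  non-responder groups.
* **Stratification.**  Patients split at P(F) ≥ 0.5 (inclusive), with
  the dip test attached.
* **Cross-tumour recurrence.**  For a connected gene, dysregulation
  co-occurring with a high-probability mutation is counted per tumour
  type; the background rate is the pooled MLE Σk/Σn; each neighbour gets
  the exact binomial upper tail P(X ≥ k | n, p̂) on its pooled counts,
  BH-adjusted, separately for up- and downregulation.
* **Hypermutators.**  A tumour is flagged iff its mutation count strictly
  exceeds Q3 + 4.5·IQR (linear-interpolation quartiles).

## Numerical conventions

Log-space message passing with log-sum-exp throughout; emission scale
floor 1e-3; ν bounded to [2, 100] during fitting ([2, 1e6] accepted in
containers); quartiles by linear interpolation; H ties break to up; the
posterior TSVs round-trip at 1e-12 (`%.17g`).  The pipeline derives
per-stage child seeds from the global seed by hashing, so partial re-runs
are reproducible; two runs with the same seed produce bit-identical
outputs.

## Problem sizes used in the shipped checks

The benchmark uses the full 200-gene × 30-patient × 20-neighbour setting
over 10 replicates; EM-layer checks use 200 genes with generative
emissions; the permutation study uses 40 genes × 50 neighbours with a
4000-gene background; dip calibration uses 200 null replicates at n = 100
against a shared 2000-draw null table.  These sizes are the package's
own choices for routine verification and match the regimes the method is
meant for.

## Known limitations

* One mutation per (patient, gene): multiple distinct events collapse to
  a single `complex` record and their positions are lost.
* H is estimated once before EM and held fixed; jointly re-estimating it
  would break the tree structure that makes inference exact.
* The anchored emission EM assigns fixed positional roles (component 1 is
  the neutral bulk); it is not invariant to arbitrary permutations of an
  externally supplied initialisation.
* Small neighbour sets (N ≲ 20) with heavy-tailed expression let
  coincidental outlier patients reach moderate P(F); interpret per-
  mutation calls cautiously when a gene has few connected genes.
* The influence graph is consumed as given; no attempt is made to
  reconstruct or validate the biological network itself.
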