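# Methods

`fragmeth` predicts the methylation status of every CpG on every plasma
cell-free DNA (cfDNA) fragment from standard whole-genome sequencing —
no bisulfite conversion — by exploiting the coupling between DNA
methylation and cfDNA fragmentation, then aggregates the per-fragment
calls into a continuous methylome and decomposes it into tissue
contributions. This note describes the model, the estimation choices,
the synthetic data used to validate the package, and the limits of what
those validations show.

## The observation model

cfDNA is fragmented non-randomly around nucleosomes, and nucleosome
organisation tracks DNA methylation: unmethylated CpG islands are
nucleosome-depleted, open chromatin, while methylated DNA tends to be
stably wrapped in mono-nucleosomes. Three per-CpG features carry this
signal:

* **fragment length** (bp) — methylated CpGs sit on mono-nucleosomal
  (~167 bp) fragments, unmethylated ones on shorter fragments from open
  chromatin;
* **normalized coverage** — fragments overlapping the CpG position per
  million high-quality fragments; nucleosome-depleted (unmethylated)
  regions yield fewer protected fragments;
* **distance to fragment center** (bp, absolute) — methylated CpGs lie
  farther from the fragment midpoint.

All three are z-scored per sample (per BAM) so the model is insensitive
to library size and scale; the coverage z-score is clipped at ±3 SD
(`cov_outlier`) to tame pile-up artifacts.

Quality filters before feature computation: properly paired,
non-duplicate, primary alignments with both mates at MAPQ ≥ 30;
template length within [30, 500] bp; autosomes only; fragments touching
ENCODE-style blacklist intervals or positions with > 250× high-quality
coverage are discarded; a CpG covered only by bases of quality ≤ 5 is
skipped. Coordinates are 0-based half-open; a CpG site is the
forward-strand position of its C, strand-collapsed.

## The non-homogeneous two-state HMM

Hidden state of each CpG on each fragment: unmethylated (U) or
methylated (M). Because CpG spacing varies over three orders of
magnitude, the chain is non-homogeneous:

* the **initiation** vector is estimated separately per first-CpG
  offset bin (default edges 25, 50, 75, 100, 150 bp);
* each **transition** matrix is estimated separately per inter-CpG
  distance bin (default edges 10, 20, 50, 100, 200, 500 bp).

Bin edges are configurable; the defaults resolve island-scale spacing
(≤ 20 bp) from open-sea spacing (hundreds of bp) while keeping per-bin
counts usable. A pseudocount of 1 on every binned count keeps all rows
stochastic when a bin is empty.

**Emissions.** Given the state, the three features are treated as
independent, each modelled by a two-component univariate Gaussian
mixture

    Pr(e | state) = ∏_f [(1 − π_f) N(μ_i, σ_i²) + π_f N(μ_j, σ_j²)].

Variances are floored at 1e−4 (z² units). All recursions run in log
space with log-sum-exp.

**Initialisation.** A 2-component diagonal-covariance Gaussian mixture
(EM, up to 10,000 iterations) clusters all training observations in the
3-dimensional feature space. In WGS mode the component with the larger
mean z-scored distance-to-center is labelled M; with fragment-level
ground truth (WGBS mode) the component with the higher mean truth
methylation is labelled M; exact ties fall back to the longer mean
fragment length. Initiation and transition matrices are counted from
the hard assignments; each state-feature mixture is initialised by a
symmetric moment split (components at mean ± SD/2, variance ¾ SD²,
weight ½).

**Training.** Baum-Welch on all fragments with ≥ 7 CpGs
(`min_cpgs_train`), at most 50 iterations. The E-step uses plain
emission densities — the methylation prior plays no role in training.
The M-step pools expected transition counts within distance bins,
expected initiation counts within offset bins, and updates each mixture
from the joint state-and-component responsibilities, which keeps the
training log-likelihood non-decreasing (checked to 1e−6 relative in the
tests).

**Convergence.** After each iteration the old and new model are scored
on a fixed random sample of up to 10,000 fragments with ≥ 5 CpGs; the
divergence statistic is the absolute mean per-CpG log-likelihood
difference, a sampled symmetrised Kullback–Leibler distance (the two
directions have equal magnitude, so the symmetrisation reduces to the
absolute value). Training stops when D < 1e−4, or when D changes by
less than 1% relative to the previous iteration. The relative rule is
only consulted after 5 burn-in iterations (`kl_min_iter`): EM can cross
a slow saddle early whose D is momentarily flat yet far from converged.
Two caveats worth knowing: on smooth geometric decay (~3%/iteration)
the relative rule never fires and training honestly runs to the cap;
and D measures *predictive* convergence — mixture component means can
still be drifting when D is tiny, because a two-component mixture is
nearly non-identifiable predictively. The parameter-recovery harness
therefore disables early stopping and runs the full cap.

**Decoding.** No minimum CpG count. At decoding — and only there — a
per-CpG methylation prior k (from healthy buffy-coat WGBS, supplied as
a bedGraph; default for unlisted CpGs is the track mean) adjusts the
emission terms to posteriors:

    Pr(m | e) = Pr(e|m) k / (Pr(e|m) k + Pr(e|u)(1 − k)),

computed in log space so simultaneous underflow never yields 0/0. A
prior weight w ∈ [0, 1] shrinks k toward ½ (k′ = w·k + (1 − w)/2);
w = 0 disables the prior entirely. Viterbi runs on these posterior
terms; tie-breaks go to the previous state on the path, and toward M at
the first CpG. Per-CpG Pr(M) comes from the analogous forward–backward
recursion. A trained model serialises to versioned JSON and can be
applied decode-only to other (e.g. ultra-low-pass) samples.

## Methylome aggregation and evaluation

Viterbi calls are counted per reference CpG into methylated/total
counts; the continuous level is their ratio (bedGraph export rounds to
4 decimals, counts are exact). Window summaries pool counts
(Σ methylated / Σ total); CpG-island shores are the ±2 kb flanks minus
the island. Binary evaluation balances the truth classes by random
downsampling before sweeping the posterior threshold (trapezoidal
auROC). Continuous evaluation reports Pearson and Spearman correlations
per coverage stratum and per 1 kb window. For sparse (ultra-low-pass)
group comparisons, per-window two-sided Wilcoxon rank-sum tests flag
windows at p < 0.01 — exact p-values for groups ≤ 10 without ties,
normal approximation with tie correction otherwise; all-tied windows
get p = 1. Benjamini–Hochberg q-values are reported alongside for
transparency, but the flag follows the raw cut-off. Anchor profiles
average site levels in offset bins around oriented reference points,
mirror-flipped for minus-strand anchors.

## Tissue-of-origin deconvolution

A sample's window methylation vector b is modelled as A w with A the
reference panel (windows × cell types) and w constrained to the
probability simplex; the quadratic program min ‖Aw − b‖² s.t. w ≥ 0,
Σw = 1 is solved by SLSQP (deterministic, ftol 1e−14), and the solution
is clipped/renormalised so the output is exactly a probability vector.

Window preparation, deep mode: 1 kb island/shore windows with ≥ 10
informative bases (Cs + Ts) in *every* reference; ranked by
across-cell-type variance of density (computed before binarization);
top 1% retained (configurable — toy-scale panels need a larger
fraction to keep ≥ 10 windows); both sides binarized at 0.1 (density
< 0.1 → 0, else 1). ULP mode: entries with < 5 informative bases are
missing; windows > 80% missing are dropped and samples > 80% missing
are rejected; the top 25% most variable windows are kept; remaining
gaps are imputed by 5-nearest-neighbour across windows; then
binarization as above.

**What binarized deconvolution can and cannot do.** Binarizing the
sample turns each window into the indicator 1{Σ_{c∈S} w_c ≥ 0.1} over
the window's methylated cell types S. That makes the method robust to
the two distortions that affect continuous predicted densities (below),
but it also means the measurement is a *presence* signal: any
contribution above roughly the threshold saturates its windows, so
continuous proportions are not identifiable from binarized data, and a
least-squares fit to binary targets is biased toward equal weights
among detected tissues. Use the default binarized mode to detect
contributions; use `binarize=False` (`--no-binarize`) when the inputs
are well-calibrated continuous densities and proportions matter.

Continuous densities predicted from WGS carry two systematic
distortions even at high accuracy: (1) coverage selection bias —
methylated fragments are over-represented wherever protection differs
by state, so the fragment-weighted density is a saturating, nonlinear
function of the true density; (2) within-fragment smoothing — Viterbi
paths are near-constant within a fragment, so windows whose fragments
carry region-level evidence move as blocks. In our end-to-end
simulations these bound continuous-mode mixture recovery to an L1
error of roughly 0.2 under favourable noise, which is what the
integration test asserts.

## Synthetic data

The generator produces, from one seed, a fully deterministic study:
FASTA genome, island/promoter BED, per-cell-type methylomes, a
buffy-coat-style prior (mean of the blood methylomes), and a sorted,
indexed BAM with fragment-level truth. Defaults (all configurable):

* genome 300 kb with 30 islands of 1 kb; CpG density 0.10/bp in
  islands, 0.01/bp in open sea (realized by construction, so counts
  match binomial expectations);
* five cell types (neutrophil, B cell, T cell, hepatocyte,
  endothelial); per 12-island cycle: one island owned by each cell type
  (methylated 0.92 in the owner, 0.08 elsewhere), one methylated in all
  types, six unmethylated in all — most islands are shared, as in real
  methylomes, and the owner islands give deconvolution its signal; open
  sea is 0.85 everywhere;
* fragments nucleate at a seed CpG with weight proportional to the
  state-dependent coverage multiplier (1.0 methylated, 0.35
  unmethylated) times the inverse local CpG density, so placement is
  approximately uniform per bp as in real cfDNA; lengths are
  N(167, 20²) for methylated and N(140, 25²) for unmethylated seeds
  (clipped to [30, 500]); the seed's offset-from-center fraction is
  Beta(3, 1) (methylated, far) vs Beta(1, 3) (unmethylated, near);
* CpGs covered by a fragment copy the seed's state with probability
  0.97, but only within the seed's methylation domain (co-methylation
  does not cross island boundaries); otherwise they draw from the
  site's marginal;
* 5,000 fragments (~2.5×) in the quick default;
  `SimulationConfig.deep_wgs` raises this to 20,000 fragments on
  200 kb (~15×), the deep-coverage condition. The distinction matters:
  the coverage feature is Poisson-limited and only becomes cleanly
  informative at depth, which is why the classification operating
  point (balanced per-CpG auROC ≥ 0.9 for fragments with ≥ 5 CpGs,
  increasing with the min-CpG threshold) is evaluated at the deep
  condition on a single-cell-type sample — the analogue of evaluating
  a healthy donor's cfDNA against that donor's own WGBS.

What the generator does **not** emulate: sequencing errors and indels,
GC/mappability bias, real nucleosome phasing (the coupling is imposed
per fragment, not via a nucleosome map), bisulfite chemistry, CNVs, and
genome-scale CpG statistics. Passing tests therefore demonstrate the
correctness and internal consistency of the estimation machinery under
the stated couplings — not clinical performance on real plasma.

Decoy fragments violating each quality filter (length, MAPQ, duplicate
flag, improper pair, blacklist overlap, pile-up) can be injected at
known counts to test the filters exactly.

## Numerical and reproducibility choices

Log-space forward/backward/Viterbi throughout; variance floor 1e−4;
SD floor 1e−6 on raw feature scales; pseudocount 1 on binned counts;
probabilities floored at exp(−745) before logs. Every stochastic step
(GMM seeding, KL sampling, simulation, balanced downsampling) derives
from an explicit seed; the full pipeline is byte-identical across runs
with the same seed, BAM included (reads are sorted in memory before
writing, so no external sort step introduces nondeterminism). Fragment
problem sizes in the test suite (hundreds to 20,000 fragments) were
chosen to keep each property measurable at desk scale.

## Known limitations

* Two states only; hemimethylation and non-CpG methylation are out of
  scope.
* The conditional-independence emission model double-counts
  fragment-level features (length is observed once per fragment but
  enters once per CpG), which makes posteriors overconfident; ROC
  ordering is unaffected, calibration is not to be trusted.
* Binarized deconvolution detects presence, not proportion (above).
* The 250× pile-up cap and the blacklist are evaluated on the toy
  scale exactly as specified, but genome-scale memory behaviour
  (per-position arrays) is untested beyond a few hundred kb.
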