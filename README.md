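# fragmeth

Methylation from fragmentation: `fragmeth` predicts the methylation
status of every CpG on every plasma cell-free DNA (cfDNA) fragment from
standard (non-bisulfite) whole-genome sequencing, aggregates the calls
into a continuous per-CpG methylation track, and estimates the tissue
composition of the cfDNA by constrained quadratic programming against
reference methylomes.

It is aimed at computational biologists working with cfDNA WGS who want
methylation-based analyses — methylome tracks, differentially
methylated windows, tissue-of-origin fractions — without bisulfite
libraries, and at methods developers who need a fully self-contained,
simulation-backed reimplementation of this class of model to build on.

## The model

cfDNA fragmentation is shaped by nucleosome protection, and nucleosome
organisation tracks DNA methylation. Each CpG observed on a fragment
carries three features: the fragment length, the normalized coverage at
the CpG position, and the CpG's distance to the fragment center (all
z-scored per sample). The hidden methylation state *u*/*m* of the CpGs
along one fragment forms a **non-homogeneous two-state HMM**:
initiation probabilities are binned by the first CpG's offset,
transition matrices by the distance to the previous CpG, and each
feature is emitted per state from a two-component Gaussian mixture

    Pr(e | state) = ∏_f [(1 − π) N(μ_i, σ_i²) + π N(μ_j, σ_j²)].

Parameters are estimated without labels: a Gaussian-mixture
initialisation (the component with the larger distance-to-center is
methylated), then Baum–Welch (≤ 50 iterations, fragments with ≥ 7
CpGs), with a sampled Kullback–Leibler divergence between successive
models as the convergence criterion. At decoding, a per-CpG methylation
prior *k* from healthy buffy-coat WGBS enters the emission as

    Pr(m | e) = Pr(e|m) k / (Pr(e|m) k + Pr(e|u)(1 − k))

and Viterbi yields the state path; forward–backward yields per-CpG
Pr(m). Calls are aggregated per reference CpG into a continuous track
(0–100%). For tissue of origin, window-level methylation is modelled as
a non-negative, sum-to-one mixture of reference cell-type methylomes,
solved as the quadratic program min ‖Aw − b‖² on the probability
simplex, with the published window filters (1 kb island/shore windows,
evidence and variability filters, 0.1 binarization; KNN imputation in
the ultra-low-pass mode).

Details, parameter tables and limitations: [docs/methods.md](docs/methods.md).

## Worked example

Everything runs on self-generated synthetic data — a toy genome with
CpG islands, five cell-type methylomes, a blood prior, and cfDNA
fragments whose length, coverage and CpG placement depend on
methylation state:

```bash
fragmeth run --seed 7 --out runs/demo
```

which executes simulate → extract → train → decode → aggregate →
evaluate → deconvolve and prints (seed 7, 5,000 fragments):

```json
{
 "auroc_min_cpgs_1": 0.8040322491024975,
 "auroc_min_cpgs_3": 0.8160588648329674,
 "auroc_min_cpgs_5": 0.8318069821962137,
 "n_fragments": 4991,
 "n_iter": 25,
 "converged": true,
 "convergence_criterion": "kl_rel",
 "final_kl": 0.0004544834821615662,
 "deconv_l1_real": 0.4190377325409128,
 ...
}
```

Reading this: balanced per-CpG auROC against the held-back fragment
truth rises from 0.80 to 0.83 as fragments are restricted to ≥ 1, ≥ 3,
≥ 5 CpGs — more CpGs per fragment, more chained evidence. Training
converged at iteration 25 when the inter-iteration KL divergence
stopped changing by more than 1%. The deconvolution L1 error refers to
the known simulated mixture (0.55 neutrophil / 0.25 B / 0.10 T /
0.07 hepatocyte / 0.03 endothelial); at this quick, shallow (~2.5×)
setting it is loose. At the deep-coverage condition
(`SimulationConfig.deep_wgs`: 20,000 fragments, ~15×) the per-CpG
auROC for ≥ 5-CpG fragments reaches ≈ 0.90 — the regime the model is
designed for; the test suite pins that operating point.

The same stages are available as individual subcommands for real data:

```bash
fragmeth train  --bam sample.bam --fasta hg.fa --blacklist exclude.bed \
                --min-cpgs 7 --cov-outlier 3 --seed 1 --out model.json
fragmeth decode --bam other.bam --fasta hg.fa --model model.json \
                --prior buffycoat.bedgraph --out decoded.tsv   # decode-only
fragmeth aggregate  --decoded decoded.tsv --out-prefix track
fragmeth deconvolve --panel references.tsv --windows windows.tsv \
                    --mode deep --out weights.tsv
fragmeth dmr --case case_windows.tsv --control control_windows.tsv \
             --mode ulp --out dmr.tsv
```

The library surface mirrors scikit-learn: `FragmentMethylationHMM`
(fit / predict / score, parameters via `get_params`) and
`MethylomeDeconvolver` (fit on a reference panel, predict weights)
compose with standard tooling.

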