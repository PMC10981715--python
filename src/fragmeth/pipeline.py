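"""End-to-end orchestration on simulated data.

simulate -> extract features -> train the NH-HMM -> decode with the
blood prior -> aggregate the per-CpG track -> evaluate per-CpG auROC ->
deconvolve tissue weights. Every stage writes its artifact; a JSON
manifest with the resolved configuration, artifact checksums and the
headline metrics is written last. Identical seeds yield identical
artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .deconv import MethylomeDeconvolver, ReferenceMethylomePanel
from .features import FilterConfig, attach_truth, build_cpg_index, extract_fragments, zscore_features
from .hmm import FragmentMethylationHMM, MethylationPrior, STATE_NAMES
from .methylome import CpGTrack, WindowSet, aggregate_track, evaluate_binary, window_summarize
from .simulate import (
    CHROM, SimulationConfig, simulate_fragments, simulate_genome,
    simulate_methylomes, simulate_sample_mixture, write_prior_bedgraph,
)

logger = logging.getLogger(__name__)

#: default simulated cfDNA composition: blood-dominated with minor
#: solid-tissue contributions, the regime the deconvolution targets
DEFAULT_MIXTURE = (0.55, 0.25, 0.10, 0.07, 0.03)

#: toy-genome window-variability percentile for the deconvolution
#: (the genome-scale default of 1% would leave < 10 of the toy panel's
#: ~150 island/shore windows)
TOY_TOP_FRACTION = 0.2


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def panel_from_methylomes(
    methylomes: pd.DataFrame,
    windows: WindowSet,
    depth: int = 30,
) -> ReferenceMethylomePanel:
    """Reference panel: per-window mean methylation of each cell type.

    Emulates window-level WGBS of purified cell types; the informative
    count is CpGs-in-window x ``depth``.
    """
    pos = methylomes.index.to_numpy()
    dens = {}
    info = {}
    starts = windows.df["start"].to_numpy()
    ends = windows.df["end"].to_numpy()
    names = [f"{c}:{s}-{e}" for c, s, e in
             zip(windows.df["chrom"], windows.df["start"], windows.df["end"])]
    lo = np.searchsorted(pos, starts)
    hi = np.searchsorted(pos, ends)
    for ct in methylomes.columns:
        vals = methylomes[ct].to_numpy()
        cs = np.concatenate([[0.0], np.cumsum(vals)])
        n = (hi - lo).astype(float)
        with np.errstate(invalid="ignore"):
            dens[ct] = np.where(n > 0, (cs[hi] - cs[lo]) / np.maximum(n, 1), np.nan)
        info[ct] = (hi - lo) * depth
    index = pd.Index(names, name="window")
    return ReferenceMethylomePanel(
        density=pd.DataFrame(dens, index=index),
        informative=pd.DataFrame(info, index=index),
    )


def sample_windows_from_track(track: CpGTrack, windows: WindowSet) -> pd.DataFrame:
    """Sample-side window table (density, n_total) for the deconvolver."""
    summary = window_summarize(track, windows)
    names = [f"{c}:{s}-{e}" for c, s, e in
             zip(summary["chrom"], summary["start"], summary["end"])]
    out = summary[["density", "n_total"]].copy()
    out.index = pd.Index(names, name="window")
    return out


def deconvolution_windows(genome, size: int = 1000) -> WindowSet:
    """1 kb tiles restricted to CpG-island and shore territory."""
    tiles = WindowSet.tiling({CHROM: genome.length}, size)
    cgi = WindowSet(genome.islands)
    shores = cgi.shores(2000, {CHROM: genome.length})
    merged = WindowSet(pd.concat([cgi.df, shores.df], ignore_index=True))
    return tiles.restrict_to(merged)


def run_pipeline(
    out_dir: Path,
    seed: int = 1,
    n_fragments: int = 5000,
    mixture_weights: tuple[float, ...] | None = None,
    max_iter: int = 50,
    top_fraction: float = TOY_TOP_FRACTION,
    config: SimulationConfig | None = None,
) -> dict:
    """Run the staged pipeline; returns the manifest dictionary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config is not None:
        cfg = config
        weights = cfg.mixture_weights or tuple(
            [1.0] + [0.0] * (len(cfg.cell_types) - 1)
        )
        seed = cfg.seed
    else:
        weights = tuple(mixture_weights) if mixture_weights else DEFAULT_MIXTURE
        cfg = SimulationConfig(seed=seed, n_fragments=n_fragments, mixture_weights=weights)

    # stage 1: simulation
    genome = simulate_genome(cfg, out_dir)
    methylomes, prior_track = simulate_methylomes(cfg, genome)
    sample_methylome = simulate_sample_mixture(methylomes, np.asarray(weights))
    simulate_fragments(cfg, genome, sample_methylome, out_dir / "reads.bam",
                       out_dir / "truth.tsv")
    write_prior_bedgraph(out_dir / "prior.bedgraph", prior_track)

    # stage 2: features
    index = build_cpg_index(str(out_dir / "genome.fa"))
    fragments, stats = extract_fragments(str(out_dir / "reads.bam"), index, FilterConfig())
    zscore_features(fragments, stats)
    attach_truth(fragments, str(out_dir / "truth.tsv"))

    # stage 3: training
    model = FragmentMethylationHMM(max_iter=max_iter, random_state=seed)
    model.fit(fragments)
    model.to_json(str(out_dir / "model.json"), feature_stats={
        "total_high_quality_fragments": stats.total_high_quality_fragments,
        "mean": stats.mean.tolist(), "sd": stats.sd.tolist(),
    })

    # stage 4: decoding with the blood prior
    prior = MethylationPrior.from_bedgraph(str(out_dir / "prior.bedgraph"))
    decoded = model.predict(fragments, prior)
    rows = []
    for d in decoded:
        f = d.fragment
        rows.append({
            "name": f.name, "chrom": f.chrom, "start": f.start, "end": f.end,
            "cpg_positions": ",".join(str(o.ref_position) for o in f.observations),
            "path": d.path_string,
            "posterior_m": ",".join(f"{p:.6g}" for p in d.posterior_m),
            "truth": "".join(s if s in STATE_NAMES else "."
                             for s in (f.truth_states or ["."] * f.n_cpgs)),
        })
    pd.DataFrame(rows).to_csv(out_dir / "decoded.tsv", sep="\t", index=False)

    # stage 5: aggregation
    track = aggregate_track(decoded)
    track.to_tsv(str(out_dir / "track.tsv"))
    track.to_bedgraph(str(out_dir / "track.bedgraph"))

    # stage 6: evaluation
    aurocs = {}
    for threshold in (1, 3, 5):
        aurocs[threshold] = evaluate_binary(decoded, threshold, seed=seed).auroc

    # stage 7: deconvolution
    windows = deconvolution_windows(genome)
    panel = panel_from_methylomes(methylomes, windows)
    panel.to_tsv(str(out_dir / "panel.tsv"))
    sample_windows = sample_windows_from_track(track, windows)
    sample_windows.to_csv(out_dir / "sample_windows.tsv", sep="\t")
    result_bin = (
        MethylomeDeconvolver(mode="deep", binarize=True, top_fraction=top_fraction)
        .fit(panel).predict(sample_windows)
    )
    result_real = (
        MethylomeDeconvolver(mode="deep", binarize=False, top_fraction=top_fraction)
        .fit(panel).predict(sample_windows)
    )
    result_real.weights.rename_axis("cell_type").to_csv(out_dir / "weights.tsv", sep="\t")
    truth_w = np.asarray(weights)
    l1_real = float(np.abs(result_real.weights.to_numpy() - truth_w).sum())
    l1_bin = float(np.abs(result_bin.weights.to_numpy() - truth_w).sum())

    history = model.history_
    final = history[-1] if history else {}
    metrics = {
        "auroc_min_cpgs_1": aurocs[1],
        "auroc_min_cpgs_3": aurocs[3],
        "auroc_min_cpgs_5": aurocs[5],
        "n_fragments": len(fragments),
        "n_iter": model.n_iter_,
        "converged": model.converged_,
        "convergence_criterion": final.get("converged_reason"),
        "final_kl": final.get("kl"),
        "deconv_weights_real": result_real.weights.round(6).to_dict(),
        "deconv_weights_binarized": result_bin.weights.round(6).to_dict(),
        "deconv_l1_real": l1_real,
        "deconv_l1_binarized": l1_bin,
        "true_mixture": dict(zip(methylomes.columns, truth_w.tolist())),
    }
    artifacts = [
        out_dir / n for n in (
            "genome.fa", "cgi.bed", "promoters.bed", "reads.bam", "truth.tsv",
            "prior.bedgraph", "model.json", "decoded.tsv", "track.tsv",
            "track.bedgraph", "panel.tsv", "sample_windows.tsv", "weights.tsv",
        )
    ]
    manifest = {
        "format_version": 1,
        "config": {**dataclasses.asdict(cfg), "seed": seed, "max_iter": max_iter,
                   "top_fraction": top_fraction},
        "metrics": metrics,
        "training_history": history,
        "artifacts": {p.name: _sha256(p) for p in artifacts if p.exists()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("pipeline complete: auROC(>=5 CpGs) = %.3f", aurocs[5])
    return manifest
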