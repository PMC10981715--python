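"""Reference-anchored methylation tracks, window summaries and evaluation.

Decoded per-fragment state paths are aggregated into a per-CpG track of
(methylated calls / total calls), summarised over window sets (1 kb
tilings, CpG islands, shores), and compared against ground truth by
balanced-class ROC at the fragment-CpG level, by Pearson/Spearman
correlation of continuous levels, and by rank-sum tests between sample
groups for sparse (ultra-low-pass) differential methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc, roc_curve
from statsmodels.stats.multitest import multipletests

from .errors import DataFormatError, UsageError
from .hmm import STATE_M, DecodedFragment

logger = logging.getLogger(__name__)


class CpGTrack:
    """Per-CpG methylated/total fragment-call counts and continuous level."""

    def __init__(self, counts: dict[tuple[str, int], list[int]] | None = None):
        # (chrom, pos) -> [n_methylated, n_total]
        self.counts: dict[tuple[str, int], list[int]] = counts or {}

    def add_call(self, chrom: str, position: int, methylated: bool) -> None:
        c = self.counts.setdefault((chrom, position), [0, 0])
        c[0] += int(methylated)
        c[1] += 1

    def level(self, chrom: str, position: int) -> float | None:
        c = self.counts.get((chrom, position))
        if c is None or c[1] == 0:
            return None
        return c[0] / c[1]

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": chrom, "position": pos, "n_methylated": c[0], "n_total": c[1],
             "level": c[0] / c[1]}
            for (chrom, pos), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "position", "n_methylated", "n_total", "level"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CpGTrack":
        track = cls()
        for _, row in df.iterrows():
            track.counts[(row["chrom"], int(row["position"]))] = [
                int(row["n_methylated"]), int(row["n_total"])
            ]
        return track

    @classmethod
    def from_levels(cls, levels: dict[tuple[str, int], float], depth: int = 1000) -> "CpGTrack":
        """Build a track from continuous levels (e.g. a simulated truth
        methylome), representing each level over a nominal depth."""
        track = cls()
        for key, lv in levels.items():
            track.counts[key] = [int(round(lv * depth)), depth]
        return track

    def to_bedgraph(self, path: str, digits: int = 4) -> None:
        with open(path, "w") as fh:
            for (chrom, pos), c in sorted(self.counts.items()):
                if c[1] == 0:
                    continue
                fh.write(f"{chrom}\t{pos}\t{pos + 2}\t{round(c[0] / c[1], digits)}\n")

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "CpGTrack":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def aggregate_track(decoded: Iterable[DecodedFragment]) -> CpGTrack:
    """Count each fragment's Viterbi call once per CpG site."""
    track = CpGTrack()
    for d in decoded:
        for obs, state in zip(d.fragment.observations, d.path):
            track.add_call(d.fragment.chrom, obs.ref_position, state == STATE_M)
    return track


# ---------------------------------------------------------------------------
# windows


@dataclass
class WindowSet:
    """Named genomic intervals (0-based half-open) with optional strand."""

    df: pd.DataFrame  # columns: chrom, start, end [, name, strand]

    def __post_init__(self) -> None:
        missing = {"chrom", "start", "end"} - set(self.df.columns)
        if missing:
            raise DataFormatError(f"window table lacks columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def tiling(cls, chrom_lengths: dict[str, int], size: int = 1000) -> "WindowSet":
        """Non-overlapping fixed-size tiling of the genome."""
        rows = []
        for chrom, length in chrom_lengths.items():
            for start in range(0, length, size):
                rows.append(
                    {"chrom": chrom, "start": start, "end": min(start + size, length),
                     "name": f"{chrom}:{start}"}
                )
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_bed(cls, path: str) -> "WindowSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                p = line.split("\t")
                rows.append(
                    {"chrom": p[0], "start": int(p[1]), "end": int(p[2]),
                     "name": p[3] if len(p) > 3 else f"{p[0]}:{p[1]}",
                     "strand": p[5] if len(p) > 5 else "+"}
                )
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"]))

    def shores(self, flank: int = 2000, chrom_lengths: dict[str, int] | None = None) -> "WindowSet":
        """The +-``flank`` bp surroundings of each interval, minus the
        interval itself (CpG-island shore convention)."""
        rows = []
        for _, w in self.df.iterrows():
            limit = (chrom_lengths or {}).get(w["chrom"])
            left = (max(0, w["start"] - flank), w["start"])
            right = (w["end"], w["end"] + flank if limit is None else min(w["end"] + flank, limit))
            for i, (s, e) in enumerate((left, right)):
                if e > s:
                    rows.append(
                        {"chrom": w["chrom"], "start": s, "end": e,
                         "name": f"{w.get('name', w['chrom'])}_shore{i}"}
                    )
        return WindowSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))

    def restrict_to(self, other: "WindowSet") -> "WindowSet":
        """Windows overlapping at least one interval of ``other``."""
        keep = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for _, w in other.df.iterrows():
            by_chrom.setdefault(w["chrom"], []).append((w["start"], w["end"]))
        for idx, w in self.df.iterrows():
            for s, e in by_chrom.get(w["chrom"], []):
                if w["start"] < e and s < w["end"]:
                    keep.append(idx)
                    break
        return WindowSet(self.df.loc[keep].reset_index(drop=True))


def window_summarize(track: CpGTrack, windows: WindowSet) -> pd.DataFrame:
    """Pooled methylation density per window.

    density = sum n_methylated / sum n_total over CpGs in the window;
    windows with no covered CpG get NaN density and informative count 0.
    The informative count (n_total pooled over CpGs) doubles as the
    window's 'Cs + Ts' evidence for the deconvolution filters.
    """
    sites = track.to_frame()
    out = windows.df.copy()
    n_meth = np.zeros(len(out), dtype=np.int64)
    n_tot = np.zeros(len(out), dtype=np.int64)
    if not sites.empty:
        for chrom, sub in sites.groupby("chrom", sort=False):
            sel = out["chrom"] == chrom
            if not sel.any():
                continue
            pos = sub["position"].to_numpy()
            order = np.argsort(pos)
            pos = pos[order]
            meth = sub["n_methylated"].to_numpy()[order]
            tot = sub["n_total"].to_numpy()[order]
            cmeth = np.concatenate([[0], np.cumsum(meth)])
            ctot = np.concatenate([[0], np.cumsum(tot)])
            lo = np.searchsorted(pos, out.loc[sel, "start"].to_numpy())
            hi = np.searchsorted(pos, out.loc[sel, "end"].to_numpy())
            n_meth[np.flatnonzero(sel)] = cmeth[hi] - cmeth[lo]
            n_tot[np.flatnonzero(sel)] = ctot[hi] - ctot[lo]
    out["n_methylated"] = n_meth
    out["n_total"] = n_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        out["density"] = np.where(n_tot > 0, n_meth / np.maximum(n_tot, 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationReport:
    """ROC / correlation summary for a comparison."""

    auroc: float | None = None
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    pearson: dict = field(default_factory=dict)
    spearman: dict = field(default_factory=dict)
    n: int = 0


def evaluate_binary(
    decoded: Sequence[DecodedFragment],
    min_cpgs_per_fragment: int = 5,
    seed: int | None = None,
) -> EvaluationReport:
    """Balanced-class per-CpG ROC of posterior Pr(M) against truth.

    CpGs on fragments with >= ``min_cpgs_per_fragment`` CpGs and a known
    truth state enter; the majority class is randomly downsampled to the
    minority size before the threshold sweep.
    """
    scores, labels = [], []
    for d in decoded:
        if d.fragment.n_cpgs < min_cpgs_per_fragment:
            continue
        truth = d.fragment.truth_states
        if truth is None:
            continue
        for p, s in zip(d.posterior_m, truth):
            if s in ("U", "M"):
                scores.append(float(p))
                labels.append(1 if s == "M" else 0)
    scores_arr = np.asarray(scores)
    labels_arr = np.asarray(labels)
    n_pos = int(labels_arr.sum())
    n_neg = int(labels_arr.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UsageError("both truth classes are required for ROC evaluation")
    rng = np.random.default_rng(seed)
    n_keep = min(n_pos, n_neg)
    keep = np.concatenate(
        [
            rng.choice(np.flatnonzero(labels_arr == 1), size=n_keep, replace=False),
            rng.choice(np.flatnonzero(labels_arr == 0), size=n_keep, replace=False),
        ]
    )
    fpr, tpr, _ = roc_curve(labels_arr[keep], scores_arr[keep])
    return EvaluationReport(
        auroc=float(auc(fpr, tpr)), roc_fpr=fpr, roc_tpr=tpr, n=int(2 * n_keep)
    )


def correlate_tracks(
    predicted: CpGTrack,
    truth: CpGTrack,
    regions: WindowSet | None = None,
    min_coverage: Sequence[int] = (1, 5, 10),
    window_size: int = 1000,
    chrom_lengths: dict[str, int] | None = None,
) -> EvaluationReport:
    """Pearson/Spearman agreement of continuous levels at shared CpGs.

    Correlations are reported per coverage stratum (site coverage >=
    threshold in BOTH tracks, optionally restricted to ``regions``) and,
    when ``chrom_lengths`` is given, over a non-overlapping window
    tiling ('window' key).
    """
    region_list: dict[str, list[tuple[int, int]]] | None = None
    if regions is not None:
        region_list = {}
        for _, w in regions.df.iterrows():
            region_list.setdefault(w["chrom"], []).append((w["start"], w["end"]))

    def in_regions(chrom: str, pos: int) -> bool:
        if region_list is None:
            return True
        return any(s <= pos < e for s, e in region_list.get(chrom, []))

    shared = [
        key for key in predicted.counts
        if key in truth.counts and in_regions(*key)
    ]
    report = EvaluationReport(n=len(shared))
    for cov in min_coverage:
        pairs = [
            (predicted.counts[k][0] / predicted.counts[k][1],
             truth.counts[k][0] / truth.counts[k][1])
            for k in shared
            if predicted.counts[k][1] >= cov and truth.counts[k][1] >= cov
        ]
        key = f"cpg_cov>={cov}"
        if len(pairs) < 3:
            report.pearson[key] = None
            report.spearman[key] = None
            continue
        x, y = np.array(pairs).T
        if np.std(x) == 0 or np.std(y) == 0:
            report.pearson[key] = None
            report.spearman[key] = None
            continue
        report.pearson[key] = float(sps.pearsonr(x, y).statistic)
        report.spearman[key] = float(sps.spearmanr(x, y).statistic)

    if chrom_lengths is not None:
        tiles = WindowSet.tiling(chrom_lengths, window_size)
        wp = window_summarize(predicted, tiles)["density"]
        wt = window_summarize(truth, tiles)["density"]
        ok = wp.notna() & wt.notna()
        if ok.sum() >= 3 and wp[ok].std() > 0 and wt[ok].std() > 0:
            report.pearson["window"] = float(sps.pearsonr(wp[ok], wt[ok]).statistic)
            report.spearman["window"] = float(sps.spearmanr(wp[ok], wt[ok]).statistic)
        else:
            report.pearson["window"] = None
            report.spearman["window"] = None
    return report


# ---------------------------------------------------------------------------
# differential methylation (sparse / ULP arm)


def _ranksum_p(case: np.ndarray, control: np.ndarray) -> float:
    """Two-sided rank-sum p: exact for groups <= 10 without ties,
    normal approximation with tie correction otherwise."""
    if np.ptp(np.concatenate([case, control])) == 0:
        return 1.0
    has_ties = np.unique(np.concatenate([case, control])).size < case.size + control.size
    if max(case.size, control.size) <= 10 and not has_ties:
        res = sps.mannwhitneyu(case, control, alternative="two-sided", method="exact")
    else:
        # tie-corrected normal approximation, no continuity correction
        res = sps.mannwhitneyu(case, control, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
    return float(res.pvalue)


def wilcoxon_dmr(
    case: pd.DataFrame,
    control: pd.DataFrame,
    p_cutoff: float = 0.01,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Per-window two-sided Wilcoxon rank-sum test between sample groups.

    ``case`` and ``control`` are windows x samples density matrices on
    the same window index (NaN = window missing in that sample). Windows
    with fewer than ``min_samples`` non-missing values in either group
    are skipped. Returns a table with p-value, Benjamini-Hochberg q,
    direction (sign of the case-control median difference) and the flag
    ``p < p_cutoff``.
    """
    if not case.index.equals(control.index):
        raise UsageError("case and control must share a window index")
    rows = []
    for win in case.index:
        a = case.loc[win].dropna().to_numpy(dtype=float)
        b = control.loc[win].dropna().to_numpy(dtype=float)
        if a.size < min_samples or b.size < min_samples:
            continue
        p = _ranksum_p(a, b)
        rows.append(
            {"window": win, "p": p,
             "direction": int(np.sign(np.median(a) - np.median(b))),
             "median_case": float(np.median(a)), "median_control": float(np.median(b))}
        )
    out = pd.DataFrame(rows, columns=["window", "p", "direction", "median_case", "median_control"])
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["flagged"] = out["p"] < p_cutoff
    else:
        out["q"] = []
        out["flagged"] = []
    return out


# ---------------------------------------------------------------------------
# anchor profiles


def anchor_profile(
    track: CpGTrack,
    anchors: pd.DataFrame,
    flank: int = 2000,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Mean methylation level around oriented anchor points.

    ``anchors`` needs columns chrom, position, strand; site offsets are
    sign-flipped for minus-strand anchors so profiles are orientation
    aligned. Returns per-bin mean level and site count.
    """
    if flank <= 0 or bin_size <= 0:
        raise UsageError("flank and bin size must be positive")
    edges = np.arange(-flank, flank + bin_size, bin_size)
    sums = np.zeros(edges.size - 1)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    site_df = track.to_frame()
    by_chrom = {c: g for c, g in site_df.groupby("chrom", sort=False)}
    for _, a in anchors.iterrows():
        g = by_chrom.get(a["chrom"])
        if g is None:
            continue
        pos = g["position"].to_numpy()
        lev = g["level"].to_numpy()
        off = pos - int(a["position"])
        if str(a.get("strand", "+")) == "-":
            off = -off
        sel = (off >= -flank) & (off < flank)
        idx = (off[sel] + flank) // bin_size
        np.add.at(sums, idx, lev[sel])
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"offset_start": edges[:-1], "offset_end": edges[1:], "mean_level": mean, "n": counts}
    )
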