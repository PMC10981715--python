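"""Self-contained synthetic data: toy genome, cell-type methylomes and
cfDNA fragments whose fragmentation features are coupled to methylation.

The generator emulates the biology the model exploits: a genome with
CpG-dense islands and CpG-poor open sea; cell-type methylomes that are
unmethylated at islands (with some islands methylated only in an owner
cell type, giving the deconvolution its discriminative windows) and
methylated in open sea; and fragments whose length, local coverage and
CpG-to-center placement depend on the methylation state: methylated
CpGs sit on longer, mono-nucleosomal fragments (~167 bp) and farther
from the fragment center, unmethylated CpGs on shorter fragments
(~140 bp) from nucleosome-depleted chromatin with reduced coverage.

All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import UsageError
from .features import CpGObservation, Fragment, scan_cpg_positions
from .hmm import FragmentMethylationHMM

CHROM = "chr1"

BLOOD_CELL_TYPES = ("neutrophil", "b_cell", "t_cell")
DEFAULT_CELL_TYPES = BLOOD_CELL_TYPES + ("hepatocyte", "endothelial")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline (all tunable).

    Lengths in bp, densities per bp, probabilities in [0, 1].
    """

    seed: int
    genome_length: int = 300_000
    n_islands: int = 30
    island_length: int = 1_000
    island_cpg_density: float = 0.10
    open_sea_cpg_density: float = 0.01

    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    meth_island_background: float = 0.08  # islands in non-owner cell types
    meth_island_owner: float = 0.92  # owner-specific methylated islands
    meth_open_sea: float = 0.85

    n_fragments: int = 5_000
    frag_len_methylated: tuple[float, float] = (167.0, 20.0)  # mean, sd
    frag_len_unmethylated: tuple[float, float] = (140.0, 25.0)
    coverage_mult_methylated: float = 1.0
    coverage_mult_unmethylated: float = 0.35  # nucleosome-depleted -> fewer fragments
    center_beta_methylated: tuple[float, float] = (3.0, 1.0)  # |2*dtc/L| ~ Beta(a,b)
    center_beta_unmethylated: tuple[float, float] = (1.0, 3.0)
    # P(CpG shares the fragment's seed state) = base + slope * positional
    # agreement, where agreement is 2|dtc|/L for methylated seeds and
    # 1 - 2|dtc|/L for unmethylated seeds (the nucleosome-phase 'wave':
    # CpGs far from the center are the methylated-prone ones)
    concordance_base: float = 0.97
    concordance_slope: float = 0.0
    noise_scale: float = 1.0  # multiplies the fragment-length SDs
    read_length: int = 60
    mixture_weights: tuple[float, ...] | None = None  # over cell_types; default: first=1

    def __post_init__(self) -> None:
        probs = (
            self.island_cpg_density, self.open_sea_cpg_density,
            self.meth_island_background, self.meth_island_owner, self.meth_open_sea,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise UsageError("densities and methylation probabilities must lie in [0, 1]")
        if self.mixture_weights is not None:
            if len(self.mixture_weights) != len(self.cell_types):
                raise UsageError("mixture_weights length must match cell_types")
            if abs(sum(self.mixture_weights) - 1.0) > 1e-8:
                raise UsageError("mixture_weights must sum to 1")
        if self.n_islands * (self.island_length + 200) > self.genome_length:
            raise UsageError("island layout exceeds the genome length")
        if self.n_fragments < 1:
            raise UsageError("n_fragments must be positive")

    @classmethod
    def deep_wgs(cls, seed: int, **overrides) -> "SimulationConfig":
        """The deep-coverage training condition: ~15x fragment depth
        (20,000 fragments on a 200 kb genome), mirroring the
        high-coverage WGS samples the model is meant to be trained on.
        The quick default condition (5,000 fragments on 300 kb) is
        shallow; the coverage feature only becomes cleanly informative
        at depth."""
        base = {"genome_length": 200_000, "n_islands": 20, "n_fragments": 20_000}
        base.update(overrides)
        return cls(seed=seed, **base)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise UsageError(f"unknown simulation config keys: {sorted(unknown)}")
        for key in ("cell_types", "mixture_weights", "frag_len_methylated",
                    "frag_len_unmethylated", "center_beta_methylated",
                    "center_beta_unmethylated"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class SimulatedGenome:
    sequence: str
    islands: pd.DataFrame  # chrom, start, end, name, owner
    promoters: pd.DataFrame  # chrom, start, end, name, strand
    cpg_positions: np.ndarray

    @property
    def length(self) -> int:
        return len(self.sequence)


def _island_layout(cfg: SimulationConfig) -> list[tuple[int, int]]:
    gap = (cfg.genome_length - cfg.n_islands * cfg.island_length) // (cfg.n_islands + 1)
    out = []
    pos = gap
    for _ in range(cfg.n_islands):
        out.append((pos, pos + cfg.island_length))
        pos += cfg.island_length + gap
    return out


def _random_sequence(length: int, cpg_density: float, rng: np.random.Generator,
                     prev_char: str) -> str:
    """Sequence of ~``length`` bp with the target CpG-per-bp density.

    At each slot a CG dinucleotide is emitted with probability
    q = d/(1-d), otherwise one random base; a random G is never placed
    directly after a C, so realized CpGs are exactly the emitted CGs.
    """
    q = cpg_density / (1.0 - cpg_density)
    chars: list[str] = []
    n = 0
    bases = "ACGT"
    emit_cg = rng.random(length) < q
    base_draws = rng.integers(0, 4, size=length)
    i = 0
    while n < length:
        if emit_cg[i % length]:
            chars.append("CG")
            prev_char = "G"
            n += 2
        else:
            b = bases[base_draws[i % length]]
            if prev_char == "C" and b == "G":
                b = "A"
            chars.append(b)
            prev_char = b
            n += 1
        i += 1
    return "".join(chars)[:length]


def simulate_genome(cfg: SimulationConfig, out_dir: str | Path | None = None) -> SimulatedGenome:
    """Deterministic toy genome with labelled islands and promoters.

    Every third island's start doubles as an annotated TSS (alternating
    strand) so promoter-anchored profiles are testable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    layout = _island_layout(cfg)
    pieces: list[str] = []
    cursor = 0
    prev = "A"
    for start, end in layout:
        pieces.append(_random_sequence(start - cursor, cfg.open_sea_cpg_density, rng, prev))
        prev = pieces[-1][-1] if pieces[-1] else prev
        pieces.append(_random_sequence(end - start, cfg.island_cpg_density, rng, prev))
        prev = pieces[-1][-1]
        cursor = end
    pieces.append(_random_sequence(cfg.genome_length - cursor, cfg.open_sea_cpg_density, rng, prev))
    seq = "".join(pieces)[: cfg.genome_length]

    # realistic island composition: most islands unmethylated in every
    # cell type, a few methylated in every cell type (imprinted/gene-
    # body-like), and a rotating minority methylated in exactly one
    # owner cell type (the deconvolution's discriminative windows)
    n_ct = len(cfg.cell_types)
    cycle = list(cfg.cell_types) + ["methylated"] + ["shared"] * max(1, n_ct + 1)
    islands = pd.DataFrame(
        [
            {"chrom": CHROM, "start": s, "end": e, "name": f"island{i}",
             "owner": cycle[i % len(cycle)]}
            for i, (s, e) in enumerate(layout)
        ]
    )
    promoters = pd.DataFrame(
        [
            {"chrom": CHROM, "start": max(0, s - 500), "end": s + 500,
             "name": f"promoter{i}", "strand": "+" if (i // 3) % 2 == 0 else "-"}
            for i, (s, e) in enumerate(layout)
            if i % 3 == 0
        ]
    )
    genome = SimulatedGenome(
        sequence=seq, islands=islands, promoters=promoters,
        cpg_positions=scan_cpg_positions(seq),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "genome.fa", {CHROM: seq})
        _write_bed(out / "cgi.bed", islands)
        _write_bed(out / "promoters.bed", promoters, strand=True)
    return genome


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_bed(path: str | Path, df: pd.DataFrame, strand: bool = False) -> None:
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fields = [row["chrom"], str(row["start"]), str(row["end"]), row["name"]]
            if strand:
                fields += ["0", row["strand"]]
            fh.write("\t".join(fields) + "\n")


def simulate_methylomes(
    cfg: SimulationConfig, genome: SimulatedGenome
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell-type per-CpG methylation probabilities plus the prior.

    The prior is the average of the blood-cell methylomes, mirroring a
    buffy-coat reference.
    """
    pos = genome.cpg_positions
    meth = pd.DataFrame(
        np.full((pos.size, len(cfg.cell_types)), cfg.meth_open_sea),
        index=pos, columns=list(cfg.cell_types),
    )
    for _, isl in genome.islands.iterrows():
        in_island = (pos >= isl["start"]) & (pos < isl["end"])
        if isl["owner"] == "methylated":
            meth.loc[in_island, :] = cfg.meth_island_owner
        else:
            meth.loc[in_island, :] = cfg.meth_island_background
            if isl["owner"] in cfg.cell_types:
                meth.loc[in_island, isl["owner"]] = cfg.meth_island_owner
    blood = [ct for ct in BLOOD_CELL_TYPES if ct in cfg.cell_types] or list(cfg.cell_types)
    prior = meth[blood].mean(axis=1)
    prior.name = "prior"
    return meth, prior


def simulate_sample_mixture(
    methylomes: pd.DataFrame, weights: dict[str, float] | np.ndarray
) -> pd.Series:
    """Per-CpG methylation probability of a weighted cell-type mixture."""
    if isinstance(weights, dict):
        w = np.array([weights.get(ct, 0.0) for ct in methylomes.columns])
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != methylomes.shape[1]:
            raise UsageError("weight vector length must match the number of cell types")
    if abs(w.sum() - 1.0) > 1e-8:
        raise UsageError("mixture weights must sum to 1")
    out = pd.Series(methylomes.to_numpy() @ w, index=methylomes.index, name="methylation")
    return out


def write_prior_bedgraph(path: str | Path, prior: pd.Series, chrom: str = CHROM) -> None:
    with open(path, "w") as fh:
        for pos, k in prior.items():
            fh.write(f"{chrom}\t{pos}\t{pos + 2}\t{k:.6g}\n")


# ---------------------------------------------------------------------------
# fragment simulation


def make_read_pair(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    start: int,
    end: int,
    sequence: str,
    read_length: int = 60,
    mapq: int = 60,
    proper_pair: bool = True,
    duplicate: bool = False,
    baseq: int = 40,
) -> list[pysam.AlignedSegment]:
    """A synthetic proper pair spanning [start, end) on ``chrom``."""
    length = end - start
    rl = min(read_length, length)
    tid = header.references.index(chrom)
    reads = []
    for is_r2 in (False, True):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.reference_id = tid
        a.mapping_quality = mapq
        a.is_paired = True
        a.is_proper_pair = proper_pair
        a.is_duplicate = duplicate
        if not is_r2:
            a.reference_start = start
            a.query_sequence = sequence[start : start + rl]
            a.is_read1 = True
            a.is_reverse = False
            a.mate_is_reverse = True
            a.next_reference_start = end - rl
            a.template_length = length
        else:
            a.reference_start = end - rl
            a.query_sequence = sequence[end - rl : end]
            a.is_read2 = True
            a.is_reverse = True
            a.mate_is_reverse = False
            a.next_reference_start = start
            a.template_length = -length
        a.next_reference_id = tid
        a.cigartuples = [(0, rl)]
        a.query_qualities = pysam.qualitystring_to_array(chr(baseq + 33) * rl)
        reads.append(a)
    return reads


def write_bam(path: str | Path, header_dict: dict, reads: list[pysam.AlignedSegment]) -> None:
    """Write reads coordinate-sorted (stable) and index the result.

    Sorting happens in memory before writing, so the BAM bytes are a
    deterministic function of the read set (no external sort step).
    """
    reads = sorted(reads, key=lambda r: (r.reference_id, r.reference_start, r.query_name,
                                         r.is_read2))
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header_dict) as bam:
        for r in reads:
            bam.write(r)
    pysam.index(path)


def simulate_fragments(
    cfg: SimulationConfig,
    genome: SimulatedGenome,
    sample_methylome: pd.Series,
    out_bam: str | Path,
    out_truth: str | Path,
    decoys: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Simulate cfDNA fragments into a sorted+indexed BAM and truth TSV.

    Each fragment nucleates at a seed CpG (sampling weighted by the
    state-dependent coverage multiplier), draws the seed's true state
    from the sample methylome, then draws fragment length and the seed's
    offset-from-center from the state-conditional distributions. Other
    CpGs covered by the fragment draw their states independently from
    the methylome. Optional ``decoys`` inject known filter violations
    (keys: short, long, low_mapq, duplicate, improper, pileup).
    """
    if cfg.n_fragments < 1:
        raise UsageError("n_fragments must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    seq = genome.sequence
    glen = genome.length
    pos = genome.cpg_positions
    p_meth = sample_methylome.reindex(pos).to_numpy(dtype=float)

    # nucleation weight: state-dependent coverage multiplier times the
    # inverse local CpG density, so fragment placement is ~uniform per bp
    # (as in real cfDNA) rather than proportional to CpG density
    gaps = np.empty(pos.size)
    gaps[1:-1] = (pos[2:] - pos[:-2]) / 2.0
    gaps[0] = pos[1] - pos[0] if pos.size > 1 else 1.0
    gaps[-1] = pos[-1] - pos[-2] if pos.size > 1 else 1.0
    gaps = np.clip(gaps, 1.0, 5000.0)
    seed_weights = gaps * (
        p_meth * cfg.coverage_mult_methylated + (1.0 - p_meth) * cfg.coverage_mult_unmethylated
    )
    seed_weights /= seed_weights.sum()
    header_dict = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": CHROM, "LN": glen}],
    }
    header = pysam.AlignmentHeader.from_dict(header_dict)

    seed_idx = rng.choice(pos.size, size=cfg.n_fragments, p=seed_weights)
    seed_state = rng.random(cfg.n_fragments) < p_meth[seed_idx]
    reads: list[pysam.AlignedSegment] = []
    truth_rows = []
    for i in range(cfg.n_fragments):
        j = int(seed_idx[i])
        methylated = bool(seed_state[i])
        mu, sd = cfg.frag_len_methylated if methylated else cfg.frag_len_unmethylated
        length = int(np.clip(round(rng.normal(mu, sd * cfg.noise_scale)), 30, 500))
        a, b = cfg.center_beta_methylated if methylated else cfg.center_beta_unmethylated
        frac = rng.beta(a, b)  # |distance-to-center| as a fraction of L/2
        side = 1 if rng.random() < 0.5 else -1
        center = pos[j] - side * frac * length / 2.0
        start = int(round(center - length / 2.0))
        start = int(np.clip(start, 0, max(0, glen - length)))
        end = start + length
        lo, hi = np.searchsorted(pos, [start, end])
        # methylation is locally coherent and phased with nucleosome
        # position: a CpG keeps the seed's state with a probability that
        # grows with positional agreement (methylated CpGs sit far from
        # the center, unmethylated ones near it); discordant CpGs fall
        # back to the site's marginal methylation probability
        u = np.abs(pos[lo:hi] - (start + end) / 2.0) / (length / 2.0)
        agreement = u if methylated else 1.0 - u
        conc = np.clip(cfg.concordance_base + cfg.concordance_slope * agreement, 0.0, 1.0)
        # co-methylation does not cross methylation-domain boundaries:
        # only CpGs whose marginal resembles the seed's copy its state
        same_domain = np.abs(p_meth[lo:hi] - p_meth[j]) < 0.3
        coherent = (rng.random(hi - lo) < conc) & same_domain
        states = np.where(coherent, methylated, rng.random(hi - lo) < p_meth[lo:hi])
        if lo <= j < hi:
            states[j - lo] = methylated
        name = f"frag{i:07d}"
        reads.extend(
            make_read_pair(header, name, CHROM, start, end, seq, cfg.read_length)
        )
        truth_rows.append(
            {"name": name, "chrom": CHROM, "start": start, "end": end,
             "states": "".join("M" if s else "U" for s in states)}
        )

    for read in _decoy_reads(decoys or {}, header, seq, glen, rng, cfg.read_length):
        reads.append(read)
    write_bam(out_bam, header_dict, reads)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_truth, sep="\t", index=False)
    return truth


def _decoy_reads(decoys: dict[str, int], header, seq: str, glen: int,
                 rng: np.random.Generator, read_length: int):
    """Fragments violating exactly one filter each, at known counts."""
    mid = glen // 2
    out: list[pysam.AlignedSegment] = []
    counter = 0
    for kind, count in decoys.items():
        for _ in range(count):
            name = f"decoy_{kind}_{counter}"
            counter += 1
            if kind == "short":
                out += make_read_pair(header, name, CHROM, mid, mid + 20, seq, read_length)
            elif kind == "long":
                out += make_read_pair(header, name, CHROM, mid, mid + 520, seq, read_length)
            elif kind == "low_mapq":
                out += make_read_pair(header, name, CHROM, mid, mid + 160, seq,
                                      read_length, mapq=10)
            elif kind == "duplicate":
                out += make_read_pair(header, name, CHROM, mid, mid + 160, seq,
                                      read_length, duplicate=True)
            elif kind == "improper":
                out += make_read_pair(header, name, CHROM, mid, mid + 160, seq,
                                      read_length, proper_pair=False)
            elif kind == "pileup":
                out += make_read_pair(header, name, CHROM, 100, 260, seq, read_length)
            else:
                raise UsageError(f"unknown decoy kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# direct sampling from a known HMM (parameter-recovery harness)


def fragments_from_hmm(
    model: FragmentMethylationHMM,
    n_fragments: int,
    seed: int,
    n_cpgs: tuple[int, int] = (7, 12),
    offset_pool: tuple[int, ...] = (5, 15, 40, 60, 90, 130, 200),
    distance_pool: tuple[int, ...] = (5, 15, 35, 75, 150, 350, 700),
) -> tuple[list[Fragment], list[np.ndarray]]:
    """Sample synthetic fragments directly from an NH-HMM's parameters.

    Offsets and inter-CpG distances are drawn uniformly from pools that
    cover every model bin; observations carry z-scored features drawn
    from the state's emission mixtures. Returns the fragments and the
    true state path of each (for parameter-recovery checks).
    """
    rng = np.random.default_rng(seed)
    bins = model.bins_
    frags: list[Fragment] = []
    paths: list[np.ndarray] = []
    for i in range(n_fragments):
        n = int(rng.integers(n_cpgs[0], n_cpgs[1] + 1))
        offset = int(rng.choice(offset_pool))
        dists = rng.choice(distance_pool, size=n - 1)
        states = np.zeros(n, dtype=int)
        states[0] = rng.choice(2, p=model.startprob_[bins.offset_bin(offset)])
        for t in range(1, n):
            row = model.transmat_[bins.distance_bin(dists[t - 1]), states[t - 1]]
            states[t] = rng.choice(2, p=row)
        comp = rng.random((n, 3)) < model.emission_weights_[states]
        mean = np.take_along_axis(
            model.emission_means_[states], comp[..., None].astype(int), axis=2
        )[..., 0]
        sdev = np.sqrt(
            np.take_along_axis(
                model.emission_vars_[states], comp[..., None].astype(int), axis=2
            )[..., 0]
        )
        Z = rng.normal(mean, sdev)
        positions = offset + np.concatenate([[0], np.cumsum(dists)]).astype(int)
        frag = Fragment(chrom="sim", start=0, end=int(positions[-1] + 50), name=f"sim{i}")
        for t in range(n):
            frag.observations.append(
                CpGObservation(
                    ref_position=int(positions[t]),
                    offset=int(positions[t]),
                    distance_to_prev=None if t == 0 else int(dists[t - 1]),
                    fragment_length=0.0, normalized_coverage=0.0, distance_to_center=0.0,
                    z=Z[t],
                )
            )
        frags.append(frag)
        paths.append(states)
    return frags, paths
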