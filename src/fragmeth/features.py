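"""Fragment extraction and fragmentation-feature computation.

Reads coordinate-sorted paired-end cfDNA alignments, applies the quality
filters (proper pair, MAPQ, duplicates, fragment length 30-500 bp,
blacklist and 250x pile-up exclusion), locates reference CpG sites on
each fragment and computes the three fragmentation features per CpG:

* fragment length (bp),
* normalized coverage at the CpG position (fragments per million
  high-quality fragments),
* absolute distance of the CpG to the fragment center (bp).

Features are z-scored per sample (per BAM) before entering the HMM; the
coverage z-score is clipped at ``cov_outlier`` standard deviations.

Coordinates are 0-based half-open throughout; a CpG site is identified
by the forward-strand position of its C, and fragments on either strand
report the same site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .errors import DataFormatError, UsageError

logger = logging.getLogger(__name__)

#: order of the feature triple everywhere in the package
FEATURE_NAMES = ("fragment_length", "normalized_coverage", "distance_to_center")

#: chromosome names never treated as autosomes
_NON_AUTOSOMES = {"chrx", "chry", "chrm", "chrmt", "x", "y", "m", "mt"}

#: floor applied to per-feature standard deviations (raw scale)
SD_FLOOR = 1e-6


@dataclass
class CpGObservation:
    """One CpG site observed on one fragment."""

    ref_position: int
    offset: int
    distance_to_prev: int | None
    fragment_length: float
    normalized_coverage: float
    distance_to_center: float
    z: np.ndarray | None = None  # z-scored (length, coverage, dist-to-center)

    @property
    def raw(self) -> np.ndarray:
        return np.array(
            [self.fragment_length, self.normalized_coverage, self.distance_to_center],
            dtype=float,
        )


@dataclass
class Fragment:
    """One sequenced cfDNA molecule (outer template coordinates)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    sample_id: str = ""
    observations: list[CpGObservation] = field(default_factory=list)
    truth_states: list[str | None] | None = None  # 'U' / 'M' / None per CpG

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_cpgs(self) -> int:
        return len(self.observations)


@dataclass
class SampleFeatureStats:
    """Per-sample moments used for z-scoring, plus the library size."""

    total_high_quality_fragments: int
    mean: np.ndarray
    sd: np.ndarray


@dataclass
class FilterConfig:
    """Fragment quality filters (defaults follow the method's settings)."""

    min_len: int = 30
    max_len: int = 500
    max_region_coverage: int = 250
    min_mapq: int = 30
    min_baseq: int = 5
    require_proper_pair: bool = True
    require_unique: bool = True
    drop_duplicates: bool = True
    blacklist: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    autosomes_only: bool = True
    cov_outlier: float = 3.0

    def __post_init__(self) -> None:
        if self.min_len >= self.max_len:
            raise UsageError("min_len must be < max_len")
        if min(self.min_len, self.min_mapq, self.min_baseq, self.max_region_coverage) < 0:
            raise UsageError("filter thresholds must be non-negative")


class GenomeCpGIndex:
    """Sorted forward-strand CpG positions per chromosome."""

    def __init__(self, positions: dict[str, np.ndarray], chrom_lengths: dict[str, int]):
        self.positions = {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()}
        self.chrom_lengths = dict(chrom_lengths)
        for chrom, pos in self.positions.items():
            if pos.size and np.any(np.diff(pos) <= 0):
                raise DataFormatError(f"CpG positions not strictly increasing on {chrom}")

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """CpG positions with start <= p < end (half-open)."""
        pos = self.positions.get(chrom)
        if pos is None:
            return np.empty(0, dtype=np.int64)
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi]

    def __contains__(self, site: tuple[str, int]) -> bool:
        chrom, p = site
        pos = self.positions.get(chrom)
        if pos is None:
            return False
        i = np.searchsorted(pos, p)
        return i < pos.size and pos[i] == p


def scan_cpg_positions(sequence: str) -> np.ndarray:
    """Positions of every CG dinucleotide in ``sequence`` (case-insensitive)."""
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")
    if seq.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G")).astype(np.int64)


def build_cpg_index(genome_fasta: str) -> GenomeCpGIndex:
    """Index every forward-strand CpG site of a FASTA genome.

    Sites whose C or G is an N (or any non-ACGT letter) are excluded by
    construction of the CG scan.
    """
    fa = Fasta(genome_fasta, as_raw=True, sequence_always_upper=True)
    positions: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for name in fa.keys():
        if name in positions:
            raise DataFormatError(f"duplicate chromosome name {name!r}")
        seq = str(fa[name][:])
        positions[name] = scan_cpg_positions(seq)
        lengths[name] = len(seq)
    if not positions:
        raise DataFormatError(f"no sequences found in {genome_fasta}")
    return GenomeCpGIndex(positions, lengths)


def load_blacklist(bed_path: str) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file of excluded intervals into the FilterConfig format."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataFormatError(f"malformed BED line: {line!r}")
            intervals.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    for ivs in intervals.values():
        ivs.sort()
    return intervals


def is_autosome(chrom: str) -> bool:
    return chrom.lower() not in _NON_AUTOSOMES


def _pair_passes(r1: pysam.AlignedSegment, r2: pysam.AlignedSegment, cfg: FilterConfig) -> bool:
    for r in (r1, r2):
        if cfg.require_proper_pair and not r.is_proper_pair:
            return False
        if cfg.drop_duplicates and r.is_duplicate:
            return False
        if r.mapping_quality < cfg.min_mapq:
            return False
        if r.is_qcfail:
            return False
    return True


def _read_qual_map(read: pysam.AlignedSegment):
    """(start, end, per-reference-position base qualities) of one read.

    Qualities are projected onto reference coordinates; deletions and
    other unaligned reference positions get -1 (treated as uncovered).
    """
    if read.query_qualities is None:
        return (read.reference_start, read.reference_end or read.reference_start, None)
    q = np.asarray(read.query_qualities, dtype=np.int16)
    start = read.reference_start
    end = read.reference_end or start
    cigar = read.cigartuples or []
    if len(cigar) == 1 and cigar[0][0] == 0:  # ungapped fast path
        return (start, end, q)
    proj = np.full(end - start, -1, dtype=np.int16)
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        proj[rpos - start] = q[qpos]
    return (start, end, proj)


def extract_fragments(
    bam_path: str,
    index: GenomeCpGIndex,
    cfg: FilterConfig | None = None,
    sample_id: str = "",
) -> tuple[list[Fragment], SampleFeatureStats]:
    """Extract filtered fragments with raw fragmentation features from a BAM.

    Two passes over the read pairs: the first collects high-quality
    fragments (pair flags, MAPQ, length, autosomes) and their genome
    coverage; the second drops fragments touching blacklisted or
    >``max_region_coverage``x positions, locates CpG sites and computes
    the raw feature triple. Fragments without CpGs are dropped.

    Returns the fragments and the sample statistics (library size plus
    feature means/SDs over all surviving observations).
    """
    cfg = cfg or FilterConfig()
    bam = pysam.AlignmentFile(bam_path, "rb")
    header_sort = (bam.header.to_dict().get("HD") or {}).get("SO")
    if header_sort != "coordinate":
        raise UsageError(f"{bam_path} is not coordinate-sorted (SO={header_sort!r})")
    if not bam.has_index():
        raise UsageError(f"{bam_path} has no index (.bai); run samtools index")

    pending: dict[str, pysam.AlignedSegment] = {}
    raw_fragments: list[tuple[str, int, int, str, tuple]] = []
    saw_paired = False
    for read in bam.fetch():
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            if cfg.require_unique and (read.is_secondary or read.is_supplementary):
                pending.pop(read.query_name, None)
            continue
        if not read.is_paired:
            raise UsageError("single-end reads found; paired-end data required")
        saw_paired = True
        mate = pending.pop(read.query_name, None)
        if mate is None:
            pending[read.query_name] = read
            continue
        if mate.reference_name != read.reference_name:
            continue
        if not _pair_passes(mate, read, cfg):
            continue
        chrom = read.reference_name
        if cfg.autosomes_only and not is_autosome(chrom):
            continue
        start = min(mate.reference_start, read.reference_start)
        end = max(mate.reference_end or 0, read.reference_end or 0)
        length = end - start
        if length < cfg.min_len or length > cfg.max_len:
            continue
        quals = tuple(_read_qual_map(r) for r in (mate, read))
        raw_fragments.append((chrom, start, end, read.query_name, quals))
    if not saw_paired and not raw_fragments:
        raise UsageError(f"no paired reads in {bam_path}")

    total_hq = len(raw_fragments)
    # per-position coverage of high-quality fragments (diff-array trick)
    coverage: dict[str, np.ndarray] = {}
    for chrom, start, end, _, _ in raw_fragments:
        clen = index.chrom_lengths.get(chrom)
        if clen is None:
            continue
        cov = coverage.setdefault(chrom, np.zeros(clen + 1, dtype=np.int32))
        cov[start] += 1
        cov[min(end, clen)] -= 1
    for chrom in coverage:
        coverage[chrom] = np.cumsum(coverage[chrom])[:-1]

    # positions excluded by the pile-up cap or the blacklist
    excluded: dict[str, np.ndarray] = {}
    for chrom, cov in coverage.items():
        mask = cov > cfg.max_region_coverage
        for bstart, bend in cfg.blacklist.get(chrom, []):
            mask[bstart : min(bend, mask.size)] = True
        excluded[chrom] = mask

    fragments: list[Fragment] = []
    for chrom, start, end, name, quals in raw_fragments:
        if chrom not in index.chrom_lengths:
            continue
        mask = excluded.get(chrom)
        if mask is not None and mask[start:end].any():
            continue
        sites = index.sites_in(chrom, start, end)
        if sites.size == 0:
            continue
        frag = Fragment(chrom=chrom, start=start, end=end, name=name, sample_id=sample_id)
        center = (start + end) / 2.0
        cov = coverage[chrom]
        prev: int | None = None
        for p in sites:
            if not _site_baseq_ok(int(p), quals, cfg):
                continue
            frag.observations.append(
                CpGObservation(
                    ref_position=int(p),
                    offset=int(p - start),
                    distance_to_prev=None if prev is None else int(p - prev),
                    fragment_length=float(end - start),
                    normalized_coverage=float(cov[p]) / total_hq * 1e6,
                    distance_to_center=abs(float(p) - center),
                )
            )
            prev = int(p)
        if frag.observations:
            fragments.append(frag)
    bam.close()

    stats = compute_feature_stats(fragments, total_hq)
    return fragments, stats


def _site_baseq_ok(pos: int, quals: tuple, cfg: FilterConfig) -> bool:
    """Drop a CpG only when the fragment's own reads cover it solely at
    base quality <= min_baseq.

    Positions in the unsequenced template middle (covered by neither
    mate) are kept: the fragment still spans them.
    """
    if cfg.min_baseq <= 0:
        return True
    seen = False
    for start, end, q in quals:
        if not (start <= pos < end):
            continue
        if q is None:
            return True  # no quality string recorded: accept
        val = q[pos - start]
        if val < 0:
            continue  # deletion at this position: not a sequenced base
        seen = True
        if val > cfg.min_baseq:
            return True
    return not seen


def compute_feature_stats(
    fragments: Iterable[Fragment], total_high_quality_fragments: int
) -> SampleFeatureStats:
    """Mean/SD of the raw feature triple over all observations."""
    rows = [obs.raw for frag in fragments for obs in frag.observations]
    if rows:
        arr = np.asarray(rows)
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0)
    else:
        mean = np.zeros(3)
        sd = np.ones(3)
    low = sd < SD_FLOOR
    if low.any():
        logger.warning(
            "feature(s) %s have ~zero variance; SD floored at %g",
            [FEATURE_NAMES[i] for i in np.flatnonzero(low)],
            SD_FLOOR,
        )
        sd = np.where(low, SD_FLOOR, sd)
    return SampleFeatureStats(
        total_high_quality_fragments=total_high_quality_fragments, mean=mean, sd=sd
    )


def zscore_features(
    fragments: Sequence[Fragment],
    stats: SampleFeatureStats,
    cov_outlier: float = 3.0,
) -> Sequence[Fragment]:
    """Populate ``obs.z`` in place: (x - mean)/sd, coverage z clipped.

    Raw values are retained on the observation. Returns the same list.
    """
    sd = np.maximum(stats.sd, SD_FLOOR)
    for frag in fragments:
        for obs in frag.observations:
            z = (obs.raw - stats.mean) / sd
            z[1] = float(np.clip(z[1], -cov_outlier, cov_outlier))
            obs.z = z
    return fragments


def attach_truth(fragments: Sequence[Fragment], truth_file: str) -> Sequence[Fragment]:
    """Attach fragment-level ground-truth methylation states from a TSV.

    Expected columns: [name] chrom, start, end, states — where ``states``
    is a string over {U, M, .} with one character per CpG observation in
    positional order ('.' = missing). Matching is by read name when a
    name column is present, otherwise by (chrom, start, end).
    """
    df = pd.read_csv(truth_file, sep="\t", dtype=str, comment="#")
    cols = {c.lower(): c for c in df.columns}
    required = {"chrom", "start", "end", "states"}
    if not required.issubset(cols):
        raise DataFormatError(
            f"truth file must have columns {sorted(required)}; got {list(df.columns)}"
        )
    by_name: dict[str, str] = {}
    by_coord: dict[tuple[str, int, int], str] = {}
    for _, row in df.iterrows():
        key = (row[cols["chrom"]], int(row[cols["start"]]), int(row[cols["end"]]))
        by_coord[key] = row[cols["states"]]
        if "name" in cols and isinstance(row[cols["name"]], str):
            by_name[row[cols["name"]]] = row[cols["states"]]

    matched: set[tuple[str, int, int]] = set()
    for frag in fragments:
        states = by_name.get(frag.name)
        if states is None:
            states = by_coord.get((frag.chrom, frag.start, frag.end))
        if states is None:
            frag.truth_states = [None] * frag.n_cpgs
            continue
        matched.add((frag.chrom, frag.start, frag.end))
        if len(states) != frag.n_cpgs:
            logger.warning(
                "truth string length %d != %d CpGs for %s:%d-%d; states set to missing",
                len(states), frag.n_cpgs, frag.chrom, frag.start, frag.end,
            )
            frag.truth_states = [None] * frag.n_cpgs
            continue
        frag.truth_states = [c if c in ("U", "M") else None for c in states]
    unmatched = len(by_coord) - len(matched)
    if unmatched:
        logger.warning("%d truth records matched no fragment; ignored", unmatched)
    return fragments


def fragments_to_table(fragments: Iterable[Fragment]) -> pd.DataFrame:
    """Flatten fragments into an inspectable per-fragment table."""
    rows = []
    for f in fragments:
        rows.append(
            {
                "name": f.name,
                "chrom": f.chrom,
                "start": f.start,
                "end": f.end,
                "length": f.length,
                "cpg_positions": ",".join(str(o.ref_position) for o in f.observations),
                "fragment_length": f.observations[0].fragment_length if f.observations else np.nan,
                "normalized_coverage": ",".join(
                    f"{o.normalized_coverage:.6g}" for o in f.observations
                ),
                "distance_to_center": ",".join(
                    f"{o.distance_to_center:.6g}" for o in f.observations
                ),
                "z": ";".join(
                    ",".join(f"{v:.6g}" for v in o.z) for o in f.observations
                ) if all(o.z is not None for o in f.observations) else "",
                "truth": "".join(
                    (s if s in ("U", "M") else ".") for s in (f.truth_states or [])
                ),
            }
        )
    return pd.DataFrame(rows)
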