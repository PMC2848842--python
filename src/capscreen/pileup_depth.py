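"""Per-base pileups over capture targets and coverage/depth summaries.

Depth is the number of aligned reads covering a single reference base;
coverage is the percentage of target bases with depth > 0. Multi-hit reads
(up to ``max_hits`` equally good placements) contribute fully at every kept
placement — the deliberate choice of this pipeline, which retains ambiguous
reads so variants in near-duplicated sequence are not silently lost, and
flags them later in the homology check instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import percent, round_half_up
from .io_formats import AlignedRead, TargetRegion

DEFAULT_MAX_HITS = 5


@dataclass
class AlleleTally:
    depth: int = 0
    qual_sum: float = 0.0
    multihit: int = 0

    @property
    def mean_quality(self) -> float:
        if self.depth == 0:
            raise ValueError("mean quality undefined at zero depth")
        return self.qual_sum / self.depth


@dataclass
class PileupColumn:
    """Allele tallies at one reference base.

    Allele keys are plain bases ("A".."T"), insertion strings ("INS:ACG",
    anchored at the base before the insertion) or deletion lengths ("DEL:2",
    recorded at every deleted base).
    """

    chrom: str
    pos: int
    ref_base: str
    alleles: dict[str, AlleleTally] = field(default_factory=dict)

    @property
    def total_depth(self) -> int:
        return sum(t.depth for t in self.alleles.values())

    @property
    def multihit_depth(self) -> int:
        return sum(t.multihit for t in self.alleles.values())

    def add(self, allele: str, quality: int, multihit: bool) -> None:
        tally = self.alleles.setdefault(allele, AlleleTally())
        tally.depth += 1
        tally.qual_sum += quality
        tally.multihit += int(multihit)


@dataclass
class SampleSummary:
    """Per-sample sequencing summary (read accounting plus depth over targets)."""

    total_reads: int
    aligned_reads: int
    on_target_reads: int
    pct_aligned: float
    pct_on_target: float
    coverage_pct: float
    mean_depth: float
    median_depth: float

    def __post_init__(self) -> None:
        if not self.on_target_reads <= self.aligned_reads <= self.total_reads:
            raise ValueError("read counts must satisfy on_target <= aligned <= total")


@dataclass
class DepthProfile:
    """Depth along the concatenated target bases (uncovered bases are 0)."""

    vectors: dict[tuple[str, int, int], np.ndarray]  # (chrom, start, end) -> depths

    @property
    def vector(self) -> np.ndarray:
        keys = sorted(self.vectors)
        return np.concatenate([self.vectors[k] for k in keys]) if keys else np.array([])

    @property
    def covered(self) -> np.ndarray:
        v = self.vector
        return v[v > 0]

    @property
    def covered_mean(self) -> float:
        c = self.covered
        return float(c.mean()) if c.size else 0.0

    @property
    def covered_median(self) -> float:
        c = self.covered
        return float(np.median(c)) if c.size else 0.0

    @property
    def overall_mean(self) -> float:
        v = self.vector
        return float(v.mean()) if v.size else 0.0


Pileup = dict[tuple[str, int], PileupColumn]


def build_pileup(
    reads: Iterable[AlignedRead],
    regions: Sequence[TargetRegion],
    reference: Mapping[str, str],
    max_hits: int = DEFAULT_MAX_HITS,
) -> Pileup:
    """Tally alleles per target base from aligned placements.

    Placements with more than ``max_hits`` equally good locations are dropped
    entirely; every placement of a kept multi-hit read contributes where it
    lands. Reads with a deletion contribute a "DEL:<len>" allele at each
    deleted base; reads with an insertion contribute an "INS:<seq>" allele at
    the anchor base (the base preceding the insertion) in place of that base.
    """
    in_target: dict[str, np.ndarray] = {}
    for r in regions:
        mask = in_target.setdefault(r.chrom, np.zeros(len(reference[r.chrom]) + 2, bool))
        mask[r.start : r.end + 1] = True

    columns: Pileup = {}

    def col(chrom: str, pos: int) -> PileupColumn:
        key = (chrom, pos)
        c = columns.get(key)
        if c is None:
            c = columns[key] = PileupColumn(chrom, pos, reference[chrom][pos - 1])
        return c

    for read in reads:
        if read.n_hits > max_hits:
            continue
        if read.chrom not in reference:
            raise ValueError(f"read {read.read_id} on unknown chromosome {read.chrom}")
        if read.ref_end > len(reference[read.chrom]):
            raise ValueError(f"read {read.read_id} extends beyond {read.chrom}")
        mask = in_target.get(read.chrom)
        if mask is None:
            continue
        multi = read.n_hits > 1
        g = read.gap
        if g is None:
            segments = [(read.pos, 0, len(read.bases))]
        elif g.kind == "DEL":
            segments = [
                (read.pos, 0, g.offset),
                (read.pos + g.offset + g.length, g.offset, len(read.bases) - g.offset),
            ]
            qual = read.quals[g.offset - 1]
            for dpos in range(read.pos + g.offset, read.pos + g.offset + g.length):
                if mask[dpos]:
                    col(read.chrom, dpos).add(f"DEL:{g.length}", qual, multi)
        else:  # insertion
            segments = [
                (read.pos, 0, g.offset),
                (read.pos + g.offset, g.offset + g.length, len(read.bases) - g.offset - g.length),
            ]
        for ref_start, read_start, n in segments:
            for i in range(n):
                pos = ref_start + i
                if not mask[pos]:
                    continue
                j = read_start + i
                if g is not None and g.kind == "INS" and j == g.offset - 1:
                    # anchor base observed as the inserted-allele event
                    ins = read.bases[g.offset : g.offset + g.length]
                    qual = int(
                        round(sum(read.quals[g.offset : g.offset + g.length]) / g.length)
                    )
                    col(read.chrom, pos).add(f"INS:{ins}", qual, multi)
                else:
                    col(read.chrom, pos).add(read.bases[j], read.quals[j], multi)
    return columns


def depth_profile(pileup: Pileup, regions: Sequence[TargetRegion]) -> DepthProfile:
    """Per-base depth vectors over the regions, zeros at uncovered bases."""
    vectors = {}
    for r in regions:
        v = np.zeros(r.length, dtype=np.int64)
        for pos in range(r.start, r.end + 1):
            c = pileup.get((r.chrom, pos))
            if c is not None:
                v[pos - r.start] = c.total_depth
        vectors[(r.chrom, r.start, r.end)] = v
    return DepthProfile(vectors)


def coverage_summary(
    pileup: Pileup,
    regions: Sequence[TargetRegion],
    total_reads: int,
    aligned_reads: int,
    on_target_reads: int,
) -> SampleSummary:
    """Table-style per-sample summary.

    Percentages are rounded half-up to 2 decimals; mean and median depth are
    computed over covered bases only (bases with depth > 0), matching the
    convention of reporting depth where there is data at all.
    """
    if not regions:
        raise ValueError("no target regions")
    profile = depth_profile(pileup, regions)
    v = profile.vector
    return SampleSummary(
        total_reads=total_reads,
        aligned_reads=aligned_reads,
        on_target_reads=on_target_reads,
        pct_aligned=percent(aligned_reads, total_reads) if total_reads else 0.0,
        pct_on_target=percent(on_target_reads, aligned_reads) if aligned_reads else 0.0,
        coverage_pct=percent(int((v > 0).sum()), v.size),
        mean_depth=profile.covered_mean,
        median_depth=profile.covered_median,
    )


def enrichment_fold(pct_on_target: float, pct_target_of_genome: float) -> float:
    """Capture enrichment: on-target % of aligned reads over the target's % of
    the genome. Scale-invariant in its two arguments."""
    if pct_on_target <= 0 or pct_target_of_genome <= 0:
        raise ValueError("enrichment requires positive percentages")
    return pct_on_target / pct_target_of_genome
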