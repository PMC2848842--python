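"""Allele-balance SNP/indel calling.

Candidate heterozygous variants are scored with two statistics built on the
same formula, score = 100 * X_V / X_R, where X_V and X_R are a property of
the variant and the reference allele respectively: read depth for the Depth
Score (DS) and mean base-call quality for the Quality Score (QS). Scores near
100 mean the two alleles are equally represented — the signature of a true
heterozygote. A bounded alternative, 200 * X_V / (X_V + X_R), is available by
configuration; the ratio form is the default because confirmed heterozygotes
in the study this reimplements carried DS values up to 185, which under the
ratio form corresponds to a plausible variant-read fraction (~0.65) while the
bounded form would imply a near-homozygous site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from ._util import round_half_up
from .io_formats import AlignedRead, TargetRegion
from .pileup_depth import DEFAULT_MAX_HITS, Pileup, PileupColumn

# Sentinel DS/QS for sites with no reference-allele evidence (homozygous).
HOMOZYGOUS_SENTINEL = 10_000.0

DEFAULT_MIN_VARIANT_READS = 2
DEFAULT_MIN_DS = 50.0
# The confirmed candidates of the original screen had depth >= 19; the global
# depth cutoff itself was not printed, so 10 is this package's default.
DEFAULT_MIN_GLOBAL_DEPTH = 10


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    kind: str  # SNP | INS | DEL
    global_depth: int
    x_v: int
    x_r: int
    q_v: float
    q_r: float
    ds: float
    qs: float
    zygosity: str
    sample: str = ""
    multihit_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.x_v < 1:
            raise ValueError("an emitted call needs at least one variant read")
        if self.global_depth < self.x_v + self.x_r:
            raise ValueError("global depth below the sum of allele depths")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def printed_ds(self) -> int:
        return int(round_half_up(self.ds))

    @property
    def printed_qs(self) -> int:
        return int(round_half_up(self.qs))


def allele_score(
    value_variant: float, value_reference: float, mode: str = "ratio"
) -> float:
    """Allele-balance score of a variant-allele property against the reference's.

    ``ratio`` (default): 100 * V / R; ``bounded``: 200 * V / (V + R). A site
    with no reference-allele evidence returns the homozygous sentinel.
    """
    if value_variant <= 0:
        raise ValueError("no variant-allele evidence (X_V <= 0)")
    if value_reference < 0:
        raise ValueError("negative reference value")
    if value_reference == 0:
        return HOMOZYGOUS_SENTINEL
    if mode == "ratio":
        return 100.0 * value_variant / value_reference
    if mode == "bounded":
        return 200.0 * value_variant / (value_variant + value_reference)
    raise ValueError(f"unknown score mode {mode!r}")


def _is_indel_allele(allele: str) -> bool:
    return allele.startswith(("INS:", "DEL:"))


def call_site(
    column: PileupColumn,
    min_variant_reads: int = DEFAULT_MIN_VARIANT_READS,
    score_mode: str = "ratio",
    sample: str = "",
) -> VariantCall | None:
    """Call the best-supported non-reference allele at one pileup column.

    The winning alt allele is the non-reference allele with the highest depth
    (ties broken by higher mean quality, then lexicographically). No call is
    made when every non-reference allele has fewer than ``min_variant_reads``
    supporting reads, or when the winner is an indel allele — gapped evidence
    is aggregated read-wise by :func:`detect_indels` instead, which anchors
    the event once rather than once per deleted base.
    """
    ref = column.ref_base
    candidates = [
        (a, t) for a, t in column.alleles.items() if a != ref and t.depth >= min_variant_reads
    ]
    if not candidates:
        return None
    candidates.sort(key=lambda at: (-at[1].depth, -at[1].mean_quality, at[0]))
    alt, tally = candidates[0]
    if _is_indel_allele(alt):
        return None
    ref_tally = column.alleles.get(ref)
    x_r = ref_tally.depth if ref_tally else 0
    q_r = ref_tally.mean_quality if ref_tally else 0.0
    ds = allele_score(tally.depth, x_r, score_mode)
    qs = allele_score(tally.mean_quality, q_r, score_mode)
    call = VariantCall(
        chrom=column.chrom,
        pos=column.pos,
        ref=ref,
        alt=alt,
        kind="SNP",
        global_depth=column.total_depth,
        x_v=tally.depth,
        x_r=x_r,
        q_v=tally.mean_quality,
        q_r=q_r,
        ds=ds,
        qs=qs,
        zygosity="het",
        sample=sample,
        multihit_frac=tally.multihit / tally.depth,
    )
    call.zygosity = classify_zygosity(call)
    return call


def call_variants(
    pileup: Pileup,
    min_variant_reads: int = DEFAULT_MIN_VARIANT_READS,
    score_mode: str = "ratio",
    sample: str = "",
) -> list[VariantCall]:
    """Apply :func:`call_site` across a pileup in coordinate order."""
    calls = []
    for key in sorted(pileup):
        call = call_site(pileup[key], min_variant_reads, score_mode, sample)
        if call is not None:
            calls.append(call)
    return calls


def classify_zygosity(
    call: VariantCall, mode: str = "absent_ref", hom_fraction: float = 0.85
) -> str:
    """``hom`` when the reference allele is absent (default), or — in
    ``fraction`` mode — when the variant-read fraction reaches ``hom_fraction``."""
    if mode == "absent_ref":
        return "hom" if call.x_r == 0 else "het"
    if mode == "fraction":
        return "hom" if call.x_v / (call.x_v + call.x_r) >= hom_fraction else "het"
    raise ValueError(f"unknown zygosity mode {mode!r}")


def primary_filter(
    calls: Iterable[VariantCall],
    min_global_depth: int = DEFAULT_MIN_GLOBAL_DEPTH,
    min_ds: float = DEFAULT_MIN_DS,
) -> list[VariantCall]:
    """The caller's integral first filter: a call survives only with
    global_depth >= min_global_depth AND ds >= min_ds (a DS of exactly 50
    survives the default threshold)."""
    if min_global_depth < 0 or min_ds < 0:
        raise ValueError("thresholds must be non-negative")
    return [c for c in calls if c.global_depth >= min_global_depth and c.ds >= min_ds]


def detect_indels(
    reads: Iterable[AlignedRead],
    regions: Sequence[TargetRegion],
    reference: Mapping[str, str],
    min_variant_reads: int = DEFAULT_MIN_VARIANT_READS,
    score_mode: str = "ratio",
    max_hits: int = DEFAULT_MAX_HITS,
    sample: str = "",
) -> list[VariantCall]:
    """Aggregate gapped reads into indel calls with the same DS/QS machinery.

    Reads sharing (chromosome, event position, kind, length, inserted bases)
    support one call; reads spanning the event without a gap there supply the
    reference-allele depth. Calls are reported VCF-style, anchored at the base
    before the event.
    """
    reads = list(reads)
    in_region = lambda chrom, pos: any((chrom, pos) in r for r in regions)

    support: dict[tuple, list[AlignedRead]] = {}
    for r in reads:
        if r.gap is None or r.n_hits > max_hits:
            continue
        if r.gap.kind == "DEL":
            event_start = r.pos + r.gap.offset  # first deleted base
            key = (r.chrom, event_start, "DEL", r.gap.length, "")
        else:
            event_start = r.pos + r.gap.offset  # ref base after the insertion point
            ins = r.bases[r.gap.offset : r.gap.offset + r.gap.length]
            key = (r.chrom, event_start, "INS", r.gap.length, ins)
        support.setdefault(key, []).append(r)

    by_chrom: dict[str, list[AlignedRead]] = {}
    for r in reads:
        if r.n_hits <= max_hits:
            by_chrom.setdefault(r.chrom, []).append(r)

    calls = []
    for key in sorted(support):
        chrom, event_start, kind, length, ins = key
        carriers = support[key]
        if len(carriers) < min_variant_reads:
            continue
        anchor = event_start - 1
        if not in_region(chrom, anchor) and not in_region(chrom, event_start):
            continue
        if anchor < 1:
            continue
        # reference-supporting reads: span the event locus without this gap
        span_end = event_start + (length - 1 if kind == "DEL" else 0)
        ref_reads = []
        for r in by_chrom.get(chrom, ()):
            if r.pos <= anchor and r.ref_end >= span_end + 1:
                if r.gap is not None and (r.chrom, r.pos + r.gap.offset, r.gap.kind, r.gap.length) == (
                    chrom,
                    event_start,
                    kind,
                    length,
                ):
                    continue
                if r.base_at(event_start) is not None or kind == "INS":
                    ref_reads.append(r)
        x_v, x_r = len(carriers), len(ref_reads)
        q_v = sum(r.quals[r.gap.offset - 1] for r in carriers) / x_v
        q_r = 0.0
        if x_r:
            quals = [b[1] for b in (r.base_at(anchor) for r in ref_reads) if b is not None]
            q_r = sum(quals) / len(quals) if quals else 0.0
        seq = reference[chrom]
        if kind == "DEL":
            ref_allele = seq[anchor - 1 : event_start + length - 1]
            alt_allele = seq[anchor - 1]
        else:
            ref_allele = seq[anchor - 1]
            alt_allele = seq[anchor - 1] + ins
        call = VariantCall(
            chrom=chrom,
            pos=anchor,
            ref=ref_allele,
            alt=alt_allele,
            kind=kind,
            global_depth=x_v + x_r,
            x_v=x_v,
            x_r=x_r,
            q_v=q_v,
            q_r=q_r,
            ds=allele_score(x_v, x_r, score_mode),
            qs=allele_score(q_v, q_r, score_mode) if q_v > 0 else HOMOZYGOUS_SENTINEL,
            zygosity="het",
            sample=sample,
            multihit_frac=sum(r.n_hits > 1 for r in carriers) / x_v,
        )
        call.zygosity = classify_zygosity(call)
        calls.append(call)
    return calls
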