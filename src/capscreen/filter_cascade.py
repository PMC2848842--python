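"""The family-screening filter cascade.

Per-sample calls are reduced to family candidates in fixed order: the
caller's primary depth/DS filter, restriction to the family's linkage
candidate chromosome, removal of homozygous calls (the causal variants are
expected to be rare heterozygotes), subtraction of variants seen in the
pooled controls, intersection across affected family members, removal of
already-described variants, consequence annotation against local gene
models, removal of purely intronic variants, and a homology check that
discards variants whose flanking sequence occurs more than once in the
genome. Variants are identified by (chrom, pos, ref, alt) throughout, so a
different allele at a known position still counts as undescribed.

A separate truncating-variant scan re-examines each individual's
post-control calls for stop-gains and essential-splice-site changes
regardless of family sharing, so that a putative truncating mutation missed
in one member cannot silently vanish in the intersection step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from ._util import revcomp
from .io_formats import FamilySpec, Transcript, VariantKey
from .variant_calling import (
    DEFAULT_MIN_DS,
    DEFAULT_MIN_GLOBAL_DEPTH,
    VariantCall,
    classify_zygosity,
    primary_filter,
)

log = logging.getLogger(__name__)

# consequence classes
NON_SYNONYMOUS_CODING = "NON_SYNONYMOUS_CODING"
SYNONYMOUS = "SYNONYMOUS"
STOP_GAINED = "STOP_GAINED"
ESSENTIAL_SPLICE_SITE = "ESSENTIAL_SPLICE_SITE"
UTR5 = "5UTR"
UTR3 = "3UTR"
INTRONIC = "INTRONIC"
NON_CODING_GENE = "NON_CODING_GENE"

TRUNCATING_CLASSES = frozenset({STOP_GAINED, ESSENTIAL_SPLICE_SITE})

DEFAULT_CONTROL_MIN_DS = 14.0
DEFAULT_HOMOLOGY_FLANK = 30
DEFAULT_HOMOLOGY_MAX_MISMATCH = 2
MULTIHIT_SUPPORT_LIMIT = 0.5
SPLICE_BASES = 2  # intronic bases at each exon boundary counted as essential


@dataclass(frozen=True)
class Consequence:
    variant: VariantKey
    transcript_id: str
    klass: str
    aa_change: str | None = None


@dataclass
class FilterTrace:
    """Surviving-variant counts after each cascade stage for one family."""

    initial_snps: dict[str, int]
    after_control: dict[str, int]
    shared_by_family: int
    undescribed: int
    consequences: int  # consequence records (one variant may carry several)
    exonic: int  # consequence records surviving the intronic drop
    pre_homology_variants: int
    candidates: int


@dataclass
class Candidate:
    """A final candidate variant with its per-member evidence."""

    key: VariantKey
    member_calls: dict[str, VariantCall]
    consequences: tuple[Consequence, ...]

    @property
    def member_ds(self) -> dict[str, float]:
        return {m: c.ds for m, c in self.member_calls.items()}


@dataclass
class CascadeResult:
    candidates: list[Candidate]
    trace: FilterTrace
    described: list[VariantKey]


@dataclass
class TruncatingEntry:
    sample: str
    call: VariantCall
    consequence: Consequence
    likely_false_positive: bool  # DS below the sample threshold


@dataclass(frozen=True)
class CascadeThresholds:
    min_global_depth: int = DEFAULT_MIN_GLOBAL_DEPTH
    min_ds: float = DEFAULT_MIN_DS
    control_min_ds: float = DEFAULT_CONTROL_MIN_DS
    homology_flank: int = DEFAULT_HOMOLOGY_FLANK
    homology_max_mismatch: int = DEFAULT_HOMOLOGY_MAX_MISMATCH


# ---------------------------------------------------------------------------
# elementary stages


def restrict_chromosome(
    calls: Iterable[VariantCall], family: FamilySpec
) -> list[VariantCall]:
    return [c for c in calls if c.chrom == family.candidate_chrom]


def subtract_controls(
    sample_calls: Iterable[VariantCall],
    control_calls: Iterable[VariantCall],
    control_min_ds: float = DEFAULT_CONTROL_MIN_DS,
) -> list[VariantCall]:
    """Remove sample calls whose allele was seen in the control pool.

    Control calls below ``control_min_ds`` are considered noise and do not
    count as control evidence (a control DS of exactly 14 does count).
    """
    control_keys = {c.key for c in control_calls if c.ds >= control_min_ds}
    return [c for c in sample_calls if c.key not in control_keys]


def intersect_family(
    member_call_sets: Mapping[str, Sequence[VariantCall]],
) -> dict[VariantKey, dict[str, VariantCall]]:
    """Variants present in every member, with per-member calls kept side by side."""
    if not member_call_sets:
        raise ValueError("family must have at least one member call set")
    members = list(member_call_sets)
    keyed = {m: {c.key: c for c in calls} for m, calls in member_call_sets.items()}
    shared_keys = set(keyed[members[0]])
    for m in members[1:]:
        shared_keys &= set(keyed[m])
    return {k: {m: keyed[m][k] for m in members} for k in sorted(shared_keys)}


def split_known(
    keys: Iterable[VariantKey], known: set[VariantKey]
) -> tuple[list[VariantKey], list[VariantKey]]:
    """(described, undescribed) partition by exact (chrom,pos,ref,alt) key."""
    described, undescribed = [], []
    for k in sorted(set(keys)):
        (described if k in known else undescribed).append(k)
    return described, undescribed


# ---------------------------------------------------------------------------
# consequence annotation


def _cds_sequence(tx: Transcript, reference: Mapping[str, str]) -> str:
    seq = "".join(reference[tx.chrom][s - 1 : e] for s, e in sorted(tx.cds))
    return revcomp(seq) if tx.strand == "-" else seq


def _cds_offset(tx: Transcript, pos: int) -> int:
    """0-based coding offset of a genomic position, strand-aware."""
    off = 0
    for s, e in sorted(tx.cds):
        if s <= pos <= e:
            off += pos - s
            break
        off += e - s + 1
    total = sum(e - s + 1 for s, e in tx.cds)
    return off if tx.strand == "+" else total - 1 - off


def _classify_in_transcript(
    call: VariantCall, tx: Transcript, reference: Mapping[str, str]
) -> Consequence | None:
    pos = call.pos
    if not tx.start <= pos <= tx.end:
        return None
    key = call.key
    exon = next((ex for ex in tx.exons if ex[0] <= pos <= ex[1]), None)
    if exon is None:
        # intronic; the 2 bases flanking each exon are essential splice sites
        for s, e in tx.introns:
            if s <= pos <= e:
                if pos - s < SPLICE_BASES or e - pos < SPLICE_BASES:
                    return Consequence(key, tx.transcript_id, ESSENTIAL_SPLICE_SITE)
                return Consequence(key, tx.transcript_id, INTRONIC)
        return Consequence(key, tx.transcript_id, INTRONIC)
    if not tx.coding:
        return Consequence(key, tx.transcript_id, NON_CODING_GENE)
    in_cds = any(s <= pos <= e for s, e in tx.cds)
    if not in_cds:
        cds_start = min(s for s, _ in tx.cds)
        cds_end = max(e for _, e in tx.cds)
        if pos < cds_start:
            klass = UTR5 if tx.strand == "+" else UTR3
        else:
            klass = UTR3 if tx.strand == "+" else UTR5
        return Consequence(key, tx.transcript_id, klass)
    if call.kind != "SNP":
        # coding indel: reported as protein-altering without a codon change
        return Consequence(key, tx.transcript_id, NON_SYNONYMOUS_CODING)
    cds_seq = _cds_sequence(tx, reference)
    idx = _cds_offset(tx, pos)
    codon_i, within = divmod(idx, 3)
    codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
    if len(codon) < 3:
        return Consequence(key, tx.transcript_id, NON_SYNONYMOUS_CODING)
    alt_base = call.alt if tx.strand == "+" else revcomp(call.alt)
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    aa_change = f"{ref_aa}{codon_i + 1}{alt_aa}"
    if alt_aa == "*" and ref_aa != "*":
        klass = STOP_GAINED
    elif alt_aa == ref_aa:
        klass = SYNONYMOUS
    else:
        klass = NON_SYNONYMOUS_CODING
    return Consequence(key, tx.transcript_id, klass, aa_change)


def annotate_consequences(
    call: VariantCall,
    transcripts: Sequence[Transcript],
    reference: Mapping[str, str],
) -> list[Consequence]:
    """One consequence per transcript overlapping the variant.

    An empty list means the variant is intergenic. Coding SNPs are classified
    by translating the affected codon (standard genetic code, strand-aware);
    the first and last two bases of each intron are essential splice sites;
    exonic positions outside the CDS are 5'/3' UTR; transcripts without a CDS
    yield NON_CODING_GENE for their exonic positions.
    """
    out = []
    for tx in transcripts:
        if tx.chrom != call.chrom:
            continue
        csq = _classify_in_transcript(call, tx, reference)
        if csq is not None:
            out.append(csq)
    return out


def drop_intronic(consequences: Iterable[Consequence]) -> list[Consequence]:
    """Remove INTRONIC records; a variant whose records were all intronic
    disappears entirely. UTR and non-coding-gene records are retained."""
    return [c for c in consequences if c.klass != INTRONIC]


# ---------------------------------------------------------------------------
# homology check


def _count_occurrences(haystack: str, query: str, max_mismatch: int) -> int:
    if len(query) > len(haystack):
        return 0
    h = np.frombuffer(haystack.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(h, len(q))
    mismatches = (windows != q).sum(axis=1)
    return int((mismatches <= max_mismatch).sum())


def homology_filter(
    call: VariantCall,
    reference: Mapping[str, str],
    flank: int = DEFAULT_HOMOLOGY_FLANK,
    max_mismatch: int = DEFAULT_HOMOLOGY_MAX_MISMATCH,
) -> tuple[bool, str]:
    """(keep, reason) after a deterministic genome-wide uniqueness scan.

    The reference context ``flank`` bases either side of the variant is
    searched genome-wide on both strands allowing up to ``max_mismatch``
    mismatches; more than one occurrence flags the variant as a homology
    artefact. Independently, a variant whose supporting reads are mostly
    multi-hit placements is flagged. The window is shortened (and logged) at
    contig edges.
    """
    chrom_seq = reference[call.chrom]
    lo = max(1, call.pos - flank)
    hi = min(len(chrom_seq), call.pos + flank)
    if hi - lo + 1 < 2 * flank + 1:
        log.warning(
            "homology window truncated at contig edge for %s:%d", call.chrom, call.pos
        )
    context = chrom_seq[lo - 1 : hi]
    hits = 0
    for seq in reference.values():
        hits += _count_occurrences(seq, context, max_mismatch)
        hits += _count_occurrences(seq, revcomp(context), max_mismatch)
    if hits > 1:
        return False, f"context occurs {hits} times"
    if call.multihit_frac > MULTIHIT_SUPPORT_LIMIT:
        return False, f"{call.multihit_frac:.0%} of supporting reads are multi-hit"
    return True, "unique"


# ---------------------------------------------------------------------------
# truncating scan and full cascade


def truncating_scan(
    post_control_calls: Mapping[str, Sequence[VariantCall]],
    transcripts: Sequence[Transcript],
    reference: Mapping[str, str],
    ds_threshold: float = DEFAULT_MIN_DS,
) -> list[TruncatingEntry]:
    """Per-individual stop-gain / essential-splice-site report, bypassing the
    family-sharing requirement. Entries with DS below ``ds_threshold`` are
    flagged as likely false positives."""
    entries = []
    for sample in sorted(post_control_calls):
        for call in sorted(post_control_calls[sample], key=lambda c: c.key):
            for csq in annotate_consequences(call, transcripts, reference):
                if csq.klass in TRUNCATING_CLASSES:
                    entries.append(
                        TruncatingEntry(sample, call, csq, call.ds < ds_threshold)
                    )
    return entries


def run_cascade(
    member_calls: Mapping[str, Sequence[VariantCall]],
    control_calls: Sequence[VariantCall],
    family: FamilySpec,
    transcripts: Sequence[Transcript],
    known: set[VariantKey],
    reference: Mapping[str, str],
    thresholds: CascadeThresholds = CascadeThresholds(),
    kinds: frozenset[str] = frozenset({"SNP"}),
) -> CascadeResult:
    """Run the full filtering cascade for one family.

    ``member_calls`` holds raw per-member calls (before the primary filter);
    the indel branch is obtained by passing kinds={"INS", "DEL"}. Identical
    inputs produce identical, (chrom, pos)-ordered output.
    """
    if not family.members:
        raise ValueError("family has no members")
    missing = [m for m in family.members if m not in member_calls]
    if missing:
        raise ValueError(f"missing calls for members: {missing}")

    initial: dict[str, int] = {}
    after_control: dict[str, int] = {}
    surviving: dict[str, list[VariantCall]] = {}
    for m in family.members:
        calls = [c for c in member_calls[m] if c.kind in kinds]
        calls = primary_filter(calls, thresholds.min_global_depth, thresholds.min_ds)
        calls = restrict_chromosome(calls, family)
        initial[m] = len(calls)
        calls = [c for c in calls if classify_zygosity(c) == "het"]
        calls = subtract_controls(calls, control_calls, thresholds.control_min_ds)
        after_control[m] = len(calls)
        surviving[m] = calls

    shared = intersect_family(surviving)
    described, undescribed = split_known(shared.keys(), known)

    csq_by_variant: dict[VariantKey, list[Consequence]] = {}
    for key in undescribed:
        call = shared[key][family.members[0]]
        csqs = annotate_consequences(call, transcripts, reference)
        if csqs:
            csq_by_variant[key] = csqs
    n_consequences = sum(len(v) for v in csq_by_variant.values())

    exonic_by_variant = {
        key: kept
        for key, csqs in csq_by_variant.items()
        if (kept := drop_intronic(csqs))
    }
    n_exonic = sum(len(v) for v in exonic_by_variant.values())

    candidates = []
    for key in sorted(exonic_by_variant):
        call = shared[key][family.members[0]]
        keep, _reason = homology_filter(
            call, reference, thresholds.homology_flank, thresholds.homology_max_mismatch
        )
        if keep:
            candidates.append(
                Candidate(key, dict(shared[key]), tuple(exonic_by_variant[key]))
            )

    trace = FilterTrace(
        initial_snps=initial,
        after_control=after_control,
        shared_by_family=len(shared),
        undescribed=len(undescribed),
        consequences=n_consequences,
        exonic=n_exonic,
        pre_homology_variants=len(exonic_by_variant),
        candidates=len(candidates),
    )
    return CascadeResult(candidates=candidates, trace=trace, described=described)
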