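"""Seeded generator of a complete toy capture-resequencing experiment.

The generator emulates the study design this pipeline targets: families of
affected relatives multiplexed with 5-base barcodes, a pooled control of
healthy unrelated individuals, capture of exon-bearing target regions on the
families' linkage candidate chromosomes, uneven capture depth (per-window
negative-binomial scaling), base-call errors, and homologous decoy loci
(duplicated blocks that confuse alignment). Planted variants carry a
machine-readable truth set so every downstream stage can be checked without
any external data.

Reads are emitted with their true placement as SAM, which makes the pipeline
testable without running an aligner; a multiplexed FASTQ path exists for
demultiplexing tests. Everything is driven by one integer seed: the same
SimConfig always produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .coverage_qc import DEFAULT_WINDOW
from .io_formats import (
    DEFAULT_BARCODES,
    AlignedRead,
    FamilySpec,
    Gap,
    TargetRegion,
    Transcript,
    VariantKey,
    write_family_manifest,
    write_fastq,
    write_gene_models,
    write_known_variants,
    write_reference,
    write_regions,
    write_alignments,
)

BASES = "ACGT"
CONTROL_POOL = "control_pool"
UTR_LENGTH = 30
REGION_SPACING = 700  # bases between successive regions on a chromosome
REGION_OFFSET = 1000  # first region starts here on each chromosome
COPY_PAD = 200  # spacing of duplicated decoy blocks in the chromosome tail


def _default_families(n_chromosomes: int) -> tuple[FamilySpec, ...]:
    chrom2 = f"chr{min(2, n_chromosomes)}"
    return (
        FamilySpec("F1", ("S1", "S2"), "chr1"),
        FamilySpec("F2", ("S3", "S4"), chrom2),
    )


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults mirror the design of the screen this pipeline reimplements:
    families of two affected members, four pooled controls, ~33x mean target
    depth for affected samples, 36-base single-end reads, balanced
    heterozygotes, and a quarter of regions duplicated elsewhere as homology
    decoys.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 20_000
    n_target_regions: int = 4
    region_length: int = 300
    families: tuple[FamilySpec, ...] | None = None
    mean_depth: float = 33.0
    depth_dispersion: float = 0.3
    base_error_rate: float = 0.002
    het_allele_balance: float = 0.5
    read_length: int = 36
    barcode_assignment: dict[str, str] | None = None
    n_controls: int = 4
    duplicated_locus_fraction: float = 0.25
    plant_decoys: bool = True
    plant_truncating: bool = True
    plant_indels: bool = True
    n_extra_het_snps: int = 0
    n_control_carriers: int = 2

    def __post_init__(self) -> None:
        if self.families is None:
            self.families = _default_families(self.n_chromosomes)
        self.families = tuple(self.families)
        for p in (self.base_error_rate, self.het_allele_balance,
                  self.duplicated_locus_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")
        if self.read_length <= 5:
            raise ValueError("read_length must exceed the 5-base barcode")
        if self.region_length < 75:
            raise ValueError("region_length too small to hold a two-exon gene")
        for fam in self.families:
            chrom_idx = int(fam.candidate_chrom.removeprefix("chr"))
            if not 1 <= chrom_idx <= self.n_chromosomes:
                raise ValueError(f"candidate chromosome {fam.candidate_chrom} absent")
        if self.barcode_assignment is not None:
            for code in self.barcode_assignment.values():
                if len(code) != 5:
                    raise ValueError("barcodes must be 5 bases")

    @property
    def member_samples(self) -> list[str]:
        return [m for fam in self.families for m in fam.members]

    @property
    def control_samples(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_controls)]

    @property
    def all_samples(self) -> list[str]:
        return self.member_samples + self.control_samples

    def barcodes(self) -> dict[str, str]:
        if self.barcode_assignment is not None:
            return dict(self.barcode_assignment)
        codes = list(DEFAULT_BARCODES)
        # deterministic extension beyond the four published codes
        i = 0
        while len(codes) < len(self.all_samples):
            candidate = "".join(BASES[(i // 4**k) % 4] for k in range(5))
            i += 1
            if candidate not in codes:
                codes.append(candidate)
        return dict(zip(self.all_samples, codes))


@dataclass
class TruthVariant:
    chrom: str
    pos: int  # 1-based; indels are VCF-style anchored at the base before
    ref: str
    alt: str
    kind: str  # SNP | INS | DEL
    carriers: dict[str, str]  # sample -> "het" | "hom"
    planted_consequence: str  # EXONIC | INTRONIC | UTR | STOP_GAINED | ...
    in_known_db: bool = False
    in_duplicated_block: bool = False

    def __post_init__(self) -> None:
        if self.kind in ("INS", "DEL") and abs(len(self.ref) - len(self.alt)) > 12:
            raise ValueError("indel length exceeds the 12-base gap cap")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GeneLayout:
    """Placement of the two-exon gene inside one target region."""

    region: TargetRegion
    transcript: Transcript

    def cds_positions(self) -> list[int]:
        return [p for s, e in self.transcript.cds for p in range(s, e + 1)]

    def intron_interior(self) -> list[int]:
        out = []
        for s, e in self.transcript.introns:
            out.extend(range(s + 3, e - 2))  # keep clear of splice sites
        return out

    def utr_positions(self) -> list[int]:
        cds = set(self.cds_positions())
        return [
            p
            for s, e in self.transcript.exons
            for p in range(s, e + 1)
            if p not in cds
        ]


@dataclass
class DuplicatedBlock:
    source: TargetRegion
    copy_chrom: str
    copy_start: int
    n_mismatches: int


@dataclass
class ExperimentBundle:
    config: SimConfig
    reference: dict[str, str]
    regions: list[TargetRegion]
    layouts: list[GeneLayout]
    families: tuple[FamilySpec, ...]
    barcodes: dict[str, str]
    truth: list[TruthVariant]
    known_keys: set[VariantKey]
    sample_reads: dict[str, list[AlignedRead]]
    control_pool_reads: list[AlignedRead]
    duplicated_blocks: list[DuplicatedBlock]

    @property
    def transcripts(self) -> list[Transcript]:
        return [l.transcript for l in self.layouts]

    @property
    def reference_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.reference.items()}

    def write(self, out_dir: str | Path, emit_fastq: bool = False) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": out / "reference.fasta",
            "regions": out / "targets.bed",
            "genes": out / "genes.gff3",
            "known": out / "known.vcf",
            "manifest": out / "manifest.tsv",
            "truth": out / "truth.json",
            "config": out / "config.yaml",
        }
        write_reference(self.reference, paths["reference"])
        write_regions(self.regions, paths["regions"])
        write_gene_models(self.transcripts, paths["genes"])
        write_known_variants(self.known_keys, self.reference_lengths, paths["known"])
        write_family_manifest(self.families, self.config.control_samples, paths["manifest"])
        truth_payload = [
            dataclasses.asdict(t) for t in sorted(self.truth, key=lambda t: t.key)
        ]
        paths["truth"].write_text(json.dumps(truth_payload, indent=1, sort_keys=True))
        cfg = dataclasses.asdict(self.config)
        cfg["families"] = [
            {"family_id": f.family_id, "members": list(f.members),
             "candidate_chrom": f.candidate_chrom}
            for f in self.config.families
        ]
        paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
        for sample in sorted(self.sample_reads):
            p = out / f"{sample}.sam"
            write_alignments(self.sample_reads[sample], self.reference_lengths, p)
            paths[f"sam:{sample}"] = p
        p = out / f"{CONTROL_POOL}.sam"
        write_alignments(self.control_pool_reads, self.reference_lengths, p)
        paths[f"sam:{CONTROL_POOL}"] = p
        if emit_fastq:
            paths["fastq"] = out / "multiplexed.fastq"
            write_fastq(self.multiplexed_fastq_reads(), paths["fastq"])
        return paths

    def multiplexed_fastq_reads(self) -> list[tuple[str, str, list[int]]]:
        """Primary placements of all samples with their barcode re-attached."""
        out = []
        for sample in sorted(self.sample_reads):
            code = self.barcodes[sample]
            seen: set[str] = set()
            for r in self.sample_reads[sample]:
                if r.read_id in seen:
                    continue  # secondary placement of a multi-hit read
                seen.add(r.read_id)
                out.append((r.read_id, code + r.bases, [35] * 5 + list(r.quals)))
        return out


# ---------------------------------------------------------------------------
# generation


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _layout_regions(config: SimConfig) -> list[TargetRegion]:
    regions = []
    per_chrom: dict[str, int] = {}
    for i in range(config.n_target_regions):
        chrom = f"chr{i % config.n_chromosomes + 1}"
        k = per_chrom.get(chrom, 0)
        per_chrom[chrom] = k + 1
        start = REGION_OFFSET + 1 + k * (config.region_length + REGION_SPACING)
        end = start + config.region_length - 1
        regions.append(TargetRegion(chrom, start, end, f"region_{i}"))
    n_dup = int(round(config.duplicated_locus_fraction * config.n_target_regions))
    tail_need = (config.region_length + COPY_PAD) * max(1, n_dup)
    for chrom, count in per_chrom.items():
        used = REGION_OFFSET + count * (config.region_length + REGION_SPACING)
        if used + tail_need + 500 > config.chrom_length:
            raise ValueError(
                f"chrom_length {config.chrom_length} too small for {count} regions "
                f"of {config.region_length} bases plus decoy copies on {chrom}"
            )
    return regions


def _build_gene(region: TargetRegion, index: int) -> Transcript:
    exon_len = max(30, (2 * region.length) // 5)
    intron_len = region.length - 2 * exon_len
    exon1 = (region.start, region.start + exon_len - 1)
    exon2 = (region.end - exon_len + 1, region.end)
    utr = min(UTR_LENGTH, exon_len // 3)
    while (2 * (exon_len - utr)) % 3 != 0:
        utr += 1
    strand = "+" if index % 2 == 0 else "-"
    if strand == "+":
        cds = ((exon1[0] + utr, exon1[1]), (exon2[0], exon2[1] - utr))
    else:
        cds = ((exon1[0] + utr, exon1[1]), (exon2[0], exon2[1] - utr))
    tx = Transcript(
        transcript_id=f"tx_{region.label}",
        gene_id=f"gene_{region.label}",
        chrom=region.chrom,
        strand=strand,
        exons=(exon1, exon2),
        cds=cds,
    )
    tx.validate()
    return tx


class _PositionAllocator:
    """Hands out non-adjacent planting positions, never reusing a site."""

    def __init__(self) -> None:
        self.used: set[tuple[str, int]] = set()

    def take(self, chrom: str, candidates: Sequence[int]) -> int:
        for pos in candidates:
            if all((chrom, pos + d) not in self.used for d in (-2, -1, 0, 1, 2)):
                self.used.add((chrom, pos))
                return pos
        raise ValueError("no free planting position left in region")


def _snp_alt(rng: np.random.Generator, ref_base: str) -> str:
    others = [b for b in BASES if b != ref_base]
    return others[int(rng.integers(0, 3))]


def _plant_variants(
    rng: np.random.Generator,
    config: SimConfig,
    reference: dict[str, str],
    layouts: list[GeneLayout],
    dup_regions: set[str],
) -> tuple[list[TruthVariant], set[VariantKey]]:
    alloc = _PositionAllocator()
    truth: list[TruthVariant] = []
    known_extra: set[VariantKey] = set()
    by_chrom: dict[str, list[GeneLayout]] = {}
    for l in layouts:
        by_chrom.setdefault(l.region.chrom, []).append(l)

    def plant_snp(
        layout: GeneLayout,
        positions: Sequence[int],
        carriers: dict[str, str],
        consequence: str,
        in_known_db: bool = False,
        in_dup: bool = False,
    ) -> TruthVariant:
        chrom = layout.region.chrom
        pos = alloc.take(chrom, positions)
        ref_base = reference[chrom][pos - 1]
        t = TruthVariant(
            chrom, pos, ref_base, _snp_alt(rng, ref_base), "SNP",
            dict(carriers), consequence, in_known_db, in_dup,
        )
        truth.append(t)
        return t

    for fam in config.families:
        chrom = fam.candidate_chrom
        clean = [l for l in by_chrom[chrom] if l.region.label not in dup_regions]
        dups = [l for l in by_chrom[chrom] if l.region.label in dup_regions]
        if not clean:
            raise ValueError(f"no non-duplicated region on {chrom} to plant in")
        lay = clean[0]
        het_all = {m: "het" for m in fam.members}
        cds = lay.cds_positions()
        # the intended candidate: shared, heterozygous, exonic, undescribed
        plant_snp(lay, cds, het_all, "EXONIC")
        if config.plant_decoys:
            # carried by a single member -> removed by the intersection step
            plant_snp(lay, cds, {fam.members[0]: "het"}, "EXONIC")
            # also present in controls -> removed by control subtraction
            ctrl = dict(het_all)
            for c in config.control_samples[: config.n_control_carriers]:
                ctrl[c] = "het"
            plant_snp(lay, cds, ctrl, "EXONIC")
            # already described -> removed by the known-variant split
            plant_snp(lay, cds, het_all, "EXONIC", in_known_db=True)
            # intron interior -> removed by the intronic drop
            plant_snp(lay, lay.intron_interior(), het_all, "INTRONIC")
            # shared but on another chromosome -> removed by the linkage filter
            other = [c for c in by_chrom if c != chrom]
            if other:
                other_lay = by_chrom[other[0]][0]
                plant_snp(other_lay, other_lay.cds_positions(), het_all, "EXONIC")
            # inside a duplicated block -> removed by the homology check
            if dups:
                plant_snp(dups[0], dups[0].cds_positions(), het_all, "EXONIC",
                          in_dup=True)
        if config.plant_truncating:
            truth.append(
                _plant_stop_gain(rng, reference, clean[-1], alloc, fam.members[0])
            )
        if config.plant_indels:
            truth.append(_plant_deletion(rng, reference, lay, alloc, fam.members[0]))

    if config.n_extra_het_snps:
        fam = config.families[0]
        carrier = {fam.members[0]: "het"}
        pool = [
            l for l in by_chrom[fam.candidate_chrom] if l.region.label not in dup_regions
        ]
        per = math.ceil(config.n_extra_het_snps / len(pool))
        planted = 0
        for lay in pool:
            for pos in lay.cds_positions():
                if planted >= config.n_extra_het_snps:
                    break
                try:
                    pos = alloc.take(lay.region.chrom, [pos])
                except ValueError:
                    continue
                ref_base = reference[lay.region.chrom][pos - 1]
                truth.append(
                    TruthVariant(lay.region.chrom, pos, ref_base,
                                 _snp_alt(rng, ref_base), "SNP", dict(carrier),
                                 "EXONIC")
                )
                planted += 1
        if planted < config.n_extra_het_snps:
            raise ValueError("not enough CDS space for n_extra_het_snps")

    # described variants nobody carries, to pad the known database
    for l in layouts[:2]:
        try:
            pos = alloc.take(l.region.chrom, l.cds_positions()[::-1])
        except ValueError:
            continue
        ref_base = reference[l.region.chrom][pos - 1]
        known_extra.add((l.region.chrom, pos, ref_base, _snp_alt(rng, ref_base)))
    return truth, known_extra


def _plant_stop_gain(
    rng: np.random.Generator,
    reference: dict[str, str],
    layout: GeneLayout,
    alloc: _PositionAllocator,
    carrier: str,
) -> TruthVariant:
    """Edit one codon to TGG and plant the G->A change that creates TAG."""
    from ._util import revcomp

    tx = layout.transcript
    chrom = tx.chrom
    cds = layout.cds_positions()
    if tx.strand == "-":
        cds = cds[::-1]
    for i in range(3, len(cds) - 5, 3):
        codon_pos = cds[i : i + 3]
        if any((chrom, p + d) in alloc.used for p in codon_pos for d in (-2, -1, 0, 1, 2)):
            continue
        # codon positions in transcript orientation; genomic edit is strand-aware
        seq = list(reference[chrom])
        codon = "TGG" if tx.strand == "+" else revcomp("TGG")
        gpos = codon_pos if tx.strand == "+" else sorted(codon_pos)
        for p, b in zip(sorted(codon_pos), codon):
            seq[p - 1] = b
        reference[chrom] = "".join(seq)
        # TGG -> TAG: substitute the middle transcript base
        mid = codon_pos[1]
        ref_base = reference[chrom][mid - 1]
        alt = "A" if tx.strand == "+" else "T"
        for p in codon_pos:
            alloc.used.add((chrom, p))
        return TruthVariant(chrom, mid, ref_base, alt, "SNP", {carrier: "het"},
                            "STOP_GAINED")
    raise ValueError("no codon slot available for a stop-gain plant")


def _plant_deletion(
    rng: np.random.Generator,
    reference: dict[str, str],
    layout: GeneLayout,
    alloc: _PositionAllocator,
    carrier: str,
    length: int = 2,
) -> TruthVariant:
    """A private intronic deletion, VCF-anchored at the base before."""
    interior = layout.intron_interior()
    chrom = layout.region.chrom
    pos = alloc.take(chrom, interior[len(interior) // 2 :])
    for d in range(1, length + 1):
        alloc.used.add((chrom, pos + d))
    seq = reference[chrom]
    ref = seq[pos - 1 : pos + length]
    alt = seq[pos - 1]
    return TruthVariant(chrom, pos, ref, alt, "DEL", {carrier: "het"}, "INTRONIC")


def _duplicate_blocks(
    rng: np.random.Generator,
    config: SimConfig,
    reference: dict[str, str],
    regions: list[TargetRegion],
) -> tuple[list[DuplicatedBlock], set[str]]:
    n_dup = int(round(config.duplicated_locus_fraction * len(regions)))
    if n_dup == 0:
        return [], set()
    blocks = []
    chosen = regions[-n_dup:]  # deterministically the last regions
    tail_used: dict[str, int] = {}
    for region in chosen:
        chrom = region.chrom
        k = tail_used.get(chrom, 0)
        tail_used[chrom] = k + 1
        copy_start = (
            config.chrom_length - (k + 1) * (region.length + COPY_PAD) + 1
        )
        src = reference[chrom][region.start - 1 : region.end]
        n_mm = int(rng.integers(0, 3))
        copy = list(src)
        for p in rng.choice(len(copy), size=n_mm, replace=False):
            copy[p] = _snp_alt(rng, copy[p])
        seq = list(reference[chrom])
        seq[copy_start - 1 : copy_start - 1 + region.length] = copy
        reference[chrom] = "".join(seq)
        blocks.append(DuplicatedBlock(region, chrom, copy_start, n_mm))
    return blocks, {b.source.label for b in blocks}


def _make_read(
    rng: np.random.Generator,
    config: SimConfig,
    reference: dict[str, str],
    chrom: str,
    start: int,
    sample: str,
    read_id: str,
    variants: Sequence[tuple[TruthVariant, str]],
) -> AlignedRead | None:
    """One read from ``start``, carrying this sample's overlapping alleles."""
    L = config.read_length
    seq = reference[chrom]
    gap: Gap | None = None
    # at most one indel per read; decide indel carriage first
    indel = None
    for t, zyg in variants:
        if t.kind == "SNP":
            continue
        del_len = len(t.ref) - len(t.alt)
        event_start = t.pos + 1
        offset = event_start - start
        if 1 <= offset <= L - 1:
            carried = zyg == "hom" or rng.random() < config.het_allele_balance
            if carried:
                indel = (t, offset, del_len)
                break
    if indel is not None:
        t, offset, del_len = indel
        if start + L + del_len - 1 > len(seq):
            indel = None
    if indel is None:
        if start + L - 1 > len(seq) or start < 1:
            return None
        bases = list(seq[start - 1 : start + L - 1])
        ref_of = {i: start + i for i in range(L)}
    else:
        t, offset, del_len = indel
        event_start = t.pos + 1
        bases = list(
            seq[start - 1 : event_start - 1]
            + seq[event_start + del_len - 1 : start + L + del_len - 1]
        )
        gap = Gap(offset=offset, length=del_len, kind="DEL")
        ref_of = {}
        for i in range(L):
            ref_of[i] = start + i if i < offset else start + i + del_len
    # SNP alleles
    for t, zyg in variants:
        if t.kind != "SNP":
            continue
        if not start <= t.pos <= start + L + (gap.length if gap else 0) - 1:
            continue
        if zyg == "het" and rng.random() >= config.het_allele_balance:
            continue
        for i, rp in ref_of.items():
            if rp == t.pos:
                bases[i] = t.alt
                break
    # base-call errors
    if config.base_error_rate > 0:
        errs = np.nonzero(rng.random(L) < config.base_error_rate)[0]
        for i in errs:
            bases[i] = _snp_alt(rng, bases[i])
    quals = tuple(rng.integers(31, 41, size=L).tolist())
    return AlignedRead(
        read_id=read_id,
        sample=sample,
        chrom=chrom,
        pos=start,
        strand="+",
        bases="".join(bases),
        quals=quals,
        gap=gap,
    )


def _sample_reads(
    rng: np.random.Generator,
    config: SimConfig,
    reference: dict[str, str],
    regions: list[TargetRegion],
    sample: str,
    truth: list[TruthVariant],
    blocks: dict[str, DuplicatedBlock],
    depth: float,
) -> list[AlignedRead]:
    carried = [
        (t, t.carriers[sample]) for t in truth if sample in t.carriers
    ]
    reads: list[AlignedRead] = []
    serial = 0
    for region in sorted(regions):
        chrom = region.chrom
        local = [
            (t, z) for t, z in carried
            if t.chrom == chrom and region.start - 20 <= t.pos <= region.end + 20
        ]
        first = region.start - config.read_length + 1
        n_starts = region.end - first + 1
        n_windows = (n_starts + DEFAULT_WINDOW - 1) // DEFAULT_WINDOW
        if config.depth_dispersion > 0:
            d = config.depth_dispersion
            factors = rng.gamma(shape=1.0 / d, scale=d, size=n_windows)
        else:
            factors = np.ones(n_windows)
        lam = depth / config.read_length
        block = blocks.get(region.label)
        for w in range(n_windows):
            w_first = first + w * DEFAULT_WINDOW
            w_last = min(w_first + DEFAULT_WINDOW - 1, region.end)
            counts = rng.poisson(lam * factors[w], size=w_last - w_first + 1)
            for off, n in enumerate(counts):
                start = w_first + off
                for _ in range(int(n)):
                    read = _make_read(
                        rng, config, reference, chrom, start, sample,
                        f"{sample}.{region.label}.{serial}", local,
                    )
                    if read is None:
                        continue
                    serial += 1
                    if block is not None:
                        read.n_hits = 2
                        twin = replace(
                            read,
                            pos=block.copy_start + (start - region.start),
                            chrom=block.copy_chrom,
                            n_mismatches=min(2, block.n_mismatches),
                        )
                        reads.extend([read, twin])
                    else:
                        reads.append(read)
    return reads


def generate_experiment(config: SimConfig) -> ExperimentBundle:
    """Build the full deterministic experiment bundle for ``config``."""
    rng = np.random.default_rng(config.seed)
    regions = _layout_regions(config)
    reference = {
        f"chr{i + 1}": _random_sequence(rng, config.chrom_length)
        for i in range(config.n_chromosomes)
    }
    layouts = [GeneLayout(r, _build_gene(r, i)) for i, r in enumerate(regions)]
    blocks, dup_labels = _duplicate_blocks(rng, config, reference, regions)
    truth, known_extra = _plant_variants(rng, config, reference, layouts, dup_labels)
    known_keys = {t.key for t in truth if t.in_known_db} | known_extra

    block_by_label = {b.source.label: b for b in blocks}
    sample_reads: dict[str, list[AlignedRead]] = {}
    for sample in config.all_samples:
        sample_reads[sample] = _sample_reads(
            rng, config, reference, regions, sample, truth, block_by_label,
            config.mean_depth,
        )
    control_pool = pool_controls(
        [sample_reads[c] for c in config.control_samples]
    ) if config.n_controls else []
    return ExperimentBundle(
        config=config,
        reference=reference,
        regions=regions,
        layouts=layouts,
        families=config.families,
        barcodes=config.barcodes(),
        truth=truth,
        known_keys=known_keys,
        sample_reads=sample_reads,
        control_pool_reads=control_pool,
        duplicated_blocks=blocks,
    )


def pool_controls(control_samples: Sequence[Sequence[AlignedRead]]) -> list[AlignedRead]:
    """Merge control read sets into a single pooled pseudo-sample.

    The pooled read multiset is the union of the inputs (depths add); reads
    are relabelled ``control_pool``.
    """
    if not control_samples:
        raise ValueError("cannot pool zero control samples")
    pooled = []
    for reads in control_samples:
        pooled.extend(replace(r, sample=CONTROL_POOL) for r in reads)
    return pooled


RETAINED_CONSEQUENCES = frozenset(
    {"EXONIC", "UTR", "STOP_GAINED", "NON_CODING_GENE", "SPLICE"}
)


def expected_candidates(
    truth: Iterable[TruthVariant],
    family: FamilySpec,
    control_samples: Iterable[str] = (),
) -> set[VariantKey]:
    """The cascade's logical definition applied directly to the truth set.

    A truth variant is an expected candidate iff it is a SNP on the family's
    candidate chromosome, heterozygous in every affected member, absent from
    all controls and from the known-variant database, not purely intronic,
    and not inside a duplicated (homologous) block.
    """
    controls = set(control_samples)
    out = set()
    for t in truth:
        if t.kind != "SNP" or t.chrom != family.candidate_chrom:
            continue
        if not all(t.carriers.get(m) == "het" for m in family.members):
            continue
        if any(c in t.carriers for c in controls):
            continue
        if t.in_known_db or t.in_duplicated_block:
            continue
        if t.planted_consequence not in RETAINED_CONSEQUENCES:
            continue
        out.add(t.key)
    return out
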