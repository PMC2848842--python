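"""On-disk format handling and barcode demultiplexing.

All coordinates are 1-based inclusive inside the package; BED input/output is
converted at the boundary (BED files are 0-based half-open on disk). SAM, VCF
and FASTA/FASTQ go through pysam and Biopython; GFF3 parsing goes through
gffutils. Gapped single-end alignments are restricted to at most one insertion
or deletion of <= 12 bases, the regime of the short-read aligner whose output
this pipeline consumes; records outside that regime are skipped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

MAX_GAP_LENGTH = 12
BARCODE_LENGTH = 5

# 5-base sample barcodes used on the multiplexed arrays (3-4 samples per array).
DEFAULT_BARCODES = ("GATCT", "ATCGT", "TGTCT", "GTGAT")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Gap:
    """A single indel within a read.

    ``offset`` is the number of read bases aligned before the event. For a
    deletion, ``length`` reference bases starting at ``read.pos + offset`` are
    absent from the read; for an insertion, ``length`` read bases starting at
    read offset ``offset`` are absent from the reference.
    """

    offset: int
    length: int
    kind: str  # "INS" | "DEL"

    def __post_init__(self) -> None:
        if self.kind not in ("INS", "DEL"):
            raise ValueError(f"gap kind must be INS or DEL, got {self.kind!r}")
        if not 1 <= self.length <= MAX_GAP_LENGTH:
            raise ValueError(f"gap length must be in [1, {MAX_GAP_LENGTH}]")
        if self.offset < 1:
            raise ValueError("gap must be preceded by at least one aligned base")


@dataclass
class AlignedRead:
    """One placement of a single-end read on the reference.

    A read aligning equally well to several locations appears as several
    AlignedRead records sharing ``read_id``, with ``n_hits`` giving the number
    of equally good placements.
    """

    read_id: str
    sample: str
    chrom: str
    pos: int  # 1-based leftmost mapped base
    strand: str
    bases: str
    quals: tuple[int, ...]
    n_hits: int = 1
    gap: Gap | None = None
    n_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and qualities differ in length")
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")
        if self.gap is not None and self.gap.offset >= len(self.bases):
            raise ValueError("gap must be followed by at least one aligned base")

    @property
    def ref_span(self) -> int:
        """Number of reference bases consumed by this placement."""
        n = len(self.bases)
        if self.gap is None:
            return n
        return n + self.gap.length if self.gap.kind == "DEL" else n - self.gap.length

    @property
    def ref_end(self) -> int:
        """1-based rightmost mapped reference base."""
        return self.pos + self.ref_span - 1

    def base_at(self, ref_pos: int) -> tuple[str, int] | None:
        """(base, quality) aligned to ``ref_pos``, or None if not aligned there.

        Positions inside a deletion return None even though the read spans them.
        """
        i = ref_pos - self.pos
        if i < 0 or ref_pos > self.ref_end:
            return None
        g = self.gap
        if g is None:
            return self.bases[i], self.quals[i]
        if g.kind == "DEL":
            if i < g.offset:
                return self.bases[i], self.quals[i]
            if i < g.offset + g.length:
                return None  # deleted base
            j = i - g.length
            return self.bases[j], self.quals[j]
        # insertion: reference coordinates skip the inserted read bases
        if i < g.offset:
            return self.bases[i], self.quals[i]
        j = i + g.length
        return self.bases[j], self.quals[j]


@dataclass(frozen=True, order=True)
class TargetRegion:
    """A capture target interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, item: tuple[str, int]) -> bool:
        chrom, pos = item
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class FamilySpec:
    """A family of affected individuals and its linkage candidate chromosome."""

    family_id: str
    members: tuple[str, ...]
    candidate_chrom: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("family must have at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError("family members must be unique")


@dataclass(frozen=True)
class Transcript:
    """A gene model: exons plus an optional CDS, all 1-based inclusive."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    partial: bool = False

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def validate(self) -> None:
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        cds_len = sum(e - s + 1 for s, e in self.cds)
        if self.cds and cds_len % 3 != 0 and not self.partial:
            raise ValueError(
                f"{self.transcript_id}: CDS length {cds_len} not divisible by 3 "
                "and transcript not flagged partial"
            )
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS outside exons")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        exons = sorted(self.exons)
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:]) if s2 - e1 > 1
        )


# ---------------------------------------------------------------------------
# barcode demultiplexing


def _check_barcodes(barcodes: dict[str, str]) -> None:
    if not barcodes:
        raise ValueError("no barcodes given")
    codes = list(barcodes.values())
    for code in codes:
        if len(code) != BARCODE_LENGTH:
            raise ValueError(f"barcode {code!r} is not {BARCODE_LENGTH} bases")
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate barcode codes")


def demultiplex_reads(
    records: Iterable[SeqRecord], barcodes: dict[str, str]
) -> tuple[dict[str, list[SeqRecord]], list[SeqRecord]]:
    """Assign multiplexed reads to samples by exact 5-base barcode match.

    The matched barcode bases (and their qualities) are trimmed from assigned
    reads; reads whose first five bases match no barcode go to the unassigned
    pool untouched. The result is a partition: every input read appears exactly
    once across the outputs.
    """
    _check_barcodes(barcodes)
    by_code = {code: sample for sample, code in barcodes.items()}
    assigned: dict[str, list[SeqRecord]] = {sample: [] for sample in barcodes}
    unassigned: list[SeqRecord] = []
    for rec in records:
        sample = by_code.get(str(rec.seq[:BARCODE_LENGTH]))
        if sample is None:
            unassigned.append(rec)
        else:
            assigned[sample].append(rec[BARCODE_LENGTH:])
    return assigned, unassigned


def demultiplex_fastq(
    path: str | Path, barcodes: dict[str, str], out_dir: str | Path
) -> dict[str, Path]:
    """File-level wrapper: one trimmed FASTQ per sample plus ``unassigned.fastq``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assigned, unassigned = demultiplex_reads(SeqIO.parse(str(path), "fastq"), barcodes)
    paths: dict[str, Path] = {}
    for sample, recs in assigned.items():
        p = out_dir / f"{sample}.fastq"
        SeqIO.write(recs, str(p), "fastq")
        paths[sample] = p
    p = out_dir / "unassigned.fastq"
    SeqIO.write(unassigned, str(p), "fastq")
    paths["unassigned"] = p
    return paths


def write_fastq(reads: Sequence[tuple[str, str, Sequence[int]]], path: str | Path) -> None:
    """Write (id, sequence, qualities) triples as Phred+33 FASTQ."""
    records = []
    for read_id, seq, quals in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# SAM


def _cigar_for(read: AlignedRead) -> list[tuple[int, int]]:
    n = len(read.bases)
    g = read.gap
    if g is None:
        return [(0, n)]
    if g.kind == "DEL":
        return [(0, g.offset), (2, g.length), (0, n - g.offset)]
    return [(0, g.offset), (1, g.length), (0, n - g.offset - g.length)]


def write_alignments(
    reads: Iterable[AlignedRead],
    reference_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write placements as coordinate-sorted plain-text SAM.

    Sample identity travels in the RG tag; the number of equally good
    placements in NH and the mismatch count in NM. Secondary placements of a
    multi-hit read are flagged as such.
    """
    reads = sorted(reads, key=lambda r: (r.chrom, r.pos, r.read_id, r.strand))
    samples = sorted({r.sample for r in reads})
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in sorted(reference_lengths.items())],
        "RG": [{"ID": s, "SM": s} for s in samples],
    }
    tids = {name: i for i, name in enumerate(sorted(reference_lengths))}
    seen: set[str] = set()
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = (16 if r.strand == "-" else 0) | (256 if r.read_id in seen else 0)
            seen.add(r.read_id)
            a.reference_id = tids[r.chrom]
            a.reference_start = r.pos - 1
            a.mapping_quality = 30
            a.cigartuples = _cigar_for(r)
            a.query_sequence = r.bases
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals)
            )
            a.set_tags(
                [("NH", r.n_hits, "i"), ("NM", r.n_mismatches, "i"), ("RG", r.sample, "Z")]
            )
            out.write(a)


def read_alignments(
    path: str | Path,
    *,
    on_skip: Callable[[str, str], None] | None = None,
) -> list[AlignedRead]:
    """Parse a SAM file into AlignedRead placements.

    CIGARs are restricted to {M, one I or D of <= 12 bases}; records outside
    that set (or unmapped) are skipped with a logged warning. ``on_skip`` is
    called with (query name, reason) for each skipped record.
    """

    def skip(name: str, reason: str) -> None:
        log.warning("skipping read %s: %s", name, reason)
        if on_skip is not None:
            on_skip(name, reason)

    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigartuples is None:
                skip(rec.query_name or "?", "unmapped")
                continue
            cig = rec.cigartuples
            gap = None
            if len(cig) == 1 and cig[0][0] == 0:
                pass
            elif (
                len(cig) == 3
                and cig[0][0] == 0
                and cig[2][0] == 0
                and cig[1][0] in (1, 2)
                and cig[1][1] <= MAX_GAP_LENGTH
            ):
                kind = "INS" if cig[1][0] == 1 else "DEL"
                gap = Gap(offset=cig[0][1], length=cig[1][1], kind=kind)
            else:
                skip(rec.query_name or "?", f"unsupported CIGAR {rec.cigarstring}")
                continue
            reads.append(
                AlignedRead(
                    read_id=rec.query_name or "",
                    sample=str(rec.get_tag("RG")) if rec.has_tag("RG") else "unknown",
                    chrom=rec.reference_name or "",
                    pos=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    bases=rec.query_sequence or "",
                    quals=tuple(int(q) for q in (rec.query_qualities or [])),
                    n_hits=int(rec.get_tag("NH")) if rec.has_tag("NH") else 1,
                    gap=gap,
                    n_mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# BED / GFF3 / VCF / FASTA


def read_regions(path: str | Path) -> list[TargetRegion]:
    """BED (0-based half-open) -> 1-based inclusive TargetRegions, sorted."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        label = fields[3] if len(fields) > 3 else ""
        regions.append(TargetRegion(chrom, start + 1, end, label))
    return sorted(regions)


def write_regions(regions: Iterable[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}\n")


def merge_regions(regions: Iterable[TargetRegion]) -> list[TargetRegion]:
    """Merge overlapping or adjacent regions per chromosome."""
    merged: list[TargetRegion] = []
    for r in sorted(regions):
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end + 1:
            prev = merged[-1]
            merged[-1] = TargetRegion(prev.chrom, prev.start, max(prev.end, r.end), prev.label)
        else:
            merged.append(r)
    return merged


def read_gene_models(path: str | Path) -> list[Transcript]:
    """Parse GFF3 gene models into validated Transcripts (gffutils-backed)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    transcripts = []
    for feat in db.all_features():
        if feat.featuretype not in ("mRNA", "transcript", "ncRNA"):
            continue
        exons = tuple(
            sorted((c.start, c.end) for c in db.children(feat, featuretype="exon"))
        )
        cds = tuple(sorted((c.start, c.end) for c in db.children(feat, featuretype="CDS")))
        parents = list(db.parents(feat, featuretype="gene"))
        tx = Transcript(
            transcript_id=feat.id,
            gene_id=parents[0].id if parents else feat.id,
            chrom=feat.seqid,
            strand=feat.strand,
            exons=exons,
            cds=cds,
            partial=feat.attributes.get("partial", ["false"])[0] == "true",
        )
        tx.validate()
        transcripts.append(tx)
    return sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))


def write_gene_models(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Emit transcripts as GFF3 (gene -> mRNA/ncRNA -> exon/CDS)."""
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[Transcript]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    for gene_id in sorted(by_gene):
        txs = sorted(by_gene[gene_id], key=lambda t: t.transcript_id)
        chrom = txs[0].chrom
        strand = txs[0].strand
        gstart = min(t.start for t in txs)
        gend = max(t.end for t in txs)
        lines.append(
            f"{chrom}\t.\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gene_id}"
        )
        for tx in txs:
            ttype = "mRNA" if tx.coding else "ncRNA"
            attrs = f"ID={tx.transcript_id};Parent={gene_id}"
            if tx.partial:
                attrs += ";partial=true"
            lines.append(
                f"{chrom}\t.\t{ttype}\t{tx.start}\t{tx.end}\t.\t{strand}\t.\t{attrs}"
            )
            for i, (s, e) in enumerate(tx.exons, 1):
                lines.append(
                    f"{chrom}\t.\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}"
                )
            for i, (s, e) in enumerate(tx.cds, 1):
                lines.append(
                    f"{chrom}\t.\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                    f"ID={tx.transcript_id}.cds{i};Parent={tx.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


VariantKey = tuple[str, int, str, str]


def read_known_variants(path: str | Path) -> set[VariantKey]:
    """Known ('described') variants as a set of (chrom, pos, ref, alt) keys."""
    known: set[VariantKey] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                known.add((rec.chrom, rec.pos, rec.ref, alt))
    return known


def write_known_variants(
    keys: Iterable[VariantKey], contigs: dict[str, int], path: str | Path
) -> None:
    header = pysam.VariantHeader()
    for name, length in sorted(contigs.items()):
        header.contigs.add(name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom, pos, ref, alt in sorted(keys):
            rec = out.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
            rec.stop = pos - 1 + len(ref)
            out.write(rec)


def _variant_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in sorted(contigs.items()):
        header.contigs.add(name, length=length)
    header.info.add("DS", 1, "Float", "Depth score: allele-balance of read depths")
    header.info.add("QS", 1, "Float", "Quality score: allele-balance of mean base qualities")
    header.info.add("GD", 1, "Integer", "Global depth at the site")
    header.info.add("XV", 1, "Integer", "Variant allele depth")
    header.info.add("XR", 1, "Integer", "Reference allele depth")
    header.info.add("ZYG", 1, "String", "Zygosity call (het/hom)")
    header.info.add("KIND", 1, "String", "Variant kind (SNP/INS/DEL)")
    header.info.add("STAGE", 1, "String", "Last filtering stage reached")
    header.info.add("CSQ", ".", "String", "Consequence classes")
    return header


def write_variants_vcf(
    calls: Iterable,  # Sequence[VariantCall]
    contigs: dict[str, int],
    path: str | Path,
    stages: dict[VariantKey, str] | None = None,
    consequences: dict[VariantKey, Sequence[str]] | None = None,
) -> None:
    """Write VariantCalls as VCF v4 with the pipeline's scores as INFO keys."""
    header = _variant_header(contigs)
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            rec = out.new_record(contig=c.chrom, start=c.pos - 1, alleles=(c.ref, c.alt))
            rec.stop = c.pos - 1 + len(c.ref)
            rec.info["DS"] = float(c.ds)
            rec.info["QS"] = float(c.qs)
            rec.info["GD"] = int(c.global_depth)
            rec.info["XV"] = int(c.x_v)
            rec.info["XR"] = int(c.x_r)
            rec.info["ZYG"] = c.zygosity
            rec.info["KIND"] = c.kind
            key = (c.chrom, c.pos, c.ref, c.alt)
            if stages and key in stages:
                rec.info["STAGE"] = stages[key]
            if consequences and key in consequences:
                rec.info["CSQ"] = list(consequences[key])
            out.write(rec)


def read_variants_vcf(path: str | Path) -> list:
    """Round-trip reader for :func:`write_variants_vcf` output."""
    from .variant_calling import VariantCall  # local import avoids a cycle

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=(rec.alts or ("",))[0],
                    kind=str(info.get("KIND", "SNP")),
                    global_depth=int(info.get("GD", 0)),
                    x_v=int(info.get("XV", 0)),
                    x_r=int(info.get("XR", 0)),
                    q_v=0.0,
                    q_r=0.0,
                    ds=float(info.get("DS", 0.0)),
                    qs=float(info.get("QS", 0.0)),
                    zygosity=str(info.get("ZYG", "het")),
                )
            )
    return calls


def load_reference(path: str | Path) -> dict[str, str]:
    """FASTA -> {chromosome: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_reference(reference: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(reference.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# family manifest


def write_family_manifest(
    families: Sequence[FamilySpec], controls: Sequence[str], path: str | Path
) -> None:
    lines = ["sample\tfamily\tcandidate_chrom"]
    for fam in families:
        for member in fam.members:
            lines.append(f"{member}\t{fam.family_id}\t{fam.candidate_chrom}")
    for sample in controls:
        lines.append(f"{sample}\tcontrol\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_family_manifest(path: str | Path) -> tuple[list[FamilySpec], list[str]]:
    families: dict[str, tuple[list[str], str]] = {}
    controls: list[str] = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        sample, family, chrom = line.split("\t")
        if family == "control":
            controls.append(sample)
        else:
            families.setdefault(family, ([], chrom))[0].append(sample)
    specs = [
        FamilySpec(fid, tuple(members), chrom) for fid, (members, chrom) in families.items()
    ]
    return specs, controls
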