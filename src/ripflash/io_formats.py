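"""Readers/writers for the external formats and the shared transcriptome model.

All internal coordinates are transcript-space, 0-based, half-open.  The GTF
dialect consumed here is Ensembl-flavoured but transcript-centric: the seqname
column carries the transcript identifier and features (``transcript``, ``exon``,
``CDS``) are given in 1-based inclusive transcript coordinates.  Genomic
alignments must be projected to transcript space by the caller; the synthetic
generator emits transcript-space SAM directly.

Every parser is total on its dialect: a record either yields a validated
object, a counted skip, or a located error -- never silent corruption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BIOTYPES = (
    "protein_coding",
    "lincRNA",
    "miRNA",
    "snoRNA",
    "snRNA",
    "rRNA",
    "tRNA",
    "other",
)

#: Region labels used for the 5'UTR / CDS / 3'UTR segmentation of coding
#: transcripts; non-coding transcripts carry a single "body" region.
REGION_LABELS = ("utr5", "cds", "utr3", "body")

MISSING = "."

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def reverse_complement(seq: str) -> str:
    """Reverse complement in DNA space (U is read as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """A malformed record; message carries file and line number."""


class ValidationError(ValueError):
    """An internally inconsistent object (e.g. CDS outside transcript bounds)."""


def normalize_biotype(raw: str) -> str:
    """Reduce an Ensembl biotype string to the 8-value vocabulary."""
    return raw if raw in BIOTYPES else "other"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

Region = tuple[str, int, int]  # (label, start, end), 0-based half-open


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's sequence, biotype and UTR/CDS segmentation.

    ``regions`` is an ordered list of ``(label, start, end)`` in transcript
    coordinates.  For protein-coding transcripts the regions tile
    ``[0, length)`` exactly; non-coding transcripts have a single ``body``
    region.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str
    sequence: str
    regions: tuple[Region, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.transcript_id}: unknown biotype {self.biotype!r}"
            )
        prev_end = 0
        for label, start, end in self.regions:
            if label not in REGION_LABELS:
                raise ValidationError(f"{self.transcript_id}: bad region label {label!r}")
            if not (0 <= start < end <= self.length):
                raise ValidationError(
                    f"{self.transcript_id}: region {label} [{start},{end}) outside "
                    f"[0,{self.length})"
                )
            if start < prev_end:
                raise ValidationError(f"{self.transcript_id}: overlapping regions")
            prev_end = end
        if self.biotype == "protein_coding":
            covered = sum(e - s for _, s, e in self.regions)
            if covered != self.length or self.regions[0][1] != 0 or self.regions[-1][2] != self.length:
                raise ValidationError(
                    f"{self.transcript_id}: coding regions must tile [0,{self.length})"
                )

    def region_of(self, label: str) -> Region | None:
        for region in self.regions:
            if region[0] == label:
                return region
        return None


@dataclass(frozen=True)
class ReadAlignment:
    """A single-end alignment in transcript coordinates (0-based half-open)."""

    read_id: str
    transcript_id: str
    start: int
    end: int
    strand: str = "+"
    n_mismatches: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"{self.read_id}: bad span [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValidationError(f"{self.read_id}: bad strand {self.strand!r}")


@dataclass
class AlignmentSet:
    """Alignments plus skip counters from parsing.

    Only sense ("+") alignments participate in downstream counting; the
    library protocols are sense-stranded.
    """

    records: list[ReadAlignment] = field(default_factory=list)
    n_skipped_unmapped: int = 0
    n_skipped_secondary: int = 0
    n_skipped_unknown_reference: int = 0
    n_skipped_antisense: int = 0

    def __iter__(self) -> Iterator[ReadAlignment]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Annotation (GTF + FASTA)
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str, path: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed attribute {chunk!r}") from None
        attrs[key] = value.strip().strip('"')
    return attrs


def read_annotation(gtf_path: str | Path, fasta_path: str | Path) -> dict[str, TranscriptModel]:
    """Read a transcript-space GTF plus FASTA into validated TranscriptModels.

    GTF coordinates are 1-based inclusive and converted to 0-based half-open.
    Transcripts present in the GTF but lacking a FASTA sequence are dropped
    with a logged warning.  Returns a dict keyed by transcript_id preserving
    GTF order.
    """
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }

    spans: dict[str, dict] = {}
    order: list[str] = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{gtf_path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            seqname, _source, feature, start_s, end_s, _score, _strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{gtf_path}:{lineno}: non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{gtf_path}:{lineno}: bad span {start1}..{end1}")
            attrs = _parse_gtf_attributes(attr_s, str(gtf_path), lineno)
            tx_id = attrs.get("transcript_id", seqname)
            entry = spans.setdefault(tx_id, {"attrs": attrs, "cds": None, "span": None})
            if feature == "transcript":
                entry["span"] = (start1 - 1, end1)
                entry["attrs"] = attrs
                if tx_id not in order:
                    order.append(tx_id)
            elif feature == "CDS":
                entry["cds"] = (start1 - 1, end1)
                if tx_id not in order:
                    order.append(tx_id)

    models: dict[str, TranscriptModel] = {}
    for tx_id in order:
        entry = spans[tx_id]
        sequence = sequences.get(tx_id)
        if sequence is None:
            logger.warning("transcript %s has no FASTA sequence; dropped", tx_id)
            continue
        attrs = entry["attrs"]
        biotype = normalize_biotype(attrs.get("gene_biotype", "other"))
        length = len(sequence)
        if entry["span"] is not None and entry["span"][1] != length:
            raise ValidationError(
                f"{tx_id}: GTF span length {entry['span'][1]} != sequence length {length}"
            )
        cds = entry["cds"]
        if cds is not None:
            cds_start, cds_end = cds
            if not (0 <= cds_start < cds_end <= length):
                raise ValidationError(
                    f"{tx_id}: CDS [{cds_start},{cds_end}) outside transcript [0,{length})"
                )
            regions: list[Region] = []
            if cds_start > 0:
                regions.append(("utr5", 0, cds_start))
            regions.append(("cds", cds_start, cds_end))
            if cds_end < length:
                regions.append(("utr3", cds_end, length))
        else:
            regions = [("body", 0, length)]
        models[tx_id] = TranscriptModel(
            transcript_id=tx_id,
            gene_id=attrs.get("gene_id", tx_id),
            gene_name=attrs.get("gene_name", attrs.get("gene_id", tx_id)),
            biotype=biotype,
            sequence=sequence,
            regions=tuple(regions),
        )
    return models


def write_annotation(
    models: Iterable[TranscriptModel], gtf_path: str | Path, fasta_path: str | Path
) -> None:
    """Write TranscriptModels back out as transcript-space GTF + FASTA."""
    models = list(models)
    records = [
        SeqRecord(Seq(m.sequence), id=m.transcript_id, description="")
        for m in models
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gtf_path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_name "{m.gene_name}"; gene_biotype "{m.biotype}";'
            )
            base = [m.transcript_id, "ripflash", None, None, None, ".", "+", ".", attrs]

            def line(feature: str, start0: int, end0: int) -> str:
                row = list(base)
                row[2] = feature
                row[3] = str(start0 + 1)  # back to 1-based inclusive
                row[4] = str(end0)
                return "\t".join(row)

            fh.write(line("transcript", 0, m.length) + "\n")
            fh.write(line("exon", 0, m.length) + "\n")
            cds = m.region_of("cds")
            if cds is not None:
                fh.write(line("CDS", cds[1], cds[2]) + "\n")


# ---------------------------------------------------------------------------
# Alignments (SAM / BED)
# ---------------------------------------------------------------------------

def read_alignments(
    path: str | Path,
    format: str = "sam",
    known_references: set[str] | None = None,
    keep_antisense: bool = False,
) -> AlignmentSet:
    """Read single-end alignments from SAM or BED6 into transcript space.

    SAM POS is 1-based (pysam normalizes); BED is already 0-based half-open.
    Unmapped, secondary and supplementary SAM records are skipped and counted,
    as are records on references not in ``known_references`` (when given) and
    antisense alignments (unless ``keep_antisense``).
    """
    if format == "sam":
        return _read_sam(path, known_references, keep_antisense)
    if format == "bed":
        return _read_bed(path, known_references, keep_antisense)
    raise ValueError(f"unknown alignment format {format!r}")


def _read_sam(path, known_references, keep_antisense) -> AlignmentSet:
    out = AlignmentSet()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                out.n_skipped_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                out.n_skipped_secondary += 1
                continue
            ref = rec.reference_name
            if known_references is not None and ref not in known_references:
                logger.warning("alignment %s on unknown reference %s; skipped", rec.query_name, ref)
                out.n_skipped_unknown_reference += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            if strand == "-" and not keep_antisense:
                out.n_skipped_antisense += 1
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.records.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    transcript_id=ref,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand=strand,
                    n_mismatches=int(nm),
                )
            )
    return out


def _read_bed(path, known_references, keep_antisense) -> AlignmentSet:
    out = AlignmentSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 needs 6 fields, got {len(fields)}")
            ref, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if known_references is not None and ref not in known_references:
                logger.warning("BED line %d on unknown reference %s; skipped", lineno, ref)
                out.n_skipped_unknown_reference += 1
                continue
            if strand == "-" and not keep_antisense:
                out.n_skipped_antisense += 1
                continue
            out.records.append(ReadAlignment(name, ref, start, end, strand))
    return out


def write_alignments_sam(
    alignments: Iterable[ReadAlignment],
    models: dict[str, TranscriptModel] | Sequence[TranscriptModel],
    path: str | Path,
) -> None:
    """Write transcript-space alignments as SAM with one @SQ line per transcript."""
    if isinstance(models, dict):
        models = list(models.values())
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": m.transcript_id, "LN": m.length} for m in models],
    }
    tid = {m.transcript_id: i for i, m in enumerate(models)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.reference_id = tid[aln.transcript_id]
            rec.reference_start = aln.start
            rec.cigarstring = f"{aln.end - aln.start}M"
            rec.flag = 16 if aln.strand == "-" else 0
            rec.mapping_quality = 255
            rec.set_tag("NM", aln.n_mismatches)
            out.write(rec)


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

DE_COLUMNS = ["gene_id", "log2_fold_change", "p_value", "adjusted_p", "fpkm_a", "fpkm_b"]


def de_direction(log2_fold_change: float, adjusted_p: float, fpkm_a: float, fpkm_b: float,
                 alpha: float = 0.05, min_fpkm: float = 1.0) -> str:
    """Classify a DE row: significant, directioned, and expressed (FPKM >= 1
    in at least one condition) -> up/down; everything else unregulated."""
    if adjusted_p < alpha and max(fpkm_a, fpkm_b) >= min_fpkm:
        if log2_fold_change < 0:
            return "down"
        if log2_fold_change > 0:
            return "up"
    return "unregulated"


def read_de_table(path: str | Path, alpha: float = 0.05, min_fpkm: float = 1.0) -> pd.DataFrame:
    """Read a DE TSV (gene, log2FC, p, adjusted p, FPKM per condition) and
    derive the regulation direction per gene."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: DE table missing columns {missing}")
    df["direction"] = [
        de_direction(r.log2_fold_change, r.adjusted_p, r.fpkm_a, r.fpkm_b, alpha, min_fpkm)
        for r in df.itertuples()
    ]
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


# ---------------------------------------------------------------------------
# Tabular outputs (clusters / hybrids / gene stats)
# ---------------------------------------------------------------------------

CLUSTER_COLUMNS = [
    "transcript_id", "gene_id", "start", "end", "read_count",
    "p_value", "q_value", "biotype", "region", "rpkm_rip", "rpkm_input",
]

HYBRID_COLUMNS = [
    "read_id", "tx1", "start1", "end1", "tx2", "start2", "end2",
    "hybrid_class", "category", "delta_g", "genomic_distance",
]

GENE_STATS_COLUMNS = [
    "gene_id", "utr3_coverage_ratio", "rpkm_ratio_utr3", "rpkm_ratio_tx",
    "n_hybrids", "de_direction", "chip_target",
]


def _write_tsv(df: pd.DataFrame, columns: list[str], sort_by: list[str], path: str | Path) -> None:
    df = df.reindex(columns=columns)
    if len(df) and sort_by:
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def write_clusters(clusters: Iterable, path: str | Path) -> None:
    """Write clusters as TSV, sorted by (transcript_id, start, end)."""
    rows = [c.as_row() if hasattr(c, "as_row") else c for c in clusters]
    df = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    _write_tsv(df, CLUSTER_COLUMNS, ["transcript_id", "start", "end"], path)


def write_hybrids(hybrids: Iterable, path: str | Path) -> None:
    """Write hybrids in a hyb-like two-arm format (one line = both arms + dG)."""
    rows = [h.as_row() if hasattr(h, "as_row") else h for h in hybrids]
    df = pd.DataFrame(rows, columns=HYBRID_COLUMNS)
    _write_tsv(df, HYBRID_COLUMNS, [], path)


def read_hybrids(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    missing = [c for c in HYBRID_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: hybrid table missing columns {missing}")
    return df


def read_clusters(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: cluster table missing columns {missing}")
    return df


def write_gene_stats(rows: Iterable[dict], path: str | Path) -> None:
    df = pd.DataFrame(list(rows), columns=GENE_STATS_COLUMNS)
    _write_tsv(df, GENE_STATS_COLUMNS, ["gene_id"], path)
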