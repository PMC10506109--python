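"""Domain types, coordinate conversion, and I/O for transcript models and ORF calls.

All internal coordinates are 0-based half-open on the genome. GTF input
(1-based inclusive) is converted at the boundary; BED12 passes through
unchanged. Stored ORF coordinates include the stop codon; reported ORF
lengths exclude it. Transcript coordinates run 5'->3' along the mature
transcript, so position 0 on a minus-strand transcript is the genomically
rightmost exonic base.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import MappingError, ParseError, ValidationError

__all__ = [
    "GenomicInterval",
    "ProvenanceTag",
    "ORFCategory",
    "TranscriptModel",
    "ORFRecord",
    "RejectionReport",
    "orf_nt_length",
    "to_transcript_coords",
    "orf_from_tx_interval",
    "read_transcript_models",
    "write_transcript_models",
    "read_orf_calls",
    "write_orf_calls",
    "TSV_COLUMNS",
]

VALID_STRANDS = ("+", "-")

# Biotypes that must never carry a CDS.
NONCODING_BIOTYPES = frozenset(
    {
        "lncRNA",
        "lincRNA",
        "antisense_RNA",
        "misc_RNA",
        "TEC",
        "processed_transcript",
        "pseudogene",
        "processed_pseudogene",
        "rRNA",
        "snoRNA",
        "snRNA",
        "tRNA",
        "miRNA",
    }
)

TSV_COLUMNS = [
    "orf_id",
    "transcript_id",
    "chrom",
    "strand",
    "block_starts",
    "block_sizes",
    "start_codon",
    "dataset",
    "caller",
    "replicate",
    "sample",
    "category",
    "aa_seq",
]


class ORFCategory(str, enum.Enum):
    """Standardized ORF category names plus the two bookkeeping values."""

    UORF = "uORF"
    UOORF = "uoORF"
    INTORF = "intORF"
    DOORF = "doORF"
    DORF = "dORF"
    LNCRNA_ORF = "lncRNA-ORF"
    CANONICAL_VARIANT = "CANONICAL_VARIANT"
    EXCLUDED = "EXCLUDED"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.value


NONCANONICAL_CATEGORIES = (
    ORFCategory.UORF,
    ORFCategory.UOORF,
    ORFCategory.INTORF,
    ORFCategory.DOORF,
    ORFCategory.DORF,
    ORFCategory.LNCRNA_ORF,
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ParseError(f"unknown strand symbol {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval [{self.start},{self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _check_chain(blocks: Sequence[GenomicInterval], what: str) -> None:
    """Validate a sorted, non-overlapping, strand/chrom-consistent chain."""
    if not blocks:
        raise ValidationError(f"{what}: empty chain forbidden")
    for a, b in zip(blocks, blocks[1:]):
        if (a.chrom, a.strand) != (b.chrom, b.strand):
            raise ValidationError(f"{what}: chain mixes chrom/strand")
        if b.start < a.end:
            raise ValidationError(f"{what}: overlapping blocks")


@dataclass(frozen=True)
class ProvenanceTag:
    dataset: str = ""
    caller: str = ""
    replicate: str = ""
    sample: str = ""

    def require_complete(self) -> None:
        if not (self.dataset and self.caller and str(self.replicate)):
            raise ValidationError("incomplete provenance for comparison analysis")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered exon chain plus an optional CDS.

    ``cds_tx`` is a half-open interval in transcript coordinates with the
    stop codon included.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    exons: tuple[GenomicInterval, ...]
    cds_tx: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        _check_chain(self.exons, f"transcript {self.transcript_id}")
        if self.cds_tx is not None:
            s, e = self.cds_tx
            if not (0 <= s < e <= self.length):
                raise ValidationError(
                    f"transcript {self.transcript_id}: cds_tx {self.cds_tx} outside "
                    f"[0,{self.length})"
                )
            if (e - s) % 3 != 0:
                raise ValidationError(
                    f"transcript {self.transcript_id}: CDS length {e - s} not divisible by 3"
                )
            if self.biotype in NONCODING_BIOTYPES:
                raise ValidationError(
                    f"transcript {self.transcript_id}: CDS on noncoding biotype {self.biotype}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    # -- coordinate conversion ------------------------------------------------

    def genomic_to_tx(self, pos: int) -> int:
        """Map a genomic base to its transcript coordinate (strand-aware)."""
        offset = 0
        if self.strand == "+":
            for exon in self.exons:
                if exon.start <= pos < exon.end:
                    return offset + (pos - exon.start)
                offset += len(exon)
        else:
            for exon in reversed(self.exons):
                if exon.start <= pos < exon.end:
                    return offset + (exon.end - 1 - pos)
                offset += len(exon)
        raise MappingError(
            f"position {pos} outside exons of transcript {self.transcript_id}"
        )

    def tx_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_tx`."""
        if not 0 <= tpos < self.length:
            raise MappingError(
                f"transcript position {tpos} outside [0,{self.length}) "
                f"of {self.transcript_id}"
            )
        offset = tpos
        exons = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        for exon in exons:
            if offset < len(exon):
                if self.strand == "+":
                    return exon.start + offset
                return exon.end - 1 - offset
            offset -= len(exon)
        raise AssertionError("unreachable")  # pragma: no cover

    def tx_interval_to_blocks(self, tx_start: int, tx_end: int) -> tuple[GenomicInterval, ...]:
        """Project a transcript-coordinate interval onto genomic exon blocks.

        Returns blocks sorted by genomic position (ascending).
        """
        if not 0 <= tx_start < tx_end <= self.length:
            raise MappingError(
                f"tx interval ({tx_start},{tx_end}) outside transcript "
                f"{self.transcript_id} of length {self.length}"
            )
        blocks: list[GenomicInterval] = []
        offset = 0
        exons = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        for exon in exons:
            lo = max(tx_start, offset)
            hi = min(tx_end, offset + len(exon))
            if lo < hi:
                if self.strand == "+":
                    g0 = exon.start + (lo - offset)
                    g1 = exon.start + (hi - offset)
                else:
                    g1 = exon.end - (lo - offset)
                    g0 = exon.end - (hi - offset)
                blocks.append(GenomicInterval(self.chrom, g0, g1, self.strand))
            offset += len(exon)
        return tuple(sorted(blocks, key=lambda b: b.start))


def _exonic_positions(blocks: Sequence[GenomicInterval]) -> list[int]:
    """Genomic positions of a block chain, ascending."""
    pos: list[int] = []
    for b in sorted(blocks, key=lambda x: x.start):
        pos.extend(range(b.start, b.end))
    return pos


def _derive_stop_codon_pos(blocks: Sequence[GenomicInterval]) -> int:
    """Genomic coordinate of the first base of the stop codon."""
    pos = _exonic_positions(blocks)
    if len(pos) < 6:
        raise ValidationError("ORF shorter than start+stop (6 nt)")
    strand = blocks[0].strand
    # last three bases in transcript order; first of those is the stop's first base
    return pos[-3] if strand == "+" else pos[2]


@dataclass(frozen=True)
class ORFRecord:
    """An exon-block genomic ORF call, stop codon included in the blocks."""

    orf_id: str
    transcript_id: str
    blocks: tuple[GenomicInterval, ...]
    start_codon: str = "ATG"
    stop_codon_pos: Optional[int] = None
    aa_seq: Optional[str] = None
    category: Optional[ORFCategory] = None
    source: ProvenanceTag = field(default_factory=ProvenanceTag)

    def __post_init__(self) -> None:
        blocks = tuple(sorted(self.blocks, key=lambda b: (b.start, b.end)))
        object.__setattr__(self, "blocks", blocks)
        _check_chain(blocks, f"ORF {self.orf_id}")
        total = sum(len(b) for b in blocks)
        if total % 3 != 0:
            raise ValidationError(f"ORF {self.orf_id}: block length {total} not divisible by 3")
        if total < 6:
            raise ValidationError(f"ORF {self.orf_id}: shorter than start+stop")
        derived = _derive_stop_codon_pos(blocks)
        if self.stop_codon_pos is None:
            object.__setattr__(self, "stop_codon_pos", derived)
        elif self.stop_codon_pos != derived:
            raise ValidationError(
                f"ORF {self.orf_id}: stop_codon_pos {self.stop_codon_pos} "
                f"inconsistent with blocks (expected {derived})"
            )
        if len(self.start_codon) != 3:
            raise ValidationError(f"ORF {self.orf_id}: start codon {self.start_codon!r}")
        if self.aa_seq is not None and len(self.aa_seq) * 3 != total - 3:
            raise ValidationError(
                f"ORF {self.orf_id}: aa_seq length {len(self.aa_seq)} != "
                f"({total} - 3)/3 nt"
            )

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def strand(self) -> str:
        return self.blocks[0].strand


def orf_nt_length(orf: ORFRecord) -> int:
    """ORF length in nucleotides excluding the stop codon."""
    return sum(len(b) for b in orf.blocks) - 3


def to_transcript_coords(orf: ORFRecord, tx: TranscriptModel) -> tuple[int, int]:
    """Map an ORF's block chain to a half-open transcript-coordinate interval.

    The stop codon stays included; length is preserved. Raises
    :class:`MappingError` if any ORF base lies outside the transcript's exons
    or the blocks are not contiguous in transcript space.
    """
    if orf.transcript_id and orf.transcript_id != tx.transcript_id:
        raise MappingError(
            f"ORF {orf.orf_id} is on {orf.transcript_id}, not {tx.transcript_id}"
        )
    tpos: list[int] = []
    for block in orf.blocks:
        for g in range(block.start, block.end):
            try:
                tpos.append(tx.genomic_to_tx(g))
            except MappingError as exc:
                raise MappingError(
                    f"ORF {orf.orf_id}: block [{block.start},{block.end}) "
                    f"outside exons of {tx.transcript_id}"
                ) from exc
    tpos.sort()
    ts, te = tpos[0], tpos[-1] + 1
    if te - ts != len(tpos):
        raise MappingError(
            f"ORF {orf.orf_id}: blocks not contiguous on transcript {tx.transcript_id}"
        )
    return ts, te


def orf_from_tx_interval(
    tx: TranscriptModel,
    tx_start: int,
    tx_end: int,
    orf_id: str,
    start_codon: str = "ATG",
    source: ProvenanceTag = ProvenanceTag(),
    category: Optional[ORFCategory] = None,
) -> ORFRecord:
    """Build an ORFRecord from a transcript-coordinate interval (stop included)."""
    blocks = tx.tx_interval_to_blocks(tx_start, tx_end)
    return ORFRecord(
        orf_id=orf_id,
        transcript_id=tx.transcript_id,
        blocks=blocks,
        start_codon=start_codon,
        source=source,
        category=category,
    )


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------


def _prescan_gtf(path: Path) -> None:
    """Cheap syntax check so parse errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: malformed GTF line {lineno} ({len(fields)} fields)")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer coordinate at line {lineno}") from exc
            if start < 1 or end < start:
                raise ParseError(f"{path}: invalid coordinates at line {lineno}")
            if fields[6] not in VALID_STRANDS:
                raise ParseError(f"{path}: unknown strand {fields[6]!r} at line {lineno}")


def read_transcript_models(path: str | Path) -> dict[str, TranscriptModel]:
    """Read an Ensembl-dialect GTF into TranscriptModel objects.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    CDS intervals are expressed in transcript coordinates; ``stop_codon``
    features are merged in, and when a coding transcript carries no
    stop_codon feature the CDS is extended 3 nt downstream (Ensembl GTFs
    exclude the stop codon from CDS rows).
    """
    import gffutils

    path = Path(path)
    _prescan_gtf(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    stops: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}

    def _tid(feat) -> str:
        try:
            return feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise ParseError(f"{path}: feature without transcript_id attribute") from exc

    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tid = _tid(feat)
        if tid not in meta:
            attrs = feat.attributes
            biotype = (
                attrs.get("transcript_biotype", attrs.get("gene_biotype", ["NA"]))
            )[0]
            meta[tid] = {
                "gene_id": attrs.get("gene_id", ["NA"])[0],
                "biotype": biotype,
            }
        start0, end0 = feat.start - 1, feat.end  # GTF -> 0-based half-open
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(
                GenomicInterval(feat.seqid, start0, end0, feat.strand)
            )
        elif feat.featuretype == "CDS":
            cds.setdefault(tid, []).append((start0, end0))
        else:
            stops.setdefault(tid, []).append((start0, end0))

    models: dict[str, TranscriptModel] = {}
    for tid in sorted(set(exons) | set(cds)):
        if tid not in exons:
            raise ValidationError(f"transcript {tid}: CDS without any exon line")
        chain = tuple(sorted(exons[tid], key=lambda e: e.start))
        _check_chain(chain, f"transcript {tid}")
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=meta[tid]["gene_id"],
            biotype=meta[tid]["biotype"],
            exons=chain,
        )
        cds_tx = None
        pieces = cds.get(tid, []) + stops.get(tid, [])
        if pieces:
            tpos: list[int] = []
            for s, e in pieces:
                for g in range(s, e):
                    try:
                        tpos.append(tx.genomic_to_tx(g))
                    except MappingError as exc:
                        raise ValidationError(
                            f"transcript {tid}: CDS base {g} outside exons"
                        ) from exc
            tpos.sort()
            if tpos[-1] - tpos[0] + 1 != len(tpos):
                raise ValidationError(f"transcript {tid}: CDS not contiguous on transcript")
            lo, hi = tpos[0], tpos[-1] + 1
            if tid not in stops:
                # Ensembl GTFs exclude the stop codon from CDS features.
                if hi + 3 <= tx.length:
                    hi += 3
            cds_tx = (lo, hi)
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=meta[tid]["gene_id"],
            biotype=meta[tid]["biotype"],
            exons=chain,
            cds_tx=cds_tx,
        )
    return models


def write_transcript_models(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as an Ensembl-dialect GTF (CDS excludes stop)."""
    lines: list[str] = []
    for tx in sorted(models, key=lambda t: t.transcript_id):
        attrs = (
            f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
            f'transcript_biotype "{tx.biotype}";'
        )
        g_start = min(e.start for e in tx.exons)
        g_end = max(e.end for e in tx.exons)
        lines.append(
            "\t".join(
                [tx.chrom, "orfkit", "transcript", str(g_start + 1), str(g_end),
                 ".", tx.strand, ".", attrs]
            )
        )
        for exon in tx.exons:
            lines.append(
                "\t".join(
                    [tx.chrom, "orfkit", "exon", str(exon.start + 1), str(exon.end),
                     ".", tx.strand, ".", attrs]
                )
            )
        if tx.cds_tx is not None:
            s, e = tx.cds_tx
            for block in tx.tx_interval_to_blocks(s, e - 3):
                lines.append(
                    "\t".join(
                        [tx.chrom, "orfkit", "CDS", str(block.start + 1), str(block.end),
                         ".", tx.strand, "0", attrs]
                    )
                )
            for block in tx.tx_interval_to_blocks(e - 3, e):
                lines.append(
                    "\t".join(
                        [tx.chrom, "orfkit", "stop_codon", str(block.start + 1),
                         str(block.end), ".", tx.strand, "0", attrs]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ORF call I/O
# ---------------------------------------------------------------------------


@dataclass
class RejectionReport:
    """Per-record invariant violations collected during a read."""

    rejected: list[tuple[str, str]] = field(default_factory=list)

    def add(self, record_id: str, reason: str) -> None:
        self.rejected.append((record_id, reason))

    def __len__(self) -> int:
        return len(self.rejected)


def _build_record(
    orf_id: str,
    transcript_id: str,
    chrom: str,
    strand: str,
    starts: Sequence[int],
    sizes: Sequence[int],
    start_codon: str,
    source: ProvenanceTag,
    category: Optional[str],
    aa_seq: Optional[str],
) -> ORFRecord:
    if strand not in VALID_STRANDS:
        raise ParseError(f"unknown strand symbol {strand!r}")
    blocks = tuple(
        GenomicInterval(chrom, s, s + n, strand) for s, n in zip(starts, sizes)
    )
    cat = ORFCategory(category) if category else None
    return ORFRecord(
        orf_id=orf_id,
        transcript_id=transcript_id,
        blocks=blocks,
        start_codon=start_codon,
        aa_seq=aa_seq or None,
        category=cat,
        source=source,
    )


def _read_orf_tsv(path: Path) -> tuple[list[ORFRecord], RejectionReport]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSV_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    records: list[ORFRecord] = []
    report = RejectionReport()
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            starts = [int(x) for x in d["block_starts"].split(",") if x != ""]
            sizes = [int(x) for x in d["block_sizes"].split(",") if x != ""]
        except ValueError:
            report.add(d.get("orf_id", "?"), "unparseable block columns")
            continue
        source = ProvenanceTag(
            dataset=d.get("dataset", ""),
            caller=d.get("caller", ""),
            replicate=d.get("replicate", ""),
            sample=d.get("sample", ""),
        )
        try:
            records.append(
                _build_record(
                    d["orf_id"], d["transcript_id"], d["chrom"], d["strand"],
                    starts, sizes, d["start_codon"], source,
                    d.get("category") or None, d.get("aa_seq") or None,
                )
            )
        except ValidationError as exc:
            report.add(d["orf_id"], str(exc))
    return records, report


def _read_orf_bed12(path: Path) -> tuple[list[ORFRecord], RejectionReport]:
    names = [
        "chrom", "chromStart", "chromEnd", "name", "score", "strand",
        "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
        "blockStarts",
    ]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, dtype=str,
                         comment="#", keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error wording varies
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] != 12:
        raise ParseError(f"{path}: expected 12 BED columns")
    records: list[ORFRecord] = []
    report = RejectionReport()
    for row in df.itertuples(index=False):
        name = row.name
        # name may carry "orf_id|transcript_id"
        orf_id, _, transcript_id = name.partition("|")
        try:
            chrom_start = int(row.chromStart)
            sizes = [int(x) for x in row.blockSizes.rstrip(",").split(",")]
            rel_starts = [int(x) for x in row.blockStarts.rstrip(",").split(",")]
        except ValueError:
            report.add(orf_id, "unparseable block columns")
            continue
        starts = [chrom_start + s for s in rel_starts]
        try:
            records.append(
                _build_record(
                    orf_id, transcript_id, row.chrom, row.strand, starts, sizes,
                    "NNN", ProvenanceTag(), None, None,
                )
            )
        except ValidationError as exc:
            report.add(orf_id, str(exc))
    return records, report


def read_orf_calls(
    path: str | Path, fmt: Optional[str] = None
) -> tuple[list[ORFRecord], RejectionReport]:
    """Read ORF calls from the TSV dialect or BED12.

    Record-level invariant violations are rejected (collected in the report);
    file-level syntax problems raise :class:`ParseError`.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed12" if path.suffix.lower() in (".bed", ".bed12") else "tsv"
    if fmt == "tsv":
        return _read_orf_tsv(path)
    if fmt == "bed12":
        return _read_orf_bed12(path)
    raise ValueError(f"unknown ORF call format {fmt!r}")


def write_orf_calls(
    records: Iterable[ORFRecord], path: str | Path, fmt: str = "tsv"
) -> None:
    """Write ORF calls in the TSV dialect or as BED12."""
    path = Path(path)
    records = list(records)
    if fmt == "tsv":
        rows = []
        for r in records:
            rows.append(
                {
                    "orf_id": r.orf_id,
                    "transcript_id": r.transcript_id,
                    "chrom": r.chrom,
                    "strand": r.strand,
                    "block_starts": ",".join(str(b.start) for b in r.blocks),
                    "block_sizes": ",".join(str(len(b)) for b in r.blocks),
                    "start_codon": r.start_codon,
                    "dataset": r.source.dataset,
                    "caller": r.source.caller,
                    "replicate": r.source.replicate,
                    "sample": r.source.sample,
                    "category": r.category.value if r.category else "",
                    "aa_seq": r.aa_seq or "",
                }
            )
        pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif fmt == "bed12":
        lines = []
        for r in records:
            start = r.blocks[0].start
            end = r.blocks[-1].end
            name = f"{r.orf_id}|{r.transcript_id}" if r.transcript_id else r.orf_id
            lines.append(
                "\t".join(
                    [
                        r.chrom, str(start), str(end), name, "0", r.strand,
                        str(start), str(end), "0", str(len(r.blocks)),
                        ",".join(str(len(b)) for b in r.blocks),
                        ",".join(str(b.start - start) for b in r.blocks),
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown ORF call format {fmt!r}")
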