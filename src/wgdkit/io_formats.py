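"""Readers and writers for the external formats the pipeline touches.

Conventions are fixed here once: coordinates are GFF3-style (1-based,
inclusive) at every file boundary, while gene *ranks* — the order of genes
along a chromosome or scaffold, which is the coordinate system colinearity
chaining works in — are 0-based and consecutive per sequence. Hit tables use
the common 12-column tab-separated dialect (query, subject, %identity,
alignment length, mismatches, gap opens, qstart, qend, sstart, send,
E-value, bit score). Genetic maps are CSV with a ``marker,lg,cM,flank``
header.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "HitRecord",
    "HitTable",
    "MarkerRecord",
    "FormatError",
    "read_gff_genes",
    "write_gff_genes",
    "read_fasta",
    "write_fasta",
    "read_hits_tab",
    "write_hits_tab",
    "read_genetic_map",
    "write_genetic_map",
    "write_block_outputs",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: 1-based inclusive coordinates plus its order rank."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")


def _assign_ranks(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Sort by (seq_id, start, end, gene_id) and assign 0-based ranks per seq."""
    out: list[GeneModel] = []
    by_seq: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    for seq_id in sorted(by_seq):
        ordered = sorted(by_seq[seq_id], key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(ordered):
            out.append(replace(g, rank=rank))
    return out


@dataclass
class GenomeAnnotation:
    """Ordered gene models of one genome, with optional sequences.

    ``cds`` maps gene_id -> coding nucleotide sequence (in-frame, no stop);
    ``chromosomes`` optionally holds full nucleotide sequences per seq_id so
    that synthetic maps and flank extraction are possible.
    """

    genome_id: str
    genes: list[GeneModel]
    cds: dict[str, str] = field(default_factory=dict)
    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate gene ids: {dup[:5]}")
        for gid, seq in self.cds.items():
            if len(seq) % 3 != 0:
                raise FormatError(f"CDS of {gid} has length {len(seq)} not divisible by 3")

    @classmethod
    def from_genes(
        cls,
        genome_id: str,
        genes: Iterable[GeneModel],
        cds: Mapping[str, str] | None = None,
        chromosomes: Mapping[str, str] | None = None,
    ) -> "GenomeAnnotation":
        return cls(
            genome_id,
            _assign_ranks(genes),
            dict(cds or {}),
            dict(chromosomes or {}),
        )

    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def seq_ids(self) -> list[str]:
        return sorted({g.seq_id for g in self.genes})

    def genes_on(self, seq_id: str) -> list[GeneModel]:
        return sorted(
            (g for g in self.genes if g.seq_id == seq_id), key=lambda g: g.rank
        )

    def protein(self, gene_id: str) -> str:
        """Translate the stored CDS (standard code, no trailing stop)."""
        seq = self.cds.get(gene_id)
        if seq is None:
            raise KeyError(f"no CDS stored for gene {gene_id}")
        return str(Seq(seq).translate())

    def proteins(self) -> dict[str, str]:
        return {gid: self.protein(gid) for gid in self.cds}


@dataclass(frozen=True)
class HitRecord:
    """One row of the 12-column tabular hit format."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise FormatError(f"{self.query_id}/{self.subject_id}: negative E-value")
        if self.bit_score <= 0:
            raise FormatError(f"{self.query_id}/{self.subject_id}: non-positive bit score")

    @property
    def is_self_hit(self) -> bool:
        return self.query_id == self.subject_id


@dataclass
class HitTable:
    """A collection of pairwise protein hits."""

    records: list[HitRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def non_self(self) -> "HitTable":
        return HitTable([r for r in self.records if not r.is_self_hit])

    def filtered(self, evalue_cutoff: float) -> "HitTable":
        return HitTable([r for r in self.records if r.e_value <= evalue_cutoff])


@dataclass(frozen=True)
class MarkerRecord:
    """A genetic-map marker: linkage group, cM position, flanking sequence."""

    marker_id: str
    linkage_group: int
    position: float
    flank: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise FormatError(f"marker {self.marker_id}: negative cM position")
        if self.linkage_group < 1:
            raise FormatError(f"marker {self.marker_id}: linkage group must be >= 1")


# ---------------------------------------------------------------------------
# GFF3 (gene-level records only)
# ---------------------------------------------------------------------------


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff_genes(path: str | Path, feature: str = "gene") -> GenomeAnnotation:
    """Read gene-level records from a GFF3 file.

    Only rows whose type column equals ``feature`` are consumed; the feature
    hierarchy (mRNA/exon/CDS) is deliberately ignored. Genes are sorted by
    (seq_id, start) and given consecutive 0-based ranks per sequence.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    genome_id = path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != feature:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("ID") or attributes.get("Name")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: record has no ID attribute")
            try:
                genes.append(GeneModel(gene_id, seq_id, start, end, strand))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return GenomeAnnotation.from_genes(genome_id, genes)


def write_gff_genes(
    annotation: GenomeAnnotation, path: str | Path, feature: str = "gene"
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes, key=lambda g: (g.seq_id, g.rank)):
            fh.write(
                f"{g.seq_id}\twgdkit\t{feature}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


# ---------------------------------------------------------------------------
# 12-column tabular hits
# ---------------------------------------------------------------------------

_HIT_COLUMNS = 12


def read_hits_tab(path: str | Path) -> HitTable:
    """Read a 12-column tab-separated hit table.

    Extra columns beyond 12 are ignored with a warning; fewer than 12 is an
    error naming the offending row.
    """
    path = Path(path)
    records: list[HitRecord] = []
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < _HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, got {len(cols)}"
                )
            if len(cols) > _HIT_COLUMNS and not warned_extra:
                warnings.warn(
                    f"{path}: rows have more than {_HIT_COLUMNS} columns; extras ignored",
                    stacklevel=2,
                )
                warned_extra = True
            try:
                records.append(
                    HitRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=float(cols[2]),
                        alignment_length=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        q_start=int(cols[6]),
                        q_end=int(cols[7]),
                        s_start=int(cols[8]),
                        s_end=int(cols[9]),
                        e_value=float(cols[10]),
                        bit_score=float(cols[11]),
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return HitTable(records)


def write_hits_tab(hits: HitTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in hits:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        f"{r.percent_identity:.2f}",
                        str(r.alignment_length),
                        str(r.mismatches),
                        str(r.gap_opens),
                        str(r.q_start),
                        str(r.q_end),
                        str(r.s_start),
                        str(r.s_end),
                        f"{r.e_value:.3g}",
                        f"{r.bit_score:.1f}",
                    ]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# genetic map CSV
# ---------------------------------------------------------------------------

_MAP_HEADER = ["marker", "lg", "cM", "flank"]


def read_genetic_map(
    path: str | Path, min_flank_length: int = 100
) -> list[MarkerRecord]:
    """Read a genetic-map CSV (header ``marker,lg,cM,flank``).

    Markers whose flank is shorter than ``min_flank_length`` are rejected
    with a warning; a duplicate (lg, marker) combination or a negative cM
    is an error.
    """
    path = Path(path)
    records: list[MarkerRecord] = []
    seen: set[tuple[int, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _MAP_HEADER:
            raise FormatError(
                f"{path}: expected header {','.join(_MAP_HEADER)!r}, got {header}"
            )
        for lineno, row in enumerate(reader, 2):
            if not row:
                continue
            if len(row) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            marker_id, lg_s, cm_s, flank = (f.strip() for f in row)
            try:
                lg = int(lg_s)
                cm = float(cm_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric lg/cM") from exc
            key = (lg, marker_id)
            if key in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate marker {marker_id} on LG{lg}"
                )
            seen.add(key)
            if len(flank) < min_flank_length:
                warnings.warn(
                    f"{path}:{lineno}: marker {marker_id} flank shorter than "
                    f"{min_flank_length} bp; record rejected",
                    stacklevel=2,
                )
                continue
            try:
                records.append(MarkerRecord(marker_id, lg, cm, flank))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_genetic_map(markers: Sequence[MarkerRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MAP_HEADER)
        for m in markers:
            writer.writerow([m.marker_id, m.linkage_group, f"{m.position:.6g}", m.flank])
    return path


# ---------------------------------------------------------------------------
# synteny block outputs (collinearity text + circular-plot link file)
# ---------------------------------------------------------------------------


def write_block_outputs(
    blocks: Sequence,
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    outdir: str | Path,
    prefix: str = "blocks",
) -> tuple[Path, Path]:
    """Write a collinearity-style text file and a link file for the blocks.

    The collinearity file carries one header line per block followed by one
    anchor pair per line. The link file carries one line per block with the
    min/max genomic coordinates spanned by its member genes on each side,
    suitable for circular-plot software.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coll_path = outdir / f"{prefix}.collinearity"
    link_path = outdir / f"{prefix}.links"
    genes_a = ann_a.by_id()
    genes_b = ann_b.by_id()
    with open(coll_path, "w") as coll, open(link_path, "w") as link:
        coll.write("# wgdkit collinearity: block_id\torientation\tseq_a\tseq_b\tn_anchors\n")
        link.write("# seq_a\tstart_a\tend_a\tseq_b\tstart_b\tend_b\tblock_id\n")
        for i, block in enumerate(blocks):
            coll.write(
                f"## block {i}\t{block.orientation}\t{block.seq_a}\t{block.seq_b}\t"
                f"{len(block.anchors)}\n"
            )
            for anchor in block.anchors:
                coll.write(
                    f"{i}\t{anchor.gene_a}\t{anchor.gene_b}\t{anchor.score:.1f}\n"
                )
            ga = [genes_a[a.gene_a] for a in block.anchors]
            gb = [genes_b[a.gene_b] for a in block.anchors]
            link.write(
                f"{block.seq_a}\t{min(g.start for g in ga)}\t{max(g.end for g in ga)}\t"
                f"{block.seq_b}\t{min(g.start for g in gb)}\t{max(g.end for g in gb)}\t"
                f"{i}\n"
            )
    return coll_path, link_path
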