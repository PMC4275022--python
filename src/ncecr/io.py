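"""Readers and writers for the plain-text genomics formats used here.

FASTA via Bio.SeqIO, MAF via Bio.AlignIO, GFF3 via gffutils, BED via
pandas; axt (UCSC pairwise blocks) has a small dedicated reader since no
installed library provides one. All coordinates follow the package
convention: 0-based half-open internally, 1-based inclusive in
human-readable output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq, reverse_complement as _bio_revcomp
from Bio.SeqRecord import SeqRecord

from .alignment import PairwiseAlignment
from .intervals import GeneModel, GenomicInterval


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def reverse_complement(seq: str) -> str:
    return str(_bio_revcomp(seq))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_SEQ_CHARS = frozenset("ABCDEFGHIKLMNPQRSTUVWXYZabcdefghiklmnpqrstuvwxyz*.-")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: residues}`` mapping.

    Names are the first whitespace-delimited token of each header and are
    case-sensitive; residues are upper-cased. Duplicate names and records
    appearing before the first header are errors (the latter with the
    offending line number).
    """
    path = os.fspath(path)
    _validate_fasta_structure(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate sequence name {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def _validate_fasta_structure(path: str) -> None:
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                seen_header = True
                continue
            if not seen_header:
                raise ParseError(f"{path}:{lineno}: expected FASTA header line starting with '>'")
            bad = set(stripped) - _SEQ_CHARS
            if bad:
                raise ParseError(
                    f"{path}:{lineno}: invalid residue characters {sorted(bad)}"
                )


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: int = 0


def identity_to_score(identity: float) -> int:
    """BED score column: identity x 1000, rounded, capped at 1000."""
    return min(1000, int(round(identity * 1000)))


def read_bed(path: str | os.PathLike) -> list[BedRecord]:
    path = os.fspath(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    records = []
    for row in df.itertuples(index=False):
        fields = list(row)
        if len(fields) < 3:
            raise ParseError(f"{path}: BED line with fewer than 3 fields")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 and pd.notna(fields[3]) else "."
        score = int(float(fields[4])) if len(fields) > 4 and pd.notna(fields[4]) else 0
        strand = fields[5] if len(fields) > 5 and pd.notna(fields[5]) else "."
        records.append(BedRecord(GenomicInterval(chrom, start, end, strand), name, score))
    return records


def write_bed(records: list[BedRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name}\t{rec.score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Pairwise alignments: MAF (read/write) and axt (read-only)
# ---------------------------------------------------------------------------


def read_alignment(path: str | os.PathLike, dialect: str = "maf") -> list[PairwiseAlignment]:
    """Read pairwise alignment blocks from a MAF or axt file.

    Every block must have exactly two rows; row-length mismatches and
    all-gap columns are rejected via the PairwiseAlignment invariants.
    MAF is the canonical dialect (also written); axt is read-only.
    """
    path = os.fspath(path)
    if dialect == "maf":
        return _read_maf(path)
    if dialect == "axt":
        return _read_axt(path)
    raise ValueError(f"unknown alignment dialect {dialect!r}; expected 'maf' or 'axt'")


def _read_maf(path: str) -> list[PairwiseAlignment]:
    out = []
    for block in AlignIO.parse(path, "maf"):
        if len(block) != 2:
            raise ParseError(f"{path}: MAF block with {len(block)} rows; expected pairwise (2)")
        ref, query = block
        for rec in (ref, query):
            if rec.annotations.get("strand", 1) not in (1, "+"):
                raise ParseError(
                    f"{path}: row {rec.id!r} on reverse strand; only forward-strand rows supported"
                )
        try:
            aln = PairwiseAlignment(
                ref.id,
                query.id,
                str(ref.seq),
                str(query.seq),
                int(ref.annotations["start"]),
                int(query.annotations["start"]),
            )
        except ValueError as exc:
            raise ParseError(f"{path}: invalid MAF block: {exc}") from exc
        out.append(aln)
    return out


def _read_axt(path: str) -> list[PairwiseAlignment]:
    """Read UCSC axt blocks: a header line, a reference row and a query row.

    Header: ``num refName refStart refEnd queryName queryStart queryEnd strand score``
    with 1-based inclusive coordinates.
    """
    out = []
    with open(path) as fh:
        lines = [(i, ln.rstrip("\n")) for i, ln in enumerate(fh, start=1)]
    content = [(i, ln) for i, ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if len(content) % 3:
        lineno = content[-1][0]
        raise ParseError(f"{path}:{lineno}: truncated axt block")
    for k in range(0, len(content), 3):
        (hno, header), (_, ref_row), (qno, query_row) = content[k : k + 3]
        fields = header.split()
        if len(fields) < 9:
            raise ParseError(f"{path}:{hno}: axt header needs 9 fields, got {len(fields)}")
        _, ref_name, ref_start, _, query_name, query_start, _, strand, _ = fields[:9]
        if strand != "+":
            raise ParseError(f"{path}:{hno}: only forward-strand axt blocks supported")
        try:
            aln = PairwiseAlignment(
                ref_name, query_name, ref_row, query_row,
                int(ref_start) - 1, int(query_start) - 1,
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{qno}: invalid axt block: {exc}") from exc
        out.append(aln)
    return out


def write_maf(alignments: list[PairwiseAlignment], path: str | os.PathLike) -> None:
    blocks = []
    for aln in alignments:
        ref = SeqRecord(Seq(aln.ref_text), id=aln.ref_name)
        ref.annotations = {
            "start": aln.ref_offset,
            "size": aln.ref_length,
            "strand": 1,
            "srcSize": aln.ref_offset + aln.ref_length,
        }
        query = SeqRecord(Seq(aln.query_text), id=aln.query_name)
        query.annotations = {
            "start": aln.query_offset,
            "size": aln.query_length,
            "strand": 1,
            "srcSize": aln.query_offset + aln.query_length,
        }
        blocks.append(MultipleSeqAlignment([ref, query]))
    AlignIO.write(blocks, os.fspath(path), "maf")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def read_gene_model(path: str | os.PathLike, gene_id: str | None = None) -> GeneModel:
    """Read a single-isoform gene model (gene + exons + UTRs) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        os.fspath(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = list(db.features_of_type("gene"))
    if gene_id is not None:
        genes = [g for g in genes if g.id == gene_id or g.attributes.get("ID", [None])[0] == gene_id]
    if not genes:
        raise ParseError(f"{path}: no gene feature" + (f" with ID {gene_id!r}" if gene_id else ""))
    if len(genes) > 1:
        raise ParseError(f"{path}: multiple gene features; pass gene_id to pick one")
    g = genes[0]
    strand = g.strand if g.strand in ("+", "-") else "."
    gene_iv = GenomicInterval(g.seqid, g.start - 1, g.end, strand)
    exons = tuple(
        GenomicInterval(f.seqid, f.start - 1, f.end, strand)
        for f in db.children(g, featuretype=("exon", "CDS"))
        if f.featuretype == "exon"
    )
    utrs = tuple(
        GenomicInterval(f.seqid, f.start - 1, f.end, strand)
        for f in db.children(g, featuretype=("five_prime_UTR", "three_prime_UTR", "UTR"))
    )
    return GeneModel(gene=gene_iv, exons=exons, utrs=utrs)


def write_gene_model_gff3(model: GeneModel, path: str | os.PathLike, gene_id: str = "gene1") -> None:
    chrom = model.gene.chrom
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        g1, g2 = model.gene.to_1based()
        fh.write(
            f"{chrom}\tncecr\tgene\t{g1}\t{g2}\t.\t{model.strand}\t.\tID={gene_id}\n"
        )
        for i, exon in enumerate(model.exons, start=1):
            e1, e2 = exon.to_1based()
            fh.write(
                f"{chrom}\tncecr\texon\t{e1}\t{e2}\t.\t{model.strand}\t.\t"
                f"ID={gene_id}.exon{i};Parent={gene_id}\n"
            )
        for i, utr in enumerate(model.utrs, start=1):
            u1, u2 = utr.to_1based()
            fh.write(
                f"{chrom}\tncecr\tUTR\t{u1}\t{u2}\t.\t{model.strand}\t.\t"
                f"ID={gene_id}.utr{i};Parent={gene_id}\n"
            )
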