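"""Windowed percent-identity profiles and conserved-region (ECR) calling.

The screen mirrors the behaviour of conservation-profile browsers: a
window of W reference residues slides one residue at a time over a
pairwise alignment; windows whose column identity meets the threshold
are merged into evolutionary conserved regions (ECRs), which are then
classified against a gene model as upstream / intronic / downstream /
exonic / UTR and labelled in transcription order (U1.., In1.., D1..).

Identity is computed over the alignment columns spanned by the window's
reference residues, so query-only insertions inside the span count as
mismatch columns (indels are penalized, as in Vista-family scorers).
Default thresholds are the established selection parameters for this
kind of screen: length >= 100 bp and identity >= 75%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import PairwiseAlignment
from .intervals import GeneModel, GenomicInterval, interval_overlap
from .io import BedRecord, identity_to_score

DEFAULT_MIN_LENGTH = 100
DEFAULT_MIN_IDENTITY = 0.75

#: label prefix per location class, following the U*/In*/D* naming scheme
SERIES_PREFIX = {
    "upstream": "U",
    "intronic": "In",
    "downstream": "D",
    "exonic": "E",
    "utr": "UTR",
}


@dataclass
class ConservationProfile:
    """Sliding-window identity over a pairwise alignment.

    ``identity[p]`` is the window identity for the window of ``window``
    reference residues starting at reference-local position ``p``; it is
    defined for ``p = 0 .. ref_length - window`` (empty if the alignment
    is shorter than the window).
    """

    alignment: PairwiseAlignment
    window: int
    identity: np.ndarray

    @property
    def column_matches(self) -> np.ndarray:
        return self.alignment.match_columns


@dataclass
class ECR:
    """A called evolutionary conserved region.

    Coordinates are genomic (alignment offsets applied) on both the
    reference and the query; ``identity`` is the column identity over the
    region's alignment span.
    """

    ref: GenomicInterval
    query: GenomicInterval
    identity: float
    location_class: str | None = None
    label: str | None = None

    @property
    def length(self) -> int:
        return self.ref.length


def windowed_identity(aln: PairwiseAlignment, window: int) -> ConservationProfile:
    """Compute the per-position window identity profile of an alignment.

    A window covers ``window`` consecutive reference residues; its
    identity is (# match columns in the spanned column range) / (# columns
    in the range). Gap and N columns count as mismatches.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    n = aln.ref_length
    if n < window:
        warnings.warn(
            f"alignment has {n} reference residues, shorter than window {window}; "
            "profile is empty",
            stacklevel=2,
        )
        return ConservationProfile(aln, window, np.empty(0, dtype=float))
    cols = aln.ref_columns
    cum = np.concatenate([[0], np.cumsum(aln.match_columns, dtype=np.int64)])
    starts = cols[: n - window + 1]
    ends = cols[window - 1 :]
    matches = cum[ends + 1] - cum[starts]
    ncols = ends - starts + 1
    return ConservationProfile(aln, window, matches / ncols)


def _span_identity(aln: PairwiseAlignment, start_local: int, end_local: int) -> float:
    """Column identity of the alignment span covering a reference range."""
    c1 = aln.column_of_ref(start_local)
    c2 = aln.column_of_ref(end_local - 1)
    m = aln.match_columns[c1 : c2 + 1]
    return float(m.sum() / len(m))


def call_ecrs(
    profile: ConservationProfile,
    min_len: int = DEFAULT_MIN_LENGTH,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[ECR]:
    """Call ECRs from a window-identity profile.

    Overlapping qualifying windows (identity >= ``min_identity``) are
    merged single-linkage (touching end-to-start does not merge, half-open
    semantics); each merged region is trimmed at both ends to the
    outermost match column, and regions of reference length >= ``min_len``
    are reported sorted by start. Query coordinates are projected through
    the alignment column map.
    """
    aln = profile.alignment
    W = profile.window
    qual = np.flatnonzero(profile.identity >= min_identity)
    if qual.size == 0:
        return []
    match_at_ref = aln.match_columns[aln.ref_columns]  # per reference residue

    regions: list[tuple[int, int]] = []
    run_start = int(qual[0])
    run_end = int(qual[0]) + W  # half-open on reference positions
    for p in qual[1:]:
        p = int(p)
        if p < run_end:  # windows overlap -> merge
            run_end = p + W
        else:
            regions.append((run_start, run_end))
            run_start, run_end = p, p + W
    regions.append((run_start, run_end))

    out: list[ECR] = []
    for s, e in regions:
        seg = match_at_ref[s:e]
        if not seg.any():
            continue
        first = s + int(np.argmax(seg))
        last = e - 1 - int(np.argmax(seg[::-1]))
        if last + 1 - first < min_len:
            continue
        ref_iv = aln.ref_interval(first, last + 1)
        query_iv = aln.query_interval_for_ref(first, last + 1)
        out.append(ECR(ref_iv, query_iv, _span_identity(aln, first, last + 1)))
    return out


def classify_location(ecr: ECR | GenomicInterval, gene: GeneModel) -> str:
    """Locate an ECR relative to a gene model.

    Exon overlap wins, then UTR overlap, then containment/overlap with the
    gene span (intronic). Outside the gene, upstream/downstream follow the
    transcription strand: for a minus-strand gene, genomically rightward
    intervals are upstream.
    """
    iv = ecr.ref if isinstance(ecr, ECR) else ecr
    if iv.chrom != gene.gene.chrom:
        raise ValueError(
            f"interval chromosome {iv.chrom!r} differs from gene chromosome {gene.gene.chrom!r}"
        )
    if any(interval_overlap(iv, exon) for exon in gene.exons):
        return "exonic"
    if any(interval_overlap(iv, utr) for utr in gene.utrs):
        return "utr"
    if interval_overlap(iv, gene.gene):
        return "intronic"
    if iv.start >= gene.gene.end:
        return "downstream" if gene.strand == "+" else "upstream"
    return "upstream" if gene.strand != "-" else "downstream"


def label_ecrs(ecrs: list[ECR], gene: GeneModel) -> list[ECR]:
    """Assign location classes and series labels (U*/In*/D*) in place.

    Labels are numbered along the direction of transcription within each
    series, reproducing the conventional locus naming (U1 is the furthest
    element reached first when reading in transcription orientation for a
    plus-strand gene the leftmost upstream element).
    """
    for ecr in ecrs:
        ecr.location_class = classify_location(ecr, gene)
    forward = gene.strand != "-"
    ordered = sorted(ecrs, key=lambda e: e.ref.start, reverse=not forward)
    counters: dict[str, int] = {}
    for ecr in ordered:
        cls = ecr.location_class or "intronic"
        counters[cls] = counters.get(cls, 0) + 1
        ecr.label = f"{SERIES_PREFIX[cls]}{counters[cls]}"
    return ecrs


def ecr_reference_sequence(aln: PairwiseAlignment, ecr: ECR) -> str:
    """Ungapped reference sequence underlying an ECR."""
    start = ecr.ref.start - aln.ref_offset
    return aln.ref_sequence[start : start + ecr.length]


def ecrs_to_bed(ecrs: list[ECR]) -> list[BedRecord]:
    return [
        BedRecord(e.ref, e.label or f"ecr{i}", identity_to_score(e.identity))
        for i, e in enumerate(ecrs, start=1)
    ]


def write_ecr_tsv(ecrs: list[ECR], aln: PairwiseAlignment, path) -> None:
    """Human-readable ECR table (1-based inclusive coordinates) with the
    underlying reference sequence, consumable by the non-coding filter."""
    with open(path, "w") as fh:
        fh.write(
            "label\tref_chrom\tref_start\tref_end\tquery_chrom\tquery_start\tquery_end\t"
            "identity\tlength\tlocation_class\tsequence\n"
        )
        for i, e in enumerate(ecrs, start=1):
            r1, r2 = e.ref.to_1based()
            q1, q2 = e.query.to_1based()
            fh.write(
                f"{e.label or f'ecr{i}'}\t{e.ref.chrom}\t{r1}\t{r2}\t"
                f"{e.query.chrom}\t{q1}\t{q2}\t{e.identity:.4f}\t{e.length}\t"
                f"{e.location_class or '.'}\t{ecr_reference_sequence(aln, e)}\n"
            )
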