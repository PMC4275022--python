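"""Coding-potential screen for candidate conserved elements.

An element is flagged coding-suspect if it overlaps any annotated
transcript/EST interval (zero tolerance: any overlap > 0 bp) or contains
an open reading frame longer than the threshold (strictly more than 20
amino acids by default). ORFs require both an ATG and an in-frame stop
within the element; amino-acid length counts the codons strictly between
start and stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass

from .conservation import ECR
from .intervals import GenomicInterval, interval_overlap
from .io import reverse_complement

DEFAULT_MAX_ORF_AA = 20

_START = "ATG"
_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfRecord:
    """An ATG-to-stop open reading frame on an element sequence.

    ``start``/``end`` are 0-based half-open forward-strand coordinates
    covering the ATG through the stop codon inclusive; ``frame`` is the
    reading frame (0-2) on the ORF's own strand; ``aa_length`` counts the
    codons strictly between start and stop codons, so the interval length
    is ``3 * aa_length + 6``.
    """

    start: int
    end: int
    strand: str
    frame: int
    aa_length: int


@dataclass(frozen=True)
class NoncodingCall:
    """Outcome of the coding-potential screen with the reasons that fired."""

    noncoding: bool
    reasons: tuple[str, ...]
    max_orf_aa: int
    annotation_overlap_bp: int


def _next_stop_table(seq: str) -> list[int]:
    """next_stop[i] = smallest j >= i with j = i mod 3 and seq[j:j+3] a stop, else -1.

    N never forms part of a recognized stop codon.
    """
    n = len(seq)
    nxt = [-1] * n
    carry = {0: -1, 1: -1, 2: -1}
    for i in range(n - 1, -1, -1):
        f = i % 3
        if i + 3 <= n and seq[i : i + 3] in _STOPS:
            carry[f] = i
        nxt[i] = carry[f]
    return nxt


def find_orfs(seq: str) -> list[OrfRecord]:
    """All ATG-to-first-in-frame-stop ORFs in all six frames.

    Nested ORFs from internal ATGs are all reported. Open-ended runs
    (ATG without a downstream in-frame stop) are not counted. Records are
    sorted by forward-strand start, then strand (+ before -).
    """
    seq = seq.upper()
    n = len(seq)
    out: list[OrfRecord] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else reverse_complement(seq)
        nxt = _next_stop_table(s)
        for i in range(n - 2):
            if s[i : i + 3] != _START:
                continue
            j = nxt[i + 3] if i + 3 < n else -1
            if j < 0:
                continue
            aa = (j - i) // 3 - 1
            if aa < 1:
                continue
            if strand == "+":
                start, end = i, j + 3
            else:
                start, end = n - (j + 3), n - i
            out.append(OrfRecord(start, end, strand, i % 3, aa))
    out.sort(key=lambda o: (o.start, o.strand, o.end))
    return out


def is_noncoding(
    ecr: ECR | GenomicInterval,
    element_seq: str,
    transcript_annotations: list[GenomicInterval] = (),
    max_orf_aa: int = DEFAULT_MAX_ORF_AA,
) -> NoncodingCall:
    """Screen one element for coding potential.

    Coding-suspect iff it overlaps any annotation interval by > 0 bp or
    contains an ORF of strictly more than ``max_orf_aa`` amino acids
    (a 20-aa ORF passes at the default threshold). Adding annotations can
    only flip non-coding -> coding-suspect, never the reverse.
    """
    iv = ecr.ref if isinstance(ecr, ECR) else ecr
    overlap = max(
        (interval_overlap(iv, ann) for ann in transcript_annotations), default=0
    )
    orfs = find_orfs(element_seq)
    max_aa = max((o.aa_length for o in orfs), default=0)
    reasons = []
    if overlap > 0:
        reasons.append("annotation overlap")
    if max_aa > max_orf_aa:
        reasons.append(f"ORF>{max_orf_aa}aa")
    return NoncodingCall(not reasons, tuple(reasons), max_aa, overlap)
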