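"""Position-weight-matrix scanning with matrix and core similarity.

The scoring follows the information-weighted similarity used by the
classical matrix-scan tools: each matrix position i carries an
information weight ``w_i = sum_b f_ib * log2(4 f_ib)`` (0 bits for a
uniform position, 2 bits for an invariant one), and a window scores

    matrix_similarity = sum_i w_i * f_i,window_i / sum_i w_i * max_b f_ib

so the per-position consensus scores exactly 1. Core similarity is the
same quantity restricted to the matrix core: the contiguous run of
(by default 4) positions with maximal summed information weight,
leftmost on ties. Scanning covers both strands; reverse-strand hits are
reported in forward coordinates.
"""

from __future__ import annotations

import io as _stdio
import os
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .io import BedRecord, identity_to_score, reverse_complement
from .intervals import GenomicInterval

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4

DEFAULT_MIN_MATRIX_SIM = 0.80
DEFAULT_MIN_CORE_SIM = 0.75
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_CORE_LENGTH = 4


def information_weights(freqs: np.ndarray) -> np.ndarray:
    """Per-position information content in bits, clipped to [0, 2].

    ``freqs`` is an (L, 4) row-normalized frequency matrix (rows must sum
    to 1; zero entries are allowed and contribute 0 to the sum).
    """
    F = np.asarray(freqs, dtype=float)
    if F.ndim != 2 or F.shape[1] != 4:
        raise ValueError(f"expected an (L, 4) matrix, got shape {F.shape}")
    if np.any(F < 0) or not np.allclose(F.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("frequency rows must be non-negative and sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(F > 0, F * np.log2(4 * F), 0.0)
    return np.clip(terms.sum(axis=1), 0.0, 2.0)


class PWM:
    """A position weight matrix with information weights and a core.

    Built either from a row-normalized frequency matrix or, via
    :meth:`from_counts`, from a count matrix with a per-cell pseudocount
    (so every frequency is strictly positive).
    """

    def __init__(
        self,
        name: str,
        tf_label: str,
        probs: np.ndarray,
        core_length: int = DEFAULT_CORE_LENGTH,
        counts: np.ndarray | None = None,
    ):
        self.name = name
        self.tf_label = tf_label
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError(f"PWM {name}: expected (L, 4) frequencies, got {probs.shape}")
        if np.any(probs <= 0):
            raise ValueError(f"PWM {name}: frequencies must be strictly positive (use pseudocounts)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {name}: frequency rows must sum to 1")
        self.probs = probs / probs.sum(axis=1, keepdims=True)
        self.counts = None if counts is None else np.asarray(counts, dtype=float)
        self.weights = information_weights(self.probs)
        core_length = min(core_length, len(self))
        sums = np.convolve(self.weights, np.ones(core_length), mode="valid")
        self.core_start = int(np.argmax(sums))  # argmax is leftmost on ties
        self.core_length = core_length

    @classmethod
    def from_counts(
        cls,
        name: str,
        tf_label: str,
        counts: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        core_length: int = DEFAULT_CORE_LENGTH,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError(f"PWM {name}: negative counts")
        padded = counts + pseudocount
        probs = padded / padded.sum(axis=1, keepdims=True)
        return cls(name, tf_label, probs, core_length=core_length, counts=counts)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @cached_property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @cached_property
    def _probs_with_n(self) -> np.ndarray:
        """(L, 5) frequency table where column 4 (N) is the row minimum."""
        return np.hstack([self.probs, self.probs.min(axis=1, keepdims=True)])

    @cached_property
    def _max_score(self) -> float:
        return float((self.weights * self.probs.max(axis=1)).sum())

    @cached_property
    def _core_max_score(self) -> float:
        sl = slice(self.core_start, self.core_start + self.core_length)
        return float((self.weights[sl] * self.probs[sl].max(axis=1)).sum())


@dataclass(frozen=True)
class MotifHit:
    """One matrix match on a sequence, in forward-strand coordinates."""

    sequence_name: str
    start: int
    strand: str
    matrix: str
    tf_label: str
    matrix_similarity: float
    core_similarity: float
    width: int

    @property
    def end(self) -> int:
        return self.start + self.width

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.sequence_name, self.start, self.end, self.strand)


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r} in sequence") from exc


def _window_scores(pwm: PWM, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(matrix_similarity, core_similarity) for every window of len(pwm)."""
    L = len(pwm)
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)  # (n, L)
    vals = pwm._probs_with_n[np.arange(L), windows]  # (n, L)
    mat = (pwm.weights * vals).sum(axis=1)
    mat = mat / pwm._max_score if pwm._max_score > 0 else np.ones(n)
    sl = slice(pwm.core_start, pwm.core_start + pwm.core_length)
    core = (pwm.weights[sl] * vals[:, sl]).sum(axis=1)
    core = core / pwm._core_max_score if pwm._core_max_score > 0 else np.ones(n)
    return mat, core


def matrix_similarity(pwm: PWM, window: str) -> float:
    """Information-weighted similarity of one window to the matrix.

    Equals 1 iff the window carries the per-position argmax base at every
    position with positive weight; N residues are scored with the minimum
    frequency of their position (penalized).
    """
    if len(window) != len(pwm):
        raise ValueError(f"window length {len(window)} != matrix length {len(pwm)}")
    mat, _ = _window_scores(pwm, _encode(window))
    return float(mat[0])


def core_similarity(pwm: PWM, window: str) -> float:
    """Similarity restricted to the matrix core positions."""
    if len(window) != len(pwm):
        raise ValueError(f"window length {len(window)} != matrix length {len(pwm)}")
    _, core = _window_scores(pwm, _encode(window))
    return float(core[0])


def scan(
    seq: str,
    pwm: PWM,
    min_matrix_sim: float = DEFAULT_MIN_MATRIX_SIM,
    min_core_sim: float = DEFAULT_MIN_CORE_SIM,
    sequence_name: str = "seq",
) -> list[MotifHit]:
    """Score every window on both strands and return the passing hits.

    A hit requires core_similarity >= ``min_core_sim`` AND
    matrix_similarity >= ``min_matrix_sim`` (the core acts as the fast
    pre-filter in the classical tools). Reverse-strand hits carry the
    forward-strand start of the window. Hits are sorted by start with +
    before - as the tiebreak.
    """
    L = len(pwm)
    n = len(seq)
    if n < L:
        return []
    hits: list[MotifHit] = []
    fwd = _encode(seq)
    rev = _encode(reverse_complement(seq))
    for strand, codes in (("+", fwd), ("-", rev)):
        mat, core = _window_scores(pwm, codes)
        for j in np.flatnonzero((core >= min_core_sim) & (mat >= min_matrix_sim)):
            start = int(j) if strand == "+" else n - int(j) - L
            hits.append(
                MotifHit(
                    sequence_name, start, strand, pwm.name, pwm.tf_label,
                    float(mat[j]), float(core[j]), L,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand, h.matrix))
    return hits


def scan_all(
    sequences: dict[str, str],
    pwms: list[PWM],
    min_matrix_sim: float = DEFAULT_MIN_MATRIX_SIM,
    min_core_sim: float = DEFAULT_MIN_CORE_SIM,
) -> dict[str, list[MotifHit]]:
    """Scan several sequences with several matrices; hits per sequence."""
    out: dict[str, list[MotifHit]] = {}
    for name, seq in sequences.items():
        hits: list[MotifHit] = []
        for pwm in pwms:
            hits.extend(scan(seq, pwm, min_matrix_sim, min_core_sim, sequence_name=name))
        hits.sort(key=lambda h: (h.start, h.strand, h.matrix))
        out[name] = hits
    return out


# ---------------------------------------------------------------------------
# JASPAR-style PFM text I/O (counts or frequencies; ">name tf_label" headers)
# ---------------------------------------------------------------------------


def read_pfm(
    path: str | os.PathLike,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    core_length: int = DEFAULT_CORE_LENGTH,
) -> list[PWM]:
    """Read JASPAR-format matrices; the header's second token is the TF label.

    TF-to-matrix mapping is many-to-one: several matrices may carry the
    same ``tf_label`` (one binding site can bind several factors).
    """
    import Bio.motifs

    with open(path) as fh:
        motifs = Bio.motifs.parse(fh, "jaspar")
    out = []
    for m in motifs:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float).T
        name = m.matrix_id or m.name
        tf_label = m.name or name
        out.append(PWM.from_counts(name, tf_label, counts, pseudocount, core_length))
    return out


def write_pfm(pwms: list[PWM], path: str | os.PathLike) -> None:
    import Bio.motifs
    from Bio.motifs.jaspar import Motif as JasparMotif

    ms = []
    for p in pwms:
        source = p.counts if p.counts is not None else np.round(p.probs * 100, 2)
        counts = {b: list(source[:, i]) for i, b in enumerate(BASES)}
        ms.append(JasparMotif(matrix_id=p.name, name=p.tf_label, counts=counts))
    with open(path, "w") as fh:
        fh.write(Bio.motifs.write(ms, "jaspar"))


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "sequence_name", "start", "strand", "matrix", "tf_label",
    "matrix_similarity", "core_similarity", "width",
]


def write_hits_tsv(hits: list[MotifHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.sequence_name}\t{h.start}\t{h.strand}\t{h.matrix}\t{h.tf_label}\t"
                f"{h.matrix_similarity:.6f}\t{h.core_similarity:.6f}\t{h.width}\n"
            )


def read_hits_tsv(path: str | os.PathLike) -> list[MotifHit]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing hit columns {sorted(missing)}")
    return [
        MotifHit(
            str(r.sequence_name), int(r.start), str(r.strand), str(r.matrix),
            str(r.tf_label), float(r.matrix_similarity), float(r.core_similarity),
            int(r.width),
        )
        for r in df.itertuples(index=False)
    ]


def hits_to_bed(hits: list[MotifHit]) -> list[BedRecord]:
    return [
        BedRecord(h.interval(), f"{h.matrix}|{h.tf_label}", identity_to_score(h.matrix_similarity))
        for h in hits
    ]
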