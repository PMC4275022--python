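"""Pairwise alignment container with column/coordinate bookkeeping.

The alignment is stored as two equal-length gapped strings over
``{A,C,G,T,N,-}``. Reference and query offsets anchor the first aligned
residue of each row in locus coordinates, so alignment-local results can
be projected back onto both genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .intervals import GenomicInterval

ALIGNMENT_ALPHABET = frozenset("ACGTN-")


@dataclass
class PairwiseAlignment:
    """A two-row gapped alignment between a reference and a query locus.

    Invariants (checked on construction): both rows have equal length, no
    column is a gap in both rows, and each row contains at least one
    residue. Residues are upper-cased on input.
    """

    ref_name: str
    query_name: str
    ref_text: str
    query_text: str
    ref_offset: int = 0
    query_offset: int = 0

    def __post_init__(self) -> None:
        self.ref_text = self.ref_text.upper()
        self.query_text = self.query_text.upper()
        if len(self.ref_text) != len(self.query_text):
            raise ValueError(
                f"row length mismatch: ref {len(self.ref_text)} vs query {len(self.query_text)}"
            )
        if not self.ref_text:
            raise ValueError("empty alignment")
        bad = set(self.ref_text + self.query_text) - ALIGNMENT_ALPHABET
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(bad)}")
        r = np.frombuffer(self.ref_text.encode(), dtype="S1")
        q = np.frombuffer(self.query_text.encode(), dtype="S1")
        if np.any((r == b"-") & (q == b"-")):
            raise ValueError("alignment contains a column that is gap in both rows")
        if not np.any(r != b"-") or not np.any(q != b"-"):
            raise ValueError("alignment row contains no residues")

    # -- cached per-column arrays ------------------------------------------

    @cached_property
    def _ref_arr(self) -> np.ndarray:
        return np.frombuffer(self.ref_text.encode(), dtype="S1")

    @cached_property
    def _query_arr(self) -> np.ndarray:
        return np.frombuffer(self.query_text.encode(), dtype="S1")

    @property
    def n_columns(self) -> int:
        return len(self.ref_text)

    @cached_property
    def ref_columns(self) -> np.ndarray:
        """Column index of each reference residue (length = ref_length)."""
        return np.flatnonzero(self._ref_arr != b"-")

    @cached_property
    def query_columns(self) -> np.ndarray:
        return np.flatnonzero(self._query_arr != b"-")

    @property
    def ref_length(self) -> int:
        return len(self.ref_columns)

    @property
    def query_length(self) -> int:
        return len(self.query_columns)

    @cached_property
    def ref_sequence(self) -> str:
        return self.ref_text.replace("-", "")

    @cached_property
    def query_sequence(self) -> str:
        return self.query_text.replace("-", "")

    @cached_property
    def match_columns(self) -> np.ndarray:
        """Per-column match flags: 1 iff identical non-gap, non-N residues.

        N counts as a mismatch even against another N (conservative
        conservation calls).
        """
        r, q = self._ref_arr, self._query_arr
        m = (r == q) & (r != b"-") & (r != b"N")
        return m.astype(np.uint8)

    @cached_property
    def _query_residues_before(self) -> np.ndarray:
        """query residue count in columns < c, for c = 0..n_columns (len n+1)."""
        nongap = (self._query_arr != b"-").astype(np.int64)
        return np.concatenate([[0], np.cumsum(nongap)])

    # -- coordinate projection ---------------------------------------------

    def column_of_ref(self, ref_local_pos: int) -> int:
        return int(self.ref_columns[ref_local_pos])

    def ref_interval(self, start_local: int, end_local: int, strand: str = "+") -> GenomicInterval:
        return GenomicInterval(
            self.ref_name, self.ref_offset + start_local, self.ref_offset + end_local, strand
        )

    def query_interval_for_ref(self, start_local: int, end_local: int) -> GenomicInterval:
        """Project a reference-local half-open range onto query coordinates.

        The projection spans from the first to the last alignment column of
        the reference range, counting query residues within that span.
        """
        c1 = self.column_of_ref(start_local)
        c2 = self.column_of_ref(end_local - 1)
        qstart = int(self._query_residues_before[c1])
        qend = int(self._query_residues_before[c2 + 1])
        if qend <= qstart:  # query all-gap across the span
            raise ValueError("reference range maps to an empty query range")
        return GenomicInterval(self.query_name, self.query_offset + qstart, self.query_offset + qend, "+")

    def swapped(self) -> "PairwiseAlignment":
        """The same alignment with reference and query roles exchanged."""
        return PairwiseAlignment(
            self.query_name, self.ref_name, self.query_text, self.ref_text,
            self.query_offset, self.ref_offset,
        )
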