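"""Cross-species TFBS framework detection.

A framework is an ordered set of binding-site slots, each a
(tf_label, strand) pair, that is supported in every input species with
identical slot order and orientation, and with adjacent start-to-start
spacings matching the reference species (the first in input order)
within a tolerance of +/- tau nucleotides. Only frameworks of at least
``min_tfs`` slots are reported (concerted binding of several factors),
and only maximal ones: no additional reference hit can be inserted at
any position without breaking an invariant.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

from .motif_scan import MotifHit

DEFAULT_MIN_TFS = 4
#: the two spacing tolerances conventionally screened
DEFAULT_TOLERANCES = (10, 15)


@dataclass(frozen=True)
class Framework:
    """A detected cross-species framework.

    ``slots`` are (tf_label, strand) pairs in order; ``ref_spacings`` are
    adjacent start-to-start distances in the reference species;
    ``support`` maps each species to the hits occupying the slots.
    """

    slots: tuple[tuple[str, str], ...]
    ref_spacings: tuple[int, ...]
    tolerance: int
    support: dict[str, tuple[MotifHit, ...]]

    @property
    def size(self) -> int:
        return len(self.slots)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.support)

    @property
    def tf_labels(self) -> frozenset[str]:
        return frozenset(label for label, _ in self.slots)

    def to_dict(self) -> dict:
        return {
            "slots": [list(s) for s in self.slots],
            "ref_spacings": list(self.ref_spacings),
            "tolerance": self.tolerance,
            "support": {
                sp: [
                    {
                        "start": h.start,
                        "strand": h.strand,
                        "matrix": h.matrix,
                        "tf_label": h.tf_label,
                        "matrix_similarity": h.matrix_similarity,
                    }
                    for h in hits
                ]
                for sp, hits in self.support.items()
            },
        }


@dataclass(frozen=True)
class PromoterInteractionSet:
    """Factors shared between a framework and a promoter scan."""

    framework_tfs: frozenset[str]
    promoter_tfs: frozenset[str]

    @property
    def shared(self) -> frozenset[str]:
        return self.framework_tfs & self.promoter_tfs


def _sorted_hits(hits: list[MotifHit]) -> list[MotifHit]:
    return sorted(hits, key=lambda h: (h.start, h.strand, h.matrix))


def _assign_species(
    hits: list[MotifHit],
    slots: list[tuple[str, str]],
    ref_spacings: list[int],
    tolerance: int,
) -> tuple[MotifHit, ...] | None:
    """First (lexicographically earliest) assignment of hits to slots.

    Hits must be used in increasing index order (preserved slot order),
    match each slot's (tf_label, strand), and keep every adjacent
    start-to-start spacing within +/- tolerance of the reference spacing.
    """
    n = len(hits)

    def extend(slot_idx: int, prev_hit_idx: int, prev_start: int, acc: list[MotifHit]):
        if slot_idx == len(slots):
            return tuple(acc)
        label, strand = slots[slot_idx]
        for i in range(prev_hit_idx + 1, n):
            h = hits[i]
            if (h.tf_label, h.strand) != (label, strand):
                continue
            if slot_idx > 0:
                spacing = h.start - prev_start
                if abs(spacing - ref_spacings[slot_idx - 1]) > tolerance:
                    if spacing - ref_spacings[slot_idx - 1] > tolerance:
                        break  # hits sorted by start: spacing only grows
                    continue
            acc.append(h)
            found = extend(slot_idx + 1, i, h.start, acc)
            if found is not None:
                return found
            acc.pop()
        return None

    return extend(0, -1, 0, [])


def find_frameworks(
    hits_by_species: dict[str, list[MotifHit]],
    tolerance: int,
    min_tfs: int = DEFAULT_MIN_TFS,
) -> list[Framework]:
    """Find all maximal cross-species frameworks.

    The first species in input order is the spacing reference; the search
    anchors on its hits (depth-first chain extension with pruning, since
    validity is hereditary under prefix truncation) and every candidate
    must be supported by all species. With fewer than two species, or any
    species with no hits, the result is empty.

    Output is deterministic, ordered by (first slot start in the
    reference, size descending).
    """
    if len(hits_by_species) < 2:
        return []
    species = list(hits_by_species)
    hits = {sp: _sorted_hits(hits_by_species[sp]) for sp in species}
    if any(not hits[sp] for sp in species):
        return []
    ref = species[0]
    ref_hits = hits[ref]
    others = species[1:]

    def chain_support(chain: tuple[int, ...]) -> dict[str, tuple[MotifHit, ...]] | None:
        slots = [(ref_hits[i].tf_label, ref_hits[i].strand) for i in chain]
        spacings = [
            ref_hits[b].start - ref_hits[a].start for a, b in zip(chain, chain[1:])
        ]
        support = {ref: tuple(ref_hits[i] for i in chain)}
        for sp in others:
            asn = _assign_species(hits[sp], slots, spacings, tolerance)
            if asn is None:
                return None
            support[sp] = asn
        return support

    valid: dict[tuple[int, ...], dict[str, tuple[MotifHit, ...]]] = {}

    def extend(chain: tuple[int, ...]) -> None:
        for k in range(chain[-1] + 1, len(ref_hits)):
            cand = chain + (k,)
            support = chain_support(cand)
            if support is not None:
                valid[cand] = support
                extend(cand)

    for i in range(len(ref_hits)):
        single = (i,)
        support = chain_support(single)
        if support is not None:  # prefix validity is hereditary: prune here
            valid[single] = support
            extend(single)

    def extendable(chain: tuple[int, ...]) -> bool:
        used = set(chain)
        for pos in range(len(chain) + 1):
            lo = chain[pos - 1] if pos > 0 else -1
            hi = chain[pos] if pos < len(chain) else len(ref_hits)
            for k in range(lo + 1, hi):
                if k in used:
                    continue
                cand = chain[:pos] + (k,) + chain[pos:]
                if chain_support(cand) is not None:
                    return True
        return False

    frameworks = []
    for chain, support in valid.items():
        if len(chain) < min_tfs or extendable(chain):
            continue
        slots = tuple((ref_hits[i].tf_label, ref_hits[i].strand) for i in chain)
        spacings = tuple(
            ref_hits[b].start - ref_hits[a].start for a, b in zip(chain, chain[1:])
        )
        frameworks.append(Framework(slots, spacings, tolerance, support))
    frameworks.sort(key=lambda f: (f.support[ref][0].start, -f.size, f.slots))
    return frameworks


def shared_promoter_tfs(
    framework: Framework, promoter_hits: list[MotifHit]
) -> PromoterInteractionSet:
    """Intersect a framework's factors with promoter-binding factors."""
    return PromoterInteractionSet(
        framework_tfs=framework.tf_labels,
        promoter_tfs=frozenset(h.tf_label for h in promoter_hits),
    )


def write_frameworks_json(frameworks: list[Framework], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump([f.to_dict() for f in frameworks], fh, indent=2)
        fh.write("\n")


def write_frameworks_tsv(frameworks: list[Framework], path: str | os.PathLike) -> None:
    """Human-readable one-line-per-framework summary."""
    with open(path, "w") as fh:
        fh.write("n_slots\ttolerance\tslots\tref_spacings\tspecies\tref_start\n")
        for f in frameworks:
            ref_sp = next(iter(f.support))
            slots = ",".join(f"{lab}({st})" for lab, st in f.slots)
            fh.write(
                f"{f.size}\t{f.tolerance}\t{slots}\t"
                f"{','.join(map(str, f.ref_spacings))}\t"
                f"{','.join(f.support)}\t{f.support[ref_sp][0].start}\n"
            )
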