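"""Independent brute-force oracles used to validate the implementation.

Everything here deliberately avoids the package's optimized code paths:
identities are recounted column by column from the raw alignment rows,
ORFs are tested from every ATG independently, matrix scores are
recomputed with plain Python arithmetic, and frameworks are enumerated
over all slot subsets with exhaustive assignment search.
"""

from __future__ import annotations

import itertools
import math

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------


def _is_match(r: str, q: str) -> bool:
    return r == q and r not in "-N"


def window_identity_oracle(ref_text: str, query_text: str, window: int) -> list[float]:
    """Per-window identity by direct recount over the column span."""
    ref_cols = [i for i, c in enumerate(ref_text) if c != "-"]
    out = []
    for p in range(len(ref_cols) - window + 1):
        c1, c2 = ref_cols[p], ref_cols[p + window - 1]
        n = c2 - c1 + 1
        m = sum(
            1 for c in range(c1, c2 + 1) if _is_match(ref_text[c], query_text[c])
        )
        out.append(m / n)
    return out


def call_ecrs_oracle(
    ref_text: str, query_text: str, window: int, min_len: int, min_identity: float
) -> list[tuple[int, int, float]]:
    """(start, end, identity) triples in reference-local coordinates, by
    exhaustive window enumeration + merge + trim + length filter."""
    ref_cols = [i for i, c in enumerate(ref_text) if c != "-"]
    idents = window_identity_oracle(ref_text, query_text, window)
    qualifying = [p for p, v in enumerate(idents) if v >= min_identity]
    if not qualifying:
        return []
    regions = []
    s = e = None
    for p in qualifying:
        if s is None:
            s, e = p, p + window
        elif p < e:  # overlapping windows merge; touching does not
            e = p + window
        else:
            regions.append((s, e))
            s, e = p, p + window
    regions.append((s, e))

    def match_at(pos: int) -> bool:
        c = ref_cols[pos]
        return _is_match(ref_text[c], query_text[c])

    out = []
    for s, e in regions:
        matches = [p for p in range(s, e) if match_at(p)]
        if not matches:
            continue
        first, last = matches[0], matches[-1]
        if last + 1 - first < min_len:
            continue
        c1, c2 = ref_cols[first], ref_cols[last]
        cols = range(c1, c2 + 1)
        ident = sum(1 for c in cols if _is_match(ref_text[c], query_text[c])) / len(cols)
        out.append((first, last + 1, ident))
    return out


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


def orf_oracle(seq: str) -> list[tuple[int, int, str, int, int]]:
    """(start, end, strand, frame, aa) tuples, scanning every ATG naively."""
    seq = seq.upper()
    n = len(seq)
    out = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for i in range(n - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i + 3
            while j + 3 <= n and s[j : j + 3] not in _STOPS:
                j += 3
            if j + 3 > n:
                continue
            aa = (j - i) // 3 - 1
            if aa < 1:
                continue
            if strand == "+":
                out.append((i, j + 3, "+", i % 3, aa))
            else:
                out.append((n - (j + 3), n - i, "-", i % 3, aa))
    out.sort(key=lambda o: (o[0], o[2], o[1]))
    return out


# ---------------------------------------------------------------------------
# motif scoring
# ---------------------------------------------------------------------------


def information_weight_oracle(row: list[float]) -> float:
    return sum(f * math.log2(4 * f) for f in row if f > 0)


def matrix_similarity_oracle(probs: list[list[float]], window: str) -> float:
    """Plain-Python matrix similarity for one window (no numpy)."""
    weights = [information_weight_oracle(row) for row in probs]
    num = 0.0
    den = 0.0
    for i, row in enumerate(probs):
        b = window[i]
        f = min(row) if b == "N" else row["ACGT".index(b)]
        num += weights[i] * f
        den += weights[i] * max(row)
    return num / den if den > 0 else 1.0


def core_similarity_oracle(probs: list[list[float]], window: str, core_length: int = 4) -> float:
    weights = [information_weight_oracle(row) for row in probs]
    core_length = min(core_length, len(probs))
    best_start, best_sum = 0, -1.0
    for s in range(len(probs) - core_length + 1):
        total = sum(weights[s : s + core_length])
        if total > best_sum + 1e-15:
            best_sum = total
            best_start = s
    num = den = 0.0
    for i in range(best_start, best_start + core_length):
        row = probs[i]
        b = window[i]
        f = min(row) if b == "N" else row["ACGT".index(b)]
        num += weights[i] * f
        den += weights[i] * max(row)
    return num / den if den > 0 else 1.0


# ---------------------------------------------------------------------------
# frameworks
# ---------------------------------------------------------------------------


def _sorted_hits(hits):
    return sorted(hits, key=lambda h: (h.start, h.strand, h.matrix))


def _assignment_exists(hits, slots, spacings, tol) -> bool:
    """Exhaustive product over per-slot label-matching candidates."""
    candidates = [
        [i for i, h in enumerate(hits) if (h.tf_label, h.strand) == slot] for slot in slots
    ]
    if any(not c for c in candidates):
        return False
    for combo in itertools.product(*candidates):
        if any(b <= a for a, b in zip(combo, combo[1:])):
            continue
        ok = True
        for k, (a, b) in enumerate(zip(combo, combo[1:])):
            spacing = hits[b].start - hits[a].start
            if abs(spacing - spacings[k]) > tol:
                ok = False
                break
        if ok:
            return True
    return False


def framework_oracle(hits_by_species, tol, min_tfs):
    """All maximal valid chains as ref-hit index tuples (set for comparison).

    A chain of reference hits is valid if every other species admits an
    order-preserving assignment within the spacing tolerance; it is
    maximal if no single extra reference hit can be inserted (index order
    makes the insertion position unique).
    """
    species = list(hits_by_species)
    if len(species) < 2:
        return set()
    hits = {sp: _sorted_hits(hits_by_species[sp]) for sp in species}
    if any(not hits[sp] for sp in species):
        return set()
    ref = species[0]
    ref_hits = hits[ref]
    others = species[1:]

    def valid(chain) -> bool:
        slots = [(ref_hits[i].tf_label, ref_hits[i].strand) for i in chain]
        spacings = [ref_hits[b].start - ref_hits[a].start for a, b in zip(chain, chain[1:])]
        return all(_assignment_exists(hits[sp], slots, spacings, tol) for sp in others)

    n = len(ref_hits)
    valid_chains = [
        chain
        for size in range(min_tfs, n + 1)
        for chain in itertools.combinations(range(n), size)
        if valid(chain)
    ]
    maximal = set()
    for chain in valid_chains:
        used = set(chain)
        if any(valid(tuple(sorted(chain + (k,)))) for k in range(n) if k not in used):
            continue
        maximal.add(chain)
    return maximal


def framework_to_ref_chain(framework, ref_species, ref_hits_sorted):
    """Map a Framework's reference support back to sorted-hit indices."""
    index = {id(h): i for i, h in enumerate(ref_hits_sorted)}
    lookup = {
        (h.start, h.strand, h.matrix, h.tf_label): i for i, h in enumerate(ref_hits_sorted)
    }
    return tuple(
        lookup[(h.start, h.strand, h.matrix, h.tf_label)]
        for h in framework.support[ref_species]
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def ttest_oracle(x, y) -> tuple[float, float]:
    """Textbook pooled-variance two-sample t, p from the t distribution."""
    from scipy.stats import t as tdist

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2)
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * tdist.sf(abs(t), nx + ny - 2)
    return t, p
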