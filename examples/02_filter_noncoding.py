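"""Screen candidate elements for coding potential.

A candidate conserved element is kept as non-coding only if it overlaps
no annotated transcript/EST interval and contains no open reading frame
longer than 20 amino acids (strict: a 20-aa ORF passes, 21 fails).
"""

import numpy as np

from ncecr import GenomicInterval, find_orfs, is_noncoding

rng = np.random.default_rng(0)


def codons(n):
    stops = {"TAA", "TAG", "TGA"}
    out = []
    while len(out) < n:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        if c not in stops:
            out.append(c)
    return "".join(out)


element = GenomicInterval("chr4", 91_000_000, 91_000_150)
annotations = [GenomicInterval("chr4", 91_000_140, 91_000_400)]  # an EST

clean_seq = codons(20)                              # no long ORF
orf_seq = codons(5) + "ATG" + codons(25) + "TAA" + codons(5)  # 25-aa ORF

for label, seq, anns in [
    ("clean element, no annotations", clean_seq, []),
    ("element overlapping an EST", clean_seq, annotations),
    ("element with a 25-aa ORF", orf_seq, []),
]:
    call = is_noncoding(element, seq, anns, max_orf_aa=20)
    orfs = find_orfs(seq)
    print(
        f"{label}: noncoding={call.noncoding}  reasons={list(call.reasons)}  "
        f"longest ORF={call.max_orf_aa} aa  ({len(orfs)} ORF(s) total)"
    )
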