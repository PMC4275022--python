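"""Call conserved regions from a pairwise locus alignment.

Simulates a human/mouse-style locus pair with two implanted conserved
blocks, computes the 100-bp sliding-window identity profile and calls
ECRs at the standard screen thresholds (length >= 100 bp, identity >=
75%). The printed intervals are 1-based inclusive; each call should
land on one implanted block.
"""

from ncecr import (
    ConservedPairConfig,
    ImplantSpec,
    call_ecrs,
    simulate_conserved_pair,
    windowed_identity,
)

cfg = ConservedPairConfig(
    seed=42,
    length=3000,
    background_divergence=0.45,            # ~55% background identity
    implants=(
        ImplantSpec(position=700, length=180, identity=0.86),
        ImplantSpec(position=2100, length=220, identity=0.82),
    ),
)
alignment, truth = simulate_conserved_pair(cfg)
profile = windowed_identity(alignment, window=100)
ecrs = call_ecrs(profile, min_len=100, min_identity=0.75)

print(f"implanted blocks: {[str(iv) for iv in truth]}")
print(f"{len(ecrs)} ECR(s) called:")
for ecr in ecrs:
    print(
        f"  ref {ecr.ref}  query {ecr.query}  "
        f"identity {ecr.identity:.3f}  length {ecr.length} bp"
    )
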