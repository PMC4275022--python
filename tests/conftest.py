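import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ncecr.motif_scan import MotifHit, PWM
from ncecr.synthetic_data import demo_pwms

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pwms() -> dict[str, PWM]:
    return demo_pwms()


@pytest.fixture
def toy_pwm() -> PWM:
    """3-position matrix with distinct per-position preferences."""
    counts = np.array(
        [
            [8.0, 1.0, 1.0, 0.0],   # A-preferring
            [1.0, 6.0, 2.0, 1.0],   # C-preferring
            [0.0, 0.0, 1.0, 9.0],   # T-preferring
        ]
    )
    return PWM.from_counts("TOY", "TOYTF", counts)


def make_hit(species: str, start: int, tf: str, strand: str = "+") -> MotifHit:
    return MotifHit(species, start, strand, f"M_{tf}", tf, 0.95, 0.97, 8)


def random_hits_instance(seed: int, n_species: int = 4):
    """A randomized multi-species hit configuration for framework tests.

    The non-reference species copy the reference hits with bounded
    positional jitter, occasional dropouts and a few extra decoy hits, so
    instances contain frameworks of varying sizes.
    """
    rng = np.random.default_rng(seed)
    labels = ["TF1", "TF2", "TF3", "TF4", "TF5"]
    species = [f"sp{i}" for i in range(n_species)]
    n_ref = int(rng.integers(6, 11))
    starts = np.sort(rng.choice(np.arange(0, 400), size=n_ref, replace=False))
    ref_hits = [
        make_hit(
            species[0], int(s), labels[int(rng.integers(0, len(labels)))],
            "+" if rng.random() < 0.7 else "-",
        )
        for s in starts
    ]
    out = {species[0]: ref_hits}
    for sp in species[1:]:
        hits = []
        for h in ref_hits:
            if rng.random() < 0.15:  # dropout
                continue
            jitter = int(rng.integers(-15, 16))
            start = max(0, h.start + jitter)
            hits.append(make_hit(sp, start, h.tf_label, h.strand))
        for _ in range(int(rng.integers(0, 3))):  # decoys
            hits.append(
                make_hit(
                    sp, int(rng.integers(0, 400)),
                    labels[int(rng.integers(0, len(labels)))],
                    "+" if rng.random() < 0.5 else "-",
                )
            )
        out[sp] = hits
    return out
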