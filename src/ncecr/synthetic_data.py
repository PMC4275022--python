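"""Ground-truth simulators for every pipeline input.

Three generators emulate the study conditions the pipeline is built for:

* a homologous locus pair with implanted conserved blocks on a divergent
  background (substitutions Jukes-Cantor-like, uniform over the three
  alternative bases; small indels outside the implants);
* a set of N species sequences carrying the same ordered motif framework
  with per-species spacing jitter relative to the first (reference)
  species;
* dual-luciferase plates with multiplicative log-normal noise,
  4 wells x 3 experiments per construct by default (12 wells), plus the
  promoter-only / basic / control reporter constructs.

All generators are deterministic under a fixed seed (identical outputs
byte for byte) and emit both the input files consumed by the analysis
modules and the ground truth needed to score recovery.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .alignment import PairwiseAlignment
from .intervals import GenomicInterval
from .io import BedRecord, write_bed, write_fasta, write_maf
from .motif_scan import PWM
from .reporter_stats import LuciferaseWell, write_wells_tsv

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImplantSpec:
    """A conserved block implanted into the locus pair."""

    position: int     # reference-local start (bp)
    length: int       # bp
    identity: float   # target per-site identity within the block

    def __post_init__(self) -> None:
        if not 0 < self.identity <= 1:
            raise ValueError(f"implant identity must be in (0, 1], got {self.identity}")
        if self.length < 1 or self.position < 0:
            raise ValueError("implant position/length must be non-negative/positive")


@dataclass(frozen=True)
class ConservedPairConfig:
    """Homologous locus pair with implanted conserved blocks.

    ``background_divergence`` is the per-site substitution probability
    outside implants; inside an implant it is ``1 - identity``. Indels
    (query-side, length 1-3) occur outside implants at ``indel_rate``
    per site, split evenly between insertions and deletions.
    """

    seed: int
    length: int = 2000
    background_divergence: float = 0.45
    implants: tuple[ImplantSpec, ...] = ()
    indel_rate: float = 0.005
    ref_name: str = "ref"
    query_name: str = "query"

    def __post_init__(self) -> None:
        if not 0 <= self.background_divergence < 1:
            raise ValueError("background divergence must be in [0, 1)")
        spans = sorted((im.position, im.position + im.length) for im in self.implants)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"implants overlap: [{s1},{e1}) and [{s2},{e2})")
        for s, e in spans:
            if e > self.length:
                raise ValueError(f"implant [{s},{e}) extends past locus length {self.length}")


@dataclass(frozen=True)
class FrameworkSpeciesConfig:
    """N-species sequences with one implanted motif framework.

    ``slots`` are (pwm_name, strand) pairs in order; ``spacings`` the
    start-to-start distances between adjacent slots in the reference
    species (the first in ``species``). Other species draw an integer
    jitter of magnitude in [jitter_min, jitter] (random sign) on each
    spacing, relative to the reference spacing.
    """

    seed: int
    species: tuple[str, ...] = ("human", "mouse", "dog", "cow")
    length: int = 600
    slots: tuple[tuple[str, str], ...] = ()
    spacings: tuple[int, ...] = ()
    jitter: int = 0
    jitter_min: int = 0
    first_slot_position: int = 60

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ValueError("need at least 2 species for a cross-species framework")
        if self.slots and len(self.spacings) != len(self.slots) - 1:
            raise ValueError("need exactly one spacing per adjacent slot pair")
        if not 0 <= self.jitter_min <= self.jitter:
            raise ValueError("need 0 <= jitter_min <= jitter")


@dataclass(frozen=True)
class AssayConfig:
    """Simulated dual-luciferase plates with known true fold changes.

    ``folds`` maps construct ids to true fold changes versus the
    promoter-only control. The control constructs prom/bas/con are added
    automatically (folds 1.0, 0.05 and 4.0) unless present. Per well,
    Renilla ~ LogNormal(renilla_mu, renilla_sigma) and
    firefly = Renilla x fold x LogNormal(0, sigma).
    """

    seed: int
    folds: tuple[tuple[str, float], ...] = ()
    sigma: float = 0.2
    wells_per_experiment: int = 4
    experiments: int = 3
    renilla_mu: float = 12.0
    renilla_sigma: float = 0.3
    control_folds: tuple[tuple[str, float], ...] = (("prom", 1.0), ("bas", 0.05), ("con", 4.0))

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for construct, fold in self.folds:
            if fold <= 0:
                raise ValueError(f"true fold for {construct!r} must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Aggregate configuration for all three generators (one file)."""

    conserved_pair: ConservedPairConfig | None = None
    framework_species: FrameworkSpeciesConfig | None = None
    assay: AssayConfig | None = None

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "SimulationConfig":
        path = os.fspath(path)
        if path.endswith(".toml"):
            import tomllib

            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            import yaml

            with open(path) as fh:
                raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        def tup(x):
            return tuple(tuple(i) if isinstance(i, (list, tuple)) else i for i in x)

        cp = raw.get("conserved_pair")
        fs = raw.get("framework_species")
        ay = raw.get("assay")
        return cls(
            conserved_pair=None if cp is None else ConservedPairConfig(
                **{**cp, "implants": tuple(ImplantSpec(**im) for im in cp.get("implants", []))}
            ),
            framework_species=None if fs is None else FrameworkSpeciesConfig(
                **{**fs,
                   "species": tuple(fs.get("species", ("human", "mouse", "dog", "cow"))),
                   "slots": tup(fs.get("slots", [])),
                   "spacings": tuple(fs.get("spacings", []))}
            ),
            assay=None if ay is None else AssayConfig(
                **{**ay, "folds": tuple((k, float(v)) for k, v in dict(ay.get("folds", {})).items())}
            ),
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _substitute(rng: np.random.Generator, base: str) -> str:
    alternatives = [b for b in "ACGT" if b != base]
    return alternatives[rng.integers(0, 3)]


def simulate_conserved_pair(
    cfg: ConservedPairConfig,
) -> tuple[PairwiseAlignment, list[GenomicInterval]]:
    """Generate an aligned locus pair plus the true implant intervals.

    The reference is i.i.d. uniform; the query substitutes per site at
    the background rate outside implants and at 1 - identity inside;
    indels are confined to the background so realized implant identity
    concentrates binomially around the target.
    """
    rng = np.random.default_rng(cfg.seed)
    ref = _random_seq(rng, cfg.length)
    in_implant = np.zeros(cfg.length, dtype=bool)
    for im in cfg.implants:
        in_implant[im.position : im.position + im.length] = True
    sub_rate = np.full(cfg.length, cfg.background_divergence)
    for im in cfg.implants:
        sub_rate[im.position : im.position + im.length] = 1.0 - im.identity

    ref_row: list[str] = []
    query_row: list[str] = []
    for i in range(cfg.length):
        base = ref[i]
        if not in_implant[i] and cfg.indel_rate > 0:
            u = rng.random()
            if u < cfg.indel_rate / 2:  # deletion in query
                ref_row.append(base)
                query_row.append("-")
                continue
            if u < cfg.indel_rate:  # insertion in query after this site
                ref_row.append(base)
                query_row.append(
                    base if rng.random() >= sub_rate[i] else _substitute(rng, base)
                )
                ins_len = int(rng.integers(1, 4))
                ins = _random_seq(rng, ins_len)
                ref_row.extend("-" * ins_len)
                query_row.extend(ins)
                continue
        query_row.append(base if rng.random() >= sub_rate[i] else _substitute(rng, base))
        ref_row.append(base)

    aln = PairwiseAlignment(
        cfg.ref_name, cfg.query_name, "".join(ref_row), "".join(query_row)
    )
    truth = [
        GenomicInterval(cfg.ref_name, im.position, im.position + im.length, "+")
        for im in cfg.implants
    ]
    return aln, truth


def simulate_framework_species(
    cfg: FrameworkSpeciesConfig, pwms: dict[str, PWM]
) -> tuple[dict[str, str], dict]:
    """Generate per-species sequences with the implanted framework.

    Each species receives every slot's PWM consensus (reverse-complemented
    for minus-strand slots) on random background; the first species uses
    the exact reference spacings, the others jittered ones. Returns the
    sequences and a truth record of implanted positions per species.
    """
    if not cfg.slots:
        raise ValueError("no slots configured")
    for name, _ in cfg.slots:
        if name not in pwms:
            raise ValueError(f"slot matrix {name!r} not in supplied PWMs")
    rng = np.random.default_rng(cfg.seed)
    from .io import reverse_complement

    sequences: dict[str, str] = {}
    truth: dict = {"slots": [list(s) for s in cfg.slots], "spacings": list(cfg.spacings),
                   "species": {}}
    for si, species in enumerate(cfg.species):
        seq = _random_seq(rng, cfg.length).tolist()
        pos = cfg.first_slot_position
        positions = []
        prev_end = -1
        for k, (name, strand) in enumerate(cfg.slots):
            motif = pwms[name].consensus
            if strand == "-":
                motif = reverse_complement(motif)
            if k > 0:
                spacing = cfg.spacings[k - 1]
                if si > 0 and cfg.jitter > 0:
                    magnitude = int(rng.integers(cfg.jitter_min, cfg.jitter + 1))
                    sign = 1 if rng.random() < 0.5 else -1
                    spacing += sign * magnitude
                pos = positions[-1] + spacing
            if pos <= prev_end:
                raise ValueError(
                    f"jitter caused slot overlap at species {species!r}, slot {k}"
                )
            if pos + len(motif) > cfg.length:
                raise ValueError(f"slot {k} does not fit in sequence of length {cfg.length}")
            seq[pos : pos + len(motif)] = list(motif)
            positions.append(pos)
            prev_end = pos + len(motif) - 1
        sequences[species] = "".join(seq)
        truth["species"][species] = {
            "positions": positions,
            "strands": [s for _, s in cfg.slots],
        }
    return sequences, truth


def simulate_assay(cfg: AssayConfig) -> tuple[list[LuciferaseWell], dict[str, float]]:
    """Generate dual-luciferase wells plus the true fold-change map."""
    rng = np.random.default_rng(cfg.seed)
    folds: dict[str, float] = dict(cfg.control_folds)
    folds.update(dict(cfg.folds))
    wells: list[LuciferaseWell] = []
    for construct, fold in folds.items():
        for exp in range(1, cfg.experiments + 1):
            for rep in range(1, cfg.wells_per_experiment + 1):
                renilla = float(rng.lognormal(cfg.renilla_mu, cfg.renilla_sigma))
                firefly = float(renilla * fold * rng.lognormal(0.0, cfg.sigma))
                wells.append(
                    LuciferaseWell(
                        construct, experiment=f"E{exp}", replicate=f"W{rep}",
                        firefly=firefly, renilla=renilla,
                    )
                )
    return wells, folds


#: true fold changes of the locus screen's regulatory elements: three
#: upstream enhancers at ~1.5x, intronic enhancers at 1.5/2/2.5x,
#: downstream enhancers at 2/2.5x and one downstream silencer at 0.35x.
LOCUS_SCREEN_FOLDS: tuple[tuple[str, float], ...] = (
    ("U3", 1.5), ("U4-1", 1.5), ("U4-3", 1.5),
    ("I2", 1.5), ("I5", 2.0), ("I6", 1.5), ("I8", 1.5), ("I12", 2.5),
    ("D1", 2.0), ("D2", 2.0), ("D3", 2.5), ("D6", 0.35),
)

#: all 32 reporter constructs of the locus screen (5 upstream, 17
#: intronic, 10 downstream; neighbouring regions combined into one
#: construct where applicable), neutral unless listed above.
LOCUS_SCREEN_CONSTRUCTS: tuple[str, ...] = (
    ("U1", "U2", "U3", "U4-1", "U4-3")
    + tuple(f"I{i}" for i in range(1, 18))
    + tuple(f"D{i}" for i in range(1, 11))
)


def synthetic_locus_assay_config(seed: int, sigma: float = 0.15) -> AssayConfig:
    """Synthetic stand-in for the deposited combined luciferase dataset.

    The real deposited table (ratio-level, elements normalized to Prom)
    is not redistributable here; this generator reproduces its layout and
    the published effect sizes so the re-analysis path can be exercised
    end to end: 12 of the 32 constructs carry a true regulatory effect
    (:data:`LOCUS_SCREEN_FOLDS`), the rest are neutral.
    """
    effect = dict(LOCUS_SCREEN_FOLDS)
    folds = tuple(
        (construct, effect.get(construct, 1.0)) for construct in LOCUS_SCREEN_CONSTRUCTS
    )
    return AssayConfig(seed=seed, folds=folds, sigma=sigma)


# ---------------------------------------------------------------------------
# Demo matrices and the on-disk bundle used by the pipeline smoke runs
# ---------------------------------------------------------------------------


def demo_pwms() -> dict[str, PWM]:
    """Four sharp 8-bp demonstration matrices with distinct consensi."""
    consensi = {
        "M_TF1": ("TF1", "ATGCAAAT"),
        "M_TF2": ("TF2", "TGACTCAG"),  # non-palindromic on purpose
        "M_TF3": ("TF3", "TGGGCGGG"),
        "M_TF4": ("TF4", "CACGTGAC"),
    }
    out = {}
    for name, (tf, consensus) in consensi.items():
        counts = np.full((len(consensus), 4), 1.0)
        for i, b in enumerate(consensus):
            counts[i, "ACGT".index(b)] = 91.0
        out[name] = PWM.from_counts(name, tf, counts)
    return out


def write_demo_bundle(outdir: str | os.PathLike, seed: int) -> dict[str, str]:
    """Write a complete synthetic input bundle for an end-to-end run.

    Emits a pairwise MAF with implanted conserved blocks plus truth BED,
    a gene model GFF3, an annotation BED, per-species FASTA with an
    implanted framework plus truth JSON, a JASPAR PFM file, and an assay
    TSV. Returns the path map.
    """
    from .io import write_gene_model_gff3
    from .intervals import GeneModel
    from .motif_scan import write_pfm

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "alignment": "pair.maf",
        "truth_bed": "implants.truth.bed",
        "gene_model": "gene.gff3",
        "annotations": "annotations.bed",
        "species_fasta": "species.fasta",
        "framework_truth": "framework.truth.json",
        "pfm": "matrices.pfm",
        "assay": "assay.tsv",
    }.items()}

    pair_cfg = ConservedPairConfig(
        seed=seed, length=4000, background_divergence=0.45,
        implants=(ImplantSpec(600, 200, 0.85), ImplantSpec(1900, 180, 0.88),
                  ImplantSpec(3300, 220, 0.82)),
    )
    aln, truth = simulate_conserved_pair(pair_cfg)
    write_maf([aln], paths["alignment"])
    write_bed([BedRecord(iv, f"implant{i}", 0) for i, iv in enumerate(truth, 1)],
              paths["truth_bed"])

    gene = GeneModel(
        gene=GenomicInterval("ref", 1200, 2800, "+"),
        exons=(GenomicInterval("ref", 1200, 1350, "+"), GenomicInterval("ref", 2600, 2800, "+")),
    )
    write_gene_model_gff3(gene, paths["gene_model"])
    write_bed([BedRecord(GenomicInterval("ref", 1200, 1350, "+"), "exon1", 0),
               BedRecord(GenomicInterval("ref", 2600, 2800, "+"), "exon2", 0)],
              paths["annotations"])

    pwms = demo_pwms()
    fw_cfg = FrameworkSpeciesConfig(
        seed=seed + 1,
        slots=(("M_TF1", "+"), ("M_TF2", "+"), ("M_TF3", "-"), ("M_TF4", "+")),
        spacings=(25, 30, 35), jitter=5,
    )
    sequences, fw_truth = simulate_framework_species(fw_cfg, pwms)
    write_fasta(sequences, paths["species_fasta"])
    with open(paths["framework_truth"], "w") as fh:
        json.dump(fw_truth, fh, indent=2)
        fh.write("\n")
    write_pfm(list(pwms.values()), paths["pfm"])

    assay_cfg = AssayConfig(
        seed=seed + 2,
        folds=(("U1", 1.5), ("In1", 1.0), ("In2", 2.5), ("D1", 0.35), ("D2", 1.0)),
        sigma=0.15,
    )
    wells, _ = simulate_assay(assay_cfg)
    write_wells_tsv(wells, paths["assay"])
    return paths
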