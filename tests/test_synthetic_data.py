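"""Determinism, ground-truth fidelity and round-trips of the simulators."""

import json

import numpy as np
import pytest

from ncecr.alignment import PairwiseAlignment
from ncecr.conservation import windowed_identity
from ncecr.io import read_alignment, read_fasta, write_fasta, write_maf
from ncecr.motif_scan import scan_all
from ncecr.reporter_stats import read_assay_table, write_wells_tsv
from ncecr.synthetic_data import (
    AssayConfig,
    ConservedPairConfig,
    FrameworkSpeciesConfig,
    ImplantSpec,
    SimulationConfig,
    demo_pwms,
    simulate_assay,
    simulate_conserved_pair,
    simulate_framework_species,
    write_demo_bundle,
)


class TestConservedPair:
    def test_zero_divergence_gives_identity_one_everywhere(self):
        cfg = ConservedPairConfig(seed=1, length=400, background_divergence=0.0, indel_rate=0.0)
        aln, _ = simulate_conserved_pair(cfg)
        prof = windowed_identity(aln, 100)
        assert np.all(prof.identity == 1.0)

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg = ConservedPairConfig(
            seed=42, length=800, implants=(ImplantSpec(200, 150, 0.85),)
        )
        p1, p2 = tmp_path / "a.maf", tmp_path / "b.maf"
        write_maf([simulate_conserved_pair(cfg)[0]], p1)
        write_maf([simulate_conserved_pair(cfg)[0]], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_generated_maf_reads_back_identically(self, tmp_path):
        cfg = ConservedPairConfig(seed=3, length=600, implants=(ImplantSpec(100, 120, 0.9),))
        aln, _ = simulate_conserved_pair(cfg)
        p = tmp_path / "pair.maf"
        write_maf([aln], p)
        assert read_alignment(p, "maf") == [aln]

    def test_realized_implant_identity_concentrates_on_target(self):
        """Mean realized in-block identity across seeds tracks the target
        within binomial sampling error (sd ~ 0.025 per seed at 200 bp)."""
        target, length = 0.85, 200
        realized = []
        for seed in range(50):
            cfg = ConservedPairConfig(
                seed=seed, length=1000, implants=(ImplantSpec(400, length, target),)
            )
            aln, (truth,) = simulate_conserved_pair(cfg)
            m = aln.match_columns[aln.ref_columns[truth.start : truth.end]]
            value = m.sum() / length
            realized.append(value)
            assert abs(value - target) <= 4 * np.sqrt(target * (1 - target) / length)
        assert abs(np.mean(realized) - target) <= 0.01

    def test_overlapping_implants_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ConservedPairConfig(
                seed=1, length=1000,
                implants=(ImplantSpec(100, 200, 0.9), ImplantSpec(250, 100, 0.9)),
            )

    def test_implant_outside_locus_rejected(self):
        with pytest.raises(ValueError, match="extends past"):
            ConservedPairConfig(seed=1, length=300, implants=(ImplantSpec(200, 200, 0.9),))


class TestFrameworkSpecies:
    def test_zero_jitter_gives_identical_spacings(self, pwms):
        cfg = FrameworkSpeciesConfig(
            seed=2, slots=(("M_TF1", "+"), ("M_TF2", "+"), ("M_TF4", "-")),
            spacings=(30, 40), jitter=0,
        )
        _, truth = simulate_framework_species(cfg, pwms)
        spacings = {
            tuple(np.diff(rec["positions"])) for rec in truth["species"].values()
        }
        assert spacings == {(30, 40)}

    def test_implants_carry_requested_strands(self, pwms):
        cfg = FrameworkSpeciesConfig(
            seed=4, slots=(("M_TF1", "+"), ("M_TF3", "-")), spacings=(40,), jitter=0,
        )
        seqs, truth = simulate_framework_species(cfg, pwms)
        hits = scan_all(seqs, [pwms["M_TF1"], pwms["M_TF3"]], 0.95, 0.95)
        for sp, rec in truth["species"].items():
            found = {(h.start, h.strand, h.matrix) for h in hits[sp]}
            assert (rec["positions"][0], "+", "M_TF1") in found
            assert (rec["positions"][1], "-", "M_TF3") in found

    def test_single_species_rejected(self):
        with pytest.raises(ValueError, match="2 species"):
            FrameworkSpeciesConfig(seed=1, species=("human",))

    def test_jitter_overlap_rejected(self, pwms):
        cfg = FrameworkSpeciesConfig(
            seed=5, slots=(("M_TF1", "+"), ("M_TF2", "+")), spacings=(9,),
            jitter=6, jitter_min=2,
        )
        with pytest.raises(ValueError, match="overlap"):
            for s in range(40):  # some draw will push the spacing under the width
                simulate_framework_species(
                    FrameworkSpeciesConfig(
                        seed=s, slots=cfg.slots, spacings=cfg.spacings,
                        jitter=cfg.jitter, jitter_min=cfg.jitter_min,
                    ),
                    demo_pwms(),
                )

    def test_fasta_round_trip(self, tmp_path, pwms):
        cfg = FrameworkSpeciesConfig(
            seed=6, slots=(("M_TF1", "+"), ("M_TF2", "+")), spacings=(30,), jitter=3,
        )
        seqs, _ = simulate_framework_species(cfg, pwms)
        p = tmp_path / "sp.fa"
        write_fasta(seqs, p)
        assert read_fasta(p) == seqs


class TestAssaySimulator:
    def test_noise_free_limit_recovers_exact_folds(self):
        cfg = AssayConfig(seed=1, folds=(("X", 2.5),), sigma=1e-12)
        wells, folds = simulate_assay(cfg)
        for w in wells:
            assert w.value == pytest.approx(folds[w.construct], rel=1e-6)

    def test_default_plate_structure(self):
        cfg = AssayConfig(seed=2, folds=(("X", 1.0),))
        wells, folds = simulate_assay(cfg)
        constructs = {w.construct for w in wells}
        assert constructs == {"prom", "bas", "con", "X"}
        per = [w for w in wells if w.construct == "X"]
        assert len(per) == 12  # 4 wells x 3 experiments
        assert len({w.experiment for w in per}) == 3

    def test_fixed_seed_tsv_identical(self, tmp_path):
        cfg = AssayConfig(seed=3, folds=(("X", 1.5),))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_wells_tsv(simulate_assay(cfg)[0], p1)
        write_wells_tsv(simulate_assay(cfg)[0], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_table_round_trip_preserves_ratios(self, tmp_path):
        cfg = AssayConfig(seed=4, folds=(("U1", 0.5),))
        wells, _ = simulate_assay(cfg)
        p = tmp_path / "w.tsv"
        write_wells_tsv(wells, p)
        back = read_assay_table(p)
        assert np.allclose([w.value for w in back], [w.value for w in wells])


class TestConfigFile:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "sim.yaml"
        p.write_text(
            "conserved_pair:\n"
            "  seed: 7\n  length: 500\n  background_divergence: 0.4\n"
            "  implants:\n    - {position: 100, length: 120, identity: 0.9}\n"
            "assay:\n  seed: 8\n  folds: {D6: 0.35}\n  sigma: 0.15\n"
        )
        cfg = SimulationConfig.from_file(p)
        assert cfg.conserved_pair.seed == 7
        assert cfg.conserved_pair.implants[0].length == 120
        assert dict(cfg.assay.folds) == {"D6": 0.35}
        assert cfg.framework_species is None


class TestBundle:
    def test_bundle_files_parse_with_their_readers(self, tmp_path):
        paths = write_demo_bundle(tmp_path / "bundle", seed=5)
        assert read_alignment(paths["alignment"], "maf")
        assert len(read_fasta(paths["species_fasta"])) == 4
        assert read_assay_table(paths["assay"])
        with open(paths["framework_truth"]) as fh:
            truth = json.load(fh)
        assert set(truth["species"]) == {"human", "mouse", "dog", "cow"}
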