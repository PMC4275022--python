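"""Normalization, t-tests and enhancer/silencer classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ncecr.reporter_stats import (
    LuciferaseWell,
    classify_elements,
    construct_sort_key,
    normalize_to_control,
    read_assay_table,
    t_test_two_sample,
    write_wells_tsv,
)
from ncecr.synthetic_data import AssayConfig, simulate_assay

from oracles import ttest_oracle


def _well(construct, ratio, experiment=None):
    return LuciferaseWell(construct, experiment=experiment, ratio=ratio)


class TestWell:
    def test_requires_positive_values(self):
        with pytest.raises(ValueError):
            LuciferaseWell("x", firefly=-1.0, renilla=2.0)
        with pytest.raises(ValueError):
            LuciferaseWell("x", ratio=0.0)
        with pytest.raises(ValueError):
            LuciferaseWell("x")  # neither channel nor ratio

    def test_ratio_from_channels(self):
        assert LuciferaseWell("x", firefly=10.0, renilla=4.0).value == pytest.approx(2.5)


class TestNormalization:
    def test_control_only_normalizes_to_mean_one(self):
        wells = [_well("prom", v) for v in (0.8, 1.0, 1.2, 1.4)]
        norm = normalize_to_control(wells)
        assert np.mean(norm) == pytest.approx(1.0)

    def test_doubled_construct_normalizes_to_two(self):
        wells = [_well("prom", 1.0), _well("prom", 1.0), _well("E", 2.0), _well("E", 2.0)]
        norm = normalize_to_control(wells)
        assert norm.tolist() == [1.0, 1.0, 2.0, 2.0]

    def test_missing_control_names_id(self):
        with pytest.raises(ValueError, match="prom"):
            normalize_to_control([_well("E", 1.0)])

    def test_per_experiment_normalization_when_ids_exist(self):
        wells = [
            _well("prom", 1.0, "E1"), _well("prom", 1.0, "E1"),
            _well("prom", 2.0, "E2"), _well("prom", 2.0, "E2"),
            _well("X", 2.0, "E1"), _well("X", 4.0, "E2"),
        ]
        norm = normalize_to_control(wells)
        # each experiment is scaled by its own control mean
        assert norm[-2:].tolist() == [2.0, 2.0]

    def test_experiment_without_control_falls_back_to_global(self):
        wells = [
            _well("prom", 2.0, "E1"), _well("prom", 2.0, "E1"),
            _well("X", 4.0, "E2"),
        ]
        with pytest.warns(UserWarning, match="E2"):
            norm = normalize_to_control(wells)
        assert norm[-1] == pytest.approx(2.0)

    def test_idempotence(self):
        cfg = AssayConfig(seed=5, folds=(("X", 2.0),))
        wells, _ = simulate_assay(cfg)
        once = normalize_to_control(wells)
        renorm_wells = [
            LuciferaseWell(w.construct, experiment=w.experiment, ratio=v)
            for w, v in zip(wells, once)
        ]
        twice = normalize_to_control(renorm_wells)
        assert np.allclose(once, twice)

    def test_scale_invariance(self):
        """Multiplying both channels by positive constants leaves the
        normalized folds unchanged."""
        cfg = AssayConfig(seed=6, folds=(("X", 1.7),))
        wells, _ = simulate_assay(cfg)
        scaled = [
            LuciferaseWell(w.construct, experiment=w.experiment,
                           firefly=w.firefly * 137.0, renilla=w.renilla * 11.0)
            for w in wells
        ]
        assert np.allclose(normalize_to_control(wells), normalize_to_control(scaled))


class TestTTest:
    def test_identical_samples_give_p_one(self):
        t, p = t_test_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_separates(self):
        t, p = t_test_two_sample([1.0, 2.0, 3.0], [1001.0, 1002.0, 1003.0])
        assert p < 1e-9

    def test_zero_variance_edge_cases(self):
        assert t_test_two_sample([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = t_test_two_sample([2.0, 2.0], [3.0, 3.0])
        assert p == 0.0 and t < 0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_sample([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=int(rng.integers(3, 15))).tolist()
        y = rng.normal(0.5, 2, size=int(rng.integers(3, 15))).tolist()
        t, p = t_test_two_sample(x, y)
        t0, p0 = ttest_oracle(x, y)
        assert t == pytest.approx(t0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)


class TestClassification:
    def test_clean_separation_classifies_enhancer_and_silencer(self):
        cfg = AssayConfig(seed=7, folds=(("In1", 2.5), ("D6", 0.35), ("U1", 1.0)), sigma=0.1)
        wells, _ = simulate_assay(cfg)
        res = {r.construct: r for r in classify_elements(wells)}
        assert res["In1"].element_class == "enhancer"
        assert res["D6"].element_class == "silencer"
        assert res["U1"].element_class == "neutral"
        assert res["In1"].n == 12
        assert res["In1"].fold == pytest.approx(2.5, rel=0.2)

    def test_results_sorted_by_label_series(self):
        cfg = AssayConfig(seed=8, folds=(("D2", 1.0), ("U1", 1.0), ("I3", 1.0), ("In2", 1.0)))
        wells, _ = simulate_assay(cfg)
        order = [r.construct for r in classify_elements(wells)]
        series = [c for c in order if c in ("U1", "In2", "I3", "D2")]
        assert series == ["U1", "In2", "I3", "D2"]
        assert order.index("bas") > order.index("D2")  # non-series sort last

    def test_construct_sort_key_handles_both_intronic_prefixes(self):
        labels = ["D1", "I12", "In2", "U4-1", "U4-3", "U3", "con"]
        ordered = sorted(labels, key=construct_sort_key)
        assert ordered == ["U3", "U4-1", "U4-3", "In2", "I12", "D1", "con"]

    def test_underreplicated_element_skipped_with_warning(self):
        wells = [_well("prom", v) for v in (0.9, 1.0, 1.1, 1.0)] + [_well("X", 2.0)]
        with pytest.warns(UserWarning, match="X"):
            res = classify_elements(wells)
        assert all(r.construct != "X" for r in res)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            classify_elements([_well("prom", 1.0)], alpha=1.5)

    def test_fdr_flag_only_increases_p(self):
        cfg = AssayConfig(seed=9, folds=(("A1", 1.4), ("A2", 1.0), ("A3", 0.7)))
        wells, _ = simulate_assay(cfg)
        raw = {r.construct: r.p for r in classify_elements(wells)}
        adj = {r.construct: r.p for r in classify_elements(wells, fdr=True)}
        for c in raw:
            assert adj[c] >= raw[c] - 1e-15


def test_box_plot_figure_is_written(tmp_path):
    from ncecr.reporter_stats import plot_results

    cfg = AssayConfig(seed=11, folds=(("U1", 1.5), ("D6", 0.35)))
    wells, _ = simulate_assay(cfg)
    out = tmp_path / "fig.png"
    plot_results(wells, out)
    assert out.stat().st_size > 0


class TestTables:
    def test_long_raw_round_trip(self, tmp_path):
        cfg = AssayConfig(seed=10, folds=(("U1", 1.5),))
        wells, _ = simulate_assay(cfg)
        p = tmp_path / "assay.tsv"
        write_wells_tsv(wells, p)
        back = read_assay_table(p)
        assert len(back) == len(wells)
        assert np.allclose([w.value for w in back], [w.value for w in wells])
        assert [w.construct for w in back] == [w.construct for w in wells]

    def test_wide_ratio_layout_parses_ragged_columns(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text(
            "prom,D6,I12\n"
            "1.02,0.36,2.4\n"
            "0.98,0.33,2.6\n"
            "1.01,0.37,\n"       # ragged: I12 has one fewer replicate
            "0.99,0.35,2.5\n"
        )
        wells = read_assay_table(p)
        by = {}
        for w in wells:
            by.setdefault(w.construct, []).append(w.value)
        assert len(by["prom"]) == 4 and len(by["D6"]) == 4 and len(by["I12"]) == 3
        res = {r.construct: r for r in classify_elements(wells)}
        assert res["D6"].element_class == "silencer"
        assert res["I12"].element_class == "enhancer"

    def test_long_and_wide_layouts_agree(self, tmp_path):
        values = {"prom": [1.0, 1.1, 0.9], "X": [2.0, 2.2, 1.9]}
        wide = tmp_path / "w.csv"
        wide.write_text(
            "prom,X\n" + "\n".join(f"{a},{b}" for a, b in zip(values["prom"], values["X"])) + "\n"
        )
        long = tmp_path / "l.csv"
        long.write_text(
            "construct,ratio\n"
            + "\n".join(f"{c},{v}" for c, vs in values.items() for v in vs) + "\n"
        )
        rw = {r.construct: r for r in classify_elements(read_assay_table(wide))}
        rl = {r.construct: r for r in classify_elements(read_assay_table(long))}
        assert rw["X"].fold == pytest.approx(rl["X"].fold)
        assert rw["X"].p == pytest.approx(rl["X"].p)
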