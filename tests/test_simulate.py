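"""Ground-truth generator: category layout, waveform, noise and round-trip."""

import numpy as np
import pandas as pd
import pytest

from rhythmdiff.circular import PhaseSample, mean_vector
from rhythmdiff.simulate import (
    GeneTruth,
    SimulationDesign,
    expression_profile,
    generate_truth,
    largest_remainder_counts,
    read_truth,
    simulate_dataset,
    truth_frame,
    write_dataset,
)
from conftest import circ_dist_h


class TestCategoryCounts:
    def test_exact_split(self):
        counts = largest_remainder_counts(
            10, {"arrhythmic_both": 0.5, "gained_in_B": 0.5}
        )
        assert counts == {"arrhythmic_both": 5, "gained_in_B": 5}

    @pytest.mark.parametrize("n", [1, 7, 99, 2000])
    def test_sum_preserved(self, n):
        fr = {"arrhythmic_both": 0.6, "rhythmic_unchanged": 0.2,
              "phase_shifted": 0.1, "gained_in_B": 0.07, "lost_in_B": 0.03}
        counts = largest_remainder_counts(n, fr)
        assert sum(counts.values()) == n
        for c, f in fr.items():
            assert abs(counts[c] - n * f) < 1  # largest remainder never off by one full unit

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            largest_remainder_counts(10, {"arrhythmic_both": 0.7})
        with pytest.raises(ValueError):
            largest_remainder_counts(10, {"not_a_category": 1.0})
        with pytest.raises(ValueError):
            largest_remainder_counts(0, {"arrhythmic_both": 1.0})


def _one_truth(amp=0.5, phase=6.0, mesor=100.0):
    return GeneTruth(
        gene_id="g",
        category="rhythmic_unchanged",
        mesor={"WT": mesor, "KO": mesor},
        rel_amplitude={"WT": amp, "KO": amp},
        phase_h={"WT": phase, "KO": phase},
        noise_cv=0.1,
    )


class TestExpressionProfile:
    def test_peak_trough_constant(self):
        tr = _one_truth()
        assert expression_profile(tr, "WT", 6.0) == pytest.approx(150.0)
        assert expression_profile(tr, "WT", 18.0) == pytest.approx(50.0)
        flat = _one_truth(amp=0.0)
        t = np.arange(0, 24, 3.0)
        assert np.allclose(expression_profile(flat, "WT", t), 100.0)

    def test_peak_at_programmed_phase(self):
        tr = _one_truth(phase=13.0)
        t = np.linspace(0, 24, 241)
        prof = expression_profile(tr, "WT", t)
        assert t[np.argmax(prof)] == pytest.approx(13.0, abs=0.06)

    def test_overunity_amplitude_rejected(self):
        with pytest.raises(ValueError):
            _one_truth(amp=1.2)


class TestGenerateTruth:
    def test_gained_phase_clustering(self):
        truth = generate_truth(
            2000, {"gained_in_B": 0.5, "arrhythmic_both": 0.5}, seed=11
        )
        gained = [tr.phase_h["KO"] for tr in truth if tr.category == "gained_in_B"]
        mean_h, r = mean_vector(PhaseSample(np.array(gained)))
        assert circ_dist_h(mean_h, 6.0) < 0.5
        assert r > 0.7  # strongly clustered

    def test_night_peaking_reference(self):
        truth = generate_truth(1000, {"rhythmic_unchanged": 1.0}, seed=2)
        phases = np.array([tr.phase_h["WT"] for tr in truth])
        mean_h, _ = mean_vector(PhaseSample(phases))
        assert circ_dist_h(mean_h, 20.5) < 1.0

    def test_category_parameter_structure(self):
        truth = generate_truth(
            600,
            {"rhythmic_unchanged": 0.2, "phase_shifted": 0.2, "other_changed": 0.2,
             "gained_in_B": 0.2, "lost_in_B": 0.2},
            seed=3,
        )
        for tr in truth:
            if tr.category == "rhythmic_unchanged":
                assert tr.rel_amplitude["WT"] == tr.rel_amplitude["KO"]
                assert tr.phase_h["WT"] == tr.phase_h["KO"]
            elif tr.category == "phase_shifted":
                assert circ_dist_h(tr.phase_h["WT"], tr.phase_h["KO"]) > 6.0
                assert tr.rel_amplitude["WT"] == tr.rel_amplitude["KO"] > 0
            elif tr.category == "gained_in_B":
                assert tr.rel_amplitude["WT"] == 0.0 < tr.rel_amplitude["KO"]
            elif tr.category == "lost_in_B":
                assert tr.rel_amplitude["KO"] == 0.0 < tr.rel_amplitude["WT"]

    def test_determinism_and_substreams(self):
        a = generate_truth(50, seed=5)
        b = generate_truth(50, seed=5)
        assert truth_frame(a, ("WT", "KO")).equals(truth_frame(b, ("WT", "KO")))
        # extending the simulation leaves earlier genes' substreams untouched
        # (fixed category layout so only the gene count changes)
        small = generate_truth(50, {"rhythmic_unchanged": 1.0}, seed=5)
        big = generate_truth(80, {"rhythmic_unchanged": 1.0}, seed=5)
        cols = ["category", "mesor_WT", "rel_amplitude_WT", "phase_h_WT"]
        assert truth_frame(small, ("WT", "KO"))[cols].equals(
            truth_frame(big[:50], ("WT", "KO"))[cols]
        )
        c = generate_truth(50, seed=6)
        assert not truth_frame(a, ("WT", "KO")).equals(truth_frame(c, ("WT", "KO")))


class TestSimulateDataset:
    def test_zero_noise_is_exact(self):
        design = SimulationDesign(seed=0)
        truth = generate_truth(20, seed=0, noise_cv=0.0)
        ds = simulate_dataset(design, truth)
        t = np.asarray(design.timepoints_h)
        for k, tr in enumerate(truth):
            for g in design.groups:
                cols = [f"{g}_ZT{int(h):02d}" for h in t]
                np.testing.assert_allclose(
                    ds.expression.iloc[k][cols].to_numpy(),
                    expression_profile(tr, g, t),
                    rtol=1e-12,
                )

    def test_pooling_variance_ratio(self):
        # pooling 3 animals cuts the sampling variance of a pooled value to ~1/3
        tr = _one_truth(amp=0.0)
        var = {}
        for n_pool in (1, 3):
            design = SimulationDesign(animals_per_pool=n_pool, seed=1)
            vals = []  # flat gene: all 16 samples per draw are iid pooled values
            for s in range(700):
                d = simulate_dataset(design, [tr], seed=s)
                vals.extend(d.expression.to_numpy().ravel())
            var[n_pool] = np.var(vals)
        assert var[3] / var[1] == pytest.approx(1 / 3, rel=0.12)

    def test_negative_binomial_integer_counts(self):
        design = SimulationDesign(seed=4)
        truth = generate_truth(30, seed=4)
        ds = simulate_dataset(design, truth, noise_model="negative_binomial_dispersion")
        vals = ds.expression.to_numpy()
        assert np.all(vals >= 0)
        assert np.allclose(vals, np.round(vals))

    def test_lognormal_strictly_positive_and_mean_converges(self):
        tr = _one_truth()
        design = SimulationDesign(timepoints_h=(0.0, 6.0), animals_per_pool=1, seed=0)
        rngs = range(200)
        draws = np.array(
            [simulate_dataset(design, [tr], seed=s).expression.iloc[0, 0] for s in rngs]
        )
        assert np.all(draws > 0)
        # mean-preserving noise: 10^5 effective draws converge to the profile
        big_design = SimulationDesign(
            timepoints_h=tuple(np.linspace(0, 23.9, 4)), animals_per_pool=1, seed=0
        )
        flat = _one_truth(amp=0.0)
        tot, n = 0.0, 0
        for s in range(250):
            d = simulate_dataset(big_design, [flat] * 100, seed=s)
            tot += d.expression.to_numpy().sum()
            n += d.expression.size
        assert tot / n == pytest.approx(100.0, rel=0.01)

    def test_invalid_noise_model(self):
        design = SimulationDesign(seed=0)
        with pytest.raises(ValueError):
            simulate_dataset(design, generate_truth(5, seed=0), noise_model="poisson")


class TestRoundTrip:
    def test_write_then_read(self, tmp_path):
        design = SimulationDesign(seed=9)
        truth = generate_truth(25, seed=9)
        ds = simulate_dataset(design, truth, seed=9)
        expr_path, truth_path = write_dataset(ds, tmp_path)
        back = pd.read_csv(expr_path, sep="\t", index_col=0)
        np.testing.assert_allclose(
            back.to_numpy(), ds.expression.to_numpy(), rtol=1e-9
        )
        tf = read_truth(truth_path)
        assert len(tf) == 25
        assert list(tf["category"]) == [tr.category for tr in truth]

    def test_sample_naming_convention(self, tmp_path):
        design = SimulationDesign(seed=0, groups=("F_WT", "F_KO"))
        ds = simulate_dataset(design, generate_truth(3, seed=0, groups=design.groups))
        assert "F_KO_ZT06" in ds.expression.columns
        assert ds.expression.shape[1] == 16
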