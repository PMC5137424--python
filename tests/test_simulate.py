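"""Synthetic-data generator: reproducibility, generative expectations and
ground-truth structure."""

import numpy as np
import pandas as pd
import pytest

from occupre.simulate import SimulationConfig, simulate_tracks
from occupre.tracks import read_bedgraph

CLASSES = ("dependent", "intermediate", "independent")


def _uniform(att):
    return {c: att for c in CLASSES}


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(chrom_length=300_000, n_pres=8, seed=5)
        a, b = simulate_tracks(cfg), simulate_tracks(cfg)
        for g in ("control", "mutant"):
            for ta, tb in zip(a.chip_tracks[g], b.chip_tracks[g]):
                np.testing.assert_array_equal(ta.values, tb.values)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = simulate_tracks(SimulationConfig(chrom_length=300_000, n_pres=8, seed=5))
        b = simulate_tracks(SimulationConfig(chrom_length=300_000, n_pres=8, seed=6))
        assert not np.array_equal(
            a.chip_tracks["control"][0].values, b.chip_tracks["control"][0].values
        )


class TestPlacement:
    def test_impossible_placement_names_constraint(self):
        with pytest.raises(ValueError, match="min_spacing"):
            simulate_tracks(SimulationConfig(chrom_length=100_000, n_pres=50))

    def test_spacing_and_bounds(self, small_sim):
        centers = np.sort(small_sim.truth["center"].values)
        cfg = small_sim.config
        assert np.diff(centers).min() >= cfg.min_spacing
        assert centers.min() >= cfg.tail_extent
        assert centers.max() <= cfg.chrom_length - cfg.tail_extent
        for iv in small_sim.catalog:
            assert 0 <= iv.start < iv.end <= cfg.chrom_length
            assert len(iv) == cfg.pre_width

    def test_class_labels_from_allowed_set(self, small_sim):
        assert set(small_sim.truth["dep_class"]) <= set(CLASSES)
        assert len(small_sim.truth) == small_sim.config.n_pres


class TestGenerativeExpectations:
    def test_no_enrichment_means_flat(self):
        """With amplitude 1 the mean coverage inside elements matches the
        mean outside within Monte-Carlo error (control genotype)."""
        cfg = SimulationConfig(
            chrom_length=500_000, n_pres=10, summit_amplitude_control=1.0,
            seed=2,
        )
        sim = simulate_tracks(cfg)
        vals = sim.chip_tracks["control"][0].values
        mask = np.zeros(cfg.chrom_length, dtype=bool)
        for iv in sim.catalog:
            mask[iv.start : iv.end] = True
        inside, outside = vals[mask], vals[~mask]
        se = np.sqrt(
            inside.var() / inside.size + outside.var() / outside.size
        )
        assert abs(inside.mean() - outside.mean()) < 3 * se

    def test_identical_genotypes_when_attenuation_one(self):
        """Attenuation 1.0 for all classes centers downstream RD on 0."""
        from occupre.dependence import PREDependenceModel

        cfg = SimulationConfig(
            chrom_length=800_000, n_pres=20,
            attenuation_by_class=_uniform(1.0),
            depth_factors={"control": [1.0, 1.3], "mutant": [0.8, 1.1]},
            seed=3,
        )
        sim = simulate_tracks(cfg)
        res = PREDependenceModel(sim.catalog, sim.chip_tracks).fit()
        rd = res.classified["RD"]
        assert abs(rd.mean()) < 0.05
        assert (rd.abs() < 0.25).all()

    def test_class_summit_coverage_expectations(self):
        """Mutant mean summit coverage per class ~ background x amplitude
        x attenuation = 1.0 / 4.0 / 9.0 reads/bp for the reference
        configuration (closed-form expectation of the generative model)."""
        cfg = SimulationConfig(
            n_pres=60,
            attenuation_by_class={
                "dependent": 0.1, "intermediate": 0.4, "independent": 0.9
            },
            background_rate=0.5,
            summit_amplitude_control=20.0,
            amplitude_cv=0.0,
            depth_factors={"control": [1.0, 1.0], "mutant": [1.0, 1.0]},
            seed=1,
        )
        sim = simulate_tracks(cfg)
        expected = {"dependent": 1.0, "intermediate": 4.0, "independent": 9.0}
        for label, exp in expected.items():
            rows = sim.truth[sim.truth["dep_class"] == label]
            cov = [
                tr.values[r.center - 100 : r.center + 100].mean()
                for _, r in rows.iterrows()
                for tr in sim.chip_tracks["mutant"]
            ]
            assert np.mean(cov) == pytest.approx(exp, rel=0.10)

    def test_depth_linearity(self):
        """Scaling a library's depth factor by k scales expected coverage
        everywhere by k (checked on large windows)."""
        base = dict(chrom_length=400_000, n_pres=8, seed=9)
        a = simulate_tracks(SimulationConfig(
            depth_factors={"control": [1.0, 1.0], "mutant": [1.0, 1.0]}, **base))
        b = simulate_tracks(SimulationConfig(
            depth_factors={"control": [3.0, 3.0], "mutant": [3.0, 3.0]}, **base))
        for g in ("control", "mutant"):
            ma = a.chip_tracks[g][0].values.mean()
            mb = b.chip_tracks[g][0].values.mean()
            assert mb / ma == pytest.approx(3.0, rel=0.02)
            assert b.chip_tracks[g][0].depth / a.chip_tracks[g][0].depth == 3.0

    def test_class_separation_of_summit_ratios(self, default_sim):
        """True-dependent elements show a lower mutant/control summit
        ratio than true-independent ones in >= 99% of pairs."""
        truth = default_sim.truth
        ratios = {}
        for label in ("dependent", "independent"):
            rows = truth[truth["dep_class"] == label]
            vals = []
            for _, r in rows.iterrows():
                c = np.mean([
                    t.values[r.center - 100 : r.center + 100].mean()
                    for t in default_sim.chip_tracks["control"]
                ])
                m = np.mean([
                    t.values[r.center - 100 : r.center + 100].mean()
                    for t in default_sim.chip_tracks["mutant"]
                ])
                vals.append(m / c)
            ratios[label] = np.array(vals)
        dep, ind = ratios["dependent"], ratios["independent"]
        frac = (dep[:, None] < ind[None, :]).mean()
        assert frac >= 0.99

    def test_input_tracks_are_background_only(self, small_sim):
        cfg = small_sim.config
        for g, tracks in small_sim.input_tracks.items():
            for i, tr in enumerate(tracks):
                d = cfg.depth_factors[g][i]
                assert tr.values.mean() == pytest.approx(
                    d * cfg.background_rate, rel=0.02
                )

    def test_negative_binomial_overdispersion(self):
        cfg_p = SimulationConfig(chrom_length=300_000, n_pres=6, seed=4)
        cfg_nb = SimulationConfig(
            chrom_length=300_000, n_pres=6, seed=4,
            noise_model="negative_binomial", nb_dispersion=2.0,
        )
        vp = simulate_tracks(cfg_p).input_tracks["control"][0].values
        vnb = simulate_tracks(cfg_nb).input_tracks["control"][0].values
        # NB variance mu + disp*mu^2 = 1.0 vs Poisson variance mu = 0.5
        assert vnb.var() > 1.5 * vp.var()


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(class_fractions={"dependent": 0.5, "intermediate": 0.2,
                                              "independent": 0.2})

    def test_depth_factor_count_checked(self):
        with pytest.raises(ValueError, match="depth_factors"):
            SimulationConfig(depth_factors={"control": [1.0], "mutant": [1.0, 1.0]})

    def test_unknown_noise_model(self):
        with pytest.raises(ValueError, match="noise_model"):
            SimulationConfig(noise_model="gauss")


class TestBundleIO:
    def test_written_bundle_round_trips(self, small_sim, tmp_path):
        small_sim.write(tmp_path)
        back = read_bedgraph(tmp_path / "chip_control_rep1.bedgraph")
        orig = small_sim.chip_tracks["control"][0].values
        np.testing.assert_array_equal(back[small_sim.config.chrom].values, orig)
        truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert len(truth) == small_sim.config.n_pres
        assert (tmp_path / "catalog.bed").exists()
        assert (tmp_path / "simulation_config.yaml").exists()
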