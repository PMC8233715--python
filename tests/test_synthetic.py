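"""Synthetic generator: moment targets, constraints, spectral shape, determinism."""

import numpy as np
import pytest

import nirspec_fa as nf
from nirspec_fa import synthetic
from nirspec_fa.reference_data import DESCRIPTIVE


@pytest.fixture(scope="module")
def big_reference():
    config = nf.SimulationConfig(n_samples=2000, seed=7)
    return nf.simulate_concentrations(config)


class TestConcentrations:
    def test_total_fa_hits_target_moments(self, big_reference):
        # Monte-Carlo check against the generator's own targets (the
        # calibration-set mean and CV of total fatty acids).
        v = big_reference[
            (big_reference.fraction == "total")
            & (big_reference.analyte == "TotalFA")
        ].value_mg_per_100g
        target_mean, _, _, _, target_cv = DESCRIPTIVE["total"]["TotalFA"]["calibration"]
        assert abs(v.mean() - target_mean) / target_mean < 0.05
        cv = v.std(ddof=1) / v.mean() * 100
        assert abs(cv - target_cv) / target_cv < 0.10

    def test_member_marginals_hit_targets(self, big_reference):
        for analyte in ("16:0", "18:1c9"):
            v = big_reference[
                (big_reference.fraction == "total")
                & (big_reference.analyte == analyte)
            ].value_mg_per_100g
            mean, _, _, _, cv_t = DESCRIPTIVE["total"][analyte]["calibration"]
            assert abs(v.mean() - mean) / mean < 0.05
            assert abs(v.std(ddof=1) / v.mean() * 100 - cv_t) / cv_t < 0.10

    def test_near_degenerate_cv_collapses_to_mean(self):
        priors = nf.default_priors()
        tight = {
            k: nf.AnalytePrior(p.name, p.fraction, p.mean, 0.01)
            for k, p in priors.items()
        }
        ref = nf.simulate_concentrations(
            nf.SimulationConfig(n_samples=50, seed=2), priors=tight
        )
        v = ref[(ref.fraction == "phospholipid") & (ref.analyte == "16:0")]
        np.testing.assert_allclose(v.value_mg_per_100g, 64.42, rtol=2e-3)

    def test_phospholipid_never_exceeds_total(self, big_reference):
        wide = big_reference.pivot_table(
            index=["sample_id", "analyte"], columns="fraction",
            values="value_mg_per_100g",
        )
        assert (wide["phospholipid"] <= wide["total"] + 1e-9).all()

    def test_group_sums_bounded_by_total(self, big_reference):
        tot = big_reference[big_reference.fraction == "total"].pivot(
            index="sample_id", columns="analyte", values="value_mg_per_100g"
        )
        groups = tot["SFA"] + tot["MUFA"] + tot["PUFA"]
        assert (groups <= tot["TotalFA"] + 1e-9).all()

    def test_total_fraction_more_variable_than_phospholipid(self, big_reference):
        cvs = {}
        for frac in ("total", "phospholipid"):
            v = big_reference[
                (big_reference.fraction == frac)
                & (big_reference.analyte == "TotalFA")
            ].value_mg_per_100g
            cvs[frac] = v.std(ddof=1) / v.mean()
        assert cvs["total"] > 2 * cvs["phospholipid"]

    def test_invalid_cv_rejected(self):
        with pytest.raises(Exception, match="CV"):
            nf.AnalytePrior("16:0", "total", 10.0, 0.0)


class TestSpectra:
    def test_noiseless_mixing_matches_band_summation_oracle(self):
        grid = nf.WavelengthGrid(1000.0, 0.5, 301)
        bands = {"16:0": [(1050.0, 20.0, 1e-4), (1120.0, 15.0, 5e-5)]}
        conc = {"16:0": 700.0}
        mixed = synthetic.mix_spectrum(conc, bands, grid)
        # independent brute-force summation
        lam = grid.wavelengths()
        oracle = synthetic.baseline_shape(grid).copy()
        for center, width, coeff in bands["16:0"]:
            oracle = oracle + 700.0 * coeff * np.exp(-((lam - center) ** 2) / (2 * width**2))
        np.testing.assert_allclose(mixed, oracle, atol=1e-14)

    def test_zero_concentrations_give_baseline(self):
        grid = nf.DEFAULT_GRID
        conc = dict.fromkeys(nf.FATTY_ACIDS, 0.0)
        mixed = synthetic.mix_spectrum(conc, nf.default_band_library(grid), grid)
        np.testing.assert_array_equal(mixed, synthetic.baseline_shape(grid))

    def test_mean_spectrum_has_study_envelope(self, sim300):
        _, _, spectra = sim300
        X = np.vstack([s.absorbance for s in spectra])
        assert 0.2 <= X[:, 0].mean() <= 0.6       # ~0.4 at 1000 nm
        assert 0.8 <= X[:, -1].mean() <= 1.4      # ~1.0 at 2500 nm

    def test_water_band_regions_stay_quiet(self, sim300):
        # freeze-dried emulation: no absorption feature at 1440-1470 or
        # 1920-1960 nm beyond the smooth baseline
        _, _, spectra = sim300
        grid = spectra[0].grid
        lam = grid.wavelengths()
        mean = np.vstack([s.absorbance for s in spectra]).mean(axis=0)
        base = synthetic.baseline_shape(grid)
        for lo, hi in ((1440, 1470), (1920, 1960)):
            sel = (lam >= lo) & (lam <= hi)
            assert np.abs(mean[sel] - base[sel]).max() < 0.02

    def test_band_outside_grid_rejected(self):
        grid = nf.WavelengthGrid(1000.0, 0.5, 101)
        with pytest.raises(Exception, match="grid"):
            nf.default_band_library(grid)


class TestGenerateDataset:
    def test_deterministic_and_correct_shape(self, tmp_path):
        config = nf.SimulationConfig(n_samples=20, seed=9)
        p1 = nf.generate_dataset(config, tmp_path / "a")
        p2 = nf.generate_dataset(config, tmp_path / "b")
        for key in ("spectra", "chemistry"):
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()
        scans = nf.read_spectra(p1["spectra"])
        assert len(scans) == 40  # two scans per sample
        assert len({s.sample_id for s in scans}) == 20
        ref = nf.read_reference(p1["chemistry"])
        assert set(ref.analyte) == set(nf.ANALYTES)
        assert set(ref.fraction) == {"phospholipid", "total"}
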