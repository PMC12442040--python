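"""Phantom generator: geometry, forward model, imzML round-trip."""

import numpy as np
import pytest

import kmdmsi as K
from kmdmsi import phantom as P
from kmdmsi.imzml_io import MSIDataset, read_imzml, write_imzml


class TestPhantomGeometry:
    def test_default_has_seven_nonempty_disjoint_regions(self, phantom64):
        masks = phantom64.region_masks
        assert len(masks) == 7
        assert all(m.any() for m in masks.values())
        total = sum(int(m.sum()) for m in masks.values())
        assert total == int((phantom64.labels > 0).sum())  # disjoint
        assert total <= 64 * 64

    def test_same_spec_reproduces_identical_labels(self):
        a = K.build_phantom(K.PhantomSpec(32, 32, seed=7))
        b = K.build_phantom(K.PhantomSpec(32, 32, seed=7))
        assert np.array_equal(a.labels, b.labels)

    def test_ovary_shell_and_core_partition_the_ovary(self, phantom64):
        shell = phantom64.sub_masks["ovary_shell"]
        core = phantom64.sub_masks["ovary_core"]
        assert not (shell & core).any()
        assert np.array_equal(shell | core, phantom64.region_masks["ovary"])

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            K.PhantomSpec(height=8, width=8)


class TestMatrixIons:
    def test_six_cluster_ions_inside_acquisition_window(self):
        ions = K.matrix_ion_set()
        assert len(ions) == 6
        assert all(200.0 <= mz <= 1400.0 for mz in ions)

    def test_monomer_sodium_adduct_from_mass_oracle(self):
        expected = K.monoisotopic_mass("C10H7NO3") + 22.98976928 - 0.00054858
        assert K.matrix_ion_set()[0] == pytest.approx(expected, abs=1e-9)

    def test_no_pair_differs_by_a_ch2_multiple(self):
        # pairwise-difference oracle: matrix clusters must not align
        # horizontally in CH2-based Kendrick space
        ions = sorted(K.matrix_ion_set())
        for i in range(len(ions)):
            for j in range(i + 1, len(ions)):
                delta = ions[j] - ions[i]
                k = round(delta / 14.01565)
                if k >= 1:
                    dev_ppm = abs(delta - k * 14.01565) / ions[j] * 1e6
                    assert dev_ppm > 2.0


def _noiseless_instrument(**kw):
    return P.InstrumentModel(ppm_sigma=0.0, noise_cv=0.0, baseline=0.0, **kw)


class TestPixelForwardModel:
    def test_matrix_only_pixel_contains_exactly_six_peaks(self):
        rng = np.random.default_rng(0)
        mz, sig, truth = P.simulate_pixel_spectrum([], _noiseless_instrument(), rng)
        peaks = K.pick_peaks(mz, sig, K.PickingParams(intensity_threshold=1e5))
        assert len(peaks) == 6
        for peak, ion in zip(peaks, sorted(K.matrix_ion_set())):
            assert abs(peak.mz - ion) / ion * 1e6 < 0.5
        assert len(truth) == 6

    def test_noiseless_apex_at_theoretical_mz(self):
        rng = np.random.default_rng(0)
        a = P.SpeciesAssignment(
            "brain", "PC 34:1", "C42H82NO8P", {"[M+Na]+": 1.0}, 1e9
        )
        instrument = _noiseless_instrument()
        mz, sig, _ = P.simulate_pixel_spectrum([a], instrument, rng, matrix_ions=[])
        target = K.ion_mz("C42H82NO8P", "[M+Na]+")
        apex = mz[np.argmax(sig)]
        grid_step = instrument.fwhm(target) / instrument.points_per_fwhm
        assert abs(apex - target) <= grid_step

    def test_rendered_fwhm_doubles_from_400_to_800(self):
        # R(m) = R0*400/m implies FWHM(800) = 4x FWHM(400) in Da is wrong;
        # FWHM(m) = m^2/(R0*400), so the ratio at 800 vs 400 is 4.  Measure
        # the rendered half-maximum widths and check the quadratic law.
        instrument = _noiseless_instrument(points_per_fwhm=40)
        mz, sig = P._profile_from_peaks([(400.0, 1.0), (800.0, 1.0)], instrument)

        def measured_fwhm(center):
            sel = (mz > center - 0.5) & (mz < center + 0.5)
            x, y = mz[sel], sig[sel]
            above = x[y >= 0.5]
            return above.max() - above.min()

        ratio = measured_fwhm(800.0) / measured_fwhm(400.0)
        assert ratio == pytest.approx(4.0, rel=0.15)
        assert instrument.fwhm(800.0) / instrument.fwhm(400.0) == pytest.approx(4.0)

    def test_out_of_range_species_skipped(self, caplog):
        rng = np.random.default_rng(0)
        a = P.SpeciesAssignment("brain", "tiny", "C2H6", {"[M+H]+": 1.0}, 1e9)
        with caplog.at_level("WARNING", logger="kmdmsi.phantom"):
            mz, sig, truth = P.simulate_pixel_spectrum(
                [a], _noiseless_instrument(), rng, matrix_ions=[]
            )
        assert len(truth) == 0 and mz.size == 0

    def test_noiseless_profile_conserves_peak_area(self):
        rng = np.random.default_rng(0)
        a = P.SpeciesAssignment("brain", "PC 34:1", "C42H82NO8P", {"[M+H]+": 1.0}, 1e8)
        instrument = _noiseless_instrument()
        mz, sig, truth = P.simulate_pixel_spectrum([a], instrument, rng, matrix_ions=[])
        integral = np.trapezoid(sig, mz)
        expected = 0.0
        for rec in truth:
            fwhm = instrument.fwhm(rec["mz_true"])
            sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
            expected += rec["intensity"] * sigma * np.sqrt(2 * np.pi)
        assert integral == pytest.approx(expected, rel=0.01)

    def test_invalid_assignment_weights_rejected(self):
        with pytest.raises(ValueError):
            P.SpeciesAssignment("brain", "x", "C2H6", {"[M+H]+": 0.0}, 1e9)
        with pytest.raises(ValueError):
            P.SpeciesAssignment("brain", "x", "C2H6", {"[M+H]+": 1.0}, -1.0)


class TestDatasetSimulation:
    def test_same_seed_reproduces_dataset_exactly(self):
        ph = K.build_phantom(K.PhantomSpec(16, 16))
        d1, t1 = K.simulate_dataset(ph, seed=5)
        d2, t2 = K.simulate_dataset(ph, seed=5)
        assert all(np.array_equal(a, b) for a, b in zip(d1.mzs, d2.mzs))
        assert all(np.array_equal(a, b) for a, b in zip(d1.intensities, d2.intensities))
        assert t1.equals(t2)

    def test_mass_accuracy_envelope(self, default_run):
        truth = default_run["truth"]
        dev = (truth.mz_observed - truth.mz_true).abs() / truth.mz_true * 1e6
        assert (dev < 3.0).mean() >= 0.99

    def test_matrix_everywhere_species_only_at_home(self, default_run):
        truth = default_run["truth"]
        phantom = default_run["phantom"]
        n_pix = phantom.labels.size
        matrix_pixels = truth[truth.species == "matrix"][["x", "y"]].drop_duplicates()
        assert len(matrix_pixels) == n_pix
        for species, grp in truth[truth.species != "matrix"].groupby("species"):
            masks = [
                phantom.mask(a.region)
                for a in default_run["assignments"]
                if a.species == species
            ]
            home = np.logical_or.reduce(masks)
            assert all(home[y, x] for x, y in grp[["x", "y"]].itertuples(index=False))

    def test_truth_covers_every_planted_peak(self):
        ph = K.build_phantom(K.PhantomSpec(16, 16))
        assigns = [
            P.SpeciesAssignment("brain", "PC 34:1", "C42H82NO8P",
                                {"[M+H]+": 1.0, "[M+Na]+": 0.5}, 1e9, "PC:1")
        ]
        _, truth = K.simulate_dataset(ph, assigns, seed=2)
        brain_px = int(ph.region_masks["brain"].sum())
        # per brain pixel: 2 adducts x 3 isotopologues + 6 matrix ions
        expected = brain_px * (2 * P.N_ISOTOPOLOGUES) + ph.labels.size * 6
        assert len(truth) == expected


class TestImzmlRoundTrip:
    def _tiny_dataset(self, shared_axis=False):
        rng = np.random.default_rng(0)
        axis = np.linspace(200, 210, 50)
        mzs, its, coords = [], [], []
        for y in range(2):
            for x in range(2):
                mz = axis if shared_axis else axis + rng.uniform(0, 1e-4)
                mzs.append(np.array(mz))
                its.append(rng.uniform(0, 1e6, size=axis.size))
                coords.append((x, y))
        return MSIDataset(mzs, its, coords, shape=(2, 2))

    @pytest.mark.parametrize("mode", ["processed", "continuous"])
    def test_round_trip_preserves_coordinates_and_arrays(self, tmp_path, mode):
        ds = self._tiny_dataset(shared_axis=(mode == "continuous"))
        path = str(tmp_path / "t.imzML")
        write_imzml(ds, path, mode=mode)
        back = read_imzml(path)
        assert back.coordinates == ds.coordinates
        for a, b in zip(ds.mzs, back.mzs):
            np.testing.assert_allclose(a, b, rtol=1e-6)
        for a, b in zip(ds.intensities, back.intensities):
            np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_continuous_mode_requires_shared_axis(self, tmp_path):
        ds = self._tiny_dataset(shared_axis=False)
        with pytest.raises(ValueError, match="continuous"):
            write_imzml(ds, str(tmp_path / "c.imzML"), mode="continuous")

    def test_reader_agrees_with_direct_parser(self, tmp_path):
        # independent route: raw pyimzml parser vs our dataset wrapper
        from pyimzml.ImzMLParser import ImzMLParser

        ds = self._tiny_dataset()
        path = str(tmp_path / "t.imzML")
        write_imzml(ds, path)
        ours = read_imzml(path)
        raw = ImzMLParser(path)
        for i, (x, y, _z) in enumerate(raw.coordinates):
            mz, it = raw.getspectrum(i)
            assert ours.coordinates[i] == (x - 1, y - 1)
            np.testing.assert_array_equal(ours.mzs[i], mz)

    def test_missing_file_raises(self):
        with pytest.raises(FileNotFoundError):
            read_imzml("/nonexistent/file.imzML")
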