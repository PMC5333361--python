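from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardax import localization as loc
from cardax import synthetic_data as sd


class TestMeasureCell:
    def test_uniform_intensity(self):
        img = np.full((20, 20), 7.0)
        cell = np.zeros((20, 20), dtype=bool)
        cell[2:18, 2:18] = True
        nuc = np.zeros_like(cell)
        nuc[8:12, 8:12] = True
        rec = loc.measure_cell(img, cell, nuc)
        assert rec.pi_tot == pytest.approx(7.0)
        assert rec.pi_nucl == pytest.approx(7.0)

    def test_partitioned_intensity_arithmetic(self):
        """Intensity 10 over a 10-px nucleus in a 50-px cell: PItot = 2."""
        img = np.zeros((1, 50))
        cell = np.ones((1, 50), dtype=bool)
        nuc = np.zeros_like(cell)
        nuc[0, :10] = True
        img[nuc] = 10.0
        rec = loc.measure_cell(img, cell, nuc)
        assert rec.pi_nucl == pytest.approx(10.0)
        assert rec.pi_tot == pytest.approx(2.0)

    def test_nucleus_outside_cell_rejected(self):
        cell = np.zeros((4, 4), dtype=bool)
        cell[0, 0] = True
        nuc = np.zeros_like(cell)
        nuc[3, 3] = True
        with pytest.raises(ValueError, match="contained"):
            loc.measure_cell(np.ones((4, 4)), cell, nuc)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            loc.measure_cell(np.ones((4, 4)), np.zeros((4, 4), bool),
                             np.zeros((4, 4), bool))

    def test_scene_two_compartment_recovery(self):
        """Measured compartment means match the closed-form expectation."""
        spec = sd.SceneSpec(shape=(16, 72, 72), n_nuclei=4, f_nuc=0.3,
                            channels=("protein",), separation_basis="cell", seed=6)
        stack, truth = sd.make_scene(spec)
        img = stack.channel("protein")
        recs = loc.measure_cells(img, truth.cell_labels, truth.nucleus_labels)
        assert len(recs) == 4
        for rec in recs:
            row = truth.nuclei[truth.nuclei.nucleus_id == rec.cell_id - 1].iloc[0]
            r, rc = row.radius_um, spec.cell_radius_factor * row.radius_um
            v_cell = 4 / 3 * np.pi * rc**3
            v_nuc = 4 / 3 * np.pi * r**3
            c_nuc = spec.f_nuc * spec.signal * v_cell / v_nuc
            c_cyt = (1 - spec.f_nuc) * spec.signal * v_cell / (v_cell - v_nuc)
            n_n, n_c = rec.nuclear_area, rec.cell_area - rec.nuclear_area
            expect_tot = spec.background + (n_n * c_nuc + n_c * c_cyt) / (n_n + n_c)
            assert rec.pi_nucl == pytest.approx(spec.background + c_nuc, rel=1e-6)
            assert rec.pi_tot == pytest.approx(expect_tot, rel=1e-6)


class TestNCRatio:
    def test_published_formula(self):
        rec = loc.CellIntensityRecord(0, 10.0, 8.0, 50.0, 10.0)
        assert loc.nc_ratio(rec).ratio == pytest.approx(4.0)

    def test_zero_nuclear_signal(self):
        rec = loc.CellIntensityRecord(0, 5.0, 0.0, 50.0, 10.0)
        res = loc.nc_ratio(rec)
        assert res.ratio == 0.0 and not res.saturated

    def test_saturated_flag_not_crash(self):
        rec = loc.CellIntensityRecord(0, 8.0, 8.0, 50.0, 10.0)
        res = loc.nc_ratio(rec)
        assert res.saturated and np.isnan(res.ratio)

    def test_corrected_variant_uses_area_weighted_cytoplasm(self):
        # nucleus mean 10 on 10 px, cytoplasm mean 2 on 40 px -> PItot = 3.6
        rec = loc.CellIntensityRecord(0, 3.6, 10.0, 50.0, 10.0)
        assert loc.nc_ratio(rec).saturated  # verbatim formula leaves its domain
        res = loc.nc_ratio(rec, corrected=True)
        assert res.ratio == pytest.approx(5.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.01, 100), st.floats(0, 0.99), st.floats(0.01, 50))
    def test_scale_invariance(self, pi_tot, frac, scale):
        """Multiplying all intensities by a constant leaves the ratio fixed."""
        rec1 = loc.CellIntensityRecord(0, pi_tot, frac * pi_tot, 50.0, 10.0)
        rec2 = loc.CellIntensityRecord(0, scale * pi_tot, scale * frac * pi_tot,
                                       50.0, 10.0)
        assert loc.nc_ratio(rec1).ratio == pytest.approx(loc.nc_ratio(rec2).ratio,
                                                         rel=1e-9)

    def test_monotone_in_nuclear_fraction_scene_series(self):
        """Median N/C ratio increases with the planted nuclear fraction."""
        medians_corr = []
        for f in np.linspace(0.1, 0.9, 5):
            spec = sd.SceneSpec(shape=(14, 96, 96), n_nuclei=10, f_nuc=float(f),
                                channels=("protein",), separation_basis="cell",
                                gaussian_noise_sd=1.0, seed=31)
            stack, truth = sd.make_scene(spec)
            recs = loc.measure_cells(stack.channel("protein"), truth.cell_labels,
                                     truth.nucleus_labels)
            ratios = [loc.nc_ratio(r, corrected=True).ratio for r in recs]
            medians_corr.append(np.median(ratios))
        assert np.all(np.diff(medians_corr) > 0)

    def test_monotone_verbatim_within_domain(self):
        """The verbatim ratio is monotone over fractions below saturation."""
        medians = []
        for f in (0.02, 0.05, 0.08, 0.11):
            spec = sd.SceneSpec(shape=(14, 96, 96), n_nuclei=10, f_nuc=f,
                                channels=("protein",), separation_basis="cell",
                                seed=32)
            stack, truth = sd.make_scene(spec)
            recs = loc.measure_cells(stack.channel("protein"), truth.cell_labels,
                                     truth.nucleus_labels)
            ratios = [loc.nc_ratio(r).ratio for r in recs]
            assert not np.any(np.isnan(ratios))
            medians.append(np.median(ratios))
        assert np.all(np.diff(medians) > 0)


class TestStrongCells:
    def _recs(self, values):
        return [loc.CellIntensityRecord(i, max(v, 0) + 1000.0, max(v, 0), 50.0, 10.0)
                for i, v in enumerate(values)]

    def test_threshold_formula(self):
        controls = self._recs([90.0, 100.0, 110.0])  # mean 100, SD 10
        strong, pct, thr = loc.strong_cells(self._recs([125.0, 115.0]), controls)
        assert thr == pytest.approx(120.0)
        assert list(strong) == [True, False]
        assert pct == pytest.approx(50.0)

    def test_self_application_tail(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(100, 10, 500)
        recs = self._recs(vals)
        strong, pct, thr = loc.strong_cells(recs, recs)
        expected = 100.0 * np.mean(vals > vals.mean() + 2 * vals.std(ddof=1))
        assert pct == pytest.approx(expected)

    def test_gaussian_null_tail_mass(self):
        """Null treatment vs Gaussian controls -> ~2.28% strong cells."""
        rng = np.random.default_rng(7)
        controls = self._recs(rng.normal(100, 10, 10_000))
        treatment = self._recs(rng.normal(100, 10, 10_000))
        _, pct, _ = loc.strong_cells(treatment, controls)
        assert pct == pytest.approx(2.28, abs=0.6)  # Monte-Carlo error

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        base_c = rng.normal(50, 5, 200)
        base_t = rng.normal(55, 5, 200)
        _, pct1, _ = loc.strong_cells(self._recs(base_t), self._recs(base_c))
        _, pct2, _ = loc.strong_cells(self._recs(3 * base_t + 7),
                                      self._recs(3 * base_c + 7))
        assert pct1 == pytest.approx(pct2)

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match="control"):
            loc.strong_cells(self._recs([1.0]), self._recs([1.0]))


class TestMosaic:
    def test_well_separated_clusters(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal((200, 20), 5, (100, 2)),
                         rng.normal((20, 200), 5, (100, 2))])
        res = loc.mosaic_classify(pts, seed=0)
        assert res.fractions == (0.5, 0.5)
        assert np.all(res.classes[:100] == "A") and np.all(res.classes[100:] == "B")

    def test_unbalanced_mixture_recovery(self):
        rng = np.random.default_rng(1)
        n_a = 350
        pts = np.vstack([rng.normal((200, 20), 5, (n_a, 2)),
                         rng.normal((20, 200), 5, (500 - n_a, 2))])
        res = loc.mosaic_classify(pts, seed=0)
        assert abs(res.fractions[0] - n_a / 500) < 0.02

    def test_recovery_degrades_with_separation(self):
        """Misclassification grows monotonically as clusters merge."""
        rng = np.random.default_rng(4)
        errors = []
        for sep in (20.0, 8.0, 2.0, 0.5):
            a = rng.normal((sep, 0.0), 1.0, (300, 2))
            b = rng.normal((-sep, 0.0), 1.0, (300, 2))
            res = loc.mosaic_classify(np.vstack([a, b]), seed=0)
            truth = np.array(["A"] * 300 + ["B"] * 300)
            errors.append(np.mean(res.classes != truth))
        assert errors == sorted(errors)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            loc.mosaic_classify(np.ones((10, 2)))

    def test_reporter_signal_measurement_excludes_nucleus(self):
        spec = sd.SceneSpec(shape=(12, 80, 80), n_nuclei=8,
                            reporters=sd.ReporterSpec(frac_a=0.5),
                            separation_basis="cell",
                            channels=("nuclei", "gfp", "tomato"), seed=12)
        stack, truth = sd.make_scene(spec)
        df = loc.measure_reporter_signals(stack.channel("gfp"),
                                          stack.channel("tomato"),
                                          truth.nucleus_labels)
        assert len(df) == 8
        res = loc.mosaic_classify(df[["signal_a", "signal_b"]].to_numpy(), seed=0)
        planted = truth.nuclei.set_index("nucleus_id").reporter_class
        recovered = dict(zip(df.nucleus_id - 1, res.classes))
        assert all(recovered[i] == planted[i] for i in recovered)


class TestProjections:
    def test_best_focus_slice_maximizes_variance(self):
        vox = np.zeros((5, 16, 16, 1))
        vox[3, ::2, ::2, 0] = 100.0  # high-contrast slice
        from cardax.io_formats import MultiChannelStack
        stack = MultiChannelStack(vox, ("nuclei",), (1, 1, 1))
        assert loc.best_focus_slice(stack) == 3

    def test_z_projection_sums(self):
        vox = np.ones((4, 8, 8, 1))
        from cardax.io_formats import MultiChannelStack
        stack = MultiChannelStack(vox, ("protein",), (1, 1, 1))
        np.testing.assert_allclose(loc.z_project_sum(stack, "protein"), 4.0)


class TestCellRecordIO:
    def test_round_trip(self, tmp_path):
        recs = [loc.CellIntensityRecord(1, 5.0, 2.0, 40.0, 9.0),
                loc.CellIntensityRecord(2, 6.5, 6.0, 30.0, 8.0)]
        path = tmp_path / "cells.csv"
        loc.write_cell_records(recs, path)
        assert loc.read_cell_records(path) == recs
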