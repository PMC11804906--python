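"""Rolling-average membrane subtraction: dedup, extraction, averaging, operator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import rotate as ndrotate

import escrtkit as ek
from escrtkit.subtraction import BoxStack


def brute_force_greedy(xy, min_dist):
    """Independent oracle: quadratic-scan greedy keep-first filter."""
    kept = []
    for i, p in enumerate(xy):
        if all(np.hypot(*(xy[j] - p)) >= min_dist for j in kept):
            kept.append(i)
    return kept


class TestDedupCoords:
    def test_15A_rule_examples(self):
        t = ek.make_coord_table([0.0, 10.0], [0.0, 0.0], s_A=[0.0, 10.0])
        out = ek.dedup_coords(t, 15.0)
        assert len(out) == 1 and out["x_A"].iloc[0] == 0.0
        t2 = ek.make_coord_table([0.0, 20.0], [0.0, 0.0], s_A=[0.0, 20.0])
        assert len(ek.dedup_coords(t2, 15.0)) == 2

    def test_collinear_triplet(self):
        t = ek.make_coord_table([0.0, 10.0, 20.0], [0.0] * 3, s_A=[0.0, 10.0, 20.0])
        out = ek.dedup_coords(t, 15.0)
        assert list(out["x_A"]) == [0.0, 20.0]

    def test_empty_table(self):
        t = ek.make_coord_table([], [])
        assert len(ek.dedup_coords(t, 15.0)) == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 200, size=(100, 2))
        t = ek.make_coord_table(xy[:, 0], xy[:, 1], s_A=np.arange(100.0))
        out = ek.dedup_coords(t, 15.0)
        expect = brute_force_greedy(xy, 15.0)
        assert np.allclose(out[["x_A", "y_A"]].to_numpy(), xy[expect])
        # survivors pairwise separated and scan idempotent
        d = np.linalg.norm(out[["x_A", "y_A"]].to_numpy()[:, None]
                           - out[["x_A", "y_A"]].to_numpy()[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 15.0
        again = ek.dedup_coords(out, 15.0)
        assert len(again) == len(out)

    def test_micrographs_do_not_interact(self):
        t = ek.make_coord_table([0.0, 5.0], [0.0, 0.0], s_A=[0.0, 5.0],
                                micrograph_name=["a", "b"])
        assert len(ek.dedup_coords(t, 15.0)) == 2


class TestExtractBoxes:
    def test_constant_raster(self):
        mic = ek.Micrograph(np.full((100, 100), 7.0, np.float32), 2.0)
        t = ek.make_coord_table([100.0], [100.0], s_A=0.0, psi_deg=30.0)
        stack = ek.extract_boxes(mic, t, 80.0)
        assert np.allclose(stack.patches, 7.0)

    def test_bright_pixel_at_center(self):
        pix = np.zeros((101, 101), np.float32)
        pix[50, 50] = 1.0
        mic = ek.Micrograph(pix, 2.0)
        t = ek.make_coord_table([100.0], [100.0], s_A=0.0, psi_deg=0.0)
        p = ek.extract_boxes(mic, t, 60.0).patches[0]
        k = p.shape[0]
        assert np.unravel_index(p.argmax(), p.shape) == ((k - 1) // 2, (k - 1) // 2)

    def test_rotation_matches_brute_force(self, rng):
        """psi=90 patch equals an independent image-rotation of the psi=0 patch."""
        base = np.zeros((200, 200))
        for _ in range(6):
            r0, c0 = rng.integers(40, 160, 2)
            a = rng.uniform(0.5, 2)
            yy, xx = np.mgrid[0:200, 0:200]
            base += a * np.exp(-(((yy - r0) / 8) ** 2 + ((xx - c0) / 5) ** 2))
        mic = ek.Micrograph(base, 2.0)
        t0 = ek.make_coord_table([200.0], [200.0], s_A=0.0, psi_deg=0.0)
        t90 = ek.make_coord_table([200.0], [200.0], s_A=0.0, psi_deg=90.0)
        p0 = ek.extract_boxes(mic, t0, 160.0).patches[0]
        p90 = ek.extract_boxes(mic, t90, 160.0).patches[0]
        oracle = ndrotate(p0, 90, reshape=False, order=1)
        rel_rms = np.sqrt(np.mean((p90 - oracle) ** 2) / np.mean(p0 ** 2))
        assert rel_rms <= 0.02

    def test_tiny_box_rejected(self):
        mic = ek.Micrograph(np.zeros((50, 50), np.float32), 2.0)
        t = ek.make_coord_table([50.0], [50.0], s_A=0.0, psi_deg=0.0)
        with pytest.raises(ValueError):
            ek.extract_boxes(mic, t, 4.0)

    def test_out_of_raster_flagged_and_filled(self):
        mic = ek.Micrograph(np.full((50, 50), 2.0, np.float32), 2.0)
        t = ek.make_coord_table([4.0], [4.0], s_A=0.0, psi_deg=0.0)
        stack = ek.extract_boxes(mic, t, 60.0)
        assert stack.out_of_bounds[0]
        assert np.allclose(stack.patches[0], 2.0)  # fill equals raster mean here


def _scalar_stack(values, edge_ids=None):
    n = len(values)
    tab = ek.make_coord_table(np.arange(n) * 30.0, np.zeros(n),
                              edge_id=0 if edge_ids is None else edge_ids,
                              s_A=np.tile(np.arange(n, dtype=float) * 30.0, 1),
                              psi_deg=0.0)
    if edge_ids is not None:
        # per-edge arc length must be strictly increasing
        tab["s_A"] = tab.groupby("edge_id").cumcount() * 30.0
    patches = np.array(values, dtype=float)[:, None, None] * np.ones((1, 5, 5))
    return BoxStack(patches, tab, 10.0, rotated=False)


class TestRollingAverage:
    def test_window_one_is_identity(self):
        stack = _scalar_stack([1, 2, 3, 4])
        out = ek.rolling_average(stack, 1)
        assert np.array_equal(out.patches, stack.patches)

    def test_identical_patches_unchanged(self):
        stack = _scalar_stack([3.0] * 6)
        out = ek.rolling_average(stack, 3)
        assert np.allclose(out.patches, 3.0)

    def test_truncated_window_arithmetic(self):
        stack = _scalar_stack([1, 2, 3, 4, 5])
        out = ek.rolling_average(stack, 3)
        assert np.allclose(out.patches[:, 0, 0], [1.5, 2.0, 3.0, 4.0, 4.5])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ek.rolling_average(_scalar_stack([1, 2, 3]), 2)

    def test_edges_never_mix(self):
        stack = _scalar_stack([1, 1, 1, 9, 9, 9], edge_ids=[0, 0, 0, 1, 1, 1])
        out = ek.rolling_average(stack, 3)
        assert np.allclose(out.patches[:3], 1.0)
        assert np.allclose(out.patches[3:], 9.0)

    @pytest.mark.parametrize("window", [1, 3, 5, 7])
    def test_matches_direct_mean_oracle(self, window, rng):
        vals = rng.normal(size=17)
        stack = _scalar_stack(vals)
        out = ek.rolling_average(stack, window)
        h = (window - 1) // 2
        oracle = [vals[max(i - h, 0):i + h + 1].mean() for i in range(len(vals))]
        assert np.allclose(out.patches[:, 0, 0], oracle)


class TestSubtractOperator:
    def test_zero_micrograph_gives_zero(self):
        mic = ek.Micrograph(np.zeros((300, 300), np.float32), 2.8)
        path = ek.build_path([(100, 420), (700, 420)], "polyline")
        res = ek.subtract_rolling_average(mic, path, 30.0, 3, 120.0)
        assert np.allclose(res.subtracted.pixels, 0.0)

    def test_membrane_only_band_power_removed(self):
        """The diffuse band is the rolling average's target: >= 95% of its
        in-band mean-square intensity must vanish (noise-free)."""
        mic, truth = ek.make_edge_scene(ek.SceneSpec(spike_amplitude=0.0,
                                                     noise_sigma=0.0))
        res = ek.subtract_rolling_average(mic, truth.path, 30.0, 3, 240.0)
        band = np.abs(truth.membrane) > 0.02 * truth.membrane.max()
        before = np.mean(mic.pixels[band].astype(float) ** 2)
        after = np.mean(res.subtracted.pixels[band] ** 2)
        assert 1 - after / before >= 0.95

    def test_protein_only_lattice_retained(self):
        """The periodic spike signal must survive: >= 80% of the spectral peak
        power at 1/30 A^-1 along the edge (noise-free)."""
        mic, truth = ek.make_edge_scene(ek.SceneSpec(membrane_amplitude=0.0,
                                                     noise_sigma=0.0))
        res = ek.subtract_rolling_average(mic, truth.path, 30.0, 3, 240.0)
        metrics = ek.evaluate_subtraction(res, truth)
        assert metrics["lattice_retention"] >= 0.80

    def test_linearity(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(300, 300))
        b = rng.normal(size=(300, 300))
        path = ek.build_path([(100, 420), (700, 420)], "polyline")

        def op(arr):
            mic = ek.Micrograph(arr.astype(np.float64), 2.8)
            return ek.subtract_rolling_average(mic, path, 30.0, 3, 120.0).subtracted.pixels

        lhs = op(2.0 * a + 3.0 * b)
        rhs = 2.0 * op(a) + 3.0 * op(b)
        scale = np.abs(lhs).max()
        assert np.abs(lhs - rhs).max() <= 1e-6 * scale

    def test_conservation_identity(self, standard_scene, standard_subtraction):
        """micrograph == subtracted + correction, pixelwise, as the operator
        defines the correction (estimate / max(weight,1) where weight > 0.5)."""
        mic, _ = standard_scene
        res = standard_subtraction
        assert np.array_equal(res.subtracted.pixels,
                              mic.pixels.astype(np.float64) - res.correction)
        assert np.all(res.correction[res.weight <= 0.5] == 0.0)
        assert np.all(res.weight >= 0.0)

    def test_pure_sinusoid_fundamental_cancelled(self):
        """Roots-of-unity guarantee: a 30-A sinusoid sampled at the 20-A rule
        interval with window 3 is attenuated by >= 1e6 in the rolling average."""
        px = 2.0
        n = 512
        x = np.arange(n) * px
        img = np.tile(np.sin(2 * np.pi * x / 30.0), (n, 1))
        mic = ek.Micrograph(img, px)
        path = ek.build_path([(40.0, 512.0), (980.0, 512.0)], "polyline")
        coords = ek.resample_path(path, ek.out_of_phase_interval(30.0, 3))
        stack = ek.extract_boxes(mic, coords, 60.0)
        avg = ek.rolling_average(stack, 3)
        interior = slice(1, len(coords) - 1)   # full windows only
        attenuation = (np.abs(stack.patches).max()
                       / max(np.abs(avg.patches[interior]).max(), 1e-300))
        assert attenuation >= 1e6


class TestEvaluateSubtraction:
    def _noop_result(self, mic, box=240.0):
        from escrtkit.subtraction import SubtractionResult
        zero = np.zeros(mic.shape)
        empty = BoxStack(np.zeros((1, 5, 5)),
                         ek.make_coord_table([10.0], [10.0], s_A=0.0, psi_deg=0.0),
                         box, rotated=True)
        return SubtractionResult(mic, zero, zero.copy(), zero.copy(), empty,
                                 {"repeat_A": 30.0, "interval_A": 20.0,
                                  "window_len": 3, "box_size_A": box}, mic.name)

    def test_noop_scores(self, standard_scene):
        mic, truth = standard_scene
        m = ek.evaluate_subtraction(self._noop_result(mic), truth)
        assert m["membrane_attenuation"] == pytest.approx(0.0, abs=1e-9)
        assert m["lattice_retention"] == pytest.approx(1.0, abs=1e-9)
        assert m["template_cc_gain"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_subtraction_scores_one(self, standard_scene):
        mic, truth = standard_scene
        from escrtkit.subtraction import SubtractionResult
        perfect = ek.Micrograph((truth.protein + truth.noise).astype(np.float64),
                                mic.pixel_size_A, mic.name)
        correction = mic.pixels.astype(np.float64) - perfect.pixels
        res = self._noop_result(mic)
        res = SubtractionResult(perfect, res.weight, res.estimate, correction,
                                res.rolling_patches, res.config, mic.name)
        m = ek.evaluate_subtraction(res, truth)
        assert m["membrane_attenuation"] == pytest.approx(1.0, abs=1e-6)

    def test_standard_scene_gain_positive(self, standard_scene, standard_subtraction):
        _, truth = standard_scene
        m = ek.evaluate_subtraction(standard_subtraction, truth)
        assert m["template_cc_gain"] > 0
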