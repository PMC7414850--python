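"""Tests for the imaging and point-pattern quantification operators."""

import math

import numpy as np
import pytest

from clhom import imaging, synthdata
from clhom.imaging import (
    FlimTrace,
    LaminarImage,
    ParticleSet,
    cl_depth_regression,
    cluster_particles,
    fit_lifetime,
    ib4_axis,
    interparticle_histogram,
    magi_index,
    masc_profile,
    oligomer_percentage,
    stern_volmer_cl,
    subtract_background,
    translaminar_profile,
)


class TestFitLifetime:
    def test_noiseless_exponential_recovered_exactly(self):
        t = (np.arange(400) + 0.5) * 0.05
        trace = FlimTrace(counts=1000.0 * np.exp(-t / 5.0), bin_width_ns=0.05)
        assert fit_lifetime(trace) == pytest.approx(5.0, rel=1e-6)

    def test_scale_invariance_in_total_counts(self):
        t = (np.arange(400) + 0.5) * 0.05
        y = 1000.0 * np.exp(-t / 3.5)
        tau1 = fit_lifetime(FlimTrace(counts=y, bin_width_ns=0.05))
        tau2 = fit_lifetime(FlimTrace(counts=17.0 * y, bin_width_ns=0.05))
        assert tau1 == pytest.approx(tau2, rel=1e-9)

    def test_poisson_noise_recovery_within_two_percent(self):
        errs = [
            abs(fit_lifetime(synthdata.gen_flim(4.0, counts=100_000, seed=s)) - 4.0) / 4.0
            for s in range(200)
        ]
        assert max(errs) < 0.02

    def test_gaussian_irf_recovery_within_three_percent(self):
        for seed in range(20):
            trace = synthdata.gen_flim(4.0, counts=200_000, irf_sigma=0.2, seed=seed)
            assert fit_lifetime(trace) == pytest.approx(4.0, rel=0.03)

    def test_too_few_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_lifetime(FlimTrace(counts=np.ones(100), bin_width_ns=0.05))


class TestSternVolmer:
    def test_unquenched_lifetime_gives_zero(self):
        tr = FlimTrace(counts=np.ones(10), bin_width_ns=0.1, tau_zero_ns=5.5)
        assert stern_volmer_cl(5.5, tr) == pytest.approx(0.0)

    def test_printed_coefficient_example(self):
        # tau0/tau = 1.32 with Ksv = 32 M-1 -> 10 mM
        tr = FlimTrace(counts=np.ones(10), bin_width_ns=0.1, tau_zero_ns=5.5)
        assert stern_volmer_cl(5.5 / 1.32, tr) == pytest.approx(10.0, rel=1e-9)

    def test_forward_inverse_consistency(self):
        tau = synthdata.flim_tau_for_cl(25.0)
        tr = FlimTrace(counts=np.ones(10), bin_width_ns=0.1, tau_zero_ns=5.5)
        assert stern_volmer_cl(tau, tr) == pytest.approx(25.0, rel=1e-9)

    def test_lifetime_above_tau0_clipped(self):
        tr = FlimTrace(counts=np.ones(10), bin_width_ns=0.1, tau_zero_ns=5.5)
        assert stern_volmer_cl(6.0, tr) == 0.0


class TestDepthRegression:
    def test_flat_data_gives_zero_slope(self):
        rng = np.random.default_rng(0)
        depth = rng.uniform(0, 100, 100)
        slope, _, _ = cl_depth_regression(depth, np.full(100, 8.0))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_binning_invariance_on_noiseless_line(self):
        depth = np.linspace(0, 100, 200)
        cl = 10.0 - 0.027 * depth
        s10 = cl_depth_regression(depth, cl, bin_um=10.0)[0]
        s20 = cl_depth_regression(depth, cl, bin_um=20.0)[0]
        assert s10 == pytest.approx(s20, abs=1e-9)
        assert s10 == pytest.approx(-0.027, abs=1e-9)

    def test_monte_carlo_slope_recovery(self):
        """Generator truth -0.027 mM/um, noise SD 2 mM, n = 200 cells."""
        rng_master = np.random.default_rng(99)
        slopes = []
        for _ in range(500):
            rng = np.random.default_rng(rng_master.integers(2**31))
            depth = rng.uniform(0, 100, 200)
            cl = 9.0 - 0.027 * depth + rng.normal(0, 2.0, 200)
            slopes.append(cl_depth_regression(depth, cl, bin_um=20.0)[0])
        assert np.mean(slopes) == pytest.approx(-0.027, abs=0.01)

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            cl_depth_regression(np.array([1.0, 2.0]), np.array([5.0, 6.0]), bin_um=20.0)


class TestIB4Axis:
    def test_horizontal_band_gives_flat_axis(self):
        img = np.zeros((64, 64))
        img[30:33, :] = 100.0
        lam = LaminarImage(channels={"ib4": img})
        ax = ib4_axis(lam)
        assert ax.coeffs[0] == pytest.approx(0.0, abs=1e-9)
        assert ax(0.0) == pytest.approx(31.0, abs=1e-6)

    def test_parabolic_band_coefficients_recovered(self):
        img = synthdata.gen_laminar_image(ib4_curvature=5e-4, noise_sd=0.0, n_cells=0, seed=1)
        ax = ib4_axis(img)
        a, b, c = img.truth["axis_coeffs"]
        assert ax.coeffs[0] == pytest.approx(a, rel=0.02)
        assert ax.coeffs[2] == pytest.approx(c, rel=0.02)

    def test_order4_weighting_matches_brute_force(self):
        # two blobs, intensity ratio 2 -> 16:1 pull toward the bright one
        col = np.zeros(64)
        col[10], col[50] = 2.0, 1.0
        img = np.tile(col[:, None], (1, 8))
        lam = LaminarImage(channels={"ib4": img})
        ax = ib4_axis(lam)
        expected = (10 * 2.0**4 + 50 * 1.0**4) / (2.0**4 + 1.0**4)
        assert ax(3.0) == pytest.approx(expected, abs=1e-9)

    def test_blank_image_rejected(self):
        lam = LaminarImage(channels={"ib4": np.zeros((16, 16))})
        with pytest.raises(ValueError):
            ib4_axis(lam)


class TestTranslaminarProfile:
    def test_uniform_image_gives_flat_profile(self):
        lam = LaminarImage(
            channels={"ib4": np.zeros((64, 64)), "kcc2": np.full((64, 64), 7.0)},
            pixel_size_um=0.1,
        )
        lam.channels["ib4"][32, :] = 1.0
        ax = ib4_axis(lam)
        prof = translaminar_profile(lam, ax, bin_um=0.5, channels=("kcc2",))
        assert np.allclose(prof["kcc2"], 7.0)

    def test_pixel_on_curve_has_zero_distance(self):
        from clhom.imaging import _signed_distance_to_axis, QuadraticAxis

        lam = LaminarImage(channels={"kcc2": np.zeros((32, 32))}, pixel_size_um=0.1)
        sd = _signed_distance_to_axis(lam, QuadraticAxis(coeffs=(0.0, 0.0, 16.0)))
        assert np.allclose(sd[16, :], 0.0)
        assert np.all(sd[:16, :] > 0)  # dorsal side positive
        assert np.all(sd[17:, :] < 0)

    def test_gradient_slope_recovered(self):
        img = synthdata.gen_laminar_image(noise_sd=0.0, n_cells=0, seed=2)
        ax = ib4_axis(img)
        prof = translaminar_profile(img, ax, bin_um=2.0, channels=("kcc2",))
        d, v = prof["distance_um"], prof["kcc2"]
        sel = (d > -12.0) & (d < 12.0)  # inside the tissue, away from white matter
        slope = np.polyfit(d[sel], v[sel], 1)[0]
        # intensity rises with depth; distance is positive dorsally -> slope < 0
        assert slope == pytest.approx(-img.truth["kcc2_gradient_iu_per_um"], rel=0.05)

    def test_matches_bruteforce_distance_binning(self):
        """Bit-exact agreement with exhaustive per-pixel distance computation."""
        img = synthdata.gen_laminar_image(shape=(64, 64), pixel_size_um=0.5,
                                          white_matter_um=2.0, ib4_depth_um=12.0,
                                          cell_radius_um=2.0, seed=3)
        ax = ib4_axis(img)
        prof = translaminar_profile(img, ax, bin_um=1.0, channels=("kcc2",))

        h, w = 64, 64
        pts = ax.sample(w)
        vals = np.asarray(img.channels["kcc2"], dtype=float)
        bins = {}
        for r in range(h):
            for c in range(w):
                d = math.sqrt(min((r - p[0]) ** 2 + (c - p[1]) ** 2 for p in pts))
                d *= img.pixel_size_um
                sign = 1.0 if (r < ax(c)) == img.dorsal_at_top else -1.0
                k = math.floor(sign * d / 1.0)
                bins.setdefault(k, []).append(vals[r, c])
        keys = sorted(bins)
        assert np.allclose(prof["distance_um"], [(k + 0.5) * 1.0 for k in keys])
        assert np.allclose(prof["kcc2"], [np.mean(bins[k]) for k in keys], rtol=0, atol=0)


class TestMagi:
    def test_equal_means_give_zero(self):
        img = LaminarImage(channels={"kcc2": np.full((32, 32), 5.0)})
        mask = np.ones((32, 32), dtype=bool)
        assert magi_index(img, mask, mask) == pytest.approx(0.0)

    def test_analytic_mixture_difference(self):
        # membrane 100 i.u. over cytoplasm 40 i.u.: M from the mask areas
        arr = np.full((40, 40), 40.0)
        arr[10:12, :] = 100.0  # 'membrane' stripe
        lam_mask = np.ones_like(arr, dtype=bool)
        intra = np.zeros_like(arr, dtype=bool)
        intra[20:30, :] = True
        img = LaminarImage(channels={"kcc2": arr})
        total = (100.0 * 80 + 40.0 * (1600 - 80)) / 1600
        assert magi_index(img, lam_mask, intra) == pytest.approx(total - 40.0)

    def test_shift_invariance(self):
        img = synthdata.gen_laminar_image(seed=4)
        m1 = magi_index(img, img.lamina_masks["LII"], img.intracellular_mask)
        shifted = LaminarImage(
            channels={"kcc2": np.asarray(img.channels["kcc2"]) + 13.0},
            lamina_masks=img.lamina_masks,
        )
        m2 = magi_index(shifted, img.lamina_masks["LII"], img.intracellular_mask)
        assert m2 == pytest.approx(m1, abs=1e-9)

    def test_empty_mask_rejected(self):
        img = LaminarImage(channels={"kcc2": np.zeros((8, 8))})
        with pytest.raises(ValueError):
            magi_index(img, np.zeros((8, 8), bool), np.ones((8, 8), bool))


class TestMascProfile:
    def test_ring_cell_profile_peaks_at_membrane(self):
        img = synthdata.gen_laminar_image(
            shape=(96, 96), pixel_size_um=0.25, white_matter_um=1.0, ib4_depth_um=8.0,
            n_cells=1, kcc2_gradient=0.0, kcc2_base=10.0,
            membrane_intensity=500.0, cytoplasm_intensity=50.0, noise_sd=0.0, seed=6,
        )
        prof = masc_profile(img, max_distance_um=1.2)
        d, m = prof["distance_um"], prof["mean"]
        peak_bin = d[np.argmax(m)]
        assert abs(peak_bin) <= 2 * img.pixel_size_um
        # decays away from the membrane on both sides by the annulus width
        assert m[np.argmax(m)] > 2 * m[-1]

    def test_matches_bruteforce_on_small_fixture(self):
        """Bit-exact distance binning vs an exhaustive O(N*M) computation."""
        img = synthdata.gen_laminar_image(shape=(64, 64), pixel_size_um=0.5,
                                          white_matter_um=2.0, ib4_depth_um=10.0,
                                          cell_radius_um=2.0, n_cells=2, noise_sd=1.0, seed=7)
        prof = masc_profile(img, max_distance_um=1.5)

        step = img.pixel_size_um
        vals = np.asarray(img.channels["kcc2"], dtype=float)
        bins = {}
        for r in range(64):
            for c in range(64):
                best, side = np.inf, 1.0
                for poly in img.membrane_polylines:
                    for p1, p2 in zip(poly[:-1], poly[1:]):
                        seg = p2 - p1
                        t = np.clip(
                            ((r - p1[0]) * seg[0] + (c - p1[1]) * seg[1]) / (seg @ seg), 0, 1
                        )
                        proj = p1 + t * seg
                        d = math.hypot(r - proj[0], c - proj[1])
                        if d < best:
                            best = d
                            cross = seg[0] * (c - p1[1]) - seg[1] * (r - p1[0])
                            side = 1.0 if cross >= 0 else -1.0
                sd = best * side * step
                if abs(sd) <= 1.5:
                    bins.setdefault(math.floor(sd / step), []).append(vals[r, c])
        keys = sorted(bins)
        assert np.allclose(prof["distance_um"], [(k + 0.5) * step for k in keys])
        assert np.allclose(prof["mean"], [np.mean(bins[k]) for k in keys], rtol=0, atol=0)

    def test_interior_of_cell_is_positive_side(self):
        img = synthdata.gen_laminar_image(shape=(96, 96), pixel_size_um=0.5,
                                          white_matter_um=2.0, ib4_depth_um=10.0,
                                          cell_radius_um=3.0, n_cells=1, seed=8)
        (cr, cc) = img.truth["cell_centres_rc"][0]
        poly = img.membrane_polylines[0]
        from clhom.imaging import _point_segment_distance

        _, cross = _point_segment_distance(np.array([[cr, cc]]), poly[0], poly[1])
        assert cross[0] > 0

    def test_no_polylines_rejected(self):
        img = LaminarImage(channels={"kcc2": np.zeros((8, 8))})
        with pytest.raises(ValueError):
            masc_profile(img, 1.0)

    def test_degenerate_polyline_rejected(self):
        img = LaminarImage(
            channels={"kcc2": np.zeros((8, 8))}, membrane_polylines=[np.array([[1.0, 1.0]])]
        )
        with pytest.raises(ValueError):
            masc_profile(img, 1.0)


class TestSubtractBackground:
    def test_uniform_image_becomes_zero(self):
        arr = np.full((16, 16), 9.0)
        region = np.zeros((16, 16), bool)
        region[:4] = True
        img = LaminarImage(channels={"kcc2": arr}, background_region=region)
        out = subtract_background(img)
        assert np.allclose(out.channels["kcc2"], 0.0)

    def test_clipping_at_zero(self):
        arr = np.full((16, 16), 5.0)
        arr[:4] = 20.0
        region = np.zeros((16, 16), bool)
        region[:4] = True
        img = LaminarImage(channels={"kcc2": arr}, background_region=region)
        out = subtract_background(img)
        assert np.all(out.channels["kcc2"] >= 0.0)
        assert np.allclose(out.channels["kcc2"][5:], 0.0)

    def test_background_region_mean_near_zero_after_subtraction(self):
        img = synthdata.gen_laminar_image(seed=9)
        out = subtract_background(img)
        resid = np.asarray(out.channels["kcc2"])[img.background_region].mean()
        assert resid < 2.0  # only clipping residue of the noise remains


class TestClusterParticles:
    def test_transitive_chain_is_one_group(self):
        # A-B 50 nm, B-C 50 nm, A-C 100 nm: all three in one oligomer
        ps = ParticleSet(xy_nm=np.array([[0.0, 0.0], [50.0, 0.0], [100.0, 0.0]]))
        res = cluster_particles(ps)
        assert len(set(res.labels)) == 1
        assert res.n_oligomeric == 3

    def test_pair_above_cutoff_stays_monomeric(self):
        ps = ParticleSet(xy_nm=np.array([[0.0, 0.0], [70.0, 0.0]]))
        res = cluster_particles(ps)
        assert res.n_monomeric == 2
        assert res.oligomer_percentage == 0.0

    def test_invariance_to_ordering_and_rigid_motion(self):
        ps = synthdata.gen_particles(120, 0.5, seed=10)
        res = cluster_particles(ps)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ps.xy_nm.shape[0])
        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        moved = ParticleSet(xy_nm=(ps.xy_nm[perm] @ rot.T) + 1234.5)
        res2 = cluster_particles(moved)
        assert res2.oligomer_percentage == pytest.approx(res.oligomer_percentage)
        # identical partitions modulo labelling
        def canon(labels, order):
            groups = {}
            for i, lab in zip(order, labels):
                groups.setdefault(lab, set()).add(i)
            return {frozenset(g) for g in groups.values()}

        assert canon(res.labels, range(len(res.labels))) == canon(res2.labels, perm)

    def test_matches_bruteforce_union_find(self):
        """Implementation vs an independent O(n^2) union-find oracle."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            xy = rng.uniform(0, 1500, size=(300, 2))
            res = cluster_particles(ParticleSet(xy_nm=xy))

            parent = list(range(300))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(300):
                for j in range(i + 1, 300):
                    if np.hypot(*(xy[i] - xy[j])) < 65.0:
                        parent[find(i)] = find(j)
            roots = [find(i) for i in range(300)]
            impl = {}
            oracle = {}
            for i in range(300):
                impl.setdefault(res.labels[i], set()).add(i)
                oracle.setdefault(roots[i], set()).add(i)
            assert {frozenset(s) for s in impl.values()} == {
                frozenset(s) for s in oracle.values()
            }

    def test_printed_category_counts_reproduce_published_percentages(self):
        # per-particle proportions: 61 % oligomeric in LI, 19 % in LII
        assert round(oligomer_percentage(506, 320)) == 61
        assert round(oligomer_percentage(133, 568)) == 19


class TestInterparticleHistogram:
    def test_three_particles_give_three_distances(self):
        ps = ParticleSet(xy_nm=np.array([[0.0, 0], [100.0, 0], [0.0, 200.0]]))
        counts, _ = interparticle_histogram(ps)
        assert counts.sum() == 3

    def test_equilateral_triangle_single_bin(self):
        d = 120.0
        xy = np.array([[0.0, 0.0], [d, 0.0], [d / 2, d * math.sqrt(3) / 2]])
        counts, edges = interparticle_histogram(ParticleSet(xy_nm=xy), bin_nm=10.0)
        occupied = np.flatnonzero(counts)
        assert occupied.size == 1
        assert edges[occupied[0]] <= d <= edges[occupied[0] + 1]

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(11)
        xy = rng.uniform(0, 800, size=(40, 2))
        counts, edges = interparticle_histogram(ParticleSet(xy_nm=xy), bin_nm=25.0)
        brute = [
            math.hypot(*(xy[i] - xy[j])) for i in range(40) for j in range(i + 1, 40)
        ]
        counts2, _ = np.histogram(brute, bins=edges)
        assert np.array_equal(counts, counts2)

    def test_single_particle_rejected(self):
        with pytest.raises(ValueError):
            interparticle_histogram(ParticleSet(xy_nm=np.array([[0.0, 0.0]])))
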