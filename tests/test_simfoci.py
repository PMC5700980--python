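import numpy as np
import pytest

from chromostoch import simfoci, synthetic_data as sd
from chromostoch.simfoci import (
    CellFoci,
    Focus,
    PRDistribution,
    VoxelStack,
    detect_foci,
    dmax_from_pr,
    max_entropy_threshold,
    pair_border_distances,
    pairing_fraction,
    pr_distribution,
    radius_of_gyration,
    segment_nucleus,
)


def brute_force_max_entropy(values, nbins=256):
    """Independent oracle: exhaustive search over all histogram cut points."""
    hist, edges = np.histogram(values, bins=nbins)
    p = hist / hist.sum()
    best, best_t = -np.inf, None
    for t in range(1, nbins):
        bg, fg = p[:t], p[t:]
        p_bg, p_fg = bg.sum(), fg.sum()
        if p_bg <= 0 or p_fg <= 0:
            continue
        h = 0.0
        for q in bg[bg > 0] / p_bg:
            h -= q * np.log(q)
        for q in fg[fg > 0] / p_fg:
            h -= q * np.log(q)
        if h > best:
            best, best_t = h, t
    return edges[best_t]


@pytest.fixture(scope="module")
def nucleus_fixture():
    cfg = sd.SimConfig(seed=11, nucleus_radii=(900.0, 900.0, 700.0), noise_level=3.0)
    center = np.array(cfg.nucleus_radii) + 500.0
    positions = [
        center + np.array([-400.0, 0.0, 0.0]),
        center + np.array([400.0, 100.0, 0.0]),
        center + np.array([0.0, -400.0, 300.0]),
    ]
    loci = [(tuple(p), "ch1", 400.0) for p in positions]
    stacks, gt = sd.generate_nucleus_stack(cfg, loci)
    return cfg, stacks, gt, np.array(positions)


class TestSegmentNucleus:
    def test_zero_stack_no_nucleus(self):
        stack = VoxelStack(np.zeros((5, 20, 20)))
        with pytest.raises(ValueError, match="no nucleus found"):
            segment_nucleus(stack)

    def test_ellipsoid_volume_recovered(self):
        # analytic ellipsoid volume on the grid, no noise
        cfg = sd.SimConfig(seed=0, nucleus_radii=(900.0, 900.0, 700.0), noise_level=0.0)
        stacks, _ = sd.generate_nucleus_stack(cfg, [])
        mask = segment_nucleus(stacks["dapi"])
        analytic = 4.0 / 3.0 * np.pi * 900.0 * 900.0 * 700.0 * 1e-9  # um^3
        assert mask.volume_um3 == pytest.approx(analytic, rel=0.05)

    def test_noise_robustness(self):
        radii = (900.0, 900.0, 700.0)
        quiet, _ = sd.generate_nucleus_stack(
            sd.SimConfig(seed=1, nucleus_radii=radii, noise_level=0.0), []
        )
        noisy, _ = sd.generate_nucleus_stack(
            sd.SimConfig(seed=1, nucleus_radii=radii, noise_level=10.0), []
        )
        v0 = segment_nucleus(quiet["dapi"]).volume_um3
        v1 = segment_nucleus(noisy["dapi"]).volume_um3
        assert abs(v1 - v0) / v0 < 0.10

    def test_roi_out_of_bounds(self):
        stack = VoxelStack(np.ones((3, 10, 10)))
        with pytest.raises(ValueError, match="ROI"):
            segment_nucleus(stack, roi=(0, 20, 0, 10))


class TestMaxEntropyThreshold:
    def test_two_valued_image(self, rng):
        values = np.concatenate([np.full(990, 10.0), np.full(10, 200.0)])
        thr = max_entropy_threshold(rng.permutation(values))
        assert 10.0 < thr < 200.0

    def test_matches_brute_force_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            values = np.concatenate([
                r.normal(50, 10, 2000).clip(0),
                r.normal(180, 15, 200).clip(0),
            ])
            assert max_entropy_threshold(values) == pytest.approx(
                brute_force_max_entropy(values)
            )

    def test_eight_level_toy_histogram(self):
        # tiny discrete histogram, exhaustive oracle at 256 bins
        values = np.repeat(np.arange(8.0), [50, 30, 10, 5, 2, 2, 10, 20])
        assert max_entropy_threshold(values) == pytest.approx(
            brute_force_max_entropy(values)
        )

    def test_permutation_invariance(self, rng):
        values = rng.normal(100, 25, 5000).clip(0)
        assert max_entropy_threshold(values) == max_entropy_threshold(
            rng.permutation(values)
        )

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            max_entropy_threshold(np.full(100, 7.0))


class TestDetectFoci:
    def test_three_separated_blobs(self, nucleus_fixture):
        cfg, stacks, gt, positions = nucleus_fixture
        mask = segment_nucleus(stacks["dapi"])
        foci = detect_foci(stacks["ch1"], mask)
        assert len(foci) == 3
        centers = np.array([f.center for f in foci])
        for true_pos in positions:
            err = np.linalg.norm(centers - true_pos, axis=1).min()
            assert err < cfg.voxel_size_z  # within one (coarsest) voxel

    def test_blank_stack_zero_foci(self):
        stack = VoxelStack(np.zeros((5, 30, 30)))
        mask = simfoci.NucleusMask(np.ones((5, 30, 30), bool), 39.5, 125.0)
        assert detect_foci(stack, mask) == []

    def test_close_blobs_merge(self):
        # two blobs separated by less than one voxel -> single focus
        cfg = sd.SimConfig(seed=2, nucleus_radii=(700.0, 700.0, 600.0), noise_level=0.0)
        center = np.array(cfg.nucleus_radii) + 500.0
        loci = [
            (tuple(center), "ch1", 400.0),
            (tuple(center + np.array([20.0, 0.0, 0.0])), "ch1", 400.0),
        ]
        stacks, _ = sd.generate_nucleus_stack(cfg, loci)
        mask = simfoci.NucleusMask(
            np.ones(stacks["ch1"].shape, bool), cfg.voxel_size_xy, cfg.voxel_size_z
        )
        assert len(detect_foci(stacks["ch1"], mask)) == 1

    def test_known_k_recovery_rate(self):
        # >= 95% of seeded replicates recover exactly K well-separated loci
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = sd.SimConfig(
                seed=seed, nucleus_radii=(900.0, 900.0, 700.0), noise_level=3.0
            )
            center = np.array(cfg.nucleus_radii) + 500.0
            offsets = np.array(
                [[-450, -300, 0], [450, -300, 0], [0, 450, 250], [0, 0, -350]],
                dtype=float,
            )
            loci = [(tuple(center + o), "ch1", 400.0) for o in offsets]
            stacks, _ = sd.generate_nucleus_stack(cfg, loci)
            mask = segment_nucleus(stacks["dapi"])
            if len(detect_foci(stacks["ch1"], mask)) == 4:
                hits += 1
        assert hits / n_rep >= 0.95


class TestPairBorderDistances:
    def test_identical_lists_zero(self):
        pts = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        np.testing.assert_allclose(pair_border_distances(pts, pts), 0.0)

    def test_nearest_selection(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[300.0, 0, 0], [1000.0, 0, 0]])
        np.testing.assert_allclose(pair_border_distances(a, b), [300.0])

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            a = rng.uniform(0, 2000, (7, 3))
            b = rng.uniform(0, 2000, (5, 3))
            fast = pair_border_distances(a, b)
            brute = np.array([
                min(np.linalg.norm(pa - pb) for pb in b) for pa in a
            ])
            np.testing.assert_allclose(fast, brute)

    def test_empty_channel_raises(self):
        with pytest.raises(ValueError, match="empty channel"):
            pair_border_distances(np.empty((0, 3)), np.array([[0.0, 0, 0]]))

    def test_translation_rotation_invariance(self, rng):
        a = rng.uniform(0, 1000, (6, 3))
        b = rng.uniform(0, 1000, (6, 3))
        d0 = pair_border_distances(a, b)
        # random rotation via QR decomposition
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.uniform(-500, 500, 3)
        np.testing.assert_allclose(
            pair_border_distances(a @ q + shift, b @ q + shift), d0, rtol=1e-9
        )


class TestPairingFraction:
    @staticmethod
    def _cells(n_foci_list):
        return [
            CellFoci(i, {"ch1": [Focus((0, 0, 0), 2, 1.0)] * k})
            for i, k in enumerate(n_foci_list)
        ]

    def test_all_single(self):
        f, se = pairing_fraction(self._cells([1, 1, 1]), "ch1")
        assert f == 1.0

    def test_binomial_oracle(self):
        rng = np.random.default_rng(0)
        p, n = 0.65, 10_000
        singles = rng.random(n) < p
        cells = self._cells([1 if s else 2 for s in singles])
        f, se = pairing_fraction(cells, "ch1")
        assert abs(f - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_no_cells_error(self):
        with pytest.raises(ValueError):
            pairing_fraction([], "ch1")


class TestPRDistribution:
    def test_two_foci_single_bin(self):
        pts = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        pr = pr_distribution(pts, bin_width=100.0)
        assert pr.probabilities.sum() == pytest.approx(1.0)
        occupied = np.flatnonzero(pr.probabilities)
        assert len(occupied) == 1
        b = occupied[0]
        assert pr.bin_edges[b] <= 500.0 < pr.bin_edges[b + 1]
        assert pr.probabilities[b] == 1.0

    def test_pair_count(self, rng):
        pts = rng.uniform(0, 2000, (10, 3))
        pr = pr_distribution(pts, bin_width=50.0)
        # histogram total must reflect exactly n(n-1)/2 distances
        assert pr.probabilities.sum() == pytest.approx(1.0)

    def test_fewer_than_two_foci(self):
        with pytest.raises(ValueError):
            pr_distribution(np.array([[0.0, 0, 0]]))

    def test_invariants(self, rng):
        pts = rng.uniform(0, 3000, (20, 3))
        pr = pr_distribution(pts, bin_width=100.0)
        from scipy.spatial.distance import pdist

        assert pr.d_max <= pdist(pts).max() + 100.0  # within one bin
        assert pr.r_g <= pr.d_max


class TestRadiusOfGyration:
    def test_single_focus(self):
        assert radius_of_gyration(np.array([[10.0, 20.0, 30.0]])) == 0.0

    def test_two_foci(self):
        pts = np.array([[0.0, 0, 0], [600.0, 0, 0]])
        assert radius_of_gyration(pts) == pytest.approx(300.0)

    def test_cube_closed_form(self):
        a = 400.0
        pts = np.array([
            [x, y, z] for x in (0, a) for y in (0, a) for z in (0, a)
        ], dtype=float)
        assert radius_of_gyration(pts) == pytest.approx(a * np.sqrt(3) / 2)


class TestDmax:
    def test_all_mass_one_bin(self):
        pr = PRDistribution(np.array([0.0, 100.0, 200.0]), np.array([0.0, 1.0]), 0, 0)
        # interpolated position 97% into the occupied bin
        assert dmax_from_pr(pr, 0.97) == pytest.approx(100.0 + 0.97 * 100.0)

    def test_fraction_one_is_last_occupied_edge(self):
        pr = PRDistribution(
            np.array([0.0, 100.0, 200.0, 300.0]), np.array([0.5, 0.5, 0.0]), 0, 0
        )
        assert dmax_from_pr(pr, 1.0) == pytest.approx(200.0)

    def test_uniform_sphere_monte_carlo(self):
        # oracle: 97th percentile of pairwise distances in a uniform ball
        rng = np.random.default_rng(1)
        n = 450  # ~1e5 pairs
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= (1000.0 * rng.random(n) ** (1 / 3))[:, None]
        from scipy.spatial.distance import pdist

        d = pdist(pts)
        oracle = np.quantile(d, 0.97)
        bin_width = 50.0
        pr = pr_distribution(pts, bin_width=bin_width)
        assert abs(pr.d_max - oracle) < bin_width


class TestAveragePr:
    def test_population_average(self, rng):
        edges = np.arange(0.0, 4000.0, 100.0)
        prs = [
            pr_distribution(rng.uniform(0, 3000, (15, 3)), bin_edges=edges)
            for _ in range(5)
        ]
        avg = simfoci.average_pr(prs)
        assert avg.probabilities.sum() == pytest.approx(1.0)
        manual = np.mean([p.probabilities for p in prs], axis=0)
        np.testing.assert_allclose(avg.probabilities, manual / manual.sum())
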