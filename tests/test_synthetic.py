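import numpy as np
import pytest

from cryptmap import synthetic as syn
from cryptmap.synthetic import InvalidConfigError, SimulationConfig


class TestLattice:
    def test_square_grid_center_count(self):
        cfg = SimulationConfig(lattice_nx=6, lattice_ny=6, crypt_pitch=75.0,
                               lattice_geometry="square", position_jitter_sd=0.0)
        centers = syn.make_crypt_lattice(cfg)
        assert centers.shape == (36, 2)
        # a 425 µm window at the origin holds floor(425/75)+1 = 6 columns/rows
        inside = ((centers >= 0) & (centers <= 425)).all(axis=1).sum()
        assert inside == 36

    def test_single_crypt_at_origin(self):
        cfg = SimulationConfig(lattice_nx=1, lattice_ny=1, position_jitter_sd=0.0)
        centers = syn.make_crypt_lattice(cfg)
        np.testing.assert_allclose(centers, [[0.0, 0.0]])

    def test_jitter_deterministic_under_seed(self):
        cfg = SimulationConfig(lattice_nx=4, lattice_ny=4, position_jitter_sd=5.0,
                               rng_seed=11)
        a = syn.make_crypt_lattice(cfg)
        b = syn.make_crypt_lattice(cfg)
        np.testing.assert_array_equal(a, b)

    def test_hex_rows_offset(self):
        cfg = SimulationConfig(lattice_nx=3, lattice_ny=2, position_jitter_sd=0.0)
        centers = syn.make_crypt_lattice(cfg)
        xs = np.unique(np.round(centers[:, 0], 6))
        assert 37.5 in xs  # odd row shifted by pitch/2

    def test_nonpositive_pitch_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(crypt_pitch=0.0)


class TestColonization:
    def test_no_spread_equals_seed_set(self):
        cfg = SimulationConfig(lattice_nx=10, lattice_ny=10, spread_prob=0.0,
                               seed_fraction=0.2, rng_seed=5)
        centers = syn.make_crypt_lattice(cfg)
        colonized, labels = syn.simulate_colonization(centers, cfg)
        cfg0 = cfg.replace(n_spread_rounds=0)
        colonized0, _ = syn.simulate_colonization(centers, cfg0)
        np.testing.assert_array_equal(colonized, colonized0)

    def test_saturation(self):
        cfg = SimulationConfig(lattice_nx=5, lattice_ny=5, seed_fraction=1.0)
        centers = syn.make_crypt_lattice(cfg)
        colonized, labels = syn.simulate_colonization(centers, cfg)
        assert colonized.all()
        assert all(l is not None for l in labels)

    def test_every_colonized_crypt_has_one_type(self):
        cfg = SimulationConfig(lattice_nx=10, lattice_ny=10, seed_fraction=0.1,
                               rng_seed=2)
        centers = syn.make_crypt_lattice(cfg)
        colonized, labels = syn.simulate_colonization(centers, cfg)
        for c, l in zip(colonized, labels):
            assert (l is None) == (not c)
            if c:
                assert l in cfg.type_labels

    def test_spreading_increases_mean_cluster_size(self):
        # Monte-Carlo comparison against the brute-force components oracle,
        # at matched expected colonized counts. Parameters sit in the sparse
        # regime: at high colonized density uniform placement percolates into
        # one giant component and the comparison inverts.
        spread_sizes, null_sizes = [], []
        for seed in range(50):
            cfg = SimulationConfig(lattice_nx=30, lattice_ny=30, crypt_pitch=75.0,
                                   seed_fraction=0.005, spread_prob=0.8,
                                   n_spread_rounds=2, rng_seed=seed)
            centers = syn.make_crypt_lattice(cfg)
            colonized, _ = syn.simulate_colonization(centers, cfg)
            if not colonized.sum():
                continue
            labels = syn.brute_force_clusters(centers[colonized], 150.0)
            spread_sizes.append(np.bincount(labels).mean())
            match = colonized.sum() / len(centers)
            cfg0 = cfg.replace(spread_prob=0.0, seed_fraction=match)
            colonized0, _ = syn.simulate_colonization(centers, cfg0)
            if colonized0.sum():
                labels0 = syn.brute_force_clusters(centers[colonized0], 150.0)
                null_sizes.append(np.bincount(labels0).mean())
        assert np.mean(spread_sizes) > np.mean(null_sizes)

    def test_coupling_one_makes_cascades_type_pure(self):
        # with coupling = 1, every crypt carries its cascade root's type
        # (clusters merging two seeds of different types can still be mixed)
        cfg = SimulationConfig(lattice_nx=15, lattice_ny=15, seed_fraction=0.03,
                               spread_prob=0.8, n_spread_rounds=3,
                               type_spatial_coupling=1.0, rng_seed=9)
        centers = syn.make_crypt_lattice(cfg)
        colonized, labels, sources = syn.simulate_colonization(
            centers, cfg, return_sources=True
        )
        for i in np.flatnonzero(colonized):
            root = i
            while sources[root] != root:
                root = sources[root]
            assert labels[i] == labels[root]


class TestAbundances:
    def test_noiseless_identity(self):
        cfg = SimulationConfig(
            abundance_noise_sd=0.0,
            type_archetypes={"X": {"a": 100, "b": 0, "c": 0}},
        )
        counts = syn.sample_crypt_abundances("X", cfg)
        assert counts == {"a": 100, "b": 0, "c": 0}

    def test_all_zero_archetype_stays_zero(self, rng):
        cfg = SimulationConfig(
            abundance_noise_sd=2.0,
            type_archetypes={"X": {"a": 0, "b": 0}},
        )
        for _ in range(50):
            counts = syn.sample_crypt_abundances("X", cfg, rng)
            assert counts == {"a": 0, "b": 0}

    def test_unknown_type_raises(self, small_config):
        with pytest.raises(KeyError):
            syn.sample_crypt_abundances("nope", small_config)

    def test_lognormal_median_property(self, rng):
        # median of round(exp(log(m+1)+N(0,sd))) - 1 stays near m
        cfg = SimulationConfig(
            abundance_noise_sd=0.3,
            type_archetypes={"X": {"a": 1000, "b": 100, "c": 10}},
        )
        draws = {t: [] for t in "abc"}
        for _ in range(10_000):
            counts = syn.sample_crypt_abundances("X", cfg, rng)
            for t in "abc":
                draws[t].append(counts[t])
        for t, mean in zip("abc", (1000, 100, 10)):
            med = np.median(draws[t])
            assert abs(med - mean) <= 0.05 * mean + 0.5


class TestRendering:
    def test_noiseless_single_blob(self):
        cfg = SimulationConfig(
            lattice_nx=1, lattice_ny=1, position_jitter_sd=0.0,
            seed_fraction=1.0, abundance_noise_sd=0.0, noise_sd=0.0,
            type_archetypes={"X": {"a": 7}},
            taxon_depth_means={"a": 30.0}, taxon_depth_sds={"a": 2.0},
            rng_seed=1,
        )
        gt = syn.simulate_dataset(cfg)
        vol, objs = syn.place_bacteria_and_render(gt, cfg)
        assert len(objs["a"]) == 1
        assert (vol.channel("a") == cfg.blob_intensity).sum() == 7

    def test_depth_ordering_preserved(self):
        # taxon a mean 10 µm, taxon b mean 40 µm; recovered depth a < b in
        # every crypt over 20 seeds
        for seed in range(20):
            cfg = SimulationConfig(
                lattice_nx=3, lattice_ny=3, seed_fraction=1.0,
                abundance_noise_sd=0.0, noise_sd=0.0,
                type_archetypes={"X": {"a": 70, "b": 70}},
                taxon_depth_means={"a": 10.0, "b": 40.0},
                taxon_depth_sds={"a": 2.0, "b": 2.0},
                rng_seed=seed,
            )
            gt = syn.simulate_dataset(cfg)
            vol, objs = syn.place_bacteria_and_render(gt, cfg)
            dz = cfg.voxel_size[0]
            for ci in range(gt.n_crypts):
                depths = {}
                for taxon in ("a", "b"):
                    vox = [v for v, oc in zip(objs[taxon], gt.object_crypts[taxon])
                           if oc == ci]
                    allv = np.concatenate(vox)
                    depths[taxon] = (allv[:, 0].mean() + 0.5) * dz
                assert depths["a"] < depths["b"]

    def test_zero_bacteria_gives_noise_field(self):
        cfg = SimulationConfig(lattice_nx=2, lattice_ny=2, seed_fraction=0.0,
                               noise_sd=1.0, rng_seed=3)
        gt = syn.simulate_dataset(cfg)
        vol, objs = syn.place_bacteria_and_render(gt, cfg)
        assert all(len(v) == 0 for v in objs.values())
        assert abs(vol.data.mean()) < 0.05

    def test_ground_truth_voxel_lists_before_mixing(self):
        cfg = SimulationConfig(
            lattice_nx=2, lattice_ny=2, seed_fraction=1.0, noise_sd=5.0,
            mixing_matrix=np.array([[1.0, 0.2, 0.0], [0.1, 1.0, 0.1],
                                    [0.0, 0.2, 1.0]]),
            rng_seed=4,
        )
        gt = syn.simulate_dataset(cfg)
        vol, objs = syn.place_bacteria_and_render(gt, cfg)
        assert vol.channel_names == ["ch0", "ch1", "ch2"]
        total_gt_vox = sum(len(v) for vs in objs.values() for v in vs)
        assert total_gt_vox > 0


class TestGelSlab:
    def test_perfect_staining(self):
        df = syn.simulate_gel_slab(500, lambda d: np.ones_like(d),
                                   SimulationConfig(rng_seed=1))
        ratio = df["hcr_signal"] / df["background"]
        assert (ratio >= 20).mean() > 0.999

    def test_no_staining(self):
        df = syn.simulate_gel_slab(500, lambda d: np.zeros_like(d),
                                   SimulationConfig(rng_seed=1))
        ratio = df["hcr_signal"] / df["background"]
        assert (ratio >= 20).mean() == 0.0

    def test_exponential_efficiency_matches_integral(self):
        # closed form: (1/600) * int_0^600 exp(-d/300) dd = (1 - e^-2)/2
        expected = (1 - np.exp(-2.0)) / 2.0
        n = 20_000
        df = syn.simulate_gel_slab(n, lambda d: np.exp(-d / 300.0),
                                   SimulationConfig(rng_seed=123))
        est = df["true_stained"].mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(est - expected) <= 2 * se

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_gel_slab(100, lambda d: d / 100.0,
                                  SimulationConfig(rng_seed=1))


class TestDeterminismAndOracle:
    def test_bit_identical_ground_truth(self, small_config):
        a = syn.simulate_dataset(small_config)
        b = syn.simulate_dataset(small_config)
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_array_equal(a.colonized, b.colonized)
        assert a.counts.equals(b.counts)
        assert a.depths.equals(b.depths)
        np.testing.assert_array_equal(a.cluster_labels, b.cluster_labels)

    def test_true_clusters_equal_oracle(self, small_config):
        gt = syn.simulate_dataset(small_config)
        idx = np.flatnonzero(gt.colonized)
        oracle = syn.brute_force_clusters(gt.centers[idx],
                                          small_config.cluster_threshold)
        np.testing.assert_array_equal(gt.cluster_labels[idx], oracle)
        assert (gt.cluster_labels[~gt.colonized] == -1).all()
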