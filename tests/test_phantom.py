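"""Phantom generation and Poisson/binomial counting statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scintidenoise import phantom
from scintidenoise.errors import ConfigurationError, DomainError
from scintidenoise.phantom import (ActivityMap, Lesion, PhantomSpec,
                                   acquire_counts, generate_activity_map,
                                   generate_paired_dataset,
                                   protocol_pair_count, simulate_point_source,
                                   thin_counts)


class TestActivityMap:
    def test_zero_background_gives_zero_map(self):
        spec = PhantomSpec(region="pelvis", background_rate=0.0)
        amap = generate_activity_map(spec)
        assert np.all(amap.values == 0.0)

    @pytest.mark.parametrize("region", phantom.REGIONS)
    def test_deterministic_given_subject_seed(self, region):
        spec = PhantomSpec(region=region, subject_seed=123)
        a = generate_activity_map(spec)
        b = generate_activity_map(spec)
        np.testing.assert_array_equal(a.values, b.values)
        other = generate_activity_map(
            PhantomSpec(region=region, subject_seed=124))
        assert not np.array_equal(a.values, other.values)

    def test_lesion_hotspot_dominates_background(self):
        les = Lesion(row=32, col=32, radius=5, intensity=3.0)
        spec = PhantomSpec(region="pelvis", lesions=(les,), subject_seed=1)
        amap = generate_activity_map(spec)
        rr, cc = np.mgrid[0:64, 0:64]
        disc = (rr - 32) ** 2 + (cc - 32) ** 2 <= 5 ** 2
        # exhaustive scan of the generated field inside the lesion disc
        assert amap.values[disc].max() >= 3.0 * spec.background_rate

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_activity_map(PhantomSpec(region="skull"))
        with pytest.raises(ConfigurationError):
            PhantomSpec(region="pelvis", image_size=(63, 64)).validate()
        with pytest.raises(ConfigurationError):
            PhantomSpec(region="pelvis", bone_rate_scale=0.5).validate()

    def test_bone_rate_scale_bounds_map(self):
        spec = PhantomSpec(region="thorax", background_rate=10.0,
                           bone_rate_scale=5.0, subject_seed=3)
        amap = generate_activity_map(spec)
        assert amap.values.min() >= 10.0 - 1e-9
        assert amap.values.max() <= 50.0 + 1e-9
        assert amap.values.max() > 10.0


class TestAcquisition:
    def test_zero_map_yields_zero_counts(self):
        amap = ActivityMap(np.zeros((8, 8)), "pelvis",
                           PhantomSpec(region="pelvis", image_size=(8, 8),
                                       background_rate=0.0))
        img = acquire_counts(amap, 0.5, seed=0)
        assert img.counts.sum() == 0

    def test_fraction_domain(self):
        amap = ActivityMap(np.ones((8, 8)), "pelvis",
                           PhantomSpec(region="pelvis", image_size=(8, 8)))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(DomainError):
                acquire_counts(amap, bad, seed=0)

    def test_total_counts_near_poisson_mean(self):
        values = np.full((64, 64), 50.0)
        amap = ActivityMap(values, "pelvis", PhantomSpec(region="pelvis"))
        img = acquire_counts(amap, 0.3, seed=7)
        mean = 0.3 * 50.0 * 64 * 64      # 61440
        assert abs(img.counts.sum() - mean) < 4 * np.sqrt(mean)

    def test_expected_count_ratio_tracks_dose_fraction(self):
        """Counts scale linearly with acquisition time (dose proxy)."""
        values = np.full((64, 64), 20.0)
        amap = ActivityMap(values, "pelvis", PhantomSpec(region="pelvis"))
        tot_full = np.mean([acquire_counts(amap, 1.0, seed=s).counts.sum()
                            for s in range(10)])
        tot_low = np.mean([acquire_counts(amap, 0.3, seed=100 + s).counts.sum()
                           for s in range(10)])
        assert tot_low / tot_full == pytest.approx(0.30, rel=0.02)

    def test_variance_to_mean_ratio_is_poissonian(self):
        values = np.full((128, 128), 30.0)
        amap = ActivityMap(values, "pelvis", PhantomSpec(region="pelvis",
                                                         image_size=(128, 128)))
        img = acquire_counts(amap, 0.5, seed=11)
        c = img.counts.astype(float)
        vmr = c.var(ddof=1) / c.mean()
        # Var(VMR) ~ 2/(n-1) for Poisson samples
        assert abs(vmr - 1.0) < 3 * np.sqrt(2 / (c.size - 1))


class TestThinning:
    def _full(self, level=50.0, size=64, seed=0):
        amap = ActivityMap(np.full((size, size), level), "pelvis",
                           PhantomSpec(region="pelvis",
                                       image_size=(size, size)))
        return acquire_counts(amap, 1.0, seed=seed)

    def test_fraction_one_is_identity(self):
        full = self._full()
        thin = thin_counts(full, 1.0, seed=1)
        np.testing.assert_array_equal(thin.counts, full.counts)

    def test_degenerate_fraction_limit(self):
        full = self._full(level=100.0, size=16)
        thin = thin_counts(full, 1e-12, seed=2)
        assert thin.counts.sum() == 0

    def test_requires_full_dose_parent(self):
        full = self._full()
        low = thin_counts(full, 0.5, seed=3)
        with pytest.raises(DomainError):
            thin_counts(low, 0.5, seed=4)
        with pytest.raises(DomainError):
            thin_counts(full, 0.0, seed=5)

    def test_binomial_moments(self):
        full = self._full(level=50.0, seed=9)   # total about 204800
        n_total = int(full.counts.sum())
        thin = thin_counts(full, 0.5, seed=10)
        # Binomial(n_total, 0.5): sd = sqrt(n p (1-p))
        assert abs(thin.counts.sum() - 0.5 * n_total) \
            < 4 * np.sqrt(0.25 * n_total)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(fraction=st.floats(min_value=0.05, max_value=1.0),
           seed=st.integers(min_value=0, max_value=2**20))
    def test_thinned_never_exceeds_parent(self, fraction, seed):
        full = self._full(level=20.0, size=16, seed=seed % 7)
        thin = thin_counts(full, fraction, seed=seed)
        assert np.all(thin.counts <= full.counts)
        assert thin.dose_fraction == fraction

    def test_thinning_composition_matches_single_step(self):
        """thin(p) then thin(q) has the moments of thin(p*q), within 3 sigma."""
        full = self._full(level=50.0, seed=20)
        n_total = int(full.counts.sum())
        p, q = 0.8, 0.5
        reps = 20
        two_step, one_step = [], []
        for r in range(reps):
            # two-step thinning requires re-labelling the intermediate as full
            inter = thin_counts(full, p, seed=300 + r)
            inter_full = phantom.CountImage(counts=inter.counts,
                                            dose_fraction=1.0,
                                            region=inter.region)
            two = thin_counts(inter_full, q, seed=600 + r)
            two_step.append(two.counts.sum())
            one_step.append(thin_counts(full, p * q, seed=900 + r).counts.sum())
        mu = p * q * n_total
        se_mean = np.sqrt(p * q * (1 - p * q) * n_total / reps)
        assert abs(np.mean(two_step) - mu) < 3 * se_mean
        assert abs(np.mean(one_step) - mu) < 3 * se_mean
        assert abs(np.mean(two_step) - np.mean(one_step)) < 3 * np.sqrt(2) * se_mean


class TestPointSource:
    def test_single_full_fraction_total(self):
        res = simulate_point_source(1e6, [1.0], seed=1)
        tot = res.table["observed_total_counts"].iloc[0]
        assert abs(tot - 1e6) < 4 * np.sqrt(1e6)

    def test_empty_fractions_rejected(self):
        with pytest.raises(DomainError):
            simulate_point_source(1e6, [], seed=0)
        with pytest.raises(DomainError):
            simulate_point_source(-5.0, [1.0], seed=0)

    def test_protocol_linearity(self):
        res = simulate_point_source(1e6, list(phantom.PROTOCOL_FRACTIONS),
                                    seed=3)
        assert len(res.table) == 8
        assert abs(res.slope - 1e6) / 1e6 < 0.01
        assert res.r_squared > 0.999


class TestPairedDataset:
    def test_manifest_arithmetic_and_determinism(self, tmp_path):
        fr = list(phantom.LOW_DOSE_FRACTIONS)
        m1 = generate_paired_dataset(1, ["pelvis"], fr, base_seed=5,
                                     out_dir=tmp_path / "a")
        assert len(m1) == 14     # 2 views x 7 fractions
        m2 = generate_paired_dataset(1, ["pelvis"], fr, base_seed=5,
                                     out_dir=tmp_path / "b")
        for f1 in sorted((tmp_path / "a").glob("*.png")):
            f2 = tmp_path / "b" / f1.name
            assert f1.read_bytes() == f2.read_bytes()
        assert (m1.drop(columns=["path_low", "path_full"])
                .equals(m2.drop(columns=["path_low", "path_full"])))

    def test_low_dose_pixels_bounded_by_parent(self, tmp_path):
        from PIL import Image
        m = generate_paired_dataset(1, ["thorax"], [0.3, 0.7], base_seed=9,
                                    out_dir=tmp_path)
        for _, row in m.iterrows():
            low = np.asarray(Image.open(tmp_path / row.path_low), dtype=int)
            full = np.asarray(Image.open(tmp_path / row.path_full), dtype=int)
            # shared count scale, so thinning order survives 8-bit rounding
            assert np.all(low <= full + 1)

    def test_protocol_pair_count_matches_clinical_bookkeeping(self):
        # 7 low-dose fractions x 2 views x 105 subjects per anatomical region
        assert protocol_pair_count(105) == 1470
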