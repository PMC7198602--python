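"""Colocalization coefficients against brute-force oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nucleoring as nr
from nucleoring import colocalization as cl
from nucleoring import synthetic_data as sd


def brute_pearson(a, b):
    """Textbook formula with explicit sums (independent oracle)."""
    a = [float(x) for x in np.ravel(a)]
    b = [float(x) for x in np.ravel(b)]
    n = len(a)
    ma = math.fsum(a) / n
    mb = math.fsum(b) / n
    num = math.fsum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.fsum((x - ma) ** 2 for x in a)
    db = math.fsum((y - mb) ** 2 for y in b)
    return num / math.sqrt(da * db)


def as_stack3(values):
    return np.asarray(values, dtype=float).reshape(1, 1, -1)


class TestPearson:
    def test_identical_channels(self):
        a = as_stack3([1, 2, 3, 4, 5])
        assert cl.pearson(a, a) == pytest.approx(1.0)

    def test_affine_anticorrelation(self):
        a = as_stack3([1, 2, 3, 4, 5])
        assert cl.pearson(a, -2.0 * a + 7.0) == pytest.approx(-1.0)

    def test_toy_matches_textbook_formula(self):
        a = as_stack3([1, 2, 3, 4, 5])
        b = as_stack3([2, 1, 4, 3, 6])
        assert cl.pearson(a, b) == pytest.approx(brute_pearson(a, b), abs=1e-12)

    def test_constant_channel_errors(self):
        a = as_stack3([1, 1, 1, 1])
        b = as_stack3([1, 2, 3, 4])
        with pytest.raises(ValueError, match="constant"):
            cl.pearson(a, b)

    @given(
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
        seed=st.integers(0, 100),
    )
    def test_invariant_under_positive_affine_rescaling(self, scale, offset, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(3, 4, 4))
        b = rng.normal(size=(3, 4, 4)) + 0.5 * a
        r0 = cl.pearson(a, b)
        r1 = cl.pearson(a * scale + offset, b)
        assert abs(r1 - r0) < 1e-10


class TestMandersSplit:
    def test_identical_below_threshold_gives_one(self):
        a = as_stack3([1.0, 2.0, 3.0])
        m1, m2 = cl.manders_split(a, a, 0.5, 0.5)
        assert (m1, m2) == (1.0, 1.0)

    def test_disjoint_supports_give_zero(self):
        a = as_stack3([5.0, 0.0, 0.0])
        b = as_stack3([0.0, 0.0, 5.0])
        m1, m2 = cl.manders_split(a, b, 1.0, 1.0)
        assert (m1, m2) == (0.0, 0.0)

    def test_toy_enumeration(self):
        a = as_stack3([10.0, 0.0, 5.0, 0.0])
        b = as_stack3([1.0, 1.0, 0.0, 0.0])
        m1, m2 = cl.manders_split(a, b, 0.5, 0.5)
        assert m1 == pytest.approx(10.0 / 15.0)
        assert m2 == pytest.approx(1.0 / 2.0)

    def test_m1_non_increasing_in_partner_threshold(self):
        rng = np.random.default_rng(3)
        a = rng.random((4, 5, 5))
        b = rng.random((4, 5, 5))
        thresholds = np.linspace(0.0, 1.0, 11)
        m1s = [cl.manders_split(a, b, 0.5, t2)[0] for t2 in thresholds]
        assert all(x >= y - 1e-12 for x, y in zip(m1s, m1s[1:]))

    def test_zero_channel_errors(self):
        with pytest.raises(ValueError, match="zero"):
            cl.manders_split(as_stack3([0.0, 0.0]), as_stack3([1.0, 1.0]), 0.1, 0.1)


class TestMandersOverlap:
    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.random((3, 4, 4))
        assert cl.manders_overlap(a, 3.7 * a) == pytest.approx(1.0)

    def test_orthogonal_supports(self):
        a = as_stack3([1.0, 0.0])
        b = as_stack3([0.0, 1.0])
        assert cl.manders_overlap(a, b) == 0.0

    def test_toy_hand_arithmetic(self):
        a = as_stack3([1.0, 2.0, 0.0])
        b = as_stack3([2.0, 1.0, 1.0])
        assert cl.manders_overlap(a, b) == pytest.approx(4.0 / math.sqrt(30.0))


def exhaustive_costes_oracle(a, b, mask=None):
    """Naive re-implementation: TLS line + exhaustive integer-level scan."""
    v1 = a[mask].astype(float) if mask is not None else a.ravel().astype(float)
    v2 = b[mask].astype(float) if mask is not None else b.ravel().astype(float)
    cov = np.cov(np.stack([v1, v2]))
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    slope = major[1] / major[0]
    intercept = v2.mean() - slope * v1.mean()
    for t1 in np.arange(v1.max(), v1.min() - 1, -1.0):
        t2 = slope * t1 + intercept
        below = (v1 < t1) & (v2 < t2)
        if below.sum() < 2:
            continue
        b1, b2 = v1[below], v2[below]
        if b1.min() == b1.max() or b2.min() == b2.max():
            continue
        if brute_pearson(b1, b2) <= 0:
            return t1, max(t2, v2.min())
    return v1.min(), max(slope * v1.min() + intercept, v2.min())


class TestCostesThreshold:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle_on_integer_images(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 50, size=(12, 12, 12))
        noise = rng.normal(0, 8, size=a.shape)
        b = np.clip(np.round(0.8 * a + 10 + noise), 0, None).astype(np.int64)
        result = cl.costes_threshold(a, b)
        t1_oracle, t2_oracle = exhaustive_costes_oracle(a, b)
        assert result.t1 == t1_oracle
        assert result.t2 == pytest.approx(t2_oracle, abs=1e-9)

    def test_definitional_property(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 60, size=(10, 10, 10))
        b = np.clip(
            np.round(0.6 * a + 5 + rng.normal(0, 10, a.shape)), 0, None
        ).astype(np.int64)
        res = cl.costes_threshold(a, b)
        v1, v2 = a.ravel().astype(float), b.ravel().astype(float)
        below = (v1 < res.t1) & (v2 < res.t2)
        assert brute_pearson(v1[below], v2[below]) <= 0
        # one scan step higher the sub-threshold population correlates positively
        t1_up = res.t1 + 1.0
        t2_up = res.slope * t1_up + res.intercept
        above = (v1 < t1_up) & (v2 < t2_up)
        assert brute_pearson(v1[above], v2[above]) > 0

    def test_perfectly_correlated_flagged_degenerate(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 30, size=(8, 8, 8))
        res = cl.costes_threshold(a, a.copy())
        assert res.degenerate
        assert res.t1 == a.min()

    def test_anticorrelated_slope_errors(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 30, size=(8, 8, 8)).astype(float)
        b = 50.0 - a + rng.normal(0, 1, a.shape)
        with pytest.raises(ValueError, match="slope"):
            cl.costes_threshold(a, b)

    def test_manders_at_costes_thresholds_interior(self):
        ds = sd.simulate_two_channel_dataset(
            n_rings=8, coloc_mixing=0.5, canvas_shape=(24, 160, 160), seed=11
        )
        res = cl.costes_threshold(ds.ch1, ds.ch2, ds.rois.nucleolus)
        m1, m2 = cl.manders_split(
            ds.ch1, ds.ch2, res.t1, res.t2, ds.rois.nucleolus
        )
        assert 0.0 < m1 < 1.0
        assert 0.0 < m2 < 1.0


class TestCostesSignificance:
    def _structured_pair(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(8, 40, 40))
        from scipy.ndimage import gaussian_filter

        a = gaussian_filter(base, 1.0)
        return nr.ImageStack(a, (40.0, 40.0, 40.0))

    def test_identical_channels_minimum_p(self):
        stack = self._structured_pair()
        sig = cl.costes_significance(
            stack, stack, block_nm=200.0, n_perm=99, seed=0
        )
        assert sig.p_value == pytest.approx(1.0 / 100.0)
        assert sig.n_blocks >= 20

    def test_same_seed_reproducible(self):
        stack = self._structured_pair()
        rng = np.random.default_rng(9)
        other = nr.ImageStack(rng.normal(size=stack.shape), stack.voxel_size)
        s1 = cl.costes_significance(stack, other, block_nm=200.0, n_perm=99, seed=5)
        s2 = cl.costes_significance(stack, other, block_nm=200.0, n_perm=99, seed=5)
        assert s1.p_value == s2.p_value
        assert s1.null_mean == s2.null_mean

    def test_small_mask_rejected(self):
        stack = self._structured_pair()
        mask = np.zeros(stack.shape, bool)
        mask[:2, :6, :6] = True
        with pytest.raises(ValueError, match="too small"):
            cl.costes_significance(stack, stack, mask, block_nm=200.0, n_perm=99)

    def test_n_perm_floor(self):
        stack = self._structured_pair()
        with pytest.raises(ValueError, match="n_perm"):
            cl.costes_significance(stack, stack, n_perm=10)


class TestRoiColocalization:
    def test_nucleolar_enrichment_ordering(self):
        ch1, ch2, rois = sd.simulate_roi_contrast_dataset(seed=3)
        table = cl.roi_colocalization(ch1, ch2, rois, n_perm=0)
        moc = table.set_index("roi")["moc"]
        assert moc["nucleolus"] > moc["extranucleolar"]

    def test_empty_extranucleolar_reported_missing(self):
        ds = sd.simulate_two_channel_dataset(
            n_rings=4, canvas_shape=(16, 96, 96), seed=13
        )
        rois = nr.RoiSet(
            cell=ds.rois.cell, nucleus=ds.rois.nucleolus, nucleolus=ds.rois.nucleolus
        )
        table = cl.roi_colocalization(ds.ch1, ds.ch2, rois, n_perm=0)
        row = table.set_index("roi").loc["extranucleolar"]
        assert np.isnan(row["pcc"]) and row["note"]
        assert not np.isnan(table.set_index("roi").loc["nucleolus"]["pcc"])

    def test_determinism(self):
        ds = sd.simulate_two_channel_dataset(
            n_rings=4, canvas_shape=(16, 96, 96), seed=14
        )
        t1 = cl.roi_colocalization(ds.ch1, ds.ch2, ds.rois, n_perm=99, seed=2)
        t2 = cl.roi_colocalization(ds.ch1, ds.ch2, ds.rois, n_perm=99, seed=2)
        assert t1.equals(t2)
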