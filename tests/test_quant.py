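"""Density ratio, overlap, rank-sum and boxplot statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from centroquant.errors import DomainError, UndefinedValueError
from centroquant.quant import (
    marker_effect, normalized_density, overlap_fraction, rank_sum_enumeration,
    rank_sum_test, spot_mean_intensity, summarize_group,
)
from centroquant.segmentation import FocusRecord, NucleusRecord


def make_nucleus(label=1, voxels=10, signal=20.0, volume=10.0, channel="m"):
    return NucleusRecord(
        label=label, voxel_count=voxels, volume_um3=volume,
        signal={channel: signal}, mean_intensity={channel: signal / voxels},
        bbox=((0, 1), (0, 1), (0, 1)),
    )


def make_focus(label=1, nucleus=1, signal=8.0, volume=2.0, channel="m"):
    return FocusRecord(label=label, nucleus_label=nucleus, channel=channel,
                       voxel_count=int(volume), volume_um3=volume, signal=signal)


class TestDensity:
    def test_worked_example(self):
        res = normalized_density([make_focus(signal=8, volume=2)],
                                 make_nucleus(signal=20, volume=10))
        assert res.density == pytest.approx(2.0)

    def test_uniform_nucleus_gives_one(self):
        # any focus mask of a uniform nucleus: focus mean = nuclear mean
        res = normalized_density([make_focus(signal=4, volume=2)],
                                 make_nucleus(signal=20, volume=10))
        assert res.density == pytest.approx(1.0)

    def test_zero_signal_foci_give_zero(self):
        res = normalized_density([make_focus(signal=0, volume=2)],
                                 make_nucleus(signal=20, volume=10))
        assert res.density == 0.0

    def test_zero_volume_raises(self):
        with pytest.raises(UndefinedValueError):
            normalized_density([make_focus(signal=1, volume=0)], make_nucleus())

    def test_foreign_focus_raises(self):
        with pytest.raises(DomainError):
            normalized_density([make_focus(nucleus=2)], make_nucleus(label=1))

    def test_pooling_is_ratio_of_sums_not_mean_of_ratios(self, rng):
        for _ in range(200):
            k = rng.integers(2, 6)
            sig = rng.uniform(0.1, 10, k)
            vol = rng.uniform(0.1, 5, k)
            nsig = sig.sum() + rng.uniform(1, 50)
            nvol = vol.sum() + rng.uniform(1, 20)
            foci = [make_focus(label=i, signal=s, volume=v)
                    for i, (s, v) in enumerate(zip(sig, vol))]
            nuc = make_nucleus(signal=nsig, volume=nvol)
            got = normalized_density(foci, nuc).density
            pooled = (sig.sum() / vol.sum()) / (nsig / nvol)
            per_focus_mean = np.mean([(s / v) / (nsig / nvol)
                                      for s, v in zip(sig, vol)])
            assert got == pytest.approx(pooled, rel=1e-12)
            if not np.isclose(pooled, per_focus_mean):
                assert got != pytest.approx(per_focus_mean, rel=1e-6)

    def test_scale_invariance(self, rng):
        foci = [make_focus(signal=3.3, volume=1.1)]
        nuc = make_nucleus(signal=17.0, volume=9.0)
        base = normalized_density(foci, nuc).density
        c = 41.7
        foci_c = [make_focus(signal=3.3 * c, volume=1.1)]
        nuc_c = make_nucleus(signal=17.0 * c, volume=9.0)
        assert normalized_density(foci_c, nuc_c).density == pytest.approx(base)


class TestSpotMeanIntensity:
    def test_examples(self):
        assert spot_mean_intensity(make_focus(signal=46, volume=2.3)) == pytest.approx(20.0)
        assert spot_mean_intensity(make_focus(signal=0, volume=1)) == 0.0
        a = spot_mean_intensity(make_focus(signal=10, volume=2))
        b = spot_mean_intensity(make_focus(signal=20, volume=4))
        assert a == pytest.approx(b)

    def test_zero_volume_raises(self):
        with pytest.raises(UndefinedValueError):
            spot_mean_intensity(make_focus(signal=1, volume=0))


class TestOverlap:
    def test_identical_candidate_gives_100(self):
        ref = np.zeros((4, 4, 4), bool)
        ref[1:3, 1:3, 1:3] = True
        cand = np.where(ref, 5, 0)
        res = overlap_fraction(ref, cand)
        assert res.partner_label == 5 and res.overlap_percent == 100.0

    def test_disjoint_gives_none(self):
        ref = np.zeros((4, 4, 4), bool)
        ref[0, 0, 0] = True
        cand = np.zeros((4, 4, 4), int)
        cand[3, 3, 3] = 1
        res = overlap_fraction(ref, cand)
        assert res.partner_label is None and res.overlap_percent == 0.0

    def test_largest_overlap_chosen(self):
        ref = np.zeros((2, 2, 2), bool).ravel()
        ref[:] = True          # 8 voxels
        ref = ref.reshape(2, 2, 2)
        cand = np.zeros((2, 2, 2), int)
        cand[0, 0, :] = 1      # overlap 2
        cand[1, 1, 1] = 2      # overlap 1
        res = overlap_fraction(ref, cand)
        assert res.partner_label == 1
        assert res.overlap_percent == pytest.approx(25.0)

    def test_empty_reference_raises(self):
        with pytest.raises(DomainError):
            overlap_fraction(np.zeros((2, 2), bool), np.zeros((2, 2), int))

    def test_matches_set_intersection_oracle(self, rng):
        for _ in range(60):
            shape = (4, 5, 5)
            ref = rng.random(shape) < 0.3
            if not ref.any():
                ref[0, 0, 0] = True
            cand = rng.integers(0, 4, shape)
            res = overlap_fraction(ref, cand)
            ref_set = set(map(tuple, np.argwhere(ref)))
            best = None
            for lab in (1, 2, 3):
                inter = len(ref_set & set(map(tuple, np.argwhere(cand == lab))))
                if inter and (best is None or inter > best[1]):
                    best = (lab, inter)
            if best is None:
                assert res.partner_label is None
            else:
                assert res.overlap_percent == pytest.approx(
                    100 * best[1] / len(ref_set))


class TestRankSum:
    def test_separated_samples_exact_p(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = rng.normal(size=7).tolist()
        b = rng.normal(1, 1, size=5).tolist()
        ua, pa = rank_sum_test(a, b)
        ub, pb = rank_sum_test(b, a)
        assert pa == pytest.approx(pb)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_empty_sample_raises(self):
        with pytest.raises(DomainError):
            rank_sum_test([], [1.0])

    @given(st.integers(2, 6), st.integers(2, 6), st.integers(0, 10_000))
    def test_exact_branch_matches_enumeration(self, n, m, seed):
        r = np.random.default_rng(seed)
        vals = r.permutation(np.arange(n + m, dtype=float) * 1.37)
        a, b = vals[:n], vals[n:]
        _, p = rank_sum_test(a, b)
        _, p_oracle = rank_sum_enumeration(a, b)
        assert p == pytest.approx(p_oracle, abs=1e-12)


class TestSummarizeGroup:
    def test_basic_quartiles(self):
        s = summarize_group([1, 2, 3, 4, 5])
        assert (s.median, s.q1, s.q3) == (3, 2, 4)
        assert (s.whisker_low, s.whisker_high) == (1, 5)

    def test_constant_sample(self):
        s = summarize_group([7, 7, 7])
        assert s.median == s.q1 == s.q3 == s.whisker_low == s.whisker_high == 7

    def test_outlier_does_not_move_whisker(self):
        base = [1, 2, 3, 4, 5, 6, 7, 8]
        s0 = summarize_group(base)
        s1 = summarize_group(base + [100.0])
        assert s1.whisker_high == s0.whisker_high == 8

    def test_empty_raises(self):
        with pytest.raises(DomainError):
            summarize_group([])


class TestMarkerEffect:
    def test_exact_on_constructed_densities(self):
        control = [1.0 + 2.0, 1.0 + 2.4]       # excess mean 2.2
        treated = [1.0 + 1.54, 1.0 + 1.98]     # excess mean 1.76 = 0.8 * 2.2
        assert marker_effect(control, treated) == pytest.approx(0.2)

    def test_no_enrichment_raises(self):
        with pytest.raises(UndefinedValueError):
            marker_effect([0.9, 1.0], [1.2])
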