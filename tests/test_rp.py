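"""Delay embedding, recurrence matrices, sign masks, and signed RPs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msrp import (
    EmbedConfig,
    EmbeddingError,
    TimeSeries,
    embed,
    encode,
    recurrence_matrix,
    sign_mask,
    signed_recurrence_matrix,
    znormalize,
)
from oracles import brute_force_rp, brute_force_sign_mask

S1 = TimeSeries([1.0, 2.0, 3.0])
S2 = TimeSeries([3.0, 2.0, 1.0])
CFG = EmbedConfig(m=2, tau=1)


finite_series = st.lists(
    st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
    min_size=6, max_size=40,
).map(lambda v: TimeSeries(np.array(v)))


class TestSeries:
    def test_rejects_too_short_and_nonfinite(self):
        with pytest.raises(ValueError):
            TimeSeries([1.0])
        with pytest.raises(ValueError):
            TimeSeries([1.0, np.nan, 2.0])

    def test_znormalize_standardizes(self, rng):
        s = TimeSeries(rng.normal(3.0, 7.0, size=200))
        z = znormalize(s)
        assert abs(z.values.mean()) < 1e-6
        assert abs(z.values.std() - 1.0) < 1e-6

    def test_znormalize_constant_series_centered_to_zero(self):
        z = znormalize(TimeSeries(np.full(10, 4.2)))
        assert np.all(z.values == 0.0)


class TestEmbed:
    def test_monotone_triple(self):
        states = embed(S1, CFG)
        assert states.states.tolist() == [[1.0, 2.0], [2.0, 3.0]]
        assert states.n_states == 2

    def test_m1_is_identity(self, random_series):
        states = embed(random_series, EmbedConfig(m=1, tau=1))
        assert states.n_states == len(random_series)
        assert np.array_equal(states.states[:, 0], random_series.values)

    def test_boundary_single_state(self):
        s = TimeSeries(np.arange(9.0))
        states = embed(s, EmbedConfig(m=3, tau=4))
        assert states.n_states == 1
        assert states.states.tolist() == [[0.0, 4.0, 8.0]]

    def test_infeasible_embedding_names_parameters(self):
        with pytest.raises(EmbeddingError, match=r"L=5.*m=3.*tau=4"):
            embed(TimeSeries(np.arange(5.0)), EmbedConfig(m=3, tau=4))

    @given(data=finite_series, m=st.integers(1, 4), tau=st.integers(1, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_state_count_formula(self, data, m, tau):
        cfg = EmbedConfig(m=m, tau=tau)
        L = len(data)
        if L - (m - 1) * tau < 1:
            with pytest.raises(EmbeddingError):
                embed(data, cfg)
        else:
            assert embed(data, cfg).n_states == L - (m - 1) * tau


class TestRecurrenceMatrix:
    def test_worked_example_and_tendency_confusion(self):
        rp1 = recurrence_matrix(embed(S1, CFG), CFG).pixels
        rp2 = recurrence_matrix(embed(S2, CFG), CFG).pixels
        assert rp1.tolist() == [[0.0, 2.0], [2.0, 0.0]]
        # opposite monotone trends yield the very same unsigned image
        assert np.array_equal(rp1, rp2)

    def test_constant_series_all_zero(self):
        s = TimeSeries(np.full(20, 5.0))
        for norm in ("l1", "l2", "l2sq", "linf"):
            cfg = EmbedConfig(m=3, tau=4, norm=norm)
            assert np.all(recurrence_matrix(embed(s, cfg), cfg).pixels == 0.0)

    @pytest.mark.parametrize("norm", ["l1", "l2", "l2sq", "linf"])
    @pytest.mark.parametrize("mt", [(2, 1), (3, 4)])
    def test_matches_brute_force(self, rng, norm, mt):
        cfg = EmbedConfig(m=mt[0], tau=mt[1], norm=norm)
        for _ in range(5):
            s = TimeSeries(rng.normal(size=50))
            states = embed(s, cfg)
            got = recurrence_matrix(states, cfg).pixels
            assert np.abs(got - brute_force_rp(states.states, norm)).max() == 0.0

    def test_binarized_is_heaviside_of_distances(self, rng):
        s = TimeSeries(rng.normal(size=30))
        plain_cfg = EmbedConfig(m=2, tau=1)
        d = recurrence_matrix(embed(s, plain_cfg), plain_cfg).pixels
        eps = float(np.median(d))
        bin_cfg = EmbedConfig(m=2, tau=1, epsilon=eps, binarize=True)
        b = recurrence_matrix(embed(s, bin_cfg), bin_cfg).pixels
        assert set(np.unique(b)) <= {0.0, 1.0}
        assert np.array_equal(b, (d <= eps).astype(float))
        # boundary: the zero diagonal is within any non-negative threshold
        assert np.all(np.diag(b) == 1.0)

    def test_binarize_requires_epsilon(self):
        with pytest.raises(ValueError, match="epsilon"):
            EmbedConfig(m=2, tau=1, binarize=True)

    @given(data=finite_series)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_with_zero_diagonal(self, data):
        rp = recurrence_matrix(embed(data, CFG), CFG).pixels
        assert np.array_equal(rp, rp.T)
        assert np.all(np.diag(rp) == 0.0)
        assert np.all(rp >= 0.0)


class TestSignMask:
    def test_worked_example(self):
        mask = sign_mask(embed(S1, CFG)).mask
        assert mask.tolist() == [[1.0, -1.0], [1.0, 1.0]]

    def test_constant_series_all_plus_one(self):
        s = TimeSeries(np.full(15, 2.0))
        assert np.all(sign_mask(embed(s, CFG)).mask == 1.0)

    def test_matches_brute_force(self, rng):
        cfg = EmbedConfig(m=3, tau=4)
        s = TimeSeries(rng.normal(size=40))
        states = embed(s, cfg)
        assert np.array_equal(sign_mask(states).mask,
                              brute_force_sign_mask(states.states))

    @given(data=finite_series)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetric_where_sum_nonzero(self, data):
        states = embed(data, CFG)
        mask = sign_mask(states).mask
        sums = states.states.sum(axis=1)
        nonzero = sums[:, None] != sums[None, :]
        assert np.all(mask[nonzero] == -mask.T[nonzero])
        assert set(np.unique(mask)) <= {-1.0, 1.0}


class TestSignedRP:
    def test_opposite_trends_now_distinguishable(self):
        srp1 = signed_recurrence_matrix(embed(S1, CFG), CFG).pixels
        srp2 = signed_recurrence_matrix(embed(S2, CFG), CFG).pixels
        assert srp1.tolist() == [[0.0, -2.0], [2.0, 0.0]]
        assert srp2.tolist() == [[0.0, 2.0], [-2.0, 0.0]]
        off = ~np.eye(2, dtype=bool)
        assert np.all(np.sign(srp1[off]) == -np.sign(srp2[off]))

    def test_magnitude_equals_unsigned(self, rng):
        cfg = EmbedConfig(m=3, tau=4, norm="l2")
        s = TimeSeries(rng.normal(size=60))
        states = embed(s, cfg)
        signed = signed_recurrence_matrix(states, cfg).pixels
        unsigned = recurrence_matrix(states, cfg).pixels
        assert np.array_equal(np.abs(signed), unsigned)

    def test_rejects_binarized_config(self):
        cfg = EmbedConfig(m=2, tau=1, epsilon=0.5, binarize=True)
        with pytest.raises(ValueError, match="signed RP undefined"):
            signed_recurrence_matrix(embed(S1, cfg), cfg)

    @given(data=finite_series)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetric_where_mask_is(self, data):
        states = embed(data, CFG)
        srp = signed_recurrence_matrix(states, CFG).pixels
        sums = states.states.sum(axis=1)
        nonzero = sums[:, None] != sums[None, :]
        assert np.allclose(srp[nonzero], -srp.T[nonzero])
        assert np.all(np.diag(srp) == 0.0)


class TestEncode:
    def test_unsigned_worked_example(self):
        img = encode(S1, CFG, signed=False)
        assert img.pixels.tolist() == [[0.0, 2.0], [2.0, 0.0]]
        assert not img.signed and img.m == 2 and img.tau == 1
        assert img.source_length == 3

    def test_constant_series_signed_is_zero(self):
        img = encode(TimeSeries(np.full(12, 1.5)), CFG, signed=True)
        assert np.all(img.pixels == 0.0)

    def test_composition_matches_components(self, rng):
        cfg = EmbedConfig(m=3, tau=4, norm="l2")
        s = TimeSeries(rng.normal(size=55))
        states = embed(s, cfg)
        expected = sign_mask(states).mask * recurrence_matrix(states, cfg).pixels
        assert np.array_equal(encode(s, cfg, signed=True).pixels, expected)

    def test_reversal_property_for_monotone_series(self):
        # the tendency confusion: an equal-increment monotone ramp and its
        # reversal share the unsigned image but differ in the signed one
        s = TimeSeries(np.linspace(-1.0, 1.0, 30))
        r = TimeSeries(s.values[::-1].copy())
        unsigned_s = encode(s, CFG, signed=False).pixels
        unsigned_r = encode(r, CFG, signed=False).pixels
        assert np.allclose(unsigned_s, unsigned_r)
        assert not np.array_equal(encode(s, CFG, True).pixels,
                                  encode(r, CFG, True).pixels)
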