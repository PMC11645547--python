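"""Repeat (copy) models: estimators, stop filter, cache table, LCG."""

import math
import random
from collections import deque

import numpy as np
import pytest

from seqzip.repeat_models import (
    CacheTable,
    HitLookupTable,
    Lcg,
    RepeatModel,
    RmConfig,
    rm_predict,
    rm_try_start,
    rm_update,
)


class TestHitLookupTable:
    def test_zero_count_cell(self):
        lut = HitLookupTable()
        ph, po = lut.get(0, 0)
        assert ph == 0.5
        assert po == (1 - 0.5) / 3

    def test_small_cells(self):
        lut = HitLookupTable()
        ph, po = lut.get(3, 1)
        assert ph == 4 / 6
        assert po == (1 - 4 / 6) / 3  # == 1/9 up to double rounding

    def test_full_domain_exactness(self):
        """Every stored cell equals the closed forms bit for bit and the
        distribution mass balances to 1 within 1e-15."""
        lut = HitLookupTable(alphabet_size=4, lut_max=200)
        for nh in range(201):
            for nm in range(201 - nh):
                ph, po = lut.get(nh, nm)
                assert ph == (nh + 1) / (nh + nm + 2)  # exact
                assert po == (1 - (nh + 1) / (nh + nm + 2)) / 3
                assert abs(ph + 3 * po - 1.0) < 1e-15

    def test_beyond_bound_analytic(self):
        lut = HitLookupTable()
        ph, po = lut.get(150, 100)
        assert ph == 151 / 252
        assert po == (1 - 151 / 252) / 3

    def test_near_bound_cell(self):
        lut = HitLookupTable()
        assert lut.get(198, 0)[0] == 199 / 200

    def test_tiny_alphabet_rejected(self):
        with pytest.raises(ValueError):
            HitLookupTable(alphabet_size=1)


class TestRmPredict:
    def test_fresh_model_distribution(self):
        lut = HitLookupTable()
        m = RepeatModel(pointer=0)
        assert rm_predict(m, lut, 2) == (1 / 6, 1 / 6, 1 / 2, 1 / 6)

    def test_inactive_model_rejected(self):
        lut = HitLookupTable()
        m = RepeatModel(pointer=0, active=False)
        with pytest.raises(RuntimeError):
            rm_predict(m, lut, 0)

    def test_distribution_sums_to_one(self):
        lut = HitLookupTable()
        m = RepeatModel(pointer=0, nh=37, nm=4)
        assert sum(rm_predict(m, lut, 1)) == pytest.approx(1.0, abs=1e-12)


class TestStopFilter:
    def test_all_hits_never_stops(self):
        cfg = RmConfig()
        m = RepeatModel(pointer=0)
        for _ in range(10_000):
            rm_update(m, cfg, True)
        assert m.active and m.y == 0.0 and m.nh == 10_000

    def test_twelve_consecutive_misses_stop(self):
        """With beta=0.9 and L=7 the filtered miss load first exceeds the
        limit at the 12th consecutive miss: Y_n = (1 - 0.9^n)/0.1."""
        cfg = RmConfig(beta=0.9, limit=7.0)
        m = RepeatModel(pointer=0)
        for n in range(1, 13):
            assert m.active
            rm_update(m, cfg, False)
            expect_y = (1 - 0.9**n) / 0.1
            assert m.y == pytest.approx(expect_y, rel=1e-12)
        assert not m.active  # stopped exactly at n=12
        assert m.nm == 12

    def test_eleven_misses_do_not_stop(self):
        cfg = RmConfig(beta=0.9, limit=7.0)
        m = RepeatModel(pointer=0)
        for _ in range(11):
            rm_update(m, cfg, False)
        assert m.active

    def test_random_trace_matches_bruteforce(self):
        """Replay hit/miss traces against an independent filter oracle."""
        rng = random.Random(8)
        cfg = RmConfig(beta=0.77, limit=3.5)
        m = RepeatModel(pointer=10)
        y, nh, nm, active, ptr = 0.0, 0, 0, True, 10
        for step in range(2000):
            if not active:
                break
            hit = rng.random() < 0.8
            rm_update(m, cfg, hit)
            # oracle
            if hit:
                nh += 1
                x = 0.0
            else:
                nm += 1
                x = 1.0
            ptr += 1
            y = x + cfg.beta * y
            if y > cfg.limit:
                active = False
            assert (m.nh, m.nm, m.pointer, m.active) == (nh, nm, ptr, active), step
            assert m.y == pytest.approx(y, rel=1e-12)


class TestCacheTable:
    def test_fifo_eviction(self):
        t = CacheTable(k=4, c=2)
        for pos in (10, 20, 30):
            t.insert(7, pos)
        assert list(t.positions(7)) == [20, 30]

    def test_distinct_kmers_independent(self):
        t = CacheTable(k=4, c=1)
        t.insert(1, 5)
        t.insert(2, 9)
        assert list(t.positions(1)) == [5]
        assert list(t.positions(2)) == [9]

    def test_ring_length_is_min_n_c(self):
        t = CacheTable(k=4, c=8)
        for n in range(1, 30):
            t.insert(3, n)
            assert len(t.positions(3)) == min(n, 8)

    def test_entry_count_bounded(self):
        cfg = RmConfig(k=2, c=3)
        t = CacheTable(k=cfg.k, c=cfg.c)
        rng = random.Random(2)
        for pos in range(5000):
            t.insert(rng.randrange(16), pos)
        assert t.n_entries <= cfg.max_cache_entries == 16 * 3

    def test_k_over_fifteen_rejected(self):
        with pytest.raises(ValueError, match="k <= 15"):
            RmConfig(k=16)


class TestLcg:
    def test_fixed_seed_reproducible(self):
        a, b = Lcg(seed=42), Lcg(seed=42)
        assert [a.next() for _ in range(100)] == [b.next() for _ in range(100)]

    def test_classic_constants(self):
        g = Lcg(seed=1)
        assert g.next() == (1664525 * 1 + 1013904223) % 2**32


class TestTryStart:
    def test_empty_ring_no_model(self):
        t = CacheTable(k=3, c=4)
        assert rm_try_start(t, Lcg(), kmer=5, current_pos=100) is None

    def test_singleton_ring_always_selected(self):
        t = CacheTable(k=3, c=4)
        t.insert(5, 17)
        for _ in range(10):
            m = rm_try_start(t, Lcg(seed=99), kmer=5, current_pos=100)
            assert m is not None and m.pointer == 18
            assert m.nh == m.nm == 0 and m.y == 0.0 and m.active

    def test_selection_uniform_over_ring(self):
        """Frequencies over 1e5 draws stay within 3 sigma of uniform."""
        t = CacheTable(k=3, c=8)
        positions = list(range(100, 108))
        for p in positions:
            t.insert(5, p)
        lcg = Lcg(seed=1)
        counts = {p: 0 for p in positions}
        n = 100_000
        for _ in range(n):
            m = rm_try_start(t, lcg, kmer=5, current_pos=200)
            counts[m.pointer - 1] += 1
        expect = n / 8
        sigma = math.sqrt(n * (1 / 8) * (7 / 8))
        for p in positions:
            assert abs(counts[p] - expect) < 3 * sigma


def test_single_rm_captures_tandem_repeat(tandem_fixture):
    """A single-repeat-model ensemble codes the 1 kb x200 tandem fixture
    (0.1% substitutions) in under 0.15 bits/base."""
    from seqzip.engine import Ensemble
    from seqzip.profiles import resolve_profile

    symbols, _ = tandem_fixture
    total = Ensemble(resolve_profile(1)).total_code_length(symbols.tolist())
    assert total / len(symbols) < 0.15
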