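"""Repeat (copy) models with probabilistic lookup tables.

A repeat model bets that the next symbol equals the symbol at a pointer
into the already-seen sequence.  Its confidence comes from hit/miss
counters through the Laplace-style estimator

    P(hit) = (Nh + 1) / (Nh + Nm + 2),

with the complementary mass spread uniformly over the other symbols,

    P(s != predicted) = (1 - P(hit)) / (|Sigma| - 1).

Because a model rarely survives long (typically under 200 symbols), both
quantities are precomputed for every (Nh, Nm) with Nh + Nm <= lut_max into
two lookup tables; beyond the bound they are evaluated analytically with
the identical expression, so table and closed form agree bit for bit.

Model health is tracked by a first-order low-pass filter over the
instantaneous miss indicator X (1 on miss, 0 on hit):

    Y_i = X_i + beta * Y_{i-1},

and the model is stopped once Y exceeds the limit L.  With the usual
beta = 0.9 and L = 7, a fresh model dies after exactly 12 consecutive
misses.

Candidate start positions come from a cache table that retains only the
``c`` most recent positions of each k-mer (worst-case 4^k * c entries);
one of them is chosen by a linear congruential generator with a fixed
seed so that encoder and decoder make identical choices.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RmConfig",
    "RepeatModel",
    "HitLookupTable",
    "CacheTable",
    "Lcg",
    "rm_predict",
    "rm_update",
    "rm_try_start",
]

MAX_KMER_ORDER = 15  # 4^k * c cache entries become prohibitive beyond this


@dataclass(frozen=True)
class RmConfig:
    """Parameters of a repeat-model bank.

    k: anchor k-mer length (12-14 typical; > 15 rejected — the exact-index
        cache table would need 4^k rings).
    c: cache slots retained per k-mer.
    beta: low-pass decay of the miss filter, in (0, 1).
    limit: stop threshold L on the filtered miss rate.
    lut_max: lookup tables cover Nh + Nm <= lut_max.
    n_models: repeat models of this bank that may run simultaneously.
    """

    k: int = 13
    c: int = 8
    beta: float = 0.9
    limit: float = 7.0
    lut_max: int = 200
    n_models: int = 1
    alphabet_size: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")
        if self.limit <= 0:
            raise ValueError("limit must be positive")
        if self.c < 1 or self.lut_max < 1 or self.n_models < 1:
            raise ValueError("c, lut_max and n_models must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > MAX_KMER_ORDER:
            raise ValueError(
                f"k={self.k} is not supported: the exact cache table needs "
                f"4^k rings; use k <= {MAX_KMER_ORDER}"
            )

    @property
    def max_cache_entries(self) -> int:
        return (4**self.k) * self.c


@dataclass
class RepeatModel:
    """State of one running copy model."""

    pointer: int  # past position whose successor stream is being copied
    nh: int = 0
    nm: int = 0
    y: float = 0.0
    active: bool = True


class HitLookupTable:
    """Precomputed hit / non-hit probabilities for Nh + Nm <= lut_max."""

    def __init__(self, alphabet_size: int = 4, lut_max: int = 200):
        if alphabet_size < 2:
            raise ValueError("alphabet size must be >= 2 (Eq. for non-hits divides by |Sigma|-1)")
        self.alphabet_size = alphabet_size
        self.lut_max = lut_max
        n = lut_max + 1
        nh = np.arange(n, dtype=np.float64)[:, None]
        nm = np.arange(n, dtype=np.float64)[None, :]
        p = (nh + 1.0) / (nh + nm + 2.0)
        self.p_hit = p
        self.p_other = (1.0 - p) / float(alphabet_size - 1)

    def get(self, nh: int, nm: int) -> tuple[float, float]:
        """(P(hit), per-symbol non-hit probability) for the given counters.

        Inside the table bound this is a lookup; beyond it the same closed
        forms are evaluated directly.
        """
        if nh + nm <= self.lut_max:
            return float(self.p_hit[nh, nm]), float(self.p_other[nh, nm])
        ph = (nh + 1.0) / (nh + nm + 2.0)
        return ph, (1.0 - ph) / float(self.alphabet_size - 1)


class CacheTable:
    """Bounded k-mer position store: the ``c`` most recent per k-mer."""

    def __init__(self, k: int, c: int):
        self.k = k
        self.c = c
        self.store: dict[int, deque[int]] = {}

    def insert(self, kmer: int, pos: int) -> None:
        ring = self.store.get(kmer)
        if ring is None:
            self.store[kmer] = ring = deque(maxlen=self.c)
        ring.append(pos)  # deque(maxlen) evicts the oldest automatically

    def positions(self, kmer: int) -> deque[int] | None:
        return self.store.get(kmer)

    @property
    def n_entries(self) -> int:
        return sum(len(r) for r in self.store.values())


@dataclass
class Lcg:
    """Numerical-Recipes linear congruential generator.

    A fixed seed makes the candidate selection deterministic, which the
    decoder must replay exactly.
    """

    seed: int = 1
    multiplier: int = 1664525
    increment: int = 1013904223
    modulus: int = 1 << 32
    state: int = field(init=False)

    def __post_init__(self) -> None:
        self.state = self.seed % self.modulus

    def next(self) -> int:
        self.state = (self.multiplier * self.state + self.increment) % self.modulus
        return self.state


def rm_predict(
    model: RepeatModel, lut: HitLookupTable, predicted_symbol: int
) -> tuple[float, ...]:
    """Distribution putting P(hit) on the copied symbol, the rest uniform."""
    if not model.active:
        raise RuntimeError("stopped repeat model queried for a prediction")
    ph, po = lut.get(model.nh, model.nm)
    dist = [po] * lut.alphabet_size
    dist[predicted_symbol] = ph
    return tuple(dist)


def rm_update(model: RepeatModel, cfg: RmConfig, was_hit: bool) -> None:
    """Record the outcome, advance the pointer, run the stop filter."""
    if was_hit:
        model.nh += 1
        x = 0.0
    else:
        model.nm += 1
        x = 1.0
    model.pointer += 1
    model.y = x + cfg.beta * model.y
    if model.y > cfg.limit:
        model.active = False


def rm_try_start(
    table: CacheTable, lcg: Lcg, kmer: int, current_pos: int
) -> RepeatModel | None:
    """Start a copy model from a cached past occurrence of ``kmer``.

    The ring entry is chosen pseudo-randomly (LCG modulo ring length); the
    new pointer is the position right after the chosen past occurrence.
    Returns None when the k-mer has never been cached.
    """
    ring = table.positions(kmer)
    if not ring:
        return None
    sel = ring[lcg.next() % len(ring)]
    return RepeatModel(pointer=sel + 1)
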