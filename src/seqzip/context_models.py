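"""Order-k finite-context models and substitution-tolerant context models.

An order-k FCM keeps per-context symbol counts and predicts the next symbol
with the smoothed estimator

    P(s | ctx) = (n_s + alpha) / (sum_s' n_s' + |Sigma| * alpha),

the standard Laplace/Krichevsky-Trofimov family used throughout the DNA
compression literature (alpha=1 behaves well at low orders, alpha=1/16 at
deep orders where contexts are sparse).

A substitution-tolerant context model (STCM) shares the count table of a
paired FCM but propagates its *own most probable symbol* into its context
whenever the true symbol mismatches, tolerating up to ``t`` substitutions
before resetting to the true history.  This lets a deep context survive the
isolated substitutions that dominate divergence between genomic repeats.

Counters are 8-bit with halve-on-saturation (all four counters of a context
are floor-halved when one reaches 255), which bounds memory and makes the
model mildly adaptive.  When ``4**k`` exceeds the configured table budget
the context is mapped by a fixed multiplicative hash into a power-of-two
table; collisions share counts silently.  The hash degenerates to the
identity whenever the exact table fits, so hashed and direct storage agree
in that regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FcmConfig", "Fcm", "Stcm", "COMPLEMENT"]

COUNTER_WIDTH = 255
# Fixed odd multiplier (64-bit golden-ratio constant) for context hashing.
_HASH_MULT = 0x9E3779B97F4A7C15
_MASK64 = (1 << 64) - 1

COMPLEMENT = (3, 2, 1, 0)  # A<->T, C<->G on the 2-bit alphabet


@dataclass(frozen=True)
class FcmConfig:
    """Parameters of one finite-context model.

    k: context order (number of conditioning symbols).
    alpha: estimator smoothing; defaults to 1 for k < 10 and 1/16 above,
        where deep contexts are sparse and need sharper estimates.
    inverted_repeats: also accumulate counts for the reverse-complemented
        context/symbol pairs, modelling DNA inverted repeats.
    max_table_entries: context-table budget; above it the table is hashed.
    """

    k: int
    alpha: float = -1.0  # sentinel: resolve by order
    inverted_repeats: bool = False
    max_table_entries: int = 1 << 24
    alphabet_size: int = 4

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("context order k must be >= 0")
        if self.alpha == -1.0:
            object.__setattr__(self, "alpha", 1.0 if self.k < 10 else 1.0 / 16.0)
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.inverted_repeats and self.alphabet_size != 4:
            raise ValueError("inverted repeats need the 4-symbol DNA alphabet")

    @property
    def n_contexts(self) -> int:
        return self.alphabet_size**self.k

    @property
    def table_entries(self) -> int:
        """Rows actually allocated (power of two when hashed)."""
        if self.n_contexts <= self.max_table_entries:
            return self.n_contexts
        size = 1
        while size * 2 <= self.max_table_entries:
            size *= 2
        return size

    @property
    def hashed(self) -> bool:
        return self.n_contexts > self.max_table_entries


class Fcm:
    """A finite-context model: count table plus rolling context state."""

    def __init__(self, cfg: FcmConfig):
        self.cfg = cfg
        a = cfg.alphabet_size
        self._a = a
        self._alpha = cfg.alpha
        self._alpha_tot = cfg.alpha * a
        self._k = cfg.k
        self._ctx_mod = a**cfg.k
        self.table = np.zeros((cfg.table_entries, a), dtype=np.uint8)
        self.ctx = 0  # rolling context, implicit 'A' (index 0) padding
        if cfg.hashed:
            self._shift = 64 - cfg.table_entries.bit_length() + 1
        else:
            self._shift = None
        if cfg.inverted_repeats:
            # Context of the reverse-complement strand; 'A' padding there
            # reads as all-T.
            self._ir_ctx = self._ctx_mod - 1
            self._ir_top = a ** (cfg.k - 1) if cfg.k > 0 else 0

    # -- context bookkeeping -------------------------------------------------

    def _row(self, ctx: int) -> int:
        if self._shift is None:
            return ctx
        return ((ctx * _HASH_MULT) & _MASK64) >> self._shift

    def reset_context(self) -> None:
        self.ctx = 0
        if self.cfg.inverted_repeats:
            self._ir_ctx = self._ctx_mod - 1

    # -- prediction ----------------------------------------------------------

    def predict(self, ctx: int | None = None) -> tuple[float, ...]:
        """Smoothed distribution over the alphabet given ``ctx`` (default:
        the model's rolling context)."""
        row = self.table[self._row(self.ctx if ctx is None else ctx)]
        counts = row.tolist()
        tot = sum(counts) + self._alpha_tot
        alpha = self._alpha
        return tuple((c + alpha) / tot for c in counts)

    def argmax(self, ctx: int | None = None) -> int:
        """Most probable next symbol (lowest index wins ties)."""
        counts = self.table[self._row(self.ctx if ctx is None else ctx)].tolist()
        return counts.index(max(counts))

    # -- update --------------------------------------------------------------

    def _bump(self, ctx: int, symbol: int) -> None:
        row = self._row(ctx)
        tab = self.table
        c = int(tab[row, symbol]) + 1
        if c >= COUNTER_WIDTH:
            tab[row] >>= 1
            tab[row, symbol] = c >> 1
        else:
            tab[row, symbol] = c

    def update(self, symbol: int) -> None:
        """Record ``symbol`` in the current context and shift the context."""
        self._bump(self.ctx, symbol)
        if self.cfg.inverted_repeats and self._k > 0:
            ir = self._ir_ctx
            # The IR event: context = reverse complement of (window minus its
            # oldest symbol) + comp(new symbol); symbol = complement of the
            # symbol falling out of the window.
            ir_new = (ir // self._a) + COMPLEMENT[symbol] * self._ir_top
            self._bump(ir_new, ir % self._a)
            self._ir_ctx = ir_new
        self.ctx = (self.ctx * self._a + symbol) % self._ctx_mod

    def shift_only(self, symbol: int) -> None:
        """Advance the rolling context without recording counts."""
        self.ctx = (self.ctx * self._a + symbol) % self._ctx_mod

    @property
    def memory_entries(self) -> int:
        return self.cfg.table_entries * self._a


class Stcm:
    """Substitution-tolerant context model over a paired FCM's counts.

    The STCM never writes to the shared table (its paired FCM does); it only
    maintains the tolerant context.  On a mismatch between the true symbol
    and the model's argmax, the argmax is propagated into the context and
    the substitution counter increments; a match decays the counter (floor
    0).  Exceeding the allowance ``t`` resets the context to the true
    history.
    """

    def __init__(self, base: Fcm, t: int):
        if t < 0:
            raise ValueError("substitution allowance t must be >= 0")
        self.base = base
        self.t = t
        self.substitutions_seen = 0
        self.active = True
        self.ctx = 0  # tolerant context
        self._true_ctx = 0  # mirror of the true history
        self._a = base._a
        self._mod = base._ctx_mod

    def predict(self) -> tuple[float, ...]:
        if not self.active:
            raise RuntimeError("inactive STCM queried")
        return self.base.predict(self.ctx)

    def update(self, true_symbol: int) -> None:
        """Advance the tolerant context given the observed symbol."""
        guess = self.base.argmax(self.ctx)
        a, mod = self._a, self._mod
        self._true_ctx = (self._true_ctx * a + true_symbol) % mod
        if true_symbol == guess:
            if self.substitutions_seen > 0:
                self.substitutions_seen -= 1
            self.ctx = (self.ctx * a + true_symbol) % mod
        else:
            self.substitutions_seen += 1
            if self.substitutions_seen > self.t:
                self.ctx = self._true_ctx
                self.substitutions_seen = 0
            else:
                self.ctx = (self.ctx * a + guess) % mod
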