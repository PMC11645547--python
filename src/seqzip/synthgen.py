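"""Deterministic synthetic DNA with known statistical structure.

Every fixture the test-suite and the analysis examples use is generated
here, reproducibly from a spec + seed, together with ground-truth metadata
(analytic entropy rates where a closed form exists, exact repeat
coordinates and applied substitutions).  Kinds:

* ``iid`` — uniform i.i.d. symbols; entropy rate log2 4 = 2 bits/base.
* ``markov`` — an order-m chain with a Dirichlet-sampled transition
  matrix; the analytic entropy rate comes from its stationary
  distribution.
* ``tandem_repeat`` / ``mutated_copy`` — one random unit tiled
  ``copies`` times, substitutions applied to every copy after the first
  at the given per-base rate.
* ``dispersed_repeat`` — i.i.d. background with one unit pasted at
  random, non-overlapping positions.

The RNG is split by purpose (base sequence vs. mutations vs. transition
matrix), so changing the substitution rate never changes the underlying
sequence — stable differential fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["GeneratorSpec", "generate", "generate_symbols", "markov_entropy_rate"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

KINDS = ("iid", "markov", "tandem_repeat", "dispersed_repeat", "mutated_copy")


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic fixture."""

    kind: str
    n: int = 0  # total length (iid/markov/dispersed); derived for repeats
    order: int = 1  # Markov order
    dirichlet: float = 0.3  # concentration of the sampled transition rows
    unit_length: int = 1000
    copies: int = 200
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.kind in ("iid", "markov", "dispersed_repeat") and self.n < 1:
            raise ValueError(f"kind {self.kind!r} needs n >= 1")
        if self.kind in ("tandem_repeat", "mutated_copy") and (
            self.unit_length < 1 or self.copies < 1
        ):
            raise ValueError("repeat kinds need unit_length >= 1 and copies >= 1")


def _rng(spec: GeneratorSpec, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, purpose]))


def _sample_transitions(spec: GeneratorSpec) -> np.ndarray:
    rng = _rng(spec, 3)
    n_ctx = 4**spec.order
    return rng.dirichlet([spec.dirichlet] * 4, size=n_ctx)


def markov_entropy_rate(transitions: np.ndarray, order: int) -> float:
    """Analytic entropy rate (bits/symbol) of an order-``order`` chain.

    The chain over contexts is lifted to a sparse stochastic matrix and its
    stationary distribution found by power iteration; the rate is the
    stationarily weighted conditional entropy of the rows.
    """
    n_ctx = 4**order
    mod = n_ctx
    pi = np.full(n_ctx, 1.0 / n_ctx)
    succ = np.array([[(c * 4 + s) % mod for s in range(4)] for c in range(n_ctx)])
    for _ in range(400):
        new = np.zeros(n_ctx)
        for s in range(4):
            np.add.at(new, succ[:, s], pi * transitions[:, s])
        if np.abs(new - pi).sum() < 1e-14:
            pi = new
            break
        pi = new
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(transitions > 0, np.log2(np.where(transitions > 0, transitions, 1.0)), 0.0)
    row_h = -(transitions * logs).sum(axis=1)
    return float((pi * row_h).sum())


def _markov_symbols(spec: GeneratorSpec, transitions: np.ndarray) -> np.ndarray:
    rng = _rng(spec, 1)
    cum = np.cumsum(transitions, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(spec.n)
    out = np.empty(spec.n, dtype=np.int64)
    ctx = 0
    mod = 4**spec.order
    cum_list = cum.tolist()
    for i in range(spec.n):
        row = cum_list[ctx]
        x = u[i]
        s = 0
        while row[s] <= x:
            s += 1
        out[i] = s
        ctx = (ctx * 4 + s) % mod
    return out


def _mutate(
    symbols: np.ndarray, start: int, rate: float, rng: np.random.Generator
) -> list[int]:
    """Substitute symbols from ``start`` on at the given rate; returns the
    mutated positions."""
    if rate <= 0 or start >= len(symbols):
        return []
    region = len(symbols) - start
    mask = rng.random(region) < rate
    positions = np.nonzero(mask)[0] + start
    # replacement drawn uniformly from the three other symbols
    offsets = rng.integers(1, 4, size=len(positions))
    symbols[positions] = (symbols[positions] + offsets) % 4
    return positions.tolist()


def generate_symbols(spec: GeneratorSpec) -> tuple[np.ndarray, dict[str, Any]]:
    """Generate the symbol-index array and ground-truth metadata."""
    meta: dict[str, Any] = {"kind": spec.kind, "seed": spec.seed}
    seq_rng = _rng(spec, 1)
    mut_rng = _rng(spec, 2)

    if spec.kind == "iid":
        symbols = seq_rng.integers(0, 4, size=spec.n)
        meta["entropy_rate"] = 2.0
    elif spec.kind == "markov":
        transitions = _sample_transitions(spec)
        symbols = _markov_symbols(spec, transitions)
        meta["order"] = spec.order
        meta["transitions"] = transitions
        meta["entropy_rate"] = markov_entropy_rate(transitions, spec.order)
    elif spec.kind in ("tandem_repeat", "mutated_copy"):
        unit = seq_rng.integers(0, 4, size=spec.unit_length)
        symbols = np.tile(unit, spec.copies)
        subs = _mutate(symbols, spec.unit_length, spec.substitution_rate, mut_rng)
        meta["unit_length"] = spec.unit_length
        meta["copies"] = spec.copies
        meta["repeat_coords"] = [
            (i * spec.unit_length, (i + 1) * spec.unit_length)
            for i in range(spec.copies)
        ]
        meta["substitutions"] = subs
    elif spec.kind == "dispersed_repeat":
        symbols = seq_rng.integers(0, 4, size=spec.n)
        unit = seq_rng.integers(0, 4, size=spec.unit_length)
        coords = []
        # paste copies at evenly spread, jittered, non-overlapping offsets
        copies = min(spec.copies, max(1, spec.n // (2 * spec.unit_length)))
        stride = spec.n // copies
        for i in range(copies):
            lo = i * stride
            hi = min(lo + stride, spec.n) - spec.unit_length
            if hi <= lo:
                continue
            start = int(seq_rng.integers(lo, hi))
            symbols[start : start + spec.unit_length] = unit
            coords.append((start, start + spec.unit_length))
        subs = []
        for start, end in coords[1:]:
            region = end - start
            mask = mut_rng.random(region) < spec.substitution_rate
            pos = np.nonzero(mask)[0] + start
            offs = mut_rng.integers(1, 4, size=len(pos))
            symbols[pos] = (symbols[pos] + offs) % 4
            subs.extend(pos.tolist())
        meta["repeat_coords"] = coords
        meta["substitutions"] = subs
    else:  # pragma: no cover - guarded by the spec validator
        raise AssertionError

    meta["n"] = int(len(symbols))
    return symbols.astype(np.int64), meta


def to_fasta(symbols: np.ndarray, header: str, width: int = 70) -> bytes:
    """Render a symbol array as wrapped FASTA bytes."""
    arr = _BASES[np.asarray(symbols, dtype=np.int64)]
    seq = arr.tobytes()
    lines = [b">" + header.encode()]
    for i in range(0, len(seq), width):
        lines.append(seq[i : i + width])
    return b"\n".join(lines) + b"\n"


def generate(spec: GeneratorSpec) -> tuple[bytes, dict[str, Any]]:
    """Generate a FASTA fixture plus its ground-truth metadata."""
    symbols, meta = generate_symbols(spec)
    header = f"synthetic kind={spec.kind} n={meta['n']} seed={spec.seed}"
    return to_fasta(symbols, header), meta
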