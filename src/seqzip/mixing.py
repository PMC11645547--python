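"""Soft-blending of model distributions with per-model forgetting factors.

The coding distribution is the convex combination sum_m w_m P_m(s) of the
member models' distributions.  After each symbol, every weight is damped
by its forgetting factor and scaled by how well the model predicted the
observed symbol:

    w_m  <-  w_m^gamma_m * P_m(observed),

then floored (so no model is ever locked out or underflows to zero) and
renormalized.  With gamma = 1 this is exact Bayesian mixture updating
(weights proportional to cumulative likelihood); gamma < 1 forgets the
distant past and lets the mixture switch quickly between models as the
local structure of the sequence changes — the behaviour repeats demand.

The mixer is a plain interface (``blend`` / ``update``); alternative
mixers (e.g. a neural one) can replace it without touching the coder.
"""

from __future__ import annotations

from typing import Sequence

__all__ = ["MixerState", "blend", "update_weights", "PROB_FLOOR"]

WEIGHT_FLOOR = 1e-6
# Every blended symbol probability is kept at or above 2^-16 so the
# 16-bit-quantized arithmetic coder can always represent it.
PROB_FLOOR = 1.0 / 65536.0


class MixerState:
    """Per-model weights and forgetting factors.

    weights: non-negative, sum to 1.
    gammas: forgetting factor per model, in (0, 1].
    """

    __slots__ = ("weights", "gammas", "weight_floor")

    def __init__(
        self,
        n_models: int,
        gammas: Sequence[float] | float = 0.95,
        weight_floor: float = WEIGHT_FLOOR,
    ):
        if n_models < 1:
            raise ValueError("mixer needs at least one model")
        if isinstance(gammas, (int, float)):
            gammas = [float(gammas)] * n_models
        gammas = list(gammas)
        if len(gammas) != n_models:
            raise ValueError("one forgetting factor per model required")
        for g in gammas:
            if not 0 < g <= 1:
                raise ValueError("forgetting factors must lie in (0, 1]")
        self.weights = [1.0 / n_models] * n_models
        self.gammas = gammas
        self.weight_floor = weight_floor


def blend(
    dists: Sequence[Sequence[float]], state: MixerState, floor: float = PROB_FLOOR
) -> tuple[float, ...]:
    """Convex combination of member distributions, floored and renormalized.

    The floor guarantees every symbol stays codable by the finite-precision
    arithmetic coder even if all models agree its probability is ~0.
    """
    w = state.weights
    if len(dists) != len(w):
        raise ValueError(f"{len(dists)} distributions for {len(w)} weights")
    a = len(dists[0])
    out = [0.0] * a
    for wm, dm in zip(w, dists):
        for s in range(a):
            out[s] += wm * dm[s]
    if floor > 0.0:
        out = [p if p > floor else floor for p in out]
    tot = sum(out)
    return tuple(p / tot for p in out)


def update_weights(
    state: MixerState, dists: Sequence[Sequence[float]], observed: int
) -> None:
    """Damp each weight by its forgetting factor and reward its likelihood."""
    w = state.weights
    g = state.gammas
    floor = state.weight_floor
    tot = 0.0
    for m in range(len(w)):
        nw = (w[m] ** g[m]) * dists[m][observed]
        if nw < floor:
            nw = floor
        w[m] = nw
        tot += nw
    inv = 1.0 / tot
    for m in range(len(w)):
        w[m] *= inv
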