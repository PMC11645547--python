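"""Preset model ensembles (compression levels).

Presets fall into three groups mirroring the tool's intended trade-offs:

* **efficient** (levels 1-3): repeat models only, soft-blended with a
  uniform fallback — fast, tiny memory, strong on redundant sequences.
* **optimized** (levels 4-6): finite-context models of several orders plus
  repeat models and a substitution-tolerant model — balanced.
* **maximal** (levels 7-9): large ensembles with deep contexts,
  inverted-repeat counting and several repeat models — best ratios,
  highest cost.

Every parameter of a resolved profile is serialized into the compressed
container, so decompression never depends on the preset table shipped with
a particular version of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

from .context_models import FcmConfig
from .repeat_models import RmConfig

__all__ = ["Profile", "StcmConfig", "resolve_profile", "list_profiles", "DEFAULT_LEVEL"]

DEFAULT_LEVEL = 1

GROUPS = ("efficient", "optimized", "maximal")


@dataclass(frozen=True)
class StcmConfig:
    """A substitution-tolerant model paired (by order k) with an FCM whose
    count table it shares."""

    k: int
    t: int = 3

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("substitution allowance t must be >= 0")


@dataclass(frozen=True)
class Profile:
    """A fully specified model ensemble.

    The mixture always contains one static uniform fallback slot in
    addition to the configured models, so a prediction exists even before
    any repeat model has started.
    """

    name: str
    group: str
    fcm_configs: tuple[FcmConfig, ...] = ()
    stcm_configs: tuple[StcmConfig, ...] = ()
    rm_configs: tuple[RmConfig, ...] = ()
    gamma: float = 0.95
    rm_seed: int = 1
    memory_budget_entries: int = 1 << 33  # count-table + worst-case cache entries

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        fcm_ks = {c.k for c in self.fcm_configs}
        for sc in self.stcm_configs:
            if sc.k not in fcm_ks:
                raise ValueError(
                    f"STCM of order {sc.k} has no FCM of the same order to share "
                    f"a count table with"
                )
        if self.group == "efficient" and self.fcm_configs:
            raise ValueError("efficient-group profiles use repeat models only")
        if not (self.fcm_configs or self.rm_configs):
            raise ValueError("profile must contain at least one model")

    @property
    def n_slots(self) -> int:
        """Mixture slots: uniform fallback + FCMs + STCMs + RM slots."""
        return (
            1
            + len(self.fcm_configs)
            + len(self.stcm_configs)
            + sum(rc.n_models for rc in self.rm_configs)
        )

    def memory_entries(self) -> int:
        """A-priori memory ceiling in table entries (counts + cache slots)."""
        total = 0
        for fc in self.fcm_configs:
            total += fc.table_entries * fc.alphabet_size
        for rc in self.rm_configs:
            total += rc.max_cache_entries
            total += (rc.lut_max + 1) ** 2 * 2
        return total

    def check_memory(self) -> None:
        need = self.memory_entries()
        if need > self.memory_budget_entries:
            raise MemoryError(
                f"profile {self.name!r} needs {need} table entries, over the "
                f"budget of {self.memory_budget_entries}"
            )

    # -- serialization (container round trip) -------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["fcm_configs"] = [asdict(c) for c in self.fcm_configs]
        d["stcm_configs"] = [asdict(c) for c in self.stcm_configs]
        d["rm_configs"] = [asdict(c) for c in self.rm_configs]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Profile":
        d = dict(d)
        d["fcm_configs"] = tuple(FcmConfig(**c) for c in d.get("fcm_configs", ()))
        d["stcm_configs"] = tuple(StcmConfig(**c) for c in d.get("stcm_configs", ()))
        d["rm_configs"] = tuple(RmConfig(**c) for c in d.get("rm_configs", ()))
        return cls(**d)


def _rm(k: int, n: int = 1, c: int = 8) -> RmConfig:
    return RmConfig(k=k, c=c, n_models=n)


_PRESETS: dict[int, Profile] = {
    # -- efficient: repeat models only --------------------------------------
    1: Profile(
        name="level-1",
        group="efficient",
        rm_configs=(_rm(13),),
    ),
    2: Profile(
        name="level-2",
        group="efficient",
        rm_configs=(_rm(13, n=2),),
    ),
    3: Profile(
        name="level-3",
        group="efficient",
        rm_configs=(_rm(11), _rm(13, n=2)),
    ),
    # -- optimized: FCMs + RMs + an STCM ------------------------------------
    4: Profile(
        name="level-4",
        group="optimized",
        fcm_configs=(FcmConfig(k=2), FcmConfig(k=11)),
        rm_configs=(_rm(13),),
    ),
    5: Profile(
        name="level-5",
        group="optimized",
        fcm_configs=(FcmConfig(k=3), FcmConfig(k=8), FcmConfig(k=13)),
        stcm_configs=(StcmConfig(k=13, t=3),),
        rm_configs=(_rm(12), _rm(13)),
    ),
    6: Profile(
        name="level-6",
        group="optimized",
        fcm_configs=(FcmConfig(k=1), FcmConfig(k=4), FcmConfig(k=8), FcmConfig(k=13)),
        stcm_configs=(StcmConfig(k=13, t=3),),
        rm_configs=(_rm(12), _rm(13, n=2)),
    ),
    # -- maximal: deep ensembles, inverted repeats --------------------------
    7: Profile(
        name="level-7",
        group="maximal",
        fcm_configs=(
            FcmConfig(k=1),
            FcmConfig(k=3),
            FcmConfig(k=6),
            FcmConfig(k=9),
            FcmConfig(k=12),
            FcmConfig(k=14),
        ),
        stcm_configs=(StcmConfig(k=12, t=2), StcmConfig(k=14, t=3)),
        rm_configs=(_rm(12), _rm(13, n=2)),
    ),
    8: Profile(
        name="level-8",
        group="maximal",
        fcm_configs=(
            FcmConfig(k=1),
            FcmConfig(k=3),
            FcmConfig(k=6),
            FcmConfig(k=9),
            FcmConfig(k=12, inverted_repeats=True),
            FcmConfig(k=14, inverted_repeats=True),
        ),
        stcm_configs=(StcmConfig(k=12, t=2), StcmConfig(k=14, t=3)),
        rm_configs=(_rm(11), _rm(12), _rm(13, n=2)),
    ),
    9: Profile(
        name="level-9",
        group="maximal",
        fcm_configs=(
            FcmConfig(k=1, inverted_repeats=True),
            FcmConfig(k=2, inverted_repeats=True),
            FcmConfig(k=4, inverted_repeats=True),
            FcmConfig(k=6, inverted_repeats=True),
            FcmConfig(k=8, inverted_repeats=True),
            FcmConfig(k=11, inverted_repeats=True),
            FcmConfig(k=14, inverted_repeats=True),
        ),
        stcm_configs=(StcmConfig(k=11, t=2), StcmConfig(k=14, t=3)),
        rm_configs=(_rm(11), _rm(12), _rm(13), _rm(14)),
    ),
}

_BY_NAME = {p.name: p for p in _PRESETS.values()}


def resolve_profile(selector: int | str) -> Profile:
    """Look up a preset by level number (1-9) or name ("level-5")."""
    if isinstance(selector, str):
        if selector in _BY_NAME:
            return _BY_NAME[selector]
        if selector.isdigit():
            selector = int(selector)
        else:
            raise KeyError(
                f"unknown preset {selector!r}; available: {', '.join(_BY_NAME)}"
            )
    if selector not in _PRESETS:
        raise KeyError(
            f"unknown preset level {selector}; available levels: "
            f"{', '.join(map(str, _PRESETS))}"
        )
    return _PRESETS[selector]


def list_profiles() -> list[Profile]:
    return [_PRESETS[lvl] for lvl in sorted(_PRESETS)]
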