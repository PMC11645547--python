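"""The per-symbol modelling pipeline and whole-file compress/decompress.

Each step over the DNA channel proceeds identically on encoder and
decoder:

1. every mixture slot produces a distribution over {A,C,G,T} — FCMs and
   STCMs from their count tables, each running repeat model from its
   hit/miss estimator (an idle repeat-model slot and the permanent
   fallback slot contribute the uniform distribution);
2. the mixer soft-blends the distributions, the blend is floored and
   quantized to 16-bit frequencies, and the symbol is arithmetic-coded
   (or, in estimation mode, only its code length is recorded);
3. weights update by forgetting-factor-damped likelihood, count models
   record the true symbol, running repeat models log hit/miss and run the
   low-pass stop filter;
4. the position cache is queried (before inserting the current position,
   so a model never points at the symbol being predicted) to start new
   repeat models in free slots, then the current k-mer position is cached.

Because every choice depends only on already-decoded symbols and on
parameters stored in the container header, the decoder replays the exact
encoder trajectory.
"""

from __future__ import annotations

import json
import math
import zlib

from . import seqio
from .coder import (
    ByteModel,
    Container,
    IntegrityError,
    Predictor,
    TOTAL,
    TOTAL_BITS,
    crc_of,
    decode_channel,
    encode_channel,
    quantize,
    read_container,
    write_container,
)
from .context_models import Fcm, Stcm
from .mixing import MixerState, blend, update_weights
from .profiles import Profile, resolve_profile
from .repeat_models import CacheTable, HitLookupTable, Lcg, rm_predict, rm_try_start, rm_update

__all__ = ["Ensemble", "EnsemblePredictor", "compress_bytes", "decompress_bytes", "container_info"]

_UNIFORM4 = (0.25, 0.25, 0.25, 0.25)

_LOG2_TOTAL = float(TOTAL_BITS)

# orders of the side-channel byte models (headers get a deeper context,
# structural channels a short one)
_CHANNEL_ORDERS = {
    "head": 3,
    "plus": 1,
    "qual": 2,
    "exc": 1,
    "case": 1,
    "layout": 1,
}


class Ensemble:
    """All models of a profile plus the mixer, advanced symbol by symbol."""

    def __init__(self, profile: Profile, trace: bool = False):
        profile.check_memory()
        self.profile = profile
        self.fcms = [Fcm(cfg) for cfg in profile.fcm_configs]
        by_k = {f.cfg.k: f for f in self.fcms}
        self.stcms = [Stcm(by_k[sc.k], sc.t) for sc in profile.stcm_configs]
        self.lcg = Lcg(seed=profile.rm_seed)
        self.banks = []  # (cfg, lut, cache, slots, rolling-kmer state)
        for rc in profile.rm_configs:
            lut = HitLookupTable(rc.alphabet_size, rc.lut_max)
            cache = CacheTable(rc.k, rc.c)
            self.banks.append(
                {
                    "cfg": rc,
                    "lut": lut,
                    "cache": cache,
                    "slots": [None] * rc.n_models,
                    "kmer": 0,
                    "kmask": 4**rc.k,
                }
            )
        self.mixer = MixerState(profile.n_slots, profile.gamma)
        self.history: list[int] = []
        self._last_dists: list[tuple[float, ...]] | None = None
        self.trace = trace
        self.trace_crc = 0

    # -- one modelling step --------------------------------------------------

    def predict_freqs(self) -> list[int]:
        """Quantized 16-bit frequencies of the blended distribution."""
        dists: list[tuple[float, ...]] = [_UNIFORM4]
        for f in self.fcms:
            dists.append(f.predict())
        for s in self.stcms:
            dists.append(s.predict())
        hist = self.history
        for bank in self.banks:
            lut = bank["lut"]
            for model in bank["slots"]:
                if model is not None and model.active:
                    dists.append(rm_predict(model, lut, hist[model.pointer]))
                else:
                    dists.append(_UNIFORM4)
        self._last_dists = dists
        freqs = quantize(blend(dists, self.mixer))
        if self.trace:
            self.trace_crc = zlib.crc32(
                b"%d,%d,%d,%d" % tuple(freqs), self.trace_crc
            )
        return freqs

    def advance(self, symbol: int) -> None:
        """Feed the true symbol to mixer, models and the repeat scheduler."""
        dists = self._last_dists
        if dists is None:
            raise RuntimeError("advance() called before predict_freqs()")
        self._last_dists = None
        update_weights(self.mixer, dists, symbol)
        for f in self.fcms:
            f.update(symbol)
        for s in self.stcms:
            s.update(symbol)
        hist = self.history
        hist.append(symbol)
        pos = len(hist) - 1
        for bank in self.banks:
            cfg = bank["cfg"]
            for i, model in enumerate(bank["slots"]):
                if model is not None and model.active:
                    rm_update(model, cfg, hist[model.pointer] == symbol)
                    if not model.active:
                        bank["slots"][i] = None  # slot free for a restart
            kmer = (bank["kmer"] * 4 + symbol) % bank["kmask"]
            bank["kmer"] = kmer
            if pos >= cfg.k - 1:
                cache = bank["cache"]
                # query before inserting the current position: a fresh model
                # must copy strictly already-known symbols
                for i, model in enumerate(bank["slots"]):
                    if model is None:
                        started = rm_try_start(cache, self.lcg, kmer, pos)
                        if started is not None:
                            bank["slots"][i] = started
                        break  # at most one start attempt per bank per step
                cache.insert(kmer, pos)

    # -- estimation mode -----------------------------------------------------

    def code_lengths(self, symbols) -> "list[float]":
        """Per-symbol code length in bits under the quantized blend."""
        out = []
        log2 = math.log2
        for s in symbols:
            freqs = self.predict_freqs()
            out.append(_LOG2_TOTAL - log2(freqs[s]))
            self.advance(s)
        return out

    def total_code_length(self, symbols) -> float:
        log2 = math.log2
        total = 0.0
        for s in symbols:
            freqs = self.predict_freqs()
            total += _LOG2_TOTAL - log2(freqs[s])
            self.advance(s)
        return total


class EnsemblePredictor(Predictor):
    """Coder-facing adapter around :class:`Ensemble`."""

    def __init__(self, ensemble: Ensemble):
        self.ensemble = ensemble

    def freqs(self):
        return self.ensemble.predict_freqs()

    def advance(self, symbol: int) -> None:
        self.ensemble.advance(symbol)


# ---------------------------------------------------------------------------
# side-channel serialization
# ---------------------------------------------------------------------------


def _varints(values) -> bytes:
    buf = bytearray()
    for v in values:
        while True:
            b = v & 0x7F
            v >>= 7
            if v:
                buf.append(b | 0x80)
            else:
                buf.append(b)
                break
    return bytes(buf)


class _VarintReader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def read(self) -> int:
        value = 0
        shift = 0
        while True:
            if self.pos >= len(self.data):
                raise IntegrityError("truncated varint in side channel")
            b = self.data[self.pos]
            self.pos += 1
            value |= (b & 0x7F) << shift
            if not b & 0x80:
                return value
            shift += 7


def _serialize_side_channels(streams: seqio.SplitStreams) -> dict[str, bytes]:
    out: dict[str, bytes] = {}
    out["head"] = "\n".join(streams.headers).encode("latin-1")
    out["plus"] = "\n".join(streams.plus_lines).encode("latin-1")
    out["qual"] = (streams.qualities or "").encode("latin-1")
    exc = bytearray(_varints([len(streams.exceptions)]))
    prev = 0
    for pos, ch in streams.exceptions:
        exc += _varints([pos - prev])
        exc.append(ord(ch))
        prev = pos
    out["exc"] = bytes(exc)
    out["case"] = _varints([len(streams.case_runs)]) + _varints(streams.case_runs)
    layout = bytearray(_varints([len(streams.layouts)]))
    for rec_layout in streams.layouts:
        layout += _varints([len(rec_layout)])
        layout += _varints(rec_layout)
    out["layout"] = bytes(layout)
    return out


def _deserialize_side_channels(
    raw: dict[str, bytes], fmt: str, final_newline: bool
) -> seqio.SplitStreams:
    headers = raw["head"].decode("latin-1").split("\n") if raw["head"] else [""]
    plus_lines = raw["plus"].decode("latin-1").split("\n") if raw["plus"] else [""]
    r = _VarintReader(raw["exc"])
    n_exc = r.read()
    exceptions = []
    prev = 0
    for _ in range(n_exc):
        delta = r.read()
        if r.pos >= len(r.data):
            raise IntegrityError("truncated exception channel")
        ch = chr(r.data[r.pos])
        r.pos += 1
        prev += delta
        exceptions.append((prev, ch))
    r = _VarintReader(raw["case"])
    case_runs = [r.read() for _ in range(r.read())]
    r = _VarintReader(raw["layout"])
    n_records = r.read()
    layouts = []
    for _ in range(n_records):
        m = r.read()
        layouts.append([r.read() for _ in range(m)])
    if n_records == 0:
        headers, plus_lines = [], []
    else:
        # a join of n strings splits back into n parts; pad when headers
        # were uniformly empty
        headers = (headers + [""] * n_records)[:n_records]
        plus_lines = (plus_lines + [""] * n_records)[:n_records]
    qual = raw["qual"].decode("latin-1")
    return seqio.SplitStreams(
        fmt=fmt,
        headers=headers,
        plus_lines=plus_lines,
        layouts=layouts,
        symbols=[],
        exceptions=exceptions,
        case_runs=case_runs,
        qualities=qual if fmt == "fastq" else None,
        final_newline=final_newline,
    )


# ---------------------------------------------------------------------------
# whole-file compression
# ---------------------------------------------------------------------------


def compress_bytes(
    data: bytes,
    profile: Profile | int | str = 1,
    fmt: str = "auto",
    trace: bool = False,
) -> bytes | tuple[bytes, int]:
    """Compress a FASTA/FASTQ/raw file into a self-describing container.

    With ``trace=True`` also returns the CRC of the model-state trajectory
    (the sequence of quantized coding distributions), which the decoder can
    be asked to reproduce.
    """
    if not isinstance(profile, Profile):
        profile = resolve_profile(profile)
    if fmt == "raw":
        records, fmt, final_newline = seqio.read_raw(data)
    else:
        records, fmt, final_newline = seqio.read_records(data, fmt)
    streams = seqio.split_streams(records, fmt, final_newline=final_newline)

    channels: dict[str, tuple[int, bytes]] = {}
    ensemble = Ensemble(profile, trace=trace)
    seq_payload = encode_channel(streams.symbols, EnsemblePredictor(ensemble))
    channels["seq"] = (len(streams.symbols), seq_payload)
    for name, raw in _serialize_side_channels(streams).items():
        payload = encode_channel(raw, ByteModel(_CHANNEL_ORDERS[name])) if raw else b""
        channels[name] = (len(raw), payload)

    meta = {
        "fmt": fmt,
        "final_newline": final_newline,
        "profile": profile.to_dict(),
    }
    container = Container(
        profile_json=json.dumps(meta, separators=(",", ":")),
        original_length=len(data),
        crc32=crc_of(data),
        channels=channels,
    )
    blob = write_container(container)
    if trace:
        return blob, ensemble.trace_crc
    return blob


def decompress_bytes(blob: bytes, trace: bool = False) -> bytes | tuple[bytes, int]:
    """Exact inverse of :func:`compress_bytes`; verifies the stored CRC."""
    container = read_container(blob)
    meta = json.loads(container.profile_json)
    profile = Profile.from_dict(meta["profile"])
    fmt = meta["fmt"]
    final_newline = meta["final_newline"]

    n_sym, seq_payload = container.channels["seq"]
    ensemble = Ensemble(profile, trace=trace)
    symbols = decode_channel(seq_payload, EnsemblePredictor(ensemble), n_sym)

    raw: dict[str, bytes] = {}
    for name in _CHANNEL_ORDERS:
        n, payload = container.channels[name]
        raw[name] = (
            bytes(decode_channel(payload, ByteModel(_CHANNEL_ORDERS[name]), n))
            if n
            else b""
        )
    streams = _deserialize_side_channels(raw, fmt, final_newline)
    streams.symbols = symbols
    data = seqio.merge_streams(streams)
    if crc_of(data) != container.crc32 or len(data) != container.original_length:
        raise IntegrityError(
            "checksum mismatch after decompression: container is corrupt or "
            "was produced by an incompatible build"
        )
    if trace:
        return data, ensemble.trace_crc
    return data


def container_info(blob: bytes) -> dict:
    """Human-readable summary of a container (the `info` CLI verb)."""
    container = read_container(blob)
    meta = json.loads(container.profile_json)
    total = len(blob)
    return {
        "format": meta["fmt"],
        "profile": meta["profile"]["name"],
        "original_bytes": container.original_length,
        "compressed_bytes": total,
        "crc32": f"{container.crc32:08x}",
        "channels": {
            name: {"items": n, "payload_bytes": len(p)}
            for name, (n, p) in container.channels.items()
        },
    }
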