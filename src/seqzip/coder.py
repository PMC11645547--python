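"""Adaptive arithmetic coding and the compressed container format.

The entropy stage is a classic CACM-style arithmetic coder with 32-bit
range registers and pending-bit (underflow) renormalization.  Model
probabilities are quantized identically on both sides to 16-bit cumulative
frequencies (total 2^16, every symbol >= 1), which maps the floating-point
blends to integer ranges deterministically and keeps encoder and decoder
bit-exact across platforms.

The container is a little-endian, length-prefixed, versioned layout:

    magic "SQZ3" | version u8 | profile JSON (varint len + utf-8)
    | original length varint | crc32 u32 | channel count varint
    | channels: name (varint len + utf-8), item count varint,
                payload length varint, payload bytes

Side channels (headers, qualities, exceptions, case mask, line layout) are
coded by small adaptive order-k byte models over the 256-symbol alphabet;
the DNA channel is coded by the full model ensemble (see ``engine``).
"""

from __future__ import annotations

import zlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ArithmeticEncoder",
    "ArithmeticDecoder",
    "quantize",
    "encode_channel",
    "decode_channel",
    "ByteModel",
    "Container",
    "write_container",
    "read_container",
    "FormatVersionError",
    "IntegrityError",
]

MAGIC = b"SQZ3"
VERSION = 1

TOTAL_BITS = 16
TOTAL = 1 << TOTAL_BITS

_HALF = 0x80000000
_QUARTER = 0x40000000
_THREEQ = 0xC0000000
_TOPMASK = 0xFFFFFFFF


class FormatVersionError(ValueError):
    """Bad magic bytes or unsupported container version."""


class IntegrityError(ValueError):
    """Checksum mismatch or structurally corrupt payload."""


# ---------------------------------------------------------------------------
# bit-level arithmetic coder
# ---------------------------------------------------------------------------


class _BitWriter:
    __slots__ = ("buf", "acc", "nbits")

    def __init__(self) -> None:
        self.buf = bytearray()
        self.acc = 0
        self.nbits = 0

    def write(self, bit: int) -> None:
        self.acc = (self.acc << 1) | bit
        self.nbits += 1
        if self.nbits == 8:
            self.buf.append(self.acc)
            self.acc = 0
            self.nbits = 0

    def write_run(self, bit: int, count: int) -> None:
        for _ in range(count):
            self.write(bit)

    def getvalue(self) -> bytes:
        if self.nbits:
            return bytes(self.buf) + bytes([self.acc << (8 - self.nbits)])
        return bytes(self.buf)


class _BitReader:
    """Bit reader that pads with zeros past the end of the payload.

    The arithmetic coder legitimately reads up to one register width past
    the flushed stream; reading further than that indicates a truncated
    payload and raises.
    """

    __slots__ = ("data", "pos", "n", "overrun")

    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0
        self.n = len(data) * 8
        self.overrun = 0

    def read(self) -> int:
        p = self.pos
        if p >= self.n:
            self.overrun += 1
            if self.overrun > 64:
                raise IntegrityError("truncated arithmetic-coded payload")
            return 0
        self.pos = p + 1
        return (self.data[p >> 3] >> (7 - (p & 7))) & 1


class ArithmeticEncoder:
    """CACM-style 32-bit arithmetic encoder with pending-bit carry handling."""

    def __init__(self) -> None:
        self.low = 0
        self.high = _TOPMASK
        self.pending = 0
        self._bits = _BitWriter()

    def encode(self, cum_lo: int, cum_hi: int, total: int = TOTAL) -> None:
        low, high = self.low, self.high
        span = high - low + 1
        high = low + (span * cum_hi) // total - 1
        low = low + (span * cum_lo) // total
        bits = self._bits
        while True:
            if high < _HALF:
                bits.write(0)
                if self.pending:
                    bits.write_run(1, self.pending)
                    self.pending = 0
            elif low >= _HALF:
                bits.write(1)
                if self.pending:
                    bits.write_run(0, self.pending)
                    self.pending = 0
                low -= _HALF
                high -= _HALF
            elif low >= _QUARTER and high < _THREEQ:
                self.pending += 1
                low -= _QUARTER
                high -= _QUARTER
            else:
                break
            low <<= 1
            high = (high << 1) | 1
        self.low, self.high = low, high

    def finish(self) -> bytes:
        self.pending += 1
        bits = self._bits
        if self.low < _QUARTER:
            bits.write(0)
            bits.write_run(1, self.pending)
        else:
            bits.write(1)
            bits.write_run(0, self.pending)
        return bits.getvalue()


class ArithmeticDecoder:
    """Mirror of :class:`ArithmeticEncoder` over a byte payload."""

    def __init__(self, payload: bytes):
        self._bits = _BitReader(payload)
        self.low = 0
        self.high = _TOPMASK
        self.code = 0
        for _ in range(32):
            self.code = (self.code << 1) | self._bits.read()

    def target(self, total: int = TOTAL) -> int:
        """The cumulative-frequency bin the next symbol falls in."""
        span = self.high - self.low + 1
        return ((self.code - self.low + 1) * total - 1) // span

    def consume(self, cum_lo: int, cum_hi: int, total: int = TOTAL) -> None:
        low, high = self.low, self.high
        span = high - low + 1
        high = low + (span * cum_hi) // total - 1
        low = low + (span * cum_lo) // total
        code = self.code
        bits = self._bits
        while True:
            if high < _HALF:
                pass
            elif low >= _HALF:
                low -= _HALF
                high -= _HALF
                code -= _HALF
            elif low >= _QUARTER and high < _THREEQ:
                low -= _QUARTER
                high -= _QUARTER
                code -= _QUARTER
            else:
                break
            low <<= 1
            high = (high << 1) | 1
            code = (code << 1) | bits.read()
        self.low, self.high, self.code = low, high, code


# ---------------------------------------------------------------------------
# probability quantization
# ---------------------------------------------------------------------------


def quantize(dist: Sequence[float], total: int = TOTAL) -> list[int]:
    """Map a probability vector to integer frequencies summing to ``total``.

    Every symbol receives at least 1 so it stays codable.  The remainder
    after flooring is assigned by largest fractional part, ties broken by
    the lower symbol index — fully deterministic, so encoder and decoder
    derive identical tables from identical floats.
    """
    a = len(dist)
    scale = total - a
    freqs = []
    rems = []
    acc = 0
    for i, p in enumerate(dist):
        x = p * scale
        f = int(x)
        freqs.append(1 + f)
        rems.append((-(x - f), i))
        acc += 1 + f
    short = total - acc
    if short:
        rems.sort()
        for j in range(short):
            freqs[rems[j][1]] += 1
    return freqs


def quantize256(counts: np.ndarray, alpha: float, total: int = TOTAL) -> np.ndarray:
    """Vectorized quantization of a 256-ary count-based distribution."""
    a = counts.shape[0]
    tot = counts.sum() + alpha * a
    x = (counts + alpha) * ((total - a) / tot)
    f = x.astype(np.int64)
    freqs = f + 1
    short = total - int(freqs.sum())
    if short:
        rem = x - f
        order = np.argsort(-rem, kind="stable")
        freqs[order[:short]] += 1
    return freqs


# ---------------------------------------------------------------------------
# generic channel coding with a predictor
# ---------------------------------------------------------------------------


def encode_channel(
    symbols: Sequence[int],
    predictor: "Predictor",
) -> bytes:
    """Arithmetic-code a symbol stream under an adaptive predictor.

    The predictor yields quantized frequency tables; it is advanced exactly
    once per symbol with the true symbol, mirroring the decoder.
    """
    enc = ArithmeticEncoder()
    for s in symbols:
        freqs = predictor.freqs()
        if isinstance(freqs, np.ndarray):
            cum = np.cumsum(freqs)
            lo = int(cum[s - 1]) if s else 0
            hi = int(cum[s])
        else:
            lo = 0
            for i in range(s):
                lo += freqs[i]
            hi = lo + freqs[s]
        enc.encode(lo, hi)
        predictor.advance(s)
    return enc.finish()


def decode_channel(payload: bytes, predictor: "Predictor", n: int) -> list[int]:
    """Inverse of :func:`encode_channel` given the same predictor state."""
    if n == 0:
        return []
    dec = ArithmeticDecoder(payload)
    out = []
    for _ in range(n):
        freqs = predictor.freqs()
        t = dec.target()
        if isinstance(freqs, np.ndarray):
            cum = np.cumsum(freqs)
            s = int(np.searchsorted(cum, t, side="right"))
            lo = int(cum[s - 1]) if s else 0
            hi = int(cum[s])
        else:
            lo = 0
            s = 0
            while lo + freqs[s] <= t:
                lo += freqs[s]
                s += 1
            hi = lo + freqs[s]
        dec.consume(lo, hi)
        predictor.advance(s)
        out.append(s)
    return out


class Predictor:
    """Interface for adaptive per-symbol predictors used by the coder."""

    def freqs(self) -> Sequence[int]:  # pragma: no cover - interface
        raise NotImplementedError

    def advance(self, symbol: int) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class ByteModel(Predictor):
    """Adaptive order-k byte model for side channels.

    Contexts are stored sparsely (dict of count vectors) so tiny channels
    cost almost nothing; counters are 16-bit with halve-on-saturation.
    """

    def __init__(self, order: int = 1, alpha: float = 1.0):
        self.order = order
        self.alpha = alpha
        self.ctx = 0
        self.mod = 256**order
        self.tables: dict[int, np.ndarray] = {}
        self._zero = np.zeros(256, dtype=np.int64)

    def freqs(self) -> np.ndarray:
        counts = self.tables.get(self.ctx)
        if counts is None:
            counts = self._zero
        return quantize256(counts, self.alpha)

    def advance(self, symbol: int) -> None:
        counts = self.tables.get(self.ctx)
        if counts is None:
            counts = self.tables[self.ctx] = np.zeros(256, dtype=np.int64)
        counts[symbol] += 1
        if counts[symbol] >= 65535:
            counts >>= 1
        self.ctx = (self.ctx * 256 + symbol) % self.mod


def _code_bytes(data: bytes, order: int) -> bytes:
    if not data:
        return b""
    return encode_channel(data, ByteModel(order))


def _decode_bytes(payload: bytes, order: int, n: int) -> bytes:
    return bytes(decode_channel(payload, ByteModel(order), n))


# ---------------------------------------------------------------------------
# varints and container
# ---------------------------------------------------------------------------


def _write_varint(buf: bytearray, value: int) -> None:
    if value < 0:
        raise ValueError("varints are unsigned")
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            buf.append(b | 0x80)
        else:
            buf.append(b)
            return


def _read_varint(data: bytes, pos: int) -> tuple[int, int]:
    shift = 0
    value = 0
    while True:
        if pos >= len(data):
            raise IntegrityError("truncated varint in container")
        b = data[pos]
        pos += 1
        value |= (b & 0x7F) << shift
        if not b & 0x80:
            return value, pos
        shift += 7


class Container:
    """Parsed compressed container: metadata plus named channel payloads."""

    def __init__(
        self,
        profile_json: str,
        original_length: int,
        crc32: int,
        channels: dict[str, tuple[int, bytes]],
    ):
        self.profile_json = profile_json
        self.original_length = original_length
        self.crc32 = crc32
        self.channels = channels  # name -> (item count, payload)


def write_container(container: Container) -> bytes:
    buf = bytearray()
    buf += MAGIC
    buf.append(VERSION)
    pj = container.profile_json.encode("utf-8")
    _write_varint(buf, len(pj))
    buf += pj
    _write_varint(buf, container.original_length)
    buf += container.crc32.to_bytes(4, "little")
    _write_varint(buf, len(container.channels))
    for name, (count, payload) in container.channels.items():
        nb = name.encode("utf-8")
        _write_varint(buf, len(nb))
        buf += nb
        _write_varint(buf, count)
        _write_varint(buf, len(payload))
        buf += payload
    return bytes(buf)


def read_container(data: bytes) -> Container:
    if data[:4] != MAGIC:
        raise FormatVersionError("not a seqzip container (bad magic)")
    if len(data) < 5 or data[4] != VERSION:
        raise FormatVersionError(
            f"unsupported container version {data[4] if len(data) > 4 else '?'}"
        )
    pos = 5
    n, pos = _read_varint(data, pos)
    profile_json = data[pos : pos + n].decode("utf-8")
    pos += n
    original_length, pos = _read_varint(data, pos)
    if pos + 4 > len(data):
        raise IntegrityError("truncated container header")
    crc = int.from_bytes(data[pos : pos + 4], "little")
    pos += 4
    n_channels, pos = _read_varint(data, pos)
    channels: dict[str, tuple[int, bytes]] = {}
    for _ in range(n_channels):
        n, pos = _read_varint(data, pos)
        name = data[pos : pos + n].decode("utf-8")
        pos += n
        count, pos = _read_varint(data, pos)
        plen, pos = _read_varint(data, pos)
        if pos + plen > len(data):
            raise IntegrityError(f"truncated payload for channel {name!r}")
        channels[name] = (count, data[pos : pos + plen])
        pos += plen
    return Container(profile_json, original_length, crc, channels)


def crc_of(data: bytes) -> int:
    return zlib.crc32(data) & 0xFFFFFFFF
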