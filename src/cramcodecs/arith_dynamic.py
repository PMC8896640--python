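"""Byte-wise adaptive arithmetic (range) coder.

Unlike the static-table rANS coder, symbol frequencies here start flat and
adapt as data flows, so no table is stored and non-stationary data codes
well.  The carry-propagating range coder (64-bit low, 32-bit range, byte
output) is the classic LZMA construction.  Models are Order-0 or Order-1;
the optional RLE mode codes each maximal run as one literal plus its extra
run length, the latter through per-symbol adaptive models in 255-continuation
chunks.  The PACK transform from :mod:`~cramcodecs.transforms` can be
applied first.  Streams reuse the :class:`~.stream_io.CodecFlags` framing.
"""

from __future__ import annotations

from .errors import MalformedError, TruncationError
from .stream_io import ByteReader, CodecFlags, write_uint7
from . import transforms

__all__ = ["AdaptiveModel", "RangeEncoder", "RangeDecoder", "arith_encode", "arith_decode"]

_TOP = 1 << 24
_INCREMENT = 16
_RESCALE_AT = 1 << 13


class AdaptiveModel:
    """Adaptive symbol-frequency model over an alphabet of ``n_symbols``.

    All counts start at 1.  After a symbol is coded its count grows by 16;
    when the total reaches 2**13 every count is halved (floored at 1), which
    bounds coder precision loss and keeps the model responsive to drift.
    Encoder and decoder apply identical updates, so their models never
    diverge.
    """

    __slots__ = ("freq", "total")

    def __init__(self, n_symbols: int):
        if not 1 <= n_symbols <= 256:
            raise ValueError(f"alphabet size must be 1..256, got {n_symbols}")
        self.freq = [1] * n_symbols
        self.total = n_symbols

    def _update(self, s: int) -> None:
        self.freq[s] += _INCREMENT
        self.total += _INCREMENT
        if self.total >= _RESCALE_AT:
            total = 0
            freq = self.freq
            for i in range(len(freq)):
                f = freq[i] >> 1
                if f == 0:
                    f = 1
                freq[i] = f
                total += f
            self.total = total

    def encode(self, rc: "RangeEncoder", s: int) -> None:
        start = sum(self.freq[:s])
        rc.encode(start, self.freq[s], self.total)
        self._update(s)

    def decode(self, rc: "RangeDecoder") -> int:
        target = rc.get_freq(self.total)
        start = 0
        for s, f in enumerate(self.freq):
            if start + f > target:
                rc.decode(start, f, self.total)
                self._update(s)
                return s
            start += f
        raise MalformedError("range-coder target beyond model total")


class RangeEncoder:
    """Carry-propagating byte-oriented range encoder (LZMA style)."""

    def __init__(self) -> None:
        self.low = 0
        self.range = 0xFFFFFFFF
        self.cache = 0
        self.cache_size = 1
        self.out = bytearray()

    def _shift_low(self) -> None:
        low = self.low
        if low < 0xFF000000 or low > 0xFFFFFFFF:
            carry = low >> 32
            temp = self.cache
            while True:
                self.out.append((temp + carry) & 0xFF)
                temp = 0xFF
                self.cache_size -= 1
                if self.cache_size == 0:
                    break
            self.cache = (low >> 24) & 0xFF
        self.cache_size += 1
        self.low = (low << 8) & 0xFFFFFFFF

    def encode(self, start: int, size: int, total: int) -> None:
        r = self.range // total
        self.low += r * start
        self.range = r * size
        while self.range < _TOP:
            self.range <<= 8
            self._shift_low()

    def finish(self) -> bytes:
        for _ in range(5):
            self._shift_low()
        return bytes(self.out)


class RangeDecoder:
    """Mirror of :class:`RangeEncoder`; reads past-the-end bytes as zero."""

    def __init__(self, buf: bytes):
        self.buf = buf
        self.pos = 0
        self.range = 0xFFFFFFFF
        self.code = 0
        for _ in range(5):
            self.code = ((self.code << 8) | self._byte()) & 0xFFFFFFFFFF
        self.code &= 0xFFFFFFFF

    def _byte(self) -> int:
        b = self.buf[self.pos] if self.pos < len(self.buf) else 0
        self.pos += 1
        return b

    def get_freq(self, total: int) -> int:
        r = self.range // total
        v = self.code // r
        return total - 1 if v >= total else v

    def decode(self, start: int, size: int, total: int) -> None:
        r = self.range // total
        self.code -= r * start
        self.range = r * size
        if self.code < 0:
            raise MalformedError("range-coder state underflow")
        while self.range < _TOP:
            self.range <<= 8
            self.code = ((self.code << 8) | self._byte()) & 0xFFFFFFFF


def _code_literals(work: bytes, order: int, rle: bool) -> bytes:
    rc = RangeEncoder()
    lit_models: dict[int, AdaptiveModel] = {}

    def model(ctx: int) -> AdaptiveModel:
        m = lit_models.get(ctx)
        if m is None:
            m = lit_models[ctx] = AdaptiveModel(256)
        return m

    if rle:
        run_models: dict[int, AdaptiveModel] = {}
        i = 0
        prev = 0
        n = len(work)
        while i < n:
            s = work[i]
            j = i + 1
            while j < n and work[j] == s:
                j += 1
            model(prev if order else 0).encode(rc, s)
            rm = run_models.get(s)
            if rm is None:
                rm = run_models[s] = AdaptiveModel(256)
            extra = j - i - 1
            while extra >= 255:
                rm.encode(rc, 255)
                extra -= 255
            rm.encode(rc, extra)
            prev = s
            i = j
    else:
        prev = 0
        for s in work:
            model(prev if order else 0).encode(rc, s)
            prev = s
    return rc.finish()


def _decode_literals(payload: bytes, n: int, order: int, rle: bool) -> bytes:
    rc = RangeDecoder(payload)
    lit_models: dict[int, AdaptiveModel] = {}

    def model(ctx: int) -> AdaptiveModel:
        m = lit_models.get(ctx)
        if m is None:
            m = lit_models[ctx] = AdaptiveModel(256)
        return m

    out = bytearray()
    if rle:
        run_models: dict[int, AdaptiveModel] = {}
        prev = 0
        while len(out) < n:
            s = model(prev if order else 0).decode(rc)
            rm = run_models.get(s)
            if rm is None:
                rm = run_models[s] = AdaptiveModel(256)
            extra = 0
            while True:
                chunk = rm.decode(rc)
                extra += chunk
                if chunk < 255:
                    break
            out.extend([s] * (extra + 1))
            prev = s
        if len(out) != n:
            raise MalformedError("RLE run overruns the declared length")
    else:
        prev = 0
        for _ in range(n):
            s = model(prev if order else 0).decode(rc)
            out.append(s)
            prev = s
    return bytes(out)


def arith_encode(data: bytes, order: int = 0, rle: bool = False, pack: bool = False) -> bytes:
    """Compress ``data`` with the adaptive coder into a self-describing block.

    Layout: flags byte, uncompressed length (uint7), PACK metadata when the
    transform is applied, then the range-coded payload prefixed with its own
    byte length.
    """
    flags = CodecFlags(order=order, rle=rle, pack=pack)
    out = bytearray([flags.to_byte()])
    out += write_uint7(len(data))
    if not data:
        return bytes(out)
    work = data
    if pack:
        work, pmeta = transforms.pack(work)
        out.append(pmeta.n_symbols)
        out += pmeta.symbol_table
    payload = _code_literals(work, order, rle)
    out += write_uint7(len(payload))
    out += payload
    return bytes(out)


def arith_decode(stream: bytes) -> bytes:
    """Inverse of :func:`arith_encode`."""
    r = ByteReader(stream)
    flags = CodecFlags.from_byte(r.byte())
    length = r.uint7()
    if length == 0:
        return b""
    pmeta = None
    if flags.pack:
        n_sym = r.byte()
        if n_sym < 1 or n_sym > 16:
            raise MalformedError(f"PACK symbol count {n_sym} outside 1..16")
        table = bytes(r.take(n_sym))
        pmeta = transforms.PackMeta(table, transforms._width_for(n_sym), length)
    n_work = pmeta.payload_length() if pmeta else length
    payload_len = r.uint7()
    if payload_len > r.remaining():
        raise TruncationError("arith payload shorter than its declared length")
    payload = bytes(r.take(payload_len))
    work = _decode_literals(payload, n_work, flags.order, flags.rle)
    if pmeta:
        if pmeta.width_bits == 0:
            work = pmeta.symbol_table * length
        else:
            work = transforms.unpack(work, pmeta)
    if len(work) != length:
        raise MalformedError("arith container length mismatch")
    return work
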