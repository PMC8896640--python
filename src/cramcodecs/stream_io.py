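"""Byte-stream primitives shared by all codecs.

Two things live here: a variable-length unsigned integer ("uint7": 7 data
bits per byte, most-significant group first, continuation bit 0x80) used
throughout the container framing, and the one-byte flag field that makes
every compressed block self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import MalformedError, TruncationError

__all__ = [
    "write_uint7",
    "read_uint7",
    "CodecFlags",
    "ByteReader",
]

_UINT7_MAX = 2**32 - 1


def write_uint7(value: int) -> bytes:
    """Encode ``value`` (0 <= value < 2**32) as a 1-5 byte varint.

    Seven data bits per byte, most-significant group first; the 0x80
    continuation bit is set on every byte except the last.  The encoding is
    minimal-length, so it sorts lexicographically in value order.
    """
    if not isinstance(value, int) or isinstance(value, bool):
        raise TypeError(f"uint7 value must be an int, got {type(value).__name__}")
    if value < 0 or value > _UINT7_MAX:
        raise ValueError(f"uint7 value out of range [0, 2^32): {value}")
    out = bytearray([value & 0x7F])
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    out.reverse()
    return bytes(out)


def read_uint7(stream: bytes, pos: int = 0) -> tuple[int, int]:
    """Decode a uint7 starting at ``pos``; return ``(value, bytes_consumed)``.

    Raises :class:`TruncationError` if the stream ends with the continuation
    bit still set, and :class:`MalformedError` if more than 5 bytes carry a
    continuation bit (no valid value needs them).
    """
    value = 0
    n = 0
    while True:
        if pos + n >= len(stream):
            raise TruncationError("uint7: stream ended inside a varint")
        b = stream[pos + n]
        value = (value << 7) | (b & 0x7F)
        n += 1
        if not b & 0x80:
            break
        if n >= 5:
            raise MalformedError("uint7: continuation bit set beyond 5 bytes")
    if value > _UINT7_MAX:
        raise MalformedError(f"uint7: decoded value {value} exceeds 2^32-1")
    return value, n


# Bit positions of the container flag byte.  Bit 1 is reserved (always 0) so
# the dialect can grow without breaking old decoders.
_ORDER_BIT = 1 << 0
_RESERVED_BIT = 1 << 1
_X32_BIT = 1 << 2
_STRIPE_BIT = 1 << 3
_NOSZ_BIT = 1 << 4
_CAT_BIT = 1 << 5
_RLE_BIT = 1 << 6
_PACK_BIT = 1 << 7


@dataclass(frozen=True)
class CodecFlags:
    """The one-byte self-description prefix of every compressed container.

    order
        0 or 1: context order of the entropy model.
    x32
        use 32 interleaved rANS states instead of 4.
    stripe
        de-interleave into N sub-streams before compressing each.
    no_size
        the uncompressed length is not stored (caller must supply it).
    cat
        data stored uncompressed ("concatenate"); excludes the other modes.
    rle, pack
        apply the run-length / bit-packing transform before entropy coding.
    """

    order: int = 0
    x32: bool = False
    stripe: bool = False
    no_size: bool = False
    cat: bool = False
    rle: bool = False
    pack: bool = False

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError(f"order must be 0 or 1, got {self.order}")
        if self.cat and (self.order or self.rle or self.pack or self.x32):
            raise ValueError("cat storage excludes order-1, rle, pack and x32")

    def to_byte(self) -> int:
        b = 0
        if self.order:
            b |= _ORDER_BIT
        if self.x32:
            b |= _X32_BIT
        if self.stripe:
            b |= _STRIPE_BIT
        if self.no_size:
            b |= _NOSZ_BIT
        if self.cat:
            b |= _CAT_BIT
        if self.rle:
            b |= _RLE_BIT
        if self.pack:
            b |= _PACK_BIT
        return b

    @classmethod
    def from_byte(cls, b: int) -> "CodecFlags":
        from .errors import UnsupportedFormatError

        if b & _RESERVED_BIT:
            raise UnsupportedFormatError("reserved flag bit 1 is set")
        return cls(
            order=b & _ORDER_BIT,
            x32=bool(b & _X32_BIT),
            stripe=bool(b & _STRIPE_BIT),
            no_size=bool(b & _NOSZ_BIT),
            cat=bool(b & _CAT_BIT),
            rle=bool(b & _RLE_BIT),
            pack=bool(b & _PACK_BIT),
        )


class ByteReader:
    """Cursor over a byte buffer with truncation-checked reads."""

    __slots__ = ("buf", "pos")

    def __init__(self, buf: bytes, pos: int = 0):
        self.buf = buf
        self.pos = pos

    def byte(self) -> int:
        if self.pos >= len(self.buf):
            raise TruncationError("unexpected end of stream")
        b = self.buf[self.pos]
        self.pos += 1
        return b

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise TruncationError("unexpected end of stream")
        chunk = self.buf[self.pos : self.pos + n]
        self.pos += n
        return chunk

    def uint7(self) -> int:
        value, n = read_uint7(self.buf, self.pos)
        self.pos += n
        return value

    def remaining(self) -> int:
        return len(self.buf) - self.pos
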