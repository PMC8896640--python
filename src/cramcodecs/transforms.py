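"""Reversible pre-entropy data transforms: PACK, RLE and STRIPE.

These reshape a byte stream so that the downstream entropy coder sees
either a denser alphabet (PACK), de-duplicated runs (RLE) or per-lane
streams of fixed-width records (STRIPE).  Each transform is exactly
invertible given its metadata; none of them compresses on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MalformedError, NotPackableError

__all__ = [
    "PackMeta",
    "RleMeta",
    "pack",
    "unpack",
    "select_run_symbols",
    "rle_encode",
    "rle_decode",
    "encode_run_lengths",
    "decode_run_lengths",
    "stripe",
    "unstripe",
]


# ---------------------------------------------------------------------------
# PACK: map a <=16 symbol alphabet onto 0/1/2/4-bit codes packed into bytes.
# ---------------------------------------------------------------------------

def _width_for(n_symbols: int) -> int:
    if n_symbols == 1:
        return 0
    if n_symbols == 2:
        return 1
    if n_symbols <= 4:
        return 2
    if n_symbols <= 16:
        return 4
    raise NotPackableError(f"PACK needs <=16 distinct symbols, got {n_symbols}")


@dataclass(frozen=True)
class PackMeta:
    """Lookup table and geometry needed to reverse a PACK transform."""

    symbol_table: bytes  # distinct byte values, index = packed code
    width_bits: int  # 0, 1, 2 or 4
    original_length: int

    @property
    def n_symbols(self) -> int:
        return len(self.symbol_table)

    def payload_length(self) -> int:
        return (self.original_length * self.width_bits + 7) // 8


def pack(data: bytes) -> tuple[bytes, PackMeta]:
    """Bit-pack ``data`` (<=16 distinct byte values) into codes of 0/1/2/4 bits.

    Codes are placed LSB-first within each payload byte, so with a 2-symbol
    alphabet 8 input values fit per output byte, with <=4 symbols 4 fit, and
    with <=16 symbols 2 fit.  A single-symbol input needs no payload at all.
    """
    if not data:
        raise ValueError("PACK of empty input is undefined")
    table = bytes(sorted(set(data)))
    width = _width_for(len(table))
    meta = PackMeta(table, width, len(data))
    if width == 0:
        return b"", meta
    index = {s: i for i, s in enumerate(table)}
    out = bytearray(meta.payload_length())
    shift = 0
    pos = 0
    acc = 0
    for b in data:
        acc |= index[b] << shift
        shift += width
        if shift == 8:
            out[pos] = acc
            pos += 1
            acc = 0
            shift = 0
    if shift:
        out[pos] = acc
    return bytes(out), meta


def unpack(packed: bytes, meta: PackMeta) -> bytes:
    """Inverse of :func:`pack`."""
    if len(packed) != meta.payload_length():
        raise MalformedError(
            f"PACK payload length {len(packed)} != expected {meta.payload_length()}"
        )
    width = meta.width_bits
    table = meta.symbol_table
    n = meta.original_length
    if width == 0:
        if len(table) != 1:
            raise MalformedError("0-bit PACK requires a 1-entry symbol table")
        return table * n
    mask = (1 << width) - 1
    per_byte = 8 // width
    out = bytearray(n)
    i = 0
    for byte in packed:
        for _ in range(per_byte):
            if i >= n:
                break
            code = byte & mask
            if code >= len(table):
                raise MalformedError(f"PACK code {code} outside symbol table")
            out[i] = table[code]
            byte >>= width
            i += 1
    return bytes(out)


# ---------------------------------------------------------------------------
# RLE, Mespotine variant: a declared symbol set always carries a run length
# (possibly zero); symbols outside the set never do.
# ---------------------------------------------------------------------------

@dataclass
class RleMeta:
    """Literal and run-length streams of a run-length encoded block."""

    run_symbols: frozenset[int]
    literals: bytes
    lengths: list[int] = field(default_factory=list)


def _runs(data: bytes):
    """Yield (symbol, run_length) for each maximal run, left to right."""
    i = 0
    n = len(data)
    while i < n:
        s = data[i]
        j = i + 1
        while j < n and data[j] == s:
            j += 1
        yield s, j - i
        i = j


def _length_cost(extra: int) -> int:
    """Bytes the length stream spends on one run (255-continuation chunks)."""
    return extra // 255 + 1


def select_run_symbols(data: bytes) -> frozenset[int]:
    """Choose the symbols whose runs are worth encoding.

    A symbol enters the run set iff the literal bytes it saves (occurrences
    minus number of runs) exceed the bytes its length entries cost.  Because
    the encoding of one symbol never affects another's accounting, the
    per-symbol rule is globally optimal.
    """
    saved: dict[int, int] = {}
    spent: dict[int, int] = {}
    for s, r in _runs(data):
        saved[s] = saved.get(s, 0) + (r - 1)
        spent[s] = spent.get(s, 0) + _length_cost(r - 1)
    return frozenset(s for s in saved if saved[s] > spent[s])


def rle_encode(data: bytes, run_symbols: frozenset[int] | set[int] | None = None) -> RleMeta:
    """Run-length encode ``data``.

    Every maximal run of a symbol in ``run_symbols`` becomes one literal plus
    one length entry holding the *additional* run length (0 for a lone
    occurrence); runs of other symbols are emitted verbatim.  When
    ``run_symbols`` is None it is chosen by :func:`select_run_symbols`.
    """
    if run_symbols is None:
        run_symbols = select_run_symbols(data)
    run_symbols = frozenset(run_symbols)
    literals = bytearray()
    lengths: list[int] = []
    for s, r in _runs(data):
        if s in run_symbols:
            literals.append(s)
            lengths.append(r - 1)
        else:
            literals.extend([s] * r)
    return RleMeta(run_symbols, bytes(literals), lengths)


def rle_decode(meta: RleMeta) -> bytes:
    """Inverse of :func:`rle_encode`."""
    out = bytearray()
    it = iter(meta.lengths)
    prev_run_sym = -1
    for s in meta.literals:
        if s in meta.run_symbols:
            try:
                extra = next(it)
            except StopIteration:
                raise MalformedError("RLE length stream exhausted early") from None
            out.extend([s] * (extra + 1))
        else:
            out.append(s)
        prev_run_sym = s
    del prev_run_sym
    remaining = sum(1 for _ in it)
    if remaining:
        raise MalformedError(f"RLE length stream has {remaining} unused entries")
    return bytes(out)


def encode_run_lengths(lengths: list[int]) -> bytes:
    """Serialize run lengths as bytes; 255 means 'add 255 and read on'."""
    out = bytearray()
    for n in lengths:
        if n < 0:
            raise ValueError("run length must be non-negative")
        while n >= 255:
            out.append(255)
            n -= 255
        out.append(n)
    return bytes(out)


def decode_run_lengths(raw: bytes) -> list[int]:
    """Inverse of :func:`encode_run_lengths`."""
    lengths: list[int] = []
    acc = 0
    pending = False
    for b in raw:
        if b == 255:
            acc += 255
            pending = True
        else:
            lengths.append(acc + b)
            acc = 0
            pending = False
    if pending:
        raise MalformedError("run-length stream ends inside a 255-chunk")
    return lengths


# ---------------------------------------------------------------------------
# STRIPE: de-interleave into N streams of bytes at positions Nx + c.
# ---------------------------------------------------------------------------

def stripe(data: bytes, n: int) -> list[bytes]:
    """Split ``data`` into ``n`` streams; stream ``c`` holds bytes c, c+n, ..."""
    if n < 1:
        raise ValueError(f"STRIPE needs n >= 1, got {n}")
    return [data[c::n] for c in range(n)]


def unstripe(streams: list[bytes]) -> bytes:
    """Re-interleave the output of :func:`stripe`."""
    n = len(streams)
    if n == 0:
        raise ValueError("unstripe needs at least one stream")
    total = sum(len(s) for s in streams)
    for c, s in enumerate(streams):
        expected = (total - c + n - 1) // n
        if len(s) != expected:
            raise MalformedError(
                f"stripe stream {c} has length {len(s)}, expected {expected}"
            )
    out = bytearray(total)
    for c, s in enumerate(streams):
        out[c::n] = s
    return bytes(out)
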