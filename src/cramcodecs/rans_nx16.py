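"""Static-frequency rANS entropy coder with 16-bit renormalization.

The coder keeps 4 (or optionally 32) interleaved 32-bit states, emitting
16 bits per renormalization step.  Symbol probabilities are static per
block: Order-0 uses one frequency table normalized to 12 bits of
precision, Order-1 one 10-bit table per preceding-symbol context.  rANS is
last-in-first-out, so the encoder walks the input backwards; input byte
``i`` is handled by lane ``i mod n_states`` and, under Order-1, modelled in
the context of byte ``i-1`` (context 0 for each lane's first byte).

The module also provides the container framing that composes the PACK,
RLE and STRIPE transforms (and raw "cat" storage) with entropy coding
into a self-describing block: one :class:`~.stream_io.CodecFlags` byte,
the original length as a varint (unless suppressed), transform metadata,
then the entropy-coded payload.
"""

from __future__ import annotations

from collections import Counter

from .errors import MalformedError, TruncationError
from .stream_io import ByteReader, CodecFlags, write_uint7
from . import transforms

__all__ = [
    "normalize_frequencies",
    "rans_encode",
    "rans_decode",
    "encode_container",
    "decode_container",
    "entropy_parts",
]

RANS_L = 1 << 15  # lower bound of the state interval [L, L << 16)
O0_BITS = 12
O1_BITS = 10


def normalize_frequencies(counts: dict[int, int], precision_bits: int) -> dict[int, int]:
    """Scale raw symbol counts so they sum to exactly ``2**precision_bits``.

    Largest-remainder apportionment: each symbol gets the floor of its exact
    quota, leftovers go to the largest fractional remainders (ties broken by
    ascending symbol value).  Every symbol with a nonzero count keeps a
    frequency of at least 1; the mass this borrows is taken back from the
    most frequent symbols.
    """
    present = sorted(s for s, c in counts.items() if c > 0)
    if not present:
        raise ValueError("cannot normalize an all-zero frequency table")
    total = sum(counts[s] for s in present)
    target = 1 << precision_bits
    if len(present) > target:
        raise ValueError(
            f"{len(present)} symbols cannot share {target} frequency units"
        )
    freq: dict[int, int] = {}
    rems: list[tuple[int, int]] = []
    for s in present:
        q, r = divmod(counts[s] * target, total)
        freq[s] = q
        rems.append((r, s))
    deficit = target - sum(freq.values())
    rems.sort(key=lambda t: (-t[0], t[1]))
    for _, s in rems[:deficit]:
        freq[s] += 1
    for s in present:
        if freq[s] == 0:
            freq[s] = 1
    excess = sum(freq.values()) - target
    while excess > 0:
        # shave the most frequent symbol (ascending value on ties)
        s = min(present, key=lambda t: (-freq[t], t))
        if freq[s] <= 1:
            raise ValueError("cannot satisfy min-frequency constraint")
        freq[s] -= 1
        excess -= 1
    return freq


# ---------------------------------------------------------------------------
# Frequency-table serialization: run-encoded symbol list + uint7 frequencies.
# ---------------------------------------------------------------------------

def _serialize_row(freq: dict[int, int]) -> bytes:
    symbols = sorted(freq)
    runs: list[tuple[int, int]] = []
    for s in symbols:
        if runs and s == runs[-1][0] + runs[-1][1]:
            runs[-1] = (runs[-1][0], runs[-1][1] + 1)
        else:
            runs.append((s, 1))
    out = bytearray(write_uint7(len(runs)))
    for start, length in runs:
        out.append(start)
        out.append(length - 1)
    for s in symbols:
        out += write_uint7(freq[s])
    return bytes(out)


def _read_row(r: ByteReader, precision_bits: int) -> tuple[list[int], list[int], bytearray]:
    """Read one table row; return (freq[256], cum[256], slot->symbol map)."""
    n_runs = r.uint7()
    symbols: list[int] = []
    for _ in range(n_runs):
        start = r.byte()
        length = r.byte() + 1
        if start + length > 256:
            raise MalformedError("frequency-table symbol run exceeds byte range")
        symbols.extend(range(start, start + length))
    if len(set(symbols)) != len(symbols):
        raise MalformedError("frequency-table symbol runs overlap")
    target = 1 << precision_bits
    freq = [0] * 256
    cum = [0] * 256
    cum2sym = bytearray(target)
    c = 0
    for s in symbols:
        f = r.uint7()
        if f < 1 or c + f > target:
            raise MalformedError("frequency table cumulative overflow")
        freq[s] = f
        cum[s] = c
        cum2sym[c : c + f] = bytes([s]) * f
        c += f
    if c != target:
        raise MalformedError(f"frequency table sums to {c}, expected {target}")
    return freq, cum, cum2sym


# ---------------------------------------------------------------------------
# Core coder.
# ---------------------------------------------------------------------------

def _contexts(data: bytes, n_states: int) -> list[int]:
    """Order-1 context of each byte: previous byte, 0 for each lane's first."""
    return [0 if i < n_states else data[i - 1] for i in range(len(data))]


def _row_bits(n_present: int, count: int) -> int:
    """Precision for one Order-1 row, scaled to how often the row is used.

    Rarely-visited contexts get coarse (hence cheap-to-store) frequencies;
    heavily-used rows keep the full 10 bits.  The floor guarantees every
    present symbol can hold a frequency of at least 1.
    """
    floor = max(1, (n_present - 1).bit_length())
    return min(O1_BITS, max(floor, count.bit_length() - 2))


def _entropy_encode(data: bytes, order: int, n_states: int) -> tuple[bytes, bytes, bytes]:
    """Return (frequency table, flushed states, renormalization words)."""
    n = len(data)
    if order == 0:
        freq = normalize_frequencies(Counter(data), O0_BITS)
        cum: dict[int, int] = {}
        c = 0
        for s in sorted(freq):
            cum[s] = c
            c += freq[s]
        table = _serialize_row(freq)
        rows = {0: (freq, cum, O0_BITS)}
        ctxs = None
    else:
        ctxs = _contexts(data, n_states)
        per_ctx: dict[int, Counter] = {}
        for ctx, s in zip(ctxs, data):
            per_ctx.setdefault(ctx, Counter())[s] += 1
        rows = {}
        parts = [write_uint7(len(per_ctx))]
        for ctx in sorted(per_ctx):
            counts = per_ctx[ctx]
            bits = _row_bits(len(counts), sum(counts.values()))
            freq = normalize_frequencies(counts, bits)
            cum = {}
            c = 0
            for s in sorted(freq):
                cum[s] = c
                c += freq[s]
            rows[ctx] = (freq, cum, bits)
            parts.append(bytes([ctx, bits]))
            parts.append(_serialize_row(freq))
        raw_table = b"".join(parts)
        # Order-1 tables grow with the square of the alphabet; storing them
        # through the coder itself keeps the header small on packed data.
        comp = encode_container(raw_table, CodecFlags(order=0))
        if len(comp) < len(raw_table):
            table = b"\x01" + comp
        else:
            table = b"\x00" + raw_table

    states = [RANS_L] * n_states
    words: list[int] = []
    for i in range(n - 1, -1, -1):
        s = data[i]
        ctx = 0 if order == 0 else ctxs[i]
        freq, cum, bits = rows[ctx]
        f = freq[s]
        c = cum[s]
        x = states[i % n_states]
        limit = ((RANS_L >> bits) << 16) * f
        while x >= limit:
            words.append(x & 0xFFFF)
            x >>= 16
        states[i % n_states] = ((x // f) << bits) + (x % f) + c

    state_bytes = b"".join(st.to_bytes(4, "little") for st in states)
    word_bytes = b"".join(w.to_bytes(2, "little") for w in reversed(words))
    return table, state_bytes, word_bytes


def _entropy_decode(r: ByteReader, n: int, order: int, n_states: int) -> bytes:
    rows: dict[int, tuple[list[int], list[int], bytearray, int]] = {}
    if order == 0:
        freq, cum, cum2sym = _read_row(r, O0_BITS)
        rows[0] = (freq, cum, cum2sym, O0_BITS)
    else:
        table_comp = r.byte()
        if table_comp not in (0, 1):
            raise MalformedError("unknown Order-1 table storage mode")
        if table_comp:
            sub = ByteReader(r.buf, r.pos)
            raw_table = _decode_container(sub, None)
            r.pos = sub.pos
            tr = ByteReader(raw_table)
        else:
            tr = r
        n_ctx = tr.uint7()
        for _ in range(n_ctx):
            ctx = tr.byte()
            if ctx in rows:
                raise MalformedError(f"duplicate Order-1 context {ctx}")
            bits = tr.byte()
            if bits < 1 or bits > O1_BITS:
                raise MalformedError(f"Order-1 row precision {bits} outside 1..{O1_BITS}")
            freq, cum, cum2sym = _read_row(tr, bits)
            rows[ctx] = (freq, cum, cum2sym, bits)
        if table_comp and tr.remaining():
            raise MalformedError("trailing bytes in compressed Order-1 table")

    states = []
    for _ in range(n_states):
        states.append(int.from_bytes(r.take(4), "little"))
        if states[-1] < RANS_L:
            raise MalformedError("rANS state underflow in flushed state")

    out = bytearray(n)
    buf = r.buf
    pos = r.pos
    end = len(buf)
    for i in range(n):
        ctx = 0 if (order == 0 or i < n_states) else out[i - 1]
        row = rows.get(ctx)
        if row is None:
            raise MalformedError(f"no frequency row for context {ctx}")
        freq, cum, cum2sym, bits = row
        lane = i % n_states
        x = states[lane]
        slot = x & ((1 << bits) - 1)
        s = cum2sym[slot]
        f = freq[s]
        if f == 0:
            raise MalformedError("decoded symbol with zero frequency")
        out[i] = s
        x = f * (x >> bits) + slot - cum[s]
        while x < RANS_L:
            if pos + 2 > end:
                raise TruncationError("rANS word stream exhausted")
            x = (x << 16) | buf[pos] | (buf[pos + 1] << 8)
            pos += 2
        states[lane] = x
    r.pos = pos
    return bytes(out)


def entropy_parts(data: bytes, order: int = 0, n_states: int = 4) -> dict[str, int]:
    """Sizes (bytes) of the table, state flush and renormalization output.

    Introspection helper for size accounting; the concatenation of the three
    parts is exactly what the container stores after the length varint.
    """
    table, states, words = _entropy_encode(data, order, n_states)
    return {"table": len(table), "states": len(states), "words": len(words)}


# ---------------------------------------------------------------------------
# Container framing.
# ---------------------------------------------------------------------------

def encode_container(data: bytes, flags: CodecFlags, n_stripe: int = 4) -> bytes:
    """Compress ``data`` into a self-describing block.

    Layout: flags byte; original length (uint7, unless ``no_size``); then
    either raw bytes (``cat``), ``n_stripe`` recursively framed
    sub-containers (``stripe``), or transform metadata followed by the
    entropy-coded literal stream.  Transforms compose as PACK then RLE; the
    RLE length stream is itself stored as a nested Order-0 container.
    """
    n_states = 32 if flags.x32 else 4
    out = bytearray([flags.to_byte()])
    if not flags.no_size:
        out += write_uint7(len(data))
    if len(data) == 0:
        return bytes(out)

    if flags.stripe:
        if n_stripe < 1 or n_stripe > 255:
            raise ValueError(f"stripe count must be in 1..255, got {n_stripe}")
        sub_flags = CodecFlags(
            order=flags.order, x32=flags.x32, rle=flags.rle,
            pack=flags.pack, cat=flags.cat,
        )
        subs = [encode_container(s, sub_flags) for s in transforms.stripe(data, n_stripe)]
        out.append(n_stripe)
        for sub in subs:
            out += write_uint7(len(sub))
        for sub in subs:
            out += sub
        return bytes(out)

    if flags.cat:
        out += data
        return bytes(out)

    work = data
    if flags.pack:
        work, pmeta = transforms.pack(work)
        out.append(pmeta.n_symbols)
        out += pmeta.symbol_table
    if flags.rle:
        rmeta = transforms.rle_encode(work)
        run_syms = sorted(rmeta.run_symbols)
        out += write_uint7(len(run_syms))
        out += bytes(run_syms)
        len_bytes = transforms.encode_run_lengths(rmeta.lengths)
        out += encode_container(len_bytes, CodecFlags(order=0))
        work = rmeta.literals

    out += write_uint7(len(work))
    if work:
        table, states, words = _entropy_encode(work, flags.order, n_states)
        out += table
        out += states
        out += words
    return bytes(out)


def _decode_container(r: ByteReader, expected_length: int | None) -> bytes:
    flags = CodecFlags.from_byte(r.byte())
    if flags.no_size:
        if expected_length is None:
            raise ValueError("container has no stored size; expected_length required")
        length = expected_length
    else:
        length = r.uint7()
    if length == 0:
        return b""

    if flags.stripe:
        n = r.byte()
        if n < 1:
            raise MalformedError("stripe container with zero streams")
        sub_lens = [r.uint7() for _ in range(n)]
        streams = []
        for c, sl in enumerate(sub_lens):
            sub = ByteReader(r.take(sl))
            streams.append(_decode_container(sub, None))
            if sub.remaining():
                raise MalformedError(f"stripe sub-container {c} has trailing bytes")
        data = transforms.unstripe(streams)
        if len(data) != length:
            raise MalformedError("striped container length mismatch")
        return data

    if flags.cat:
        return bytes(r.take(length))

    pmeta = None
    if flags.pack:
        n_sym = r.byte()
        if n_sym < 1 or n_sym > 16:
            raise MalformedError(f"PACK symbol count {n_sym} outside 1..16")
        table = bytes(r.take(n_sym))
        pmeta = transforms.PackMeta(table, transforms._width_for(n_sym), length)
    run_syms: frozenset[int] | None = None
    lengths: list[int] | None = None
    if flags.rle:
        n_run = r.uint7()
        if n_run > 256:
            raise MalformedError("RLE run-symbol set larger than the alphabet")
        run_syms = frozenset(r.take(n_run))
        len_bytes = _decode_container(r, None)
        lengths = transforms.decode_run_lengths(len_bytes)

    n_lit = r.uint7()
    n_states = 32 if flags.x32 else 4
    work = _entropy_decode(r, n_lit, flags.order, n_states) if n_lit else b""

    if flags.rle:
        work = transforms.rle_decode(transforms.RleMeta(run_syms, work, lengths))
    if flags.pack:
        work = transforms.unpack(work, pmeta)
    if len(work) != length:
        raise MalformedError(
            f"container decodes to {len(work)} bytes, header says {length}"
        )
    return work


def decode_container(stream: bytes, expected_length: int | None = None) -> bytes:
    """Decompress a block produced by :func:`encode_container`."""
    r = ByteReader(stream)
    return _decode_container(r, expected_length)


def rans_encode(data: bytes, order: int = 0, n_states: int = 4) -> bytes:
    """Entropy-code ``data`` (no transforms): table + payload, self-describing."""
    if n_states not in (4, 32):
        raise ValueError(f"n_states must be 4 or 32, got {n_states}")
    if order == 1 and not data:
        raise ValueError("Order-1 coding of empty input is undefined")
    return encode_container(data, CodecFlags(order=order, x32=(n_states == 32)))


def rans_decode(stream: bytes) -> bytes:
    """Inverse of :func:`rans_encode`."""
    return decode_container(stream)
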