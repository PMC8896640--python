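"""Structure-aware read-name compression.

Sequencing read identifiers such as ``HSQ1004:134:C0D8DACXX:4:2107:20375:180666``
are highly structured: instrument/run/flowcell prefixes repeat verbatim and
trailing tile/x/y coordinates drift slowly between consecutive reads.  The
tokenizer splits each name into typed fragments (alphabetic runs, digit runs
with or without leading zeros, single punctuation characters), then encodes
each fragment relative to the same column of the immediately preceding
name: an exact repeat becomes MATCH, a small non-negative numeric change
becomes a one-byte delta (DDELTA, or DDELTA0 when both numbers carry the
same leading zeros), and anything else falls back to a literal token.
Token types and values are grouped into per-(column, type) streams, each
compressed independently with the rANS or adaptive arithmetic codec.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from . import arith_dynamic, rans_nx16
from .errors import InvalidNameError, MalformedError
from .stream_io import ByteReader, CodecFlags, write_uint7

__all__ = [
    "TokenType",
    "Token",
    "TokenizedName",
    "split_raw",
    "tokenize_name",
    "expand_tokens",
    "encode_names",
    "decode_names",
]

_DIGIT_CHUNK = 10
_U32 = 1 << 32


class TokenType(enum.IntEnum):
    CHAR = 0  # single non-alphanumeric character
    ALPHA = 1  # run of letters
    DIGITS = 2  # digit run without leading zeros, value < 2^32
    DIGITS0 = 3  # digit run with leading zeros (fixed total width)
    MATCH = 4  # identical to the prior name's fragment in this column
    DDELTA = 5  # numeric delta 0..255, no leading zeros on either side
    DDELTA0 = 6  # numeric delta 0..255 with matching leading zeros/width
    NOP = 7  # empty filler keeping token counts aligned
    END = 8  # terminator


_VALUE_TYPES = (
    TokenType.CHAR,
    TokenType.ALPHA,
    TokenType.DIGITS,
    TokenType.DIGITS0,
    TokenType.DDELTA,
    TokenType.DDELTA0,
)


@dataclass(frozen=True)
class Token:
    type: TokenType
    value: str | int | None = None


@dataclass
class TokenizedName:
    """A name as typed tokens plus its expanded fragments (for the next name)."""

    tokens: list[Token]
    fragments: list[str]


def _check_name(name: str) -> None:
    if not name:
        raise InvalidNameError("empty read name")
    for ch in name:
        o = ord(ch)
        if o < 0x20 or o > 0x7E:
            raise InvalidNameError(
                f"read name contains non-printable byte {o:#04x}"
            )


def split_raw(name: str) -> list[str]:
    """Split a name into maximal digit runs, letter runs and single chars.

    Digit runs longer than 10 are chunked left-to-right into pieces of at
    most 10 digits; a 10-digit piece whose value does not fit 32 bits is
    split 5+5 so every numeric fragment stays below 2**32.
    """
    _check_name(name)
    frags: list[str] = []
    i = 0
    n = len(name)
    while i < n:
        ch = name[i]
        if ch.isdigit():
            j = i + 1
            while j < n and name[j].isdigit():
                j += 1
            run = name[i:j]
            while run:
                chunk, run = run[:_DIGIT_CHUNK], run[_DIGIT_CHUNK:]
                if len(chunk) == _DIGIT_CHUNK and int(chunk) >= _U32:
                    frags.append(chunk[:5])
                    frags.append(chunk[5:])
                else:
                    frags.append(chunk)
            i = j
        elif ch.isalpha() and ch.isascii():
            j = i + 1
            while j < n and name[j].isalpha() and name[j].isascii():
                j += 1
            frags.append(name[i:j])
            i = j
        else:
            frags.append(ch)
            i += 1
    return frags


def _leading_zeros(s: str) -> int:
    n = 0
    for ch in s:
        if ch == "0":
            n += 1
        else:
            break
    return n if n < len(s) else len(s) - 1  # "0" itself has no leading zero


def _literal_token(frag: str) -> Token:
    if frag.isdigit():
        if frag[0] == "0" and len(frag) > 1:
            return Token(TokenType.DIGITS0, frag)
        return Token(TokenType.DIGITS, frag)
    if frag.isalpha():
        return Token(TokenType.ALPHA, frag)
    return Token(TokenType.CHAR, frag)


def tokenize_name(name: str, prev: TokenizedName | None = None) -> TokenizedName:
    """Tokenize ``name`` against the previous name's fragments.

    Column ``t`` of the new name is compared with column ``t`` of ``prev``:
    byte-identical fragments become MATCH; numeric fragments whose value
    grew by 0..255 become DDELTA (no leading zeros on either side) or
    DDELTA0 (identical leading-zero count and width); everything else is a
    literal.  If the name has fewer columns than the previous one, NOP
    tokens keep the column count consistent.  The token list always ends
    with END.
    """
    frags = split_raw(name)
    prev_frags = prev.fragments if prev is not None else []
    tokens: list[Token] = []
    for t, frag in enumerate(frags):
        p = prev_frags[t] if t < len(prev_frags) else None
        if p is not None and frag == p:
            tokens.append(Token(TokenType.MATCH))
            continue
        if p is not None and frag.isdigit() and p.isdigit():
            delta = int(frag) - int(p)
            if 0 <= delta <= 255:
                cur_lz = _leading_zeros(frag)
                prev_lz = _leading_zeros(p)
                if cur_lz == 0 and prev_lz == 0:
                    tokens.append(Token(TokenType.DDELTA, delta))
                    continue
                if cur_lz == prev_lz and cur_lz >= 1 and len(frag) == len(p):
                    tokens.append(Token(TokenType.DDELTA0, delta))
                    continue
        tokens.append(_literal_token(frag))
    for _ in range(len(frags), len(prev_frags)):
        tokens.append(Token(TokenType.NOP))
    tokens.append(Token(TokenType.END))
    return TokenizedName(tokens, frags)


def expand_tokens(tokens: list[Token], prev_frags: list[str]) -> list[str]:
    """Regenerate the fragments a token list describes (inverse of tokenizing)."""
    frags: list[str] = []
    for t, tok in enumerate(tokens):
        if tok.type is TokenType.END:
            return frags
        if tok.type is TokenType.NOP:
            continue
        if tok.type is TokenType.MATCH:
            frags.append(prev_frags[t])
        elif tok.type is TokenType.DDELTA:
            frags.append(str(int(prev_frags[t]) + tok.value))
        elif tok.type is TokenType.DDELTA0:
            p = prev_frags[t]
            frags.append(str(int(p) + tok.value).zfill(len(p)))
        else:
            frags.append(tok.value)
    raise MalformedError("token list lacks an END marker")


# ---------------------------------------------------------------------------
# Stream serialization.
# ---------------------------------------------------------------------------

_METHOD_RAW = 0
_METHOD_RANS = 1
_METHOD_ARITH = 2


def _compress_stream(raw: bytes, entropy: str, level: str) -> bytes:
    candidates: list[tuple[int, bytes]] = [(_METHOD_RAW, raw)]
    if raw:
        if entropy == "rans" or level == "max":
            candidates.append((_METHOD_RANS, rans_nx16.rans_encode(raw, 0)))
        if entropy == "arith":
            candidates.append((_METHOD_ARITH, arith_dynamic.arith_encode(raw, 0)))
        if level == "max":
            candidates.append((_METHOD_RANS, rans_nx16.rans_encode(raw, 1)))
            try:
                candidates.append(
                    (
                        _METHOD_RANS,
                        rans_nx16.encode_container(
                            raw, CodecFlags(order=1, pack=True, rle=True)
                        ),
                    )
                )
            except ValueError:
                pass
            candidates.append((_METHOD_ARITH, arith_dynamic.arith_encode(raw, 1)))
            candidates.append(
                (_METHOD_ARITH, arith_dynamic.arith_encode(raw, 1, rle=True))
            )
    method, payload = min(candidates, key=lambda mp: len(mp[1]))
    return bytes([method]) + write_uint7(len(payload)) + payload


def _decompress_stream(r: ByteReader) -> bytes:
    method = r.byte()
    length = r.uint7()
    payload = bytes(r.take(length))
    if method == _METHOD_RAW:
        return payload
    if method == _METHOD_RANS:
        return rans_nx16.decode_container(payload)
    if method == _METHOD_ARITH:
        return arith_dynamic.arith_decode(payload)
    raise MalformedError(f"unknown stream compression method {method}")


def _token_value_bytes(tok: Token) -> bytes:
    t = tok.type
    if t is TokenType.CHAR:
        return bytes([ord(tok.value)])
    if t is TokenType.ALPHA:
        raw = tok.value.encode("ascii")
        return write_uint7(len(raw)) + raw
    if t is TokenType.DIGITS:
        return int(tok.value).to_bytes(4, "little")
    if t is TokenType.DIGITS0:
        return bytes([len(tok.value)]) + int(tok.value).to_bytes(4, "little")
    if t in (TokenType.DDELTA, TokenType.DDELTA0):
        return bytes([tok.value])
    return b""


def encode_names(names: list[str], entropy: str = "rans", level: str = "fast") -> bytes:
    """Tokenize and compress a list of read names (order preserved exactly).

    ``entropy`` selects the per-stream coder family; ``level`` "fast" uses
    Order-0 coding per stream while "max" additionally tries Order-1,
    PACK+RLE and adaptive-arithmetic candidates and keeps the smallest.
    """
    if entropy not in ("rans", "arith"):
        raise ValueError(f"entropy must be 'rans' or 'arith', got {entropy!r}")
    if level not in ("fast", "max"):
        raise ValueError(f"level must be 'fast' or 'max', got {level!r}")
    if not names:
        raise ValueError("encode_names requires at least one name")

    type_streams: dict[int, bytearray] = {}
    value_streams: dict[tuple[int, TokenType], bytearray] = {}
    prev: TokenizedName | None = None
    for name in names:
        tn = tokenize_name(name, prev)
        for col, tok in enumerate(tn.tokens):
            type_streams.setdefault(col, bytearray()).append(int(tok.type))
            if tok.type in _VALUE_TYPES:
                value_streams.setdefault((col, tok.type), bytearray()).extend(
                    _token_value_bytes(tok)
                )
        prev = tn

    out = bytearray(write_uint7(len(names)))
    for col in sorted(type_streams):
        ts = bytes(type_streams[col])
        out += _compress_stream(ts, entropy, level)
        for vt in _VALUE_TYPES:
            if (col, vt) in value_streams:
                out += _compress_stream(bytes(value_streams[(col, vt)]), entropy, level)
    return bytes(out)


def decode_names(stream: bytes) -> list[str]:
    """Inverse of :func:`encode_names`."""
    r = ByteReader(stream)
    n_names = r.uint7()

    type_streams: list[bytes] = []
    value_readers: dict[tuple[int, TokenType], ByteReader] = {}
    active = n_names
    col = 0
    while active > 0:
        ts = _decompress_stream(r)
        if len(ts) != active:
            raise MalformedError(
                f"type stream for column {col} has {len(ts)} entries, expected {active}"
            )
        type_streams.append(ts)
        present = set(ts)
        for vt in _VALUE_TYPES:
            if int(vt) in present:
                value_readers[(col, vt)] = ByteReader(_decompress_stream(r))
        active = sum(1 for t in ts if t != int(TokenType.END))
        col += 1
    n_cols = col

    cursors = [0] * n_cols
    names: list[str] = []
    prev_frags: list[str] = []
    try:
        names = _reconstruct(n_names, n_cols, type_streams, value_readers, cursors)
    except (IndexError, ValueError, UnicodeDecodeError) as exc:
        raise MalformedError(f"corrupt token streams: {exc}") from exc
    return names


def _reconstruct(
    n_names: int,
    n_cols: int,
    type_streams: list[bytes],
    value_readers: dict[tuple[int, TokenType], ByteReader],
    cursors: list[int],
) -> list[str]:
    names: list[str] = []
    prev_frags: list[str] = []
    for _ in range(n_names):
        frags: list[str] = []
        t = 0
        while True:
            if t >= n_cols:
                raise MalformedError("name runs past the last token column")
            ttype = TokenType(type_streams[t][cursors[t]])
            cursors[t] += 1
            if ttype is TokenType.END:
                break
            if ttype is TokenType.NOP:
                t += 1
                continue
            if ttype is TokenType.MATCH:
                frags.append(prev_frags[t])
            elif ttype in (TokenType.DDELTA, TokenType.DDELTA0):
                vr = value_readers[(t, ttype)]
                delta = vr.byte()
                p = prev_frags[t]
                if ttype is TokenType.DDELTA:
                    frags.append(str(int(p) + delta))
                else:
                    frags.append(str(int(p) + delta).zfill(len(p)))
            elif ttype is TokenType.CHAR:
                frags.append(chr(value_readers[(t, ttype)].byte()))
            elif ttype is TokenType.ALPHA:
                vr = value_readers[(t, ttype)]
                ln = vr.uint7()
                frags.append(vr.take(ln).decode("ascii"))
            elif ttype is TokenType.DIGITS:
                vr = value_readers[(t, ttype)]
                frags.append(str(int.from_bytes(vr.take(4), "little")))
            elif ttype is TokenType.DIGITS0:
                vr = value_readers[(t, ttype)]
                width = vr.byte()
                val = int.from_bytes(vr.take(4), "little")
                frags.append(str(val).zfill(width))
            else:
                raise MalformedError(f"unexpected token type {ttype}")
            t += 1
        names.append("".join(frags))
        prev_frags = frags
    return names
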