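"""FQZComp quality-score codec.

Quality values are coded with the adaptive range coder under a context of
at most 16 bits assembled from four ingredients, each passed through a
lookup table into its own bit-field:

* recent quality values, shifted into a rolling accumulator (``qbits`` wide,
  ``qshift`` bits per value, via ``qtab``);
* the position along the read (``pbits``, via ``ptab``);
* a cumulative-difference counter that increments whenever a quality
  differs from its predecessor (``dbits``, via ``dtab``);
* caller-supplied selector bits copied verbatim (``sbits``), used to
  partition records into groups such as read-1 versus read-2.

One adaptive model exists per context value.  Per-record metadata carries
the length, an optional reverse flag (qualities coded right-to-left), a
duplicate flag (quality string equals the previous record's, so only the
flag is stored) and the selector.  The whole model description — bit
widths, field positions and tables — is serialized into the stream, so the
decoder simply follows the encoder's instructions and any parameter choice
remains decodable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .arith_dynamic import AdaptiveModel, RangeDecoder, RangeEncoder
from .errors import MalformedError, TruncationError, UnsupportedAlphabetError
from .stream_io import ByteReader, write_uint7

__all__ = [
    "QualityRecord",
    "FqzParams",
    "FqzState",
    "compute_context",
    "build_params",
    "fqz_encode",
    "fqz_decode",
    "fqz_parts",
    "PRESETS",
]

MAX_SYM = 94  # Phred 0-63 for Illumina; lifted to the 0-93 range for PacBio CLR
POS_CLAMP = 1023
DELTA_CLAMP = 255
PRESETS = ("generic", "small_alphabet", "position_heavy", "selector_read12")


@dataclass(frozen=True)
class QualityRecord:
    """One read's quality string plus the per-record coding metadata."""

    quals: tuple[int, ...]
    reverse: bool = False
    duplicate: bool = False
    selector: int = 0

    def __post_init__(self):
        object.__setattr__(self, "quals", tuple(self.quals))

    @property
    def length(self) -> int:
        return len(self.quals)


@dataclass
class FqzParams:
    """Self-describing context-model parameters (serialized per stream)."""

    max_sym: int
    qbits: int = 0
    qshift: int = 0
    qloc: int = 0
    pbits: int = 0
    ploc: int = 0
    dbits: int = 0
    dloc: int = 0
    sbits: int = 0
    sloc: int = 0
    qtab: list[int] = field(default_factory=list)
    ptab: list[int] = field(default_factory=list)
    dtab: list[int] = field(default_factory=list)
    qmap: list[int] | None = None  # symbol index -> original quality value
    fixed_length: bool = False
    do_dedup: bool = False
    do_reverse: bool = False
    do_selector: bool = False

    @property
    def store_qmap(self) -> bool:
        return self.qmap is not None

    def validate(self) -> None:
        if not 1 <= self.max_sym <= MAX_SYM:
            raise UnsupportedAlphabetError(
                f"max_sym must be 1..{MAX_SYM}, got {self.max_sym}"
            )
        widths = (self.qbits, self.pbits, self.dbits, self.sbits)
        locs = (self.qloc, self.ploc, self.dloc, self.sloc)
        if sum(widths) > 16:
            raise ValueError("context fields exceed 16 bits in total")
        if self.sbits > 8:
            raise ValueError("selector limited to 8 bits")
        used = 0
        for w, loc in zip(widths, locs):
            if w == 0:
                continue
            m = ((1 << w) - 1) << loc
            if m > 0xFFFF:
                raise ValueError("context field extends beyond bit 15")
            if used & m:
                raise ValueError("context bit-fields overlap")
            used |= m
        if len(self.qtab) < self.max_sym:
            raise ValueError("qtab must cover every symbol index")
        for name, tab, w in (
            ("qtab", self.qtab, max(self.qbits, self.qshift)),
            ("ptab", self.ptab, self.pbits),
            ("dtab", self.dtab, self.dbits),
        ):
            for v in tab:
                if v >= (1 << w) and w < 16:
                    raise ValueError(f"{name} entry {v} does not fit {w} bits")
        if self.qmap is not None and len(self.qmap) != self.max_sym:
            raise ValueError("qmap length must equal max_sym")

    def n_contexts(self) -> int:
        return 1 << 16


class FqzState:
    """Rolling per-record coding state (reset at every record start)."""

    __slots__ = ("qctx", "pos", "delta", "prev_q")

    def __init__(self) -> None:
        self.qctx = 0
        self.pos = 0
        self.delta = 0
        self.prev_q = 0

    def update(self, q: int, params: FqzParams) -> None:
        """Advance the state after coding symbol index ``q``."""
        self.qctx = ((self.qctx << params.qshift) + params.qtab[q]) & 0xFFFF
        if self.pos > 0 and q != self.prev_q:
            if self.delta < DELTA_CLAMP:
                self.delta += 1
        self.prev_q = q
        self.pos += 1


def compute_context(state: FqzState, selector: int, params: FqzParams) -> int:
    """Assemble the 16-bit coding context from the current state."""
    ctx = (state.qctx & ((1 << params.qbits) - 1)) << params.qloc
    if params.pbits:
        ctx |= params.ptab[min(state.pos, POS_CLAMP)] << params.ploc
    if params.dbits:
        ctx |= params.dtab[min(state.delta, DELTA_CLAMP)] << params.dloc
    if params.sbits:
        ctx |= (selector & ((1 << params.sbits) - 1)) << params.sloc
    return ctx & 0xFFFF


# ---------------------------------------------------------------------------
# Preset construction.
# ---------------------------------------------------------------------------

def _default_qtab(nvals: int, qshift: int) -> list[int]:
    cap = 1 << qshift
    if nvals <= cap:
        return list(range(nvals))
    return [i * cap // nvals for i in range(nvals)]


def _default_ptab(pbits: int) -> list[int]:
    if pbits == 0:
        return []
    cap = (1 << pbits) - 1
    if pbits >= 7:
        return [min(i, cap) for i in range(POS_CLAMP + 1)]
    shift = 7 - pbits  # buckets of 2^shift cycles over the first 128
    return [min(cap, i >> shift) for i in range(POS_CLAMP + 1)]


def _default_dtab(dbits: int) -> list[int]:
    if dbits == 0:
        return []
    cap = (1 << dbits) - 1
    return [min(cap, i.bit_length()) for i in range(DELTA_CLAMP + 1)]


def build_params(records: Sequence[QualityRecord], preset: str = "generic") -> FqzParams:
    """Derive codec parameters from a sample of records.

    ``generic`` balances history/position/delta bits; ``small_alphabet``
    spends 2 bits per historic quality (NovaSeq-style 4-value data);
    ``position_heavy`` tracks the read cycle exactly for 128 cycles
    (productive when specific cycles are erroneous); ``selector_read12``
    devotes one selector bit to a read-1/read-2 style record split.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if not records:
        raise ValueError("cannot build parameters from an empty sample")
    vals = sorted({q for r in records for q in r.quals})
    if not vals:
        raise ValueError("sample contains no quality values")
    if vals[0] < 0 or vals[-1] > MAX_SYM - 1:
        raise UnsupportedAlphabetError(
            f"quality values must lie in 0..{MAX_SYM - 1}, saw {vals[0]}..{vals[-1]}"
        )
    nvals = len(vals)
    if nvals > MAX_SYM:
        raise UnsupportedAlphabetError(f"{nvals} distinct quality values unsupported")

    sbits = 0
    if preset == "generic":
        qshift = max(1, min(6, (nvals - 1).bit_length()))
        qbits, pbits, dbits = 12, 2, 2
    elif preset == "small_alphabet":
        qshift = 2
        qbits, pbits, dbits = 6, 4, 3
    elif preset == "position_heavy":
        qshift = max(1, min(7, (nvals - 1).bit_length()))
        qbits, pbits, dbits = 7, 7, 2
    else:  # selector_read12
        # deliberately lean context: halving the training data per model by
        # splitting on the selector only pays off when each half still
        # converges within a block
        qshift = max(1, min(3, (nvals - 1).bit_length()))
        qbits, pbits, dbits, sbits = 3, 3, 1, 1

    params = FqzParams(
        max_sym=nvals,
        qbits=qbits,
        qshift=qshift,
        qloc=pbits + dbits,
        pbits=pbits,
        ploc=dbits,
        dbits=dbits,
        dloc=0,
        sbits=sbits,
        sloc=pbits + dbits + qbits,
        qtab=_default_qtab(nvals, qshift),
        ptab=_default_ptab(pbits),
        dtab=_default_dtab(dbits),
        qmap=vals,
        fixed_length=len({r.length for r in records}) == 1,
        do_dedup=any(r.duplicate for r in records),
        do_reverse=any(r.reverse for r in records),
        do_selector=sbits > 0,
    )
    params.validate()
    return params


# ---------------------------------------------------------------------------
# Parameter-block serialization.
# ---------------------------------------------------------------------------

_VERSION = 1


def _write_table(out: bytearray, tab: list[int]) -> None:
    runs: list[tuple[int, int]] = []
    for v in tab:
        if runs and runs[-1][0] == v:
            runs[-1] = (v, runs[-1][1] + 1)
        else:
            runs.append((v, 1))
    out += write_uint7(len(runs))
    for v, n in runs:
        out += write_uint7(v)
        out += write_uint7(n)


def _read_table(r: ByteReader, expected_len: int) -> list[int]:
    n_runs = r.uint7()
    tab: list[int] = []
    for _ in range(n_runs):
        v = r.uint7()
        n = r.uint7()
        tab.extend([v] * n)
    if len(tab) != expected_len:
        raise MalformedError(
            f"lookup table decodes to {len(tab)} entries, expected {expected_len}"
        )
    return tab


def _serialize_params(params: FqzParams) -> bytes:
    out = bytearray([_VERSION])
    fb = (
        (params.fixed_length << 0)
        | (params.do_dedup << 1)
        | (params.do_reverse << 2)
        | (params.do_selector << 3)
        | (params.store_qmap << 4)
    )
    out.append(fb)
    out.append(params.max_sym)
    out += bytes(
        [
            params.qbits,
            params.qshift,
            params.qloc,
            params.pbits,
            params.ploc,
            params.dbits,
            params.dloc,
            params.sbits,
            params.sloc,
        ]
    )
    if params.store_qmap:
        out += bytes(params.qmap)
    _write_table(out, params.qtab)
    if params.pbits:
        _write_table(out, params.ptab)
    if params.dbits:
        _write_table(out, params.dtab)
    return bytes(out)


def _deserialize_params(r: ByteReader) -> FqzParams:
    version = r.byte()
    if version != _VERSION:
        raise MalformedError(f"unknown FQZComp parameter version {version}")
    fb = r.byte()
    max_sym = r.byte()
    (qbits, qshift, qloc, pbits, ploc, dbits, dloc, sbits, sloc) = r.take(9)
    qmap = list(r.take(max_sym)) if fb & 0x10 else None
    qtab = _read_table(r, max_sym)
    ptab = _read_table(r, POS_CLAMP + 1) if pbits else []
    dtab = _read_table(r, DELTA_CLAMP + 1) if dbits else []
    params = FqzParams(
        max_sym=max_sym,
        qbits=qbits,
        qshift=qshift,
        qloc=qloc,
        pbits=pbits,
        ploc=ploc,
        dbits=dbits,
        dloc=dloc,
        sbits=sbits,
        sloc=sloc,
        qtab=qtab,
        ptab=ptab,
        dtab=dtab,
        qmap=qmap,
        fixed_length=bool(fb & 0x01),
        do_dedup=bool(fb & 0x02),
        do_reverse=bool(fb & 0x04),
        do_selector=bool(fb & 0x08),
    )
    try:
        params.validate()
    except ValueError as exc:
        raise MalformedError(f"invalid FQZComp parameter block: {exc}") from exc
    return params


def _bitset(flags: Iterable[bool]) -> bytes:
    flags = list(flags)
    out = bytearray((len(flags) + 7) // 8)
    for i, f in enumerate(flags):
        if f:
            out[i >> 3] |= 1 << (i & 7)
    return bytes(out)


def _read_bitset(r: ByteReader, n: int) -> list[bool]:
    raw = r.take((n + 7) // 8)
    return [bool(raw[i >> 3] & (1 << (i & 7))) for i in range(n)]


def _pack_selectors(selectors: Iterable[int], sbits: int) -> bytes:
    out = bytearray()
    acc = fill = 0
    mask = (1 << sbits) - 1
    for s in selectors:
        acc |= (s & mask) << fill
        fill += sbits
        while fill >= 8:
            out.append(acc & 0xFF)
            acc >>= 8
            fill -= 8
    if fill:
        out.append(acc & 0xFF)
    return bytes(out)


def _unpack_selectors(r: ByteReader, n: int, sbits: int) -> list[int]:
    raw = r.take((n * sbits + 7) // 8)
    out = []
    acc = fill = pos = 0
    mask = (1 << sbits) - 1
    for _ in range(n):
        while fill < sbits:
            acc |= raw[pos] << fill
            pos += 1
            fill += 8
        out.append(acc & mask)
        acc >>= sbits
        fill -= sbits
    return out


# ---------------------------------------------------------------------------
# Encode / decode.
# ---------------------------------------------------------------------------

def _fqz_encode_parts(
    records: Sequence[QualityRecord],
    params: FqzParams,
    trace: list | None = None,
) -> tuple[bytes, bytes, bytes]:
    params.validate()
    if params.store_qmap:
        inv = {v: i for i, v in enumerate(params.qmap)}
    else:
        inv = None

    header = _serialize_params(params)

    meta = bytearray(write_uint7(len(records)))
    if params.fixed_length:
        lengths = {r.length for r in records}
        if len(lengths) > 1:
            raise ValueError("fixed_length set but record lengths differ")
        meta += write_uint7(records[0].length if records else 0)
    else:
        for rec in records:
            meta += write_uint7(rec.length)
    if params.do_reverse:
        meta += _bitset(r.reverse for r in records)
    if params.do_dedup:
        meta += _bitset(r.duplicate for r in records)
    if params.do_selector:
        meta += _pack_selectors((r.selector for r in records), params.sbits)

    rc = RangeEncoder()
    models: dict[int, AdaptiveModel] = {}
    prev_quals: tuple[int, ...] | None = None
    for rec in records:
        if params.do_dedup and rec.duplicate:
            if rec.quals != prev_quals:
                raise ValueError("record flagged duplicate does not match previous")
            continue
        qs = rec.quals[::-1] if (params.do_reverse and rec.reverse) else rec.quals
        state = FqzState()
        sel = rec.selector if params.do_selector else 0
        for q in qs:
            if inv is not None:
                idx = inv.get(q)
                if idx is None:
                    raise UnsupportedAlphabetError(f"quality {q} not in the model alphabet")
            else:
                if not 0 <= q < params.max_sym:
                    raise UnsupportedAlphabetError(f"quality {q} >= max_sym {params.max_sym}")
                idx = q
            ctx = compute_context(state, sel, params)
            if trace is not None:
                trace.append((ctx, idx))
            m = models.get(ctx)
            if m is None:
                m = models[ctx] = AdaptiveModel(params.max_sym)
            m.encode(rc, idx)
            state.update(idx, params)
        prev_quals = rec.quals
    payload = rc.finish()
    return header, bytes(meta), payload


def fqz_encode(
    records: Sequence[QualityRecord],
    params: FqzParams,
    trace: list | None = None,
) -> bytes:
    """Compress quality records under ``params`` into a self-describing stream."""
    header, meta, payload = _fqz_encode_parts(records, params, trace)
    return header + meta + write_uint7(len(payload)) + payload


def fqz_parts(records: Sequence[QualityRecord], params: FqzParams) -> dict[str, int]:
    """Byte sizes of the parameter block, record metadata and coded payload."""
    header, meta, payload = _fqz_encode_parts(records, params)
    return {"params": len(header), "meta": len(meta), "payload": len(payload)}


def fqz_decode(stream: bytes, trace: list | None = None) -> list[QualityRecord]:
    """Inverse of :func:`fqz_encode`, restoring all per-record metadata."""
    r = ByteReader(stream)
    params = _deserialize_params(r)
    n_records = r.uint7()
    if params.fixed_length:
        fixed = r.uint7() if n_records else 0
        lengths = [fixed] * n_records
    else:
        lengths = [r.uint7() for _ in range(n_records)]
    reverses = _read_bitset(r, n_records) if params.do_reverse else [False] * n_records
    dups = _read_bitset(r, n_records) if params.do_dedup else [False] * n_records
    selectors = (
        _unpack_selectors(r, n_records, params.sbits)
        if params.do_selector
        else [0] * n_records
    )
    payload_len = r.uint7()
    if payload_len > r.remaining():
        raise TruncationError("FQZComp payload shorter than declared")
    rc = RangeDecoder(bytes(r.take(payload_len)))

    models: dict[int, AdaptiveModel] = {}
    out: list[QualityRecord] = []
    prev_quals: tuple[int, ...] | None = None
    for i in range(n_records):
        if params.do_dedup and dups[i]:
            if prev_quals is None:
                raise MalformedError("first record flagged as duplicate")
            out.append(
                QualityRecord(prev_quals, reverses[i], True, selectors[i])
            )
            continue
        state = FqzState()
        sel = selectors[i]
        idxs: list[int] = []
        for _ in range(lengths[i]):
            ctx = compute_context(state, sel, params)
            m = models.get(ctx)
            if m is None:
                m = models[ctx] = AdaptiveModel(params.max_sym)
            idx = m.decode(rc)
            if trace is not None:
                trace.append((ctx, idx))
            idxs.append(idx)
            state.update(idx, params)
        quals = [params.qmap[x] for x in idxs] if params.store_qmap else idxs
        if params.do_reverse and reverses[i]:
            quals = quals[::-1]
        quals = tuple(quals)
        out.append(QualityRecord(quals, reverses[i], False, selectors[i]))
        prev_quals = quals
    return out
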