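"""FQZComp quality codec: context assembly, presets, round trips, entropy."""

import math
import random

import numpy as np
import pytest

from cramcodecs.errors import UnsupportedAlphabetError
from cramcodecs.fqzcomp import (
    PRESETS,
    FqzParams,
    FqzState,
    QualityRecord,
    build_params,
    compute_context,
    fqz_decode,
    fqz_encode,
    fqz_parts,
)
from cramcodecs.synthetic import QualityProfile, gen_qualities, novaseq_profile


# ---------------------------------------------------------------------------
# Context computation
# ---------------------------------------------------------------------------

def test_context_worked_example():
    """qbits=4 at bit 0, 2 position bits at bit 4; history [3,1] at qshift 2."""
    p = FqzParams(
        max_sym=16,
        qbits=4,
        qshift=2,
        qloc=0,
        pbits=2,
        ploc=4,
        qtab=list(range(16)),
        ptab=[min(i, 3) for i in range(1024)],
    )
    p.validate()
    st = FqzState()
    for q in (3, 1):
        st.update(q, p)
    assert st.qctx == (3 << 2) + 1 == 13
    assert st.pos == 2
    assert compute_context(st, 0, p) == 13 + (2 << 4) == 45


def test_context_degenerate_and_selector_placement():
    p0 = FqzParams(max_sym=4, qtab=[0] * 4)
    assert compute_context(FqzState(), 0, p0) == 0
    p1 = FqzParams(max_sym=4, qtab=[0] * 4, sbits=1, sloc=15, do_selector=True)
    assert compute_context(FqzState(), 1, p1) == 32768


def test_delta_counts_changes_only():
    p = FqzParams(max_sym=4, qbits=2, qshift=2, qtab=[0, 1, 2, 3], dbits=2,
                  dtab=[min(i, 3) for i in range(256)])
    st = FqzState()
    for q in (1, 1, 2, 2, 3):
        st.update(q, p)
    # changes happened at steps 1->2 and 2->3
    assert st.delta == 2


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _records(nvals, n=20, length=50, seed=0):
    rng = random.Random(seed)
    vals = list(range(nvals))
    return [
        QualityRecord(tuple(rng.choice(vals) for _ in range(length))) for _ in range(n)
    ]


@pytest.mark.parametrize("preset", PRESETS)
@pytest.mark.parametrize("nvals", [2, 4, 8, 40, 94])
def test_preset_invariants(preset, nvals):
    params = build_params(_records(nvals), preset)
    params.validate()
    assert params.qbits + params.pbits + params.dbits + params.sbits <= 16


def test_small_alphabet_preset_two_bit_qualities():
    params = build_params(_records(4), "small_alphabet")
    assert params.qshift == 2
    assert len(set(params.qtab)) <= 4
    assert max(params.qtab) < 4


def test_position_heavy_preset_tracks_cycles():
    params = build_params(_records(40), "position_heavy")
    assert params.pbits >= 7


def test_selector_preset_one_bit():
    params = build_params(_records(4), "selector_read12")
    assert params.sbits == 1 and params.do_selector


def test_alphabet_limit():
    rec = QualityRecord(tuple(range(94)))
    with pytest.raises(UnsupportedAlphabetError):
        build_params([QualityRecord((95,))], "generic")
    build_params([rec], "generic")  # 94 distinct values is the ceiling


# ---------------------------------------------------------------------------
# Round trips
# ---------------------------------------------------------------------------

def _mixed_corpus(nvals, seed, n=40):
    rng = random.Random(seed)
    vals = sorted(rng.sample(range(min(94, nvals * 3)), nvals)) if nvals < 94 else list(range(94))
    recs = []
    prev = None
    for i in range(n):
        length = rng.randrange(1, 500)
        quals = tuple(rng.choice(vals) for _ in range(length))
        dup = prev is not None and rng.random() < 0.15
        if dup:
            quals = prev
        recs.append(
            QualityRecord(quals, reverse=rng.random() < 0.3, duplicate=dup, selector=i & 1)
        )
        prev = quals
    return recs


@pytest.mark.parametrize("nvals", [2, 4, 8, 40, 94])
@pytest.mark.parametrize("preset", PRESETS)
def test_round_trip_alphabets_and_flags(nvals, preset):
    recs = _mixed_corpus(nvals, seed=nvals)
    params = build_params(recs, preset)
    out = fqz_decode(fqz_encode(recs, params))
    assert [r.quals for r in out] == [r.quals for r in recs]
    assert [r.reverse for r in out] == [r.reverse for r in recs]
    assert [r.duplicate for r in out] == [r.duplicate for r in recs]
    assert [r.selector & 1 for r in out] == [r.selector & 1 for r in recs] or not params.do_selector


def test_round_trip_preserves_selectors_explicitly():
    recs = [
        QualityRecord((1, 2, 3), selector=s) for s in (0, 1, 0)
    ]
    params = build_params(recs, "selector_read12")
    out = fqz_decode(fqz_encode(recs, params))
    assert [r.selector for r in out] == [0, 1, 0]


def test_reverse_flag_restores_orientation():
    recs = [QualityRecord((1, 1, 1, 3, 2), reverse=True), QualityRecord((2, 3, 1))]
    params = build_params(recs, "generic")
    assert params.do_reverse
    out = fqz_decode(fqz_encode(recs, params))
    assert out[0].quals == (1, 1, 1, 3, 2) and out[0].reverse


def test_duplicate_record_costs_only_its_flag():
    base = QualityRecord(tuple([3, 1, 2, 3] * 25))
    dup = QualityRecord(base.quals, duplicate=True)
    params = build_params([base, dup], "generic")
    two = fqz_parts([base, dup], params)
    one = fqz_parts([base], params)
    assert two["payload"] - one["payload"] < 2
    out = fqz_decode(fqz_encode([base, dup], params))
    assert out[0].quals == out[1].quals == base.quals


def test_encoder_decoder_context_traces_match():
    """Instrumented coding paths visit identical (context, symbol) sequences."""
    recs = _mixed_corpus(8, seed=2, n=10)
    params = build_params(recs, "generic")
    enc_trace: list = []
    stream = fqz_encode(recs, params, trace=enc_trace)
    dec_trace: list = []
    fqz_decode(stream, trace=dec_trace)
    assert enc_trace == dec_trace
    assert len(enc_trace) > 0


def test_all_zero_width_context_is_order0_adaptive():
    rec = QualityRecord(tuple(random.Random(1).randrange(4) for _ in range(200)))
    params = FqzParams(max_sym=4, qtab=[0, 0, 0, 0], fixed_length=True)
    out = fqz_decode(fqz_encode([rec], params))
    assert out[0].quals == rec.quals


# ---------------------------------------------------------------------------
# Information-theoretic checks
# ---------------------------------------------------------------------------

def test_coded_rate_approaches_conditional_entropy():
    """On data from a known first-order model, with a context that captures
    exactly the previous quality, the coded rate converges to the model's
    conditional entropy (within 5% at 1e5 symbols)."""
    T = np.array(
        [
            [0.70, 0.10, 0.10, 0.10],
            [0.10, 0.70, 0.10, 0.10],
            [0.10, 0.10, 0.70, 0.10],
            [0.05, 0.05, 0.10, 0.80],
        ]
    )
    # stationary distribution by power iteration
    pi = np.full(4, 0.25)
    for _ in range(500):
        pi = pi @ T
    h_cond = float(-(pi[:, None] * T * np.log2(T)).sum())

    profile = QualityProfile(
        alphabet=[0, 1, 2, 3],
        transition=T,
        initial=pi,
        n_records=1000,
        record_length=100,
        seed=3,
    )
    recs = gen_qualities(profile)
    n_sym = sum(r.length for r in recs)
    assert n_sym == 100000
    params = FqzParams(
        max_sym=4, qbits=2, qshift=2, qloc=0, qtab=[0, 1, 2, 3],
        qmap=[0, 1, 2, 3], fixed_length=True,
    )
    rate = fqz_parts(recs, params)["payload"] * 8 / n_sym
    assert abs(rate - h_cond) <= 0.05 * h_cond, (rate, h_cond)


def _selector_sizes(recs):
    with_sel = build_params(recs, "selector_read12")
    no_sel = FqzParams(
        **{**with_sel.__dict__, "sbits": 0, "sloc": 0, "do_selector": False}
    )
    return len(fqz_encode(recs, with_sel)), len(fqz_encode(recs, no_sel))


def test_informative_selector_reduces_size():
    """Splitting records by read-1/read-2 source costs at most the 1-bit
    per-record metadata, and shrinks the stream when read 2 has cycle
    errors that quality history cannot predict."""
    from cramcodecs.synthetic import hiseq_profile

    # two populations with different per-cycle error profiles: clear win
    recs = gen_qualities(hiseq_profile(1000, 100, seed=5, paired=True))
    size_with, size_without = _selector_sizes(recs)
    assert size_with < size_without

    # two populations differing mostly in ways history already reveals:
    # the selector may not help, but never costs more than its metadata
    recs = gen_qualities(novaseq_profile(1500, 100, seed=5, paired=True))
    size_with, size_without = _selector_sizes(recs)
    assert size_with <= size_without + (len(recs) + 7) // 8 + 8
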