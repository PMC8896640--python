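"""Static-frequency rANS coder and container framing."""

import math
import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cramcodecs.errors import CodecError, UnsupportedFormatError
from cramcodecs.rans_nx16 import (
    decode_container,
    encode_container,
    entropy_parts,
    normalize_frequencies,
    rans_decode,
    rans_encode,
)
from cramcodecs.stream_io import CodecFlags


# ---------------------------------------------------------------------------
# Frequency normalization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts,bits,expected",
    [
        ({65: 1}, 12, {65: 4096}),
        ({65: 1, 66: 1}, 12, {65: 2048, 66: 2048}),
        ({65: 3, 66: 1}, 12, {65: 3072, 66: 1024}),
    ],
)
def test_normalize_known_apportionments(counts, bits, expected):
    assert normalize_frequencies(counts, bits) == expected


@settings(max_examples=500)
@given(
    st.dictionaries(
        st.integers(min_value=0, max_value=255),
        st.integers(min_value=0, max_value=10**6),
        min_size=1,
        max_size=64,
    ).filter(lambda d: any(v > 0 for v in d.values())),
    st.sampled_from([10, 12]),
)
def test_normalize_properties(counts, bits):
    freq = normalize_frequencies(counts, bits)
    assert sum(freq.values()) == 1 << bits
    assert set(freq) == {s for s, c in counts.items() if c > 0}
    assert all(f >= 1 for f in freq.values())


def test_normalize_all_zero_rejected():
    with pytest.raises(ValueError):
        normalize_frequencies({1: 0}, 12)


# ---------------------------------------------------------------------------
# Core coder
# ---------------------------------------------------------------------------

def _random_corpus(seed, n_cases=40, max_len=600):
    rng = random.Random(seed)
    out = []
    for _ in range(n_cases):
        alpha = rng.randrange(1, 257)
        n = rng.randrange(0, max_len)
        out.append(bytes(rng.randrange(alpha) for _ in range(n)))
    return out


@pytest.mark.parametrize("order", [0, 1])
@pytest.mark.parametrize("n_states", [4, 32])
def test_rans_round_trip_random(order, n_states):
    for data in _random_corpus(17):
        if order == 1 and not data:
            continue
        assert rans_decode(rans_encode(data, order, n_states)) == data


def test_rans_empty_and_order1_empty():
    assert rans_decode(rans_encode(b"", 0)) == b""
    with pytest.raises(ValueError):
        rans_encode(b"", 1)


def test_cross_variant_same_decoded_output():
    data = bytes(random.Random(3).randrange(7) for _ in range(5000))
    for order in (0, 1):
        s4 = rans_encode(data, order, 4)
        s32 = rans_encode(data, order, 32)
        assert rans_decode(s4) == rans_decode(s32) == data


def test_constant_data_emits_almost_no_payload():
    """1000 identical bytes have zero entropy: only table and state flush remain."""
    parts = entropy_parts(b"\x41" * 1000, 0, 4)
    assert parts["words"] <= 8


def test_uniform_four_symbol_payload_near_two_bits():
    rng = random.Random(5)
    data = bytes(rng.randrange(4) for _ in range(4096))
    parts = entropy_parts(data, 0, 4)
    # Shannon: 2 bits/symbol = 1024 bytes, plus bounded normalization loss
    assert 1024 - 64 <= parts["words"] + parts["states"]
    assert parts["words"] <= 1024 + 192


@settings(max_examples=300)
@given(st.binary(min_size=1, max_size=2000))
def test_entropy_lower_bound(data):
    """Payload (words + state flush) cannot beat the empirical entropy."""
    counts = Counter(data)
    n = len(data)
    h0 = -sum(c / n * math.log2(c / n) for c in counts.values())
    parts = entropy_parts(data, 0, 4)
    assert parts["words"] + parts["states"] >= math.ceil(n * h0 / 8) - 1


def test_order1_beats_order0_on_markov_data():
    rng = random.Random(11)
    data = bytearray([0])
    for _ in range(50000):
        prev = data[-1]
        # strong transition structure: mostly repeat, else cycle forward
        data.append(prev if rng.random() < 0.85 else (prev + 1) % 5)
    data = bytes(data)
    assert len(rans_encode(data, 1)) < len(rans_encode(data, 0))


def test_32_state_overhead_bounded_on_large_block():
    rng = random.Random(7)
    data = bytes(rng.choice(b"ACGT") for _ in range(1 << 16))
    s4 = len(rans_encode(data, 0, 4))
    s32 = len(rans_encode(data, 0, 32))
    assert s32 <= s4 * 1.01 + 128


# ---------------------------------------------------------------------------
# Container framing
# ---------------------------------------------------------------------------

_FLAG_SETS = [
    CodecFlags(),
    CodecFlags(order=1),
    CodecFlags(x32=True),
    CodecFlags(order=1, x32=True),
    CodecFlags(cat=True),
    CodecFlags(rle=True),
    CodecFlags(pack=True),
    CodecFlags(order=1, pack=True, rle=True),
    CodecFlags(stripe=True, order=1),
    CodecFlags(stripe=True, pack=True, rle=True),
]


@pytest.mark.parametrize("flags", _FLAG_SETS, ids=lambda f: f"0x{f.to_byte():02x}")
def test_container_round_trip_all_flag_sets(flags):
    rng = random.Random(23)
    for n in (0, 1, 2, 7, 100, 1000):
        data = bytes(rng.randrange(12) for _ in range(n))
        stream = encode_container(data, flags)
        assert decode_container(stream) == data


@settings(max_examples=400)
@given(st.binary(max_size=400), st.sampled_from(_FLAG_SETS[:8]))
def test_container_round_trip_random_bytes(data, flags):
    if flags.pack and len(set(data)) > 16:
        return
    assert decode_container(encode_container(data, flags)) == data


def test_striped_16bit_integers_round_trip():
    rng = random.Random(9)
    vals = []
    x = 5000
    for _ in range(4000):
        x += rng.randrange(-3, 4)
        vals.append(x & 0xFFFF)
    data = b"".join(v.to_bytes(2, "little") for v in vals)
    flags = CodecFlags(stripe=True, order=1)
    stream = encode_container(data, flags, n_stripe=2)
    assert decode_container(stream) == data


def test_no_size_container_uses_caller_length():
    stream = encode_container(b"xyz", CodecFlags(no_size=True))
    assert decode_container(stream, expected_length=3) == b"xyz"
    with pytest.raises(ValueError):
        decode_container(stream)


def test_cat_container_is_framed_raw_copy():
    stream = encode_container(b"abc", CodecFlags(cat=True))
    assert stream == b"\x20\x03abc"
    assert decode_container(stream) == b"abc"


def test_reserved_flag_bit_rejected():
    with pytest.raises(UnsupportedFormatError):
        decode_container(b"\x02\x00")


def test_truncated_stream_raises_codec_error():
    stream = rans_encode(bytes(range(10)) * 30, 0)
    with pytest.raises(CodecError):
        rans_decode(stream[: len(stream) // 2])


def test_pack_flag_with_rich_alphabet_rejected():
    from cramcodecs.errors import NotPackableError

    with pytest.raises(NotPackableError):
        encode_container(bytes(range(17)), CodecFlags(pack=True))
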