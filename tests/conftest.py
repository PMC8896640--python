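import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def novaseq_block():
    """The reference NovaSeq-like corpus: 10000 reads x 100 cycles (~1 MB)."""
    from cramcodecs import synthetic

    records = synthetic.gen_qualities(synthetic.novaseq_profile(10000, 100, seed=1))
    return records, synthetic.records_to_bytes(records)


@pytest.fixture(scope="session")
def novaseq_sizes(novaseq_block):
    """Compressed sizes of the reference corpus under each coder (computed once)."""
    from cramcodecs import CodecFlags, fqzcomp, rans_nx16

    records, data = novaseq_block
    params = fqzcomp.build_params(records, "small_alphabet")
    return {
        "raw": len(data),
        "rans_o0": len(rans_nx16.rans_encode(data, 0)),
        "rans_o1": len(rans_nx16.rans_encode(data, 1)),
        "rans_o1_pack_rle": len(
            rans_nx16.encode_container(data, CodecFlags(order=1, pack=True, rle=True))
        ),
        "fqz": len(fqzcomp.fqz_encode(records, params)),
    }


@pytest.fixture(scope="session")
def sorted_names():
    from cramcodecs import synthetic

    return synthetic.gen_names(synthetic.NameProfile(5000, "name_sorted", seed=1))


@pytest.fixture(scope="session")
def scrambled_names():
    from cramcodecs import synthetic

    return synthetic.gen_names(synthetic.NameProfile(5000, "position_scrambled", seed=1))
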