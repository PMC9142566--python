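import pytest

from twodna import dna_codec, uep_ldpc


@pytest.fixture(scope="session")
def primer_book():
    return dna_codec.design_primers(seed=12345)


@pytest.fixture(scope="session")
def addr_code():
    return dna_codec.address_code()


@pytest.fixture(scope="session")
def pay_code():
    return dna_codec.payload_code()


@pytest.fixture(scope="session")
def ldpc_half():
    """(3,6)-regular rate-1/2 code of length 1024, shared across tests."""
    return uep_ldpc.build_ldpc(uep_ldpc.LDPCSpec(n=1024, rate=0.5, d_v=3, seed=1))
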