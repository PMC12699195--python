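import pytest

from dsbquant import BUNDLED_ENZYMES, GenomeAssembly, GenomeRecord


@pytest.fixture
def alu():
    return BUNDLED_ENZYMES["AluI"]


@pytest.fixture
def ecorv():
    return BUNDLED_ENZYMES["EcoRV"]


@pytest.fixture
def tiny_assembly():
    """One 8-mer linear record with a single AluI site at position 2."""
    return GenomeAssembly("tiny", [GenomeRecord("r1", "TTAGCTTT")])


@pytest.fixture
def fasta_file(tmp_path):
    def _write(content: str, name: str = "g.fa"):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write
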