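import pytest

from arecpe.synthetic import SyntheticSpec, generate_study


@pytest.fixture(scope="session")
def small_bundle():
    """A 40-gene ground-truthed study shared across tests (read-only)."""
    return generate_study(SyntheticSpec(n_genes=40, seed=123))


@pytest.fixture()
def bundle_dir(small_bundle, tmp_path):
    """The small study written out as FASTA/TSV files."""
    from arecpe.synthetic import write_bundle

    return write_bundle(small_bundle, tmp_path / "bundle")
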