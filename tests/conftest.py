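import pytest

from biplink import make_fig1_fixture
from biplink.synth import FIG1_LINKS


@pytest.fixture(scope="session")
def fig1():
    """The 8-node, 11-link worked-example graph."""
    return make_fig1_fixture()


@pytest.fixture()
def fig1_edgelist(tmp_path):
    """The worked-example graph as a two-column TSV file."""
    path = tmp_path / "fig1.tsv"
    path.write_text("".join(f"{u}\t{v}\n" for u, v in sorted(FIG1_LINKS)))
    return path
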