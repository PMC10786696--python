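import pytest

from cfmethyl import MarkerPanel, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def liver_panel(panel):
    """The five liver markers only — the spike-in assay fixture."""
    return MarkerPanel(panel.loci_for("liver"))
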