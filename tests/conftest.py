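import pytest

from xenoprio.simulate import default_config, simulate_study, write_study
from xenoprio.types import GenePanelEntry, PanelCategory


@pytest.fixture(scope="session")
def study():
    """One simulated study shared across read-only tests."""
    return simulate_study(default_config(seed=11))


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory):
    """The same study materialized as flat files."""
    outdir = tmp_path_factory.mktemp("study")
    return write_study(study, outdir)


@pytest.fixture
def small_panel():
    return [
        GenePanelEntry("GENE1", PanelCategory.DET, "CYPs"),
        GenePanelEntry("GENE2", PanelCategory.BBB, "SLCs"),
    ]


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
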