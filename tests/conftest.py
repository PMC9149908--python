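import pandas as pd
import pytest

from lopitmap.synth import (
    SynthConfig,
    generate_bioid_experiment,
    generate_ev_experiment,
    generate_reference_map,
)


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig(seed=7)


@pytest.fixture(scope="session")
def refmap(synth_cfg):
    return generate_reference_map(synth_cfg)


@pytest.fixture(scope="session")
def bioid_data(synth_cfg, refmap):
    return generate_bioid_experiment(synth_cfg, refmap)


@pytest.fixture(scope="session")
def ev_data(synth_cfg, refmap):
    return generate_ev_experiment(synth_cfg, refmap)


@pytest.fixture
def small_map_file(tmp_path):
    """Three-protein reference map: one cytosolic, one nuclear, one unknown."""
    path = tmp_path / "map.tsv"
    path.write_text(
        "accession\tx\ty\tcompartment\n"
        "A1\t0.0\t0.0\tcytosol\n"
        "A2\t1.0\t2.0\tnucleus\n"
        "A3\t-1.5\t0.5\tunknown\n"
    )
    return path


@pytest.fixture
def small_quant_file(tmp_path):
    """Four proteins x three wash/elute fractions with a missing cell."""
    path = tmp_path / "quant.csv"
    path.write_text(
        "accession,W-1,W-2,Elute\n"
        "A1,100,50,150\n"
        "A2,200,80,\n"
        "A3,10,2.0,6.0\n"
        "B9,5,5,25\n"
    )
    return path


def make_marker_frame(rows):
    frame = pd.DataFrame(rows, columns=["accession", "category", "role"])
    return frame.set_index("accession")
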