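from pathlib import Path

import pytest

from qspharm.interactions import InteractionMatrix


@pytest.fixture()
def stitch_table(tmp_path: Path) -> Path:
    """3-row STITCH-dialect fixture with 0-1000 integer scores."""
    path = tmp_path / "stitch.tsv"
    path.write_text(
        "chemical\tprotein\texperimental\tdatabase\ttextmining\tprediction\tcombined\n"
        "cocaine\tSLC6A3\t400\t0\t0\t0\t400\n"
        "cocaine\tSLC6A4\t900\t100\t0\t0\t900\n"
        "morphine\tOPRM1\t150\t0\t50\t0\t200\n"
    )
    return path


@pytest.fixture()
def drugbank_table(tmp_path: Path) -> Path:
    path = tmp_path / "drugbank.tsv"
    path.write_text(
        "drug_id\ttarget_id\n"
        "# curated pairs\n"
        "cocaine\tSLC6A3\n"
        "ketamine\tGRIN1\n"
    )
    return path


@pytest.fixture()
def small_matrix() -> InteractionMatrix:
    """3 drugs x 4 targets with 4 interactions."""
    return InteractionMatrix(
        ["d1", "d2", "d3"],
        ["t1", "t2", "t3", "t4"],
        {(0, 0), (0, 1), (1, 1), (2, 3)},
    )
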