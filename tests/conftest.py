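import pandas as pd
import pytest

from escapex.model import BetaMatrix


def build_matrix(rows, samples, positions=None):
    """Construct a small BetaMatrix by hand.

    rows: dict probe_id -> list of beta values (one per sample, in order).
    samples: list of (sample_id, sex, age_group, role) tuples.
    positions default to 100, 200, ... in probe insertion order.
    """
    sample_ids = [s[0] for s in samples]
    sheet = pd.DataFrame(
        [
            {"sample_id": sid, "sex": sex, "age_group": age, "role": role, "batch": "b1"}
            for sid, sex, age, role in samples
        ]
    ).set_index("sample_id")
    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    if positions is None:
        positions = pd.Series(
            range(100, 100 + 100 * len(values), 100), index=values.index, name="pos"
        )
    else:
        positions = pd.Series(positions, index=values.index, name="pos")
    return BetaMatrix(values=values, positions=positions, samples=sheet)


@pytest.fixture
def four_controls():
    """Two male + two female adult controls."""
    return [
        ("M1", "M", "adult", "control"),
        ("M2", "M", "adult", "control"),
        ("F1", "F", "adult", "control"),
        ("F2", "F", "adult", "control"),
    ]


@pytest.fixture
def controls_and_patient(four_controls):
    return four_controls + [("P1", "F", "child", "patient")]
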