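import pytest

from honchains import parse_chain_line
from honchains.synthetic import ChainModel


@pytest.fixture
def worked_chains():
    """The two example accident chains (unfamiliar road / fatigue driving
    paths through collision)."""
    return [
        parse_chain_line("H10→H05→A01→A06"),
        parse_chain_line("H01→A01→V04→A07"),
    ]


@pytest.fixture
def worked_chain_file(tmp_path, worked_chains):
    path = tmp_path / "chains.txt"
    path.write_text(
        "# worked example\nH10→H05→A01→A06\nH01→A01→V04→A07\n", encoding="utf-8"
    )
    return path


def planted_model() -> ChainModel:
    """Backbone over four factors with one planted order-2 override.

    Base: H01→H02, H02→{A1: .5, A6: .5}, A1/A6→H01.  Override: after the
    subpath H01→H02 the successor is A1 with probability 1 (KL from the
    base row = 1 bit).  Chains starting at H02 keep the base 50/50 row.
    """
    return ChainModel(
        states=["H01", "H02", "A1", "A6"],
        start_dist={"H01": 0.5, "H02": 0.5},
        base_transitions={
            "H01": {"H02": 1.0},
            "H02": {"A1": 0.5, "A6": 0.5},
            "A1": {"H01": 1.0},
            "A6": {"H01": 1.0},
        },
        overrides={("H01", "H02"): {"A1": 1.0}},
        length_dist={3: 1.0},
    )


def null_model() -> ChainModel:
    """Pure first-order backbone (no overrides): the null for dependency
    detection."""
    return ChainModel(
        states=["H01", "H02", "A1", "A6", "V04"],
        start_dist={"H01": 0.4, "H02": 0.3, "V04": 0.3},
        base_transitions={
            "H01": {"H02": 0.5, "A1": 0.3, "V04": 0.2},
            "H02": {"A1": 0.5, "A6": 0.5},
            "A1": {"A6": 0.6, "V04": 0.4},
            "A6": {"H01": 0.3, "V04": 0.7},
            "V04": {"A6": 0.5, "A1": 0.5},
        },
        length_dist={3: 0.25, 4: 0.25, 5: 0.25, 6: 0.25},
    )
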