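import numpy as np
import pytest

from molkit import fixtures as fx
from molkit import rule_based_process


@pytest.fixture
def helix10():
    return fx.make_polyala_helix(10)


@pytest.fixture
def helix10_bonded():
    ent = fx.make_polyala_helix(10)
    rule_based_process(ent)
    return ent


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_mixed_entity():
    """Small hand-built entity: ALA + HOH + HEM-like iron site, two chains."""
    from molkit import build_entity

    return build_entity([
        {"name": "A", "residues": [
            {"name": "ALA", "number": 1, "one_letter_code": "A",
             "is_protein": True,
             "atoms": [
                 {"name": "N", "element": "N", "pos": (0.0, 0.0, 0.0)},
                 {"name": "CA", "element": "C", "pos": (1.46, 0.0, 0.0)},
                 {"name": "C", "element": "C", "pos": (2.0, 1.4, 0.0)},
                 {"name": "O", "element": "O", "pos": (1.4, 2.4, 0.0)},
             ]},
            {"name": "HOH", "number": 2,
             "atoms": [{"name": "O", "element": "O", "pos": (8.0, 0.0, 0.0),
                        "is_hetatm": True}]},
        ]},
        {"name": "B", "residues": [
            {"name": "HEM", "number": 1,
             "atoms": [
                 {"name": "FE", "element": "FE", "pos": (0.0, 8.0, 0.0),
                  "is_hetatm": True},
                 {"name": "NA", "element": "N", "pos": (2.0, 8.0, 0.0),
                  "is_hetatm": True},
             ]},
        ]},
    ], name="mixed")


@pytest.fixture
def mixed_entity():
    return make_mixed_entity()
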