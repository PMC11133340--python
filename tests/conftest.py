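import numpy as np
import pytest

from eetnet import (
    FixtureSpec,
    PigmentKind,
    Placement,
    extract_pigments,
    make_fixture,
    read_structure,
)


@pytest.fixture
def chl_pair_spec():
    """Two chlorophylls a, parallel dipoles perpendicular to a 10 A separation."""
    return FixtureSpec(
        placements=[
            Placement(
                kind=PigmentKind.CHL_A,
                chain_id="A",
                residue_number=601,
                mg_position=np.array([0.0, 0.0, 0.0]),
                dipole_direction=np.array([0.0, 0.0, 1.0]),
            ),
            Placement(
                kind=PigmentKind.CHL_A,
                chain_id="A",
                residue_number=602,
                mg_position=np.array([10.0, 0.0, 0.0]),
                dipole_direction=np.array([0.0, 0.0, 1.0]),
            ),
        ]
    )


@pytest.fixture
def mixed_spec():
    """3 chlorophyll-a, 1 chlorophyll-c and 2 carotenoid-like placements."""
    placements = []
    for i, kind in enumerate(
        [PigmentKind.CHL_A, PigmentKind.CHL_A, PigmentKind.CHL_A, PigmentKind.CHL_C]
    ):
        placements.append(
            Placement(
                kind=kind,
                chain_id="A",
                residue_number=601 + i,
                mg_position=np.array([15.0 * i, 0.0, 0.0]),
                dipole_direction=np.array([0.0, 1.0, 0.0]),
            )
        )
    for i in range(2):
        placements.append(
            Placement(
                kind=PigmentKind.ALX,
                chain_id="B",
                residue_number=615 + i,
                mg_position=np.array([5.0 * i, 20.0, 0.0]),
            )
        )
    return FixtureSpec(placements=placements)


@pytest.fixture
def inventory_from(tmp_path):
    """Factory: write a spec to mmCIF, read it back, extract pigments."""

    def _build(spec, code_map=None):
        from eetnet.synthetic import FIXTURE_CODE_MAP

        path = tmp_path / "fixture.cif"
        make_fixture(spec, path)
        model = read_structure(path)
        return extract_pigments(model, code_map or FIXTURE_CODE_MAP)

    return _build
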