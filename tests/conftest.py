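"""Shared fixtures: synthetic structures with controlled geometry."""

from __future__ import annotations

import numpy as np
import pytest

from vartriage.structmodel import StructureModel, build_fixture


@pytest.fixture(scope="session")
def tripeptide_arg() -> StructureModel:
    return build_fixture("tripeptide", "R")


@pytest.fixture(scope="session")
def helix20() -> StructureModel:
    return build_fixture("helix", "A" * 20)


@pytest.fixture(scope="session")
def decapeptide() -> StructureModel:
    return build_fixture("extended", "ARNDCQEGHI")


def place_bridge_dimer(distance: float) -> StructureModel:
    """Dimer with chain A Arg and chain B Glu, the Arg NH1 placed exactly
    ``distance`` Å from the Glu OE1 along z."""
    model = build_fixture("two_chain_dimer", "ARA", translation=(0.0, 0.0, 60.0))
    # replace chain B with a Glu-containing chain at the same pose
    glu = build_fixture("extended", "AEA")
    chain_b = glu.chains[0]
    chain_b.chain_id = "B"
    for res in chain_b:
        res.chain_id = "B"
    model.chains[1] = chain_b
    nh1 = model.get_residue("A", 2).atom("NH1").coords
    oe1 = model.get_residue("B", 2).atom("OE1").coords
    shift = nh1 + np.array([0.0, 0.0, distance]) - oe1
    for res in model.chains[1]:
        for atom in res.atoms:
            atom.coords = atom.coords + shift
    return StructureModel(identifier=f"bridge-{distance}", chains=model.chains)


@pytest.fixture()
def bridge_dimer_close() -> StructureModel:
    return place_bridge_dimer(3.0)


@pytest.fixture()
def bridge_dimer_far() -> StructureModel:
    return place_bridge_dimer(9.0)
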