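"""Shared fixtures: study parameter sets and synthetic structure models."""

import numpy as np
import pytest

from fluornmr.datasets import EXCHANGE_FIXTURES, StudyFixture
from fluornmr.structures import AtomRecord, StructureModel


@pytest.fixture
def study():
    return StudyFixture()


@pytest.fixture(params=sorted(EXCHANGE_FIXTURES), ids=lambda k: f"{k[0]}-{k[1]}")
def exchange_fixture(request):
    """(key, FastExchangeFitParams) for each reported parameter set."""
    return request.param, EXCHANGE_FIXTURES[request.param]


def make_atom(resnum, name, xyz, resname="GLY", icode="", element=None,
              chain="A", occupancy=1.0, het=False):
    return AtomRecord(
        chain=chain,
        resnum=resnum,
        icode=icode,
        resname=resname,
        atom=name,
        element=element if element is not None else name[0],
        xyz=tuple(float(v) for v in xyz),
        occupancy=occupancy,
        b_factor=20.0,
        het=het,
    )


def make_trp(resnum, icode="", with_f=True, origin=(0.0, 0.0, 0.0)):
    """Minimal 5-fluoro-Trp stand-in: CA, CZ3 and (optionally) a bonded F."""
    ox, oy, oz = origin
    atoms = [
        make_atom(resnum, "CA", (ox, oy, oz), "FTR", icode),
        make_atom(resnum, "CZ3", (ox + 1.0, oy, oz), "FTR", icode, element="C"),
    ]
    if with_f:
        atoms.append(
            make_atom(resnum, "F", (ox + 1.0, oy + 1.35, oz), "FTR", icode, element="F")
        )
    return atoms


@pytest.fixture
def ca_cloud():
    """A 12-residue CA-only synthetic model and its raw coordinates."""
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(12, 3)) * 6.0
    model = StructureModel(
        [make_atom(i + 1, "CA", p) for i, p in enumerate(pts)], id="synthetic"
    )
    return model, pts


@pytest.fixture
def nine_trp_model():
    """Synthetic model carrying fluorinated Trp at all nine positions."""
    sites = [("29", ""), ("51", ""), ("60", "D"), ("96", ""), ("141", ""),
             ("148", ""), ("207", ""), ("215", ""), ("237", "")]
    atoms = []
    for j, (num, icode) in enumerate(sites):
        atoms.extend(make_trp(int(num), icode, origin=(10.0 * j, 0.0, 0.0)))
    return StructureModel(atoms, id="synthetic-9trp")
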