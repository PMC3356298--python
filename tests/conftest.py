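"""Shared fixtures: printed per-step barriers and small synthetic inputs."""

import numpy as np
import pytest

from methylspec import BarrierSet, RoleMap
from methylspec.io import AtomRecord, Frame, FrameSeries

#: ideal tetrahedral angle, degrees
TET = 109.47122063449069


@pytest.fixture
def wt():
    return BarrierSet(enzyme="WT", barriers=(13.4, 15.8, 22.1))


@pytest.fixture
def f1209y():
    return BarrierSet(enzyme="F1209Y", barriers=(13.8, 17.4, None))


@pytest.fixture
def y1124f():
    return BarrierSet(enzyme="Y1124F", barriers=(13.9, 15.9, 13.3))


def tetrahedral_substituents(p_n, u, bond_length=1.47, azimuth=0.0):
    """Three substituent positions whose lone-pair construction yields u."""
    u = np.asarray(u, float)
    u = u / np.linalg.norm(u)
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    cb, sb = np.cos(np.radians(TET)), np.sin(np.radians(TET))
    out = []
    for j in range(3):
        a = azimuth + 2.0 * np.pi * j / 3.0
        d = cb * u + sb * (np.cos(a) * e1 + np.sin(a) * e2)
        out.append(np.asarray(p_n) + bond_length * d)
    return out


def make_sn2_frame(r_cn, r_cs, u_lone_pair, index=0, extra_atoms=()):
    """Minimal S–C–N frame: CM at origin, Sδ on +z, Nζ on −z."""
    p_c = np.zeros(3)
    p_s = np.array([0.0, 0.0, r_cs])
    p_n = np.array([0.0, 0.0, -r_cn])
    subs = tetrahedral_substituents(p_n, u_lone_pair)
    atoms = [
        AtomRecord("SD", "S", p_s),
        AtomRecord("CM", "C", p_c),
        AtomRecord("NZ", "N", p_n),
        AtomRecord("CE", "C", subs[0]),
        AtomRecord("HZ1", "H", subs[1]),
        AtomRecord("HZ2", "H", subs[2]),
    ]
    atoms.extend(extra_atoms)
    return Frame(index=index, atoms=tuple(atoms))


@pytest.fixture
def sn2_role_map():
    return RoleMap(
        s_delta="SD", c_methyl="CM", n_zeta="NZ",
        n_substituents=("CE", "HZ1", "HZ2"),
    )


def series_of(frames, role_map, temperature=283.15):
    return FrameSeries(frames=tuple(frames), role_map=role_map, temperature=temperature)
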