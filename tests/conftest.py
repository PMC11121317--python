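import numpy as np
import pytest

from parepi.config import Config
from parepi.structio import ComplexRecord, Residue


def make_residue(chain_id, number, aa, c_mu, icode=""):
    """Residue with a single pseudo side-chain atom at c_mu."""
    c = np.asarray(c_mu, dtype=float)
    atoms = [("CA", c + np.array([0.4, 0.4, 0.4])), ("CB", c.copy())]
    if aa == "G":
        atoms = [("CA", c.copy())]
    return Residue(chain_id, number, icode, aa, atoms, c.copy())


def make_record(ab_points, ag_points, ab_aas=None, ag_aas=None, rec_id="rec"):
    """ComplexRecord from explicit C-mu coordinates (H gets all but one ab residue)."""
    ab_points = [np.asarray(p, float) for p in ab_points]
    ag_points = [np.asarray(p, float) for p in ag_points]
    ab_aas = ab_aas or ["K"] * len(ab_points)
    ag_aas = ag_aas or ["D"] * len(ag_points)
    n_h = max(1, len(ab_points) - 1)
    heavy = [make_residue("H", i + 1, ab_aas[i], p)
             for i, p in enumerate(ab_points[:n_h])]
    light = [make_residue("L", i + 1, ab_aas[n_h + i], p)
             for i, p in enumerate(ab_points[n_h:])]
    if not light:   # single-residue antibody test cases still need both chains
        light = [make_residue("L", 1, "G", ab_points[0] + np.array([0, 0, 200.0]))]
    antigen = [make_residue("A", i + 1, ag_aas[i], p)
               for i, p in enumerate(ag_points)]
    return ComplexRecord(rec_id, heavy, light, {"A": antigen})


@pytest.fixture
def small_config():
    cfg = Config()
    cfg.imaging.size = 64
    return cfg


@pytest.fixture(scope="session")
def session_config():
    cfg = Config()
    cfg.imaging.size = 64
    return cfg
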