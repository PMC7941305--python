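import numpy as np
import pytest

import saxskit as sk
from saxskit import fixtures as fx

MINI_CIF = """data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . ALA A 1 1 1.000 2.000 3.000 1.00 10.0 1
ATOM 2 N N . ALA A 1 1 -1.500 0.250 2.125 1.00 10.0 1
ATOM 3 O O . ALA A 1 1 0.000 -4.375 1.750 0.50 10.0 1
"""

MINI_PDB = (
    "HEADER    TEST\n"
    "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00"
    "           C\n"
    "END\n"
)


@pytest.fixture
def mini_cif(tmp_path):
    p = tmp_path / "mini.cif"
    p.write_text(MINI_CIF)
    return p


@pytest.fixture
def mini_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    return p


@pytest.fixture(scope="session")
def detector_setup():
    """A small-angle detector with a circular mask reaching sR = 4 for R = 30 A,
    plus an absolute-scale sphere source curve giving ~500 counts/pixel at the
    beam center."""
    R = 30.0
    shape = (740, 740)
    geom = sk.DetectorGeometry(shape=shape, pixel_size=0.172, distance=3000.0,
                               wavelength=1.0, beam_center=(369.5, 369.5))
    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    mask = np.hypot(ii - 369.5, jj - 369.5) <= 369.0
    src = fx.sphere_curve(R, np.linspace(0.0, 0.14, 3000), i0=0.2
                          ).with_(scale="absolute")
    model = sk.ExposureModel(flux=1e12, exposure=1.0, concentration=1.0,
                             transmission=0.9, efficiency=0.9)
    expected = sk.expected_image(src, geom, model, mask=mask)
    return {"R": R, "geom": geom, "mask": mask, "src": src, "model": model,
            "expected": expected}


@pytest.fixture(scope="session")
def exp_corr_pair():
    """Exponential-correlation transform pair: I(s) = I0 b^4/(b^2+s^2)^2 is the
    exact scattering of p(r) = c r^2 exp(-r/a), b = 1/a -- a curve whose
    high-angle tail is asymptotically exactly A s^-4."""
    a, I0 = 10.0, 100.0
    b = 1.0 / a

    def intensity(s):
        return I0 * b ** 4 / (b ** 2 + np.asarray(s) ** 2) ** 2

    def pofr(r):
        r = np.asarray(r)
        raw = r ** 2 * np.exp(-r / a)
        return raw  # caller normalizes

    return {"a": a, "I0": I0, "rg": np.sqrt(6) * a, "intensity": intensity,
            "pofr_raw": pofr}
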