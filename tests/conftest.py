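"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from edcorr.kinematic_sf import CrystalModel
from edcorr.reflection_io import UnitCell
from edcorr.scattering_factors import electron_form_factor, evaluate_form_factor
from edcorr.synthetic_data import default_toy_model

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_model() -> CrystalModel:
    return default_toy_model()


@pytest.fixture
def ortho_cell() -> UnitCell:
    return UnitCell(8.090, 9.940, 17.700)


def direct_sum_structure_factors(model: CrystalModel,
                                 hkl: np.ndarray) -> np.ndarray:
    """Brute-force oracle: expand every atom over all symmetry operators
    in direct space (position Rx+t, displacement tensor R U R^T), then sum
    occ * f(s) * DW * exp(2 pi i h.x) over the expanded list with plain
    Python loops. No reciprocal-space symmetry shortcuts.
    """
    import gemmi

    cell = model.cell.to_gemmi()
    rec = cell.reciprocal()
    astar = np.array([rec.a, rec.b, rec.c])
    expanded = []
    for atom in model.atoms:
        if atom.u_aniso is None:
            for rot, tran in model.symmetry:
                expanded.append((atom.element, atom.occupancy,
                                 rot @ atom.frac + tran,
                                 atom.u_iso or 0.0, None))
        else:
            # scaled tensor U*_ij = U_ij a*_i a*_j transforms as
            # U*' = R U* R^T for the copy at Rx+t
            ustar = atom.u_matrix() * np.outer(astar, astar)
            for rot, tran in model.symmetry:
                expanded.append((atom.element, atom.occupancy,
                                 rot @ atom.frac + tran, None,
                                 rot @ ustar @ rot.T))
    coeffs = {el: electron_form_factor(el)
              for el in {a.element for a in model.atoms}}
    out = []
    for h in np.asarray(hkl):
        d = cell.calculate_d([int(h[0]), int(h[1]), int(h[2])])
        s = 1.0 / (2.0 * d)
        total = 0j
        for el, occ, pos, u_iso, ustar in expanded:
            f = evaluate_form_factor(coeffs[el], s)
            if ustar is None:
                dw = np.exp(-8 * np.pi ** 2 * u_iso * s * s)
            else:
                expo = 0.0
                for i in range(3):
                    for j in range(3):
                        expo += ustar[i, j] * h[i] * h[j]
                dw = np.exp(-2 * np.pi ** 2 * expo)
            total += occ * f * dw * np.exp(2j * np.pi * float(h @ pos))
        out.append(total)
    return np.array(out)
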