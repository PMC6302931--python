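"""Kinematic structure factors from a crystal model.

Computes complex structure factors

    F(h) = sum_sym sum_atoms occ * f_elem(s) * T_adp * exp(2 pi i h.(Rx+t))

with electron form factors f(s), s = sin(theta)/lambda = 1/(2d) (this
convention is used everywhere in the package), isotropic Debye-Waller
factor T = exp(-8 pi^2 U_iso s^2), and anisotropic
T = exp(-2 pi^2 sum_ij U_ij h_i h_j a*_i a*_j) in the CIF U convention.
Symmetry is applied in reciprocal space: for an operator (R, t) both the
phase and the displacement factor are evaluated at the transformed index
h' = h.R, which is equivalent to expanding the atom to Rx+t with the
rotated U tensor.

Also provides CIF/PDB model readers, least-squares amplitude scaling and
the R1 residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import gemmi
import numpy as np

from .reflection_io import UnitCell
from .scattering_factors import (CromerMann9Coefficients, Gaussian5Coefficients,
                                 electron_form_factor, evaluate_form_factor)

__all__ = [
    "Atom",
    "CrystalModel",
    "parse_model_cif",
    "parse_model_pdb",
    "write_model_cif",
    "calc_structure_factors",
    "scale_amplitudes",
    "r1",
]

FormFactor = Union[Gaussian5Coefficients, CromerMann9Coefficients]


@dataclass
class Atom:
    """An atom in fractional coordinates with occupancy and ADP.

    ``u_aniso`` is (U11, U22, U33, U23, U13, U12) in A^2 (CIF order);
    if both ADP fields are None the atom scatters as if at rest.
    """

    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    u_iso: float | None = None
    u_aniso: tuple[float, float, float, float, float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("fractional coordinates must be finite")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")
        if self.u_iso is not None and self.u_iso < 0:
            raise ValueError("U_iso must be non-negative")
        if self.u_aniso is not None:
            m = self.u_matrix()
            if np.min(np.linalg.eigvalsh(m)) < -1e-3:
                raise ValueError(f"U_aniso of {self.label or self.element} "
                                 "is not positive-semidefinite")

    def u_matrix(self) -> np.ndarray:
        """Symmetric 3x3 U tensor (zeros if no aniso ADP)."""
        if self.u_aniso is None:
            u = self.u_iso or 0.0
            return np.eye(3) * u
        u11, u22, u33, u23, u13, u12 = self.u_aniso
        return np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])

    @property
    def frac(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    def u_equiv(self) -> float:
        """Equivalent isotropic U (trace/3 of the aniso tensor, or U_iso)."""
        if self.u_aniso is not None:
            return (self.u_aniso[0] + self.u_aniso[1] + self.u_aniso[2]) / 3.0
        return self.u_iso or 0.0


@dataclass
class CrystalModel:
    """Unit cell, symmetry operators and atoms — the source of |F_calc|."""

    cell: UnitCell
    atoms: list[Atom]
    symmetry: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    space_group_name: str = "P 1"

    def __post_init__(self) -> None:
        if not self.symmetry:
            self.symmetry = symmetry_from_spacegroup(self.space_group_name)

    @property
    def n_symmetry(self) -> int:
        return len(self.symmetry)

    def expanded_atoms(self) -> list[tuple[Atom, np.ndarray]]:
        """All symmetry copies as (source atom, fractional position) pairs."""
        return [(atom, rot @ atom.frac + tran)
                for atom in self.atoms for rot, tran in self.symmetry]

    def gemmi_spacegroup(self) -> gemmi.SpaceGroup:
        sg = gemmi.find_spacegroup_by_name(self.space_group_name)
        if sg is None:
            ops = gemmi.GroupOps([_to_gemmi_op(r, t) for r, t in self.symmetry])
            sg = gemmi.find_spacegroup_by_ops(ops)
        if sg is None:
            raise ValueError(f"unknown space group {self.space_group_name!r}")
        return sg


def _to_gemmi_op(rot: np.ndarray, tran: np.ndarray) -> gemmi.Op:
    op = gemmi.Op()
    op.rot = [[int(round(v * gemmi.Op.DEN)) for v in row] for row in rot]
    op.tran = [int(round(v * gemmi.Op.DEN)) for v in tran]
    return op


def symmetry_from_spacegroup(name: str) -> list[tuple[np.ndarray, np.ndarray]]:
    sg = gemmi.find_spacegroup_by_name(name)
    if sg is None:
        raise ValueError(f"unknown space group {name!r}")
    return [(np.array(op.rot, float) / gemmi.Op.DEN,
             np.array(op.tran, float) / gemmi.Op.DEN)
            for op in sg.operations()]


def _inherit_hydrogen_adps(atoms: list[Atom], cell: UnitCell) -> None:
    """Riding convention: H atoms without an ADP take 1.2x the equivalent
    isotropic U of the nearest non-hydrogen atom."""
    heavies = [a for a in atoms if a.element != "H"]
    if not heavies:
        return
    g = cell.metric_tensor
    for atom in atoms:
        if atom.element == "H" and atom.u_iso is None and atom.u_aniso is None:
            best, best_d2 = None, np.inf
            for heavy in heavies:
                delta = heavy.frac - atom.frac
                delta -= np.round(delta)
                d2 = delta @ g @ delta
                if d2 < best_d2:
                    best, best_d2 = heavy, d2
            atom.u_iso = 1.2 * best.u_equiv()


def parse_model_cif(source: Union[str, Path], block: str | None = None
                    ) -> CrystalModel:
    """Read a small-molecule crystal model from CIF.

    Requires a cell and an atom-site loop; symmetry comes from the xyz
    operator loop when present, otherwise from the space-group name.
    Anisotropic ADP entries are matched to atom labels; an aniso label
    with no matching atom is an error.
    """
    doc = gemmi.cif.read(str(source))
    blk = doc[block] if block is not None else doc.sole_block()

    # validation gemmi's reader does silently
    labels = set(blk.find_values("_atom_site_label"))
    aniso_labels = list(blk.find_values("_atom_site_aniso_label"))
    for al in aniso_labels:
        if al not in labels:
            raise ValueError(f"aniso entry {al!r} has no matching atom site")

    small = gemmi.read_small_structure(str(source))
    if small.cell.a == 0 or small.cell.volume == 0:
        raise ValueError("CIF is missing unit-cell parameters")
    if not small.sites:
        raise ValueError("CIF contains no atom-site loop")
    cell = UnitCell.from_gemmi(small.cell)

    atoms: list[Atom] = []
    for site in small.sites:
        el = site.type_symbol or site.element.name
        el = "".join(ch for ch in el if ch.isalpha())
        aniso = None
        if site.aniso.nonzero():
            a = site.aniso
            aniso = (a.u11, a.u22, a.u33, a.u23, a.u13, a.u12)
        u_iso = site.u_iso if (site.u_iso and aniso is None) else None
        atoms.append(Atom(element=el.capitalize(), x=site.fract.x,
                          y=site.fract.y, z=site.fract.z,
                          occupancy=site.occ or 1.0,
                          u_iso=u_iso, u_aniso=aniso, label=site.label))

    if small.symops:
        sym = [(np.array(gemmi.Op(s).rot, float) / gemmi.Op.DEN,
                np.array(gemmi.Op(s).tran, float) / gemmi.Op.DEN)
               for s in small.symops]
        name = small.spacegroup_hm or "P 1"
    elif small.spacegroup_hm:
        sym = symmetry_from_spacegroup(small.spacegroup_hm)
        name = small.spacegroup_hm
    else:
        sym = symmetry_from_spacegroup("P 1")
        name = "P 1"

    _inherit_hydrogen_adps(atoms, cell)
    return CrystalModel(cell=cell, atoms=atoms, symmetry=sym,
                        space_group_name=name)


def parse_model_pdb(source: Union[str, Path]) -> CrystalModel:
    """Read a protein model from PDB-style ATOM/ANISOU records."""
    st = gemmi.read_structure(str(source))
    st.setup_entities()
    cell = UnitCell.from_gemmi(st.cell)
    name = st.spacegroup_hm or "P 1"
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    frac = st.cell.fractionalize(at.pos)
                    aniso = None
                    if at.aniso.nonzero():
                        a = at.aniso
                        aniso = (a.u11, a.u22, a.u33, a.u23, a.u13, a.u12)
                    atoms.append(Atom(
                        element=at.element.name, x=frac.x, y=frac.y, z=frac.z,
                        occupancy=min(at.occ, 1.0) or 1.0,
                        u_iso=None if aniso else at.b_iso / (8 * math.pi ** 2),
                        u_aniso=aniso, label=at.name))
        break  # first model only
    return CrystalModel(cell=cell, atoms=atoms,
                        symmetry=symmetry_from_spacegroup(name),
                        space_group_name=name)


def write_model_cif(model: CrystalModel, dest: Union[str, Path],
                    block_name: str = "model") -> None:
    """Write a crystal model as a minimal core-dictionary CIF."""
    cell = model.cell
    lines = [
        f"data_{block_name}",
        f"_cell_length_a {cell.a:.6f}",
        f"_cell_length_b {cell.b:.6f}",
        f"_cell_length_c {cell.c:.6f}",
        f"_cell_angle_alpha {cell.alpha:.4f}",
        f"_cell_angle_beta {cell.beta:.4f}",
        f"_cell_angle_gamma {cell.gamma:.4f}",
        f"_space_group_name_H-M_alt '{model.space_group_name}'",
        "loop_",
        "_space_group_symop_operation_xyz",
    ]
    for rot, tran in model.symmetry:
        lines.append(f"'{_to_gemmi_op(rot, tran).triplet()}'")
    lines += ["loop_", "_atom_site_label", "_atom_site_type_symbol",
              "_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z",
              "_atom_site_occupancy", "_atom_site_U_iso_or_equiv"]
    for i, a in enumerate(model.atoms):
        label = a.label or f"{a.element}{i + 1}"
        lines.append(f"{label} {a.element} {a.x:.8f} {a.y:.8f} {a.z:.8f} "
                     f"{a.occupancy:.6f} {a.u_equiv():.8f}")
    aniso = [(a.label or f"{a.element}{i + 1}", a.u_aniso)
             for i, a in enumerate(model.atoms) if a.u_aniso is not None]
    if aniso:
        lines += ["loop_", "_atom_site_aniso_label"] + [
            f"_atom_site_aniso_U_{ij}" for ij in
            ("11", "22", "33", "23", "13", "12")]
        for label, u in aniso:
            lines.append(label + " " + " ".join(f"{v:.8f}" for v in u))
    Path(dest).write_text("\n".join(lines) + "\n")


def calc_structure_factors(
    model: CrystalModel,
    hkl: Sequence[Sequence[int]] | np.ndarray,
    tables: dict[str, FormFactor] | None = None,
) -> np.ndarray:
    """Complex kinematic structure factors for a list of reflections.

    ``tables`` maps element symbols to form-factor coefficients; elements
    not listed fall back to the built-in electron table. Unknown elements
    raise ``KeyError`` naming the element.
    """
    hkl = np.asarray(hkl, dtype=float).reshape(-1, 3)
    n = len(hkl)
    cell = model.cell
    d = cell.d_spacing(hkl.astype(int))
    d = np.atleast_1d(d)
    s = 1.0 / (2.0 * d)
    s2 = s * s

    tables = tables or {}
    ff: dict[str, np.ndarray] = {}
    for el in {a.element for a in model.atoms}:
        coeffs = tables.get(el)
        if coeffs is None:
            try:
                coeffs = electron_form_factor(el)
            except KeyError:
                raise KeyError(f"no scattering coefficients for element {el!r}")
        ff[el] = np.atleast_1d(evaluate_form_factor(coeffs, s))

    # reciprocal axis lengths for the CIF aniso convention
    astar = np.sqrt(np.diag(cell.reciprocal_metric_tensor))

    pos = np.array([a.frac for a in model.atoms])            # (m, 3)
    occ = np.array([a.occupancy for a in model.atoms])       # (m,)
    fmat = np.column_stack([ff[a.element] for a in model.atoms])  # (n, m)

    iso_mask = np.array([a.u_aniso is None for a in model.atoms])
    u_iso = np.array([a.u_iso or 0.0 if a.u_aniso is None else 0.0
                      for a in model.atoms])
    ustar = []  # scaled tensors for aniso atoms: U*_ij = U_ij a*_i a*_j
    for a in model.atoms:
        if a.u_aniso is None:
            ustar.append(None)
        else:
            ustar.append(a.u_matrix() * np.outer(astar, astar))

    F = np.zeros(n, dtype=complex)
    two_pi_i = 2j * np.pi
    for rot, tran in model.symmetry:
        hp = hkl @ rot                                       # (n, 3)
        phase_t = np.exp(two_pi_i * (hkl @ tran))            # (n,)
        phases = np.exp(two_pi_i * (hp @ pos.T))             # (n, m)
        T = np.empty((n, len(model.atoms)))
        if iso_mask.any():
            T[:, iso_mask] = np.exp(-8 * np.pi ** 2
                                    * np.outer(s2, u_iso[iso_mask]))
        for j, u in enumerate(ustar):
            if u is not None:
                expo = -2 * np.pi ** 2 * np.einsum("ni,ij,nj->n", hp, u, hp)
                T[:, j] = np.exp(expo)
        F += phase_t * np.sum(occ * fmat * T * phases, axis=1)
    return F


def scale_amplitudes(f_obs: np.ndarray, f_calc: np.ndarray) -> float:
    """Least-squares scale k minimizing sum(|F_obs| - k |F_calc|)^2.

    Observed amplitudes divided by k are on the calculated scale.
    """
    fo = np.abs(np.asarray(f_obs, float))
    fc = np.abs(np.asarray(f_calc, float))
    if len(fo) != len(fc):
        raise ValueError("F_obs and F_calc must be paired")
    den = np.sum(fc * fc)
    if den == 0:
        raise ValueError("all F_calc are zero; scale undefined")
    return float(np.sum(fo * fc) / den)


def r1(f_obs: np.ndarray, f_calc: np.ndarray) -> float:
    """R1 = sum||F_obs| - |F_calc|| / sum|F_obs| on a common scale."""
    fo = np.abs(np.asarray(f_obs, float))
    fc = np.abs(np.asarray(f_calc, float))
    den = fo.sum()
    if den == 0:
        raise ValueError("sum |F_obs| is zero; R1 undefined")
    return float(np.sum(np.abs(fo - fc)) / den)
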