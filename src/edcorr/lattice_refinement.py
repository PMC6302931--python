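"""Restraint-based unit-cell refinement.

In electron diffraction the unit-cell dimensions and the effective
detector distance are strongly correlated and cannot both be calibrated
from the diffraction geometry alone. The lattice can instead be refined
against idealized model geometry: holding the fractional coordinates
fixed, the cell parameters are adjusted to minimize the weighted squared
deviation of model interatomic distances from their restraint targets
(SHELX DFIX 1-2 distances and DANG 1-3 distances).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .kinematic_sf import CrystalModel
from .reflection_io import UnitCell

__all__ = [
    "Restraint",
    "RestraintSet",
    "parse_restraints",
    "refine_cell",
    "solvent_cube_side",
]

_CELL_PARAMS = ("a", "b", "c", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class Restraint:
    """A target interatomic distance with its standard uncertainty."""

    kind: str  # "DFIX" (1-2) or "DANG" (1-3)
    target: float
    sigma: float
    atom_pair: tuple[str, str]

    def __post_init__(self) -> None:
        if self.kind not in ("DFIX", "DANG"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.target <= 0:
            raise ValueError("restraint target must be positive")
        if self.sigma <= 0:
            raise ValueError("restraint sigma must be positive")


@dataclass
class RestraintSet:
    restraints: list[Restraint]
    source: str = ""

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)


_DEFAULT_SIGMA = {"DFIX": 0.02, "DANG": 0.04}


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def parse_restraints(lines: Iterable[str] | str,
                     source: str = "") -> RestraintSet:
    """Parse SHELX-style DFIX/DANG instruction lines.

    Each instruction carries a target distance, an optional sigma
    (SHELX defaults: 0.02 A for DFIX, 0.04 A for DANG) and an even
    number of atom labels expanded pairwise in order. Lines with an odd
    atom count raise; unknown instructions are skipped with a warning.
    """
    if isinstance(lines, str):
        lines = lines.splitlines()
    restraints: list[Restraint] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("!")[0].strip()
        if not line:
            continue
        tokens = line.split()
        kind = tokens[0].upper()
        if kind not in ("DFIX", "DANG"):
            warnings.warn(f"line {lineno}: skipping unknown instruction "
                          f"{tokens[0]!r}")
            continue
        if len(tokens) < 2 or not _is_number(tokens[1]):
            raise ValueError(f"line {lineno}: {kind} needs a target distance")
        target = float(tokens[1])
        rest = tokens[2:]
        if rest and _is_number(rest[0]):
            sigma = float(rest[0])
            rest = rest[1:]
        else:
            sigma = _DEFAULT_SIGMA[kind]
        if not rest or len(rest) % 2:
            raise ValueError(
                f"line {lineno}: {kind} requires an even number of atom "
                f"labels, got {len(rest)}")
        for i in range(0, len(rest), 2):
            restraints.append(Restraint(kind=kind, target=target, sigma=sigma,
                                        atom_pair=(rest[i], rest[i + 1])))
    return RestraintSet(restraints, source=source)


def _resolve_pairs(model: CrystalModel, restraints: RestraintSet
                   ) -> list[tuple[np.ndarray, np.ndarray, float, float]]:
    by_label = {a.label: a for a in model.atoms}
    pairs = []
    for r in restraints:
        try:
            a1 = by_label[r.atom_pair[0]]
            a2 = by_label[r.atom_pair[1]]
        except KeyError as exc:
            raise ValueError(f"restraint atom {exc.args[0]!r} not in model")
        pairs.append((a1.frac, a2.frac, r.target, r.sigma))
    return pairs


def _min_image_distance(x1: np.ndarray, x2: np.ndarray, g: np.ndarray,
                        symmetry) -> float:
    """Distance to the nearest symmetry/lattice image of the second atom."""
    best = math.inf
    for rot, tran in symmetry:
        delta = rot @ x2 + tran - x1
        delta -= np.round(delta)
        d2 = delta @ g @ delta
        if d2 < best:
            best = d2
    return math.sqrt(best)


def _build_cell(base: UnitCell, free: Sequence[str], x: np.ndarray) -> UnitCell:
    values = dict(a=base.a, b=base.b, c=base.c, alpha=base.alpha,
                  beta=base.beta, gamma=base.gamma)
    if free == ("cubic",):
        values["a"] = values["b"] = values["c"] = x[0]
    else:
        for name, v in zip(free, x):
            values[name] = v
    return UnitCell(**values)


def refine_cell(model: CrystalModel, restraints: RestraintSet,
                refine_mask: str | Sequence[str] = "orthorhombic",
                n_restarts: int = 2) -> tuple[UnitCell, dict]:
    """Refine cell parameters against distance restraints.

    Fractional coordinates are held fixed; only the unmasked cell
    parameters move. ``refine_mask`` is "orthorhombic" (a, b, c free,
    angles fixed), "cubic" (a = b = c, one parameter) or an explicit
    subset of ("a","b","c","alpha","beta","gamma"). Minimizes
    sum(((d_model - target)/sigma)^2) with distances taken to the nearest
    symmetry/lattice image, using a derivative-free simplex with
    restarts. Returns the refined cell and a report with the initial and
    final weighted residual and per-restraint deviations.
    """
    if len(restraints) == 0:
        raise ValueError("restraint set is empty")
    if refine_mask == "orthorhombic":
        free: tuple[str, ...] = ("a", "b", "c")
    elif refine_mask == "cubic":
        free = ("cubic",)
    else:
        free = tuple(refine_mask)
        bad = set(free) - set(_CELL_PARAMS)
        if bad:
            raise ValueError(f"unknown cell parameter(s) {sorted(bad)}")
    n_free = len(free)
    if len(restraints) < n_free:
        raise ValueError(
            f"under-determined: {len(restraints)} restraints for "
            f"{n_free} free cell parameters")

    pairs = _resolve_pairs(model, restraints)
    base = model.cell
    sym = model.symmetry

    def residual(x: np.ndarray) -> float:
        if np.any(x[:3 if free != ("cubic",) else 1] <= 0):
            return 1e30
        try:
            cell = _build_cell(base, free, x)
        except ValueError:
            return 1e30
        g = cell.metric_tensor
        total = 0.0
        for x1, x2, target, sigma in pairs:
            dmod = _min_image_distance(x1, x2, g, sym)
            total += ((dmod - target) / sigma) ** 2
        return total

    if free == ("cubic",):
        x0 = np.array([base.a])
    else:
        x0 = np.array([getattr(base, name) for name in free])
    initial = residual(x0)

    best_x, best_f = x0, initial
    xstart = x0
    for _ in range(n_restarts + 1):
        sol = minimize(residual, xstart, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-12,
                                "maxiter": 10_000})
        if sol.fun < best_f:
            best_x, best_f = sol.x, float(sol.fun)
        xstart = best_x
    # never report a cell worse than the start
    if best_f > initial:
        best_x, best_f = x0, initial

    final_cell = _build_cell(base, free, best_x)
    g = final_cell.metric_tensor
    deviations = []
    for (x1, x2, target, sigma), r in zip(pairs, restraints):
        dmod = _min_image_distance(x1, x2, g, sym)
        deviations.append({"kind": r.kind, "atoms": r.atom_pair,
                           "target": target, "model": dmod,
                           "delta": dmod - target, "sigma": sigma})
    report = {
        "initial_residual": initial,
        "final_residual": best_f,
        "free_parameters": free,
        "initial_cell": (base.a, base.b, base.c,
                         base.alpha, base.beta, base.gamma),
        "final_cell": (final_cell.a, final_cell.b, final_cell.c,
                       final_cell.alpha, final_cell.beta, final_cell.gamma),
        "deviations": deviations,
    }
    return final_cell, report


def solvent_cube_side(delta_volume: float, z: int) -> float:
    """Side of the cube whose volume is a per-molecule share of a cell
    volume change: (delta_volume / z)^(1/3).

    Used to interpret unit-cell shrinkage as lost solvent: e.g. a 90 A^3
    contraction in a Z = 4 cell corresponds to a 2.83 A cube per missing
    water molecule, close to the ~3 A cube one H2O occupies in liquid
    water.
    """
    if delta_volume <= 0:
        raise ValueError("delta_volume must be positive")
    if not isinstance(z, (int, np.integer)) or z < 1:
        raise ValueError("z must be a positive integer")
    return (delta_volume / z) ** (1.0 / 3.0)
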