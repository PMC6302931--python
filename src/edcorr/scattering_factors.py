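"""Electron atomic form factors and their 9-coefficient refit.

Electron scattering factors come tabulated as sums of five Gaussians
(the Peng parameterization, International Tables vol. C, table 4.3.2.2):

    f(s) = sum_{i=1..5} a_i exp(-b_i s^2),   s = sin(theta)/lambda  [1/A]

Small-molecule refinement programs in the SHELX family instead expect
the nine Cromer-Mann coefficients (four Gaussians plus a constant):

    f9(s) = sum_{i=1..4} a_i exp(-b_i s^2) + c

This module evaluates both forms and refits the 5-Gaussian curve to the
9-coefficient form by least squares over a working s-grid, so electron
data can be refined with programs built around the X-ray convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import gemmi
import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Gaussian5Coefficients",
    "CromerMann9Coefficients",
    "electron_form_factor",
    "load_coefficient_table",
    "evaluate_form_factor",
    "fit_cromer_mann9",
    "DEFAULT_ELEMENTS",
]

#: elements guaranteed present (covers C16O5H18 and C18O6N2S2H16 chemistry);
#: any element known to the underlying table can be requested as well.
DEFAULT_ELEMENTS = ("H", "C", "N", "O", "S")


@dataclass(frozen=True)
class Gaussian5Coefficients:
    """Five-Gaussian electron form factor for one element (b in A^2)."""

    element: str
    a: tuple[float, float, float, float, float]
    b: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.a) != 5 or len(self.b) != 5:
            raise ValueError("expected 5 a- and 5 b-coefficients")
        if any(bi < 0 for bi in self.b):
            raise ValueError("Gaussian widths b_i must be non-negative")
        if sum(self.a) <= 0:
            raise ValueError("f(0) = sum(a_i) must be positive")

    def __call__(self, s: float | np.ndarray) -> float | np.ndarray:
        return evaluate_form_factor(self, s)


@dataclass(frozen=True)
class CromerMann9Coefficients:
    """Four Gaussians plus constant (the SHELX SFAC convention)."""

    element: str
    a: tuple[float, float, float, float]
    b: tuple[float, float, float, float]
    c: float

    def __call__(self, s: float | np.ndarray) -> float | np.ndarray:
        return evaluate_form_factor(self, s)

    def sfac_line(self) -> str:
        """Coefficients in SHELX SFAC ordering: a1 b1 a2 b2 a3 b3 a4 b4 c."""
        parts = [f"{self.element:2s}"]
        for ai, bi in zip(self.a, self.b):
            parts.append(f"{ai:9.5f} {bi:9.5f}")
        parts.append(f"{self.c:9.5f}")
        return " ".join(parts)


def electron_form_factor(element: str) -> Gaussian5Coefficients:
    """Built-in 5-Gaussian electron form factor for an element symbol."""
    el = gemmi.Element(element)
    if el.name == "X" or not el.c4322.a:
        raise KeyError(f"no electron form factor available for {element!r}")
    coeffs = el.c4322
    return Gaussian5Coefficients(element=element,
                                 a=tuple(coeffs.a), b=tuple(coeffs.b))


def load_coefficient_table(source: Union[str, Path]) -> dict[str, Gaussian5Coefficients]:
    """Load user-supplied coefficients from CSV: element,a1..a5,b1..b5."""
    out: dict[str, Gaussian5Coefficients] = {}
    with open(source, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().startswith("#"):
                continue
            if len(row) != 11:
                raise ValueError(
                    f"expected 11 fields (element,a1..a5,b1..b5), got {len(row)}")
            el = row[0].strip()
            vals = [float(x) for x in row[1:]]
            out[el] = Gaussian5Coefficients(el, tuple(vals[:5]), tuple(vals[5:]))
    return out


def evaluate_form_factor(
    coeffs: Gaussian5Coefficients | CromerMann9Coefficients,
    s: float | np.ndarray,
) -> float | np.ndarray:
    """Evaluate f(s) with s = sin(theta)/lambda in 1/A; s must be >= 0."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("s = sin(theta)/lambda must be non-negative")
    s2 = s_arr * s_arr
    a = np.asarray(coeffs.a)
    b = np.asarray(coeffs.b)
    f = np.sum(a * np.exp(-b * s2[..., None]), axis=-1)
    if isinstance(coeffs, CromerMann9Coefficients):
        f = f + coeffs.c
    return float(f) if np.isscalar(s) or s_arr.ndim == 0 else f


def _default_grid() -> np.ndarray:
    return np.arange(0.0, 2.0 + 1e-12, 0.01)


def fit_cromer_mann9(
    source: Gaussian5Coefficients,
    s_grid: Sequence[float] | np.ndarray | None = None,
) -> tuple[CromerMann9Coefficients, float]:
    """Refit a 5-Gaussian form factor to 4 Gaussians plus a constant.

    Unweighted least squares on ``s_grid`` (default 0..2 1/A, step 0.01).
    Initialization keeps the four largest-amplitude source Gaussians and
    seeds the constant with the amplitude of the fifth; widths are bounded
    below by zero, so the fit is deterministic. Returns the coefficients
    and the maximum absolute residual over the grid.

    Raises ``RuntimeError`` (carrying the best residual reached) if the
    optimizer fails to converge.
    """
    grid = np.asarray(s_grid if s_grid is not None else _default_grid(), float)
    target = evaluate_form_factor(source, grid)

    order = np.argsort(source.a)[::-1]
    keep, drop = order[:4], order[4]
    a0 = np.array([source.a[i] for i in keep])
    b0 = np.array([max(source.b[i], 1e-6) for i in keep])
    c0 = source.a[drop]
    x0 = np.concatenate([a0, b0, [c0]])

    s2 = grid * grid

    def resid(x: np.ndarray) -> np.ndarray:
        a, b, c = x[:4], x[4:8], x[8]
        return np.sum(a * np.exp(-b * s2[:, None]), axis=1) + c - target

    lb = np.concatenate([np.full(4, -np.inf), np.zeros(4), [-np.inf]])
    ub = np.full(9, np.inf)
    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14,
                        gtol=1e-14, max_nfev=20000)
    max_resid = float(np.max(np.abs(sol.fun)))
    if not sol.success:
        raise RuntimeError(
            f"Cromer-Mann refit did not converge for {source.element}; "
            f"best max|residual| = {max_resid:.3e}")
    fitted = CromerMann9Coefficients(
        element=source.element,
        a=tuple(sol.x[:4]), b=tuple(sol.x[4:8]), c=float(sol.x[8]))
    return fitted, max_resid
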