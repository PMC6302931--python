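"""Synthetic reflection data with known kinematic truth.

The generator draws, for every unique reflection, a complex-valued
dynamical component F_dyn uncorrelated with the kinematic structure
factor — independent Gaussian real/imaginary parts with standard
deviation eps(d)/sqrt(2), so E|F_dyn|^2 = eps(d)^2 — and records

    I_obs = |F_kin + F_dyn|^2  (+ optional counting noise).

This reproduces the statistical signature the correction targets: weak
reflections are overestimated on average (E[I_obs] = I_kin + eps^2, a
fixed additive excess that is relatively largest for weak I_kin) while
strong reflections are nearly untouched in relative terms. Because the
perturbation is drawn independently per reflection, no inter-reflection
intensity coupling of real dynamical diffraction is emulated; recovery
tests on these data validate the estimator and the correction algebra,
not the physics of any particular crystal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .dynamical_correction import DynamicalErrorModel
from .kinematic_sf import Atom, CrystalModel, calc_structure_factors, \
    symmetry_from_spacegroup
from .reflection_io import ReflectionSet, UnitCell, laue_canonical_hkl

__all__ = [
    "SimulationConfig",
    "random_toy_structure",
    "unique_reflections",
    "simulate_observed",
    "default_toy_model",
    "DEFAULT_ELEMENT_MIX",
]

NoiseSpec = tuple  # ("none",) | ("gaussian", sigma) | ("poisson", scale)

#: organic-like element mix (roughly C3NO2S, cf. small pharmaceuticals)
DEFAULT_ELEMENT_MIX = ("C", "C", "C", "N", "O", "O", "S")


def default_toy_model(seed: int = 11) -> CrystalModel:
    """The package's default study-condition structure: 24 atoms of an
    organic-like element mix in an 11 x 12 x 13 A P1 cell.

    At d_min = 0.8 A this yields >5000 unique reflections whose
    amplitude distribution sits a factor of a few above a dynamical
    error term of ~2 (amplitude units) — strong reflections well clear
    of it, the weakest shell comparable to it — mirroring the regime of
    sub-angstrom organic 3D electron diffraction data.
    """
    return random_toy_structure(24, UnitCell(11.0, 12.0, 13.0),
                                elements=DEFAULT_ELEMENT_MIX, seed=seed)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``epsilon`` is either a constant (amplitude units) or a full
    resolution-dependent error model. ``n_reflections`` optionally trims
    the generated set to the N lowest-resolution (largest d) uniques.
    """

    model: CrystalModel
    d_min: float = 0.8
    epsilon: Union[float, DynamicalErrorModel] = 2.0
    noise: NoiseSpec = ("none",)
    seed: int = 0
    n_crystals: int = 1
    n_reflections: int | None = None

    def __post_init__(self) -> None:
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic simulation")
        if self.n_crystals < 1:
            raise ValueError("n_crystals must be >= 1")
        kind = self.noise[0]
        if kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {kind!r}")

    def epsilon_model(self) -> DynamicalErrorModel:
        if isinstance(self.epsilon, DynamicalErrorModel):
            return self.epsilon
        return DynamicalErrorModel.constant(float(self.epsilon))


def random_toy_structure(n_atoms: int, cell: UnitCell,
                         elements: Sequence[str] = ("C", "N", "O"),
                         seed: int = 0, spacegroup: str = "P 1",
                         min_dist: float = 1.0,
                         max_rejections: int = 10_000) -> CrystalModel:
    """Random crystal model with a minimum-distance rejection rule.

    Atoms are placed uniformly in the cell; a candidate is rejected if
    any symmetry image of an already placed atom (or of itself) lies
    closer than ``min_dist``. U_iso is drawn from [0.01, 0.05] A^2.
    Deterministic given the seed.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    sym = symmetry_from_spacegroup(spacegroup)
    g = cell.metric_tensor
    placed: list[np.ndarray] = []
    atoms: list[Atom] = []
    rejections = 0
    while len(atoms) < n_atoms:
        cand = rng.random(3)
        ok = True
        images = [rot @ cand + tran for rot, tran in sym]
        # self-clash across symmetry copies (skip the identity pairing)
        for img in images[1:]:
            delta = img - cand
            delta -= np.round(delta)
            if delta @ g @ delta < min_dist ** 2:
                ok = False
                break
        if ok:
            for prev in placed:
                for img in images:
                    delta = img - prev
                    delta -= np.round(delta)
                    if delta @ g @ delta < min_dist ** 2:
                        ok = False
                        break
                if not ok:
                    break
        if not ok:
            rejections += 1
            if rejections > max_rejections:
                raise RuntimeError(
                    f"could not place {n_atoms} atoms with min_dist="
                    f"{min_dist} A after {max_rejections} rejections")
            continue
        placed.append(cand)
        atoms.append(Atom(element=str(rng.choice(list(elements))),
                          x=float(cand[0]), y=float(cand[1]), z=float(cand[2]),
                          occupancy=1.0,
                          u_iso=float(rng.uniform(0.01, 0.05)),
                          label=f"X{len(atoms) + 1}"))
    return CrystalModel(cell=cell, atoms=atoms, symmetry=sym,
                        space_group_name=spacegroup)


def unique_reflections(cell: UnitCell, spacegroup: str, d_min: float,
                       d_max: float | None = None) -> np.ndarray:
    """Unique Miller indices (Laue-reduced, systematic absences removed)
    with d >= d_min, sorted by d descending then (h,k,l)."""
    import gemmi

    sg = gemmi.SpaceGroup(spacegroup)
    ops = sg.operations()
    hmax = int(cell.a / d_min) + 1
    kmax = int(cell.b / d_min) + 1
    lmax = int(cell.c / d_min) + 1
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacing(hkl)
    sel = d >= d_min
    if d_max is not None:
        sel &= d <= d_max
    hkl = hkl[sel]
    canon = np.unique(laue_canonical_hkl(hkl, sg), axis=0)
    absent = np.array([ops.is_systematically_absent(list(x)) for x in canon])
    canon = canon[~absent]
    d = cell.d_spacing(canon)
    order = np.lexsort((canon[:, 2], canon[:, 1], canon[:, 0], -d))
    return canon[order]


def simulate_observed(config: SimulationConfig
                      ) -> tuple[ReflectionSet, pd.DataFrame]:
    """Simulate observed intensities with a known dynamical perturbation.

    Returns the (possibly multi-crystal, unmerged) reflection set and a
    truth table with per-reflection h, k, l, d, |F_kin| and eps(d).
    With ``n_crystals > 1`` each crystal wedge gets an independent
    log-normal(0, 0.1) overall scale, exercising the merging statistics.
    """
    model = config.model
    cell = model.cell
    rng = np.random.default_rng(config.seed)
    hkl = unique_reflections(cell, model.space_group_name, config.d_min)
    d = cell.d_spacing(hkl)
    if config.n_reflections is not None:
        if config.n_reflections > len(hkl):
            raise ValueError(
                f"requested {config.n_reflections} reflections but only "
                f"{len(hkl)} unique to d_min={config.d_min}")
        hkl = hkl[:config.n_reflections]
        d = d[:config.n_reflections]

    f_kin = np.abs(calc_structure_factors(model, hkl))
    eps_model = config.epsilon_model()
    eps = np.atleast_1d(eps_model.epsilon(d))

    all_hkl, all_i, all_s = [], [], []
    for _ in range(config.n_crystals):
        re = rng.normal(0.0, eps / np.sqrt(2.0))
        im = rng.normal(0.0, eps / np.sqrt(2.0))
        i_obs = (f_kin + re) ** 2 + im ** 2
        kind = config.noise[0]
        if kind == "none":
            sigma = np.zeros_like(i_obs)
        elif kind == "gaussian":
            noise_sd = float(config.noise[1])
            i_obs = i_obs + rng.normal(0.0, noise_sd, size=i_obs.shape)
            sigma = np.full_like(i_obs, noise_sd)
        else:  # poisson counting on a scaled intensity
            scale = float(config.noise[1])
            counts = rng.poisson(np.maximum(i_obs, 0.0) * scale)
            i_obs = counts / scale
            sigma = np.sqrt(np.maximum(counts, 1)) / scale
        if config.n_crystals > 1:
            crystal_scale = rng.lognormal(0.0, 0.1)
            i_obs = i_obs * crystal_scale
            sigma = sigma * crystal_scale
        all_hkl.append(hkl)
        all_i.append(i_obs)
        all_s.append(sigma)

    rset = ReflectionSet(np.vstack(all_hkl), np.concatenate(all_i),
                         np.concatenate(all_s), cell=cell,
                         merged=config.n_crystals == 1)
    truth = pd.DataFrame({
        "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
        "d": d, "f_kin": f_kin, "epsilon_d": eps,
    })
    return rset, truth
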