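"""Likelihood-based correction of dynamical scattering.

Dynamical (multiple elastic) scattering redistributes intensity from
strong Bragg reflections into weak ones, so weak observed intensities
are systematically overestimated relative to the kinematic value.
Modelling the dynamical contribution as a complex-valued component
uncorrelated with the kinematic structure factor, the expected observed
amplitude follows the hyperbola

    <|F_obs|> = (|F_kin|^2 + eps_dyn^2)^(1/2)

whose y-intercept eps_dyn is the dynamical error term, generally a
function of resolution d. The factor by which an expected intensity is
inflated,

    k_dyn = (I_kin + eps(d)^2) / I_kin,

is the reciprocal of a generalized Wiener filter, and its inverse is the
correction weight applied to the observed data:

    I_corr = I_obs / k_dyn = I_obs * I~ / (I~ + eps(d)^2)

where the unknown kinematic intensity is replaced by the plug-in
estimate I~ = max(I_obs - eps(d)^2, sigma): since E[I_obs] = I_kin +
eps^2 under the model, subtracting the expected dynamical power is the
natural moment estimate of I_kin, and the sigma floor keeps the factor
meaningful for weak, zero or negative measurements, which are retained
and down-weighted most strongly. Sigmas are scaled by the same factor,
so I/sigma is preserved. Amplitude data (the protein case) use the
amplitude-domain square root of the same factor with a
per-resolution-bin discrete eps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinematic_sf import r1, scale_amplitudes
from .reflection_io import ReflectionSet, ResolutionBinning

__all__ = [
    "DynamicalErrorModel",
    "CorrectionReport",
    "fit_epsilon",
    "fit_epsilon_binned",
    "fit_continuous",
    "fit_scale_and_epsilon",
    "k_dyn",
    "correct_intensities",
    "correct_amplitudes",
]

ContinuousForm = Literal["constant", "linear", "exp2", "discrete"]


@dataclass
class DynamicalErrorModel:
    """Resolution-dependent dynamical error term eps_dyn(d).

    ``form`` selects the continuous model: "constant" (global eps),
    "linear" eps(d) = a*d + b, "exp2" eps(d) = a*exp(b*d) + c*exp(e*d),
    or "discrete" (step function through the per-bin values). Evaluation
    clamps d to the fitted range [d_fit_min, d_fit_max] (no extrapolation)
    and clamps eps below zero to zero.
    """

    form: ContinuousForm
    params: tuple[float, ...] = ()
    epsilon_global: float = 0.0
    bins: list[tuple[float, float]] = field(default_factory=list)  # (mean_d, eps)
    binning: ResolutionBinning | None = None

    def __post_init__(self) -> None:
        if self.epsilon_global < 0:
            raise ValueError("epsilon_global must be non-negative")
        if any(e < 0 for _, e in self.bins):
            raise ValueError("per-bin epsilon values must be non-negative")

    @classmethod
    def constant(cls, epsilon: float) -> "DynamicalErrorModel":
        return cls(form="constant", params=(epsilon,), epsilon_global=epsilon)

    @property
    def d_fit_range(self) -> tuple[float, float] | None:
        if not self.bins:
            return None
        ds = [d for d, _ in self.bins]
        return min(ds), max(ds)

    def epsilon(self, d: float | np.ndarray) -> float | np.ndarray:
        """eps_dyn at resolution d (A); clamped to the fitted range and >= 0."""
        d_arr = np.atleast_1d(np.asarray(d, float))
        rng = self.d_fit_range
        if rng is not None and self.form != "constant":
            d_arr = np.clip(d_arr, rng[0], rng[1])
        if self.form == "constant":
            eps = np.full_like(d_arr, self.params[0] if self.params
                               else self.epsilon_global)
        elif self.form == "linear":
            a, b = self.params
            eps = a * d_arr + b
        elif self.form == "exp2":
            a, b, c, e = self.params
            eps = a * np.exp(b * d_arr) + c * np.exp(e * d_arr)
        elif self.form == "discrete":
            mean_ds = np.array([x for x, _ in self.bins])
            vals = np.array([e for _, e in self.bins])
            if self.binning is not None:
                eps = np.array([vals[self.binning.bin_of(x)] for x in d_arr])
            else:  # nearest bin centre
                idx = np.argmin(np.abs(d_arr[:, None] - mean_ds[None, :]), axis=1)
                eps = vals[idx]
        else:
            raise ValueError(f"unknown form {self.form!r}")
        eps = np.maximum(eps, 0.0)
        return float(eps[0]) if np.isscalar(d) or np.ndim(d) == 0 else eps

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "params": list(self.params),
            "epsilon_global": self.epsilon_global,
            "bins": [[d, e] for d, e in self.bins],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DynamicalErrorModel":
        return cls(form=data["form"], params=tuple(data.get("params", ())),
                   epsilon_global=data.get("epsilon_global", 0.0),
                   bins=[tuple(b) for b in data.get("bins", [])])


@dataclass
class CorrectionReport:
    """What a correction pass did: per-reflection factors and summaries."""

    factors: np.ndarray
    epsilon_pre: float | None = None
    epsilon_post: float | None = None
    r1_pre: float | None = None
    r1_post: float | None = None
    bin_table: pd.DataFrame | None = None


def fit_epsilon(f_obs: Sequence[float] | np.ndarray,
                f_calc: Sequence[float] | np.ndarray) -> float:
    """Global dynamical error term from paired amplitudes.

    Fits the hyperbola <|F_obs|> = (|F_calc|^2 + eps^2)^(1/2) by least
    squares in the squared ordinate, i.e. minimizes
    sum(|F_obs|^2 - |F_calc|^2 - eps^2)^2 over eps >= 0. Measuring the
    residual on the squared amplitudes makes the estimator a consistent
    method of moments for the expected dynamical power E|F_dyn|^2 =
    eps^2 (the relation is exact in second moments for an uncorrelated
    complex perturbation, whereas the mean observed *amplitude* of a
    strong reflection picks up only half the quadrature excess, so an
    amplitude-residual fit would underestimate eps by up to sqrt(2)).
    The minimizer has the closed form eps^2 = mean(|F_obs|^2 -
    |F_calc|^2), clamped at zero.

    F_obs must already be on the F_calc scale (see ``scale_amplitudes``
    or ``fit_scale_and_epsilon``).
    """
    fo = np.abs(np.asarray(f_obs, float))
    fc = np.abs(np.asarray(f_calc, float))
    if fo.size == 0:
        raise ValueError("cannot fit epsilon on empty input")
    if len(fo) != len(fc):
        raise ValueError("F_obs and F_calc must be paired")
    eps_sq = float(np.mean(fo * fo - fc * fc))
    return math.sqrt(eps_sq) if eps_sq > 0 else 0.0


def fit_epsilon_binned(f_obs: np.ndarray, f_calc: np.ndarray,
                       binning: ResolutionBinning,
                       min_bin_size: int = 5) -> list[tuple[float, float]]:
    """Per-resolution-bin epsilon fits: list of (mean_d, eps_bin).

    The binning must have been computed on the same reflection order.
    Bins with fewer than ``min_bin_size`` reflections fall back to the
    global fit with a warning.
    """
    fo = np.abs(np.asarray(f_obs, float))
    fc = np.abs(np.asarray(f_calc, float))
    eps_global = None
    out = []
    for bi, idx in enumerate(binning.bin_indices):
        if len(idx) < min_bin_size:
            if eps_global is None:
                eps_global = fit_epsilon(fo, fc)
            warnings.warn(f"bin {bi} has {len(idx)} < {min_bin_size} "
                          "reflections; using global epsilon")
            out.append((float(binning.mean_d[bi]), eps_global))
        else:
            out.append((float(binning.mean_d[bi]),
                        fit_epsilon(fo[idx], fc[idx])))
    return out


def fit_continuous(bins: Sequence[tuple[float, float]],
                   form: ContinuousForm = "linear",
                   binning: ResolutionBinning | None = None,
                   n_starts: int = 8, seed: int = 0) -> DynamicalErrorModel:
    """Fit a continuous eps(d) model through per-bin (mean_d, eps) points.

    ``linear``: eps = a*d + b by ordinary least squares.
    ``exp2``: eps = a*exp(b*d) + c*exp(e*d) by multi-start nonlinear least
    squares; falls back to ``discrete`` with a warning on non-convergence.
    ``discrete``: step function through the bins themselves.
    """
    bins = [(float(d), float(e)) for d, e in bins]
    ds = np.array([d for d, _ in bins])
    es = np.array([e for _, e in bins])
    eps_global = float(np.mean(es))

    if form == "discrete":
        return DynamicalErrorModel(form="discrete", bins=bins,
                                   epsilon_global=eps_global, binning=binning)
    if form == "linear":
        if len(bins) < 2:
            raise ValueError("linear fit needs >= 2 bins")
        a, b = np.polyfit(ds, es, 1)
        return DynamicalErrorModel(form="linear", params=(float(a), float(b)),
                                   bins=bins, epsilon_global=eps_global,
                                   binning=binning)
    if form == "exp2":
        if len(bins) < 4:
            raise ValueError("exp2 fit needs >= 4 bins")

        def resid(x):
            a, b, c, e = x
            return a * np.exp(b * ds) + c * np.exp(e * ds) - es

        rng = np.random.default_rng(seed)
        scale = max(np.max(np.abs(es)), 1e-6)
        best = None
        starts = [np.array([scale, 0.1, -scale, -1.0]),
                  np.array([scale, -0.5, 0.0, 0.0])]
        while len(starts) < n_starts:
            starts.append(np.array([
                scale * rng.uniform(0.1, 3.0),
                rng.uniform(-2.0, 2.0),
                scale * rng.uniform(-3.0, 3.0),
                rng.uniform(-4.0, 1.0)]))
        for x0 in starts:
            try:
                sol = least_squares(resid, x0, xtol=1e-14, ftol=1e-14,
                                    gtol=1e-14, max_nfev=10000)
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            warnings.warn("exp2 fit did not converge; "
                          "falling back to discrete bins")
            return DynamicalErrorModel(form="discrete", bins=bins,
                                       epsilon_global=eps_global,
                                       binning=binning)
        return DynamicalErrorModel(form="exp2", params=tuple(map(float, best.x)),
                                   bins=bins, epsilon_global=eps_global,
                                   binning=binning)
    raise ValueError(f"unknown continuous form {form!r}")


def fit_scale_and_epsilon(f_obs: np.ndarray, f_calc: np.ndarray,
                          rtol: float = 1e-8, max_rounds: int = 50
                          ) -> tuple[float, float]:
    """Alternating fit of the observed->calculated scale and epsilon.

    Works on the squared amplitudes, where the model is linear:
    E|F_obs|^2 = k^2 (|F_calc|^2 + eps^2). The scale step regresses the
    observed on the predicted squared amplitudes through the origin; the
    epsilon step refits on the rescaled data. Both moment conditions
    hold exactly at the true parameters, so the alternation converges to
    a consistent joint estimate (relative tolerance ``rtol``, at most
    ``max_rounds`` rounds). Returns (scale k, eps) with eps on the
    calculated scale.
    """
    fo = np.abs(np.asarray(f_obs, float))
    fc = np.abs(np.asarray(f_calc, float))
    io = fo * fo
    ic = fc * fc
    eps = 0.0
    k = scale_amplitudes(fo, fc)
    for _ in range(max_rounds):
        eps_new = fit_epsilon(fo / k, fc)
        pred = ic + eps_new * eps_new
        den = float(pred @ pred)
        if den == 0:
            raise ValueError("all predicted intensities are zero")
        k_new = math.sqrt(max(float(io @ pred) / den, 1e-300))
        dk = abs(k_new - k) / max(abs(k), 1e-30)
        de = abs(eps_new - eps) / max(abs(eps), 1e-30) if eps else np.inf
        k, eps = k_new, eps_new
        if dk < rtol and (de < rtol or eps == 0.0):
            break
    return k, eps


def k_dyn(i_kin: float | np.ndarray, d: float | np.ndarray,
          model: DynamicalErrorModel) -> float | np.ndarray:
    """Intensity inflation factor k_dyn = (I_kin + eps(d)^2)/I_kin >= 1.

    Requires I_kin > 0; callers correcting measured data must floor the
    intensity first (see ``correct_intensities``).
    """
    i_arr = np.asarray(i_kin, float)
    if np.any(i_arr <= 0):
        raise ValueError("k_dyn requires positive kinematic intensity")
    eps = model.epsilon(d)
    out = (i_arr + np.square(eps)) / i_arr
    return float(out) if np.ndim(i_kin) == 0 else out


def correct_intensities(rset: ReflectionSet, model: DynamicalErrorModel,
                        f_calc: np.ndarray | None = None
                        ) -> tuple[ReflectionSet, CorrectionReport]:
    """Down-weight observed intensities (and sigmas) by 1/k_dyn.

    The kinematic intensity inside the factor is the plug-in estimate
    I~ = max(I_obs - eps(d)^2, sigma) (see the module docstring); weak
    and negative observations are retained and get the factor evaluated
    at the floor. When ``f_calc`` amplitudes are supplied the report
    carries pre/post epsilon and R1.
    """
    d = rset.d
    eps = np.atleast_1d(model.epsilon(d))
    i_obs = rset.intensity
    i_tilde = np.maximum(i_obs - eps * eps, rset.sigma)
    i_tilde = np.maximum(i_tilde, 1e-30)  # keep the factor in (0, 1]
    factors = i_tilde / (i_tilde + eps * eps)
    corrected = ReflectionSet(rset.hkl.copy(), i_obs * factors,
                              rset.sigma * factors, cell=rset.cell,
                              merged=rset.merged)
    report = CorrectionReport(factors=factors)
    if f_calc is not None:
        fc = np.abs(np.asarray(f_calc, float))
        fo_pre = np.sqrt(np.maximum(i_obs, 0.0))
        fo_post = np.sqrt(np.maximum(corrected.intensity, 0.0))
        k_pre, report.epsilon_pre = fit_scale_and_epsilon(fo_pre, fc)
        k_post, report.epsilon_post = fit_scale_and_epsilon(fo_post, fc)
        report.r1_pre = r1(fo_pre / k_pre, fc)
        report.r1_post = r1(fo_post / k_post, fc)
    return corrected, report


def correct_amplitudes(f_obs: np.ndarray, sigma_f: np.ndarray,
                       binning: ResolutionBinning,
                       eps_bins: Sequence[tuple[float, float]],
                       d: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discrete per-bin amplitude correction (the protein-data route).

    Each amplitude and its sigma are multiplied by the amplitude-domain
    Wiener factor (I~ / (I~ + eps_bin^2))^(1/2), the square root of the
    intensity-domain factor evaluated at the plug-in kinematic intensity
    I~ = max(F^2 - eps_bin^2, sigma_F^2), using the eps of the
    reflection's resolution bin — so correcting amplitudes agrees with
    correcting the corresponding intensities. Reflections outside every
    bin (only possible when ``d`` is supplied for data the binning was
    not built on) take the nearest bin's eps with a warning.

    Returns (corrected F, corrected sigma, factors).
    """
    fo = np.asarray(f_obs, float)
    sf = np.asarray(sigma_f, float)
    eps_vals = np.array([e for _, e in eps_bins])
    if len(eps_vals) != binning.n_bins:
        raise ValueError("eps_bins must match the binning")
    eps = np.empty_like(fo)
    if d is None:
        for bi, idx in enumerate(binning.bin_indices):
            eps[idx] = eps_vals[bi]
    else:
        d = np.asarray(d, float)
        lo, hi = binning.boundaries[-1], binning.boundaries[0]
        if np.any((d < lo) | (d > hi)):
            warnings.warn("reflection(s) outside the binned resolution "
                          "range; using nearest bin epsilon")
        for i, dv in enumerate(d):
            eps[i] = eps_vals[binning.bin_of(dv)]
    i_tilde = np.maximum(np.maximum(fo * fo - eps * eps, sf * sf), 1e-30)
    factors = np.sqrt(i_tilde / (i_tilde + eps * eps))
    return fo * factors, sf * factors, factors
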