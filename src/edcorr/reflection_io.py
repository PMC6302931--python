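"""Reflection data I/O, resolution binning and merging statistics.

Reads and writes SHELX HKLF4 fixed-width reflection files (``3I4,2F8.2``:
h, k, l, intensity, sigma) and CIF structure-factor loops, computes
d-spacings from the general triclinic reciprocal metric, partitions
reflections into equal-count resolution bins, and computes the standard
data-merging statistics (R_merge, R_meas, CC1/2, mean I/sigma,
completeness, multiplicity).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence, TextIO, Union

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Reflection",
    "UnitCell",
    "ReflectionSet",
    "ResolutionBinning",
    "MergeStats",
    "read_hklf4",
    "write_hklf4",
    "read_refln_cif",
    "d_spacing",
    "assign_resolution_bins",
    "merge_stats",
    "laue_canonical_hkl",
]


class Reflection(NamedTuple):
    """A single indexed observation: Miller indices, intensity, sigma, d."""

    h: int
    k: int
    l: int
    intensity: float
    sigma: float
    d: float | None = None


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters in angstroms and degrees.

    Provides the metric tensors and d-spacing for the general triclinic
    case; orthorhombic and cubic cells are special cases.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if not self.volume > 0:
            raise ValueError("cell parameters give non-positive volume")

    @property
    def volume(self) -> float:
        """Cell volume from the standard triclinic closed form (A^3)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (3x3, A^2)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @property
    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G^-1 (A^-2)."""
        return np.linalg.inv(self.metric_tensor)

    def d_spacing(self, hkl: Sequence[int] | np.ndarray) -> np.ndarray | float:
        """d-spacing(s) in A for one (h,k,l) or an (n,3) array of indices."""
        arr = np.asarray(hkl, dtype=float)
        single = arr.ndim == 1
        arr = np.atleast_2d(arr)
        if np.any(np.all(arr == 0, axis=1)):
            raise ValueError("d-spacing undefined for (0,0,0)")
        gstar = self.reciprocal_metric_tensor
        inv_d2 = np.einsum("ni,ij,nj->n", arr, gstar, arr)
        d = 1.0 / np.sqrt(inv_d2)
        return float(d[0]) if single else d

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @classmethod
    def from_gemmi(cls, cell: gemmi.UnitCell) -> "UnitCell":
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)


def d_spacing(h: int, k: int, l: int, cell: UnitCell) -> float:
    """d-spacing in A of reflection (h,k,l) for the given cell."""
    return cell.d_spacing((h, k, l))


@dataclass
class ReflectionSet:
    """An ordered collection of indexed reflections.

    Stores columns as numpy arrays; ``d`` is derived once a cell is known.
    The carrier of observed intensities/amplitudes throughout the package.
    """

    hkl: np.ndarray  # (n, 3) int
    intensity: np.ndarray  # (n,)
    sigma: np.ndarray  # (n,)
    cell: UnitCell | None = None
    merged: bool = False
    _d: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=float).ravel()
        self.sigma = np.asarray(self.sigma, dtype=float).ravel()
        n = len(self.hkl)
        if len(self.intensity) != n or len(self.sigma) != n:
            raise ValueError("hkl, intensity and sigma must have equal length")
        if np.any(self.sigma < 0):
            raise ValueError("sigma values must be non-negative")
        if n and np.any(np.all(self.hkl == 0, axis=1)):
            raise ValueError("(0,0,0) is not a valid data record")

    def __len__(self) -> int:
        return len(self.hkl)

    def __iter__(self) -> Iterator[Reflection]:
        d = self._d if self._d is not None else [None] * len(self)
        for (h, k, l), i, s, dd in zip(self.hkl, self.intensity, self.sigma, d):
            yield Reflection(int(h), int(k), int(l), float(i), float(s),
                             None if dd is None else float(dd))

    @property
    def d(self) -> np.ndarray:
        """Per-reflection d-spacings (A); requires a cell."""
        if self._d is None:
            if self.cell is None:
                raise ValueError("no unit cell assigned; cannot derive d-spacings")
            self._d = self.cell.d_spacing(self.hkl)
        return self._d

    def with_cell(self, cell: UnitCell) -> "ReflectionSet":
        return ReflectionSet(self.hkl.copy(), self.intensity.copy(),
                             self.sigma.copy(), cell=cell, merged=self.merged)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"h": self.hkl[:, 0], "k": self.hkl[:, 1], "l": self.hkl[:, 2],
             "intensity": self.intensity, "sigma": self.sigma}
        )
        if self.cell is not None:
            df["d"] = self.d
        return df


_TERMINATOR = "   0   0   0    0.00    0.00"


def _open_text(source: Union[str, Path, TextIO], mode: str) -> tuple[TextIO, bool]:
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False  # type: ignore[return-value]
    return open(source, mode), True


def read_hklf4(source: Union[str, Path, TextIO],
               cell: UnitCell | None = None) -> ReflectionSet:
    """Read a SHELX HKLF4 reflection file (columns ``3I4,2F8.2``).

    An all-zero index line, if present, terminates the data; trailing
    lines (e.g. cell or symmetry info some programs append) are ignored.
    Batch numbers beyond column 28 are ignored.
    """
    stream, close = _open_text(source, "r")
    hkl, ii, ss = [], [], []
    try:
        for lineno, line in enumerate(stream, start=1):
            if not line.strip():
                continue
            try:
                h = int(line[0:4])
                k = int(line[4:8])
                l = int(line[8:12])
                inten = float(line[12:20])
                sig = float(line[20:28])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"malformed HKLF4 record on line {lineno}: {line.rstrip()!r}"
                ) from exc
            if h == 0 and k == 0 and l == 0:
                break  # SHELX terminator convention
            hkl.append((h, k, l))
            ii.append(inten)
            ss.append(sig)
    finally:
        if close:
            stream.close()
    return ReflectionSet(np.array(hkl, dtype=int).reshape(-1, 3),
                         np.array(ii), np.array(ss), cell=cell)


def write_hklf4(rset: ReflectionSet, dest: Union[str, Path, TextIO],
                terminator: bool = True) -> None:
    """Write reflections in SHELX HKLF4 fixed-width format.

    Raises if any value does not fit its field (indices: 4 columns,
    intensity/sigma: 8 columns with 2 decimals) — rescale such data first.
    """
    stream, close = _open_text(dest, "w")
    try:
        for h, k, l, inten, sig, _ in rset:
            line = f"{h:4d}{k:4d}{l:4d}{inten:8.2f}{sig:8.2f}"
            if len(line) != 28:
                raise ValueError(
                    f"value out of HKLF4 field width for ({h},{k},{l}): "
                    f"I={inten}, sigma={sig}; rescale the data"
                )
            stream.write(line + "\n")
        if terminator:
            stream.write(_TERMINATOR + "\n")
    finally:
        if close:
            stream.close()


def read_refln_cif(source: Union[str, Path], block: str | None = None
                   ) -> tuple[ReflectionSet, str]:
    """Read a CIF structure-factor loop.

    Returns the reflections plus the kind of the value column:
    ``"intensity"`` for _refln_F_squared_meas, ``"amplitude"`` for
    _refln_F_meas. Accepts both underscore and dotted tag dialects.
    """
    doc = gemmi.cif.read(str(source))
    blk = doc[block] if block is not None else doc.sole_block()

    def col(names: list[str]) -> list[str] | None:
        for name in names:
            vals = blk.find_values(name)
            if vals:
                return list(vals)
        return None

    h = col(["_refln_index_h", "_refln.index_h"])
    k = col(["_refln_index_k", "_refln.index_k"])
    l = col(["_refln_index_l", "_refln.index_l"])
    if h is None or k is None or l is None:
        raise ValueError("no _refln index loop found in CIF")
    val = col(["_refln_F_squared_meas", "_refln.F_squared_meas"])
    sig = col(["_refln_F_squared_sigma", "_refln.F_squared_sigma"])
    kind = "intensity"
    if val is None:
        val = col(["_refln_F_meas", "_refln.F_meas", "_refln.F_meas_au"])
        sig = col(["_refln_F_sigma", "_refln.F_sigma", "_refln.F_meas_sigma_au"])
        kind = "amplitude"
    if val is None:
        raise ValueError("no F_squared_meas or F_meas column found in CIF")
    n = len(h)
    if sig is None:
        sig = ["0"] * n
    hkl = np.array([[int(x), int(y), int(z)] for x, y, z in zip(h, k, l)])
    vals = np.array([gemmi.cif.as_number(v) for v in val])
    sigs = np.array([gemmi.cif.as_number(s) for s in sig])
    return ReflectionSet(hkl, vals, np.nan_to_num(sigs)), kind


@dataclass
class ResolutionBinning:
    """Equal-count partition of reflections into resolution bins.

    Bins are ordered from low resolution (large d) to high; sizes differ
    by at most one reflection. ``mean_d`` is the arithmetic mean of the
    member d-spacings and serves as the bin's representative resolution.
    """

    n_bins: int
    boundaries: np.ndarray          # n_bins+1 d-values, descending
    bin_indices: list[np.ndarray]   # indices into the original set
    mean_d: np.ndarray              # per-bin mean d, descending

    def bin_of(self, d: float) -> int:
        """Index of the bin whose d-range contains (or is nearest to) d."""
        if d >= self.boundaries[1]:
            return 0
        if d <= self.boundaries[-2]:
            return self.n_bins - 1
        # interior boundaries are descending
        for i in range(self.n_bins):
            if self.boundaries[i] >= d >= self.boundaries[i + 1]:
                return i
        return int(np.argmin(np.abs(self.mean_d - d)))


def assign_resolution_bins(rset_or_d: ReflectionSet | np.ndarray,
                           n_bins: int = 10) -> ResolutionBinning:
    """Partition reflections into ``n_bins`` equal-count resolution bins.

    Reflections are sorted by d descending (stable, so ties keep input
    order) and split into contiguous groups whose sizes differ by <= 1.
    """
    d = rset_or_d.d if isinstance(rset_or_d, ReflectionSet) else np.asarray(rset_or_d, float)
    n = len(d)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds the number of reflections ({n})")
    order = np.argsort(-d, kind="stable")
    groups = np.array_split(order, n_bins)
    mean_d = np.array([d[g].mean() for g in groups])
    bounds = np.empty(n_bins + 1)
    bounds[0] = d[groups[0]].max()
    bounds[-1] = d[groups[-1]].min()
    for i in range(1, n_bins):
        bounds[i] = 0.5 * (d[groups[i - 1]].min() + d[groups[i]].max())
    return ResolutionBinning(n_bins=n_bins, boundaries=bounds,
                             bin_indices=[np.asarray(g) for g in groups],
                             mean_d=mean_d)


def _laue_rotations(spacegroup: str | gemmi.SpaceGroup) -> np.ndarray:
    sg = (spacegroup if isinstance(spacegroup, gemmi.SpaceGroup)
          else gemmi.SpaceGroup(spacegroup))
    rots = []
    for op in sg.operations():
        r = np.array(op.rot, dtype=float) / gemmi.Op.DEN
        rots.append(r)
        rots.append(-r)  # Friedel: the Laue group always contains -1
    uniq = {tuple(np.rint(r).astype(int).ravel()) for r in rots}
    return np.array([np.array(t).reshape(3, 3) for t in sorted(uniq)])


def laue_canonical_hkl(hkl: np.ndarray,
                       spacegroup: str | gemmi.SpaceGroup) -> np.ndarray:
    """Canonical representative of each (h,k,l) under the Laue group.

    Applies every Laue-group rotation (point group plus inversion) to the
    indices and keeps the lexicographically largest equivalent, giving a
    deterministic merging key.
    """
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    rots = _laue_rotations(spacegroup)
    # reciprocal indices transform as row vectors: h' = h R
    equiv = np.einsum("nj,rjk->rnk", hkl.astype(float), rots)
    equiv = np.rint(equiv).astype(int)  # (n_rot, n, 3)
    # lexicographic max over rotations on (h, k, l)
    keys = (equiv[..., 0].astype(np.int64) * 4_000_000
            + equiv[..., 1].astype(np.int64) * 2_000
            + equiv[..., 2].astype(np.int64))
    best = np.argmax(keys, axis=0)
    return equiv[best, np.arange(hkl.shape[0])]


@dataclass
class MergeStats:
    """Overall and per-bin merging statistics.

    R-factors are reported as fractions (multiply by 100 for percent);
    ``None`` where undefined (no multiply-observed reflections).
    """

    n_observations: int
    n_unique: int
    multiplicity: float
    r_merge: float | None
    r_meas: float | None
    cc_half: float | None
    mean_i_over_sigma: float
    completeness: float | None
    per_bin: pd.DataFrame
    first_bin_failing_i_over_sigma: int | None
    first_bin_failing_cc_half: int | None


def _r_factors(groups: list[np.ndarray], intensities: np.ndarray
               ) -> tuple[float | None, float | None]:
    num_rm = num_rms = den = 0.0
    any_multi = False
    for idx in groups:
        if len(idx) < 2:
            continue
        any_multi = True
        vals = intensities[idx]
        mean = vals.mean()
        dev = np.abs(vals - mean).sum()
        n = len(vals)
        num_rm += dev
        num_rms += math.sqrt(n / (n - 1)) * dev
        den += vals.sum()
    if not any_multi or den == 0:
        return None, None
    return num_rm / den, num_rms / den


def _cc_half(groups: list[np.ndarray], intensities: np.ndarray,
             rng: np.random.Generator) -> float | None:
    x, y = [], []
    for idx in groups:
        if len(idx) < 2:
            continue
        perm = rng.permutation(len(idx))
        half = len(idx) // 2
        a = intensities[idx[perm[:half]]].mean()
        b = intensities[idx[perm[half:]]].mean()
        x.append(a)
        y.append(b)
    if len(x) < 2:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r)


def _theoretical_unique_count(cell: UnitCell, spacegroup: str | gemmi.SpaceGroup,
                              d_min: float, d_max: float) -> int:
    """Count unique reflections in [d_min, d_max] by direct enumeration,
    excluding systematic absences."""
    sg = (spacegroup if isinstance(spacegroup, gemmi.SpaceGroup)
          else gemmi.SpaceGroup(spacegroup))
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
    sel = (d >= d_min) & (d <= d_max)
    hkl = hkl[sel]
    absent = np.array([ops.is_systematically_absent(list(x)) for x in hkl])
    hkl = hkl[~absent]
    canon = laue_canonical_hkl(hkl, sg)
    return len(np.unique(canon, axis=0))


def merge_stats(rset: ReflectionSet, spacegroup: str | gemmi.SpaceGroup,
                n_bins: int = 10, seed: int = 0,
                completeness: bool = True) -> MergeStats:
    """Merging statistics of an unmerged reflection set.

    R_merge = sum_hkl sum_i |I_i - <I>| / sum_hkl sum_i I_i and R_meas
    (its multiplicity-weighted variant with the sqrt(n/(n-1)) factor) run
    over reflections observed at least twice. CC1/2 is the Pearson
    correlation between mean intensities of random half-datasets (seeded
    split). Completeness compares unique observed against a direct
    enumeration of the theoretically measurable reflections. Also flags
    the first resolution bin failing the conventional truncation checks
    I/sigma > 1.0 and CC1/2 > 50%.
    """
    if len(rset) == 0:
        raise ValueError("empty reflection set")
    canon = laue_canonical_hkl(rset.hkl, spacegroup)
    uniq, inverse = np.unique(canon, axis=0, return_inverse=True)
    groups = [np.flatnonzero(inverse == i) for i in range(len(uniq))]
    rng = np.random.default_rng(seed)

    d = rset.d
    uniq_d = np.array([d[g].mean() for g in groups])
    merged_i = np.array([rset.intensity[g].mean() for g in groups])
    merged_sig = np.array(
        [math.sqrt(np.sum(rset.sigma[g] ** 2)) / len(g) for g in groups])
    with np.errstate(divide="ignore", invalid="ignore"):
        iosig = np.where(merged_sig > 0, merged_i / merged_sig, np.nan)

    r_merge, r_meas = _r_factors(groups, rset.intensity)
    cc = _cc_half(groups, rset.intensity, rng)

    nb = min(n_bins, len(uniq))
    binning = assign_resolution_bins(uniq_d, nb)
    rows = []
    for bi, uidx in enumerate(binning.bin_indices):
        bin_groups = [groups[u] for u in uidx]
        brm, brms = _r_factors(bin_groups, rset.intensity)
        bcc = _cc_half(bin_groups, rset.intensity, rng)
        bios = np.nanmean(iosig[uidx]) if np.any(np.isfinite(iosig[uidx])) else np.nan
        rows.append({
            "bin": bi,
            "d_max": d_maxmin(uniq_d, uidx)[0],
            "d_min": d_maxmin(uniq_d, uidx)[1],
            "mean_d": binning.mean_d[bi],
            "n_unique": len(uidx),
            "n_obs": int(sum(len(g) for g in bin_groups)),
            "r_merge": brm, "r_meas": brms, "cc_half": bcc,
            "i_over_sigma": bios,
        })
    per_bin = pd.DataFrame(rows)

    def first_failing(colvals, threshold) -> int | None:
        for bi, v in enumerate(colvals):
            if v is not None and np.isfinite(v) and v <= threshold:
                return bi
        return None

    fail_ios = first_failing(per_bin["i_over_sigma"].to_numpy(), 1.0)
    fail_cc = first_failing(
        [None if v is None else v for v in per_bin["cc_half"]], 0.50)

    comp = None
    if completeness and rset.cell is not None:
        theo = _theoretical_unique_count(rset.cell, spacegroup,
                                         float(d.min()), float(d.max()))
        comp = len(uniq) / theo if theo else None

    return MergeStats(
        n_observations=len(rset),
        n_unique=len(uniq),
        multiplicity=len(rset) / len(uniq),
        r_merge=r_merge,
        r_meas=r_meas,
        cc_half=cc,
        mean_i_over_sigma=(float(np.mean(iosig[np.isfinite(iosig)]))
                           if np.any(np.isfinite(iosig)) else float("nan")),
        completeness=comp,
        per_bin=per_bin,
        first_bin_failing_i_over_sigma=fail_ios,
        first_bin_failing_cc_half=fail_cc,
    )


def d_maxmin(uniq_d: np.ndarray, idx: np.ndarray) -> tuple[float, float]:
    vals = uniq_d[idx]
    return float(vals.max()), float(vals.min())
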