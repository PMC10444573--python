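"""Nullcline geometry of the reduced model and the slow-motion timing estimate.

The V-nullcline (total membrane current = 0) is Z-shaped in the
([Na+]_i, V) plane; its two fold (knee) points bound the slow variable's
oscillation range.  Burst duration and interburst interval are approximated
by integrating d[Na+]_i / |d[Na+]_i/dt| along the depolarized and
hyperpolarized stable branches between the knees, with the local speed
evaluated from the Na+ flux balance at 100 sample points equally spaced in
[Na+]_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .reduced_model import ReducedModelParams, na_flux, total_current

__all__ = [
    "NullclineCurve", "KneeSet", "BranchSamples", "FixedPoint",
    "v_nullcline", "na_nullcline", "knee_points", "fixed_points",
    "branch_samples", "approx_bd_ibi", "sweep_relative_change",
]

#: [Na+]_i root-scan interval (M) and resolution for nullcline construction.
NA_SCAN = (1e-4, 0.1)
NA_SCAN_POINTS = 2000
V_GRID_DEFAULT = (-0.075, 0.005, 2001)


@dataclass
class NullclineCurve:
    """Sampled nullcline, ordered by voltage; possibly several roots per V."""

    v: np.ndarray
    na: np.ndarray
    kind: str  # "v" (current balance) or "na" (flux balance)

    def __len__(self):
        return self.v.size


@dataclass
class KneeSet:
    """The two fold points of the Z-shaped V-nullcline.

    ``lower`` is the hyperpolarized-side fold, ``upper`` the depolarized-side
    fold; each is (V, [Na+]_i).
    """

    lower: tuple
    upper: tuple

    @property
    def na_range(self) -> tuple:
        a, b = self.lower[1], self.upper[1]
        return (min(a, b), max(a, b))

    @property
    def na_amplitude(self) -> float:
        lo, hi = self.na_range
        return hi - lo


@dataclass
class BranchSamples:
    """Equally spaced-in-[Na+]_i samples on one stable branch with speeds."""

    branch: str          # "depolarized" or "hyperpolarized"
    na: np.ndarray       # arithmetic sequence strictly between the knees (M)
    v: np.ndarray        # branch voltage at each sample (V)
    speed: np.ndarray    # d[Na+]_i/dt at each sample (M/s)
    cell_width: float    # [Na+]_i width of each sampling cell (M)


@dataclass
class FixedPoint:
    v: float
    na: float
    branch: str  # V-nullcline branch: "lower", "middle" or "upper"


def _roots_in_na(fn, V, params, ngrid=NA_SCAN_POINTS):
    """All [Na+]_i roots of ``fn(V, na, params)`` by log-grid scan + brentq."""
    grid = np.logspace(np.log10(NA_SCAN[0]), np.log10(NA_SCAN[1]), ngrid)
    f = np.asarray(fn(V, grid, params))
    s = np.sign(f)
    roots = []
    for i in np.flatnonzero(s[:-1] * s[1:] < 0):
        roots.append(brentq(lambda n: float(fn(V, n, params)),
                            grid[i], grid[i + 1], xtol=1e-14))
    for i in np.flatnonzero(f == 0.0):
        roots.append(float(grid[i]))
    return sorted(roots)


def _nullcline(fn, kind, params, v_grid):
    if v_grid is None:
        v_grid = np.linspace(*V_GRID_DEFAULT)
    vs, nas = [], []
    for V in np.asarray(v_grid, dtype=float):
        for r in _roots_in_na(fn, V, params):
            vs.append(V)
            nas.append(r)
    if not vs:
        raise ValueError(f"{kind}-nullcline has no points on the grid "
                         "(degenerate parameters)")
    return NullclineCurve(np.asarray(vs), np.asarray(nas), kind)


def v_nullcline(params: ReducedModelParams, v_grid=None) -> NullclineCurve:
    """States where inward and outward membrane currents balance exactly."""
    return _nullcline(total_current, "v", params, v_grid)


def na_nullcline(params: ReducedModelParams, v_grid=None) -> NullclineCurve:
    """States where inward and outward Na+ fluxes balance exactly."""
    return _nullcline(na_flux, "na", params, v_grid)


def _na_on_branch(V, params):
    roots = _roots_in_na(total_current, V, params)
    if not roots:
        raise ValueError(f"V-nullcline has no root at V={V}")
    return roots  # caller picks by branch context


def knee_points(curve: NullclineCurve, params: ReducedModelParams) -> KneeSet:
    """Fold points: local extrema of [Na+]_i along the V-ordered curve.

    Each discrete extremum is refined by a parabolic fit through it and its
    two neighbours (two rounds, shrinking the stencil), then the [Na+]_i
    coordinate is re-solved exactly at the refined voltage.  Raises if the
    curve does not show exactly two folds.
    """
    if curve.kind != "v":
        raise ValueError("knee points are defined for the V-nullcline")
    v, na = curve.v, curve.na
    ext_idx = [i for i in range(1, len(na) - 1)
               if (na[i] - na[i - 1]) * (na[i + 1] - na[i]) < 0]
    if len(ext_idx) != 2:
        raise ValueError(
            f"expected a Z-shaped curve with 2 folds, found {len(ext_idx)} "
            "extrema of [Na+]_i along the curve")
    knees = []
    for i in ext_idx:
        vk, h = v[i], v[i + 1] - v[i]
        for _ in range(2):
            vv = np.array([vk - h, vk, vk + h])
            yy = np.array([_nearest_root(x, curve, params) for x in vv])
            denom = yy[0] - 2 * yy[1] + yy[2]
            if denom != 0:
                vk = vk + 0.5 * h * (yy[0] - yy[2]) / denom
            h /= 10.0
        knees.append((float(vk), _nearest_root(vk, curve, params)))
    knees.sort(key=lambda p: p[0])
    return KneeSet(lower=knees[0], upper=knees[1])


def _nearest_root(V, curve, params):
    """[Na+]_i root at V closest to the curve's local continuation."""
    roots = _roots_in_na(total_current, V, params)
    if not roots:
        raise ValueError(f"no V-nullcline root at V={V}")
    j = np.argmin(np.abs(curve.v - V))
    return float(min(roots, key=lambda r: abs(r - curve.na[j])))


def fixed_points(params: ReducedModelParams, v_grid=None,
                 knees: KneeSet | None = None) -> list:
    """Intersections of the two nullclines, tagged by V-nullcline branch.

    Scans the [Na+]_i-nullcline for sign changes of the total current and
    refines each crossing by bisection in V.  An intersection on the middle
    branch (between the knee voltages) is the unstable stationary state
    inside the relaxation limit cycle.
    """
    if v_grid is None:
        v_grid = np.linspace(*V_GRID_DEFAULT)
    v_grid = np.asarray(v_grid, dtype=float)
    if knees is None:
        try:
            knees = knee_points(v_nullcline(params, v_grid), params)
        except ValueError:
            knees = None  # not Z-shaped; branch tags stay "middle"

    def current_on_na_nullcline(V):
        roots = _roots_in_na(na_flux, V, params)
        if not roots:
            return np.nan
        return float(total_current(V, roots[0], params))

    vals = np.array([current_on_na_nullcline(V) for V in v_grid])
    out = []
    ok = np.isfinite(vals)
    for i in range(len(v_grid) - 1):
        if not (ok[i] and ok[i + 1]) or vals[i] * vals[i + 1] > 0:
            continue
        vstar = brentq(current_on_na_nullcline, v_grid[i], v_grid[i + 1],
                       xtol=1e-13)
        nastar = _roots_in_na(na_flux, vstar, params)[0]
        branch = "middle"
        if knees is not None:
            if vstar < knees.lower[0]:
                branch = "lower"
            elif vstar > knees.upper[0]:
                branch = "upper"
        out.append(FixedPoint(float(vstar), float(nastar), branch))
    return out


def branch_samples(curve: NullclineCurve, knees: KneeSet, n: int = 100,
                   params: ReducedModelParams | None = None) -> dict:
    """Sample both stable branches between the knees and evaluate speeds.

    Each branch is divided into ``n`` cells of equal [Na+]_i width strictly
    between the knee concentrations; samples sit at the cell midpoints (so
    the fold points themselves, where the speed is ill-defined, are
    excluded).  The branch voltage at each sample is found by inverting the
    branch's monotone Na(V) relation with bisection; the speed is the Na+
    flux balance evaluated there.

    Returns ``{"depolarized": BranchSamples, "hyperpolarized": ...}``.
    """
    if params is None:
        raise ValueError("params are required to evaluate branch speeds")
    lo, hi = knees.na_range
    width = (hi - lo) / n
    mids = lo + (np.arange(n) + 0.5) * width
    v_lo_end, v_hi_end = curve.v.min(), curve.v.max()
    vk_lo, vk_hi = knees.lower[0], knees.upper[0]
    out = {}
    for branch, (a, b) in (("hyperpolarized", (v_lo_end, vk_lo)),
                           ("depolarized", (vk_hi, v_hi_end))):
        j = np.argmin(np.abs(curve.v - 0.5 * (a + b)))

        def na_at(V):
            roots = _roots_in_na(total_current, V, params)
            if not roots:
                raise ValueError(f"branch lost at V={V}")
            return min(roots, key=lambda r: abs(r - curve.na[j]))

        na_a, na_b = na_at(a), na_at(b)
        if not (min(na_a, na_b) <= mids[0] and mids[-1] <= max(na_a, na_b)):
            raise ValueError(
                f"{branch} branch does not span the inter-knee [Na+]_i range")
        vs = np.array([brentq(lambda V, tgt=t: na_at(V) - tgt, a, b,
                              xtol=1e-13) for t in mids])
        speeds = np.array([na_flux(V, nam, params)
                           for V, nam in zip(vs, mids)])
        out[branch] = BranchSamples(branch, mids.copy(), vs, speeds, width)
    return out


def approx_bd_ibi(samples: dict) -> tuple:
    """Slow-motion timing estimate: sum of cell width over |speed| per branch.

    The depolarized branch yields the burst duration, the hyperpolarized
    branch the interburst interval.  Raises if any sampled speed is zero
    (a fixed point on the branch).
    """
    out = []
    for branch in ("depolarized", "hyperpolarized"):
        s = samples[branch]
        if np.any(s.speed == 0.0):
            raise ValueError(f"zero [Na+]_i speed on the {branch} branch")
        out.append(float(np.sum(s.cell_width / np.abs(s.speed))))
    return tuple(out)


def nullcline_analysis(params: ReducedModelParams, n: int = 100,
                       v_grid=None) -> dict:
    """One-stop geometry: curve, knees, branch samples, timing estimate."""
    curve = v_nullcline(params, v_grid)
    knees = knee_points(curve, params)
    samples = branch_samples(curve, knees, n=n, params=params)
    bd, ibi = approx_bd_ibi(samples)
    return {"curve": curve, "knees": knees, "samples": samples,
            "bd_approx": bd, "ibi_approx": ibi}


def sweep_relative_change(params: ReducedModelParams, imax_list,
                          n: int = 100) -> pd.DataFrame:
    """Relative [Na+]_i amplitude and branch-mean speeds across pump levels.

    For each pump maximum: amplitude = inter-knee [Na+]_i distance; speeds =
    plain means of |d[Na+]_i/dt| over the ``n`` samples per branch.  All
    three columns are normalized by the first (reference) pump value.
    """
    rows = []
    for imax in imax_list:
        res = nullcline_analysis(params.with_(ipump_max=float(imax)), n=n)
        rows.append({
            "ipump_max": float(imax),
            "na_amplitude": res["knees"].na_amplitude,
            "burst_speed": float(np.abs(
                res["samples"]["depolarized"].speed).mean()),
            "ibi_speed": float(np.abs(
                res["samples"]["hyperpolarized"].speed).mean()),
            "bd_approx": res["bd_approx"],
            "ibi_approx": res["ibi_approx"],
        })
    df = pd.DataFrame(rows)
    ref = df.iloc[0]
    for col in ("na_amplitude", "burst_speed", "ibi_speed"):
        df[f"delta_{col}"] = df[col] / ref[col]
    return df
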