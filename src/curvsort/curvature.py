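"""Leaflet spline fitting and signed pointwise curvature.

Each leaflet of each frame is reduced to a curve z = f(x): all headgroup
(x, z) pairs (y collapsed, x wrapped into one box period) are aggregated on
a fine x grid and fitted with a periodic cubic smoothing spline, which
gives the C2 continuity required for the second derivative.  The pointwise
curvature is the plane-curve formula

    C(x) = f''(x) / (1 + f'(x)^2)^(3/2)        [1/nm]

evaluated at each lipid's own headgroup x.  Outer-leaflet values are
multiplied by -1 so that, for both leaflets, membrane regions concave /
convex as seen from the outside are negative / positive.

Smoothing calibration: grid-cell means are weighted by sqrt(n)/rho where
rho is the configured roughness scale (nm), and the FITPACK smoothing
budget is set to the number of grid cells (discrepancy principle).  When
the true headgroup noise equals rho the fitted curve tracks the underlying
surface without chasing noise; the parameter is exposed because the
extreme-curvature tails of the analysis are sensitive to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.interpolate import splev, splrep

from .core_model import (
    INNER,
    LEAFLETS,
    OUTER,
    MembraneFrame,
    Registry,
    assign_leaflets,
    headgroup_leaflet_split,
)
from .errors import DegenerateMembraneError, FitError

logger = logging.getLogger(__name__)

__all__ = [
    "LeafletCurve",
    "fit_leaflet_spline",
    "pointwise_curvature",
    "per_lipid_curvature",
]


@dataclass
class LeafletCurve:
    """A fitted leaflet height function on a (possibly periodic) x domain."""

    tck: tuple
    period: float
    leaflet: str | None = None
    periodic: bool = True
    residual_rms: float = float("nan")
    x0: float = 0.0  # start of the fitted periodic domain

    def _wrap(self, x):
        x = np.asarray(x, dtype=float)
        if not self.periodic:
            return x
        return self.x0 + np.mod(x - self.x0, self.period)

    def f(self, x):
        return splev(self._wrap(x), self.tck)

    def df(self, x):
        return splev(self._wrap(x), self.tck, der=1)

    def d2f(self, x):
        return splev(self._wrap(x), self.tck, der=2)

    @property
    def n_knots(self) -> int:
        return len(self.tck[0])

    def curvature(self, x):
        """Raw (leaflet-unsigned) curvature f''/(1+f'^2)^(3/2)."""
        fp = self.df(x)
        return self.d2f(x) / (1.0 + np.asarray(fp) ** 2) ** 1.5


def fit_curve_xz(
    x: np.ndarray,
    z: np.ndarray,
    period: float,
    roughness: float = 0.5,
    grid_spacing: float = 0.25,
    periodic: bool = True,
    min_points: int = 20,
) -> LeafletCurve:
    """Fit a (periodic) cubic smoothing spline to scattered (x, z) points.

    Points are averaged in x-grid cells (``grid_spacing`` nm) with weights
    proportional to sqrt(count)/roughness, which also disposes of duplicate
    and near-duplicate x values.  ``roughness = 0`` requests an
    interpolating spline through the cell means (appropriate for noiseless
    data).  A warning is logged when the residual RMS exceeds 5x the
    roughness scale (frame flagged, not dropped).
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.size < min_points:
        raise FitError(f"need >= {min_points} headgroup beads, got {x.size}")
    if periodic:
        x = np.mod(x, period)
        start, span = 0.0, period
    else:
        start, span = float(x.min()), float(np.ptp(x))
        if span <= 0:
            raise FitError("degenerate x range")

    if roughness <= 0:
        # noiseless data: interpolate the points directly (averaging into
        # cells first would jitter the second derivative)
        order = np.argsort(x, kind="stable")
        xs, zs = x[order], z[order]
        distinct = np.concatenate([[True], np.diff(xs) > 1e-9])
        xs, zs = xs[distinct], zs[distinct]
        if periodic:
            xs = np.append(xs, xs[0] + period)
            zs = np.append(zs, zs[0])
        try:
            tck = splrep(xs, zs, k=3, s=0.0, per=int(periodic))
        except Exception as exc:
            raise FitError(f"spline solver failed: {exc}") from exc
        curve = LeafletCurve(tck=tck, period=period, periodic=periodic,
                             x0=float(xs[0]))
        curve.residual_rms = float(np.sqrt(np.mean((z - curve.f(x)) ** 2)))
        return curve

    M = max(16, int(round(span / grid_spacing)))
    idx = np.clip(((x - start) / span * M).astype(int), 0, M - 1)
    cnt = np.bincount(idx, minlength=M)
    sum_z = np.bincount(idx, weights=z, minlength=M)
    sum_x = np.bincount(idx, weights=x, minlength=M)
    keep = cnt > 0
    if keep.sum() < 8:
        raise FitError(f"only {int(keep.sum())} occupied grid cells; cannot fit")
    # abscissa = within-cell mean x (a cell-center abscissa aliases the
    # local slope into apparent height noise and roughens f'')
    xg = sum_x[keep] / cnt[keep]
    yg = sum_z[keep] / cnt[keep]
    if roughness > 0:
        wg = np.sqrt(cnt[keep]) / roughness
        smooth = float(len(xg))
    else:
        wg = np.ones(int(keep.sum()))
        smooth = 0.0
    if periodic:
        xg = np.append(xg, xg[0] + period)
        yg = np.append(yg, yg[0])
        wg = np.append(wg, wg[0])
    try:
        tck = splrep(xg, yg, w=wg, k=3, s=smooth, per=int(periodic))
    except Exception as exc:  # FITPACK failures surface as generic errors
        raise FitError(f"spline solver failed: {exc}") from exc

    curve = LeafletCurve(tck=tck, period=period, periodic=periodic,
                         x0=float(xg[0]))
    resid = z - curve.f(x)
    curve.residual_rms = float(np.sqrt(np.mean(resid**2)))
    if roughness > 0 and curve.residual_rms > 5.0 * roughness:
        logger.warning(
            "leaflet fit residual RMS %.3f nm exceeds 5x roughness scale %.3f",
            curve.residual_rms, roughness,
        )
    return curve


def fit_leaflet_spline(
    frame: MembraneFrame,
    leaflet: str,
    registry: Registry | None = None,
    roughness: float = 0.5,
    grid_spacing: float = 0.25,
) -> LeafletCurve:
    """Fit the periodic leaflet curve through one leaflet's headgroup beads.

    ``frame.leaflet`` must already hold labels (see
    :func:`curvsort.core_model.assign_leaflets`).
    """
    if registry is None:
        from .species import default_registry
        registry = default_registry()
    if frame.leaflet is None:
        raise FitError("frame has no leaflet labels; run assign_leaflets first")
    mask = frame.headgroup_mask(registry)
    in_leaflet = np.array(
        [frame.leaflet.get(int(r)) == leaflet for r in frame.residue_id[mask]]
    )
    x = frame.positions[mask, 0][in_leaflet]
    z = frame.positions[mask, 2][in_leaflet]
    curve = fit_curve_xz(x, z, period=frame.box[0], roughness=roughness,
                         grid_spacing=grid_spacing, periodic=True)
    curve.leaflet = leaflet
    return curve


def pointwise_curvature(curve: LeafletCurve, x) -> np.ndarray:
    """Raw curvature of the fitted curve at x (leaflet sign not applied)."""
    return curve.curvature(x)


def _frame_curvature_arrays(
    frame: MembraneFrame,
    registry: Registry,
    roughness: float = 0.5,
    leaflet_bin: float = 2.0,
    grid_spacing: float = 0.25,
    reassign: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Array core of the per-frame curvature evaluation.

    Returns ``(resid, species, upper, x, C)`` over the frame's lipids,
    where ``upper`` is the outer-leaflet flag and ``C`` is already
    sign-inverted for the outer leaflet.
    """
    mask = frame.headgroup_mask(registry)
    if reassign or frame.leaflet is None:
        resid_h, x_h, z_h, upper = headgroup_leaflet_split(
            frame, registry, bin_width=leaflet_bin, mask=mask)
        frame.leaflet = dict(zip(resid_h.tolist(),
                                 np.where(upper, OUTER, INNER).tolist()))
    else:
        resid_h = frame.residue_id[mask]
        x_h = np.mod(frame.positions[mask, 0], frame.box[0])
        z_h = frame.positions[mask, 2]
        upper = np.array([frame.leaflet[int(r)] == OUTER for r in resid_h])

    species = frame.species[mask]
    period = frame.box[0]
    C = np.empty(resid_h.size)
    for leaflet, sel in ((OUTER, upper), (INNER, ~upper)):
        if not sel.any():
            continue
        curve = fit_curve_xz(x_h[sel], z_h[sel], period=period,
                             roughness=roughness,
                             grid_spacing=grid_spacing, periodic=True)
        curve.leaflet = leaflet
        Cl = np.asarray(curve.curvature(x_h[sel]), dtype=float)
        C[sel] = -Cl if leaflet == OUTER else Cl
    return resid_h, species, upper, x_h, C


def frame_curvature_records(
    frame: MembraneFrame,
    frame_index: int,
    registry: Registry,
    roughness: float = 0.5,
    leaflet_bin: float = 2.0,
    grid_spacing: float = 0.25,
    reassign: bool = True,
) -> pd.DataFrame:
    """Signed per-lipid curvature records of a single frame.

    Leaflets are (re)assigned, one periodic spline is fitted per leaflet,
    and the curvature is evaluated at each lipid's headgroup x.  Outer
    leaflet values are sign-inverted.
    """
    resid, species, upper, x, C = _frame_curvature_arrays(
        frame, registry, roughness=roughness, leaflet_bin=leaflet_bin,
        grid_spacing=grid_spacing, reassign=reassign)
    return pd.DataFrame({
        "frame": frame_index,
        "residue_id": resid.astype(np.int64),
        "species": species,
        "leaflet": np.where(upper, OUTER, INNER),
        "x": x,
        "C": C,
    })


class CurvatureTableBuilder:
    """Accumulates per-frame curvature arrays into one compact table.

    Species and leaflet columns are stored as categoricals (codes against
    the registry's species list), which keeps multi-thousand-frame tables
    within a modest memory footprint.
    """

    def __init__(self, registry: Registry):
        self.categories = np.array(sorted(registry), dtype=np.str_)
        self._frames: list[np.ndarray] = []
        self._resid: list[np.ndarray] = []
        self._codes: list[np.ndarray] = []
        self._upper: list[np.ndarray] = []
        self._x: list[np.ndarray] = []
        self._C: list[np.ndarray] = []

    def add(self, frame_index: int, resid, species, upper, x, C) -> None:
        n = resid.size
        self._frames.append(np.full(n, frame_index, dtype=np.int32))
        self._resid.append(resid.astype(np.int64))
        self._codes.append(
            np.searchsorted(self.categories, species).astype(np.int8))
        self._upper.append(upper)
        self._x.append(x)
        self._C.append(C)

    def build(self) -> pd.DataFrame:
        leaf_cat = pd.CategoricalDtype(categories=[INNER, OUTER])
        upper = np.concatenate(self._upper)
        return pd.DataFrame({
            "frame": np.concatenate(self._frames),
            "residue_id": np.concatenate(self._resid),
            "species": pd.Categorical.from_codes(
                np.concatenate(self._codes), categories=list(self.categories)),
            "leaflet": pd.Categorical.from_codes(
                upper.astype(np.int8), dtype=leaf_cat),
            "x": np.concatenate(self._x),
            "C": np.concatenate(self._C),
        })


def per_lipid_curvature(
    frames: Iterable[MembraneFrame],
    registry: Registry | None = None,
    roughness: float = 0.5,
    leaflet_bin: float = 2.0,
    grid_spacing: float = 0.25,
    max_skip_frac: float = 0.1,
) -> pd.DataFrame:
    """Signed curvature table over a trajectory.

    Columns: frame, residue_id, species, leaflet, x (nm), C (1/nm).
    Unfittable frames are skipped with a logged warning; if more than
    ``max_skip_frac`` of the frames are skipped a hard error is raised.
    """
    if registry is None:
        from .species import default_registry
        registry = default_registry()
    builder = CurvatureTableBuilder(registry)
    n_total = 0
    skipped = 0
    for i, frame in enumerate(frames):
        n_total += 1
        try:
            builder.add(i, *_frame_curvature_arrays(
                frame, registry, roughness=roughness,
                leaflet_bin=leaflet_bin, grid_spacing=grid_spacing))
        except (FitError, DegenerateMembraneError):
            skipped += 1
            logger.warning("frame %d skipped: unfittable leaflet spline", i)
    if n_total == 0:
        raise FitError("no frames supplied")
    if skipped > max_skip_frac * n_total:
        raise FitError(
            f"{skipped}/{n_total} frames skipped (> {max_skip_frac:.0%})"
        )
    return builder.build()
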