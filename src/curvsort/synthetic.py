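"""Synthetic buckled-bilayer generator with known geometry and sorting.

The generator replaces molecular-dynamics trajectories for testing: a
bilayer is buckled along x by compressional strain gamma = (X0 - Xi)/X0,
with a single-period cosine midplane z(x) = A cos(2 pi x / Xi) whose
amplitude is solved so that the arc length over one period equals the
unbuckled length X0.  The two leaflet surfaces are normal offsets of the
midplane at +/- d/2, lipids are placed uniformly in arc length on their
leaflet surface, and species identities are drawn from a curvature-dependent
categorical model, so every downstream statistic has an analytic or
ground-truth oracle.

Signed curvature convention (matching the analysis pipeline): the raw graph
curvature z''/(1+z'^2)^(3/2) is kept for the inner leaflet and inverted for
the outer leaflet, so that regions concave/convex as seen from outside the
cell are negative/positive for both leaflets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .core_model import (
    INNER,
    LEAFLETS,
    OUTER,
    Composition,
    MembraneFrame,
    Registry,
    Trajectory,
)
from .errors import GeometryError, ModelInconsistencyError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "strain",
    "make_buckle_profile",
    "BuckleProfile",
    "SortingModel",
    "sample_frame",
    "generate_trajectory",
]


def strain(X0: float, Xi: float) -> float:
    """Compressional strain gamma = (X0 - Xi) / X0 of a buckled box."""
    if X0 <= 0:
        raise ValidationError("X0 must be positive")
    if Xi <= 0:
        raise ValidationError("Xi must be positive")
    if Xi > X0:
        raise GeometryError(
            f"Xi={Xi} > X0={X0}: extension (negative strain) is not modelled"
        )
    return (X0 - Xi) / X0


@dataclass(frozen=True)
class BuckleProfile:
    """Parametric cosine buckle: z_mid(x) = A cos(2 pi x / Xi).

    ``X0`` is the unbuckled box length, ``Xi = (1 - gamma) X0`` the buckled
    one; ``amplitude`` is solved so the arc length of one period equals X0.
    All lengths in nm; curvature in 1/nm.
    """

    X0: float
    Xi: float
    gamma: float
    amplitude: float

    @property
    def k(self) -> float:
        """Angular wavenumber 2 pi / Xi."""
        return 2.0 * np.pi / self.Xi

    def z(self, x):
        return self.amplitude * np.cos(self.k * np.asarray(x, dtype=float))

    def dz(self, x):
        return -self.amplitude * self.k * np.sin(self.k * np.asarray(x, dtype=float))

    def d2z(self, x):
        return -self.amplitude * self.k**2 * np.cos(self.k * np.asarray(x, dtype=float))

    def curvature(self, x):
        """Signed midplane graph curvature z'' / (1 + z'^2)^(3/2)."""
        zp = self.dz(x)
        return self.d2z(x) / (1.0 + zp**2) ** 1.5

    @property
    def max_curvature(self) -> float:
        """|curvature| at the crest/trough, A k^2 (slope vanishes there)."""
        return self.amplitude * self.k**2

    def arc_length(self) -> float:
        """Numerically integrated arc length of one period."""
        val, _ = quad(lambda u: np.sqrt(1.0 + self.dz(u) ** 2), 0.0, self.Xi,
                      limit=200)
        return val

    # --- normal-offset leaflet surfaces -----------------------------------

    def offset_validity(self, t: float) -> float:
        """min over x of (1 - t * curvature): must stay > 0 for the offset
        surface at signed distance t along the upward normal to be regular."""
        return 1.0 - abs(t) * self.max_curvature

    def offset_point(self, u, t: float):
        """Point of the offset surface at midplane parameter u.

        The upward unit normal of the graph is (-z', 1)/s with
        s = sqrt(1 + z'^2); the surface point is (x_p, z_p) =
        (u - t z'/s, z + t/s).
        """
        u = np.asarray(u, dtype=float)
        zp = self.dz(u)
        s = np.sqrt(1.0 + zp**2)
        return u - t * zp / s, self.z(u) + t / s

    def offset_speed(self, u, t: float):
        """|d(offset point)/du| = (1 - t kappa) s; used for arc length."""
        u = np.asarray(u, dtype=float)
        zp = self.dz(u)
        s = np.sqrt(1.0 + zp**2)
        return (1.0 - t * self.curvature(u)) * s

    def offset_curvature(self, u, t: float):
        """Signed graph curvature of the offset surface: kappa/(1 - t kappa)."""
        kap = self.curvature(u)
        return kap / (1.0 - t * kap)


def make_buckle_profile(X0: float, gamma: float, tol: float = 1e-6) -> BuckleProfile:
    """Construct the cosine buckle for strain ``gamma`` at box length ``X0``.

    The amplitude is found by bisection (Brent) on the arc-length condition
    L(A) = X0 to within ``tol`` nm.  gamma = 0 returns the flat profile
    (A = 0) exactly.
    """
    if not (0.0 <= gamma < 0.5):
        raise ValidationError(f"gamma={gamma} outside [0, 0.5)")
    if X0 <= 0:
        raise ValidationError("X0 must be positive")
    Xi = (1.0 - gamma) * X0
    if gamma == 0.0:
        return BuckleProfile(X0=X0, Xi=Xi, gamma=0.0, amplitude=0.0)
    k = 2.0 * np.pi / Xi

    def arclen(A: float) -> float:
        val, _ = quad(lambda u: np.sqrt(1.0 + (A * k * np.sin(k * u)) ** 2),
                      0.0, Xi, limit=200)
        return val

    lo, hi = 0.0, X0
    f_lo, f_hi = arclen(lo) - X0, arclen(hi) - X0
    if f_lo > 0 or f_hi < 0:  # pragma: no cover - cannot happen for gamma<0.5
        raise GeometryError(
            f"amplitude solver bracket failed: L(0)-X0={f_lo:.3g}, "
            f"L({X0})-X0={f_hi:.3g}"
        )
    A = brentq(lambda a: arclen(a) - X0, lo, hi, xtol=tol)
    return BuckleProfile(X0=X0, Xi=Xi, gamma=gamma, amplitude=float(A))


@dataclass(frozen=True)
class SortingModel:
    """Curvature-dependent placement model.

    ``slopes`` maps ``(leaflet, species)`` to the linear coefficient s of
    the species weight 1 + s*C (clipped at zero) used in the categorical
    species draw; C is the signed leaflet curvature (outer inverted).
    Unlisted pairs have s = 0.  ``d_half`` is the leaflet offset from the
    midplane along the local normal (nm), ``sigma_z`` the Gaussian noise on
    the headgroup z placement (nm) and ``bead_spacing`` the fixed spacing of
    the remaining beads stacked along the inward normal (nm).
    """

    slopes: Mapping[tuple[str, str], float] = field(default_factory=dict)
    d_half: float = 2.0
    sigma_z: float = 0.3
    bead_spacing: float = 0.3

    def __post_init__(self) -> None:
        if self.sigma_z < 0:
            raise ValidationError("sigma_z must be >= 0")
        if self.d_half <= 0:
            raise ValidationError("d_half must be positive")
        for (leaflet, _), s in self.slopes.items():
            if leaflet not in LEAFLETS:
                raise ValidationError(f"unknown leaflet {leaflet!r} in slopes")
            float(s)

    def slope(self, leaflet: str, species: str) -> float:
        return float(self.slopes.get((leaflet, species), 0.0))


@lru_cache(maxsize=32)
def _offset_tables(profile: BuckleProfile, t: float, n_grid: int):
    """Precomputed per-(profile, offset) arrays reused across frames:
    midplane parameter grid, cumulative offset arc length, slope and
    signed leaflet-surface curvature on the grid."""
    u_grid = np.linspace(0.0, profile.Xi, n_grid + 1)
    speed = profile.offset_speed(u_grid, t)
    cum = np.concatenate([[0.0], np.cumsum(
        (speed[1:] + speed[:-1]) / 2.0 * np.diff(u_grid))])
    return u_grid, cum


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def _leaflet_sign(leaflet: str) -> float:
    # outer leaflet sits along the upward normal, inner along the downward
    return 1.0 if leaflet == OUTER else -1.0


def sample_frame(
    profile: BuckleProfile,
    composition: Composition,
    model: SortingModel,
    seed,
    registry: Registry | None = None,
    Ly: float = 20.0,
    Lz: float = 20.0,
    headgroup_only: bool = False,
    with_truth: bool = True,
    n_grid: int = 4096,
) -> tuple[MembraneFrame, pd.DataFrame | None]:
    """Draw one equilibrium configuration plus its ground truth.

    For each leaflet, lipid anchor points are drawn uniformly in arc length
    along the normal-offset leaflet surface; species are assigned by a
    categorical draw with probability proportional to
    ``fraction_s * max(0, 1 + s * C(x))`` renormalized at each position,
    where C is the signed leaflet curvature (outer inverted).  If every
    slope of a leaflet is exactly zero the composition counts are honoured
    exactly (shuffled deterministic assignment).  The headgroup bead sits on
    the surface with Gaussian z noise; remaining beads are stacked along the
    inward local normal at ``model.bead_spacing``; y is uniform in [0, Ly).

    Returns the frame (with ground-truth leaflet labels attached) and a
    tidy ground-truth table (residue_id, species, leaflet, x,
    curvature_true, u).  Deterministic given ``seed``.
    """
    if registry is None:
        from .species import default_registry
        registry = default_registry()
    rng = np.random.default_rng(_as_seed_sequence(seed))

    for leaflet in LEAFLETS:
        t = _leaflet_sign(leaflet) * model.d_half
        if profile.offset_validity(t) < 0.05:
            raise GeometryError(
                f"leaflet offset d/2={model.d_half} too large for the "
                f"buckle (max |t*kappa| = {abs(t) * profile.max_curvature:.3f}); "
                "the offset surface would self-intersect"
            )

    Xi = profile.Xi
    bead_arrays = {"resid": [], "species": [], "bead": [], "pos": []}
    truth_rows = []
    leaflet_labels: dict[int, str] = {}
    next_resid = 1

    for leaflet in LEAFLETS:
        t = _leaflet_sign(leaflet) * model.d_half
        counts = composition.counts(leaflet)
        names = [s for s in counts if counts[s] > 0]
        n_lip = int(sum(counts.values()))
        if n_lip <= 0:
            raise ValidationError(f"{leaflet} leaflet has no lipids")
        fracs = np.array([counts[s] / n_lip for s in names])
        slopes = np.array([model.slope(leaflet, s) for s in names])

        # uniform-in-arc-length draw along the offset surface
        u_grid, cum = _offset_tables(profile, t, n_grid)
        targets = rng.uniform(0.0, cum[-1], size=n_lip)
        u = np.interp(targets, cum, u_grid)

        xs, zs = profile.offset_point(u, t)
        xs = np.mod(xs, Xi)
        kap_leaf = profile.offset_curvature(u, t)
        C = kap_leaf if leaflet == INNER else -kap_leaf

        if np.all(slopes == 0.0):
            # null model: counts, not fractions, drive the assignment
            pool = np.repeat(np.arange(len(names)), [counts[s] for s in names])
            rng.shuffle(pool)
            choice = pool
        else:
            w = fracs[None, :] * np.clip(1.0 + slopes[None, :] * C[:, None],
                                         0.0, None)
            tot = w.sum(axis=1)
            if np.any(tot <= 0):
                raise ModelInconsistencyError(
                    "sorting model clips every species to zero probability "
                    "at some curvature"
                )
            cdf = np.cumsum(w, axis=1) / tot[:, None]
            r = rng.random(n_lip)
            choice = (r[:, None] > cdf).sum(axis=1)

        y = rng.uniform(0.0, Ly, size=n_lip)
        z_noise = rng.normal(0.0, model.sigma_z, size=n_lip) if model.sigma_z > 0 \
            else np.zeros(n_lip)

        # inward unit normal: -(upward normal) for outer, +(upward) for inner
        zp = profile.dz(u)
        s_len = np.sqrt(1.0 + zp**2)
        nx, nz = -zp / s_len, 1.0 / s_len
        sign_in = -_leaflet_sign(leaflet)
        in_x, in_z = sign_in * nx, sign_in * nz

        resids = np.arange(next_resid, next_resid + n_lip)
        next_resid += n_lip
        if headgroup_only:
            # one headgroup bead per lipid: assemble without a species loop
            head_beads = np.array([registry[s].headgroup_bead for s in names])
            bead_arrays["resid"].append(resids)
            bead_arrays["species"].append(np.array(names)[choice])
            bead_arrays["bead"].append(head_beads[choice])
            bead_arrays["pos"].append(np.stack(
                [xs, y, zs + z_noise], axis=1))
            leaflet_labels.update(dict.fromkeys(resids.tolist(), leaflet))
            if with_truth:
                truth_rows.append(pd.DataFrame({
                    "residue_id": resids,
                    "species": np.array(names)[choice],
                    "leaflet": leaflet,
                    "x": xs,
                    "curvature_true": C,
                    "u": u,
                }))
            continue
        for i, sp in enumerate(names):
            sel = choice == i
            n_sel = int(sel.sum())
            if n_sel == 0:
                continue
            spec = registry[sp]
            if headgroup_only:
                bead_names = [spec.headgroup_bead]
                offsets = np.array([0.0])
            else:
                bead_names = list(spec.bead_names)
                i_head = bead_names.index(spec.headgroup_bead)
                offsets = model.bead_spacing * np.abs(
                    np.arange(len(bead_names)) - i_head)
            nb = len(bead_names)
            px = xs[sel, None] + in_x[sel, None] * offsets[None, :]
            pz = zs[sel, None] + in_z[sel, None] * offsets[None, :]
            pz[:, offsets == 0.0] += z_noise[sel, None]
            py = np.broadcast_to(y[sel, None], (n_sel, nb))
            pos = np.stack([np.mod(px, Xi).ravel(),
                            py.ravel(),
                            pz.ravel()], axis=1)
            bead_arrays["resid"].append(np.repeat(resids[sel], nb))
            bead_arrays["species"].append(np.repeat(np.array([sp], dtype=object),
                                                    n_sel * nb))
            bead_arrays["bead"].append(np.tile(np.array(bead_names, dtype=object),
                                               n_sel))
            bead_arrays["pos"].append(pos)

        leaflet_labels.update(dict.fromkeys(resids.tolist(), leaflet))
        if with_truth:
            truth_rows.append(pd.DataFrame({
                "residue_id": resids,
                "species": np.array(names)[choice],
                "leaflet": leaflet,
                "x": xs,
                "curvature_true": C,
                "u": u,
            }))

    order = np.argsort(np.concatenate(bead_arrays["resid"]), kind="stable")
    positions = np.concatenate(bead_arrays["pos"])[order]
    # shift z so the box holds all beads with the midplane at Lz/2
    positions[:, 2] += Lz / 2.0
    frame = MembraneFrame(
        box=(Xi, Ly, Lz),
        residue_id=np.concatenate(bead_arrays["resid"])[order],
        species=np.concatenate(bead_arrays["species"])[order],
        bead_name=np.concatenate(bead_arrays["bead"])[order],
        positions=positions,
        leaflet=leaflet_labels,
        title=f"synthetic buckled bilayer gamma={profile.gamma:g}",
    )
    truth = pd.concat(truth_rows, ignore_index=True) if with_truth else None
    return frame, truth


def generate_trajectory(
    profile: BuckleProfile,
    composition: Composition,
    model: SortingModel,
    n_frames: int,
    seed,
    **kwargs,
) -> tuple[Trajectory, pd.DataFrame]:
    """n_frames independent draws; per-frame seeds spawned from the master.

    Frames are statistically independent equilibrium samples (no
    autocorrelation); the ground-truth tables gain a ``frame`` column.
    Reproducible bit-for-bit for a given master seed.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    children = _as_seed_sequence(seed).spawn(n_frames)
    frames, truths = [], []
    for i, child in enumerate(children):
        frame, truth = sample_frame(profile, composition, model, child, **kwargs)
        frame.time = float(i)
        truth.insert(0, "frame", i)
        frames.append(frame)
        truths.append(truth)
    return Trajectory(frames=frames), pd.concat(truths, ignore_index=True)
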