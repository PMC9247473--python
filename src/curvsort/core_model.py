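"""Membrane data model, leaflet assignment, composition builder and GRO I/O.

The in-memory representation of a configuration is :class:`MembraneFrame`,
which stores bead-level arrays (residue id, species name, bead name,
position) plus the orthorhombic box.  Coordinates are nanometres throughout.
Leaflets are labelled ``"outer"`` (above the local midplane) and ``"inner"``
(below); labels are recomputed per frame because species such as cholesterol
can flip between leaflets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateMembraneError,
    GeometryError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

OUTER = "outer"
INNER = "inner"
LEAFLETS = (OUTER, INNER)


# ---------------------------------------------------------------------------
# static species description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidSpec:
    """Static description of one coarse-grained lipid species.

    Parameters
    ----------
    name : str
        Short species label, e.g. ``"POPC"``.
    headgroup_bead : str
        Bead that defines the leaflet surface (phosphate-type bead for
        phospholipids, hydroxyl bead for cholesterol).  The measured
        curvature depends on this choice, so it is configurable.
    bead_names : tuple of str
        Ordered bead inventory of the species.
    n_head_beads, n_tail_beads : int
        Head-region (headgroup + linker) and tail-region bead counts.
    n_tail_bonds, n_unsaturated_bonds : int
        Number of bonds within the acyl tails and how many of them are
        unsaturated.
    tails : tuple of tuple of str
        Per-tail bead-name sequences (0, 1 or 2 tails).
    """

    name: str
    headgroup_bead: str
    bead_names: tuple[str, ...]
    n_head_beads: int
    n_tail_beads: int
    n_tail_bonds: int
    n_unsaturated_bonds: int
    tails: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("species name must be nonempty")
        if any(not b for b in self.bead_names):
            raise ValidationError(f"{self.name}: empty bead name")
        if self.headgroup_bead not in self.bead_names:
            raise ValidationError(
                f"{self.name}: headgroup bead {self.headgroup_bead!r} "
                "not in bead inventory"
            )
        if self.n_head_beads + self.n_tail_beads > len(self.bead_names):
            raise ValidationError(
                f"{self.name}: head + tail bead counts exceed inventory"
            )
        if self.n_unsaturated_bonds > self.n_tail_bonds:
            raise ValidationError(
                f"{self.name}: more unsaturated bonds than tail bonds"
            )
        for tail in self.tails:
            for b in tail:
                if b not in self.bead_names:
                    raise ValidationError(
                        f"{self.name}: tail bead {b!r} not in inventory"
                    )

    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    @property
    def head_tail_ratio(self) -> float:
        if self.n_tail_beads == 0:
            raise ZeroDivisionError(f"{self.name} has no tail beads")
        return self.n_head_beads / self.n_tail_beads

    @property
    def unsaturation_fraction(self) -> float:
        if self.n_tail_bonds == 0:
            return 0.0
        return self.n_unsaturated_bonds / self.n_tail_bonds


Registry = Mapping[str, LipidSpec]


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionEntry:
    species: str
    fraction: float | None = None
    count: int | None = None

    def __post_init__(self) -> None:
        if self.fraction is None and self.count is None:
            raise ValidationError(
                f"{self.species}: need a fraction or a count"
            )
        if self.fraction is not None and not (0.0 <= self.fraction <= 1.0):
            raise ValidationError(
                f"{self.species}: fraction {self.fraction} outside [0, 1]"
            )
        if self.count is not None and (self.count < 0 or self.count != int(self.count)):
            raise ValidationError(f"{self.species}: count must be a nonnegative integer")


@dataclass(frozen=True)
class Composition:
    """Per-leaflet species fractions and/or explicit counts.

    Explicit counts always take precedence over fractions: the published
    per-species counts of the reference plasma-membrane composition are not
    reproducible from the printed fractions by any single rounding rule, so
    they are treated as authoritative when supplied.
    """

    leaflets: Mapping[str, tuple[CompositionEntry, ...]]

    def __post_init__(self) -> None:
        for leaflet, entries in self.leaflets.items():
            if leaflet not in LEAFLETS:
                raise ValidationError(f"unknown leaflet {leaflet!r}")
            names = [e.species for e in entries]
            if len(set(names)) != len(names):
                raise ValidationError(f"duplicate species in {leaflet} leaflet")
            fractions = [e.fraction for e in entries]
            if all(f is not None for f in fractions) and fractions:
                total = sum(fractions)
                if abs(total - 1.0) > 0.005:
                    raise ValidationError(
                        f"{leaflet} leaflet fractions sum to {total:.4f}, "
                        "outside 1 +/- 0.005"
                    )

    def species(self, leaflet: str) -> list[str]:
        return [e.species for e in self.leaflets[leaflet]]

    def counts(self, leaflet: str, total: int | None = None) -> dict[str, int]:
        """Resolve per-species integer counts for one leaflet.

        Explicit counts win; otherwise counts are apportioned from the
        fractions by :func:`build_counts` (``total`` required).
        """
        entries = self.leaflets[leaflet]
        if all(e.count is not None for e in entries):
            return {e.species: int(e.count) for e in entries}
        if total is None:
            raise ValidationError(
                f"{leaflet} leaflet has no explicit counts; a total is required"
            )
        fractions = [e.fraction for e in entries]
        if any(f is None for f in fractions):
            raise ValidationError(
                f"{leaflet} leaflet mixes missing fractions and missing counts"
            )
        counts = build_counts(fractions, total)
        return {e.species: c for e, c in zip(entries, counts)}

    def fractions(self, leaflet: str) -> dict[str, float]:
        counts = self.counts(leaflet)
        total = sum(counts.values())
        return {s: c / total for s, c in counts.items()}


def build_counts(fractions: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` lipids over species by largest remainder.

    Quotas ``fraction * total`` are floored; the leftover lipids go to the
    species with the largest fractional remainders, ties broken in favour of
    the first-listed species.  The result always sums exactly to ``total``.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.ndim != 1 or fr.size == 0:
        raise ValidationError("fractions must be a nonempty 1-D sequence")
    if np.any(fr < 0):
        raise ValidationError("fractions must be nonnegative")
    if abs(fr.sum() - 1.0) > 0.005:
        raise ValidationError(
            f"fractions sum to {fr.sum():.4f}, outside 1 +/- 0.005"
        )
    if total <= 0:
        raise ValidationError("total must be positive")
    quota = fr * total
    base = np.floor(quota).astype(int)
    leftover = int(total - base.sum())
    # stable argsort on the negated remainder: ties keep input order
    order = np.argsort(-(quota - base), kind="stable")
    counts = base.copy()
    counts[order[:leftover]] += 1
    return counts.tolist()


# ---------------------------------------------------------------------------
# frames and trajectories
# ---------------------------------------------------------------------------

@dataclass
class MembraneFrame:
    """One bilayer configuration: bead arrays plus an orthorhombic box."""

    box: tuple[float, float, float]
    residue_id: np.ndarray        # (n_beads,) int
    species: np.ndarray           # (n_beads,) str
    bead_name: np.ndarray         # (n_beads,) str
    positions: np.ndarray         # (n_beads, 3) float, nm
    leaflet: dict[int, str] | None = None
    time: float | None = None     # ns, optional metadata
    title: str = "curvsort frame"

    def __post_init__(self) -> None:
        self.residue_id = np.asarray(self.residue_id, dtype=np.int64)
        self.species = np.asarray(self.species, dtype=np.str_)
        self.bead_name = np.asarray(self.bead_name, dtype=np.str_)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.residue_id.size, 3):
            raise ValidationError("positions must be (n_beads, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("non-finite positions")
        if any(b <= 0 for b in self.box):
            raise ValidationError("box components must be positive")

    @property
    def n_beads(self) -> int:
        return self.residue_id.size

    @property
    def n_residues(self) -> int:
        return np.unique(self.residue_id).size

    def headgroup_mask(self, registry: Registry) -> np.ndarray:
        """Boolean mask over beads selecting each residue's headgroup bead."""
        present = np.unique(self.species)
        unknown = set(present) - set(registry)
        if unknown:
            raise ValidationError(
                f"species not in registry: {sorted(unknown)}"
            )
        mask = np.zeros(self.n_beads, dtype=bool)
        for name in present:
            spec = registry[name]
            mask |= (self.species == name) & (self.bead_name == spec.headgroup_bead)
        return mask


@dataclass
class Trajectory:
    """Ordered list of frames sharing one species registry."""

    frames: list[MembraneFrame]
    dt: float | None = None  # frame spacing, ns (metadata only)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValidationError("a trajectory needs at least one frame")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[MembraneFrame]:
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


# ---------------------------------------------------------------------------
# GRO format I/O
# ---------------------------------------------------------------------------

def read_gro(path: str | Path) -> MembraneFrame:
    """Read a GRO coordinate file (fixed width, nm) into a MembraneFrame.

    Velocities, if present, are ignored.  Only orthorhombic boxes are
    supported: a box line with any of the six off-diagonal components
    nonzero raises :class:`GeometryError`.  Residue ids are taken verbatim
    (the format wraps them at 100000; systems here are far smaller).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: file too short for GRO format")
    title = lines[0]
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"{path}: bad atom count line {lines[1]!r}") from exc
    if len(lines) < n_atoms + 3:
        raise ParseError(
            f"{path}: header declares {n_atoms} atoms but only "
            f"{len(lines) - 3} atom records precede the box line"
        )
    resid = np.empty(n_atoms, dtype=np.int64)
    resname = np.empty(n_atoms, dtype=object)
    atomname = np.empty(n_atoms, dtype=object)
    pos = np.empty((n_atoms, 3), dtype=float)
    for i in range(n_atoms):
        line = lines[2 + i]
        try:
            resid[i] = int(line[0:5])
            resname[i] = line[5:10].strip()
            atomname[i] = line[10:15].strip()
            pos[i, 0] = float(line[20:28])
            pos[i, 1] = float(line[28:36])
            pos[i, 2] = float(line[36:44])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: malformed atom record on line {3 + i}: "
                             f"{line!r}") from exc
    box_fields = lines[2 + n_atoms].split()
    try:
        box_vals = [float(v) for v in box_fields]
    except ValueError as exc:
        raise ParseError(f"{path}: malformed box line") from exc
    if len(box_vals) < 3:
        raise ParseError(f"{path}: box line has fewer than 3 components")
    if len(box_vals) > 3 and any(abs(v) > 1e-9 for v in box_vals[3:]):
        raise GeometryError(
            f"{path}: non-orthorhombic box not supported "
            f"(off-diagonal components {box_vals[3:]})"
        )
    time = None
    if "t=" in title:
        try:
            time = float(title.rsplit("t=", 1)[1].split()[0])
        except (ValueError, IndexError):
            time = None
    return MembraneFrame(
        box=(box_vals[0], box_vals[1], box_vals[2]),
        residue_id=resid,
        species=resname,
        bead_name=atomname,
        positions=pos,
        time=time,
        title=title,
    )


def write_gro(frame: MembraneFrame, path: str | Path) -> Path:
    """Write a MembraneFrame as a GRO file (positions at 3 decimals).

    Residue and atom ids are wrapped modulo 100000 silently, per the format.
    """
    path = Path(path)
    title = frame.title
    if frame.time is not None and "t=" not in title:
        title = f"{title} t= {frame.time:.3f}"
    out = [title, f"{frame.n_beads:5d}"]
    for i in range(frame.n_beads):
        out.append(
            f"{int(frame.residue_id[i]) % 100000:5d}"
            f"{str(frame.species[i]):<5.5s}"
            f"{str(frame.bead_name[i]):>5.5s}"
            f"{(i + 1) % 100000:5d}"
            f"{frame.positions[i, 0]:8.3f}"
            f"{frame.positions[i, 1]:8.3f}"
            f"{frame.positions[i, 2]:8.3f}"
        )
    out.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# leaflet assignment
# ---------------------------------------------------------------------------

def _periodic_interp(x: np.ndarray, centers: np.ndarray, values: np.ndarray,
                     period: float) -> np.ndarray:
    """Linear interpolation of bin-center values, periodic in x."""
    cx = np.concatenate([centers - period, centers, centers + period])
    cv = np.tile(values, 3)
    return np.interp(x, cx, cv)


def headgroup_leaflet_split(
    frame: MembraneFrame,
    registry: Registry,
    bin_width: float = 2.0,
    n_iter: int = 2,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Classify headgroup beads against the local midplane.

    Returns ``(resid, x, z, upper)`` arrays over headgroup beads, where
    ``upper`` is True for the outer leaflet.  This is the array core of
    :func:`assign_leaflets`, reused by the curvature pipeline to avoid a
    dict round trip on large trajectories.  ``mask`` may supply a
    precomputed headgroup-bead mask.
    """
    if mask is None:
        mask = frame.headgroup_mask(registry)
    resid = frame.residue_id[mask]
    if np.unique(resid).size < 2:
        raise DegenerateMembraneError("need at least 2 residues with headgroup beads")
    Lx = frame.box[0]
    x = np.mod(frame.positions[mask, 0], Lx)
    z = frame.positions[mask, 2]

    # keep every x bin populated (>= ~8 headgroups) so the binned midplane
    # is defined everywhere; sparse systems get coarser bins
    nb = max(4, min(int(round(Lx / bin_width)), x.size // 8))
    idx = np.minimum((x / Lx * nb).astype(int), nb - 1)
    centers = (np.arange(nb) + 0.5) * Lx / nb

    cnt = np.bincount(idx, minlength=nb)
    sums = np.bincount(idx, weights=z, minlength=nb)
    occ = cnt > 0
    mid = _periodic_interp(x, centers[occ], sums[occ] / cnt[occ], Lx)
    upper = z > mid

    for _ in range(n_iter):
        if upper.all() or not upper.any():
            break
        halves = []
        for sel in (upper, ~upper):
            c = np.bincount(idx[sel], minlength=nb)
            s = np.bincount(idx[sel], weights=z[sel], minlength=nb)
            halves.append(np.where(c > 0, s / np.maximum(c, 1), np.nan))
        # midplane defined only where both leaflets occupy the bin;
        # elsewhere it is interpolated periodically between valid bins
        prof = (halves[0] + halves[1]) / 2.0
        ok = np.isfinite(prof)
        if not ok.any():
            break
        mid = _periodic_interp(x, centers[ok], prof[ok], Lx)
        upper = z > mid

    if upper.all() or not upper.any():
        raise DegenerateMembraneError(
            "all lipids fell on one side of the midplane; "
            "input is not a bilayer"
        )
    return resid, x, z, upper


def assign_leaflets(
    frame: MembraneFrame,
    registry: Registry | None = None,
    bin_width: float = 2.0,
    n_iter: int = 2,
) -> dict[int, str]:
    """Label every lipid outer/inner relative to the local midplane.

    A buckled membrane's leaflets interleave in global z, so a global
    threshold is useless.  Instead, headgroup-bead z values are averaged in
    x bins (default 2 nm wide, periodic), the binned profile is linearly
    interpolated at each lipid's x, and lipids above it are labelled
    ``outer``.  The midplane is then refined ``n_iter`` times as the mean of
    the two per-leaflet binned surfaces, which removes the bias caused by
    unequal leaflet occupancy along the buckle.  Labels are recomputed per
    frame: species such as cholesterol may flip between leaflets.

    The labels are stored on ``frame.leaflet`` and returned.
    """
    if registry is None:
        from .species import default_registry
        registry = default_registry()
    resid, _, _, upper = headgroup_leaflet_split(frame, registry,
                                                 bin_width=bin_width,
                                                 n_iter=n_iter)
    labels = dict(zip(resid.tolist(),
                      np.where(upper, OUTER, INNER).tolist()))
    frame.leaflet = labels
    return labels
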