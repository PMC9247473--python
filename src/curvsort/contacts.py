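"""Lipid-lipid contact matrices and per-species structural descriptors.

A pair of distinct lipids in the same leaflet is "in contact" in a frame if
any bead-bead distance (minimum image in x and y) is below the cutoff
(default 1.0 nm); each unordered pair counts once per frame.  Raw contact
counts are normalized by the random-mixing expectation

    E_random(i, j) = T * f_i * f_j * (2 - delta_ij)

with T the total mean number of contacts and f the leaflet composition
fractions, so that ideal mixing gives 1 in every cell.

Descriptors: bead count (molecular volume proxy), head-to-tail bead ratio,
tail unsaturation fraction, P2 tail order parameter against the local
leaflet normal, and the splay angle between the two tail end-to-end
vectors.  Contacts are intra-leaflet only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .core_model import (
    INNER,
    LEAFLETS,
    OUTER,
    MembraneFrame,
    Registry,
    assign_leaflets,
)
from .curvature import fit_leaflet_spline
from .errors import (
    GeometryError,
    NotApplicableError,
    ValidationError,
)
from .sorting_stats import BlockStat, block_average

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "contact_matrix",
    "tail_order_parameter",
    "splay_angle",
    "descriptor_table",
    "curvature_descriptor_correlation",
]


def _ensure_labels(frame: MembraneFrame, registry: Registry) -> None:
    if frame.leaflet is None:
        assign_leaflets(frame, registry)


def _leaflet_bead_mask(frame: MembraneFrame, leaflet: str) -> np.ndarray:
    lab = frame.leaflet
    return np.array([lab.get(int(r)) == leaflet for r in frame.residue_id])


@dataclass
class ContactMatrix:
    """Symmetric species-by-species contact statistics for one leaflet."""

    leaflet: str
    species: list[str]
    raw: np.ndarray          # (S, S) mean contacts per frame
    norm: np.ndarray         # (S, S) block-mean normalized contacts
    norm_sd: np.ndarray      # (S, S) block SD
    norm_blocks: np.ndarray  # (n_blocks, S, S)
    n_blocks: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.species):
            for j, b in enumerate(self.species):
                if j < i:
                    continue
                rows.append({
                    "leaflet": self.leaflet, "species_a": a, "species_b": b,
                    "raw_mean": self.raw[i, j], "normalized": self.norm[i, j],
                    "normalized_sd": self.norm_sd[i, j],
                })
        return pd.DataFrame(rows)


def _frame_pair_counts(frame: MembraneFrame, leaflet: str, cutoff: float,
                       species_order: list[str],
                       bead_level: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Contact-count matrix and species composition counts for one frame.

    By default an unordered lipid pair counts once per frame if any bead
    pair is within the cutoff; with ``bead_level`` every bead pair within
    the cutoff is counted.
    """
    Lx, Ly, Lz = frame.box
    if cutoff >= min(Lx, Ly) / 2.0:
        raise GeometryError(
            f"cutoff {cutoff} nm violates the minimum-image convention for "
            f"box ({Lx}, {Ly})"
        )
    mask = _leaflet_bead_mask(frame, leaflet)
    if not mask.any():
        raise ValidationError(f"no beads in leaflet {leaflet!r}")
    pos = frame.positions[mask].copy()
    pos[:, 0] %= Lx
    pos[:, 1] %= Ly
    z0 = pos[:, 2].min()
    pos[:, 2] -= z0
    boxsize = [Lx, Ly, pos[:, 2].max() + 4.0 * cutoff + 1.0]
    tree = cKDTree(pos, boxsize=boxsize)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")

    resid = frame.residue_id[mask]
    species = frame.species[mask]
    # species per residue for the leaflet
    res_ids, first = np.unique(resid, return_index=True)
    res_species = species[first]
    code_of = {s: i for i, s in enumerate(species_order)}
    res_code = np.array([code_of[s] for s in res_species])
    res_index = {int(r): i for i, r in enumerate(res_ids)}
    bead_res = np.array([res_index[int(r)] for r in resid])

    S = len(species_order)
    mat = np.zeros((S, S))
    comp = np.bincount(res_code, minlength=S).astype(float)
    if pairs.size:
        ra, rb = bead_res[pairs[:, 0]], bead_res[pairs[:, 1]]
        distinct = ra != rb
        ra, rb = ra[distinct], rb[distinct]
        lo, hi = np.minimum(ra, rb), np.maximum(ra, rb)
        keys = lo.astype(np.int64) * len(res_ids) + hi
        if not bead_level:
            keys = np.unique(keys)
        ua, ub = keys // len(res_ids), keys % len(res_ids)
        ca, cb = res_code[ua], res_code[ub]
        np.add.at(mat, (np.minimum(ca, cb), np.maximum(ca, cb)), 1.0)
        mat = mat + np.triu(mat, 1).T  # symmetrize off-diagonal
    return mat, comp


def contact_matrix(
    frames,
    leaflet: str,
    registry: Registry | None = None,
    cutoff: float = 1.0,
    n_blocks: int = 4,
    bead_level: bool = False,
) -> ContactMatrix:
    """Normalized lipid-lipid contact matrix for one leaflet.

    Ideal mixing yields 1 in every cell; values above 1 indicate preferred
    association of the species pair.  ``bead_level`` switches from
    once-per-lipid-pair counting to counting every bead pair within the
    cutoff.
    """
    if registry is None:
        from .species import default_registry
        registry = default_registry()
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    frames = list(frames)
    for f in frames:
        _ensure_labels(f, registry)
    species_order = sorted({
        str(s) for f in frames
        for s in f.species[_leaflet_bead_mask(f, leaflet)]
    })
    if not species_order:
        raise ValidationError(f"leaflet {leaflet!r} is empty")

    mats, comps = [], []
    for f in frames:
        m, c = _frame_pair_counts(f, leaflet, cutoff, species_order,
                                  bead_level=bead_level)
        mats.append(m)
        comps.append(c)
    mats = np.array(mats)
    comps = np.array(comps)

    from .sorting_stats import block_bounds
    bounds = block_bounds(len(frames), n_blocks)
    S = len(species_order)
    norm_blocks = np.full((n_blocks, S, S), np.nan)
    for b, (a, z) in enumerate(bounds):
        raw_b = mats[a:z].mean(axis=0)
        f_b = comps[a:z].mean(axis=0)
        f_b = f_b / f_b.sum()
        T = np.triu(raw_b).sum()
        expected = T * np.outer(f_b, f_b) * (2.0 - np.eye(S))
        with np.errstate(invalid="ignore", divide="ignore"):
            norm_blocks[b] = np.where(expected > 0, raw_b / expected, np.nan)

    raw_mean = mats.mean(axis=0)
    return ContactMatrix(
        leaflet=leaflet, species=species_order, raw=raw_mean,
        norm=np.nanmean(norm_blocks, axis=0),
        norm_sd=np.nanstd(norm_blocks, axis=0, ddof=1),
        norm_blocks=norm_blocks, n_blocks=n_blocks,
    )


# ---------------------------------------------------------------------------
# dynamic descriptors
# ---------------------------------------------------------------------------

def _residue_bead_positions(frame: MembraneFrame, species: str,
                            spec) -> tuple[np.ndarray, np.ndarray]:
    """Positions reshaped (n_residues, n_beads, 3) in topology bead order."""
    mask = frame.species == species
    if not mask.any():
        raise ValidationError(f"species {species!r} not present in frame")
    resid = frame.residue_id[mask]
    names = frame.bead_name[mask]
    pos = frame.positions[mask]
    order = np.argsort(resid, kind="stable")
    resid, names, pos = resid[order], names[order], pos[order]
    nb = spec.n_beads
    if resid.size % nb != 0:
        raise ValidationError(
            f"{species}: bead count not a multiple of the inventory size"
        )
    n_res = resid.size // nb
    names = names.reshape(n_res, nb)
    if not np.all(names == np.array(spec.bead_names, dtype=object)[None, :]):
        raise ValidationError(
            f"{species}: bead order does not match the registry inventory"
        )
    return resid.reshape(n_res, nb)[:, 0], pos.reshape(n_res, nb, 3)


def _local_normals(frame: MembraneFrame, resids: np.ndarray,
                   x: np.ndarray, registry: Registry,
                   roughness: float, use_local_normal: bool) -> np.ndarray:
    """Unit membrane normal at each lipid's x (local from the leaflet
    spline's tangent rotated 90 degrees in the XZ plane, or global z)."""
    n = np.zeros((resids.size, 3))
    if not use_local_normal:
        n[:, 2] = 1.0
        return n
    curves = {}
    for leaflet in LEAFLETS:
        if any(frame.leaflet.get(int(r)) == leaflet for r in resids):
            curves[leaflet] = fit_leaflet_spline(frame, leaflet, registry,
                                                 roughness=roughness)
    for i, r in enumerate(resids):
        curve = curves[frame.leaflet[int(r)]]
        fp = float(curve.df(x[i]))
        s = np.sqrt(1.0 + fp * fp)
        n[i] = (-fp / s, 0.0, 1.0 / s)
    return n


def tail_order_parameter(
    frames,
    species: str,
    registry: Registry | None = None,
    use_local_normal: bool = True,
    roughness: float = 0.5,
    n_blocks: int = 4,
) -> BlockStat:
    """P2 = <(3 cos^2 theta - 1)/2> of consecutive tail-bead bonds.

    theta is measured against the membrane normal at the lipid's x position
    (local normal from the fitted leaflet spline by default; a flat
    membrane reduces to the global z axis).  Averaged over bonds, lipids
    and frames; block statistics over frames.
    """
    if registry is None:
        from .species import default_registry
        registry = default_registry()
    spec = registry[species]
    if not spec.tails or max(len(t) for t in spec.tails) < 2:
        raise NotApplicableError(
            f"{species}: no tail with >= 2 beads; P2 undefined")
    frames = list(frames)
    per_frame = []
    for frame in frames:
        _ensure_labels(frame, registry)
        resids, pos = _residue_bead_positions(frame, species, spec)
        i_head = spec.bead_names.index(spec.headgroup_bead)
        x = pos[:, i_head, 0]
        normals = _local_normals(frame, resids, x, registry, roughness,
                                 use_local_normal)
        cos2 = []
        for tail in spec.tails:
            idx = [spec.bead_names.index(b) for b in tail]
            for a, b in zip(idx[:-1], idx[1:]):
                bond = pos[:, b, :] - pos[:, a, :]
                norm = np.linalg.norm(bond, axis=1)
                ok = norm > 1e-12
                if not ok.all():
                    logger.warning("%s: %d zero-length bonds skipped",
                                   species, int((~ok).sum()))
                c = (bond[ok] * normals[ok]).sum(axis=1) / norm[ok]
                cos2.append(c**2)
        cos2 = np.concatenate(cos2)
        per_frame.append(float(np.mean(1.5 * cos2 - 0.5)))
    return block_average(per_frame, n_blocks=n_blocks)


def splay_angle(
    frames,
    species: str,
    registry: Registry | None = None,
    n_blocks: int = 4,
) -> BlockStat:
    """Mean angle (degrees) between the two tail end-to-end vectors."""
    if registry is None:
        from .species import default_registry
        registry = default_registry()
    spec = registry[species]
    if len(spec.tails) != 2:
        raise NotApplicableError(
            f"{species} has {len(spec.tails)} tails; splay needs exactly 2")
    frames = list(frames)
    per_frame = []
    for frame in frames:
        resids, pos = _residue_bead_positions(frame, species, spec)
        vecs = []
        for tail in spec.tails:
            a = spec.bead_names.index(tail[0])
            b = spec.bead_names.index(tail[-1])
            vecs.append(pos[:, b, :] - pos[:, a, :])
        v1, v2 = vecs
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        ok = (n1 > 1e-12) & (n2 > 1e-12)
        cosang = np.clip((v1[ok] * v2[ok]).sum(axis=1) / (n1[ok] * n2[ok]),
                         -1.0, 1.0)
        per_frame.append(float(np.degrees(np.arccos(cosang)).mean()))
    return block_average(per_frame, n_blocks=n_blocks)


def descriptor_table(
    registry: Registry,
    frames=None,
    species: list[str] | None = None,
    use_local_normal: bool = True,
    n_blocks: int = 4,
) -> pd.DataFrame:
    """Static (and, when frames are given, dynamic) species descriptors.

    Static: bead count, head-to-tail bead ratio, unsaturation fraction.
    Dynamic (frames required): mean P2 order parameter and mean splay angle
    (NaN for species without exactly two tails).
    """
    if species is None:
        species = list(registry)
    rows = []
    for name in species:
        spec = registry[name]
        if spec.n_tail_beads == 0:
            raise ValidationError(f"{name}: missing head/tail bead partition")
        row = {
            "species": name,
            "n_beads": spec.n_beads,
            "head_tail_ratio": spec.n_head_beads / spec.n_tail_beads,
            "unsaturation_fraction": spec.unsaturation_fraction,
        }
        if frames is not None:
            frames = list(frames)
            try:
                p2 = tail_order_parameter(frames, name, registry,
                                          use_local_normal=use_local_normal,
                                          n_blocks=n_blocks)
                row["p2"], row["p2_sd"] = p2.mean, p2.sd
            except NotApplicableError:
                row["p2"], row["p2_sd"] = np.nan, np.nan
            try:
                sp = splay_angle(frames, name, registry, n_blocks=n_blocks)
                row["splay_deg"], row["splay_sd"] = sp.mean, sp.sd
            except NotApplicableError:
                row["splay_deg"], row["splay_sd"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def curvature_descriptor_correlation(
    mean_curvature: dict[str, float],
    descriptor: dict[str, float],
    exclude: tuple[str, ...] = (),
) -> float:
    """Pearson r between per-species mean curvatures and a descriptor.

    The exclusion list (e.g. cholesterol) is applied before pairing; fewer
    than 3 pairs or zero variance raises an error.  The correlation is
    invariant to affine rescaling of either input.
    """
    keys = [k for k in mean_curvature if k in descriptor and k not in exclude]
    if len(keys) < 3:
        raise ValidationError(
            f"need >= 3 paired species after exclusion, got {len(keys)}")
    a = np.array([mean_curvature[k] for k in keys], dtype=float)
    b = np.array([descriptor[k] for k in keys], dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("zero variance: correlation undefined")
    return float(pearsonr(a, b).statistic)
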