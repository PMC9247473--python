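"""Curvature-partitioning statistics with 4-block averaging.

Every statistic is computed per contiguous frame block (default 4 blocks)
and reported as mean +/- sample SD across blocks, mirroring standard
block-averaged trajectory analysis.  The central object is the enrichment
profile: for curvature bin b and species s,

    F_s(b) = [n_s(b) / n_all(b)] / [N_s / N_all]

i.e. the species' share of lipids in the bin divided by its overall leaflet
share, so F = 1 everywhere means no curvature sorting.  Bins holding fewer
than 5% of the per-frame leaflet lipid count (on average) are masked and
excluded from all fits.  The partition slope is the per-block ordinary
least-squares slope of F_s against the bin-center curvature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import INNER, LEAFLETS, OUTER
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BlockStat",
    "block_average",
    "block_bounds",
    "leaflet_curvature_distribution",
    "EnrichmentProfile",
    "enrichment_profile",
    "partition_slope",
    "mean_curvature_per_species",
    "extreme_fraction",
    "localization_profile",
]


@dataclass(frozen=True)
class BlockStat:
    """Mean and sample SD of a statistic over contiguous trajectory blocks."""

    mean: float
    sd: float
    n_blocks: int
    values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


def _block_stat(values, ddof: int = 1) -> BlockStat:
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=ddof)) if arr.size > ddof else 0.0
    return BlockStat(mean=float(np.mean(arr)), sd=sd,
                     n_blocks=arr.size, values=tuple(arr.tolist()))


def block_bounds(n_frames: int, n_blocks: int = 4) -> list[tuple[int, int]]:
    """Contiguous equal blocks of frames; trailing remainder frames dropped."""
    if n_frames < n_blocks:
        raise ValidationError(
            f"{n_frames} frames cannot form {n_blocks} blocks"
        )
    size = n_frames // n_blocks
    dropped = n_frames - size * n_blocks
    if dropped:
        logger.warning("dropping %d trailing frames to form %d equal blocks",
                       dropped, n_blocks)
    return [(b * size, (b + 1) * size) for b in range(n_blocks)]


def block_average(values, n_blocks: int = 4, ddof: int = 1) -> BlockStat:
    """Split a per-frame series into contiguous blocks; mean +/- SD of the
    per-block means.  ``ddof=1`` (sample SD) by default."""
    arr = np.asarray(values, dtype=float)
    bounds = block_bounds(arr.size, n_blocks)
    means = [arr[a:b].mean() for a, b in bounds]
    return _block_stat(means, ddof=ddof)


def _frame_block_map(table: pd.DataFrame, n_blocks: int) -> tuple[pd.Series, int]:
    """Map each record's frame to a block id (-1 = dropped remainder)."""
    values = table["frame"].to_numpy()
    frames = np.unique(values)
    bounds = block_bounds(frames.size, n_blocks)
    block_of = np.full(frames.size, -1, dtype=int)
    for b, (a, z) in enumerate(bounds):
        block_of[a:z] = b
    mapped = block_of[np.searchsorted(frames, values)]
    used = int(sum(z - a for a, z in bounds))
    return pd.Series(mapped, index=table.index), used


# ---------------------------------------------------------------------------
# curvature histograms (leaflet distributions)
# ---------------------------------------------------------------------------

@dataclass
class LeafletHistogram:
    edges: np.ndarray
    centers: np.ndarray
    density: dict[str, np.ndarray]      # leaflet -> per-bin block mean
    density_sd: dict[str, np.ndarray]   # leaflet -> per-bin block SD
    occupancy: dict[str, np.ndarray]    # leaflet -> mean per-frame count per bin
    n_blocks: int = 4


def _aligned_edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi <= lo:
        hi = lo + width
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


def leaflet_curvature_distribution(
    table: pd.DataFrame,
    bin_width: float = 0.05,
    n_blocks: int = 4,
) -> LeafletHistogram:
    """Density-normalized curvature histogram per leaflet, block-averaged.

    Shared zero-aligned bin edges across leaflets so the two histograms are
    directly comparable bin by bin.
    """
    if table.empty:
        raise ValidationError("empty curvature table")
    edges = _aligned_edges(table["C"].to_numpy(), bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    blocks, _ = _frame_block_map(table, n_blocks)
    density, density_sd, occupancy = {}, {}, {}
    for leaflet in LEAFLETS:
        sub = table[table["leaflet"] == leaflet]
        if sub.empty:
            continue
        per_block = []
        for b in range(n_blocks):
            vals = sub.loc[blocks[sub.index] == b, "C"].to_numpy()
            if vals.size == 0:
                per_block.append(np.zeros(centers.size))
                continue
            h, _ = np.histogram(vals, bins=edges, density=True)
            per_block.append(h)
        per_block = np.array(per_block)
        density[leaflet] = per_block.mean(axis=0)
        density_sd[leaflet] = per_block.std(axis=0, ddof=1)
        n_frames = np.unique(sub["frame"]).size
        counts, _ = np.histogram(sub["C"].to_numpy(), bins=edges)
        occupancy[leaflet] = counts / n_frames
    return LeafletHistogram(edges=edges, centers=centers, density=density,
                            density_sd=density_sd, occupancy=occupancy,
                            n_blocks=n_blocks)


# ---------------------------------------------------------------------------
# enrichment profiles and partition slopes
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentProfile:
    """Binned normalized per-species lipid fraction versus curvature."""

    leaflet: str
    edges: np.ndarray
    centers: np.ndarray
    species: list[str]
    F: np.ndarray               # (S, B) pooled enrichment; nan in empty bins
    F_blocks: np.ndarray        # (n_blocks, S, B); nan where block bin empty
    occupancy: np.ndarray       # (B,) mean per-frame lipid count per bin
    low_occupancy: np.ndarray   # (B,) True = masked (< occupancy_frac share)
    share: np.ndarray           # (S,) overall leaflet share N_s / N_all
    n_blocks: int
    n_frames: int

    def masked_centers(self) -> np.ndarray:
        return self.centers[~self.low_occupancy]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (species, bin)."""
        rows = []
        sd = np.nanstd(self.F_blocks, axis=0, ddof=1)
        for i, s in enumerate(self.species):
            for j, c in enumerate(self.centers):
                rows.append({
                    "leaflet": self.leaflet, "species": s,
                    "bin_center": c, "F": self.F[i, j],
                    "F_sd": sd[i, j],
                    "occupancy": self.occupancy[j],
                    "masked": bool(self.low_occupancy[j]),
                })
        return pd.DataFrame(rows)


def enrichment_profile(
    table: pd.DataFrame,
    leaflet: str,
    bin_width: float = 0.05,
    occupancy_frac: float = 0.05,
    n_blocks: int = 4,
) -> EnrichmentProfile:
    """Normalized species fraction versus signed curvature for one leaflet.

    Bins are zero-aligned with uniform width.  The low-occupancy mask flags
    bins whose mean per-frame occupancy is below ``occupancy_frac`` times
    the per-frame leaflet lipid count; masked bins are excluded from fits
    but retained in the profile.
    """
    sub = table[table["leaflet"] == leaflet]
    if sub.empty:
        raise ValidationError(f"no records for leaflet {leaflet!r}")
    species = sorted(sub["species"].unique().tolist())
    edges = _aligned_edges(sub["C"].to_numpy(), bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    B, S = centers.size, len(species)

    blocks, _ = _frame_block_map(table, n_blocks)
    blk = blocks[sub.index].to_numpy()
    sp_code = pd.Categorical(sub["species"], categories=species).codes
    bin_idx = np.clip(np.digitize(sub["C"].to_numpy(), edges) - 1, 0, B - 1)

    keep = blk >= 0
    counts = np.zeros((n_blocks, S, B))
    np.add.at(counts, (blk[keep], sp_code[keep], bin_idx[keep]), 1.0)

    n_all_blk = counts.sum(axis=1)                      # (n_blocks, B)
    n_s_tot_blk = counts.sum(axis=2)                    # (n_blocks, S)
    n_tot_blk = n_s_tot_blk.sum(axis=1)                 # (n_blocks,)

    with np.errstate(invalid="ignore", divide="ignore"):
        share_blk = n_s_tot_blk / n_tot_blk[:, None]
        F_blocks = (counts / n_all_blk[:, None, :]) / share_blk[:, :, None]

    pooled = counts.sum(axis=0)                         # (S, B)
    n_all = pooled.sum(axis=0)
    share = pooled.sum(axis=1) / pooled.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (pooled / n_all[None, :]) / share[:, None]

    n_frames = np.unique(sub["frame"]).size
    all_counts = np.zeros(B)
    np.add.at(all_counts, bin_idx, 1.0)
    occupancy = all_counts / n_frames
    per_frame_total = len(sub) / n_frames
    low = occupancy < occupancy_frac * per_frame_total

    return EnrichmentProfile(
        leaflet=leaflet, edges=edges, centers=centers, species=species,
        F=F, F_blocks=F_blocks, occupancy=occupancy, low_occupancy=low,
        share=share, n_blocks=n_blocks, n_frames=n_frames,
    )


def partition_slope(profile: EnrichmentProfile, species: str) -> BlockStat:
    """OLS slope of F_s versus bin-center curvature, per block.

    Fits use unmasked bins that are nonempty in the block; fewer than 3
    such bins is an error.  The reported uncertainty is the block SD, not
    the fit standard error.
    """
    if species not in profile.species:
        raise ValidationError(
            f"species {species!r} absent from {profile.leaflet} leaflet"
        )
    i = profile.species.index(species)
    slopes = []
    for b in range(profile.n_blocks):
        Fb = profile.F_blocks[b, i]
        valid = (~profile.low_occupancy) & np.isfinite(Fb)
        if valid.sum() < 3:
            raise ValidationError(
                f"block {b}: only {int(valid.sum())} unmasked bins (< 3)"
            )
        slope, _ = np.polyfit(profile.centers[valid], Fb[valid], 1)
        slopes.append(slope)
    return _block_stat(slopes)


# ---------------------------------------------------------------------------
# per-species summaries
# ---------------------------------------------------------------------------

def _per_species_blockstat(table: pd.DataFrame, value_col: pd.Series,
                           n_blocks: int) -> pd.DataFrame:
    blocks, _ = _frame_block_map(table, n_blocks)
    df = pd.DataFrame({
        "species": table["species"], "leaflet": table["leaflet"],
        "block": blocks, "value": value_col,
    })
    df = df[df["block"] >= 0]
    per_block = df.groupby(["species", "leaflet", "block"], observed=True)["value"].mean()
    out = per_block.groupby(["species", "leaflet"], observed=True).agg(
        mean="mean", sd=lambda v: v.std(ddof=1), n_blocks="count")
    return out.reset_index()


def mean_curvature_per_species(table: pd.DataFrame,
                               n_blocks: int = 4) -> pd.DataFrame:
    """Block-averaged mean signed curvature per (species, leaflet)."""
    if table.empty:
        raise ValidationError("empty curvature table")
    return _per_species_blockstat(table, table["C"], n_blocks)


def extreme_fraction(table: pd.DataFrame, threshold: float = 0.1,
                     n_blocks: int = 4) -> pd.DataFrame:
    """Block-averaged fraction of |C| > threshold per (species, leaflet)."""
    if table.empty:
        raise ValidationError("empty curvature table")
    return _per_species_blockstat(
        table, (table["C"].abs() > threshold).astype(float), n_blocks)


def localization_profile(
    table: pd.DataFrame,
    leaflet: str,
    period: float,
    bin_width: float = 1.0,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Probability of lipid localization along the buckle coordinate x.

    Rows (species) sum to 1; species absent from the leaflet keep an
    all-zero row (flagged absent by the zero sum).
    """
    sub = table[table["leaflet"] == leaflet]
    if species is None:
        species = sorted(sub["species"].unique().tolist())
    n_bins = max(1, int(round(period / bin_width)))
    edges = np.linspace(0.0, period, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    out = np.zeros((len(species), n_bins))
    x = np.mod(sub["x"].to_numpy(), period)
    bin_idx = np.minimum((x / period * n_bins).astype(int), n_bins - 1)
    codes = pd.Categorical(sub["species"], categories=species).codes
    keep = codes >= 0
    np.add.at(out, (codes[keep], bin_idx[keep]), 1.0)
    totals = out.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(totals > 0, out / totals, 0.0)
    return pd.DataFrame(prob, index=pd.Index(species, name="species"),
                        columns=np.round(centers, 6))
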