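"""Bulk-flow observables: radial diffusivity, hematocrit profiles, cell-free
layer width and the near-wall platelet margination metric.

Conventions: the vessel axis is x; the radial coordinate of a point is
``r = sqrt(y^2 + z^2)`` about the tube axis.  The radius range [0, R] is
tiled by seven equal bins by default (at R = 50 um the bin centres fall at
3.6, 10.7, 17.9, 25.0, 32.1, 39.3, 46.4 um, width 7.14 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import TriMesh

__all__ = [
    "RadialBinning",
    "TrajectoryEnsemble",
    "DiffusivityProfile",
    "ConcentrationProfile",
    "radial_diffusivity",
    "cfl_width",
    "margination_index",
    "volume_fraction_profile",
]


@dataclass(frozen=True)
class RadialBinning:
    """Equal-width bins tiling [0, R]."""

    edges: np.ndarray  # (n+1,) um, increasing, edges[0] = 0

    @classmethod
    def for_radius(cls, radius_um: float, n_bins: int = 7) -> "RadialBinning":
        return cls(np.linspace(0.0, radius_um, n_bins + 1))

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def radius(self) -> float:
        return float(self.edges[-1])

    def annulus_volumes(self, length_um: float = 1.0) -> np.ndarray:
        """Volume of each annular bin for a tube segment of given length."""
        return np.pi * (self.edges[1:] ** 2 - self.edges[:-1] ** 2) * length_um

    def assign(self, radii: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.edges, radii, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class TrajectoryEnsemble:
    """Centre-of-mass time series for a population of cells.

    positions: (n_cells, n_times, 3) um; species: (n_cells,) labels.
    ``ground_truth`` carries generator parameters for synthetic ensembles.
    """

    times: np.ndarray  # (T,) s
    positions: np.ndarray  # (N, T, 3) um
    species: np.ndarray  # (N,) str labels
    axis_center: tuple = (0.0, 0.0)  # (y, z) of the tube axis
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species)
        if self.positions.shape[:2] != (len(self.species), len(self.times)):
            raise ValueError("positions shape inconsistent with times/species")

    @property
    def sampling_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def radii(self) -> np.ndarray:
        """(N, T) radial coordinate about the tube axis [um]."""
        cy, cz = self.axis_center
        return np.sqrt(
            (self.positions[:, :, 1] - cy) ** 2 + (self.positions[:, :, 2] - cz) ** 2
        )

    def to_frame(self) -> pd.DataFrame:
        n, t = self.positions.shape[:2]
        return pd.DataFrame(
            {
                "cell": np.repeat(np.arange(n), t),
                "species": np.repeat(self.species, t),
                "time_s": np.tile(self.times, n),
                "x_um": self.positions[:, :, 0].ravel(),
                "y_um": self.positions[:, :, 1].ravel(),
                "z_um": self.positions[:, :, 2].ravel(),
            }
        )


@dataclass
class DiffusivityProfile:
    """Radial diffusion coefficient D_rr per bin per species [um^2/s].

    Bins never visited by a species hold NaN (flagged missing, not zero).
    """

    binning: RadialBinning
    d_rr: dict  # species -> (n_bins,) um^2/s, NaN where missing
    counts: dict  # species -> (n_bins,) window counts
    stderr: dict = field(default_factory=dict)  # species -> (n_bins,)
    window_s: float = 5e-4
    duration_s: float = 0.4

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp, d in self.d_rr.items():
            se = self.stderr.get(sp)
            for b in range(self.binning.n_bins):
                rows.append(
                    {
                        "bin_center_um": self.binning.centers[b],
                        "species": sp,
                        "d_rr_um2_s": d[b],
                        "stderr": np.nan if se is None else se[b],
                        "n_windows": self.counts[sp][b],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def radial_diffusivity(
    ensemble: TrajectoryEnsemble,
    bins: RadialBinning,
    window_s: float = 5e-4,
    duration_s: float = 0.4,
) -> DiffusivityProfile:
    """D_rr per radial bin from windowed mean-squared radial displacements.

    Non-overlapping windows of length `window_s` are taken from the trailing
    `duration_s` of each trajectory; a window contributes
    ``dr^2 / (2 * window)`` to the bin containing its starting radius.
    """
    dt = ensemble.sampling_interval
    if dt > window_s / 2 * 1.05:
        raise ValueError("sampling interval must be <= window/2")
    w = int(round(window_s / dt))
    r = ensemble.radii()
    t0 = max(0, len(ensemble.times) - int(round(duration_s / dt)) - 1)
    starts = np.arange(t0, r.shape[1] - w, w)
    if len(starts) == 0:
        raise ValueError("duration too short for a single window")
    r0 = r[:, starts]
    dr2 = (r[:, starts + w] - r0) ** 2
    bin_idx = bins.assign(r0)
    species = np.unique(ensemble.species)
    d_rr, counts, stderr = {}, {}, {}
    for sp in species:
        sel = ensemble.species == sp
        d = np.full(bins.n_bins, np.nan)
        se = np.full(bins.n_bins, np.nan)
        n = np.zeros(bins.n_bins, dtype=int)
        bi = bin_idx[sel].ravel()
        vals = dr2[sel].ravel() / (2.0 * w * dt)
        for b in range(bins.n_bins):
            m = bi == b
            n[b] = m.sum()
            if n[b]:
                d[b] = vals[m].mean()
                if n[b] > 1:
                    se[b] = vals[m].std(ddof=1) / np.sqrt(n[b])
        d_rr[str(sp)] = d
        counts[str(sp)] = n
        stderr[str(sp)] = se
    return DiffusivityProfile(
        bins, d_rr, counts, stderr, window_s=w * dt, duration_s=duration_s
    )


def _frame_points(frame):
    """Normalise a snapshot to (points (M,3), labels (M,))."""
    if isinstance(frame, TriMesh):
        frame = [frame]
    if isinstance(frame, (list, tuple)) and frame and isinstance(frame[0], TriMesh):
        pts = np.concatenate([m.vertices for m in frame])
        lab = np.concatenate(
            [np.full(m.n_vertices, m.species_label, dtype=object) for m in frame]
        )
        return pts, lab
    pts, lab = frame
    return np.asarray(pts, dtype=float), np.asarray(lab)


def cfl_width(
    snapshots,
    wall_radius_um: float,
    axis_center=(0.0, 0.0),
    n_sectors: int = 12,
    species_prefix: str = "",
) -> dict:
    """Cell-free layer width per species [um].

    For every snapshot and azimuthal sector, the distance from the wall to the
    nearest membrane point in that sector (the wall radius when the sector is
    empty); sector values are averaged over sectors and snapshots.

    `snapshots` is a list of frames; each frame is a list of TriMesh or a
    (points, labels) tuple.  Returns {species: mean CFL}.
    """
    if isinstance(snapshots, TriMesh) or (
        isinstance(snapshots, tuple) and len(snapshots) == 2
    ):
        snapshots = [snapshots]
    cy, cz = axis_center
    per_species: dict = {}
    for frame in snapshots:
        pts, lab = _frame_points(frame)
        keep = np.char.startswith(lab.astype(str), species_prefix)
        pts, lab = pts[keep], lab[keep]
        for sp in np.unique(lab).tolist() if len(lab) else []:
            sel = lab == sp
            y = pts[sel, 1] - cy
            z = pts[sel, 2] - cz
            r = np.sqrt(y * y + z * z)
            ang = np.mod(np.arctan2(z, y), 2 * np.pi)
            sector = np.minimum((ang / (2 * np.pi) * n_sectors).astype(int), n_sectors - 1)
            widths = np.full(n_sectors, wall_radius_um)
            for s in range(n_sectors):
                m = sector == s
                if m.any():
                    widths[s] = max(wall_radius_um - r[m].max(), 0.0)
            per_species.setdefault(str(sp), []).append(widths.mean())
    return {sp: float(np.mean(v)) for sp, v in per_species.items()}


@dataclass
class ConcentrationProfile:
    """Per-bin volume fraction per species, with the platelet profile also
    available normalised to its vessel mean (C_plt)."""

    binning: RadialBinning
    fractions: dict  # species -> (n_bins,) local volume fraction

    def c_plt(self, platelet_label: str = "platelet") -> np.ndarray:
        """Normalised platelet concentration: local fraction over the
        bin-volume-weighted vessel mean (weighted mean of the result is 1)."""
        frac = self.fractions[platelet_label]
        vols = self.binning.annulus_volumes()
        mean = (frac * vols).sum() / vols.sum()
        if mean == 0:
            raise ZeroDivisionError("platelet fraction is identically zero")
        return frac / mean

    @classmethod
    def from_points(
        cls, points, labels, binning: RadialBinning, axis_center=(0.0, 0.0)
    ) -> "ConcentrationProfile":
        """Point-particle concentration profile (number density per bin,
        in units of count per um^3 of annulus; adequate for ratios)."""
        pts = np.asarray(points, dtype=float)
        lab = np.asarray(labels)
        cy, cz = axis_center
        r = np.sqrt((pts[:, 1] - cy) ** 2 + (pts[:, 2] - cz) ** 2)
        vols = binning.annulus_volumes()
        fractions = {}
        for sp in np.unique(lab):
            idx = binning.assign(r[lab == sp])
            counts = np.bincount(idx, minlength=binning.n_bins).astype(float)
            fractions[str(sp)] = counts / vols
        return cls(binning, fractions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp, f in self.fractions.items():
            for b in range(self.binning.n_bins):
                rows.append(
                    {
                        "bin_center_um": self.binning.centers[b],
                        "species": sp,
                        "volume_fraction": f[b],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def _wall_band_mean(profile: ConcentrationProfile, width_um: float, label: str) -> float:
    """Mean platelet concentration in the annular band within `width_um` of
    the wall, bin overlaps volume-weighted."""
    b = profile.binning
    r_in = b.radius - width_um
    lo = np.maximum(b.edges[:-1], r_in)
    hi = b.edges[1:]
    overlap = np.pi * np.maximum(hi**2 - lo**2, 0.0) * (hi > r_in)
    frac = profile.fractions[label]
    w = overlap.sum()
    if w == 0:
        raise ValueError("wall region does not overlap any bin")
    return float((frac * overlap).sum() / w)


def margination_index(
    profile: ConcentrationProfile,
    wall_region_width_um: float,
    reference: ConcentrationProfile,
    platelet_label: str = "platelet",
) -> float:
    """Near-wall platelet concentration of `profile` divided by the same
    quantity in `reference` (conventionally the 100% healthy run)."""
    val = _wall_band_mean(profile, wall_region_width_um, platelet_label)
    ref = _wall_band_mean(reference, wall_region_width_um, platelet_label)
    if ref == 0:
        raise ZeroDivisionError("reference near-wall platelet concentration is zero")
    return val / ref


def volume_fraction_profile(
    meshes,
    bins: RadialBinning,
    dx_um: float = 0.5,
    axis_center=(0.0, 0.0),
    x_range=None,
) -> ConcentrationProfile:
    """Species-resolved volume-fraction profile by voxelised membership.

    Voxel centres at resolution `dx_um` inside the annular bins are tested
    against each closed mesh; a bin's fraction for a species is the occupied
    voxel count over the bin's voxel count.  `x_range` defaults to the tight
    x-extent of the meshes (a periodic tube segment should pass its period).
    """
    from .voxel import inside_mask

    meshes = list(meshes)
    if x_range is None:
        lo = min(m.vertices[:, 0].min() for m in meshes)
        hi = max(m.vertices[:, 0].max() for m in meshes)
        x_range = (lo, hi)
    R = bins.radius
    cy, cz = axis_center
    xs = np.arange(x_range[0] + dx_um / 2, x_range[1], dx_um)
    ys = np.arange(cy - R + dx_um / 2, cy + R, dx_um)
    zs = np.arange(cz - R + dx_um / 2, cz + R, dx_um)
    yy, zz = np.meshgrid(ys - cy, zs - cz, indexing="ij")
    rr = np.sqrt(yy**2 + zz**2)
    bin_of_col = bins.assign(rr.ravel()).reshape(rr.shape)
    in_tube = rr < R
    col_counts = np.bincount(bin_of_col[in_tube].ravel(), minlength=bins.n_bins)
    total = col_counts.astype(float) * len(xs)  # voxels per bin
    species = sorted({m.species_label for m in meshes})
    occupied = {sp: np.zeros(bins.n_bins) for sp in species}
    for m in meshes:
        mask = inside_mask(m.vertices, m.triangles, xs, ys, zs)
        mask &= in_tube[None, :, :]
        counts = np.bincount(
            bin_of_col[None, :, :].repeat(len(xs), axis=0)[mask].ravel(),
            minlength=bins.n_bins,
        )
        occupied[m.species_label] += counts
    fractions = {
        sp: np.divide(occ, total, out=np.zeros_like(occ), where=total > 0)
        for sp, occ in occupied.items()
    }
    return ConcentrationProfile(bins, fractions)
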