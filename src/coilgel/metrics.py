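"""Fibril trajectory analysis: radial densities, normalized diameters and
the dielectric × size stability phase diagram.

* ``radial_density`` — the normalized radial density g̃(r) = n(r)/N, where
  n(r) is the ensemble-averaged inter-CC pair count per bin of width
  δr = 0.5 Å and N is the fibril size (N = 4 for the 4 × 4 fibril).  All
  intra-CC pairs are excluded.
* ``com_radial_density`` — the same distribution on coiled-coil centers of
  mass, multiplied by 20,000 to be plottable on the all-site scale.
* ``fibril_diameter`` — after aligning each frame's CC COMs to their
  principal axes (long axis → x, second → z), COM histograms along y and z
  (1 nm bins, counts normalized per √(protofibril count) = N) are
  thresholded at 3.0; the diameter is the distance between the outermost
  bin edges above threshold, averaged over y and z, and the *normalized*
  diameter d̃ divides by the total protofibril count N².  No bin above
  threshold means the fibril dissociated and d̃ = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


@dataclass
class RadialDensityProfile:
    bin_edges: np.ndarray   # Å
    values: np.ndarray      # g̃ per bin
    fibril_size: int
    variant: str            # "all-site" | "com"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class DiameterEstimate:
    diameter_y: float       # nm
    diameter_z: float       # nm
    diameter: float         # nm, mean of y and z
    normalized: float       # nm / protofibril (d̃ = diameter / N²)
    associated: bool


@dataclass
class StabilityPhaseDiagram:
    table: pd.DataFrame     # columns: dielectric, n_side, mean, sd, n, ...

    def cell(self, dielectric: float, n_side: int) -> pd.Series:
        t = self.table
        row = t[(t.dielectric == dielectric) & (t.n_side == n_side)]
        if row.empty:
            raise KeyError(f"no cell ({dielectric}, {n_side})")
        return row.iloc[0]


def _as_frames(trajectory: np.ndarray) -> np.ndarray:
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.ndim == 2:
        trajectory = trajectory[None]
    if trajectory.ndim != 3:
        raise ValueError("trajectory must be (n_frames, n_sites, 3)")
    return trajectory


def radial_density(trajectory: np.ndarray, cc_labels: np.ndarray,
                   dr: float = 0.5, fibril_size: int = 1,
                   r_max: float | None = None,
                   variant: str = "all-site") -> RadialDensityProfile:
    """Ensemble-averaged inter-CC pair histogram, normalized by fibril size."""
    frames = _as_frames(trajectory)
    cc_labels = np.asarray(cc_labels)
    if len(cc_labels) != frames.shape[1]:
        raise ValueError("every site needs a coiled-coil label")
    iu, ju = np.triu_indices(frames.shape[1], k=1)
    inter = cc_labels[iu] != cc_labels[ju]
    iu, ju = iu[inter], ju[inter]
    if r_max is None:
        r_max = 0.0
        for f in frames:
            if iu.size:
                r_max = max(r_max, float(
                    np.linalg.norm(f[ju] - f[iu], axis=1).max()))
        r_max = max(r_max + dr, dr)
    edges = dr * np.arange(int(np.ceil(r_max / dr)) + 1)
    counts = np.zeros(len(edges) - 1)
    for f in frames:
        if iu.size:
            d = np.linalg.norm(f[ju] - f[iu], axis=1)
            counts += np.histogram(d, bins=edges)[0]
    counts /= len(frames)
    return RadialDensityProfile(edges, counts / fibril_size, fibril_size,
                                variant)


def cc_centers_of_mass(frames: np.ndarray, cc_labels: np.ndarray,
                       masses: np.ndarray | None = None) -> np.ndarray:
    """(n_frames, n_cc, 3) per-CC centers of mass (unit masses by default)."""
    frames = _as_frames(frames)
    cc_labels = np.asarray(cc_labels)
    masses = (np.ones(frames.shape[1]) if masses is None
              else np.asarray(masses, dtype=float))
    ccs = np.unique(cc_labels)
    coms = np.empty((frames.shape[0], len(ccs), 3))
    for ci, cc in enumerate(ccs):
        sel = cc_labels == cc
        w = masses[sel] / masses[sel].sum()
        coms[:, ci] = np.einsum("s,fsi->fi", w, frames[:, sel])
    return coms


def com_radial_density(trajectory: np.ndarray, cc_labels: np.ndarray,
                       masses: np.ndarray | None = None, dr: float = 0.5,
                       fibril_size: int = 1, r_max: float | None = None,
                       scale: float = 20_000.0) -> RadialDensityProfile:
    """Radial density of coiled-coil centers of mass, scaled by ×20,000."""
    coms = cc_centers_of_mass(trajectory, cc_labels, masses)
    prof = radial_density(coms, np.arange(coms.shape[1]), dr=dr,
                          fibril_size=fibril_size, r_max=r_max, variant="com")
    prof.values = prof.values * scale
    return prof


def align_principal_axes(points: np.ndarray) -> np.ndarray:
    """Center points and rotate: largest-variance axis → x, second → z.

    Raises on degenerate (rank < 2) covariance.  The returned frame has a
    proper rotation applied (det = +1); axis signs are otherwise arbitrary.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 3:
        raise ValueError("need >= 3 points to define principal axes")
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / len(points)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] <= 1e-12 * max(evals[-1], 1e-30):
        raise ValueError("degenerate COM covariance: points are collinear")
    # columns: new x (largest), y (smallest), z (second)
    R = np.column_stack([evecs[:, 2], evecs[:, 0], evecs[:, 1]])
    if np.linalg.det(R) < 0:
        R[:, 1] = -R[:, 1]
    rotated = centered @ R
    check = rotated.T @ rotated / len(points)
    off = np.abs(check - np.diag(np.diag(check))).max()
    if off > 1e-6 * np.trace(check):
        raise ValueError("principal-axis alignment failed")
    return rotated


def fibril_diameter(trajectory: np.ndarray, cc_labels: np.ndarray,
                    n_side: int, masses: np.ndarray | None = None,
                    bin_nm: float = 1.0, threshold: float = 3.0
                    ) -> DiameterEstimate:
    """Normalized fibril diameter d̃ from thresholded COM histograms.

    Each frame's CC COMs are aligned to principal axes; y and z histograms
    (``bin_nm`` bins, ensemble-averaged counts divided by n_side) are
    thresholded at ``threshold`` #/protofibril^1/2.  Dissociation (no bin
    above threshold in either direction) yields d̃ = 0.
    """
    coms = cc_centers_of_mass(trajectory, cc_labels, masses) / 10.0  # Å -> nm
    aligned = np.stack([align_principal_axes(f) for f in coms])
    extent = max(1.0, float(np.abs(aligned[:, :, 1:]).max()) + bin_nm)
    n_bins = int(np.ceil(extent / bin_nm))
    # half-open bins *centered* on the aligned centroid's origin grid, so a
    # ±-symmetric lattice is not split across bin edges
    edges = bin_nm * (np.arange(-n_bins, n_bins + 2) - 0.5)
    diameters = []
    for axis in (1, 2):  # y, z
        counts = np.zeros(len(edges) - 1)
        for f in aligned:
            counts += np.histogram(f[:, axis], bins=edges)[0]
        norm = counts / len(aligned) / n_side
        above = np.nonzero(norm > threshold)[0]
        if above.size == 0:
            diameters.append(0.0)
        else:
            diameters.append(float(edges[above[-1] + 1] - edges[above[0]]))
    dy, dz = diameters
    if dy == 0.0 or dz == 0.0:
        return DiameterEstimate(dy, dz, 0.0, 0.0, associated=False)
    diameter = 0.5 * (dy + dz)
    return DiameterEstimate(dy, dz, diameter, diameter / n_side**2,
                            associated=True)


def build_phase_diagram(runs) -> StabilityPhaseDiagram:
    """Aggregate per-replica diameter estimates into an (ϵ, N) table.

    ``runs`` is an iterable of ``(dielectric, n_side, replicas)`` where
    ``replicas`` is a non-empty list of :class:`DiameterEstimate`.  Cells
    report mean ± sd of d̃ over replicas; a single-replica cell carries
    ``single_replica=True``; a cell is associated iff its mean d̃ > 0.
    """
    rows = []
    for dielectric, n_side, replicas in runs:
        replicas = list(replicas)
        if not replicas:
            raise ValueError(f"empty cell ({dielectric}, {n_side})")
        vals = np.array([r.normalized for r in replicas])
        rows.append({
            "dielectric": dielectric, "n_side": n_side,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=0)),
            "n": len(vals),
            "single_replica": len(vals) == 1,
            "associated": bool(vals.mean() > 0),
        })
    return StabilityPhaseDiagram(pd.DataFrame(rows))


@dataclass
class PairDistanceProfile:
    bin_edges: np.ndarray
    p: np.ndarray            # normalized: sum(p) * bin width = 1
    peaks: np.ndarray        # peak positions (bin centers)


def pair_distance_distribution(coordinates: np.ndarray, bin_width: float = 1.0
                               ) -> PairDistanceProfile:
    """Normalized all-pair distance histogram P(r) with peak positions.

    A model-side analog of a small-angle-scattering pair distance
    distribution, for qualitative peak-position comparison only.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or len(coords) < 2:
        raise ValueError("need >= 2 points")
    iu, ju = np.triu_indices(len(coords), k=1)
    d = np.linalg.norm(coords[ju] - coords[iu], axis=1)
    edges = bin_width * np.arange(int(np.ceil(d.max() / bin_width)) + 2)
    counts = np.histogram(d, bins=edges)[0].astype(float)
    p = counts / counts.sum() / bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx, _ = find_peaks(np.concatenate([[0.0], p, [0.0]]))
    return PairDistanceProfile(edges, p, centers[idx - 1])
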