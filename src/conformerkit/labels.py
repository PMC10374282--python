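"""Accessible-volume (AV/ACV) label simulation and inter-label distance observables.

FRET dyes and nitroxide spin labels are coupled to the protein through flexible
linkers, so an experiment reports a distance between two *positional
distributions*, not between two backbone atoms.  The accessible volume (AV)
model approximates the label as a sphere on a flexible tether: every grid point
that (i) lies within the linker length of the attachment atom, (ii) does not
clash with any protein bead, and (iii) can be reached from the attachment point
through clash-free space carries equal weight.  The accessible *contact* volume
(ACV) refinement re-weights points close to the protein surface to model dyes
that transiently stack against it.

From a pair of clouds one obtains the inter-label distance distribution
``p(R)``, its moments, and the FRET observables: the mean efficiency

    E = sum_ij w_i w_j / (1 + (R_ij / R0)^6)

(with the orientation factor fixed at kappa^2 = 2/3 for mobile dyes) and the
FRET-averaged distance ``R_E = R0 * (1/E - 1)^(1/6)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure import CoarseStructure

__all__ = [
    "LabelSite",
    "LabelCloud",
    "DistanceDistribution",
    "InaccessibleSiteError",
    "compute_av",
    "apply_acv",
    "distance_distribution",
    "fret_observables",
    "MTSSL_SITE_DEFAULTS",
]


class InaccessibleSiteError(RuntimeError):
    """Raised when an attachment site has no sterically allowed label position."""


@dataclass(frozen=True)
class LabelSite:
    """Geometric parameters of one label attachment site.

    ``linker_length``/``linker_width`` and ``label_radius`` follow the
    single-effective-radius AV convention; ``contact_distance`` and
    ``contact_fraction`` parameterize the ACV re-weighting (fraction of dyes
    trapped within ``contact_distance`` of the protein surface).
    All lengths in angstrom.
    """

    residue_id: int
    attachment: np.ndarray = None  # resolved from structure when None
    linker_length: float = 20.0
    linker_width: float = 4.5
    label_radius: float = 3.5
    contact_distance: float = 4.0
    contact_fraction: float = 0.0
    chain_id: str | None = None

    def __post_init__(self):
        if self.linker_length <= 0:
            raise ValueError("linker length must be positive")
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact fraction must lie in [0, 1]")


#: AV parameters used for MTSSL spin labels (shorter tether than FRET dyes).
MTSSL_SITE_DEFAULTS = dict(linker_length=8.0, linker_width=4.5, label_radius=2.5)


@dataclass
class LabelCloud:
    """Weighted point cloud of allowed label positions around one anchor."""

    points: np.ndarray
    weights: np.ndarray
    anchor: np.ndarray
    site: LabelSite = None
    contact_mask: np.ndarray = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.weights = np.asarray(self.weights, float)
        if len(self.points) == 0:
            raise InaccessibleSiteError("label cloud is empty")
        if np.any(self.weights < 0):
            raise ValueError("cloud weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("cloud weights must have positive sum")
        self.weights = self.weights / total
        self.anchor = np.asarray(self.anchor, float)

    def __len__(self):
        return len(self.points)

    @property
    def mean_position(self) -> np.ndarray:
        return self.weights @ self.points

    def save_xyz(self, path):
        """Write as open XYZ-with-weights text: x y z w per line."""
        header = f"{len(self)}\nlabel cloud; columns: x y z weight (angstrom)"
        data = np.column_stack([self.points, self.weights])
        np.savetxt(path, data, header=header, comments="")


@dataclass
class DistanceDistribution:
    """Probability density over an inter-label distance grid (uniform spacing)."""

    r: np.ndarray
    p: np.ndarray
    kind: str = "FRET"  # or "spin"
    scaled_by: float = 1.0  # 1 - x_DOnly when deliberately sub-normalized

    def __post_init__(self):
        self.r = np.asarray(self.r, float)
        self.p = np.asarray(self.p, float)
        if np.any(self.p < -1e-12):
            raise ValueError("distance density must be non-negative")
        self.p = np.clip(self.p, 0.0, None)
        dr = np.diff(self.r)
        if len(dr) and not np.allclose(dr, dr[0], rtol=1e-6):
            raise ValueError("distance grid must be uniform")

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0]) if len(self.r) > 1 else 1.0

    def normalized(self) -> "DistanceDistribution":
        area = np.trapezoid(self.p, self.r)
        return replace(self, p=self.p / area, scaled_by=1.0)

    def mean(self) -> float:
        return float(np.trapezoid(self.r * self.p, self.r) / np.trapezoid(self.p, self.r))

    def std(self) -> float:
        m = self.mean()
        var = np.trapezoid((self.r - m) ** 2 * self.p, self.r) / np.trapezoid(self.p, self.r)
        return float(np.sqrt(max(var, 0.0)))

    def save_csv(self, path):
        np.savetxt(
            path,
            np.column_stack([self.r, self.p]),
            delimiter=",",
            header=f"distance_A,p ({self.kind})",
            comments="",
        )

    @classmethod
    def gaussian_mixture(cls, means, widths, fractions, r_grid, kind="FRET"):
        """Normalized Gaussian mixture truncated to a positive distance grid.

        ``widths`` follow the FWHM-like convention w such that each component
        is ``exp(-2 ((r - mean)/w)^2)`` (i.e. sigma = w / 2).
        """
        r = np.asarray(r_grid, float)
        means = np.atleast_1d(np.asarray(means, float))
        widths = np.broadcast_to(np.atleast_1d(np.asarray(widths, float)), means.shape)
        fractions = np.atleast_1d(np.asarray(fractions, float))
        p = np.zeros_like(r)
        for m, w, x in zip(means, widths, fractions):
            p += x * np.exp(-2.0 * ((r - m) / w) ** 2)
        area = np.trapezoid(p, r)
        if area <= 0:
            raise ValueError("mixture has zero mass on the grid")
        return cls(r=r, p=p / area, kind=kind)


# ---------------------------------------------------------------------------
# accessible volume
# ---------------------------------------------------------------------------

def compute_av(
    structure: CoarseStructure,
    site: LabelSite,
    grid_spacing: float = 1.0,
) -> LabelCloud:
    """Simulate the accessible volume of a tethered label.

    Grid points within ``site.linker_length`` of the anchor are kept if they
    clear every protein bead by ``bead_radius + label_radius`` and are
    connected to the anchor through clash-free grid neighbours (6-neighbour
    flood fill).  Returned weights are uniform.

    Raises
    ------
    InaccessibleSiteError
        If the site is fully buried (empty accessible volume).
    """
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    anchor = site.attachment
    if anchor is None:
        anchor = structure.site_coord(site.residue_id, site.chain_id)
    anchor = np.asarray(anchor, float)

    L = float(site.linker_length)
    n_half = int(np.ceil(L / grid_spacing))
    axis = np.arange(-n_half, n_half + 1) * grid_spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + anchor
    shape = gx.shape

    within = (gx**2 + gy**2 + gz**2) <= L**2

    # clash mask: a point clashes if it is inside any inflated bead.  The
    # attachment bead itself (bead at the anchor coordinate) is ignored so the
    # tether can leave its own backbone site.
    keep_beads = np.linalg.norm(structure.coords - anchor, axis=1) > 1e-6
    clash = np.zeros(len(pts), dtype=bool)
    if keep_beads.any():
        coords = structure.coords[keep_beads]
        radii = structure.radii[keep_beads] + site.label_radius
        reach = np.linalg.norm(coords - anchor, axis=1) - radii
        near = reach <= L  # only beads whose inflated sphere can intersect the ball
        if near.any():
            tree = cKDTree(pts)
            for c, r in zip(coords[near], radii[near]):
                idx = tree.query_ball_point(c, r)
                clash[idx] = True
    free = within & ~clash.reshape(shape)

    # connectivity: flood fill from the anchor cell (center of the grid)
    center = (n_half, n_half, n_half)
    seed_ok = free[center]
    if not seed_ok:
        # allow seeding from the nearest free cell within one linker width
        free_idx = np.argwhere(free)
        if len(free_idx) == 0:
            raise InaccessibleSiteError(
                f"site at residue {site.residue_id}: accessible volume is empty"
            )
        d = np.linalg.norm((free_idx - center) * grid_spacing, axis=1)
        j = int(np.argmin(d))
        if d[j] > max(site.linker_width, 2 * grid_spacing):
            raise InaccessibleSiteError(
                f"site at residue {site.residue_id}: anchor region is buried"
            )
        center = tuple(free_idx[j])
    conn = ndimage.generate_binary_structure(3, 1)
    lab, _ = ndimage.label(free, structure=conn)
    comp = lab == lab[center]
    if not comp.any():
        raise InaccessibleSiteError(
            f"site at residue {site.residue_id}: accessible volume is empty"
        )

    sel = comp.ravel()
    cloud_pts = pts[sel]
    # a sterically trapped pocket smaller than the label head itself is not a
    # usable accessible volume (fully caged site)
    min_volume = 4.0 / 3.0 * np.pi * (site.linker_width / 2.0) ** 3
    if len(cloud_pts) * grid_spacing**3 < min_volume:
        raise InaccessibleSiteError(
            f"site at residue {site.residue_id}: accessible volume below the "
            f"label volume ({len(cloud_pts)} grid points)"
        )
    weights = np.full(len(cloud_pts), 1.0 / len(cloud_pts))
    return LabelCloud(points=cloud_pts, weights=weights, anchor=anchor, site=site)


def apply_acv(
    cloud: LabelCloud,
    site: LabelSite,
    structure: CoarseStructure = None,
) -> LabelCloud:
    """Re-weight an AV cloud into an accessible *contact* volume.

    Points within ``site.contact_distance`` of any protein bead surface carry
    total weight ``site.contact_fraction``; the remaining points share
    ``1 - contact_fraction``.  ``f = 0`` returns the input unchanged.
    """
    f = float(site.contact_fraction)
    if structure is None and cloud.site is None and f > 0:
        raise ValueError("a structure is required to locate the contact shell")
    if f == 0.0:
        return cloud
    coords = structure.coords
    surf = structure.radii + site.label_radius
    tree = cKDTree(coords)
    d, idx = tree.query(cloud.points)
    shell = d <= (surf[idx] + site.contact_distance)
    if not shell.any():
        raise InaccessibleSiteError(
            f"contact fraction {f} requested but no cloud point lies within "
            f"{site.contact_distance} A of the protein surface"
        )
    w = cloud.weights.copy()
    w_shell = w[shell].sum()
    w_free = w[~shell].sum()
    out = np.empty_like(w)
    out[shell] = w[shell] * (f / w_shell)
    if w_free > 0:
        out[~shell] = w[~shell] * ((1.0 - f) / w_free)
    else:
        out[~shell] = 0.0
    return LabelCloud(
        points=cloud.points,
        weights=out,
        anchor=cloud.anchor,
        site=site,
        contact_mask=shell,
    )


# ---------------------------------------------------------------------------
# inter-label observables
# ---------------------------------------------------------------------------

def subsample_cloud(cloud: LabelCloud, max_points: int, seed: int = 0) -> LabelCloud:
    """Weight-proportional subsample of a cloud (unbiased for observables).

    Returns the cloud unchanged when it has at most ``max_points`` points.
    """
    if len(cloud) <= max_points:
        return cloud
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cloud), size=max_points, replace=False, p=cloud.weights)
    return LabelCloud(
        points=cloud.points[idx],
        weights=np.full(max_points, 1.0 / max_points),
        anchor=cloud.anchor,
        site=cloud.site,
    )


def _pair_iter(cloud1: LabelCloud, cloud2: LabelCloud, chunk: int = 2048):
    """Yield (distances, product-weights) blocks over all point pairs."""
    p1, w1 = cloud1.points, cloud1.weights
    p2, w2 = cloud2.points, cloud2.weights
    for start in range(0, len(p1), chunk):
        a = p1[start : start + chunk]
        wa = w1[start : start + chunk]
        d = np.sqrt(np.sum((a[:, None, :] - p2[None, :, :]) ** 2, axis=-1))
        yield d.ravel(), np.outer(wa, w2).ravel()


def distance_distribution(
    cloud1: LabelCloud,
    cloud2: LabelCloud,
    nbins: int = 128,
    kind: str = "FRET",
    r_range: tuple[float, float] | None = None,
) -> DistanceDistribution:
    """Histogram of pairwise inter-cloud distances, weighted by product weights.

    The returned density integrates to one (trapezoid rule); mean and SD are
    available through :meth:`DistanceDistribution.mean` / ``.std``.
    """
    if r_range is None:
        d_anchor = float(np.linalg.norm(cloud1.anchor - cloud2.anchor))
        span = (
            cloud1.site.linker_length if cloud1.site else 25.0,
            cloud2.site.linker_length if cloud2.site else 25.0,
        )
        lo = max(0.0, d_anchor - sum(span) - 5.0)
        hi = d_anchor + sum(span) + 5.0
        r_range = (lo, hi)
    edges = np.linspace(r_range[0], r_range[1], nbins + 1)
    hist = np.zeros(nbins)
    for d, w in _pair_iter(cloud1, cloud2):
        h, _ = np.histogram(d, bins=edges, weights=w)
        hist += h
    centers = 0.5 * (edges[:-1] + edges[1:])
    dr = edges[1] - edges[0]
    p = hist / dr
    area = np.trapezoid(p, centers)
    if area <= 0:
        raise ValueError("no pairwise distances fell inside r_range")
    return DistanceDistribution(r=centers, p=p / area, kind=kind)


def fret_observables(cloud1: LabelCloud, cloud2: LabelCloud, R0: float = 52.0) -> dict:
    """Mean distance, mean FRET efficiency and FRET-averaged distance.

    ``E`` is averaged over the isotropic (kappa^2 = 2/3) pair efficiency
    ``1/(1 + (R/R0)^6)``; coincident points contribute ``E = 1``.
    """
    if R0 <= 0:
        raise ValueError("Forster radius must be positive")
    mean_r = 0.0
    mean_e = 0.0
    for d, w in _pair_iter(cloud1, cloud2):
        mean_r += float(np.sum(w * d))
        mean_e += float(np.sum(w / (1.0 + (d / R0) ** 6)))
    if mean_e >= 1.0:
        r_fret = 0.0
    elif mean_e <= 0.0:
        r_fret = np.inf
    else:
        r_fret = R0 * (1.0 / mean_e - 1.0) ** (1.0 / 6.0)
    return {
        "mean_distance": mean_r,
        "mean_efficiency": mean_e,
        "fret_averaged_distance": float(r_fret),
    }
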