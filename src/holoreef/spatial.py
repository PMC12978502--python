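"""Finite-element machinery for the Matérn spatial field and RW2 smooths.

The continuous Matérn field (smoothness nu = 1 in two dimensions) is
represented as the solution of a stochastic partial differential equation
discretized on a triangular mesh, which yields a sparse-precision Gaussian
Markov random field:

    Q(kappa, tau) = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G)

with lumped mass matrix ``C`` and stiffness matrix ``G`` from linear
(P1) finite elements.  The marginal field variance has the closed form
``sigma^2 = 1 / (4 pi kappa^2 tau^2)`` and the distance at which
correlation falls to ~0.13 is ``sqrt(8) / kappa``.

Second-order random walks on binned covariates are penalized by the
second-difference matrix ``D2' D2`` (rank ``n_bins - 2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError, cKDTree

EARTH_RADIUS_KM = 6371.0


def project_local(lon, lat, lon0: float | None = None, lat0: float | None = None):
    """Project lon/lat (degrees) to a local tangent plane in km.

    An equirectangular projection about the site centroid: adequate for
    the regional extents used here, where it is equal-area to first
    order.  Distances feed the Matérn kernel, so the unit is km.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon0 is None:
        lon0 = float(lon.mean())
    if lat0 is None:
        lat0 = float(lat.mean())
    x = np.deg2rad(lon - lon0) * EARTH_RADIUS_KM * np.cos(np.deg2rad(lat0))
    y = np.deg2rad(lat - lat0) * EARTH_RADIUS_KM
    return np.column_stack([x, y])


@dataclass
class Mesh:
    """A conforming triangulation with point-location support."""

    points: np.ndarray          # (m, 2)
    triangles: np.ndarray       # (k, 3) vertex indices
    _tri: Delaunay = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    def find_triangle(self, xy: np.ndarray) -> np.ndarray:
        return self._tri.find_simplex(np.atleast_2d(xy))

    def projector(self, xy: np.ndarray) -> sp.csr_matrix:
        """Barycentric interpolation matrix from mesh nodes to points."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        simplex = self._tri.find_simplex(xy)
        if np.any(simplex < 0):
            raise ValueError("points outside the mesh hull")
        T = self._tri.transform[simplex]
        b = np.einsum("nij,nj->ni", T[:, :2], xy - T[:, 2])
        bary = np.column_stack([b, 1.0 - b.sum(axis=1)])
        rows = np.repeat(np.arange(xy.shape[0]), 3)
        cols = self._tri.simplices[simplex].ravel()
        return sp.csr_matrix(
            (bary.ravel(), (rows, cols)), shape=(xy.shape[0], self.n_nodes)
        )

    def write_off(self, path) -> None:
        """OFF-style plain-text node/triangle file."""
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{self.n_nodes} {len(self.triangles)} 0\n")
            for p in self.points:
                fh.write(f"{p[0]:.8g} {p[1]:.8g} 0\n")
            for t in self.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def build_mesh(
    sites: np.ndarray,
    fine_edge: float,
    coarse_edge: float,
    buffer: float,
    fine_radius: float | None = None,
) -> Mesh:
    """Triangulate the site domain: fine near sites, coarse elsewhere.

    Candidate nodes are the sites themselves, a fine lattice (spacing
    ``fine_edge``) within ``fine_radius`` of any site, and a coarse
    lattice (spacing ``coarse_edge``) over the buffered bounding box;
    near-duplicates are dropped and the rest Delaunay-triangulated.
    Deterministic given inputs.
    """
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    if sites.shape[0] < 3:
        raise ValueError("need at least 3 sites to build a mesh")
    centered = sites - sites.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("degenerate (collinear) site configuration")
    if fine_radius is None:
        fine_radius = 3.0 * coarse_edge
    lo = sites.min(axis=0) - buffer
    hi = sites.max(axis=0) + buffer

    def lattice(spacing):
        xs = np.arange(lo[0], hi[0] + spacing, spacing)
        ys = np.arange(lo[1], hi[1] + spacing, spacing)
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    tree = cKDTree(sites)
    fine = lattice(fine_edge)
    fine = fine[tree.query(fine)[0] <= fine_radius]
    coarse = lattice(coarse_edge)
    coarse = coarse[tree.query(coarse)[0] > fine_radius]

    nodes = [sites]
    kept = sites
    for cand in (fine, coarse):
        if cand.size == 0:
            continue
        d = cKDTree(kept).query(cand)[0]
        cand = cand[d > 0.45 * fine_edge]
        if cand.size:
            nodes.append(cand)
            kept = np.vstack([kept, cand])
    points = np.vstack(nodes)
    try:
        tri = Delaunay(points)
    except QhullError as err:
        raise ValueError(f"degenerate site configuration: {err}") from err
    return Mesh(points=points, triangles=tri.simplices, _tri=tri)


def fem_matrices(mesh: Mesh) -> tuple[np.ndarray, sp.csr_matrix]:
    """Lumped mass vector ``c`` (diagonal of C) and stiffness matrix ``G``."""
    pts, tris = mesh.points, mesh.triangles
    c = np.zeros(mesh.n_nodes)
    rows, cols, vals = [], [], []
    for t in tris:
        p = pts[t]
        e = np.array([p[2] - p[1], p[0] - p[2], p[1] - p[0]])  # opposite edges
        area = 0.5 * abs(e[1, 0] * e[2, 1] - e[1, 1] * e[2, 0])
        if area <= 0:
            continue
        c[t] += area / 3.0
        # grad(phi_i) = rot90(e_i) / (2 area); stiffness entries e_i . e_j / (4 area)
        local = (e @ e.T) / (4.0 * area)
        for a in range(3):
            for b in range(3):
                rows.append(t[a]); cols.append(t[b]); vals.append(local[a, b])
    G = sp.csr_matrix((vals, (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes))
    return c, G


def spde_precision(mesh: Mesh, kappa: float, tau: float,
                   fem: tuple[np.ndarray, sp.csr_matrix] | None = None) -> sp.csr_matrix:
    """Sparse GMRF precision of the Matérn (alpha = 2) field on the mesh."""
    if kappa <= 0 or tau <= 0:
        raise ValueError("kappa and tau must be positive")
    c, G = fem_matrices(mesh) if fem is None else fem
    Cinv = sp.diags(1.0 / c)
    C = sp.diags(c)
    Q = tau**2 * (kappa**4 * C + 2.0 * kappa**2 * G + G @ Cinv @ G)
    return Q.tocsr()


def field_variance(kappa: float, tau: float) -> float:
    """Closed-form marginal variance of the alpha=2 Matérn field in 2-D."""
    return 1.0 / (4.0 * np.pi * kappa**2 * tau**2)


def matern_parameters(range_km: float, sigma: float) -> tuple[float, float]:
    """(kappa, tau) for a given correlation range (sqrt(8)/kappa) and sd."""
    kappa = np.sqrt(8.0) / range_km
    tau = 1.0 / np.sqrt(4.0 * np.pi * kappa**2 * sigma**2)
    return float(kappa), float(tau)


def sample_field(Q, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Draws from N(0, Q^{-1}); dense Cholesky (mesh sizes here are modest)."""
    from scipy.linalg import cholesky, solve_triangular

    Qd = Q.toarray() if sp.issparse(Q) else np.asarray(Q)
    L = cholesky(Qd, lower=True)
    z = rng.standard_normal((Qd.shape[0], n_draws))
    return solve_triangular(L, z, lower=True, trans="T").T


# ---------------------------------------------------------------------------
# second-order random walks on bins

def rw2_precision(n_bins: int) -> np.ndarray:
    """Second-difference penalty ``D2' D2`` with rank ``n_bins - 2``."""
    if n_bins < 5:
        raise ValueError("random-walk smooths need at least 5 bins")
    D = np.zeros((n_bins - 2, n_bins))
    for i in range(n_bins - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D.T @ D


def bin_covariate(values, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bin index per observation and the bin midpoints.

    The minimum maps to the first bin and the maximum to the last.
    A constant covariate cannot be binned and raises.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("constant covariate cannot be binned")
    width = (hi - lo) / n_bins
    idx = np.clip(((v - lo) / width).astype(int), 0, n_bins - 1)
    mids = lo + (np.arange(n_bins) + 0.5) * width
    return idx, mids
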