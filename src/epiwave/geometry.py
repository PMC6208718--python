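"""Synthetic torso-heart geometries and surrogate transfer matrices.

The inverse problem of electrocardiography maps potentials on the outer
heart surface (epicardium, ``q`` nodes) to potentials on the body surface
(``r`` electrode nodes) through a linear transfer matrix ``A``.  Real
transfer matrices come from CT-derived geometries and a boundary-element
solve; this module builds idealized concentric-sphere geometries and an
infinite-homogeneous-medium monopole surrogate for ``A`` that preserves
the properties the reconstruction methods care about: linearity,
instantaneity, and severe ill-conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


__all__ = [
    "TorsoHeartGeometry",
    "TransferMatrix",
    "make_sphere_geometry",
    "monopole_transfer_matrix",
]


@dataclass
class TorsoHeartGeometry:
    """Node coordinates (mm) for the heart and torso surfaces.

    Attributes
    ----------
    heart_nodes : (q, 3) float array
        Epicardial node coordinates in mm.
    torso_nodes : (r, 3) float array
        Body-surface electrode coordinates in mm.
    heart_faces : (f, 3) int array
        Triangles (index triples into ``heart_nodes``) describing the
        epicardial mesh; used for geodesic activation propagation.
    """

    heart_nodes: np.ndarray
    torso_nodes: np.ndarray
    heart_faces: np.ndarray

    def __post_init__(self) -> None:
        self.heart_nodes = np.asarray(self.heart_nodes, dtype=float)
        self.torso_nodes = np.asarray(self.torso_nodes, dtype=float)
        self.heart_faces = np.asarray(self.heart_faces, dtype=int)
        self.validate()

    @property
    def n_heart(self) -> int:
        return self.heart_nodes.shape[0]

    @property
    def n_torso(self) -> int:
        return self.torso_nodes.shape[0]

    def validate(self) -> None:
        if self.heart_nodes.ndim != 2 or self.heart_nodes.shape[1] != 3:
            raise ValueError("heart_nodes must be (q, 3)")
        if self.torso_nodes.ndim != 2 or self.torso_nodes.shape[1] != 3:
            raise ValueError("torso_nodes must be (r, 3)")
        if self.heart_faces.ndim != 2 or self.heart_faces.shape[1] != 3:
            raise ValueError("heart_faces must be (f, 3)")
        q = self.n_heart
        if self.heart_faces.min(initial=0) < 0 or self.heart_faces.max(initial=0) >= q:
            raise ValueError("heart_faces reference invalid node indices")
        # pairwise-distinct heart nodes
        d2 = _pairwise_sq_dists(self.heart_nodes)
        np.fill_diagonal(d2, np.inf)
        if d2.min() <= 0.0:
            raise ValueError("heart nodes must be pairwise distinct")
        # connectivity of the triangle edge graph
        g = self.edge_graph()
        n_comp, _ = connected_components(g, directed=False)
        if n_comp != 1:
            raise ValueError("heart mesh edge graph is not connected")

    def edge_graph(self) -> csr_matrix:
        """Sparse symmetric edge-length graph of the heart mesh (mm)."""
        f = self.heart_faces
        i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
        j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
        w = np.linalg.norm(self.heart_nodes[i] - self.heart_nodes[j], axis=1)
        q = self.n_heart
        g = csr_matrix((np.concatenate([w, w]),
                        (np.concatenate([i, j]), np.concatenate([j, i]))),
                       shape=(q, q))
        # duplicate edges from shared triangles: keep one weight
        g.sum_duplicates()
        counts = csr_matrix((np.ones_like(np.concatenate([w, w])),
                             (np.concatenate([i, j]), np.concatenate([j, i]))),
                            shape=(q, q))
        counts.sum_duplicates()
        g.data = g.data / counts.data
        return g

    def heart_inside_torso_hull(self) -> bool:
        """True when every heart node is strictly inside the torso hull."""
        hull = ConvexHull(self.torso_nodes)
        # hull.equations: outward normals; inside iff n.x + d < 0 for all facets
        vals = self.heart_nodes @ hull.equations[:, :3].T + hull.equations[:, 3]
        return bool((vals < 0).all())


@dataclass
class TransferMatrix:
    """The r x q linear operator mapping heart to body-surface potentials."""

    entries: np.ndarray
    geometry: TorsoHeartGeometry | None = None
    condition_number: float = field(init=False)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2:
            raise ValueError("transfer matrix must be 2-D")
        if not np.isfinite(self.entries).all():
            raise ValueError("transfer matrix has non-finite entries")
        if self.geometry is not None:
            r, q = self.entries.shape
            if (r, q) != (self.geometry.n_torso, self.geometry.n_heart):
                raise ValueError(
                    f"transfer matrix shape {self.entries.shape} does not match "
                    f"geometry ({self.geometry.n_torso}, {self.geometry.n_heart})"
                )
        self.condition_number = float(np.linalg.cond(self.entries))

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def __matmul__(self, other):
        return self.entries @ other


def _pairwise_sq_dists(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on a sphere via the Fibonacci lattice."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return radius * pts


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    qmat, rmat = np.linalg.qr(m)
    qmat *= np.sign(np.diag(rmat))
    if np.linalg.det(qmat) < 0:
        qmat[:, 0] *= -1.0
    return qmat


def make_sphere_geometry(
    q_target: int,
    r_target: int,
    heart_radius: float,
    torso_radius: float,
    seed: int = 0,
) -> TorsoHeartGeometry:
    """Concentric-sphere torso-heart geometry with quasi-uniform nodes.

    Heart nodes sit on a Fibonacci lattice of radius ``heart_radius`` and
    are triangulated by their convex hull (a valid sphere triangulation);
    torso nodes sit on an independently rotated lattice of radius
    ``torso_radius``.  Deterministic given ``seed``.

    Parameters
    ----------
    q_target, r_target : int
        Number of heart and torso nodes (>= 4); produced exactly.
    heart_radius, torso_radius : float
        Sphere radii in mm; ``0 < heart_radius < torso_radius``.
    seed : int
        Seeds the lattice rotations only.
    """
    if not (0 < heart_radius < torso_radius):
        raise ValueError("radii must satisfy 0 < heart_radius < torso_radius")
    if q_target < 4 or r_target < 4:
        raise ValueError("need at least 4 nodes on each surface")
    rng = np.random.default_rng(seed)
    heart = _fibonacci_sphere(q_target, heart_radius) @ _random_rotation(rng).T
    torso = _fibonacci_sphere(r_target, torso_radius) @ _random_rotation(rng).T
    faces = ConvexHull(heart).simplices
    return TorsoHeartGeometry(heart_nodes=heart, torso_nodes=torso,
                              heart_faces=faces)


def monopole_transfer_matrix(
    geometry: TorsoHeartGeometry, sigma: float = 0.2
) -> TransferMatrix:
    """Row-normalized monopole kernel surrogate for the BEM transfer matrix.

    Entry (i, j) is proportional to ``1 / (4 pi sigma d_ij)`` with ``d_ij``
    the torso-heart node distance; rows are then scaled to sum to one so
    that a spatially uniform epicardial potential maps to the same uniform
    body-surface potential.  The resulting operator is smoothing and badly
    conditioned, as the physical problem is.

    Parameters
    ----------
    geometry : TorsoHeartGeometry
    sigma : float
        Medium conductivity in S/m (> 0); cancels under row normalization
        but is validated for physical sanity.
    """
    if sigma <= 0:
        raise ValueError("conductivity sigma must be positive")
    diff = geometry.torso_nodes[:, None, :] - geometry.heart_nodes[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if d.min() <= 0.0:
        raise ValueError("coincident torso and heart node (zero distance)")
    k = 1.0 / (4.0 * np.pi * sigma * d)
    k /= k.sum(axis=1, keepdims=True)
    return TransferMatrix(entries=k, geometry=geometry)
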