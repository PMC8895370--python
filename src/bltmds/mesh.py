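"""Tetrahedral phantom meshes: generation, region labelling, sources, file I/O.

Phantoms are structured boxes split into tetrahedra (Kuhn 6-tet subdivision),
optionally carved into curved shapes by masking cells, with integer region
labels per tetrahedron standing in for segmented organs.  All coordinates are
in millimetres; node and element indices are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Kuhn subdivision: six tets around the main diagonal (0,0,0)-(1,1,1) of each
# cube.  Vertex bit-patterns per tet, already oriented to positive volume.
_KUHN_PATHS = (
    (0, 1, 2),
    (0, 2, 1),
    (1, 0, 2),
    (1, 2, 0),
    (2, 0, 1),
    (2, 1, 0),
)

_FACE_LOCAL = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))


class MeshError(ValueError):
    """Raised for malformed meshes or mesh files."""


@dataclass
class TetMesh:
    """Tetrahedral mesh with per-element region labels.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array, mm
    tets : (n_tets, 4) int array, positively oriented
    region_labels : (n_tets,) int array
    boundary_faces : (n_faces, 3) int array, outward-oriented triangles
    """

    nodes: np.ndarray
    tets: np.ndarray
    region_labels: np.ndarray
    boundary_faces: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.region_labels = np.asarray(self.region_labels, dtype=np.int64).ravel()
        if self.region_labels.shape[0] != self.tets.shape[0]:
            raise MeshError("one region label per tetrahedron required")
        if self.tets.size and (
            self.tets.min() < 0 or self.tets.max() >= len(self.nodes)
        ):
            raise MeshError("tet node index out of range")
        if self.boundary_faces is None:
            self.boundary_faces = extract_boundary_faces(self.nodes, self.tets)
        else:
            self.boundary_faces = np.asarray(
                self.boundary_faces, dtype=np.int64
            ).reshape(-1, 3)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    @property
    def boundary_nodes(self) -> np.ndarray:
        """Sorted indices of nodes on the boundary surface."""
        return np.unique(self.boundary_faces)

    def tet_volumes(self) -> np.ndarray:
        """Signed volume of every tetrahedron (positive for valid meshes)."""
        p = self.nodes[self.tets]
        a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def lumped_node_volumes(self) -> np.ndarray:
        """Per-node lumped volume: a quarter of each incident tet's volume."""
        vols = self.tet_volumes()
        lumped = np.zeros(self.n_nodes)
        np.add.at(lumped, self.tets.ravel(), np.repeat(vols / 4.0, 4))
        return lumped

    def validate(self) -> None:
        """Check volume positivity and watertightness of the boundary surface."""
        vols = self.tet_volumes()
        if vols.size and vols.min() <= 0:
            raise MeshError(f"non-positive tet volume (min {vols.min():.3e})")
        edges = np.concatenate(
            [self.boundary_faces[:, [0, 1]], self.boundary_faces[:, [1, 2]],
             self.boundary_faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if counts.size and not np.all(counts == 2):
            raise MeshError("boundary surface is not watertight")


@dataclass(frozen=True)
class RegionSpec:
    """Geometric region used to assign an organ-like label to tets.

    ``shape`` is one of ``sphere`` (center, radius), ``box`` (center, extents)
    or ``cylinder`` (center, radius, height along ``axis``).
    """

    label: int
    shape: str
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 0.0
    extents: tuple[float, float, float] = (0.0, 0.0, 0.0)
    height: float = 0.0
    axis: int = 2

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points) - np.asarray(self.center)
        if self.shape == "sphere":
            if self.radius <= 0:
                raise ValueError("sphere radius must be positive")
            return np.einsum("ij,ij->i", pts, pts) <= self.radius**2
        if self.shape == "box":
            ext = np.asarray(self.extents)
            if np.any(ext <= 0):
                raise ValueError("box extents must be positive")
            return np.all(np.abs(pts) <= ext / 2.0, axis=1)
        if self.shape == "cylinder":
            if self.radius <= 0 or self.height <= 0:
                raise ValueError("cylinder radius and height must be positive")
            perp = [i for i in range(3) if i != self.axis]
            r2 = pts[:, perp[0]] ** 2 + pts[:, perp[1]] ** 2
            return (r2 <= self.radius**2) & (
                np.abs(pts[:, self.axis]) <= self.height / 2.0
            )
        raise ValueError(f"unknown region shape {self.shape!r}")


@dataclass(frozen=True)
class SourceSpec:
    """Spherical bioluminescent source: center (mm), radius (mm), total power."""

    center: tuple[float, float, float]
    radius: float
    total_power: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("source radius must be positive")
        if self.total_power <= 0:
            raise ValueError("source power must be positive")


@dataclass
class SourceDistribution:
    """Nodal source power density (arbitrary units per mm^3) on a mesh."""

    values: np.ndarray
    mesh: TetMesh

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape[0] != self.mesh.n_nodes:
            raise ValueError("one source density value per mesh node required")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValueError("source densities must be finite and non-negative")

    def total_power(self) -> float:
        """Lumped-volume integral of the density."""
        return float(self.values @ self.mesh.lumped_node_volumes())


def extract_boundary_faces(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Faces owned by exactly one tet, oriented with outward normals."""
    faces = tets[:, _FACE_LOCAL].reshape(-1, 3)  # (4*n_tets, 3)
    opposite = tets[:, [0, 1, 2, 3]].reshape(-1)  # vertex not on each face
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inv] == 1
    bfaces = faces[on_boundary].copy()
    opp = opposite[on_boundary]
    # orient so the normal points away from the opposite (interior) vertex
    a, b, c = (nodes[bfaces[:, i]] for i in range(3))
    normal = np.cross(b - a, c - a)
    flip = np.einsum("ij,ij->i", normal, a - nodes[opp]) < 0
    bfaces[flip] = bfaces[flip][:, [0, 2, 1]]
    return bfaces


def generate_box_mesh(
    extent: Sequence[float], spacing: float, origin: Sequence[float] = (0.0, 0.0, 0.0)
) -> TetMesh:
    """Structured box phantom; each cubic cell is split into six tetrahedra.

    Parameters
    ----------
    extent : side lengths (mm); must be (near-)integer multiples of ``spacing``
        with at least 2 cells per axis.
    spacing : grid spacing (mm), > 0.
    """
    extent = np.asarray(extent, dtype=float)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ncells = np.round(extent / spacing).astype(int)
    if np.any(np.abs(ncells * spacing - extent) > 1e-9 * spacing):
        raise ValueError("extent must be a multiple of spacing")
    if np.any(ncells < 2):
        raise ValueError("need at least 2 cells per axis")
    nx, ny, nz = ncells
    xs, ys, zs = (np.arange(n + 1) * spacing + o for n, o in zip(ncells, origin))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    corner = {}
    for b in range(8):
        bx, by, bz = b & 1, (b >> 1) & 1, (b >> 2) & 1
        corner[b] = nid(ii + bx, jj + by, kk + bz)

    tet_list = []
    for path in _KUHN_PATHS:
        bits = [0]
        acc = 0
        for ax in path:
            acc |= 1 << ax
            bits.append(acc)
        tet_list.append(
            np.column_stack([corner[bits[0]], corner[bits[1]],
                             corner[bits[2]], corner[bits[3]]])
        )
    tets = np.concatenate(tet_list)
    mesh = TetMesh(nodes, tets, np.zeros(len(tets), dtype=np.int64),
                   boundary_faces=np.empty((0, 3), dtype=np.int64))
    # fix orientation cheaply: swap last two vertices of negative-volume tets
    vols = mesh.tet_volumes()
    neg = vols < 0
    mesh.tets[neg] = mesh.tets[neg][:, [0, 1, 3, 2]]
    mesh.boundary_faces = extract_boundary_faces(mesh.nodes, mesh.tets)
    mesh.validate()
    return mesh


def label_regions(mesh: TetMesh, specs: Sequence[RegionSpec]) -> TetMesh:
    """Assign region labels to tets whose centroid falls inside each spec.

    Specs are applied in order; later specs overwrite earlier labels.  Returns
    a new mesh sharing node/tet arrays.
    """
    labels = mesh.region_labels.copy()
    centroids = mesh.tet_centroids()
    for spec in specs:
        labels[spec.contains(centroids)] = spec.label
    return TetMesh(mesh.nodes, mesh.tets, labels, boundary_faces=mesh.boundary_faces)


def carve_region(mesh: TetMesh, spec: RegionSpec) -> TetMesh:
    """Keep only tets whose centroid lies inside ``spec`` and re-extract the
    boundary.  The stair-step surface approximates the curved shape."""
    keep = spec.contains(mesh.tet_centroids())
    if not keep.any():
        raise MeshError("carve region contains no tet centroids")
    tets = mesh.tets[keep]
    used = np.unique(tets)
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[used] = np.arange(used.size)
    out = TetMesh(mesh.nodes[used], remap[tets], mesh.region_labels[keep])
    out.validate()
    return out


def embed_spherical_source(mesh: TetMesh, spec: SourceSpec) -> SourceDistribution:
    """Uniform density inside a sphere, normalised to the spec's total power.

    Nodes within ``spec.radius`` of the center receive equal density, scaled so
    that the lumped-volume integral equals ``total_power``.  If no node falls
    inside, the nearest node (lowest index on ties) carries all the power.
    """
    center = np.asarray(spec.center, dtype=float)
    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    if np.any(center < lo) or np.any(center > hi):
        raise ValueError("source center lies outside the mesh bounding box")
    d2 = np.einsum("ij,ij->i", mesh.nodes - center, mesh.nodes - center)
    inside = d2 <= spec.radius**2
    lumped = mesh.lumped_node_volumes()
    values = np.zeros(mesh.n_nodes)
    if inside.any() and lumped[inside].sum() > 0:
        values[inside] = 1.0
    else:
        values[int(np.argmin(d2))] = 1.0
    values *= spec.total_power / (values @ lumped)
    return SourceDistribution(values, mesh)


# ---------------------------------------------------------------------------
# File I/O: VTK legacy ASCII unstructured grid, and a plain node/element format
# ---------------------------------------------------------------------------

def write_mesh(mesh: TetMesh, path, fmt: str | None = None) -> None:
    """Write a mesh as VTK legacy ASCII (``.vtk``) or plain text (``.txt``)."""
    path = str(path)
    fmt = fmt or ("vtk" if path.endswith(".vtk") else "txt")
    if fmt == "vtk":
        _write_vtk(mesh, path)
    elif fmt == "txt":
        _write_txt(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


def read_mesh(path, fmt: str | None = None) -> TetMesh:
    """Read a mesh written by :func:`write_mesh` (VTK legacy or plain text)."""
    path = str(path)
    fmt = fmt or ("vtk" if path.endswith(".vtk") else "txt")
    if fmt == "vtk":
        return _read_vtk(path)
    if fmt == "txt":
        return _read_txt(path)
    raise ValueError(f"unknown mesh format {fmt!r}")


def _write_vtk(mesh: TetMesh, path: str, point_data: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbltmds mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.12g")
        fh.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        cells = np.column_stack(
            [np.full(mesh.n_tets, 4, dtype=np.int64), mesh.tets]
        )
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        np.savetxt(fh, np.full(mesh.n_tets, 10, dtype=np.int64), fmt="%d")
        fh.write(f"CELL_DATA {mesh.n_tets}\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.region_labels, fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, values in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(values, dtype=float), fmt="%.12g")


def write_nodal_field(mesh: TetMesh, values: np.ndarray, path, name="field") -> None:
    """Write mesh plus one nodal scalar field to VTK legacy for visualisation."""
    _write_vtk(mesh, str(path), point_data={name: values})


def _tokens(path: str):
    with open(path) as fh:
        for line in fh:
            yield from line.split()


def _read_vtk(path: str) -> TetMesh:
    tok = _tokens(path)
    toks = list(tok)
    upper = [t.upper() for t in toks]
    if "ASCII" not in upper:
        raise MeshError("only ASCII VTK legacy files are supported")
    try:
        i = upper.index("POINTS")
        n_pts = int(toks[i + 1])
        pts = np.array(toks[i + 3 : i + 3 + 3 * n_pts], dtype=float).reshape(-1, 3)
        i = upper.index("CELLS")
        n_cells = int(toks[i + 1])
        total = int(toks[i + 2])
        raw = np.array(toks[i + 3 : i + 3 + total], dtype=np.int64)
        j = upper.index("CELL_TYPES")
        types = np.array(toks[j + 2 : j + 2 + n_cells], dtype=np.int64)
    except (ValueError, IndexError) as exc:
        raise MeshError(f"malformed VTK file {path!r}: {exc}") from None
    if not np.all(types == 10):
        raise MeshError("mesh contains non-tetrahedral cells")
    cells = raw.reshape(n_cells, 5)
    if not np.all(cells[:, 0] == 4):
        raise MeshError("tetrahedral cells must have 4 vertices")
    tets = cells[:, 1:]
    labels = np.zeros(n_cells, dtype=np.int64)
    if "CELL_DATA" in upper:
        k = upper.index("CELL_DATA")
        sub, subu = toks[k:], upper[k:]
        found = False
        for m, t in enumerate(subu):
            if t == "SCALARS" and sub[m + 1] == "region":
                # SCALARS name type ncomp / LOOKUP_TABLE default / values...
                start = m + 6
                labels = np.array(sub[start : start + n_cells], dtype=np.int64)
                found = True
                break
        if not found:
            logger.warning("no 'region' cell array in %s; defaulting to 0", path)
    else:
        logger.warning("no 'region' cell array in %s; defaulting to 0", path)
    return TetMesh(pts, tets, labels)


def _write_txt(mesh: TetMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{mesh.n_nodes} {mesh.n_tets}\n")
        np.savetxt(fh, mesh.nodes, fmt="%.12g")
        np.savetxt(
            fh,
            np.column_stack([mesh.tets, mesh.region_labels]),
            fmt="%d",
        )


def _read_txt(path: str) -> TetMesh:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise MeshError("expected header 'N_nodes N_tets'")
        n_nodes, n_tets = int(header[0]), int(header[1])
        nodes = np.loadtxt(fh, max_rows=n_nodes).reshape(n_nodes, 3)
        elems = np.loadtxt(fh, dtype=np.int64, max_rows=n_tets).reshape(n_tets, 5)
    return TetMesh(nodes, elems[:, :4], elems[:, 4])
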