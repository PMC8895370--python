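"""Steady-state diffusion forward model on tetrahedral meshes.

Solves  -div(D grad Phi) + mu_a Phi = q  with P1 (linear) elements and a
Robin (type-III) boundary condition  -D dPhi/dn = Phi / (2 A_n), where A_n
accounts for internal reflection at the refractive-index-mismatched surface
(Groenhuis polynomial).  The assembled operator

    K = sum_tets (D_t * stiffness + mu_a_t * mass) + sum_bfaces surface_mass/(2 A_n)

is symmetric positive definite; fluence is obtained by a sparse direct solve
(conjugate-gradient fallback).  Per-wavelength system matrices map nodal
source power density to detector fluence via one adjoint solve per detector.

A measurement-noise model mirrors CCD acquisition: a wavelength-dependent
Gaussian "light spot" sampling error plus a wavelength-independent offset
(photon + readout + dark current) shared bitwise across wavelengths, which is
exactly what spectral differencing cancels.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import SourceDistribution, TetMesh
from .optics import OpticalPropertyTable

logger = logging.getLogger(__name__)


def reflection_coefficient(n_rel: float) -> float:
    """Effective internal reflection coefficient (Groenhuis polynomial)."""
    return -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel


@dataclass
class FemSystem:
    """Assembled diffusion operator for one wavelength."""

    wavelength: int
    K: sp.csr_matrix
    mesh: TetMesh
    bc: str = "robin"
    _lu: object = field(default=None, repr=False)

    def factor(self):
        if self._lu is None:
            try:
                # symmetric pattern -> MMD on A^T+A orders much better here
                self._lu = spla.splu(self.K.tocsc(), permc_spec="MMD_AT_PLUS_A")
            except (MemoryError, RuntimeError) as exc:  # pragma: no cover
                logger.warning("sparse LU failed (%s); using CG", exc)
                self._lu = "cg"
        return self._lu

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Solve K x = b for one or several right-hand sides."""
        lu = self.factor()
        if lu == "cg":  # pragma: no cover - large-mesh fallback
            b2 = np.atleast_2d(b.T).T
            out = np.empty_like(b2, dtype=float)
            for i in range(b2.shape[1]):
                x, info = spla.cg(self.K, b2[:, i], rtol=1e-10, atol=0.0)
                if info != 0:
                    raise RuntimeError(f"CG did not converge (info={info})")
                out[:, i] = x
            return out.reshape(b.shape)
        return lu.solve(np.asarray(b, dtype=float))


def _boundary_faces_with_owner(mesh: TetMesh):
    """Boundary faces together with the region label of the owning tet."""
    from .mesh import _FACE_LOCAL

    faces = mesh.tets[:, _FACE_LOCAL].reshape(-1, 3)
    owner = np.repeat(np.arange(mesh.n_tets), 4)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inv] == 1
    return faces[on_boundary], mesh.region_labels[owner[on_boundary]]


def assemble_system(
    mesh: TetMesh,
    props: OpticalPropertyTable,
    wavelength: int,
    bc: str = "robin",
    n_air: float = 1.0,
) -> FemSystem:
    """Assemble the P1 finite-element diffusion operator at one wavelength.

    Optical properties are piecewise constant per region label.  ``bc`` is
    ``"robin"`` (default) or ``"dirichlet"`` (implemented as a large diagonal
    penalty on boundary nodes, preserving symmetry).
    """
    labels = np.unique(mesh.region_labels)
    by_label = {int(lab): props.get(int(lab), wavelength) for lab in labels}
    D = np.array([by_label[int(l)].D for l in mesh.region_labels])
    mu_a = np.array([by_label[int(l)].mu_a for l in mesh.region_labels])

    p = mesh.nodes[mesh.tets]  # (nt, 4, 3)
    edge = p[:, 1:] - p[:, :1]  # (nt, 3, 3)
    vols = np.linalg.det(edge) / 6.0
    if np.any(vols <= 0):
        raise ValueError("degenerate or inverted tetrahedron")
    # gradients of barycentric coordinates: rows of inv(edge)^T for lambda_1..3
    inv_edge = np.linalg.inv(edge)
    grads = np.empty((mesh.n_tets, 4, 3))
    grads[:, 1:, :] = np.transpose(inv_edge, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)

    # element stiffness V * (g_i . g_j); absorption mass lumped (V/4 per
    # vertex) so K stays an M-matrix on the nonobtuse Kuhn tets and the
    # discrete solution of a non-negative source stays non-negative
    local_stiff = np.einsum("tid,tjd->tij", grads, grads) * vols[:, None, None]
    mass_pattern = np.eye(4) / 4.0
    local = D[:, None, None] * local_stiff + (mu_a * vols)[:, None, None] * mass_pattern

    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sp.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()

    if bc == "robin":
        bfaces, bregions = _boundary_faces_with_owner(mesh)
        n_rel = np.array(
            [by_label[int(l)].n_tissue / n_air for l in bregions]
        )
        reff = np.array([reflection_coefficient(nr) for nr in n_rel])
        A_n = (1.0 + reff) / (1.0 - reff)
        q = mesh.nodes[bfaces]
        areas = 0.5 * np.linalg.norm(
            np.cross(q[:, 1] - q[:, 0], q[:, 2] - q[:, 0]), axis=1
        )
        coeff = areas / (2.0 * A_n)  # lumped surface mass (area/3 per vertex)
        pattern = np.eye(3) / 3.0
        local_b = coeff[:, None, None] * pattern
        rb = np.repeat(bfaces, 3, axis=1).ravel()
        cb = np.tile(bfaces, (1, 3)).ravel()
        K = K + sp.coo_matrix(
            (local_b.ravel(), (rb, cb)), shape=(mesh.n_nodes, mesh.n_nodes)
        ).tocsr()
    elif bc == "dirichlet":
        bn = mesh.boundary_nodes
        penalty = 1e12 * K.diagonal().max()
        K = K + sp.coo_matrix(
            (np.full(bn.size, penalty), (bn, bn)),
            shape=(mesh.n_nodes, mesh.n_nodes),
        ).tocsr()
    else:
        raise ValueError(f"unknown boundary condition {bc!r}")
    return FemSystem(int(wavelength), K, mesh, bc)


def solve_fluence(fem: FemSystem, source: SourceDistribution) -> np.ndarray:
    """Nodal fluence for a source density: solves K Phi = V_lumped * S."""
    if source.mesh is not fem.mesh and source.mesh.n_nodes != fem.mesh.n_nodes:
        raise ValueError("source defined on an incompatible mesh")
    b = fem.mesh.lumped_node_volumes() * source.values
    phi = fem.solve(b)
    res = np.linalg.norm(fem.K @ phi - b)
    scale = np.linalg.norm(b)
    if scale > 0 and res > 1e-8 * scale:
        raise RuntimeError(f"solver residual too large: {res / scale:.2e}")
    return phi


@dataclass(frozen=True)
class DetectorSet:
    """Ordered boundary-node indices acting as measurement locations."""

    nodes: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(int(i) for i in self.nodes))
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate detector nodes")
        if not self.nodes:
            raise ValueError("empty detector set")

    def __len__(self):
        return len(self.nodes)

    def index_array(self) -> np.ndarray:
        return np.asarray(self.nodes, dtype=np.int64)

    def positions(self, mesh: TetMesh) -> np.ndarray:
        return mesh.nodes[self.index_array()]

    @classmethod
    def from_boundary(cls, mesh: TetMesh, stride: int = 1) -> "DetectorSet":
        """Every ``stride``-th boundary node, in sorted node order."""
        return cls(tuple(mesh.boundary_nodes[::stride]))


def validate_detectors(mesh: TetMesh, detectors: DetectorSet) -> None:
    if not set(detectors.nodes) <= set(mesh.boundary_nodes.tolist()):
        raise ValueError("detectors must be boundary nodes")


@dataclass
class SystemMatrix:
    """Linear map from source density on permissible nodes to detector fluence."""

    wavelength: int
    matrix: np.ndarray  # (n_detectors, n_permissible)
    detectors: DetectorSet
    permissible: np.ndarray  # node indices


def build_system_matrix(
    mesh: TetMesh,
    props: OpticalPropertyTable,
    wavelength: int,
    detectors: DetectorSet,
    permissible: Sequence[int] | None = None,
    fem: FemSystem | None = None,
    chunk: int = 512,
) -> SystemMatrix:
    """Per-wavelength system matrix via one adjoint solve per detector.

    Because K is symmetric, column j of the map equals the detector-restricted
    solve for a unit load at node j; solving K y = e_d per detector d gives
    the same matrix row-wise at the cost of |detectors| solves.
    """
    validate_detectors(mesh, detectors)
    if permissible is None:
        permissible = np.arange(mesh.n_nodes)
    permissible = np.asarray(permissible, dtype=np.int64)
    if permissible.size == 0:
        raise ValueError("permissible node set must be non-empty")
    if fem is None:
        fem = assemble_system(mesh, props, wavelength)
    lumped = mesh.lumped_node_volumes()
    det = detectors.index_array()
    A = np.empty((det.size, permissible.size))
    for start in range(0, det.size, chunk):
        idx = det[start : start + chunk]
        E = np.zeros((mesh.n_nodes, idx.size))
        E[idx, np.arange(idx.size)] = 1.0
        Y = fem.solve(E)  # (n_nodes, chunk)
        A[start : start + chunk] = (Y[permissible] * lumped[permissible, None]).T
    return SystemMatrix(int(wavelength), A, detectors, permissible)


def analytic_infinite_medium(
    points: np.ndarray,
    source_center,
    total_power: float,
    mu_a: float,
    mu_s_prime: float,
) -> np.ndarray:
    """Infinite-medium diffusion Green's function (validation oracle).

    Phi(r) = P exp(-mu_eff r) / (4 pi D r), with D = 1/(3(mu_a + mu_s')) and
    mu_eff = sqrt(mu_a / D).
    """
    if mu_a <= 0 or mu_s_prime <= 0:
        raise ValueError("mu_a and mu_s' must be positive")
    D = 1.0 / (3.0 * (mu_a + mu_s_prime))
    mu_eff = np.sqrt(mu_a / D)
    r = np.linalg.norm(
        np.atleast_2d(points) - np.asarray(source_center, dtype=float), axis=1
    )
    if np.any(r == 0):
        raise ValueError("evaluation point coincides with the source")
    return total_power * np.exp(-mu_eff * r) / (4.0 * np.pi * D * r)


# ---------------------------------------------------------------------------
# Measurement simulation and noise
# ---------------------------------------------------------------------------

_OT_STREAM = 0x0FF5E7  # substream key for the wavelength-independent offset


@dataclass
class NoiseModel:
    """CCD-style measurement noise for surface fluence.

    The sampling error ``s(lambda)`` is a Gaussian light-spot profile centred
    on the brightest detector, with wavelength-dependent amplitude and width,
    modulated by per-detector Gaussian jitter.  The offset ``Ot``
    (photon + readout + dark current) is a constant dark level plus a
    per-detector Gaussian draw and is *wavelength independent*: for a fixed
    seed, every wavelength sees the bitwise-identical realization.
    """

    seed: int
    sampling_amplitude: Mapping[int, float]
    sampling_width_mm: Mapping[int, float]
    offset_level: float = 0.0
    offset_sigma: float = 0.0
    jitter_rel: float = 0.2
    #: CCD digitization step (power of two recommended).  When nonzero, the
    #: signal and the offset are rounded to this shared fixed-point grid, so
    #: the wavelength-independent offset cancels *bitwise* under spectral
    #: differencing (fixed-point sums and differences are exact in float64).
    quantum: float = 0.0

    def offset(self, n_detectors: int) -> np.ndarray:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _OT_STREAM])
        )
        return self.offset_level + self.offset_sigma * rng.standard_normal(
            n_detectors
        )

    def sampling_error(
        self, wavelength: int, positions: np.ndarray, clean: np.ndarray
    ) -> np.ndarray:
        wavelength = int(wavelength)
        amp = float(self.sampling_amplitude[wavelength])
        width = float(self.sampling_width_mm[wavelength])
        center = positions[int(np.argmax(clean))]
        r2 = np.einsum("ij,ij->i", positions - center, positions - center)
        profile = np.exp(-r2 / (2.0 * width**2))
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.seed), wavelength])
        )
        jitter = 1.0 + self.jitter_rel * rng.standard_normal(len(clean))
        return amp * profile * jitter


def default_noise_model(
    clean_by_wavelength: Mapping[int, np.ndarray],
    seed: int,
    sampling_frac: float = 0.01,
    offset_frac: float = 0.005,
    width_base_mm: float = 5.0,
) -> NoiseModel:
    """Default noise magnitudes relative to the clean measurements.

    Sampling amplitude is ``sampling_frac`` of each wavelength's peak signal;
    spot width grows mildly with wavelength (longer wavelengths blur more).
    The shared offset level is ``offset_frac`` of the global peak.
    """
    wavelengths = sorted(int(w) for w in clean_by_wavelength)
    peak = {w: float(np.max(clean_by_wavelength[w])) for w in wavelengths}
    global_peak = max(peak.values())
    quantum = 2.0 ** (np.floor(np.log2(global_peak)) - 40) if global_peak > 0 else 0.0
    return NoiseModel(
        seed=int(seed),
        sampling_amplitude={w: sampling_frac * peak[w] for w in wavelengths},
        sampling_width_mm={
            w: width_base_mm * (w / wavelengths[0]) for w in wavelengths
        },
        offset_level=offset_frac * global_peak,
        offset_sigma=0.2 * offset_frac * global_peak,
        quantum=quantum,
    )


@dataclass
class SurfaceMeasurement:
    """Per-wavelength fluence sampled at detector nodes."""

    wavelength: int
    values: np.ndarray  # measured Phi
    detectors: DetectorSet
    noisy: bool = False
    clean: np.ndarray | None = None  # actual signal M when known

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape[0] != len(self.detectors):
            raise ValueError("one value per detector required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite measurement values")


def simulate_measurement(
    mesh: TetMesh,
    props: OpticalPropertyTable,
    wavelength: int,
    source: SourceDistribution,
    detectors: DetectorSet,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    fem: FemSystem | None = None,
) -> SurfaceMeasurement:
    """Simulate a surface measurement Phi = M + s(lambda) + Ot.

    ``M`` is the detector restriction of the diffusion solve; with
    ``noise=None`` the measurement equals ``M``.  ``seed`` overrides the
    noise model's seed (runs are bit-reproducible for a fixed seed).
    """
    if fem is None:
        fem = assemble_system(mesh, props, wavelength)
    phi = solve_fluence(fem, source)
    M = phi[detectors.index_array()]
    if noise is None:
        return SurfaceMeasurement(int(wavelength), M, detectors, False, M.copy())
    if seed is not None:
        noise = dataclasses.replace(noise, seed=int(seed))
    s = noise.sampling_error(wavelength, detectors.positions(mesh), M)
    ot = noise.offset(len(detectors))
    if noise.quantum > 0:
        q = noise.quantum
        phi_m = np.round((M + s) / q) * q + np.round(ot / q) * q
    else:
        phi_m = M + s + ot
    return SurfaceMeasurement(int(wavelength), phi_m, detectors, True, M)


def write_measurement(m: SurfaceMeasurement, mesh: TetMesh, path) -> None:
    pos = m.detectors.positions(mesh)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["detector_node", "x", "y", "z", "wavelength_nm", "fluence"])
        for node, (x, y, z), v in zip(m.detectors.nodes, pos, m.values):
            w.writerow([node, f"{x:.9g}", f"{y:.9g}", f"{z:.9g}",
                        m.wavelength, f"{v:.12e}"])


def read_measurement(path) -> SurfaceMeasurement:
    nodes, values, wl = [], [], None
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            nodes.append(int(row["detector_node"]))
            values.append(float(row["fluence"]))
            wl = int(row["wavelength_nm"])
    if wl is None:
        raise ValueError(f"empty measurement file {path!r}")
    return SurfaceMeasurement(wl, np.asarray(values), DetectorSet(tuple(nodes)), True)
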