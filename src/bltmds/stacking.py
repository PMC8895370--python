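"""Multispectral system stacking: traditional, spectral-derivative, differential.

Three strategies combine per-wavelength system matrices A_lam and surface
measurements Phi_lam into one linear system for the source density S:

* ``tm``  (traditional multispectral): vertically stack the energy-weighted
  blocks  [eta_n A_n] S = [Phi_n].
* ``mds`` (multispectral differential): stack every ordered pair (j < k) of
  block differences  [eta_j A_j - eta_k A_k] S = [Phi_j - Phi_k]; with n
  wavelengths that is n(n-1)/2 blocks, ordered (1,2),(1,3),...,(n-1,n).
* ``sd``  (spectral derivative): the adjacent-pair subset (1,2),(2,3),...

Because any wavelength-independent measurement offset appears identically in
every Phi_n, differencing removes it exactly, bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .optics import SpectralWeights

STRATEGIES = ("tm", "sd", "mds")


@dataclass
class StackedSystem:
    """Combined matrix/data of one stacking strategy with block provenance."""

    strategy: str
    wavelengths: tuple[int, ...]
    blocks: tuple[tuple[int, ...], ...]  # (lam,) for tm; (lam_j, lam_k) for pairs
    matrix: np.ndarray
    data: np.ndarray
    eta: np.ndarray
    n_detectors: int

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.blocks) * self.n_detectors:
            raise ValueError("matrix rows must equal blocks x detectors")
        if self.data.shape[0] != self.matrix.shape[0]:
            raise ValueError("data length must match matrix rows")

    def block_rows(self, i: int) -> slice:
        return slice(i * self.n_detectors, (i + 1) * self.n_detectors)

    def descriptor(self) -> dict:
        return {
            "strategy": self.strategy,
            "wavelengths": list(self.wavelengths),
            "blocks": [list(b) for b in self.blocks],
            "eta": self.eta.tolist(),
            "n_detectors": self.n_detectors,
            "shape": list(self.matrix.shape),
        }


def _collect(
    A_by_wavelength: Mapping[int, np.ndarray],
    phi_by_wavelength: Mapping[int, np.ndarray],
    weights: SpectralWeights,
):
    wavelengths = tuple(int(w) for w in weights.wavelengths)
    A = [np.asarray(A_by_wavelength[w], dtype=float) for w in wavelengths]
    phi = [np.asarray(phi_by_wavelength[w], dtype=float).ravel() for w in wavelengths]
    m, n = A[0].shape
    for a, p in zip(A, phi):
        if a.shape != (m, n):
            raise ValueError("system matrices must share one shape")
        if p.shape[0] != m:
            raise ValueError("measurement length must match detector count")
    return wavelengths, A, phi, m


def stack_traditional(
    A_by_wavelength: Mapping[int, np.ndarray],
    phi_by_wavelength: Mapping[int, np.ndarray],
    weights: SpectralWeights,
) -> StackedSystem:
    """Traditional multispectral stack [eta_n A_n] S = [Phi_n]."""
    wavelengths, A, phi, m = _collect(A_by_wavelength, phi_by_wavelength, weights)
    eta = weights.eta
    matrix = np.concatenate([eta[i] * A[i] for i in range(len(wavelengths))])
    data = np.concatenate(phi)
    return StackedSystem(
        "tm", wavelengths, tuple((w,) for w in wavelengths),
        matrix, data, eta.copy(), m,
    )


def stack_differential(
    A_by_wavelength: Mapping[int, np.ndarray],
    phi_by_wavelength: Mapping[int, np.ndarray],
    weights: SpectralWeights,
    pairs: str = "all",
) -> StackedSystem:
    """Pairwise-difference stack [eta_j A_j - eta_k A_k] S = [Phi_j - Phi_k].

    ``pairs="all"`` gives the full differential strategy (``mds``) with
    n(n-1)/2 blocks; ``pairs="adjacent"`` gives the spectral-derivative
    comparison (``sd``) with n-1 blocks.
    """
    wavelengths, A, phi, m = _collect(A_by_wavelength, phi_by_wavelength, weights)
    n = len(wavelengths)
    if n < 2:
        raise ValueError("differencing needs at least 2 wavelengths")
    if pairs == "all":
        idx_pairs = [(j, k) for j in range(n) for k in range(j + 1, n)]
        strategy = "mds"
    elif pairs == "adjacent":
        idx_pairs = [(j, j + 1) for j in range(n - 1)]
        strategy = "sd"
    else:
        raise ValueError(f"unknown pair selection {pairs!r}")
    eta = weights.eta
    matrix = np.concatenate([eta[j] * A[j] - eta[k] * A[k] for j, k in idx_pairs])
    data = np.concatenate([phi[j] - phi[k] for j, k in idx_pairs])
    blocks = tuple((wavelengths[j], wavelengths[k]) for j, k in idx_pairs)
    return StackedSystem(strategy, wavelengths, blocks, matrix, data, eta.copy(), m)


def build_stack(
    strategy: str,
    A_by_wavelength: Mapping[int, np.ndarray],
    phi_by_wavelength: Mapping[int, np.ndarray],
    weights: SpectralWeights,
) -> StackedSystem:
    if strategy == "tm":
        return stack_traditional(A_by_wavelength, phi_by_wavelength, weights)
    if strategy == "mds":
        return stack_differential(A_by_wavelength, phi_by_wavelength, weights, "all")
    if strategy == "sd":
        return stack_differential(
            A_by_wavelength, phi_by_wavelength, weights, "adjacent"
        )
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def condition_number(matrix: np.ndarray, rtol: float = 1e-12):
    """2-norm condition number sigma_max / sigma_min of a (rectangular) matrix.

    Returns ``(cond, cond_effective)`` where the effective value excludes
    singular values below ``rtol * sigma_max`` (numerical rank deficiency).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty matrix")
    sv = np.linalg.svd(matrix, compute_uv=False)
    if sv[0] == 0:
        raise ValueError("all-zero matrix has no condition number")
    cond = np.inf if sv[-1] == 0 else float(sv[0] / sv[-1])
    kept = sv[sv > rtol * sv[0]]
    return cond, float(sv[0] / kept[-1])


def export_stack(stack: StackedSystem, matrix_path, sidecar_path,
                 cond: bool = False) -> None:
    """Write the stacked matrix/data as delimited text plus a JSON sidecar."""
    np.savetxt(matrix_path, np.column_stack([stack.matrix, stack.data]),
               fmt="%.12e", delimiter="\t")
    desc = stack.descriptor()
    if cond:
        c, ce = condition_number(stack.matrix)
        desc["condition_number"] = None if np.isinf(c) else c
        desc["condition_number_effective"] = ce
    with open(sidecar_path, "w") as fh:
        json.dump(desc, fh, indent=2)
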