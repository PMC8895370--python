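"""Reconstruction and forward-model quality metrics.

Location error (distance between energy-weighted centres), Dice overlap of
node sets, contrast-to-noise ratio, cosine similarity of surface-energy
vectors, and per-detector energy differences in specific-spectrum or
spectral-differential mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh import TetMesh


@dataclass(frozen=True)
class Region:
    """A node-index set on a mesh (ROI or background)."""

    nodes: frozenset[int]

    @classmethod
    def from_indices(cls, indices) -> "Region":
        return cls(frozenset(int(i) for i in np.asarray(indices).ravel()))

    @classmethod
    def from_threshold(cls, values, threshold_frac: float = 0.1) -> "Region":
        """Nodes with value >= threshold_frac * max(values)."""
        values = np.asarray(values, dtype=float)
        if values.max() <= 0:
            raise ValueError("no positive values to threshold")
        return cls.from_indices(np.nonzero(values >= threshold_frac * values.max())[0])

    @classmethod
    def from_sphere(cls, mesh: TetMesh, center, radius: float) -> "Region":
        d2 = np.einsum(
            "ij,ij->i", mesh.nodes - np.asarray(center), mesh.nodes - np.asarray(center)
        )
        return cls.from_indices(np.nonzero(d2 <= radius**2)[0])

    def __len__(self):
        return len(self.nodes)


def energy_difference(phi_ref_j, phi_model_j, phi_ref_k=None, phi_model_k=None,
                      mode: str = "specific", detector_slice: slice | None = None):
    """Per-detector energy difference between reference and model data.

    ``specific`` mode compares one wavelength: |ref_j - model_j|.
    ``differential`` mode compares a wavelength pair's differences:
    ||ref_j - ref_k| - |model_j - model_k||.  Returns ``(values, mean)``
    where the mean is taken over ``detector_slice`` (default: all detectors).
    """
    phi_ref_j = np.atleast_1d(np.asarray(phi_ref_j, dtype=float))
    phi_model_j = np.atleast_1d(np.asarray(phi_model_j, dtype=float))
    if phi_ref_j.shape != phi_model_j.shape:
        raise ValueError("mismatched detector counts")
    if mode == "specific":
        values = np.abs(phi_ref_j - phi_model_j)
    elif mode == "differential":
        if phi_ref_k is None or phi_model_k is None:
            raise ValueError("differential mode needs both wavelengths")
        phi_ref_k = np.atleast_1d(np.asarray(phi_ref_k, dtype=float))
        phi_model_k = np.atleast_1d(np.asarray(phi_model_k, dtype=float))
        if phi_ref_k.shape != phi_ref_j.shape or phi_model_k.shape != phi_ref_j.shape:
            raise ValueError("mismatched detector counts")
        values = np.abs(
            np.abs(phi_ref_j - phi_ref_k) - np.abs(phi_model_j - phi_model_k)
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sub = values[detector_slice] if detector_slice is not None else values
    return values, float(np.mean(sub))


def cosine_similarity(a, b) -> float:
    """cos(theta) = a.b / (|a| |b|); both vectors must be nonzero."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def energy_weighted_center(S, mesh: TetMesh, threshold_frac: float = 0.0):
    """Energy-weighted centre of a nodal source density.

    Only nodes with S_i >= threshold_frac * max(S) contribute (default: all
    positive nodes).
    """
    S = np.asarray(S, dtype=float).ravel()
    if S.max() <= 0:
        raise ValueError("source density has no positive entry")
    mask = S >= max(threshold_frac * S.max(), np.finfo(float).tiny)
    w = S[mask]
    return (w[:, None] * mesh.nodes[mask]).sum(axis=0) / w.sum()


def location_error(center_recon, center_true) -> float:
    """Euclidean distance (mm) between reconstructed and true centres."""
    return float(
        np.linalg.norm(np.asarray(center_recon, float) - np.asarray(center_true, float))
    )


def dice_coefficient(x: Region, y: Region) -> float:
    """Dice overlap 2|X & Y| / (|X| + |Y|) of two node sets."""
    if len(x) == 0 and len(y) == 0:
        raise ValueError("Dice undefined for two empty regions")
    return 2.0 * len(x.nodes & y.nodes) / (len(x) + len(y))


def cnr(values, roi: Region, bck: Region) -> float:
    """Contrast-to-noise ratio between ROI and background node values.

    |mu_ROI - mu_BCK| / sqrt(w_ROI var_ROI + w_BCK var_BCK) with node-count
    weights and population variances.
    """
    if len(roi) == 0 or len(bck) == 0:
        raise ValueError("ROI and background must be non-empty")
    if roi.nodes & bck.nodes:
        raise ValueError("ROI and background must be disjoint")
    values = np.asarray(values, dtype=float).ravel()
    vr = values[sorted(roi.nodes)]
    vb = values[sorted(bck.nodes)]
    w_roi = len(roi) / (len(roi) + len(bck))
    w_bck = 1.0 - w_roi
    denom = np.sqrt(w_roi * vr.var() + w_bck * vb.var())
    num = abs(vr.mean() - vb.mean())
    if denom == 0.0:
        if num == 0.0:
            warnings.warn("CNR 0/0: both regions constant with equal means")
            return 0.0
        return np.inf
    return float(num / denom)


@dataclass
class EvaluationReport:
    """Collected reconstruction metrics, serialisable to JSON/CSV rows."""

    location_error_mm: float | None = None
    dice: float | None = None
    cnr: float | None = None
    condition_numbers: dict = field(default_factory=dict)
    cosine_similarities: dict = field(default_factory=dict)
    energy_difference_means: dict = field(default_factory=dict)
    runtimes_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if v is None:
                return None
            if isinstance(v, float) and np.isinf(v):
                return "inf"
            return v

        return {
            "location_error_mm": clean(self.location_error_mm),
            "dice": clean(self.dice),
            "cnr": clean(self.cnr),
            "condition_numbers": clean(self.condition_numbers),
            "cosine_similarities": clean(self.cosine_similarities),
            "energy_difference_means": clean(self.energy_difference_means),
            "runtimes_s": clean(self.runtimes_s),
        }
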