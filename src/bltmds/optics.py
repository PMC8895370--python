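"""Per-region, per-wavelength optical properties and spectral energy weights.

Houses the absorption coefficient mu_a, the (reduced) scattering coefficient,
the diffusion coefficient D = 1/(3(mu_a + mu_s')), and the effective
attenuation mu_eff = sqrt(mu_a / D), all in mm^-1 (D in mm).

The builtin mouse table covers six torso tissues at the four red/NIR
wavelengths (610, 630, 650, 670 nm) commonly used for firefly-luciferase
bioluminescence.  The table's scattering column is treated as
already-reduced scattering by default (anisotropy g = 0); set ``anisotropy``
to reinterpret the values as raw mu_s with mu_s' = mu_s * (1 - g).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

DEFAULT_WAVELENGTHS = (610, 630, 650, 670)

#: (tissue, region label) -> {wavelength: (mu_a, mu_s)} in mm^-1
_MOUSE_TISSUES = {
    "muscle": (0, {610: (0.2971, 5.5902), 630: (0.1605, 5.1041),
                   650: (0.1164, 4.6735), 670: (0.0870, 4.2907)}),
    "heart": (1, {610: (0.2015, 7.3484), 630: (0.1085, 7.0171),
                  650: (0.0786, 6.7104), 670: (0.0588, 6.4258)}),
    "stomach": (2, {610: (0.0384, 19.6728), 630: (0.0207, 19.0667),
                    650: (0.0150, 18.4973), 670: (0.0114, 17.9615)}),
    "liver": (3, {610: (1.2086, 7.4826), 630: (0.6505, 7.2334),
                  650: (0.4708, 6.9999), 670: (0.3815, 6.7807)}),
    "kidneys": (4, {610: (0.2258, 18.5421), 630: (0.1216, 17.6605),
                    650: (0.0881, 16.8465), 670: (0.0660, 16.0929)}),
    "lungs": (5, {610: (0.6687, 38.0785), 630: (0.3622, 37.4330),
                  650: (0.2630, 36.8181), 670: (0.1964, 36.2314)}),
}

MOUSE_REGION_LABELS = {name: lab for name, (lab, _) in _MOUSE_TISSUES.items()}


def diffusion_coefficient(mu_a: float, mu_s_prime: float) -> float:
    """D = 1/(3 (mu_a + mu_s')), mm.  Both coefficients must be positive."""
    if mu_a <= 0 or mu_s_prime <= 0:
        raise ValueError("mu_a and mu_s' must be positive")
    return 1.0 / (3.0 * (mu_a + mu_s_prime))


@dataclass(frozen=True)
class OpticalEntry:
    mu_a: float
    mu_s: float
    g: float = 0.0
    n_tissue: float = 1.37

    def __post_init__(self):
        if self.mu_a <= 0 or self.mu_s <= 0:
            raise ValueError("mu_a and mu_s must be positive")
        if not 0.0 <= self.g < 1.0:
            raise ValueError("anisotropy g must be in [0, 1)")

    @property
    def mu_s_prime(self) -> float:
        return self.mu_s * (1.0 - self.g)

    @property
    def D(self) -> float:
        return diffusion_coefficient(self.mu_a, self.mu_s_prime)

    @property
    def mu_eff(self) -> float:
        return float(np.sqrt(self.mu_a / self.D))


@dataclass
class OpticalPropertyTable:
    """Entries keyed by (region label, wavelength in nm)."""

    entries: dict[tuple[int, int], OpticalEntry] = field(default_factory=dict)

    def add(self, region: int, wavelength: int, mu_a: float, mu_s: float,
            g: float = 0.0, n_tissue: float = 1.37) -> None:
        self.entries[(int(region), int(wavelength))] = OpticalEntry(
            mu_a, mu_s, g, n_tissue
        )

    def get(self, region: int, wavelength: int) -> OpticalEntry:
        key = (int(region), int(wavelength))
        if key not in self.entries:
            raise KeyError(
                f"no optical properties for region {region} at {wavelength} nm"
            )
        return self.entries[key]

    def regions(self) -> list[int]:
        return sorted({r for r, _ in self.entries})

    def wavelengths(self) -> list[int]:
        return sorted({w for _, w in self.entries})

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["region", "wavelength_nm", "mu_a", "mu_s", "g", "n"])
            for (r, wl), e in sorted(self.entries.items()):
                w.writerow([r, wl, e.mu_a, e.mu_s, e.g, e.n_tissue])

    @classmethod
    def from_csv(cls, path) -> "OpticalPropertyTable":
        table = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                table.add(
                    int(row["region"]), int(row["wavelength_nm"]),
                    float(row["mu_a"]), float(row["mu_s"]),
                    float(row.get("g") or 0.0), float(row.get("n") or 1.37),
                )
        return table


def builtin_mouse_properties(
    anisotropy: float = 0.0, n_tissue: float = 1.37
) -> OpticalPropertyTable:
    """Mouse torso tissue properties at 610/630/650/670 nm.

    With the default ``anisotropy=0`` the tabulated scattering values are used
    directly as reduced scattering; a nonzero ``anisotropy`` reinterprets them
    as raw mu_s.
    """
    table = OpticalPropertyTable()
    for _, (label, by_wl) in _MOUSE_TISSUES.items():
        for wl, (mu_a, mu_s) in by_wl.items():
            table.add(label, wl, mu_a, mu_s, g=anisotropy, n_tissue=n_tissue)
    return table


def single_region_properties(
    tissue: str = "muscle", wavelengths=DEFAULT_WAVELENGTHS, region: int = 0,
    n_tissue: float = 1.37,
) -> OpticalPropertyTable:
    """Homogeneous-phantom table using one builtin tissue for region ``region``."""
    _, by_wl = _MOUSE_TISSUES[tissue.lower()]
    table = OpticalPropertyTable()
    for wl in wavelengths:
        mu_a, mu_s = by_wl[int(wl)]
        table.add(region, wl, mu_a, mu_s, n_tissue=n_tissue)
    return table


@dataclass
class SpectralWeights:
    """Per-wavelength energy fractions eta (sum to 1)."""

    wavelengths: tuple[int, ...]
    eta: np.ndarray

    def __post_init__(self):
        self.wavelengths = tuple(int(w) for w in self.wavelengths)
        self.eta = np.asarray(self.eta, dtype=float).ravel()
        if self.eta.shape[0] != len(self.wavelengths):
            raise ValueError("one weight per wavelength required")
        if np.any(self.eta < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.eta.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def __getitem__(self, wavelength: int) -> float:
        return float(self.eta[self.wavelengths.index(int(wavelength))])


def spectral_weights(energies, wavelengths) -> SpectralWeights:
    """Normalise per-wavelength spectral energies to fractions eta."""
    energies = np.asarray(energies, dtype=float).ravel()
    if len(wavelengths) < 2:
        raise ValueError("need at least 2 wavelengths")
    if energies.shape[0] != len(wavelengths):
        raise ValueError("one energy per wavelength required")
    if np.any(energies < 0):
        raise ValueError("energies must be non-negative")
    total = energies.sum()
    if total == 0:
        raise ValueError("energies must not all be zero")
    return SpectralWeights(tuple(wavelengths), energies / total)


def uniform_weights(wavelengths) -> SpectralWeights:
    n = len(wavelengths)
    return SpectralWeights(tuple(wavelengths), np.full(n, 1.0 / n))
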