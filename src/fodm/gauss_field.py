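"""Gaussian encapsulation of a structure unit and the theoretical profile T.

The fuzzy-oil-drop model idealizes a soluble globule's hydrophobicity as a
3D Gaussian spanning the molecule: maximal at the center (the hydrophobic
core), close to zero at the surface. The unit is first brought to a canonical
frame — principal axes of the effective-atom cloud aligned with x >= y >= z
by spread, centered on the bounding-box midpoint of that frame — and the
per-axis sigmas are chosen so the molecular extent sits near 3 sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: smallest allowed (half-extent + pad) before division by 3, in Angstrom
SIGMA_FLOOR = 1.0

#: profile entries are floored here before normalization (Gaussian tail underflow)
PROFILE_FLOOR = 1e-12


@dataclass
class Encapsulation:
    """A fitted 3D Gaussian: frame (center, rotation) plus per-axis sigmas.

    ``rotation`` maps original coordinates into the canonical frame:
    ``local = (p - center) @ rotation.T``. det(rotation) = +1.
    """

    center: np.ndarray  # (3,) original-frame point mapped to the origin
    rotation: np.ndarray  # (3, 3) orthonormal, original -> local
    sigma: np.ndarray | None = None  # (3,) Angstrom, set by encapsulate()

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation determinant is not +1")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise ValueError("sigmas must be positive")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.center) @ self.rotation.T


@dataclass
class HydroProfile:
    """Aligned per-residue probability vectors over one residue index.

    T theoretical, O observed, R uniform reference, and optionally M — the
    environment-modified target at the optimal K. Each present vector is
    non-negative and sums to 1.
    """

    index: list  # residue keys, in unit order
    T: np.ndarray
    O: np.ndarray
    R: np.ndarray | None = None
    M: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.index)
        if self.R is None:
            self.R = np.full(n, 1.0 / n)
        for name in ("T", "O", "R", "M"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            setattr(self, name, v)
            if len(v) != n:
                raise ValueError(f"{name} length {len(v)} != index length {n}")
            if np.any(v < 0):
                raise ValueError(f"{name} has negative entries")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {v.sum()}, not 1")


def orient_unit(points: np.ndarray) -> tuple[np.ndarray, Encapsulation]:
    """Bring a point cloud to its canonical frame.

    Rotates onto the principal axes of the cloud (covariance eigenvectors),
    ordered so spread decreases x -> z, each eigenvector's largest-magnitude
    component made positive, determinant forced to +1; then translates so the
    per-axis bounding-box midpoint of the rotated cloud is at the origin.
    Centering in the principal frame (not the input frame) is what makes the
    downstream T profile invariant to rigid-body transforms of the input.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("need at least one point")
    centroid = pts.mean(axis=0)
    if pts.shape[0] == 1:
        axes = np.eye(3)
    else:
        cov = np.atleast_2d(np.cov((pts - centroid).T))
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]  # spread decreasing onto x, y, z
        axes = evecs[:, order]
        for k in range(3):
            j = int(np.argmax(np.abs(axes[:, k])))
            if axes[j, k] < 0:
                axes[:, k] = -axes[:, k]
        if np.linalg.det(axes) < 0:
            axes[:, 2] = -axes[:, 2]  # smallest-spread axis; T is even per axis

    rotated = (pts - centroid) @ axes
    bbox_mid = 0.5 * (rotated.min(axis=0) + rotated.max(axis=0))
    oriented = rotated - bbox_mid
    # local = axes.T @ (p - center) with center = centroid + axes @ bbox_mid
    enc = Encapsulation(center=centroid + axes @ bbox_mid, rotation=axes.T)
    return oriented, enc


def encapsulate(oriented: np.ndarray, pad: float = 0.0,
                floor: float = SIGMA_FLOOR) -> np.ndarray:
    """Per-axis sigmas for a cloud already in its canonical frame.

    sigma_axis = max(extent_axis / 2 + pad, floor) / 3, so the molecular
    surface lies near 3 sigma where the Gaussian is close to zero.
    """
    pts = np.atleast_2d(np.asarray(oriented, dtype=float))
    half_extent = 0.5 * (pts.max(axis=0) - pts.min(axis=0))
    return np.maximum(half_extent + pad, floor) / 3.0


def fit_encapsulation(points: np.ndarray, pad: float = 0.0,
                      floor: float = SIGMA_FLOOR) -> Encapsulation:
    """orient_unit + encapsulate in one call."""
    oriented, enc = orient_unit(points)
    enc.sigma = encapsulate(oriented, pad=pad, floor=floor)
    return enc


def t_profile(points: np.ndarray, enc: Encapsulation) -> np.ndarray:
    """Theoretical hydrophobicity profile: the Gaussian sampled at each residue.

    ``points`` are original-frame effective-atom positions; they are mapped
    into the encapsulation's frame internally. The unnormalized value at a
    local point (x, y, z) is exp(-x^2/2sx^2 - y^2/2sy^2 - z^2/2sz^2); values
    are floored at 1e-12 and normalized to sum 1.
    """
    if enc.sigma is None:
        raise ValueError("encapsulation has no sigmas; call encapsulate first")
    local = enc.to_local(points)
    g = np.exp(-0.5 * np.sum((local / enc.sigma) ** 2, axis=1))
    g = np.maximum(g, PROFILE_FLOOR)
    return g / g.sum()
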