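"""Observed hydrophobicity profile O from pairwise hydrophobic interactions.

Each residue collects hydrophobicity from every other residue within a
cutoff, weighted by a smooth distance-damping function; the collected values
are normalized to a probability vector comparable with the theoretical T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateProfileError

#: default interaction cutoff, Angstrom
DEFAULT_CUTOFF = 9.0


@dataclass
class InteractionParams:
    """Parameters of the pairwise hydrophobic interaction."""

    cutoff: float = DEFAULT_CUTOFF
    form: Literal["sigmoid", "linear"] = "sigmoid"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def contact_weight(r, c: float = DEFAULT_CUTOFF,
                   form: Literal["sigmoid", "linear"] = "sigmoid"):
    """Distance damping w(r) in [0, 1]: 1 at contact, 0 at and beyond the cutoff.

    The default is the sigmoid polynomial standard in hydrophobic-interaction
    models, w = 1 - 1/2 (7 x^2 - 9 x^4 + 5 x^6 - x^8) with x = r/c, which is
    continuous (and flat) at r = c. A linear ramp 1 - x is provided for
    sensitivity checks. Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    x = np.minimum(r / c, 1.0)
    if form == "sigmoid":
        x2 = x * x
        w = 1.0 - 0.5 * (7 * x2 - 9 * x2**2 + 5 * x2**3 - x2**4)
    elif form == "linear":
        w = 1.0 - x
    else:
        raise ValueError(f"unknown interaction form {form!r}")
    w = np.where(np.asarray(r) > c, 0.0, w)
    return float(w) if w.ndim == 0 else w


def o_profile(points: np.ndarray, H: np.ndarray,
              params: InteractionParams | None = None) -> np.ndarray:
    """Observed profile: raw_i = sum_{j != i} (H_i + H_j) w(r_ij), normalized.

    ``points`` are effective-atom positions, ``H`` intrinsic hydrophobicities.
    The normalized profile is invariant to rigid transforms and to rescaling
    all H by a common factor.
    """
    params = params or InteractionParams()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    H = np.asarray(H, dtype=float)
    n = pts.shape[0]
    if n < 2:
        raise DegenerateProfileError("observed profile needs at least 2 residues")
    if len(H) != n:
        raise ValueError("H length does not match number of points")

    w = squareform(contact_weight(pdist(pts), c=params.cutoff, form=params.form))
    np.fill_diagonal(w, 0.0)
    # sum_j (H_i + H_j) w_ij = H_i * sum_j w_ij + sum_j H_j w_ij
    raw = H * w.sum(axis=1) + w @ H
    total = raw.sum()
    if total <= 0:
        if not np.any(w > 0):
            raise DegenerateProfileError(
                f"no residue pair within the {params.cutoff} A cutoff"
            )
        raise DegenerateProfileError("all intrinsic hydrophobicities are zero")
    return raw / total
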