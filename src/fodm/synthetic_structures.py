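"""Synthetic structure and profile generators.

These produce inputs with the statistical structure the analysis assumes —
residue point clouds sampled from a 3D Gaussian, intrinsic hydrophobicity
arranged micelle-like (core-hydrophobic), inverted (surface-hydrophobic) or
uniform, and two-chain complexes with a controllable contact interface — as
valid PDB, so the entire pipeline is exercisable with no downloads. All
generators are pure functions of their seed and config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .fod_stats import m_profile
from .structure_io import ResidueModel, StructureUnit, load_scale

#: minimum pairwise spacing between effective atoms, Angstrom
MIN_SPACING = 3.5

#: default per-axis sigmas of the generating Gaussian, Angstrom (anisotropic,
#: roughly the proportions of a small globular protein)
DEFAULT_SIGMAS = (18.0, 14.0, 10.0)


@dataclass
class GeneratorConfig:
    """Configuration of one synthetic chain."""

    n_residues: int = 300
    seed: int = 0
    sigmas: tuple[float, float, float] = DEFAULT_SIGMAS
    mode: Literal["ideal_micelle", "inverted_micelle", "uniform_h", "mixed"] = "ideal_micelle"
    k_true: float | None = None
    noise: float | None = None  # sd of Gaussian jitter on target H
    chain_id: str = "A"
    scale: str = "kyte_doolittle"

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be positive")


def _sample_points(rng: np.random.Generator, n: int,
                   sigmas: np.ndarray, max_tries: int = 200) -> np.ndarray:
    """Gaussian cloud with rejection to enforce the minimum spacing."""
    pts: list[np.ndarray] = []
    for _ in range(n):
        for attempt in range(max_tries):
            p = rng.normal(0.0, sigmas)
            if not pts or np.min(np.linalg.norm(np.asarray(pts) - p, axis=1)) >= MIN_SPACING:
                pts.append(p)
                break
        else:
            raise RuntimeError(
                f"could not place {n} residues at >= {MIN_SPACING} A spacing; "
                "increase sigmas or reduce n_residues"
            )
    # quantize to the PDB %8.3f coordinate precision so fixtures survive a
    # write/reload round trip bit-exactly
    return np.round(np.asarray(pts), 3)


def _nearest_aa(target_h: np.ndarray, scale: dict[str, float]) -> list[str]:
    """Amino-acid code whose scale value is closest to each target H."""
    codes = sorted(scale)
    values = np.asarray([scale[c] for c in codes])
    picks = np.argmin(np.abs(values[None, :] - target_h[:, None]), axis=1)
    return [codes[i] for i in picks]


def gen_unit(cfg: GeneratorConfig) -> StructureUnit:
    """Generate a single synthetic chain as a StructureUnit.

    Effective-atom positions are sampled from the configured Gaussian with a
    3.5 A minimum spacing. Hydrophobicity follows the mode: ``ideal_micelle``
    rank-maps H to decrease with (sigma-scaled) distance from the center,
    ``inverted_micelle`` reverses that, ``uniform_h`` holds H constant at
    mid-scale, ``mixed`` assigns H at random. Residue types are the
    nearest-H amino acids under the active scale, so H survives a PDB
    round trip; each residue carries a single CA pseudo-atom.
    """
    rng = np.random.default_rng(cfg.seed)
    sigmas = np.asarray(cfg.sigmas, dtype=float)
    pts = _sample_points(rng, cfg.n_residues, sigmas)
    scale = load_scale(cfg.scale)
    lo, hi = 0.0, 1.0  # scale is min-max normalized

    radius = np.linalg.norm(pts / sigmas, axis=1)
    rank = np.argsort(np.argsort(radius))  # 0 = most central
    grades = np.linspace(hi, lo, cfg.n_residues)
    if cfg.mode == "ideal_micelle":
        target = grades[rank]
    elif cfg.mode == "inverted_micelle":
        target = grades[cfg.n_residues - 1 - rank]
    elif cfg.mode == "uniform_h":
        target = np.full(cfg.n_residues, 0.5)
    elif cfg.mode == "mixed":
        target = rng.uniform(lo, hi, cfg.n_residues)
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")
    if cfg.noise:
        target = np.clip(target + rng.normal(0.0, cfg.noise, cfg.n_residues), lo, hi)

    codes = _nearest_aa(target, scale)
    residues = []
    for i, (code, p) in enumerate(zip(codes, pts), start=1):
        r = ResidueModel(chain_id=cfg.chain_id, seq_num=i, icode="", aa=code,
                         atoms=[("C", "CA", np.asarray(p, dtype=float))],
                         H=scale[code], ca_fallback=True)
        r.effective_xyz = np.asarray(p, dtype=float)
        residues.append(r)
    return StructureUnit(residues=residues,
                         source_id=f"synthetic_{cfg.mode}_s{cfg.seed}")


def gen_profile_pair(n: int, k_true: float, seed: int = 0,
                     noise: float = 0.0, alpha: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (T, O) pair for K recovery.

    T is a seeded Dirichlet draw; O = M(T, k_true), optionally with
    multiplicative log-normal-style noise (1 + noise * N(0,1), clipped
    positive) and renormalized.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if k_true < 0:
        raise ValueError("k_true must be non-negative")
    rng = np.random.default_rng(seed)
    T = rng.dirichlet(np.full(n, alpha))
    O = m_profile(T, k_true)
    if noise:
        O = O * np.clip(1.0 + rng.normal(0.0, noise, n), 1e-6, None)
        O = O / O.sum()
    return T, O


def gen_toy_complex(configs: list[GeneratorConfig], gap: float = 8.0,
                    seed: int | None = None) -> StructureUnit:
    """Two or more generated chains with centroids separated along x by ``gap``.

    Whether an interface exists is controlled by gap versus the interaction
    cutoff. Chain ids are forced distinct (A, B, C, ...); per-chain seeds
    derive from ``seed`` when given.
    """
    if len(configs) < 2:
        raise ValueError("a complex needs at least 2 chain configs")
    residues = []
    offset = 0.0
    for i, cfg in enumerate(configs):
        chain_id = chr(ord("A") + i)
        sub_seed = cfg.seed if seed is None else seed * 1000 + i
        sub = GeneratorConfig(n_residues=cfg.n_residues, seed=sub_seed,
                              sigmas=cfg.sigmas, mode=cfg.mode,
                              noise=cfg.noise, chain_id=chain_id,
                              scale=cfg.scale)
        unit = gen_unit(sub)
        shift = np.array([offset, 0.0, 0.0])
        for r in unit.residues:
            r.atoms = [(el, name, xyz + shift) for el, name, xyz in r.atoms]
            r.effective_xyz = r.effective_xyz + shift
            residues.append(r)
        offset += gap
    return StructureUnit(residues=residues, source_id="synthetic_complex")
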