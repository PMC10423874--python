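"""Assessment modes built on the field + statistic machinery.

A structure can be judged as a whole complex, as individual chains (the
Gaussian spans one chain), as chains-in-context (the Gaussian and the
observed interactions span the whole complex, profiles restricted to the
chain and renormalized), on its protein-protein interface, on domains, on
disulfide-delimited fragments, and across bound/unbound forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateSelectionError, MappingError
from .fod_stats import (DEFAULT_K_MAX, DEFAULT_K_STEP, FodStatus,
                        evaluate_profiles)
from .gauss_field import HydroProfile, fit_encapsulation, t_profile
from .observed_field import DEFAULT_CUTOFF, InteractionParams, o_profile
from .structure_io import ResidueKey, StructureUnit

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Knobs shared by every assessment mode."""

    cutoff: float = DEFAULT_CUTOFF  # interaction + interface cutoff, Angstrom
    pad: float = 0.0  # extent padding before sigma = extent/2 / 3
    sigma_floor: float = 1.0
    k_step: float = DEFAULT_K_STEP
    k_max: float = DEFAULT_K_MAX
    interaction_form: Literal["sigmoid", "linear"] = "sigmoid"

    @property
    def interaction(self) -> InteractionParams:
        return InteractionParams(cutoff=self.cutoff, form=self.interaction_form)


@dataclass
class SelectionSpec:
    """A named set of residues within a target unit.

    ``members`` are residue keys (chain_id, seq_num, icode); ``ranges`` are
    (chain_id, first, last) closed intervals in author numbering, expanded
    against the unit at resolve time.
    """

    name: str
    kind: Literal["chain", "domain", "interface", "ss_fragment", "custom",
                  "cross_form"] = "custom"
    members: list[ResidueKey] = field(default_factory=list)
    ranges: list[tuple[str, int, int]] = field(default_factory=list)

    def resolve(self, unit: StructureUnit) -> list[int]:
        """Indices into unit.residues, in unit order; errors if empty."""
        keys = set(self.members)
        idx = []
        for i, r in enumerate(unit.residues):
            if r.key in keys:
                idx.append(i)
                keys.discard(r.key)
            else:
                for chain, lo, hi in self.ranges:
                    if r.chain_id == chain and lo <= r.seq_num <= hi:
                        idx.append(i)
                        break
        if keys:
            raise DegenerateSelectionError(
                f"selection {self.name!r}: members not in unit: {sorted(keys)}"
            )
        if not idx:
            raise DegenerateSelectionError(f"selection {self.name!r} is empty")
        return idx


def unit_profiles(unit: StructureUnit, params: AnalysisParams | None = None) -> HydroProfile:
    """T and O over all residues of the unit, Gaussian spanning the unit."""
    params = params or AnalysisParams()
    pts = unit.effective_coords()
    enc = fit_encapsulation(pts, pad=params.pad, floor=params.sigma_floor)
    T = t_profile(pts, enc)
    O = o_profile(pts, unit.hydrophobicity(), params.interaction)
    return HydroProfile(index=[r.key for r in unit.residues], T=T, O=O)


def status_individual(unit: StructureUnit, params: AnalysisParams | None = None,
                      mode: str = "individual_chain",
                      name: str = "") -> tuple[FodStatus, HydroProfile]:
    """Status of a unit treated as a standalone structural unit.

    The Gaussian is fitted to this unit alone and observed interactions are
    those among its own residues. ``mode`` is ``complex``, ``individual_chain``
    or ``domain`` depending on what the caller passes in.
    """
    params = params or AnalysisParams()
    profile = unit_profiles(unit, params)
    status = evaluate_profiles(profile.O, profile.T, mode=mode,
                               name=name or unit.source_id,
                               k_max=params.k_max, step=params.k_step)
    from .fod_stats import m_profile
    profile.M = m_profile(profile.T, status.k_opt)
    return status, profile


def fragment_status(profile: HydroProfile, sel: SelectionSpec | Sequence[int],
                    params: AnalysisParams | None = None,
                    mode: str = "fragment", name: str = "") -> FodStatus:
    """Status of a profile fragment: sub-vectors of T and O renormalized.

    The T and O obtained for the whole unit are sliced to the selection and
    each renormalized to sum 1; RD then measures the fragment's share in the
    unit-wide hydrophobic core, and the optimal K is recomputed on the
    normalized fragments.
    """
    params = params or AnalysisParams()
    if isinstance(sel, SelectionSpec):
        keymap = {k: i for i, k in enumerate(profile.index)}
        missing = [m for m in sel.members if m not in keymap]
        if missing:
            raise DegenerateSelectionError(
                f"selection {sel.name!r}: not in profile index: {missing}")
        idx = sorted({keymap[m] for m in sel.members}
                     | {i for i, k in enumerate(profile.index)
                        for chain, lo, hi in sel.ranges
                        if k[0] == chain and lo <= k[1] <= hi})
        name = name or sel.name
    else:
        idx = sorted(int(i) for i in sel)
    if len(idx) < 2:
        raise DegenerateSelectionError(
            f"fragment {name!r}: needs at least 2 residues, got {len(idx)}")
    T = np.asarray(profile.T)[idx]
    O = np.asarray(profile.O)[idx]
    if O.sum() <= 0:
        raise DegenerateSelectionError(f"fragment {name!r}: zero observed mass")
    return evaluate_profiles(O / O.sum(), T / T.sum(), mode=mode, name=name,
                             k_max=params.k_max, step=params.k_step)


def status_in_context(complex_unit: StructureUnit, sel: SelectionSpec | Sequence[int],
                      params: AnalysisParams | None = None,
                      mode: str = "chain_in_complex",
                      name: str = "",
                      profile: HydroProfile | None = None) -> FodStatus:
    """Status of a selection as a component of the whole complex.

    The Gaussian spans the whole complex and O includes interactions with
    every complex residue; T and O are then restricted to the selection and
    renormalized. Pass a precomputed complex ``profile`` to avoid recomputing
    it per selection.
    """
    params = params or AnalysisParams()
    if profile is None:
        profile = unit_profiles(complex_unit, params)
    if isinstance(sel, SelectionSpec):
        idx = sel.resolve(complex_unit)
        name = name or sel.name
    else:
        idx = list(sel)
    return fragment_status(profile, idx, params, mode=mode, name=name)


def interface_selection(complex_unit: StructureUnit,
                        cutoff: float = DEFAULT_CUTOFF,
                        pair: tuple[str, str] | None = None) -> SelectionSpec:
    """Residues whose effective atom lies within ``cutoff`` of another chain.

    With ``pair`` given, only contacts between those two chains count;
    otherwise the union over all chain pairs. A structure whose chains never
    approach within the cutoff yields an empty selection (members == []),
    reported rather than raised so callers can record "no interface".
    """
    chains = complex_unit.chains
    if len(chains) < 2:
        raise ValueError("interface requires at least 2 chains")
    if pair is not None:
        for c in pair:
            if c not in chains:
                raise ValueError(f"no chain {c!r} in unit")
    pts = complex_unit.effective_coords()
    members: set[ResidueKey] = set()
    ids = list(chains)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if pair is not None and set(pair) != {ids[a], ids[b]}:
                continue
            ia, ib = chains[ids[a]], chains[ids[b]]
            d = cdist(pts[ia], pts[ib])
            close = d <= cutoff
            for i in np.flatnonzero(close.any(axis=1)):
                members.add(complex_unit.residues[ia[i]].key)
            for j in np.flatnonzero(close.any(axis=0)):
                members.add(complex_unit.residues[ib[j]].key)
    ordered = [r.key for r in complex_unit.residues if r.key in members]
    label = "interface" if pair is None else f"interface_{pair[0]}_{pair[1]}"
    return SelectionSpec(name=label, kind="interface", members=ordered)


def ss_fragment_selections(unit: StructureUnit) -> list[SelectionSpec]:
    """One contiguous chain fragment per disulfide bond.

    Each intra-chain SS bond Cys_i-Cys_j yields the closed residue range
    [min(i,j), max(i,j)] on that chain; inter-chain bonds are skipped with a
    warning. No bonds -> empty list.
    """
    out = []
    for n, (k1, k2) in enumerate(unit.ss_bonds, start=1):
        if k1[0] != k2[0]:
            logger.warning("skipping inter-chain SS bond %s-%s", k1, k2)
            continue
        lo, hi = sorted((k1[1], k2[1]))
        out.append(SelectionSpec(name=f"SS{n}_{k1[0]}{lo}-{hi}",
                                 kind="ss_fragment",
                                 ranges=[(k1[0], lo, hi)]))
    return out


def cross_form_status(unbound_profile: HydroProfile,
                      bound_interface: SelectionSpec,
                      mapping: Mapping[ResidueKey, ResidueKey] | None = None,
                      params: AnalysisParams | None = None) -> FodStatus:
    """Status, in the unbound form, of the residues that form the bound interface.

    ``mapping`` sends bound residue keys to unbound keys; default is identity
    on (chain, seq_num, icode). Unmapped residues raise, listing them.
    """
    index = set(unbound_profile.index)
    mapped: list[ResidueKey] = []
    unmappable: list[ResidueKey] = []
    for key in bound_interface.members:
        target = mapping.get(key) if mapping is not None else key
        if target is None or target not in index:
            unmappable.append(key)
        else:
            mapped.append(target)
    if unmappable:
        raise MappingError(
            f"bound-interface residues with no unbound counterpart: {unmappable}")
    sel = SelectionSpec(name=f"{bound_interface.name}@unbound",
                        kind="cross_form", members=mapped)
    return fragment_status(unbound_profile, sel, params, mode="cross_form",
                           name=sel.name)
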