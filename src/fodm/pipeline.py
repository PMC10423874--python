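"""End-to-end orchestration: per-structure reports and batch tables.

``analyze`` runs every applicable assessment mode on one structure and
returns an :class:`AnalysisReport`; ``batch`` maps it over a manifest,
isolating per-entry failures, and writes a combined table shaped like a
per-structure summary (one row per mode). Reports serialize to JSON at
fixed floating-point precision so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import DegenerateProfileError, DegenerateSelectionError, FodmError
from .fod_stats import FodStatus, m_profile
from .gauss_field import HydroProfile
from .structure_io import StructureUnit, load_structure
from .unit_analysis import (AnalysisParams, SelectionSpec, cross_form_status,
                            fragment_status, interface_selection,
                            ss_fragment_selections, status_in_context,
                            status_individual)

logger = logging.getLogger(__name__)

RCSB_URL = "https://files.rcsb.org/download/{}.pdb"

_TABLE_COLUMNS = ["unit", "mode", "N", "D(O|T)", "D(O|R)", "RD", "K", "D(O|M)"]


@dataclass
class AnalysisConfig:
    """What to compute for one structure and with which parameters."""

    params: AnalysisParams = field(default_factory=AnalysisParams)
    scale: str = "kyte_doolittle"
    format: str = "auto"
    selections: list[SelectionSpec] = field(default_factory=list)  # domains etc.
    interface: bool = True
    ss_fragments: bool = True
    per_chain: bool = True
    cross_form_partner: str | None = None  # bound-form path for unbound analyses
    fetch: bool = False  # resolve bare accessions against RCSB (off by default)


@dataclass
class AnalysisReport:
    """All FodStatus records for one structure plus the per-residue table."""

    source_id: str
    statuses: list[FodStatus] = field(default_factory=list)
    skipped_modes: dict[str, str] = field(default_factory=dict)
    residue_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        def _round(x):
            return round(float(x), 6)

        table = None
        if self.residue_table is not None:
            table = self.residue_table.copy()
            for c in table.columns:
                if table[c].dtype.kind == "f":
                    table[c] = table[c].map(_round)
            table = table.to_dict(orient="records")
        return {
            "source_id": self.source_id,
            "statuses": [
                {k: (_round(v) if isinstance(v, float) else v)
                 for k, v in s.to_dict().items()}
                for s in self.statuses
            ],
            "skipped_modes": self.skipped_modes,
            "residue_table": table,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def table(self) -> pd.DataFrame:
        rows = [
            {"unit": s.name, "mode": s.mode, "N": s.n_residues,
             "D(O|T)": s.d_ot, "D(O|R)": s.d_or, "RD": s.rd,
             "K": s.k_opt, "D(O|M)": s.d_om}
            for s in self.statuses
        ]
        return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def fetch_structure(accession: str, dest: Path) -> Path:
    """Download a PDB entry from RCSB. Requires network; off by default."""
    url = RCSB_URL.format(accession.upper())
    dest.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(url, timeout=30) as resp:
        dest.write_bytes(resp.read())
    return dest


def _resolve_source(source: str | Path | StructureUnit,
                    config: AnalysisConfig) -> StructureUnit:
    if isinstance(source, StructureUnit):
        return source
    p = Path(source)
    if not p.exists() and len(str(source)) == 4 and config.fetch:
        p = fetch_structure(str(source), Path("fetched") / f"{source}.pdb")
    return load_structure(p, format=config.format, scale=config.scale)


def _residue_table(unit: StructureUnit, profile: HydroProfile,
                   k_opt: float, interface_keys: set) -> pd.DataFrame:
    M = m_profile(profile.T, k_opt)
    return pd.DataFrame({
        "chain": [r.chain_id for r in unit.residues],
        "seq_num": [r.seq_num for r in unit.residues],
        "icode": [r.icode for r in unit.residues],
        "aa": [r.aa for r in unit.residues],
        "H": [r.H for r in unit.residues],
        "T": profile.T,
        "O": profile.O,
        "R": profile.R,
        "M": M,
        "interface": [r.key in interface_keys for r in unit.residues],
    })


def analyze(source: str | Path | StructureUnit,
            config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run every applicable assessment mode on one structure.

    Modes that do not apply (interface on a monomer) or that degenerate (a
    chain with no contact pair) are recorded in ``skipped_modes`` with the
    reason rather than failing the whole report.
    """
    config = config or AnalysisConfig()
    unit = _resolve_source(source, config)
    params = config.params
    report = AnalysisReport(source_id=unit.source_id)
    multi_chain = len(unit.chains) > 1

    # whole unit: Gaussian over everything
    whole_mode = "complex" if multi_chain else "individual_chain"
    status, profile = status_individual(unit, params, mode=whole_mode,
                                        name=unit.source_id)
    report.statuses.append(status)

    interface_keys: set = set()
    if multi_chain and config.interface:
        sel = interface_selection(unit, cutoff=params.cutoff)
        if sel.members:
            interface_keys = set(sel.members)
            try:
                report.statuses.append(
                    status_in_context(unit, sel, params, mode="interface",
                                      name="interface", profile=profile))
            except (DegenerateProfileError, DegenerateSelectionError) as exc:
                report.skipped_modes["interface"] = str(exc)
        else:
            report.skipped_modes["interface"] = "no interface within cutoff"
    elif not multi_chain:
        report.skipped_modes["interface"] = "single-chain structure"

    if multi_chain and config.per_chain:
        for chain_id, idx in unit.chains.items():
            sub = unit.subunit(idx, source_id=f"{unit.source_id}:{chain_id}")
            try:
                s, _p = status_individual(sub, params, mode="individual_chain",
                                          name=f"chain {chain_id}")
                report.statuses.append(s)
            except FodmError as exc:
                report.skipped_modes[f"individual_chain:{chain_id}"] = str(exc)
            try:
                report.statuses.append(
                    status_in_context(unit, idx, params, mode="chain_in_complex",
                                      name=f"chain {chain_id} in complex",
                                      profile=profile))
            except FodmError as exc:
                report.skipped_modes[f"chain_in_complex:{chain_id}"] = str(exc)

    if config.ss_fragments:
        for sel in ss_fragment_selections(unit):
            try:
                report.statuses.append(
                    fragment_status(profile, sel, params, mode="fragment"))
            except FodmError as exc:
                report.skipped_modes[sel.name] = str(exc)

    for sel in config.selections:
        try:
            if sel.kind == "domain":
                idx = sel.resolve(unit)
                sub = unit.subunit(idx, source_id=f"{unit.source_id}:{sel.name}")
                s, _p = status_individual(sub, params, mode="domain", name=sel.name)
                report.statuses.append(s)
                report.statuses.append(
                    status_in_context(unit, idx, params, mode="chain_in_complex",
                                      name=f"{sel.name} in unit", profile=profile))
            else:
                report.statuses.append(
                    fragment_status(profile, sel, params, mode="fragment"))
        except FodmError as exc:
            report.skipped_modes[sel.name] = str(exc)

    if config.cross_form_partner:
        try:
            bound = load_structure(config.cross_form_partner,
                                   format=config.format, scale=config.scale)
            bsel = interface_selection(bound, cutoff=params.cutoff)
            if bsel.members:
                report.statuses.append(
                    cross_form_status(profile, bsel, params=params))
            else:
                report.skipped_modes["cross_form"] = "partner has no interface"
        except FodmError as exc:
            report.skipped_modes["cross_form"] = str(exc)

    report.residue_table = _residue_table(unit, profile,
                                          report.statuses[0].k_opt,
                                          interface_keys)
    return report


def load_selections(path: str | Path) -> list[SelectionSpec]:
    """Read named selections from a YAML config.

    Format: ``selections: [{name, kind, chain, ranges: [[lo, hi], ...]}]``,
    author numbering, 1-based closed intervals.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    out = []
    for entry in doc.get("selections", []):
        ranges = [(entry["chain"], int(lo), int(hi))
                  for lo, hi in entry.get("ranges", [])]
        out.append(SelectionSpec(name=entry["name"],
                                 kind=entry.get("kind", "custom"),
                                 ranges=ranges))
    return out


def batch(manifest: str | Path, out_dir: str | Path,
          config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Analyze every manifest entry; write per-entry reports + a combined TSV.

    The manifest is a TSV with columns ``id`` and ``path`` (and optionally
    ``selections``, a YAML file of named residue ranges). A failing entry is
    flagged in the combined table; the rest still complete.
    """
    manifest = Path(manifest)
    entries = pd.read_csv(manifest, sep="\t")
    if entries.empty:
        raise ValueError(f"empty manifest: {manifest}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or AnalysisConfig()

    frames = []
    for _, row in entries.iterrows():
        entry_id = str(row["id"])
        cfg = AnalysisConfig(**{**config.__dict__})
        if "selections" in entries.columns and isinstance(row.get("selections"), str):
            cfg.selections = load_selections(row["selections"])
        try:
            report = analyze(row["path"], cfg)
            report.to_json(out_dir / f"{entry_id}.json")
            if report.residue_table is not None:
                report.residue_table.to_csv(out_dir / f"{entry_id}_profile.tsv",
                                            sep="\t", index=False)
            t = report.table()
            t.insert(0, "id", entry_id)
            t["failed"] = False
            frames.append(t)
        except (FodmError, OSError, ValueError) as exc:
            logger.warning("entry %s failed: %s", entry_id, exc)
            frames.append(pd.DataFrame([{"id": entry_id, "unit": "",
                                         "mode": "error", "failed": True,
                                         "error": str(exc)}]))
    combined = pd.concat(frames, ignore_index=True)
    combined.to_csv(out_dir / "combined.tsv", sep="\t", index=False,
                    float_format="%.6f")
    return combined
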