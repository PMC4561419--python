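"""End-to-end comparison pipeline.

Orchestrates the per-module operations into the comparative analysis a
receptor-family study performs: number the sequences (motif-anchored
Ballesteros-Weinstein), compute a transmembrane identity matrix, superpose
structures and report selection RMSDs, and profile binding cavities.  The
result is a :class:`ComparisonReport` written as JSON plus TSV tables, with a
provenance block (config hash, package version) so re-runs are checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from . import motifs as motif_defaults
from .pocket import CavitySelection, ResidueClassScheme, cavity_profile
from .seq import (Alignment, GAP, SequenceRecord, anchor_alignment,
                  annotate_helices, assign_bw, bw_table, helix_column_ranges,
                  read_alignment, read_fasta, round_half_up, tm_identity)
from .structure import Structure, read_structure, selection_rmsd

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    sequence_files: list[str] = field(default_factory=list)
    alignment_file: Optional[str] = None
    alignment_format: str = "clustal"
    structure_files: list[str] = field(default_factory=list)
    chain_map: dict[str, str] = field(default_factory=dict)
    boundary_offsets: dict[int, tuple[int, int]] = field(default_factory=dict)
    selections: dict[str, list] = field(default_factory=dict)
    atom_set: str = "backbone"
    superpose: bool = True
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    grid_spacing: float = 0.5
    identity_mode: str = "tm"  # "tm" | "full"
    out_dir: str = "seventm_out"
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.identity_mode not in ("tm", "full"):
            raise ConfigError("identity_mode must be 'tm' or 'full'")
        if cfg.atom_set not in ("backbone", "CA", "all"):
            raise ConfigError("atom_set must be backbone, CA or all")
        cfg.boundary_offsets = {int(k): tuple(v)
                                for k, v in (cfg.boundary_offsets or {}).items()}
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ComparisonReport:
    identity_percent: dict[str, dict[str, float]]
    identity_rounded: dict[str, dict[str, int]]
    bw_tables: dict[str, Any]  # sequence id -> DataFrame
    rmsd_records: list[dict[str, Any]]
    cavity_profiles: list[dict[str, Any]]
    provenance: dict[str, Any]

    def body(self) -> dict[str, Any]:
        """The deterministic report body (provenance hash included,
        timestamps excluded)."""
        return {
            "identity_percent": self.identity_percent,
            "identity_rounded": self.identity_rounded,
            "bw_tables": {k: v.to_dict(orient="records")
                          for k, v in self.bw_tables.items()},
            "rmsd_records": self.rmsd_records,
            "cavity_profiles": self.cavity_profiles,
            "config_digest": self.provenance["config_digest"],
        }


def stack_and_anchor(records: list[SequenceRecord],
                     annotations: list[list]) -> Alignment:
    """Anchored alignment built by stacking sequences and registering anchors.

    Sequences are padded with trailing gaps to a common width, then the
    helix anchors are brought into the same columns.  Loop regions are not
    optimally aligned by this construction, which is irrelevant for
    helix-restricted identity.
    """
    width = max(len(r) for r in records)
    rows = [(r.id, r.residues + GAP * (width - len(r))) for r in records]
    return anchor_alignment(Alignment(rows=rows), annotations)


def run_compare(config: RunConfig) -> ComparisonReport:
    """Run the full comparison and write the report under ``config.out_dir``.

    Stages: sequence loading -> helix annotation and BW numbering ->
    anchored alignment -> identity matrix -> structure superposition/RMSD ->
    cavity profiles.  Any stage failure aborts with a stage-named error.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    offsets = config.boundary_offsets or None

    # --- sequences -------------------------------------------------------
    try:
        records: list[SequenceRecord] = []
        for path in config.sequence_files:
            records.extend(read_fasta(path))
        aln_in = (read_alignment(config.alignment_file, config.alignment_format)
                  if config.alignment_file else None)
        if aln_in is not None and not records:
            records = [SequenceRecord(id=name, residues=g.replace(GAP, ""))
                       for name, g in aln_in.rows]
    except Exception as exc:
        raise RuntimeError(f"[stage: sequence input] {exc}") from exc

    bw_tables = {}
    identity: dict[str, dict[str, float]] = {}
    identity_rounded: dict[str, dict[str, int]] = {}
    if records:
        try:
            patterns = motif_defaults.default_patterns()
            annotations = [annotate_helices(r, patterns, offsets)
                           for r in records]
            for rec, anns in zip(records, annotations):
                bw_tables[rec.id] = bw_table(rec, assign_bw(anns))
        except Exception as exc:
            raise RuntimeError(f"[stage: helix annotation] {exc}") from exc
        try:
            aln = aln_in if aln_in is not None else stack_and_anchor(
                records, annotations)
            if config.identity_mode == "tm":
                aln = anchor_alignment(aln, annotations)
                ranges = helix_column_ranges(aln, annotations)
            else:
                ranges = None
            for i, a in enumerate(records):
                identity[a.id] = {}
                identity_rounded[a.id] = {}
                for j, b in enumerate(records):
                    pct = (100.0 if i == j else
                           tm_identity(aln, i, j, ranges))
                    identity[a.id][b.id] = pct
                    identity_rounded[a.id][b.id] = round_half_up(pct)
        except Exception as exc:
            raise RuntimeError(f"[stage: identity matrix] {exc}") from exc

    # --- structures ------------------------------------------------------
    rmsd_records: list[dict[str, Any]] = []
    profiles: list[dict[str, Any]] = []
    try:
        structures = [read_structure(p) for p in config.structure_files]
    except Exception as exc:
        raise RuntimeError(f"[stage: structure input] {exc}") from exc
    try:
        for i in range(len(structures)):
            for j in range(i + 1, len(structures)):
                a, b = structures[i], structures[j]
                shared = sorted(
                    {r for _, r in a.residue_atoms()} &
                    {r for _, r in b.residue_atoms()})
                if not shared:
                    continue
                value = selection_rmsd(a, b, residue_indices=shared,
                                       atom_set=config.atom_set,
                                       superpose=config.superpose,
                                       chain_map=config.chain_map)
                rmsd_records.append({
                    "mobile": a.id, "reference": b.id,
                    "atom_set": config.atom_set,
                    "superposed": config.superpose,
                    "n_residues": len(shared),
                    "rmsd": round(value, 4)})
    except Exception as exc:
        raise RuntimeError(f"[stage: superposition] {exc}") from exc
    try:
        profiles = _profiles_for(structures, config)
    except Exception as exc:
        raise RuntimeError(f"[stage: cavity profile] {exc}") from exc

    report = ComparisonReport(
        identity_percent=identity, identity_rounded=identity_rounded,
        bw_tables=bw_tables, rmsd_records=rmsd_records,
        cavity_profiles=profiles,
        provenance={"config_digest": config.digest(),
                    "package_version": __version__})
    _write_report(report, out)
    return report


def run_profile(config: RunConfig) -> list[dict[str, Any]]:
    """Cavity profiles only, sorted by structure id."""
    if not config.structure_files:
        raise RuntimeError("[stage: cavity profile] no structures configured")
    structures = [read_structure(p) for p in config.structure_files]
    return _profiles_for(structures, config)


def _profiles_for(structures: list[Structure], config: RunConfig
                  ) -> list[dict[str, Any]]:
    profiles = []
    scheme = ResidueClassScheme()
    for st in sorted(structures, key=lambda s: s.id):
        if st.id not in config.selections:
            continue
        residues = tuple((c, int(r)) for c, r in config.selections[st.id])
        sel = CavitySelection(structure_id=st.id, residues=residues)
        prof = cavity_profile(st, sel, scheme,
                              probe_radius=config.probe_radius,
                              n_sphere_points=config.n_sphere_points,
                              grid_spacing=config.grid_spacing)
        row = asdict(prof)
        row = {k: (round(v, 3) if isinstance(v, float) else v)
               for k, v in row.items()}
        profiles.append(row)
    return profiles


def _write_report(report: ComparisonReport, out: Path) -> None:
    import pandas as pd

    with open(out / "report.json", "w") as fh:
        json.dump(report.body(), fh, indent=2, sort_keys=True)
    if report.identity_percent:
        pd.DataFrame(report.identity_percent).to_csv(
            out / "identity_matrix.tsv", sep="\t")
    for seq_id, table in report.bw_tables.items():
        table.to_csv(out / f"bw_{seq_id}.tsv", sep="\t", index=False)
    if report.cavity_profiles:
        pd.DataFrame(report.cavity_profiles).to_csv(
            out / "cavity_profiles.tsv", sep="\t", index=False)
    if report.rmsd_records:
        pd.DataFrame(report.rmsd_records).to_csv(
            out / "rmsd.tsv", sep="\t", index=False)
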