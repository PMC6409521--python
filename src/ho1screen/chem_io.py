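"""Compound library I/O and structure normalization.

Reads and writes compound libraries (.smi, SDF, CSV) as lists of
:class:`MoleculeRecord`, canonicalizes SMILES through RDKit, strips salt
counter-ions down to the largest organic fragment and neutralizes formal
charges (screening filters downstream all address the neutral parent
structure at physiological pH).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

log = logging.getLogger("ho1screen.chem_io")

# RDKit is chatty on unparseable SMILES; parse failures are reported through
# our own error/log channel instead.
RDLogger.DisableLog("rdApp.error")

SOURCE_TAGS = ("MNP", "ZNP", "SN2", "SYNTH", "OTHER")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the input."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"could not parse SMILES {smiles!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class LibraryError(ValueError):
    """Fatal library-level problem (empty library, duplicate identifiers)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One library entry.

    ``smiles`` is always the canonical (parent, neutral) form; ``provenance``
    keeps the original identifier as found in the source file.
    """

    id: str
    smiles: str
    source: str = "OTHER"
    provenance: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")


_uncharger = rdMolStandardize.Uncharger()
_fragment_chooser = rdMolStandardize.LargestFragmentChooser()


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`SmilesParseError` on failure."""
    if not smiles or not isinstance(smiles, str):
        raise SmilesParseError(str(smiles), "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def normalize_mol(mol: Chem.Mol) -> Chem.Mol:
    """Largest organic fragment + neutralized formal charges.

    Databases carry salt forms; every filter in the funnel addresses the
    parent structure, so counter-ions are stripped before anything else.
    """
    mol = _fragment_chooser.choose(mol)
    mol = _uncharger.uncharge(mol)
    Chem.SanitizeMol(mol)
    return mol


def canonicalize(smiles: str, normalize: bool = True) -> str:
    """Canonical SMILES (RDKit dialect); idempotent.

    Aromaticity is perceived at parse time, so Kekulé and aromatic spellings
    of the same ring (e.g. imidazole ``C1=CN=CN1`` vs ``c1c[nH]cn1``) map to
    one form. With ``normalize`` (the default) salts are stripped and charges
    neutralized first.
    """
    mol = mol_from_smiles(smiles)
    if normalize:
        mol = normalize_mol(mol)
    return Chem.MolToSmiles(mol)


def record_from_smiles(smiles: str, id: str, source: str = "OTHER",
                       provenance: str = "") -> MoleculeRecord:
    return MoleculeRecord(id=id, smiles=canonicalize(smiles), source=source,
                          provenance=provenance or id)


@dataclass
class ReadReport:
    """Per-file parse accounting; failures are counted, never silently dropped."""

    n_lines: int = 0
    n_parsed: int = 0
    failures: list = field(default_factory=list)  # (locator, reason)


def _check_ids(records: Sequence[MoleculeRecord]) -> None:
    seen: dict[str, int] = {}
    for r in records:
        seen[r.id] = seen.get(r.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise LibraryError(f"duplicate record ids: {', '.join(dups)}")


def read_library(path, format: str | None = None, source: str = "OTHER",
                 id_property: str = "_Name") -> list[MoleculeRecord]:
    """Read a compound library; returns canonical records.

    ``format`` is one of ``smi`` (whitespace-separated SMILES + id per line),
    ``sdf`` (V2000; id from ``id_property`` or the title line) or ``csv``
    (columns ``id,smiles[,source]``); inferred from the suffix when omitted.
    Unparseable entries are counted and logged. Zero parseable records or
    duplicate ids are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".smi": "smi", ".sdf": "sdf", ".csv": "csv"}.get(
            path.suffix.lower(), "smi")
    report = ReadReport()
    records: list[MoleculeRecord] = []

    if format == "smi":
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            report.n_lines += 1
            parts = line.split()
            smi = parts[0]
            rid = parts[1] if len(parts) > 1 else f"{path.stem}_{i}"
            try:
                records.append(record_from_smiles(smi, rid, source))
                report.n_parsed += 1
            except SmilesParseError as e:
                report.failures.append((f"line {i}", str(e)))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier, start=1):
            report.n_lines += 1
            if mol is None:
                report.failures.append((f"record {i}", "unparseable SDF record"))
                continue
            if id_property != "_Name" and mol.HasProp(id_property):
                rid = mol.GetProp(id_property)
            elif mol.HasProp("_Name") and mol.GetProp("_Name").strip():
                rid = mol.GetProp("_Name").strip()
            else:
                rid = f"{path.stem}_{i}"
            mol = normalize_mol(mol)
            records.append(MoleculeRecord(id=rid, smiles=Chem.MolToSmiles(mol),
                                          source=source, provenance=rid))
            report.n_parsed += 1
    elif format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames \
                    or "id" not in reader.fieldnames:
                raise LibraryError(f"{path}: CSV needs 'id' and 'smiles' columns")
            for i, row in enumerate(reader, start=2):
                report.n_lines += 1
                try:
                    records.append(record_from_smiles(
                        row["smiles"], row["id"], row.get("source") or source))
                    report.n_parsed += 1
                except SmilesParseError as e:
                    report.failures.append((f"row {i}", str(e)))
    else:
        raise ValueError(f"unknown library format {format!r}")

    for locator, reason in report.failures:
        log.warning("%s %s: %s", path.name, locator, reason)
    if not records:
        raise LibraryError(f"{path}: zero parseable records")
    _check_ids(records)
    log.info("read %d records from %s (%d parse failures)",
             len(records), path, len(report.failures))
    return records


def write_library(records: Iterable[MoleculeRecord], path, format: str | None = None) -> None:
    """Write records to .smi, SDF or CSV (header row ``id,smiles,source``)."""
    path = Path(path)
    if format is None:
        format = {".smi": "smi", ".sdf": "sdf", ".csv": "csv"}.get(
            path.suffix.lower(), "smi")
    records = list(records)
    if format == "smi":
        path.write_text("".join(f"{r.smiles} {r.id}\n" for r in records))
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        for r in records:
            mol = mol_from_smiles(r.smiles)
            mol.SetProp("_Name", r.id)
            mol.SetProp("source", r.source)
            writer.write(mol)
        writer.close()
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "smiles", "source"])
            for r in records:
                w.writerow([r.id, r.smiles, r.source])
    else:
        raise ValueError(f"unknown library format {format!r}")
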