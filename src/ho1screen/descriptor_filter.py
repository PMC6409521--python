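"""Descriptor-window filter: ten 2D properties and admission intervals.

The second funnel stage keeps molecules whose 2D descriptors fall inside
windows spanned by potent and selective reference inhibitors (HO-1 IC50
<= 10 uM and HO-2/HO-1 selectivity >= 10). The ten descriptors are
molecular weight, cLogP, cLogS, H-acceptor count, H-donor count,
druglikeness, drug score, total surface area, relative PSA and topological
PSA. Four of them (cLogS, druglikeness, drug score, total surface area)
come from proprietary software in the original workflow; this module ships
clearly-labelled surrogate calculators for them, disabled by default, and
accepts precomputed values instead. Window bounds are inclusive: the
printed endpoints are observed reference min/max, which must themselves
pass.

A relaxed mode admits molecules satisfying the Lipinski rule of five
(zero violations) together with at least ``min_passes`` (default 7) of
the ten windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors

from .chem_io import MoleculeRecord, mol_from_smiles

log = logging.getLogger("ho1screen.descriptor_filter")

DESCRIPTOR_NAMES = (
    "mw", "clogp", "clogs", "h_acceptors", "h_donors",
    "druglikeness", "drugscore", "tsa", "rel_psa", "psa",
)

# Enabled by default: the six descriptors computable from published
# atomic-contribution schemes. The four surrogate-backed ones are opt-in.
DEFAULT_ENABLED = ("mw", "clogp", "h_acceptors", "h_donors", "rel_psa", "psa")


@dataclass(frozen=True)
class DescriptorVector:
    """The ten 2D properties of one molecule; ``None`` = unavailable."""

    mw: Optional[float] = None            # g/mol
    clogp: Optional[float] = None
    clogs: Optional[float] = None         # log10 mol/L
    h_acceptors: Optional[int] = None     # N+O count
    h_donors: Optional[int] = None        # NH+OH count
    druglikeness: Optional[float] = None
    drugscore: Optional[float] = None     # [0, 1]
    tsa: Optional[float] = None           # A^2
    rel_psa: Optional[float] = None       # psa / tsa, in [0, 1]
    psa: Optional[float] = None           # topological PSA, A^2

    def value(self, name: str) -> Optional[float]:
        return getattr(self, name)

    def available(self, name: str) -> bool:
        return getattr(self, name) is not None

    def with_overrides(self, overrides: Mapping[str, float]) -> "DescriptorVector":
        unknown = set(overrides) - set(DESCRIPTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown descriptors: {sorted(unknown)}")
        return replace(self, **dict(overrides))


@dataclass
class Window:
    lower: float
    upper: float
    enabled: bool = True

    def __post_init__(self):
        if self.enabled and self.lower > self.upper:
            raise ValueError(f"window lower {self.lower} > upper {self.upper}")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class DescriptorWindows:
    """Admission interval per descriptor; bounds inclusive."""

    windows: dict = field(default_factory=dict)  # name -> Window

    def __post_init__(self):
        unknown = set(self.windows) - set(DESCRIPTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown descriptors: {sorted(unknown)}")
        if not any(w.enabled for w in self.windows.values()):
            raise ValueError("at least one descriptor window must be enabled")

    @property
    def enabled_names(self) -> list:
        return [n for n in DESCRIPTOR_NAMES
                if n in self.windows and self.windows[n].enabled]

    def to_yaml(self, path) -> None:
        data = {n: {"min": w.lower, "max": w.upper, "enabled": w.enabled}
                for n, w in self.windows.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "DescriptorWindows":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(windows={
            n: Window(float(d["min"]), float(d["max"]), bool(d.get("enabled", True)))
            for n, d in data.items()})


def reference_inhibitor_windows(enabled: Sequence[str] = DEFAULT_ENABLED) -> DescriptorWindows:
    """The published admission windows spanned by the 62 potent & selective
    reference HO-1 inhibitors. Descriptors not in ``enabled`` are kept but
    flagged disabled."""
    bounds = {
        "mw": (200.0, 535.0),
        "clogp": (-0.35, 5.4),
        "clogs": (-5.90, -0.85),
        "h_acceptors": (2.0, 8.0),
        "h_donors": (0.0, 1.0),
        "druglikeness": (-13.20, 8.2),
        "drugscore": (0.12, 0.96),
        "tsa": (164.0, 390.0),
        "rel_psa": (0.085, 0.35),
        "psa": (18.0, 90.0),
    }
    return DescriptorWindows(windows={
        n: Window(lo, hi, enabled=(n in enabled)) for n, (lo, hi) in bounds.items()})


@dataclass(frozen=True)
class ReferenceCompound:
    """A known inhibitor with HO-1/HO-2 potencies (uM)."""

    id: str
    smiles: str
    ho1_ic50: float
    ho2_ic50: Optional[float] = None
    selectivity: Optional[float] = None  # ho2_ic50 / ho1_ic50

    def __post_init__(self):
        if self.ho1_ic50 <= 0:
            raise ValueError(f"{self.id}: ho1_ic50 must be > 0")
        if self.ho2_ic50 is not None and self.ho2_ic50 <= 0:
            raise ValueError(f"{self.id}: ho2_ic50 must be > 0")
        if self.selectivity is None and self.ho2_ic50 is not None:
            object.__setattr__(self, "selectivity", self.ho2_ic50 / self.ho1_ic50)
        if self.selectivity is not None and self.selectivity <= 0:
            raise ValueError(f"{self.id}: selectivity must be > 0")


# --------------------------------------------------------------------------
# Calculators
# --------------------------------------------------------------------------

def _esol_clogs(mol: Chem.Mol) -> float:
    # ESOL-type estimated aqueous solubility (log10 mol/L): a linear model in
    # cLogP, MW, rotatable bonds and aromatic proportion. Approximate
    # surrogate for the proprietary cLogS; disabled by default.
    logp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    arom = sum(a.GetIsAromatic() for a in mol.GetAtoms()) / heavy if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * arom


def _druglikeness_surrogate(mol: Chem.Mol) -> float:
    # QED rescaled to a druglikeness-style axis (negative = unlike). The
    # original fragment-based score is proprietary; approximate surrogate,
    # disabled by default.
    return 20.0 * QED.qed(mol) - 10.0


def _drugscore_surrogate(mol: Chem.Mol) -> float:
    # Composite in [0, 1]: sigmoid desirabilities of cLogP, cLogS, MW and
    # the druglikeness surrogate, geometric-mean combined. Approximate
    # surrogate for the proprietary composite; disabled by default.
    def s(v, a, b):
        return 1.0 / (1.0 + math.exp(a * (v - b)))
    logp = Crippen.MolLogP(mol)
    logs = _esol_clogs(mol)
    mw = Descriptors.MolWt(mol)
    dl = _druglikeness_surrogate(mol)
    parts = [s(logp, 1.0, 5.0), s(-logs, 1.0, 5.0), s(mw, 0.012, 500.0),
             s(-dl, 1.0, 5.0)]
    return math.prod(0.5 + 0.5 * p for p in parts)


def _labute_tsa(mol: Chem.Mol) -> float:
    # Approximate total surface area from Labute's atomic contributions;
    # surrogate for the proprietary TSA, disabled by default.
    return rdMolDescriptors.CalcLabuteASA(mol)


def _rel_psa(mol: Chem.Mol) -> float:
    tsa = _labute_tsa(mol)
    return rdMolDescriptors.CalcTPSA(mol) / tsa if tsa > 0 else 0.0


DEFAULT_CALCULATORS: dict[str, Callable[[Chem.Mol], float]] = {
    "mw": Descriptors.MolWt,
    "clogp": Crippen.MolLogP,
    "clogs": _esol_clogs,
    "h_acceptors": Lipinski.NOCount,      # Lipinski N+O convention
    "h_donors": Lipinski.NHOHCount,       # Lipinski NH+OH convention
    "druglikeness": _druglikeness_surrogate,
    "drugscore": _drugscore_surrogate,
    "tsa": _labute_tsa,
    "rel_psa": _rel_psa,
    "psa": rdMolDescriptors.CalcTPSA,
}


def compute_descriptors(record: MoleculeRecord | str,
                        calculators: Mapping[str, Callable] | None = None) -> DescriptorVector:
    """Compute the descriptor vector for one molecule.

    Descriptors without a registered calculator are marked unavailable; a
    calculator exception marks that field unavailable with a logged warning.
    All fields unavailable is an error.
    """
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = mol_from_smiles(smiles)
    calculators = DEFAULT_CALCULATORS if calculators is None else calculators
    values: dict[str, float] = {}
    for name in DESCRIPTOR_NAMES:
        calc = calculators.get(name)
        if calc is None:
            continue
        try:
            values[name] = float(calc(mol))
        except Exception as e:  # noqa: BLE001 - calculator faults are per-field
            log.warning("calculator %s failed on %s: %s", name, smiles, e)
    if not values:
        raise ValueError(f"no descriptor could be computed for {smiles!r}")
    return DescriptorVector(**values)


# --------------------------------------------------------------------------
# Window derivation & reporting
# --------------------------------------------------------------------------

def qualifying_references(refs: Sequence[ReferenceCompound],
                          ic50_max: float = 10.0,
                          selectivity_min: float = 10.0) -> list:
    """References passing the potency & selectivity thresholds."""
    return [r for r in refs
            if r.ho1_ic50 <= ic50_max
            and r.selectivity is not None and r.selectivity >= selectivity_min]


def derive_windows(refs: Sequence[ReferenceCompound],
                   ic50_max: float = 10.0,
                   selectivity_min: float = 10.0,
                   calculators: Mapping[str, Callable] | None = None,
                   enabled: Sequence[str] = DEFAULT_ENABLED) -> DescriptorWindows:
    """Admission windows = per-descriptor [min, max] over the qualifying
    reference subset (HO-1 IC50 <= ``ic50_max`` AND selectivity >=
    ``selectivity_min``)."""
    if not refs:
        raise ValueError("reference set is empty")
    if ic50_max <= 0 or selectivity_min <= 0:
        raise ValueError("thresholds must be > 0")
    qual = qualifying_references(refs, ic50_max, selectivity_min)
    if not qual:
        raise ValueError(
            f"no reference qualifies under ic50_max={ic50_max} uM and "
            f"selectivity_min={selectivity_min}")
    log.info("deriving windows from %d / %d qualifying references",
             len(qual), len(refs))
    vecs = [compute_descriptors(r.smiles, calculators) for r in qual]
    windows: dict[str, Window] = {}
    for name in DESCRIPTOR_NAMES:
        vals = [v.value(name) for v in vecs if v.available(name)]
        if not vals:
            continue
        windows[name] = Window(min(vals), max(vals), enabled=(name in enabled))
    return DescriptorWindows(windows=windows)


@dataclass
class WindowReport:
    """Per-descriptor verdicts for one molecule against the windows."""

    per_descriptor: dict           # name -> bool (enabled & available only)
    unavailable: list              # enabled windows lacking a value
    passes: int
    overall: bool


def window_report(vec: DescriptorVector, windows: DescriptorWindows) -> WindowReport:
    """Inclusive-bound test of every enabled & available descriptor."""
    verdicts: dict[str, bool] = {}
    unavailable = []
    for name in windows.enabled_names:
        if not vec.available(name):
            unavailable.append(name)
            continue
        verdicts[name] = windows.windows[name].contains(vec.value(name))
    if not verdicts:
        raise ValueError("no descriptor both enabled and available")
    passes = sum(verdicts.values())
    return WindowReport(per_descriptor=verdicts, unavailable=unavailable,
                        passes=passes, overall=passes == len(verdicts))


def lipinski_pass(vec: DescriptorVector) -> bool:
    """Lipinski rule of five, zero-violation convention:
    MW <= 500, cLogP <= 5, H-donors <= 5, H-acceptors <= 10."""
    for name in ("mw", "clogp", "h_donors", "h_acceptors"):
        if not vec.available(name):
            raise ValueError(f"Lipinski test needs descriptor {name!r}")
    return (vec.mw <= 500 and vec.clogp <= 5
            and vec.h_donors <= 5 and vec.h_acceptors <= 10)


def relaxed_filter(vec: DescriptorVector, windows: DescriptorWindows,
                   min_passes: int = 7) -> bool:
    """Relaxed admission: Lipinski (zero violations) AND at least
    ``min_passes`` descriptor windows passed."""
    return lipinski_pass(vec) and window_report(vec, windows).passes >= min_passes


def read_reference_csv(path) -> list:
    """refs.csv columns: id,smiles,ho1_ic50_um[,ho2_ic50_um][,selectivity]."""
    import csv as _csv
    refs = []
    with open(path, newline="") as fh:
        for row in _csv.DictReader(fh):
            refs.append(ReferenceCompound(
                id=row["id"], smiles=row["smiles"],
                ho1_ic50=float(row["ho1_ic50_um"]),
                ho2_ic50=float(row["ho2_ic50_um"]) if row.get("ho2_ic50_um") else None,
                selectivity=float(row["selectivity"]) if row.get("selectivity") else None))
    return refs


def write_reference_csv(refs: Sequence[ReferenceCompound], path) -> None:
    import csv as _csv
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["id", "smiles", "ho1_ic50_um", "ho2_ic50_um", "selectivity"])
        for r in refs:
            w.writerow([r.id, r.smiles, r.ho1_ic50,
                        "" if r.ho2_ic50 is None else r.ho2_ic50,
                        "" if r.selectivity is None else r.selectivity])
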