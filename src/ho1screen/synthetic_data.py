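"""Synthetic libraries, reference sets and activities with known ground truth.

Every funnel stage is testable without downloading the natural-product
databases: this module builds libraries with a known mix of qualifying
imidazoles (N1-decorated or C4-decorated plain imidazoles), disqualified
imidazoles (benzimidazoles, 2-substituted imidazoles) and decoys that are
deliberate near-misses (pyrazoles, oxazoles, thiazoles, pyridines) rather
than trivially different scaffolds; reference-inhibitor tables whose
qualifying subset is fixed by construction; and activities that are an
exact linear function of hidden SMILES-attribute weights plus Gaussian
noise — the same attribute dialect the QSAR stage fits, so parameter
recovery is well-posed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem_io import MoleculeRecord, record_from_smiles
from .coral_qsar import extract_attributes
from .descriptor_filter import ReferenceCompound

# Substituent fragments written as SMILES prefixes: the last-written atom is
# the attachment point. Fragments only use ring-closure digit 1; scaffold
# cores use 8/9, so composition never collides.
DEFAULT_DECORATIONS = (
    "C", "CC", "CCC", "CC(C)C", "OCC", "NCC",
    "c1ccccc1C", "c1ccccc1CC", "Clc1ccccc1C", "COc1ccccc1C", "FC(F)(F)C",
)

# Scaffold cores, appended after a decoration prefix.
QUALIFYING_CORES = (
    "n8ccnc8",      # N1-substituted imidazole
    "c8c[nH]cn8",   # C4-substituted imidazole, free NH
)
DISQUALIFIED_CORES = (
    "n8cnc9ccccc98",  # N1-substituted benzimidazole (fused)
    "c8ncc[nH]8",     # 2-substituted imidazole
)
DECOY_CORES = (
    "n8cccn8",      # N1-substituted pyrazole (1,2-diaza)
    "c8ocnc8",      # oxazole
    "c8scnc8",      # thiazole
    "c8ccncc8",     # pyridine
    "n8cccc8",      # N1-substituted pyrrole
    "c8ccccc8",     # benzene
)

CLASS_LABELS = ("qualifying", "disqualified", "decoy")


@dataclass
class LibrarySpec:
    """Composition of a synthetic screening library."""

    n_total: int = 100
    frac_qualifying: float = 0.5
    frac_disqualified: float = 0.3
    frac_decoy: float = 0.2
    decorations: Sequence[str] = DEFAULT_DECORATIONS
    max_decorations: int = 2   # chain 1..k fragments for structural diversity
    seed: int = 0

    def __post_init__(self):
        if self.max_decorations < 1:
            raise ValueError("max_decorations must be >= 1")
        fracs = (self.frac_qualifying, self.frac_disqualified, self.frac_decoy)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fracs)}")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")


def _chainable(frag: str) -> bool:
    # A fragment can follow another only if its first-written atom accepts an
    # extra bond; halogen-initial fragments are chain starts only.
    return not (frag.startswith("Cl") or frag.startswith("Br")
                or frag[0] in "FI")


def _largest_remainder_counts(n: int, fracs: Sequence[float]) -> list[int]:
    """Integer class counts summing to n: floor allocation, remaining units
    to the largest fractional remainders (ties by class order)."""
    raw = [f * n for f in fracs]
    counts = [math.floor(r) for r in raw]
    order = sorted(range(len(fracs)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in range(n - sum(counts)):
        counts[order[i % len(fracs)]] += 1
    return counts


def generate_library(spec: LibrarySpec):
    """Build a labelled synthetic library.

    Returns ``(records, labels)`` where ``labels`` maps record id to one of
    ``qualifying`` / ``disqualified`` / ``decoy``. Class counts follow the
    largest-remainder rule; deterministic given ``spec.seed``; every SMILES
    parses and canonicalizes.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _largest_remainder_counts(
        spec.n_total,
        (spec.frac_qualifying, spec.frac_disqualified, spec.frac_decoy))
    cores_by_class = (QUALIFYING_CORES, DISQUALIFIED_CORES, DECOY_CORES)
    records: list[MoleculeRecord] = []
    labels: dict[str, str] = {}
    k = 0
    for label, n_class, cores in zip(CLASS_LABELS, counts, cores_by_class):
        for _ in range(n_class):
            k += 1
            depth = int(rng.integers(1, spec.max_decorations + 1))
            chain_safe = [f for f in spec.decorations if _chainable(f)] \
                or list(spec.decorations)
            frags = [spec.decorations[int(rng.integers(len(spec.decorations)))]]
            frags += [chain_safe[int(rng.integers(len(chain_safe)))]
                      for _ in range(depth - 1)]
            core = cores[int(rng.integers(len(cores)))]
            rid = f"SYN{k:05d}"
            records.append(record_from_smiles("".join(frags) + core, rid,
                                              source="SYNTH"))
            labels[rid] = label
    return records, labels


@dataclass
class ActivityModelSpec:
    """Hidden linear-in-attributes activity model.

    ``weights`` maps namespaced attribute keys (``A:``/``P:``/``G:``, the
    QSAR dialect) to pIC50 contributions per occurrence.
    """

    weights: dict = field(default_factory=dict)
    intercept: float = 4.0    # pIC50 units: a typical mid-micromolar baseline
    noise_sd: float = 0.1     # pIC50 units: assay-replicate-scale noise
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not all(np.isfinite(list(self.weights.values()) or [0.0])):
            raise ValueError("weights must be finite")


def default_activity_spec(noise_sd: float = 0.1, seed: int = 0) -> ActivityModelSpec:
    """A hidden model touching common atom, pair and global attributes."""
    return ActivityModelSpec(
        weights={
            "A:C": 0.06, "A:c": 0.04, "A:n": 0.20, "A:O": 0.12,
            "A:Cl": 0.25, "A:F": 0.10,
            "P:C|C": 0.03, "P:c|c": 0.02, "P:c|n": 0.05,
            "G:HALO": 0.30, "G:RINGS=2": 0.15,
        },
        intercept=4.0, noise_sd=noise_sd, seed=seed)


def true_activity(smiles: str, spec: ActivityModelSpec) -> float:
    """Noise-free systematic component of the hidden model."""
    merged = extract_attributes(smiles).merged()
    return spec.intercept + sum(
        cnt * spec.weights.get(attr, 0.0) for attr, cnt in merged.items())


def simulate_activities(records: Sequence[MoleculeRecord],
                        spec: ActivityModelSpec) -> list[tuple[str, float]]:
    """(id, pIC50) with pIC50 = intercept + sum(attr count x hidden weight)
    + Normal(0, noise_sd); noise seeded by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=len(records)) \
        if spec.noise_sd > 0 else np.zeros(len(records))
    return [(r.id, true_activity(r.smiles, spec) + float(e))
            for r, e in zip(records, noise)]


def generate_reference_set(n: int,
                           n_qualifying: Optional[int] = None,
                           n_high_quality: Optional[int] = None,
                           seed: int = 0,
                           decorations: Sequence[str] = DEFAULT_DECORATIONS):
    """Reference-inhibitor table with a construction-fixed qualifying subset.

    ``n_qualifying`` members satisfy HO-1 IC50 <= 10 uM and selectivity
    >= 10 (defaults to 60% of ``n``); ``n_high_quality`` of those also
    satisfy the stricter IC50 <= 5 uM and selectivity >= 30 tier used for
    docking validation (defaults to half the qualifying members). The rest
    fail potency, selectivity or both.

    Returns ``(refs, qualifying_ids, high_quality_ids)``.
    """
    if n < 2:
        raise ValueError("need n >= 2 reference compounds")
    if n_qualifying is None:
        n_qualifying = max(1, round(0.6 * n))
    if n_high_quality is None:
        n_high_quality = n_qualifying // 2
    if not (0 <= n_high_quality <= n_qualifying <= n):
        raise ValueError("need 0 <= n_high_quality <= n_qualifying <= n")
    rng = np.random.default_rng(seed)
    refs: list[ReferenceCompound] = []
    qualifying_ids: list[str] = []
    high_quality_ids: list[str] = []
    for i in range(n):
        frag = decorations[int(rng.integers(len(decorations)))]
        smiles = frag + "n8ccnc8"
        rid = f"REF{i + 1:03d}"
        if i < n_high_quality:
            ho1 = float(rng.uniform(0.05, 5.0))
            sel = float(rng.uniform(30.0, 300.0))
            qualifying_ids.append(rid)
            high_quality_ids.append(rid)
        elif i < n_qualifying:
            # qualifying but outside the strict tier: either 5 < IC50 <= 10,
            # or 10 <= selectivity < 30
            if rng.integers(2):
                ho1 = float(rng.uniform(5.0 + 1e-6, 10.0))
                sel = float(rng.uniform(10.0, 300.0))
            else:
                ho1 = float(rng.uniform(0.05, 10.0))
                sel = float(rng.uniform(10.0, 30.0 - 1e-6))
            qualifying_ids.append(rid)
        else:
            # non-qualifying: fail potency, selectivity, or both
            mode = int(rng.integers(3))
            ho1 = float(rng.uniform(10.5, 200.0)) if mode in (0, 2) \
                else float(rng.uniform(0.05, 10.0))
            sel = float(rng.uniform(0.1, 9.5)) if mode in (1, 2) \
                else float(rng.uniform(10.0, 300.0))
        refs.append(ReferenceCompound(
            id=rid, smiles=smiles, ho1_ic50=ho1, ho2_ic50=ho1 * sel))
    return refs, qualifying_ids, high_quality_ids
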