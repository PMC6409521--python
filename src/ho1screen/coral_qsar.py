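"""Monte-Carlo correlation-weight SMILES QSAR (CORAL-style).

The 2D ligand-based funnel stage. Each molecule's canonical SMILES is
decomposed into *attributes* — single atom tokens (Sk), adjacent token
pairs (SSk) and a small set of whole-molecule features — and every
attribute carries an optimizable *correlation weight*. The single model
descriptor is

    DCW(molecule) = sum over attribute occurrences of weight(attribute)

and the endpoint is the linear regression  pIC50 = C0 + C1 * DCW.
Weights are fitted by a seeded Monte-Carlo hill-climb that maximizes the
training Pearson r^2 between DCW and pIC50; (C0, C1) are then set by
ordinary least squares. Attributes rarer in the training set than a
census threshold are *blocked* (weight fixed at 0); molecules containing
attributes never seen in training fall outside the applicability domain
and receive no trusted prediction.

Attribute dialect (version 1)
-----------------------------
The SMILES string is split into raw tokens: bracket atoms ``[...]`` are
one token, two-character elements (Cl, Br) are one token, ``%nn`` ring
closures are one token, every other character is its own token. Sk are
the atom tokens; SSk are consecutive raw-token pairs with the two members
sorted lexicographically (bond, branch and ring-closure symbols thus fold
into the pairs). Global attributes: a ring-count bucket and halogen
presence. Extraction must see one fixed canonical dialect, so inputs are
canonicalized first.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .chem_io import canonicalize, mol_from_smiles

log = logging.getLogger("ho1screen.coral_qsar")

DIALECT_VERSION = 1

_TWO_CHAR = ("Cl", "Br")
_HALOGEN_TOKENS = {"F", "Cl", "Br", "I", "[F-]", "[Cl-]", "[Br-]", "[I-]"}
# Atom tokens: bracket atoms, organic-subset elements, aromatic atoms.
_ATOM_RE = re.compile(r"^(\[[^\]]+\]|Cl|Br|B|C|N|O|P|S|F|I|b|c|n|o|p|s)$")


class TokenizationError(ValueError):
    def __init__(self, smiles: str, pos: int):
        self.smiles, self.pos = smiles, pos
        super().__init__(f"cannot tokenize {smiles!r} at position {pos}")


def tokenize(smiles: str) -> list[str]:
    """Raw token stream of a SMILES string (see module docstring)."""
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise TokenizationError(smiles, i)
            tokens.append(smiles[i:j + 1])
            i = j + 1
        elif smiles[i:i + 2] in _TWO_CHAR:
            tokens.append(smiles[i:i + 2])
            i += 2
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1:i + 3].isdigit():
                raise TokenizationError(smiles, i)
            tokens.append(smiles[i:i + 3])
            i += 3
        else:
            tokens.append(ch)
            i += 1
    return tokens


def is_atom_token(token: str) -> bool:
    return bool(_ATOM_RE.match(token))


@dataclass
class AttributeProfile:
    """Multisets of SMILES attributes for one molecule."""

    atom_attributes: Counter = field(default_factory=Counter)   # Sk
    pair_attributes: Counter = field(default_factory=Counter)   # SSk
    global_attributes: Counter = field(default_factory=Counter)

    def merged(self) -> Counter:
        """One namespaced counter over all attributes (keys as stored in
        weight maps: ``A:<token>``, ``P:<t1>|<t2>``, ``G:<feature>``)."""
        out: Counter = Counter()
        for k, v in self.atom_attributes.items():
            out[f"A:{k}"] = v
        for k, v in self.pair_attributes.items():
            out[f"P:{k}"] = v
        for k, v in self.global_attributes.items():
            out[f"G:{k}"] = v
        return out


def extract_attributes(smiles: str, assume_canonical: bool = False) -> AttributeProfile:
    """Decompose a SMILES string into its attribute profile.

    The string is canonicalized first unless ``assume_canonical`` — the
    weights attach to one fixed SMILES dialect, so extraction must never
    see ad-hoc spellings.
    """
    if not assume_canonical:
        smiles = canonicalize(smiles)
    tokens = tokenize(smiles)
    atoms = Counter(t for t in tokens if is_atom_token(t))
    pairs = Counter(
        "|".join(sorted((tokens[i], tokens[i + 1])))
        for i in range(len(tokens) - 1))
    glob: Counter = Counter()
    mol = mol_from_smiles(smiles)
    n_rings = mol.GetRingInfo().NumRings()
    glob[f"RINGS={min(n_rings, 4)}"] = 1  # bucket: 0..3, 4 = "4 or more"
    if any(t in _HALOGEN_TOKENS for t in tokens):
        glob["HALO"] = 1
    return AttributeProfile(atom_attributes=atoms, pair_attributes=pairs,
                            global_attributes=glob)


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

@dataclass
class CoralModel:
    """Correlation weights plus the final linear regression.

    ``threshold_t`` is the minimum number of training molecules an
    attribute must occur in to be active; blocked attributes have weight
    exactly 0. ``threshold_param`` stores the model's threshold parameter
    verbatim as published (its operational mapping to ``threshold_t`` is a
    package choice, see :func:`threshold_from_param`).
    """

    weights: dict = field(default_factory=dict)          # attr -> float
    training_census: dict = field(default_factory=dict)  # attr -> n molecules
    n_train: int = 0
    threshold_t: int = 1
    threshold_param: float = 0.0
    n_epochs: int = 0
    c0: float = 0.0   # intercept, pIC50 units
    c1: float = 1.0   # slope, pIC50 per DCW unit
    rng_seed: int = 0
    r2_train: Optional[float] = None
    dialect_version: int = DIALECT_VERSION

    def is_novel(self, attr: str) -> bool:
        return attr not in self.training_census

    def to_json(self, path) -> None:
        data = {
            "dialect_version": self.dialect_version,
            "n_train": self.n_train,
            "threshold_t": self.threshold_t,
            "threshold_param": self.threshold_param,
            "n_epochs": self.n_epochs,
            "c0": self.c0, "c1": self.c1,
            "rng_seed": self.rng_seed,
            "r2_train": self.r2_train,
            "weights": self.weights,
            "training_census": self.training_census,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CoralModel":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def published_ho1_model() -> CoralModel:
    """The published HO-1 2D-QSAR regression: pIC50 = C0 + C1 * DCW with
    C0 = 0.0000163, C1 = 0.0473151 and threshold parameter 0.41.

    Only the regression layer was published — the correlation weights were
    not — so this model has an empty weight map and census: it evaluates
    user-supplied DCW values (:func:`predict_from_dcw`) but cannot compute
    DCW from structures, and every structure is outside its domain.
    """
    return CoralModel(weights={}, training_census={}, threshold_t=1,
                      threshold_param=0.41, c0=0.0000163, c1=0.0473151)


def threshold_from_param(param: float, n_train: int) -> int:
    """Operational mapping of the published threshold parameter: an
    attribute is active iff present in >= max(1, round(param% of the
    training set)) molecules."""
    return max(1, round(param / 100.0 * n_train))


def compute_dcw(profile: AttributeProfile, model: CoralModel) -> float:
    """DCW = sum over attribute occurrences of weight(attribute).

    Attributes without a weight (blocked or never trained) contribute 0.
    Linear in the weight map.
    """
    w = model.weights
    return float(sum(cnt * w.get(attr, 0.0)
                     for attr, cnt in profile.merged().items()))


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

class TrainingError(RuntimeError):
    pass


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # closed-form simple least squares of y on x
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise TrainingError(
            "degenerate DCW variance after training; increase n_epochs or "
            "lower the census threshold")
    c1 = float(((x - xm) * (y - ym)).sum()) / sxx
    return ym - c1 * xm, c1


def train(training: Sequence[tuple[str, float]],
          threshold_t: int | None = None,
          threshold_param: float = 0.41,
          n_epochs: int = 20000,
          seed: int = 0,
          delta: float = 0.05,
          record_history: bool = False) -> CoralModel:
    """Fit a correlation-weight model on (smiles, pIC50) pairs.

    Active-attribute weights start at 1.0; each epoch proposes a random
    +/-``delta`` perturbation of one random active weight and accepts it
    iff the training Pearson r^2 between DCW and pIC50 does not decrease.
    After ``n_epochs`` proposals, (c0, c1) are set by ordinary least
    squares of pIC50 on DCW. Deterministic given ``seed``.

    ``threshold_t`` defaults to the operational mapping of
    ``threshold_param`` (see :func:`threshold_from_param`).
    """
    if len(training) < 10:
        raise TrainingError(f"need >= 10 training molecules, got {len(training)}")
    y = np.array([float(p) for _, p in training])
    if not np.all(np.isfinite(y)):
        raise TrainingError("non-finite training endpoint")
    if np.all(y == y[0]):
        raise TrainingError("all training endpoints identical; r^2 undefined")

    profiles = [extract_attributes(s).merged() for s, _ in training]
    census: Counter = Counter()
    for prof in profiles:
        census.update(prof.keys())
    if threshold_t is None:
        threshold_t = threshold_from_param(threshold_param, len(training))
    active = sorted(a for a, n in census.items() if n >= threshold_t)
    if not active:
        raise TrainingError(
            f"no attribute occurs in >= {threshold_t} training molecules")
    a_index = {a: j for j, a in enumerate(active)}
    # occurrence matrix over active attributes only (blocked contribute 0)
    M = np.zeros((len(training), len(active)))
    for i, prof in enumerate(profiles):
        for attr, cnt in prof.items():
            j = a_index.get(attr)
            if j is not None:
                M[i, j] = cnt

    rng = np.random.default_rng(seed)
    w = np.ones(len(active))
    dcw = M @ w
    r2 = _pearson_r2(dcw, y)
    history = [r2]
    for _ in range(n_epochs):
        j = int(rng.integers(len(active)))
        step = delta if rng.integers(2) else -delta
        cand = dcw + step * M[:, j]
        r2_new = _pearson_r2(cand, y)
        if r2_new >= r2:
            w[j] += step
            dcw = cand
            r2 = r2_new
            if record_history:
                history.append(r2)
    c0, c1 = _ols(dcw, y)
    log.info("trained on %d molecules, %d active / %d total attributes, "
             "r^2 = %.4f", len(training), len(active), len(census), r2)
    model = CoralModel(
        weights={a: float(w[a_index[a]]) for a in active},
        training_census={a: int(n) for a, n in sorted(census.items())},
        n_train=len(training),
        threshold_t=threshold_t, threshold_param=threshold_param,
        n_epochs=n_epochs, c0=c0, c1=c1, rng_seed=seed,
        r2_train=r2)
    if record_history:
        model.r2_history = history  # type: ignore[attr-defined]
    return model


# --------------------------------------------------------------------------
# Prediction & applicability domain
# --------------------------------------------------------------------------

@dataclass
class QsarPrediction:
    pic50_pred: float
    dcw: float
    in_domain: bool
    novel_attributes: list


def predict_from_dcw(model: CoralModel, dcw: float) -> float:
    """Evaluate the regression layer on a given DCW value."""
    return model.c0 + model.c1 * dcw


def predict(model: CoralModel, smiles: str) -> QsarPrediction:
    """Predict pIC50 = c0 + c1 * DCW for one structure.

    ``in_domain`` is False iff the molecule carries any attribute absent
    from the training census (the default applicability-domain rule).
    """
    profile = extract_attributes(smiles)
    novel = sorted(a for a in profile.merged() if model.is_novel(a))
    dcw = compute_dcw(profile, model)
    return QsarPrediction(pic50_pred=predict_from_dcw(model, dcw), dcw=dcw,
                          in_domain=not novel, novel_attributes=novel)


def attribute_defect(smiles: str, model: CoralModel) -> float:
    """Frequency-defect domain score: mean training rarity of the
    molecule's attribute occurrences.

    Each occurrence of attribute *a* contributes ``1 - census(a)/n_train``
    (novel attributes contribute 1). The score lies in [0, 1]; 0 means
    every attribute occurred in every training molecule. An alternative
    to the strict novel-attribute rule when a graded cutoff is wanted.
    """
    if model.n_train <= 0:
        raise ValueError("model carries no training census")
    merged = extract_attributes(smiles).merged()
    total = sum(merged.values())
    defect = sum(
        cnt * (1.0 - model.training_census.get(attr, 0) / model.n_train)
        for attr, cnt in merged.items())
    return defect / total if total else 0.0


def apply_qsar_filter(records: Iterable, model: CoralModel,
                      defect_cutoff: float | None = None):
    """Partition records into in-domain (with predictions) and outliers.

    The default domain rule flags any molecule with a never-trained
    attribute; passing ``defect_cutoff`` switches to the graded
    :func:`attribute_defect` score (outlier iff defect > cutoff).

    Returns ``(in_domain, outliers, summary)`` where ``in_domain`` is a
    list of (record, QsarPrediction), ``outliers`` a list of (record,
    QsarPrediction), and ``summary`` carries the min/max predicted pIC50
    of the in-domain set (None when empty).
    """
    in_domain, outliers = [], []
    for rec in records:
        pred = predict(model, rec.smiles)
        if defect_cutoff is not None:
            ok = attribute_defect(rec.smiles, model) <= defect_cutoff
        else:
            ok = pred.in_domain
        (in_domain if ok else outliers).append((rec, pred))
    pic50s = [p.pic50_pred for _, p in in_domain]
    summary = {
        "n_in_domain": len(in_domain),
        "n_outliers": len(outliers),
        "pic50_min": min(pic50s) if pic50s else None,
        "pic50_max": max(pic50s) if pic50s else None,
    }
    return in_domain, outliers, summary
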