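"""Consensus ranking and the full four-stage screening funnel.

The last funnel stage merges the 2D-QSAR channel with externally computed
3D-QSAR (predicted pIC50) and docking (predicted pKi) score tables and
orders candidates by the arithmetic mean of the available channel scores.
The mean deliberately mixes pIC50 and pKi on their native log scales —
that is the published protocol — with an optional z-score mode clearly
marked as a deviation. ``run_pipeline`` chains structural filter →
descriptor windows (strict, or the relaxed Lipinski + >= 7-windows mesh)
→ 2D-QSAR applicability domain → channel merge → consensus, and emits a
per-stage funnel report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chem_io, coral_qsar, descriptor_filter, imidazole_filter

log = logging.getLogger("ho1screen.consensus_pipeline")

CHANNELS = ("pic50_2d", "pic50_3d", "pki_dock")
SANE_SCORE_RANGE = (0.0, 14.0)


@dataclass
class ChannelScores:
    """Per-compound scores from the three prediction channels."""

    id: str
    pic50_2d: Optional[float] = None
    pic50_3d: Optional[float] = None
    pki_dock: Optional[float] = None

    def present(self) -> list[str]:
        return [c for c in CHANNELS if getattr(self, c) is not None]

    def __post_init__(self):
        vals = [getattr(self, c) for c in self.present()]
        if not vals:
            raise ValueError(f"{self.id}: at least one channel score required")
        if not all(np.isfinite(vals)):
            raise ValueError(f"{self.id}: non-finite channel score")
        lo, hi = SANE_SCORE_RANGE
        for c in self.present():
            v = getattr(self, c)
            if not lo <= v <= hi:
                log.warning("%s: %s = %.3g outside the expected %g-%g range",
                            self.id, c, v, lo, hi)


@dataclass
class ConsensusRow:
    id: str
    scores: ChannelScores
    n_channels: int
    mean_score: float
    rank: int = 0


def load_channel_scores(path, channel: str,
                        known_ids: Optional[Sequence[str]] = None) -> dict[str, float]:
    """Read one external score table (CSV columns ``id,score``).

    ``channel`` is ``qsar3d`` or ``docking``. Duplicate ids and non-numeric
    scores are errors; ids not in ``known_ids`` (the surviving set) produce
    warnings but are kept out of the returned map.
    """
    if channel not in ("qsar3d", "docking"):
        raise ValueError(f"unknown channel {channel!r}")
    df = pd.read_csv(path, dtype={"id": str})
    if not {"id", "score"} <= set(df.columns):
        raise ValueError(f"{path}: needs columns id,score")
    dups = sorted(df.loc[df["id"].duplicated(), "id"].unique())
    if dups:
        raise ValueError(f"{path}: duplicate ids {', '.join(dups)}")
    scores: dict[str, float] = {}
    unknown = []
    for row_no, (rid, raw) in enumerate(zip(df["id"], df["score"]), start=2):
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"{path} row {row_no}: non-numeric score {raw!r}")
        if not np.isfinite(val):
            raise ValueError(f"{path} row {row_no}: non-finite score")
        if known_ids is not None and rid not in set(known_ids):
            unknown.append(rid)
            continue
        scores[rid] = val
    if unknown:
        log.warning("%s: %d ids not in the surviving set: %s",
                    path, len(unknown), ", ".join(unknown[:10]))
    return scores


def consensus_rank(rows: Sequence[ChannelScores],
                   require_all: bool = True,
                   normalize: bool = False) -> list[ConsensusRow]:
    """Order compounds by the mean of their channel scores, descending.

    With ``require_all`` (the published protocol) only compounds carrying
    all three channels are ranked; otherwise the mean runs over the
    channels present. Ties break by id lexicographic order (logged).
    ``normalize`` z-scores each channel first — a documented deviation
    from the published direct mean, off by default.
    """
    if not rows:
        raise ValueError("no rows to rank")
    usable = [r for r in rows
              if (len(r.present()) == len(CHANNELS)) or not require_all]
    if not usable:
        raise ValueError("require_all: no compound carries all three channels")

    values: dict[str, dict[str, float]] = {
        r.id: {c: getattr(r, c) for c in r.present()} for r in usable}
    if normalize:
        for c in CHANNELS:
            vals = np.array([v[c] for v in values.values() if c in v])
            mu, sd = vals.mean(), vals.std()
            for v in values.values():
                if c in v:
                    v[c] = (v[c] - mu) / sd if sd > 0 else 0.0

    out = []
    for r in usable:
        chans = values[r.id]
        out.append(ConsensusRow(
            id=r.id, scores=r, n_channels=len(chans),
            mean_score=float(np.mean(list(chans.values())))))
    out.sort(key=lambda c: (-c.mean_score, c.id))
    # dense 1-based ranks: equal means share a rank
    rank = 0
    prev = None
    for row in out:
        if prev is None or row.mean_score < prev:
            rank += 1
        row.rank = rank
        prev = row.mean_score
    if len({r.mean_score for r in out}) != len(out):
        log.info("consensus ties broken by id lexicographic order")
    return out


# --------------------------------------------------------------------------
# Full funnel
# --------------------------------------------------------------------------

@dataclass
class FunnelStage:
    name: str
    n_in: int
    n_out: int


@dataclass
class FunnelReport:
    stages: list = field(default_factory=list)       # FunnelStage
    per_source: dict = field(default_factory=dict)   # stage -> {source: n_out}

    def add(self, name: str, records_in, records_out) -> None:
        self.stages.append(FunnelStage(name, len(records_in), len(records_out)))
        counts: dict[str, int] = {}
        for r in records_out:
            counts[r.source] = counts.get(r.source, 0) + 1
        self.per_source[name] = counts

    def to_dict(self) -> dict:
        return {
            "stages": [{"name": s.name, "in": s.n_in, "out": s.n_out}
                       for s in self.stages],
            "per_source": self.per_source,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


@dataclass
class PipelineConfig:
    """Everything one funnel run needs.

    ``windows`` may be a DescriptorWindows, a windows YAML path, or None
    (then ``refs`` — a CSV path or list of ReferenceCompound — is required
    and windows are derived at the published thresholds). ``model`` is a
    CoralModel or a model-JSON path. ``mode`` is ``strict`` (all enabled
    windows must pass) or ``relaxed`` (Lipinski + >= ``min_passes``
    windows).
    """

    library: object                       # path or list of MoleculeRecord
    model: object                         # CoralModel or path
    windows: object = None                # DescriptorWindows or path or None
    refs: object = None                   # path or list of ReferenceCompound
    ic50_max: float = 10.0
    selectivity_min: float = 10.0
    mode: str = "strict"
    min_passes: int = 7
    qsar3d_scores: object = None          # CSV path or {id: score}
    docking_scores: object = None
    require_all: bool = True
    enabled_descriptors: Sequence[str] = descriptor_filter.DEFAULT_ENABLED
    precomputed: Optional[Mapping[str, Mapping[str, float]]] = None
    out_dir: object = None                # write ranked.csv + funnel.json here

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class PipelineResult:
    funnel: FunnelReport
    ranked: pd.DataFrame
    predictions: dict                     # id -> QsarPrediction (in-domain)
    outliers: list                        # ids flagged by the domain rule


def _resolve_windows(cfg: PipelineConfig) -> descriptor_filter.DescriptorWindows:
    if isinstance(cfg.windows, descriptor_filter.DescriptorWindows):
        return cfg.windows
    if cfg.windows is not None:
        return descriptor_filter.DescriptorWindows.from_yaml(cfg.windows)
    if cfg.refs is None:
        raise ValueError("config needs either windows or refs")
    refs = cfg.refs if isinstance(cfg.refs, list) \
        else descriptor_filter.read_reference_csv(cfg.refs)
    return descriptor_filter.derive_windows(
        refs, cfg.ic50_max, cfg.selectivity_min, enabled=cfg.enabled_descriptors)


def run_pipeline(config: PipelineConfig | str) -> PipelineResult:
    """Execute the full screening funnel; deterministic given inputs."""
    cfg = config if isinstance(config, PipelineConfig) \
        else PipelineConfig.from_yaml(config)
    if cfg.mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {cfg.mode!r}")

    records = cfg.library if isinstance(cfg.library, list) \
        else chem_io.read_library(cfg.library)
    funnel = FunnelReport()
    funnel.add("input", records, records)

    # stage 1: structural filter
    structural, _ = imidazole_filter.filter_library(records)
    funnel.add("structural", records, structural)
    log.info("structural filter: %d -> %d", len(records), len(structural))

    # stage 2: descriptor windows (strict or relaxed mesh)
    windows = _resolve_windows(cfg)
    descriptor_pass = []
    for rec in structural:
        vec = descriptor_filter.compute_descriptors(rec)
        if cfg.precomputed and rec.id in cfg.precomputed:
            vec = vec.with_overrides(cfg.precomputed[rec.id])
        if cfg.mode == "strict":
            ok = descriptor_filter.window_report(vec, windows).overall
        else:
            ok = descriptor_filter.relaxed_filter(vec, windows, cfg.min_passes)
        if ok:
            descriptor_pass.append(rec)
    funnel.add(f"descriptor_{cfg.mode}", structural, descriptor_pass)
    log.info("descriptor filter (%s): %d -> %d",
             cfg.mode, len(structural), len(descriptor_pass))

    # stage 3: 2D-QSAR applicability domain
    model = cfg.model if isinstance(cfg.model, coral_qsar.CoralModel) \
        else coral_qsar.CoralModel.from_json(cfg.model)
    in_domain, outliers, summary = coral_qsar.apply_qsar_filter(
        descriptor_pass, model)
    survivors = [rec for rec, _ in in_domain]
    funnel.add("qsar_in_domain", descriptor_pass, survivors)
    log.info("2D-QSAR domain: %d -> %d in-domain (pIC50 %s-%s)",
             len(descriptor_pass), len(survivors),
             summary["pic50_min"], summary["pic50_max"])
    preds = {rec.id: pred for rec, pred in in_domain}

    # stage 4: channel merge + consensus
    survivor_ids = [r.id for r in survivors]

    def _scores(source, channel):
        if source is None:
            return {}
        if isinstance(source, Mapping):
            return {k: float(v) for k, v in source.items() if k in set(survivor_ids)}
        return load_channel_scores(source, channel, known_ids=survivor_ids)

    s3d = _scores(cfg.qsar3d_scores, "qsar3d")
    sdock = _scores(cfg.docking_scores, "docking")
    rows = [ChannelScores(id=r.id,
                          pic50_2d=preds[r.id].pic50_pred,
                          pic50_3d=s3d.get(r.id),
                          pki_dock=sdock.get(r.id))
            for r in survivors]
    require_all = cfg.require_all and bool(s3d) and bool(sdock)
    ranked_rows = consensus_rank(rows, require_all=require_all) if rows else []
    ranked_recs = {r.id: r for r in survivors}
    ranked = pd.DataFrame([{
        "id": c.id,
        "smiles": ranked_recs[c.id].smiles,
        "source": ranked_recs[c.id].source,
        "pic50_2d": c.scores.pic50_2d,
        "pic50_3d": c.scores.pic50_3d,
        "pki_dock": c.scores.pki_dock,
        "mean": c.mean_score,
        "rank": c.rank,
    } for c in ranked_rows],
        columns=["id", "smiles", "source", "pic50_2d", "pic50_3d",
                 "pki_dock", "mean", "rank"])
    funnel.add("ranked", survivors, [ranked_recs[c.id] for c in ranked_rows])

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ranked.to_csv(out / "ranked.csv", index=False, float_format="%.6f")
        funnel.write_json(out / "funnel.json")
    return PipelineResult(funnel=funnel, ranked=ranked, predictions=preds,
                          outliers=[rec.id for rec, _ in outliers])
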