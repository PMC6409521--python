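# ho1screen

A virtual-screening funnel for discovering imidazole-based inhibitors of
heme oxygenase 1 (HO-1), an enzyme whose over-expression in many tumors
correlates with poor clinical outcome. Classical HO-1 inhibitors anchor to
the Fe(II) of the heme substrate through the N3 lone pair of a free
imidazole ring; the package screens large compound libraries for that
chemotype and ranks the survivors by predicted potency.

The funnel has four stages:

1. **Structural filter** — keep molecules containing a *non-fused*
   aromatic imidazole whose C2 (the carbon between the two ring
   nitrogens) bears only hydrogen. N1-linked substituents are allowed:
   that is where the classical inhibitors carry their hydrophobic tail.
2. **Descriptor windows** — ten 2D properties (MW, cLogP, cLogS,
   H-acceptors, H-donors, druglikeness, drug score, total surface area,
   relative PSA, PSA) must fall inside the intervals spanned by potent and
   selective reference inhibitors (HO-1 IC50 ≤ 10 μM, HO-2/HO-1
   selectivity ≥ 10). A *relaxed mesh* instead requires the Lipinski rule
   of five plus at least 7 of the 10 windows.
3. **2D-QSAR** — a Monte-Carlo correlation-weight SMILES QSAR. Each
   molecule's canonical SMILES is decomposed into attributes (single
   tokens Sk, adjacent token pairs SSk, and global features); the single
   regressor is the descriptor of correlation weights,
   `DCW = Σ_attributes count · weight`, and the endpoint is
   `pIC50 = C0 + C1·DCW`. Weights are fitted by a seeded hill-climb on
   the training Pearson r²; molecules carrying attributes never seen in
   training fall outside the applicability domain and are flagged as
   outliers rather than scored.
4. **Consensus** — the 2D-QSAR pIC50 is averaged with externally computed
   3D-QSAR pIC50 and docking pKi tables, and candidates are ranked by
   the mean.

A synthetic-data module generates libraries (qualifying imidazoles,
disqualified near-misses, decoys), reference tables and
linear-in-attributes activities with known ground truth, so the whole
funnel is testable without the natural-product databases or external
3D/docking software.

## Worked example

```sh
ho1screen simulate --n 200 --seed 5 --out-lib lib.smi --out-refs refs.csv \
    --out-activities act.csv
ho1screen filter-structure --in lib.smi --out hits.csv
ho1screen derive-windows --refs refs.csv --ic50-max 10 --sel-min 10 \
    --out windows.yaml
ho1screen qsar-train --train train.csv --seed 17 --epochs 20000 --out model.json
ho1screen run --config run.yaml
```

(`train.csv` joins `lib.smi` with `act.csv`; `run.yaml` points at the
library, windows and model.) Output:

```
input: 200 -> 200
structural: 200 -> 100
descriptor_strict: 100 -> 48
qsar_in_domain: 48 -> 48
ranked: 48 -> 48
```

200 synthetic compounds enter; 100 carry the qualifying imidazole motif;
48 of those sit inside the descriptor windows derived from the 12
qualifying reference inhibitors; all 48 are inside the QSAR applicability
domain and get ranked. The training step reports `r^2 = 0.9519` on 200
molecules, and the head of the ranked table looks like

```
id,smiles,source,pic50_2d,pic50_3d,pki_dock,mean,rank
SYN00029,Clc1ccccc1Cn1ccnc1,OTHER,5.710738,,,5.710738,1
```

— with no external channels supplied the mean is the 2D-QSAR prediction
alone; supplying `--qsar3d`/`--docking` CSV tables (columns `id,score`)
folds them into the mean.

The same workflow is available programmatically through
`ho1screen.run_pipeline(PipelineConfig(...))`, which returns the funnel
report, the ranked table as a DataFrame, per-compound predictions and the
outlier list.

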