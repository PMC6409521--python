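# Methods

## Screening model

The package implements a four-stage filtration funnel for imidazole-based
HO-1 inhibitor candidates. The stages are strictly ordered and each
stage's output is a subset of its input; a funnel report records the
per-stage and per-source counts.

### Structural filter

The pharmacophore is a non-fused aromatic 1,3-diazole (imidazole) whose
C2 carbon bears only hydrogen. Operationally, every aromatic five-ring
with exactly two nitrogens is examined; the ring qualifies when (a) the
two nitrogens are in a 1,3 relationship — there is a unique ring carbon
bonded to both, which is C2 (this excludes pyrazoles); (b) no two of its
atoms are shared with another smallest-set-of-smallest-rings ring (the
standard fused-ring definition, excluding benzimidazoles and purines);
and (c) C2 has no heavy-atom neighbor outside the ring. N1 substitution
is deliberately allowed, since classical inhibitors are N1-linked. The
molecule passes if *any* of its imidazole rings qualifies.

Charged and salt forms are handled upstream: library records are reduced
to their largest organic fragment and neutralized at parse time, so an
imidazolium salt matches through its neutral parent. Aromaticity is
perceived by RDKit, which folds Kekulé and NH-tautomer spellings into one
canonical form; non-aromatic exocyclic tautomers are not enumerated.

### Descriptor windows

Ten 2D descriptors with their default admission intervals (the ranges
spanned by 62 potent & selective reference inhibitors: HO-1 IC50 ≤ 10 μM
and an HO-2/HO-1 IC50 ratio ≥ 10):

| descriptor | window | unit | default calculator |
|---|---|---|---|
| mw | 200–535 | g/mol | exact MW sum |
| clogp | −0.35–5.4 | — | Crippen atomic contributions |
| clogs | −5.90–−0.85 | log mol/L | ESOL-type estimate, **surrogate, disabled** |
| h_acceptors | 2–8 | count | N+O (Lipinski convention) |
| h_donors | 0–1 | count | NH+OH (Lipinski convention) |
| druglikeness | −13.20–8.2 | — | rescaled QED, **surrogate, disabled** |
| drugscore | 0.12–0.96 | — | sigmoid composite, **surrogate, disabled** |
| tsa | 164–390 | Å² | Labute ASA, **surrogate, disabled** |
| rel_psa | 0.085–0.35 | — | PSA / Labute ASA |
| psa | 18–90 | Å² | topological PSA |

Four descriptors originate from proprietary software whose algorithms are
not published. Rather than silently shipping wrong filters, the package
provides clearly-labelled approximate surrogates for them that are
**disabled by default**; users can enable them explicitly or supply
precomputed values per compound via CSV. Bounds are inclusive: the
endpoints are observed reference min/max, which must themselves pass.
`derive_windows` recomputes intervals from any reference table at any
thresholds as the elementwise min/max over the qualifying subset.

The relaxed mesh admits a compound when it satisfies the Lipinski rule of
five with zero violations (MW ≤ 500, cLogP ≤ 5, donors ≤ 5, acceptors
≤ 10) *and* at least `min_passes` (default 7) of the enabled windows.
Zero violations is the chosen reading of "satisfies the rule of five";
the common one-violation allowance can be obtained by lowering
`min_passes` only for the window clause, not the Lipinski clause.

### Correlation-weight 2D-QSAR

Attribute dialect (version 1): the canonical SMILES is split into raw
tokens (bracket atoms, two-character elements, `%nn` closures, single
characters). Sk are the atom tokens with multiplicities; SSk are
consecutive raw-token pairs with the two members sorted lexicographically,
so bond, branch and ring-closure symbols fold into the pairs and
`C=N` ≡ `N=C`. Two global attributes are added: a ring-count bucket
(0–3, 4 = "4 or more") and halogen presence. This is the smallest dialect
that exercises the method; extraction always canonicalizes first so
weights attach to one fixed SMILES dialect.

Training: attributes occurring in fewer than `threshold_t` training
molecules are blocked (weight fixed at 0). Active weights start at 1.0;
each epoch proposes a ±δ (δ = 0.05) perturbation of one uniformly chosen
active weight and accepts it iff the training Pearson r² between DCW and
pIC50 does not decrease — so r² is non-decreasing by construction and the
whole trajectory is deterministic given the seed. After `n_epochs`
(default 20,000) proposals, the intercept and slope are set by the
closed-form least squares of pIC50 on DCW. Degenerate inputs error out:
fewer than 10 molecules, identical endpoints (r² undefined), or zero DCW
variance at the end of training.

The published regression layer for HO-1 (intercept 0.0000163, slope
0.0473151 pIC50 per DCW unit, threshold parameter 0.41) ships as
`published_ho1_model()`. Its correlation weights were never published, so
the object carries an empty weight map: it evaluates user-supplied DCW
values and serves regression-wiring checks, but cannot score structures —
fabricating weights would be worse than declining to predict. The 0.41
threshold parameter is stored verbatim; since its operational meaning is
not documented, new training maps it to "active iff present in
≥ max(1, round(0.41% · n_train)) molecules", overridable via
`threshold_t`.

Applicability domain: by default a molecule is an outlier iff it carries
any attribute absent from the training census. This is the strictest
membership rule; it errs toward flagging, which is the conservative
direction for a screening funnel (an outlier is excluded from ranking,
not mis-scored). A graded alternative, `attribute_defect`, scores the
mean training rarity of a molecule's attribute occurrences (novel
attributes count as rarity 1) and can replace the strict rule through a
cutoff in `apply_qsar_filter`.

### Consensus

The final ranking orders survivors by the arithmetic mean of the 2D-QSAR
pIC50, the 3D-QSAR pIC50 and the docking pKi. The mean deliberately mixes
pIC50 and pKi on their native −log10 molar scales without normalization —
that is the protocol being reproduced; an optional z-score mode exists
and is marked as a deviation. By default only compounds carrying all
three channels are ranked (`require_all=True`); when no external tables
are supplied the pipeline falls back to the channels present. Ties break
by id lexicographic order, logged. 3D-QSAR and docking are *ingested*,
never computed: conformer generation, field-point alignment and docking
need external tools and are out of scope.

## Synthetic study conditions

The generator emulates the screening situation, not natural-product
chemistry. Libraries mix three classes in configurable fractions
(default 50% qualifying / 30% disqualified / 20% decoy, allocated by the
largest-remainder rule): qualifying compounds are N1- or C4-decorated
plain imidazoles; disqualified ones are N1-decorated benzimidazoles or
2-substituted imidazoles; decoys are deliberate near-misses (pyrazoles,
oxazoles, thiazoles, pyridines, pyrroles, benzenes) chosen to stress the
ring-topology logic where it can actually fail. Decorations chain one to
three fragments from an 11-fragment alphabet (alkyl, hydroxy/amino-alkyl,
benzyl-type, halogenated), giving ~170 unique structures per 200 records.

Activities are pIC50 = 4.0 + Σ count·weight + N(0, σ) over a hidden
weight map in the same attribute dialect the QSAR fits (weights
0.02–0.30 per occurrence; defaults in `default_activity_spec`). σ
defaults to 0.1 pIC50 — assay-replicate scale; recovery tests use σ = 0
(contract: held-out RMSE ≤ 0.1) and σ = 0.1 (≤ 0.2). Reference tables
plant a qualifying subset by construction (IC50 and selectivity drawn on
the correct side of the 10 μM / 10-fold thresholds, with a stricter
5 μM / 30-fold sub-tier), so window derivation has an exact oracle.

What the generator does **not** emulate: real natural-product scaffold
diversity, stereochemistry-dependent activity, tautomer-rich systems,
activity cliffs, or any relationship between the descriptor values and
the simulated potencies. Passing tests therefore demonstrate the
correctness of the filtering, training and ranking machinery under
controlled conditions — not predictive validity on real libraries, which
depends on the quality of the trained weights and external channels.

## Numerical choices

- Window bounds inclusive; descriptor unavailability excludes a window
  from the verdict and is reported, never silently passed.
- Hill-climb acceptance uses ≥ (ties accepted), allowing drift along r²
  plateaus; r² of a zero-variance DCW is defined as 0.
- OLS is the closed-form two-parameter solution; tests require agreement
  with an independent fit to 1e-9.
- Consensus ties break by id; re-runs with identical inputs produce
  byte-identical ranked CSV and funnel JSON (fixed float formatting).
- Problem sizes in the test-suite and acceptance script — 1,000-compound
  structural runs, 200-molecule training with 20,000 epochs, 50 reference
  sets, 500 DCW oracle pairs — were chosen to exercise each contract at
  comfortably more than toy scale while keeping a full run in seconds.

## Known limitations

- The four surrogate descriptor calculators approximate unpublished
  algorithms; their absolute values are not comparable to the original
  tools', which is why they are disabled by default and the published
  windows for them are applied only to user-supplied values.
- The published HO-1 model cannot score structures (weights unavailable).
- Neither domain rule can reproduce the published 90/144 outlier split
  exactly — the original model's attribute census is not available.
- Multi-fragment records keep only the largest organic fragment;
  genuinely multi-component actives are out of scope.
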