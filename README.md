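# pharmscreen

Ligand-based pharmacophore screening and validation, built around a
published five-feature pharmacophore model for dual inhibitors of the
tryptophan-catabolizing enzymes hIDO1 (human indoleamine 2,3-dioxygenase 1)
and hTDO2 (human tryptophan 2,3-dioxygenase) — immuno-oncology targets of
the kynurenine pathway. The package is for computational medicinal chemists
who want a reproducible, scriptable version of the classic
screen → drug-likeness filter → actives/decoys validation workflow that
commercial modeling suites run behind closed doors.

## What it computes

A pharmacophore model is an ordered set of typed spherical features
F₁…F₅, each with a boolean type expression over the five primitive kinds
(Aro aromatic center, Hyd hydrophobic center, Acc H-bond acceptor, Don
H-bond donor, ML metal ligator), a centroid **c**ᵢ ∈ ℝ³ (Å) and a tolerance
radius rᵢ (Å). The built-in dual-inhibitor model has

| id | expression   | radius (Å) | essential |
|----|--------------|-----------|-----------|
| F1 | Aro\|Hyd     | 1.5       | yes |
| F2 | Aro\|Hyd     | 1.5       | yes |
| F3 | Aro\|Hyd     | 0.7       | yes |
| F4 | ML\|Acc\|Don | 1.3       | no  |
| F5 | ML&(Acc\|Don)| 0.4       | yes |

with `min_match = 4`: a molecule is a **hit** when an injective,
type-compatible assignment of its perceived features to model features —
covering every essential feature and at least four in total — can be
rigidly superposed (weighted least squares, proper rotations only) so that
each assigned feature lands inside its feature's tolerance sphere. The
fitting score is n/5, the number of model features matched.

Screening performance on labeled actives/decoys is summarized by the six
standard statistics

```
sensitivity = TP/P   specificity = TN/N   FPR = FP/N
accuracy = (TP+TN)/(P+N)   PPV = TP/(TP+FP)   NPV = TN/(TN+FN)
```

The package also derives consensus models from aligned ligand ensembles
(support threshold 50%, clustering tolerance 1.15 Å), applies
Lipinski/Veber drug-likeness filtration, and generates seeded synthetic
actives/decoys benchmarks, since the original validation compound
structures were never published.

## Worked example

```python
import pharmscreen as ps

model = ps.builtin_dual_model()
print(round(ps.feature_distance(model, "F1", "F3"), 2))   # 4.85  (Å)
print(round(ps.feature_angle(model, "F1", "F3", "F4"), 1))  # 44.8  (degrees, apex F1)

# synthetic 56-active / 207-decoy benchmark, screened and validated
bench = ps.make_benchmark(model, ps.GeneratorParams(seed=7))
screener = ps.PharmacophoreScreener().fit()
table = screener.screen(bench.feature_sets)
counts = ps.counts_from_screen(bench.labels, table)
print(counts)   # ConfusionCounts(tp=56, fn=0, fp=0, tn=207)
print(ps.metrics_from_counts(counts).format()["sensitivity"])   # 100.00%

# the published validation outcome, as counts, gives the published statistics
m = ps.metrics_from_counts(ps.ConfusionCounts(tp=45, fn=11, fp=16, tn=191))
print(m.as_percent())
# {'sensitivity': 80.36, 'specificity': 92.27, 'false_positive_rate': 7.73,
#  'accuracy': 89.73, 'ppv': 73.77, 'npv': 94.55}
```

The first two numbers are the model's own geometry: the F1–F3 centroid
distance and the angle at F1 between the directions to F3 and F4. The
benchmark block shows a noise-controlled end-to-end recovery: at the
default generation conditions (0.2 Å jitter, 30% dropout of the
non-essential feature, hard decoys) the screener recovers essentially all
actives and rejects all decoys. The last block evaluates the six
validation statistics on an externally given confusion matrix.

Estimators follow scikit-learn conventions (`get_params`/`set_params`,
`fit`/`predict`/`transform`, trailing-underscore fitted attributes), so
they compose with sklearn model selection; `ConsensusPharmacophore.fit`
builds a model from an aligned ensemble, `DruglikenessFilter.transform`
filters molecule lists.

A CLI mirrors the library:

```bash
pharmscreen geometry --out geom.tsv
pharmscreen synth --seed 7 --out bench.jsonl
pharmscreen screen --library bench.jsonl --out screen.tsv
pharmscreen validate --screen-table screen.tsv --labels bench.jsonl.labels.tsv --out metrics.tsv
pharmscreen filter --library drugs.smi --out filtered.tsv
pharmscreen consensus --ensemble aligned.jsonl --out model.json
```

## Layout

- `pharmscreen.model` — model representation, feature-type expressions, built-in model, JSON I/O, geometry audit
- `pharmscreen.perception` — SMARTS feature perception, SDF/SMILES reading, 3D embedding, packaged drug fixtures
- `pharmscreen.matching` — correspondence enumeration, rigid superposition, best-match fitting, library screening
- `pharmscreen.consensus` — consensus model derivation from aligned ensembles
- `pharmscreen.druglikeness` — Lipinski/Veber descriptors and filter
- `pharmscreen.validation` — confusion counts and the six screening statistics
- `pharmscreen.synthetic` — seeded actives/decoys benchmark generator
- `pharmscreen.cli` — command-line pipeline

See `docs/methods.md` for the modeling assumptions and numerical choices.
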