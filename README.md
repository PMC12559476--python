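# t3pks

A toolkit for kingdom-wide characterisation of **type III polyketide
synthases (T3PKSs)** — homodimeric enzymes that iteratively condense
malonyl-CoA extender units onto an acyl-CoA starter in a single active
site.  Fungal genomes encode hundreds of uncharacterised T3PKSs; this
package implements the computational arm of a characterisation campaign:

1. **Mining** — detect candidate enzymes in protein FASTA collections by
   Smith–Waterman similarity to seed queries (BLOSUM62, gap open 11 /
   extend 1), then merge and dereplicate hit sets from multiple sources.
2. **Sequence similarity networks (SSN)** — collapse sequences sharing
   >95% identity into representative nodes, connect representatives at a
   chosen identity cutoff (e.g. 80%), and label connected components as
   clusters approximating functional groups.
3. **Active-site analysis** — map each candidate onto chalcone-synthase
   reference numbering (MsCHS; catalytic triad C164/H303/N336, pocket
   positions G256, F265, 197) by global alignment, build per-group
   residue-frequency logos, and flag triad substitutions ("H303D").
4. **Specificity prediction** — represent an enzyme by mean-pooling its
   per-residue features into a fixed-length vector `h = (1/L) Σ_i h_i`,
   a substrate by a binary fingerprint (167-bit MACCS keys or Morgan/ECFP,
   radius 2), concatenate the two per enzyme–substrate pair, and train
   binary activity classifiers (decision tree, random forest, MLP).
   Evaluation is seed-repeated stratified cross-validation reported as
   mean ± sd; deployment averages predicted probabilities over 100
   seeded model runs before binarising at 0.5.
5. **Position importance** — rank alignment columns by grouped
   permutation importance as candidate specificity-determining residues.

A synthetic-data module generates homologous enzyme families at
controlled identity, a small substrate panel and planted motif ×
substructure activity rules (31 enzymes × 11 substrates = 341 pairs, 43%
active by default), so the entire stack runs and is tested offline; per-
residue embedders are pluggable, with a deterministic physicochemical
fallback and an adapter slot for transformer protein language models.

## Worked example

```python
from t3pks.featurize import featurize_pairs
from t3pks.model import ModelConfig, cross_validate
from t3pks.ssn import build_network
from t3pks.synthetic import SyntheticSpec, generate_activity, generate_families

spec = SyntheticSpec(seed=11, label_noise_rate=0.05)
enzymes = generate_families(spec)            # 31 enzymes, 3 families
activity = generate_activity(spec, enzymes)  # 341 labelled pairs

network = build_network(enzymes, cutoff=0.80)
print(network.n_clusters)                    # -> 3 (one per family)

features = featurize_pairs(enzymes, spec.substrate_panel)
report = cross_validate(
    activity.observed, features,
    ModelConfig(classifier="mlp", cv_folds=5, cv_repeats=10, base_seed=3),
)
print(report.summary())                      # -> accuracy 88 ± 3%, F1 score 0.85 ± 0.04
```

The network recovers the three planted families as separate clusters at
the 80% cutoff, and the MLP recovers the planted specificity rule well
above the 57% majority-class baseline despite 5% label noise.  The
`examples/` directory holds one narrative script per capability
(mining+SSN, active sites, train+predict, importance, full pipeline);
each prints the numbers it computes and what they mean.

A thin CLI mirrors the library:

```bash
t3pks simulate --seed 5 --out fixtures/
t3pks ssn --in fixtures/enzymes.faa --cutoff 0.80 --out net/
t3pks run --config pipeline.yaml
```

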