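# alertminer

Automatic derivation of **structural alerts** — substructures statistically
associated with a biological or toxicological response — from bioactivity
data sets, plus hashed and unhashed (keyed) circular fingerprints for
interpretable QSAR modelling.

Screening drug candidates against structural alerts (toxicophores such as
nitroaromatics, often active only after metabolic bioactivation) is a
standard early-toxicity filter. `alertminer` derives such alerts
automatically from two kinds of data:

* **categorical** data (active/inactive, toxic/non-toxic), via a binomial
  enrichment test on circular atom environments;
* **continuous** data (pIC50, Ki), via a normality-gated two-sample
  comparison of the activity distributions with and without each
  substructure.

## The statistics

Substructures are circular Morgan/ECFP-style atom environments: for each
heavy atom and each bond radius *r* in a user-chosen set, the environment
within *r* bonds of the root atom receives a stable integer identifier from
the standard connectivity-invariant hashing (RDKit).

**Categorical.** For a training set of *n* compounds with *m* actives, a
substructure *S* contained in *n_S* compounds of which *m_S,act* are
active is scored by the upper binomial tail

```
P = Σ_{i = m_S,act}^{n_S}  C(n_S, i) (m/n)^i (1 − m/n)^(n_S − i)
```

— the probability of seeing at least *m_S,act* active carriers by chance
if *S* were unrelated to activity. The scan over a test set processes each
root atom smallest-radius-first, computes P only when *n_S* ≥
`min_support` (default 5) and *m_S,act*/*n_S* ≥ `min_frequency`
(required, no default), flags substructures with P < α (default 0.05),
and suppresses larger environments rooted at an atom where an alert fired.
The Bonferroni correction (default on) multiplies P values by the number
of P values computed in the run.

**Continuous.** For each substructure, training activities split into
distribution *A* (compounds containing *S*) and *B* (the rest). Shapiro–Wilk
(α = 0.05) gates the choice of test: both normal → two-tailed pooled
*t* test; otherwise the two-sample Kolmogorov–Smirnov test. The signed
effect size mean(*A*) − mean(*B*), in activity units, gives the direction
of the association — and deserves as much attention as the P value, since
large samples can make a chemically negligible shift highly significant.

**Fingerprints.** Hashed fingerprints place each identifier at position
`identifier mod size`; unhashed (keyed) fingerprints give each distinct
substructure its own column, optionally on a basis frozen from a training
set so new compounds map onto interpretable, stable columns.

## Worked example

No external data is needed: the built-in generator plants a nitroaromatic
fragment into drug-like scaffolds with controlled activity structure.

```python
from alertminer import (FixtureSpec, CategoricalAlertMiner,
                        generate_categorical_set, probe_set)
from alertminer.alerts_categorical import results_to_frame

spec = FixtureSpec(n_molecules=200, p_frag_given_active=0.4,
                   p_frag_given_inactive=0.02, seed=1)
train = generate_categorical_set(spec)          # 200 molecules, 100 active
miner = CategoricalAlertMiner(radii=(1, 2), min_support=5,
                              min_frequency=0.7, alpha=0.05)
miner.fit(train)                                # builds the substructure index
results = miner.derive(probe_set(spec, 1))      # scan a fragment-bearing probe
print(results_to_frame(results).head(6))
```

Output (seed 1):

```
 identifier        smiles  radius  n_S  m_S_act      p_value  p_value_corrected  significant
 1323467736     c-c(c)ccc       2   36       35 5.384209e-10       5.384209e-09         True
 3982076256       c-c(c)c       1   36       35 5.384209e-10       5.384209e-09         True
  271903915 c[N+](=O)[O-]       1   38       36 2.699380e-09       2.699380e-08         True
 1514095308     cc([N+])c       1   38       36 2.699380e-09       2.699380e-08         True
 2378775366      [N+][O-]       1   38       36 2.699380e-09       2.699380e-08         True
 2378779377        [N+]=O       1   38       36 2.699380e-09       2.699380e-08         True
```

Of the 200 training compounds (n = 200, m = 100 actives), 38 carry the
planted fragment, 36 of them active; seeing ≥ 36 actives among 38 carriers
by chance has probability ≈ 2.7 × 10⁻⁹, so the nitro environments
(`c[N+](=O)[O-]`, `[N+][O-]`, …) are flagged as alerts after Bonferroni
correction. Substructures common to actives and inactives never reach the
P-value stage: the frequency gate removes them.

The same workflow is available from the shell:

```bash
alertminer fixtures --mode categorical --n 200 --seed 1 \
    --out train.smi --labels labels.csv
alertminer categorical --train train.smi --train-labels labels.csv \
    --test train.smi --radii 1,2 --min-frequency 0.7 --out alerts.csv
```

plus `alertminer continuous ...` (with `--min-support/--min-ratio`) and
`alertminer fp ...` for fingerprint matrices.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the seeded synthetic categorical and continuous data sets,
derives alerts with both pipelines, verifies keyed→folded vs directly
hashed fingerprints, prints a run summary and writes the result JSON.

See `docs/methods.md` for the statistical model, parameter semantics,
numerical choices and known limitations.
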