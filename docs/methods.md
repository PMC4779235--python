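# Methods

## Substructure model

A molecule's substructures are its circular atom environments: for every
heavy atom (root) and every bond radius `r` in the user-supplied set, the
subgraph within `r` bonds of the root, identified by the integer produced
by the Morgan/ECFP connectivity-invariant hashing (RDKit's Morgan
generator with default invariants; implicit hydrogens are folded into the
atom invariants, no explicit-H graphs). Identifiers are stable across
runs and platforms. Hash collisions — distinct environments with equal
identifiers — are accepted and treated as one substructure, consistent
with the fingerprint semantics the identifiers come from.

Two consequences of the enumeration design:

* **Per-root enumeration.** Environments are enumerated with one
  generator call per root atom. RDKit's whole-molecule bit info
  deduplicates environments that cover identical bond sets (e.g. the two
  radius-1 environments of ethane), which would silently drop root atoms
  from the scan. Per-root enumeration reports every (root, radius) pair
  for which the environment exists — a radius exceeding the reachable
  graph distance from the root yields nothing.
* **Count semantics.** Count-format fingerprints count environment
  *occurrences* (root atoms) per molecule. On symmetric molecules this
  can exceed RDKit's own deduplicated counts; presence/absence is
  identical. Containment bookkeeping (`n_S`) is presence-based: a
  molecule with three occurrences of S counts once, because the binomial
  model counts compounds, not occurrences.

## Categorical alerts

Training data: `n` compounds, `m` active. For substructure S with `n_S`
training carriers, `m_S_act` of them active, the score is the upper
binomial tail `P(X >= m_S_act)` for `X ~ Binomial(n_S, m/n)`, computed
via `scipy.stats.binom.sf` (accurate well beyond the 1e-12 relative
tolerance the tests demand; the test oracle is independent term-by-term
summation with exact binomial coefficients). Only enrichment among
actives is tested — the statistic is a one-sided upper tail; depletion is
not scored.

Scan semantics (test set, in input order; per molecule, root atoms in
index order; per root, ascending radius):

1. identifiers absent from the training index are skipped;
2. gates, both **inclusive**: `n_S >= min_support` (default 5) and
   `m_S_act / n_S >= min_frequency` (required, no default). The
   inclusive reading follows the worked description of the threshold
   ("set to 5 ... only 4 compounds ... will not calculate"); gate
   failures mark the identifier as globally processed, an optimization
   with identical output since training counts cannot change;
3. a computed P value marks the identifier processed (never re-evaluated
   in later molecules); if raw `P < alpha`, the substructure is flagged
   and larger radii at that root atom are suppressed.

Bonferroni multiplicity is the number of P values actually computed in
the run — known only after the scan. Hence the two-phase default: in-scan
suppression decisions use raw P against `alpha`; the reported
significance flag uses the corrected values. Since corrected >= raw, the
corrected-significant set is a subset of the raw-flagged set and the two
phases are mutually consistent. `bonferroni_during_scan=True` instead
compares raw P against `alpha / k_running` (running count including the
current test) during the scan and reports those flags — a stricter,
order-dependent variant provided because the correction's timing is
genuinely underdetermined; default off.

Results report **all** evaluated substructures (alerts first, ascending
corrected P), with `n_S`, `m_S_act`, the carrier frequency, raw and
corrected P, and a (molecule, root atom) example for depiction. The
effect of a substructure is modelled as independent of all others: a
substructure that merely co-occurs with a true alert will also be
flagged. Judge candidate alerts with their counts and frequencies, not
the P value alone.

## Continuous alerts

For each distinct test-set substructure (first-encounter order, no
radius suppression — the categorical smallest-radius rule does not apply
here), training activities split into A (carriers) and B (non-carriers,
both defined on the training set). Gates, inclusive: `n_A >= min_support`
and `n_A / n >= min_ratio`; both are required parameters with no
default.

Test choice: Shapiro–Wilk on A and on B, each at the same `alpha` used
for the main test (default 0.05). Both normal → two-tailed
independent-samples t test, **pooled** variance by default (the plain
reading of "t test for independent samples"; Welch available via
`welch=True`). Otherwise → two-sample Kolmogorov–Smirnov, two-sided,
asymptotic P. Numerical edge cases: a zero-variance sample is treated as
non-normal (KS branch); samples with fewer than 3 values on either side
are skipped with a logged reason (a skip, not a statistical result);
samples beyond 5000 points are subsampled with a fixed seed before
Shapiro–Wilk, whose power and implementation degrade there.

Effect size = mean(A) − mean(B) in activity units (e.g. pIC50);
direction "increases" iff positive. With large samples a trivially small
shift can reach significance — the effect size column is the guard
against over-reading such results. Bonferroni as in the categorical
module.

## Fingerprints

Hashed: position = `identifier mod size`; counts accumulate over
colliding identifiers, binary is the indicator of a nonzero count
(indicator-after-fold — identical to indicator-before-fold for
presence). Keyed: columns are the distinct identifiers of the basis set
in ascending identifier order (deterministic, reproducible). Projecting
onto a frozen training basis drops out-of-basis substructures silently
with one INFO line counting distinct dropped identifiers; dropping (not
appending) keeps the column meaning fixed, which is the point of a
frozen basis. `fold` bridges the schemes and is tested against directly
hashed fingerprints. Substructure SMILES are rendered from one example
occurrence (root, radius) via the environment subgraph, canonicalized;
depictions highlight the environment's atoms and bonds, SVG by default,
PDF behind a flag.

## Synthetic data generator

The generator emulates the enrichment structure the two algorithms
assume: a planted fragment (default nitrobenzene — a classic
mutagenicity toxicophore) joined by a single bond onto one of ~20
hand-written drug-like scaffolds, none of which contains a nitro group,
so the fragment contributes identifiers present in carriers and absent
in all non-carriers. Attachment sites are spare-hydrogen carbons
(aromatic preferred); rejected joins are resampled; every generated
molecule is sanitized and round-trips through SMILES.

Categorical mode fixes the active fraction (default 0.5) and plants the
fragment per molecule with probability P(fragment | label) — Bernoulli,
so conditional frequencies match the specification within binomial
sampling error and Monte-Carlo calibration across seeds is meaningful.
Continuous mode: activity = baseline (default 6.0, a mid-range pIC50) +
shift × carrier + Normal(0, noise_sd); noise_sd defaults to 0.3, a
typical inter-assay pIC50 reproducibility scale. All randomness flows
through one `numpy.random.default_rng(seed)`.

What a green test on this generator does **not** establish: realistic
chemistry-space coverage, property-matched decoys, correlated
substructures (each molecule is scaffold ± one fragment), label noise,
or assay artifacts. The generator validates the statistics and the scan
logic, not chemical generality.

## Design choices where the design was open

* Gates inclusive (>=) in both modules — see above.
* B = training-set non-carriers (not test-set): both distributions are
  defined on the training set.
* Keyed column order: ascending identifier.
* Depiction default SVG; PDF via the Cairo drawer behind a flag.
* `radii` never has a default — analyses at different radii are
  different analyses, and the choice is the user's.
* The categorical CLI requires `--min-frequency`; the continuous CLI
  requires `--min-support` and `--min-ratio` (no published defaults).

## Limitations

Substructure effects are treated as independent events; co-occurring
substructures are flagged together (use large, diverse training sets).
Only active-enrichment is tested in the categorical module. No 3-D,
conformer or stereochemistry-aware identity beyond the standard
environment invariants. Serial implementation; training sets in the
10^4–10^5 range index in minutes, not seconds.
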