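# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic data do and do not establish.

## The study system

European black cherry aphids comprise two morphologically similar,
winter-host-specific taxa: *Myzus cerasi cerasi* overwinters on sour
cherry (*Prunus cerasus*) and *M. c. pruniavium* on sweet cherry
(*P. avium*, also *P. mahaleb*, *P. maackii*, *P. serrulata*). The
package reproduces a two-pronged delimitation: (i) partial mitochondrial
COI sequences collapse into host-associated haplotype clades whose
divergence is measured on the Kimura 2-parameter (K2P) scale; (ii) a
linear discriminant key over three metric characters of apterous
viviparous females separates the subspecies, with its error rates
estimated on hold-out samples.

## Sequence reconstruction

The real sequences are GenBank accessions and are not shipped or
downloaded; instead the generator realises the published *structure* of
the alignment, which suffices for every statistic in scope.

* 616 aligned positions; 51 in-group records (one per population
  sample); five haplotypes with membership counts 2/23/23/2/1, exactly
  the published sample-to-haplotype table.
* Three variable positions — 300, 321, 390, all third codon positions —
  each with two states. The actual bases were never published. The
  state assignment used (position 300 splitting haplotypes 1–2 from 3–4;
  321 carried by haplotype 3 alone among 1–4; 390 by haplotype 2 alone;
  *M. borealis* = clade-1/2 state at 300 + haplotype 3's state at 321 +
  haplotype 2's state at 390) is the only assignment class that
  simultaneously reproduces the published intraspecific range 0.0–0.5%
  (mean 0.2%), the borealis–cerasi range 0.2–0.5%, and borealis's
  placement inside the sour-cherry clade. All three sites are modelled
  as T↔C transitions; the real transition/transversion identities are
  unknown, and a single substitution class keeps the rounded K2P bands
  stable.
* The invariant background realises the published average base
  composition (A 34.0, C 12.7, G 12.3, T 41.0%) as exact counts
  (largest-remainder apportionment, then one shuffle). Frame-0 stop
  codons (TAA/TAG under the invertebrate mitochondrial code, NCBI table
  5) are repaired by base swaps, which preserve the composition exactly;
  the published screening ("no stop codons") is then a checkable
  post-condition, not an accident of the draw.
* The outgroup (a *M. persicae*-like sequence) differs from the
  background at 23 fixed transitions + 15 fixed transversions placed at
  invariant positions, and carries the sweet-cherry state at 300, the
  majority state at 321 and haplotype 2's state at 390. These defaults
  are the solution of a grid search (kept as a test) over (ts, tv)
  pairs whose K2P band to the in-group rounds to the published 6.6–6.8%
  interval, with the borealis–outgroup cell at 6.8%.

Consequence worth knowing: because the outgroup must share haplotype 2's
state at 390, the two deep signals (sites 300 and 390) conflict on any
tree that includes the outgroup. Exhaustive parsimony on the four cerasi
haplotypes alone is homoplasy-free (CI = RI = 1.00); adding the
calibrated outgroup yields CI = 41/42 on five taxa and CI = 41/43 with
borealis included, and the sour-cherry clade's bootstrap support tops
the ranking (~43% at haplotype scale) without reaching a majority. The
published full-data MP statistics (length 43, 930 trees, CI = 1.00)
depend on ~40 unpublished outgroup site states and are out of scope.

## Sequence statistics

* K2P: d = −½·ln(1−2P−Q) − ¼·ln(1−2Q); saturation (non-positive log
  arguments) raises an error naming the pair. Percentages are reported
  to 1 decimal, rounding half away from zero — the convention that
  reproduces every published range (0.163 → 0.2, 0.489 → 0.5).
* Site classification: a column is parsimony-informative iff at least
  two states are each carried by at least two sequences.
* Gaps and ambiguity codes are rejected; the target alignments contain
  none, and pairwise-deletion handling is deliberately deferred.

## Trees and network

* Neighbor joining (Saitou–Nei Q-criterion). Ties are broken by the
  earliest pair in the current node ordering; negative branch lengths
  are clamped to zero with the deficit moved to the sister branch. On
  additive matrices of ≤ 6 taxa the topology is recovered exactly
  (property-tested, plus a cross-check against scikit-bio).
* Fitch parsimony length by set-intersection counts on pattern-
  compressed columns; verified against brute-force minimisation over all
  internal state assignments on small trees.
* Exhaustive maximum parsimony enumerates all unrooted binary
  topologies over the distinct sequences (refusing > 8, where the
  enumeration—1, 3, 15, 105, 945, 10395 topologies—stops being a desk
  computation) and reports every minimum-length tree with
  CI = M/S and RI = (G−S)/(G−M), where M is the site-wise minimum
  (states − 1), G the site-wise maximum (n − majority count) and S the
  realised length. RI is NaN when G = M; both indices are 1 on an
  invariant alignment.
* The haplotype network is a minimum spanning network over raw Hamming
  steps: a deterministic Kruskal tree plus every non-tree edge that ties
  the bottleneck weight of its tree path, with edges above a parsimony
  connection limit dropped (default 10 steps for ~600 bp, the magnitude
  the TCS software yields at this length; the in-group maximum is 3
  steps, so any limit ≥ 3 gives the published connectivity). The
  Templeton–Crandall–Sing probability calculation is not re-derived.
  The "outgroup probability" root weight is a documented surrogate:
  weight ∝ haplotype frequency × (1 + degree), normalised; the argmax
  (one of the two 23-member haplotypes) is flagged as root candidate.
* Bootstrap support: site resampling with replacement, one rebuild per
  replicate, bipartition tallies; fully seeded.

## Morphometric generator

No raw measurements were published; the generator's normative targets
are the published aggregates, and its means/sds are documented fixtures
at realistic magnitudes for slide-mounted apterae.

* **Design**: the published sampling table — 20 bold (training) samples
  (79 sour-cherry + 73 sweet-cherry apterae) and 30 hold-out samples
  (118 + 110), validated as sums.
* **Size structure**: one standard-normal allometric factor per sample
  (colony condition) carries `sample_effect_fraction` (default 0.25) of
  the body-length variance; each character loads on it through its
  body-length correlation. Characters uncorrelated with body length —
  including the three key characters — have no sample-level component;
  this is the minimal covariance model consistent with the published
  correlation structure.
* **Correlations**: the published Pearson r values with body length
  (F3L 0.83, T3L 0.82, A3L 0.75, A4L 0.71, A2L 0.70, A5L 0.70; others
  ~0) are enforced as *realised sample statistics* by orthonormalising
  each residual against body length within each train/hold-out stratum.
  Rationale: at n = 152 a population r of exactly 0.70 would leave the
  published filter outcome (7 removed, 12 retained) to a coin flip per
  borderline character; the published values are treated as what the
  study measured, not as population parameters. The 0.70 threshold
  comparison tolerates float rounding (1e-9).
* **Key-score calibration**: the three key characters are independent
  normals whose group means place the published key's score at
  ±z·σ_score per taxon, σ_score = √Σ(wᵢsᵢ)². Hold-out samples use
  z = Φ⁻¹ of the published hold-out rates (1.430, 1.525 for 92.37% and
  93.64%); training samples use Φ⁻¹ of the published reclassification
  rates (1.774, 2.197 for 96.2% and 98.6%) along the same contrast
  direction. The two calibrations are genuinely different in the source
  data (training material was more separable than the hold-outs), and a
  single homogeneous calibration cannot reproduce both sets of printed
  rates. The arithmetic 96.2% = 76/79 and 98.6% = 72/73 fixes which
  rate belongs to which host cohort.
* **Fixture means/sds**: SL 0.94/0.81 ± 0.07 mm, VBSLmax 0.016/0.024
  ± 0.006 mm, A6TPL back-solved from the z-constraint (≈ 0.624/0.718
  ± 0.05), BL 1.85 ± 0.15; remaining characters at realistic magnitudes
  with no group effect except a small (0.3 within-sd) host effect on
  Bwant3, URL and A6BL, which the source ranks as mid-level predictors.
  SL and VBSLmax were chosen to make the between-taxon contrast
  Fisher-consistent with the published key (population angle < 1°), so
  each key character's standardized separation (1.86, 1.87, 1.33 sd) is
  large enough for its published contribution rank to be statistically
  determined at n = 152 — with weaker VBSLmax separation the published
  top-three ordering degenerates into a lottery against 19-df group
  noise. The z-constraints, not the means, are normative.
* Measurements are floored at 0.0001 mm (≈ 0.4% of VBSLmax draws in the
  cerasi tail); the effect on classification rates is < 0.1 point.
* Seeding: one master seed; stage streams are spawned deterministically,
  so identical seeds give byte-identical FASTA/TSV artifacts.

**What a green test does and does not establish.** The generator
reproduces the published aggregate structure (haplotype memberships,
divergence bands, correlation/filter outcome, separability, sampling
design) but not real measurement distributions: no allometric curvature,
no measurement error correlated between observers, no geographic or
seasonal structure beyond the single sample factor, no alate or
oviparous morphs, and no attempt at the real GenBank base composition at
individual sites. Green tests establish that the *methods* recover the
published statistics from data with the published structure — not that
they would do so on the real slides.

## Discriminant chain

* Correlation filter: two-sided p from t = r·√((n−2)/(1−r²)) with n−2
  df; removal iff |r| ≥ 0.70 and p < 0.05; body length removes itself
  (r = 1); zero-variance characters are flagged and retained. No
  multiple-testing correction (the source applies none).
* Stepwise discriminant analysis: forward selection on Wilks'
  Λ = det(W)/det(T) with groups = collection samples (20 in training),
  F-to-enter = ((n−g−p)/(g−1))·(Λ_p/Λ_p+1 − 1), defaults
  F-enter = 1.0 / F-remove = 0.0 (the originating commercial package's
  convention; the source is silent). The per-character table reports
  Λ-if-removed, partial Λ, F-remove with (g−1, n−g−p+1) df, p-level and
  tolerance (1 − R² against the other in-model characters, with a 1e-6
  floor as a collinearity guard). Λ is non-increasing along the path.
* Canonical variates: generalized symmetric eigenproblem B·v = λ·W·v,
  scores scaled to unit pooled within-group variance, eigenvalues
  non-increasing; group means on CV1/CV2 are the scatter-plot data
  product.
* Two-group key fit: Fisher discriminant with pooled covariance and
  equal priors, boundary at score 0, oriented so *cerasi* is positive.
  The printed key is applied with its full-precision coefficients;
  a score of exactly 0 is reported as indeterminate (the published key
  only covers > 0 and < 0).
* Classification summaries report exact n_correct/n percentages to two
  decimals, matching the published 92.37/93.64/97.37 style.

## Numerical and reporting conventions

* Percent rounding: half away from zero, 1 decimal for divergences,
  2 decimals for classification rates.
* All randomness flows from a single integer seed through deterministic
  child streams; reports contain no timestamps, so repeat runs are
  byte-identical.
* Alignment coordinates are 1-based and inclusive.

## Known limitations

* Model-based phylogenetics (ML, Bayesian), model selection and
  heuristic tree search are out of scope by design; NJ + exhaustive MP
  at haplotype scale carry the reproducible content.
* The network's connection limit and root weighting are documented
  surrogates for the TCS calculations, adequate at ≤ 3-step scale.
* Bootstrap support values on the reconstruction are not comparable to
  the published ones (those depend on unpublished outgroup states); only
  the rank of the sour-cherry clade is asserted.
* The exhaustive-search bound (8 distinct haplotypes) is far below real
  alignment sizes; the neighbor-joining path is the intended fallback.
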