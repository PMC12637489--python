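# Methods

## The filtering model

The pipeline operates on protein-level reporter intensities from a
4-plex TMT proximity-labeling design: a no-ligase control, a spatial
control targeted to the bait's compartment, and two independent bait
replicates. Its core is an empirical decision rule, not a statistical
test: no distributional assumption is placed on the enrichment ratios,
and no p-values are produced. Instead, a curated set of proteins that
*cannot* be bait-proximal (an irrelevant compartment, e.g. ER membrane
for a nuclear bait) serves as a null population measured under identical
conditions, and the cutoff is placed at an order statistic of that
population's observed ratios.

Formally, for false-positive ratios r₁ ≤ … ≤ rₙ and target rate α, the
cutoff is the smallest observed value c with
|{i : rᵢ > c}| / n ≤ α — the (n−k)-th smallest ratio, k = ⌊αn⌋.
Properties that follow and are enforced by tests:

* **Guarantee.** The achieved FPI never exceeds α, for every input
  including heavy ties (strict exceedance can only shrink when values
  collide).
* **Minimality.** Any smaller candidate cutoff would admit more than a
  fraction α of the null population (verified against exhaustive
  search).
* **Monotonicity.** A stricter target gives a cutoff at least as large
  and a survivor set that is a subset of the looser target's.

Candidate cutoffs are restricted to observed false-positive values: the
data give no basis for interpolating between order statistics, and any
interpolated cutoff admits exactly the same survivor sets.

Each replicate's cutoffs are derived from that replicate's own ratio
table. The final proteome is (filter1 ∩ filter2) per replicate,
intersected across replicates, ranked by the mean spatial-control
log2 ratio across the two replicates. Ranking on the spatial-control
axis was an open design choice; it is the axis on which "proximal to the
bait specifically" is defined, whereas the no-ligase axis mixes in
compartment-generic labeling. False-positive list members that pass all
filters are retained and tagged `fp_list:<name>` — the lists calibrate
the cutoffs, they are not blacklists.

## Upstream normalization and hygiene

* Proteins with ≤ 2 unique peptides are removed first (strictly more
  than `min_unique` survive; the threshold is configurable).
* Channel medians are equalized before ratio formation: each channel is
  divided by its median positive intensity and rescaled by the median of
  the per-channel medians. Using the median-of-medians as the grand
  scale (rather than the pooled median) makes the operation exactly
  idempotent. Equal channel loading is the experimental intent, so
  residual median differences are treated as technical. Normalization
  can be switched off.
* Zero intensities are never imputed. A protein with a zero in either
  channel of a ratio is dropped from that table and counted in
  `n_dropped`; parsing likewise never silently drops a row.

Replicate-agreement QC is an ordinary least-squares fit of replicate 2's
ratios on replicate 1's over their shared proteins, reporting the
squared Pearson correlation, slope and intercept. The default
comparison space is the vs-no-ligase ratio (both replicates against the
common reference channel); this is configurable
(`PipelineConfig.correlation_axis`) since the choice of axis for this QC
is a convention, not part of the filtering contract.

## The synthetic-data generator

The generator emulates the screening conditions the pipeline is designed
for, with known truth labels. Log2 intensities are Gaussian
(intensities log-normal — the standard rough model for reporter-ion
data): for protein *i*, channel *c*,

    log2 I[i,c] = b_i + E(class_i, c) + d_i[c] + ε[i,c]

* `b_i ~ N(base_log_intensity = 16, base_sd = 2)` — protein abundance,
  cancels in every ratio.
* `E` — the class/channel effect matrix. All labeled classes gain
  `bait_vs_noligase_effect = 3` log2 units in ligase-containing
  channels over the no-ligase control; true proximal proteins gain an
  additional `bait_effect = 2` in the bait channels; the bait itself
  gains `bait_self_factor × bait_effect` (factor 2), making
  self-labeling the strongest signal, as observed for ligase fusions.
  Contaminants are elevated by 3 log2 units in *all* channels, so their
  ratios center on zero and the no-ligase filter axis is what removes
  them. ER-/cell-membrane false-positive classes carry exactly the
  background profile — their ratio distributions are exchangeable with
  background by construction, which is what makes them valid calibration
  populations.
* `d_i` — per-protein effect deviations on the two bait channels,
  bivariate normal with sd `effect_sd = 0.2` and correlation
  `replicate_rho = 0.9`: protein-level biology that reproduces (or not)
  across independent labeling experiments. `effect_sd` is kept below
  the measurement noise because independent bait replicates in such
  designs are reported as highly concordant.
* `ε` — i.i.d. per-channel noise, `noise_sd = 0.5` log2 units.

Unique-peptide counts are `1 + Poisson(peptide_lambda − 1)` with
`peptide_lambda = 8`, so the >2-peptide filter removes a small, tunable
fraction; the bait's count is shifted up by 16 because a very large
fusion protein yields far more tryptic peptides than average. One RNG
stream with a documented draw order (abundances, deviation pairs, noise
matrix, peptide counts) makes output bit-identical for a fixed seed.

Default class sizes — 2000 background, 25 true proximal, 150 + 150
false positives, 50 contaminants — describe a background-dominated
nuclear proteome in which the filters must achieve a large (here
~100-fold) reduction.

### What the generator does not emulate

Missing values, peptide-level variation and rollup, isotopic-impurity
leakage between channels, batch effects, abundance-dependent noise, and
compositional distortions of real TMT data. Passing recovery tests on
this generator therefore shows the *decision rule* behaves as designed
under its stated noise model, not that any particular real dataset will
yield the same recall.

### Known limitation: recall under the default noise

With per-channel noise of 0.5 log2 units, a ratio carries √2·0.5 ≈ 0.71
units of noise, while the cutoff sits near the 97th percentile of a null
population with the same spread. A true proximal protein's margin is
`bait_effect = 2`, so a single filter passes ≈ 80 % of true proximals —
and the final list requires four passes (two filters × two replicates)
whose noise is only partially shared. Measured recall at the defaults is
therefore ≈ 0.6, while precision stays ≈ 0.9: the intersection design
trades sensitivity for specificity, exactly as intended for generating a
high-confidence candidate list. Larger effects, lower noise, or more
replicates raise recall; loosening α raises it at the cost of the FPI
guarantee being looser too. For the same reason the bait, whose margin
over true proximals is 2 log2 units against a ~0.9-sd ranking noise,
tops the list in ≈ 80 % of simulated runs rather than always.

## GO-category tagging

Categories are defined operationally as case-insensitive substring
matches on GO term *names*: phosphatase ("dephosphorylation"), protein
quality control ("proteasome", "ubiquitin", "protein folding"), nuclear
import ("import into nucleus"), mitochondria ("mitoch"), cell division
("cell division", "mitotic" — the exact keyword set behind published
cell-division highlights is not standardized, so this rule is explicitly
configurable). No ontology-graph propagation is attempted; the substring
rule is transparent and reproducible, at the cost of missing synonyms.
Tagging is idempotent, order-independent and monotone in the rule set;
category counts exclude the bait.

## Numerical and interface choices

* Ratios are computed from the protein-level intensities as given;
  peptide-level re-rollup is out of scope.
* All result tables are delimited text with `repr`-formatted floats, so
  re-running on identical inputs is byte-identical and read∘write is the
  identity.
* The run manifest records the configuration, package version and
  SHA-256 of every input — enough to re-run bit-identically. No
  timestamps are written.
* Exit codes: 0 success, 2 configuration/validation error, 1 runtime
  error. Plot failures are logged, never fatal; tables are the record.
* Problem sizes in the test suite: most tests run on a few-hundred
  protein simulation; convergence checks use 5,000–10,000 proteins;
  recovery statistics average 20 seeds at the full default size (2,376
  proteins). These sizes give the quoted tolerances comfortable margins
  under the law-of-large-numbers bounds stated in each test.
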