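# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `pathscreen`, and what the test suite does and does not
demonstrate about real data.

## Gene-state inference

Each gene's expression vector across samples is modelled as a two-component
gamma mixture. The low ("down", unexpressed) component is initialised as an
exponential — shape 1, a special case of the gamma — with its shape free
during fitting; the high ("up", expressed) component is a larger-mean gamma.
The fit is by EM:

- **E-step** in log space: responsibilities from the two weighted gamma
  log-densities, with the usual max-shift for numerical stability.
- **M-step** by weighted maximum likelihood per component: the scale has the
  closed form θ = mean_w(x)/k, and the shape solves
  ln k − ψ(k) = ln mean_w(x) − mean_w(ln x) by Newton iteration on ln k
  (the objective is monotone in k, so the iteration is safe from any
  positive start; Minka's closed form seeds the very first solve). A
  moments-based M-step would be cheaper but would not preserve EM's
  monotone-likelihood guarantee, which the test suite asserts on every fit.
- **Initialisation** is deterministic: split at the median, method-of-moments
  gamma on the upper half, exponential scale from the lower half, weight
  0.5. No random restarts are used; at the separations typical of bimodal
  expression the likelihood surface is benign, and determinism makes every
  downstream artifact a pure function of the input and seed.
- **Convergence**: relative log-likelihood change < 1e-6, cap 500
  iterations. Component labels are ordered by mean on exit, so "up" is
  always the larger-mean component regardless of the initialisation path.

Model selection between one and two components uses
BIC = −2·logL + k·ln n with k = 2 for the single gamma (shape, scale) and
k = 5 for the mixture (two shapes, two scales, one weight); ties go to the
single component. For mixture genes the UDP is the up-component posterior;
by construction UDP and 1 − UDP sum to one.

Degenerate inputs: a constant vector cannot support a gamma fit and is
refused; in matrix-level computation such genes are flagged, not fatal.
Values ≤ 0 (RPKM-style zeros) are shifted up by half the gene's smallest
positive value before fitting, since gamma support is (0, ∞); RMA-style
microarray values are already positive and pass through unchanged.

**Single-component genes** have no within-cohort contrast, so their UDP is
assigned uniformly: 1 when the gene's mean exceeds the cohort-wide median of
per-gene means, else 0. This is the simplest monotone rule consistent with a
gene being "up" or "down" across all samples; it is configurable
(`single_component_rule="half"` assigns 0.5 instead). The rule's failure
mode is a gene whose mean sits near the cohort median: trivially different
datasets can flip its uniform value, which is one reason cross-platform
model-selection stability needs a reasonably sized cohort (see the
robustness section below).

## Pathway activity

Interaction activity is the product of activator UDPs and inhibitor
complements (1 − UDP); pathway activity is the arithmetic mean over the
pathway's interactions. Genes absent from the UDP matrix contribute a
neutral factor 1 rather than 0 — annihilating an interaction because of a
platform coverage gap would conflate missingness with repression — and
per-pathway coverage (fraction of interactions with at least one measured
gene) is reported so users can filter thinly measured pathways. An
interaction with no measured gene at all is excluded from the mean, and a
pathway with no measured interaction is dropped with a warning.

Every input is a single gene with a role; there is no complex/family-node
propagation and no interaction weighting. GMT import represents each member
gene as a single-input activator interaction, which makes the pathway score
reduce exactly to the mean member UDP — a useful oracle and a reasonable
semantics for flat gene sets.

For qPCR validation assays, ΔΔCt fold changes (2^−ΔΔCt against a reference
gene and calibrator sample) are converted to a pseudo-UDP by min–max
rescaling each gene's log2 fold changes across conditions into [0, 1], with
0.5 for a zero-range gene, then scored by the same pathway machinery. The
min–max choice is the weakest assumption that lands fold changes on the
probability scale; it needs at least two conditions and is sensitive to the
condition set, which is inherent to any per-experiment rescaling.

## The association screen

Thresholds (all in `ScreenConfig`, defaults as listed): sensitivity
z ≤ −1.5, resistance z ≥ 0, promiscuity 20% (drug screens only),
per-tissue minimal-AUC cut-off 8 (drug screens only; `None` disables),
pathway activity range 0.1, minimum 3 lines per test arm, tiers q ≤ 0.05
and q ≤ 0.25. z-scores use the sample standard deviation (n − 1). The
boundary cases are inclusive on both labels (z = −1.5 is sensitive, z = 0 is
not sensitive); the excluded band keeps intermediate responders out of both
arms. The promiscuity filter is applied once, after classification, without
re-running classification on the reduced panel (configurable), and the
pathway-variance filter commutes with classification, which the suite
checks. Essentiality screens reuse the z thresholds and skip both
drug-specific filters.

Mann–Whitney: with both arms ≤ 8 the two-sided p comes from exact
enumeration of all group assignments, using midranks so ties are handled
correctly (p = P(|U − μ| ≥ |u − μ|) under the permutation null); larger
groups use the normal approximation with tie and continuity correction.
Exhaustive enumeration over every tie-free 8v8 outcome shows the
approximation is within 0.0109 of exact everywhere (worst at p ≈ 0.5) and
within 0.01 in the p ≤ 0.25 region, so the crossover at 8 never moves a
tier boundary materially. BH q-values are the standard step-up with
monotone enforcement, computed per tissue over all of that tissue's tests;
an optional family size m supports correcting a subset of a declared
family. Direction is the sign of the sensitive-minus-not-sensitive median
activity difference, and cross-platform intersection requires the same
direction in both platforms — a biomarker flipping sign is not a
replication.

## Robustness analyses

The cross-platform comparison z-scores each feature within each dataset
(putting genes on the same scale as [0, 1]-bounded pathway activities) and
records the per-feature Euclidean distance between its two profiles;
gene-vs-pathway distance distributions are compared by the same
Mann–Whitney kernel as the screen. Raw (un-normalized) mode is retained for
audit. The negative control shuffles gene identities by one seeded global
permutation per library — preserving interaction topology, roles and
per-pathway gene counts — drawn independently per platform: a shared
permutation would preserve cross-platform agreement and could not show that
biologically meaningless groupings lose it.

Cluster validity is computed in the original feature space with known class
labels (never on a 2-D embedding): silhouette and Calinski–Harabasz via
scikit-learn, and the Dunn index in its classical form (minimum pairwise
inter-cluster distance over maximum intra-cluster diameter). QQ data uses
expected quantiles (i − 0.5)/m with a 1e-300 floor before −log10. The
down-sampling power curve re-runs the full screen on seeded
without-replacement subsets (default 10 replicates per size) and counts
pathways at q < 0.25.

## Evaluation metrics

dr-AUC is the trapezoidal area of fractional viability over unit-spaced
concentration indices — no parametric curve fit — anchored so that a flat
100%-viability 16-point curve scores 15 and complete kill scores 0; values
above n − 1 indicate drug-induced proliferation. ROC AUC is the
probability a positive outranks a negative with 0.5 for ties, identical to
U/(n₁·n₂), with a flag for the low-score-positive orientation. The Bliss
index is observed combination viability over the independence expectation
v_A·v_B — the ratio convention is the one under which a fixed 0.5 synergy
threshold is meaningful — undefined (and non-synergistic) when the expected
viability vanishes; the threshold is configurable.

## Synthetic data and what the tests show

The generators emulate the structure each stage assumes, not the marginal
distributions of any real panel:

- **Expression**: per-gene mixtures of Γ(1, 1) and Γ(25, 0.5) (means 1 vs
  12.5 — separated enough that EM-recovery checks are sharp; a weaker
  Γ(6, 0.5) preset exists for stress tests), up-weight uniform on
  (0.2, 0.8), genes independent. Default 40% of genes bimodal.
- **Matched platforms**: a monotone power transform (1.2·x^0.9) of the
  shared latent values times log-normal noise (sd 0.2). The default
  cross-platform comparison cohort is 120 samples: per-gene BIC model
  selection needs a cohort of that order to be stable across platforms, and
  the many-hundred-line panels this emulates are larger still. At 40
  samples, model-selection flips between platforms dominate the pathway
  distances and the gene-vs-pathway contrast washes out — itself a useful
  caution about running cross-platform pathway comparisons on small
  cohorts.
- **Drug screens**: planted (tissue, pathway, direction) triples tie
  sensitivity to the implicated 30% pathway-activity tail; sensitive lines
  draw dr-AUC from N(4, 1), all others N(12, 1), clipped to [0, 16].
  Unplanted compounds are pure null. Planting at pathway-activity level
  rather than single genes mirrors the working hypothesis that the signal
  lives at pathway level.
- **Essentiality screens**: planted lines ~ N(−2.5, 0.5), others N(0, 1).
  Note a structural consequence of the classifier: after per-entity
  z-scoring, a 30% planted tail sits near z ≈ −1.2, above the −1.5 cut, so
  planted essentiality effects of this size are usually under-labelled at
  n = 40 and rarely reach q ≤ 0.25 within a per-tissue BH family; the
  suite asserts the attainable property (the planted pair dominates by raw
  p whenever testable). Drug-screen effects (~8 response-sd units) do not
  suffer this.
- **Tumor/normal cohorts**: member genes of designated pathways get their
  up-weight raised by the shift in tumor samples (capped at 0.95), forcing
  a pathway-level contrast on top of shared gene-level structure.

Null-screen FDR tests disable the minimal-AUC compound filter: a pure null
has no responsive compound by construction, so the filter would empty the
screen and make the check vacuous; disabling it only adds tests that could
produce false discoveries.

Problem sizes used by the default suite: 30 pathways over 300 genes with
cohorts of 40 (screens) or 120 (cross-platform) samples; 50 pathways over
400 genes with 30 lines for the 100-replicate null-FDR run; 50 replicates
of n = 1000 for EM recovery. These sizes make every statistical check
decisive while keeping the full suite around a minute.

Passing tests demonstrate internal correctness and qualitative reproduction
of the pipeline's statistical phenomena under the generative model above.
They do not demonstrate performance on real panels: real expression has
correlated genes, batch effects, heavier tails and pathway overlap far
beyond the generator's independence assumptions, and real response data
have dose-range artifacts the clipped normals do not imitate.

## Known limitations

- No >2-component mixtures and no per-tissue stratified fitting; the
  mixture is fitted across all samples of a dataset.
- The flat gene-input interaction model ignores complex/family nodes and
  any process hierarchy in the source pathway databases; the
  `pathway_table` TSV dialect is this package's normalization of such
  content, not a reconstruction of any vendor format.
- The uniform 0/1 UDP rule for single-component genes is discontinuous at
  the cohort median (see above).
- dr-AUC assumes unit-spaced concentration indices; actual molar
  concentrations are not modelled.
- The Bliss ratio index is undefined when either single agent kills
  everything; such pairs are flagged rather than scored.
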