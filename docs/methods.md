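# Methods

## Model and procedure

`rmtnet` builds an unweighted co-occurrence network from an OTU x sample
abundance table and characterizes it.  The only modelling assumption in the
construction phase is that pairwise Pearson correlation of standardized
abundance profiles is a meaningful similarity, and that the eigenvalue
fluctuation statistics of the thresholded similarity matrix separate noise
from structure: correlated eigenvalues (GOE / Wigner–Dyson spacing law)
indicate residual random coupling, uncorrelated eigenvalues (Poisson law,
P(d) = exp(−d)) indicate a matrix dominated by system-specific, roughly
block-diagonal structure.  The threshold scan therefore looks for the
GOE → Poisson transition and is entirely data-driven: no threshold, p-value
cutoff on correlations, or network density is chosen by the user.

Standardization uses the population denominator (divide by m, not m−1);
the choice cancels in every Pearson correlation computed downstream and is
fixed for reproducibility.  "Present in a sample" for the prevalence filter
means strictly positive abundance.  Missing values are rejected in
abundance tables (the correlation model assumes complete profiles) and
handled pairwise-complete in trait tables.

## Threshold detection details

* **Scan schedule.** Coarse ascent from 0.3 in steps of 0.1 until the
  Poisson null is first accepted; fine ascent over the last coarse interval
  in steps of 0.01; the smallest accepted fine threshold wins.  The scan
  aborts ("no RMT transition") if the retained matrix falls below
  `min_matrix_size` (default 50) OTUs or the threshold exceeds 0.99.
* **Spectrum.** Eigenvalues are taken from the weighted thresholded matrix
  (entries ≥ s_tb kept at their value, diagonal 1) rather than the
  binarized adjacency: binarization discards the spectral signal the test
  depends on.  A switch is not exposed because the binarized variant is
  strictly less informative at equal cost.
* **Degeneracies.** Eigenvalues closer than 1e−8 are collapsed before
  unfolding; exact ties produce artificial zero spacings that mimic Poisson
  clustering.
* **Unfolding.** Default: cubic least-squares spline fitted to the
  cumulative eigenvalue count, knots at every 15th order statistic.  The
  knot spacing was calibrated against the nominal test size: with knots at
  every 10th eigenvalue the spline partially follows the eigenvalue
  staircase, which distorts the spacing fluctuations and inflates the
  χ² test's type-I error to ≈ 4%; every 15th gives ≈ 1.3% (nominal 1%)
  uniformly over matrix sizes 60–500 while the rejection rate on GOE
  matrices stays at 100%.  A moving-average density estimate
  (`local_average`) is available as an alternative; it is slightly
  anti-conservative (≈ 9% type-I at n = 500) and not the default.
* **χ² test.** Spacings are histogrammed on [0, max d] with
  ceil(sqrt(n)) uniform bins; expected counts come from the unit-rate
  exponential (no parameters are fitted after unfolding — the unfolded mean
  spacing is 1 by construction); the tail mass beyond max d is pooled into
  the last bin and bins are merged from the right until every expected
  count is ≥ 5 (deficient bins always form a right-tail suffix under the
  exponential).  Degrees of freedom u = #bins − 1; H0 is accepted when
  χ² ≤ χ²_u(α), α = 0.01.

## Topology conventions

Shortest-path sums (betweenness, stress) run over unordered node pairs
{j, k}, j ≠ k ≠ i, endpoints excluded.  GD averages geodesics over
reachable pairs only; efficiency E uses 1/d = 0 for unreachable pairs, so
HD = 1/E is the disconnection-safe distance summary.  Degree
centralization is normalized by (n−1)(n−2); betweenness, stress and
eigenvector centralizations are normalized by the corresponding sum
attained by the same-size star graph, computed numerically on that star.
The star maximizes degree and betweenness centralization (so CD, CB ≤ 1)
but not necessarily stress centralization; CS can exceed 1 on networks
with heavy path multiplicity and should be read as "relative to a star".
Eigenvector centrality is the leading eigenvector of the largest connected
component's adjacency matrix (unit Euclidean norm, non-negative); nodes
outside that component get 0.  CC_i = 0 for nodes with fewer than two
neighbours.  Vulnerability V_i = (E − E_i)/E recomputes efficiency over
the n−1 surviving nodes.

Power-law (scale-free) and C(k) ~ k^−γ (hierarchy) relations are fitted by
OLS on log–log points, requiring ≥ 3 distinct degrees (k ≥ 2 and mean
CC > 0 for the scaling law); fewer points yield an explicit undefined-fit
flag rather than a number.

## Modules, roles, eigengenes

Modularity uses the standard Newman form M = Σ_b [l_b/L − (K_b/2L)²]
(consistent with the stated range [−1, 1]).  Fast-greedy agglomeration
starts from singletons and repeatedly applies the largest-gain merge until
no merge increases M; among equal-gain merges the lexicographically
smallest module-label pair (labels = smallest member id) is taken, making
the result deterministic.  With ties, different max-gain branches can end
at different M, so no deterministic tie-break dominates all others; the
declared rule is fixed and reproducible.  Leading-eigenvector and
short-random-walks backends are delegated to igraph; simulated annealing
(geometric cooling 0.995, initial temperature set so a median uphill move
accepts with probability ~0.5, seeded) directly maximizes M from the
greedy solution.

Node roles use z_i (within-module degree z-score, population sd over
module members; z = 0 when the sd is 0) and the participation coefficient
P_i, with the boundaries z = 2.5 and P = 0.62 defining peripheral /
connector / module hub / network hub.

Module eigengenes come from the economy SVD of the standardized member
matrix; the leading right-singular vector's sign is flipped so its mean
correlation with member profiles is positive, making E^b an interpretable
average profile.  Φ_b = d₁²/Σd² equals the leading eigenvalue share of the
member correlation matrix (PCA–SVD identity on standardized rows).
Eigengene analysis is restricted to modules with ≥ 8 members by default;
a Φ below 0.30 triggers a warning, never a failure.  Meta-modules are
average-linkage clusters of eigengenes at dissimilarity 1 − r below 0.3
(i.e. r > 0.7); the cut height is configurable.

## Null models and statistics

Maslov–Sneppen rewiring performs double-edge swaps, rejecting self-loops
and duplicate edges, targeting 10 accepted swaps per edge with an attempt
cap of 100 per edge (a graph with no valid swap, e.g. a triangle, returns
unchanged and is logged).  Ensembles (default 100 networks) supply the
mean and sd per index; Z uses the two-sided normal approximation.  An
ensemble of bitwise-equal values (degree-determined indices such as avgK
and density) can report an sd of ~1e−15 from round-off; sds below
1e−10 x |mean| are treated as zero and the index flagged
degree-determined with Z = 0.  Two networks are compared per index with a
Welch t-test built from their ensemble means/sds.

Mantel tests correlate the lower triangles of two distance matrices; the
permutation p-value is one-tailed (greater), p = (1 + #{r_perm ≥ r_obs}) /
(n_perm + 1), default 999 permutations, seeded.  The GS distance matrix is
Euclidean over the selected trait columns of the GS matrix; the
connectivity distance is |k_i − k_j|.  The partial Mantel test uses the
method of residuals (both triangles regressed on the control triangle,
permutations applied to the first matrix with residuals recomputed);
residual sds below 1e−10 of the input sd are treated as zero and flagged,
since an input affinely identical to the control leaves only regression
round-off.

## Synthetic communities

The generator emulates the shape of a prevalence-filtered amplicon
dataset: a few blocks of strongly co-varying OTUs driven by latent
per-sample factors, a majority of independent background OTUs, strictly
positive abundances, per-sample normalization, and traits that are linear
in chosen block drivers plus noise.  Defaults — 4 blocks x 20 OTUs + 120
background OTUs, 30 samples, within-block pairwise |r| = 0.9, trait noise
sd 0.5 — give a community of realistic scale (a few hundred OTUs, tens of
replicates) whose four blocks the full pipeline recovers exactly.

Two deliberate constructions keep the ground truth sharp:

* the raw factor draws are orthogonalized in-sample (QR against the
  intercept and each other, rescaled to unit sd), because at m = 30 chance
  correlations between independent draws reach |r| ≈ 0.5 and would merge
  planted blocks, making "truth" ill-defined;
* member profiles x = √ρ·f_b + √(1−ρ)·ε are exponentiated to abundances
  exp(x/2), and since that transform attenuates correlation
  (corr(e^{X/2}, e^{Y/2}) = (e^{ρ/4}−1)/(e^{1/4}−1)), the latent ρ is
  pre-compensated as ρ = 4·ln(1 + r·(e^{1/4}−1)) so the abundance-scale
  within-block correlation equals the requested value in expectation.

What the generator does **not** emulate: zero inflation, sequencing-depth
count noise, compositional closure effects beyond simple normalization,
and phylogenetic correlation among OTUs.  Tests passing on these fixtures
therefore demonstrate the correctness and calibration of the machinery,
not performance on every pathology of real amplicon data.

## Problem sizes and determinism

The test suite and the reproduction script run the generator at its
default size (200 OTUs x 30 samples), calibration experiments at p = 500
with 100 trials per ensemble, null ensembles of 30–100 networks, and
Mantel tests with 199–999 permutations — sizes at which every quantity is
stable yet the whole suite completes in a couple of minutes.  Every source
of randomness takes an explicit seed; rerunning any entry point with the
same seed reproduces its outputs bit for bit.

## Known limitations

* Only unweighted networks are analyzed; edge weights (the similarity
  values) are carried as annotations but do not enter the indices.
* The NNSD test needs ≥ 50 retained OTUs (configurable) to be meaningful;
  very small communities cannot use the automatic threshold.
* On data with no block structure the scan may still accept Poisson
  statistics once only sparse chance correlations survive — a
  near-diagonal matrix genuinely has uncorrelated eigenvalues.  The
  resulting network is small and structureless; interpreting it is the
  analyst's responsibility (compare against the null ensemble).
* Per-subset Mantel tests on very few nodes (< ~10) are statistically
  fragile; the package only enforces n ≥ 4.
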