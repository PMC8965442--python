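# Methods

## The model

`switchnet` treats a case/control expression matrix as the observable of a
two-layer structure: groups of co-regulated genes (modules) driven by
shared latent activity, plus a small class of *switch genes* that sit
between modules and move against their network neighbourhood. The pipeline
estimates that structure in five stages, each with a small number of
interpretable tunables.

### Differential filter

Genes with no or low expression are removed first: a gene is kept when the
fraction of samples with log2 expression ≥ `min_mean` (default 1.0)
reaches `min_fraction_expressed` (default 0.5). Setting the fraction to 0
disables the step. The differential statistic is the log2 fold change
(case mean − control mean on the log2 scale) combined with a two-sided
unequal-variance (Welch) t-test and Benjamini–Hochberg correction. The
test behind the FDR step is a deliberate design choice: Welch on log2
values is the standard two-group comparison for expression arrays, and
`alpha = 1` disables it entirely, leaving a pure fold-change filter.
Retention requires both `|log2FC| ≥ log2(fold_change)` and `q ≤ alpha`
(default 0.05). Fold-change thresholds are dataset-specific by design —
tighter thresholds for noisier or larger platforms — so `fold_change` is a
first-class per-run parameter rather than a constant.

Degenerate genes (zero variance in both groups) get p = 1 when the group
means agree and p = 0 otherwise.

### Correlation network

Pearson correlation is computed over all samples pooled (a subset flag
allows case-only or control-only networks). The graph keeps an edge where
`|r| ≥ threshold` and stores the *signed* correlation as the weight:
negative edges are what make fight-club hubs detectable, so absolute-value
thresholding with signed weights is essential. Zero-variance genes are
dropped with a warning. Isolated nodes stay in the node set, flagged.

The threshold itself is the one genuinely free parameter of the pipeline
and is always logged. Two policies exist:

* `"auto"` (default for real data): the smallest value on the grid
  0.50–0.95 (step 0.05) whose graph density is ≤ 10%. A density cap keeps
  the cartography meaningful on large transcriptome-wide networks.
* a fixed value. The planted benchmark uses **0.6**, chosen from the
  closed-form planted correlations (within-module ≈ 0.94, switch–member
  ≈ 0.8, the case/control-axis correlation between modules ≈ 0.4): 0.6
  separates real structure from the disease-axis background. The density
  rule is inappropriate there — a graph of four 25-gene cliques has
  density ≈ 0.22 by construction, so the cap can only be met by shattering
  the cliques.

### Communities

Community detection is expression-driven, not topology-driven: graph
nodes are clustered by Lloyd k-means on per-gene z-scored profiles
(population sd; flat profiles map to zero). Each k runs `replicates`
(default 10) independent k-means++ initializations; the replicate with the
smallest within-cluster SSE wins. Replicate seeds are a prefix sequence,
so increasing the replicate count can only improve the best-of-replicates
SSE. The community count comes from the elbow of the best-of-replicates
SSE scree curve: the interior candidate maximizing perpendicular distance
to the chord joining the curve's endpoints, ties toward smaller k. A flat
curve returns the smallest k with a warning; a perfectly linear decline
returns the smallest interior k with a warning. `k` can always be fixed
explicitly.

### Cartography and switch calls

For node *i* with community C(i):

* `Zg(i) = (κ_i − mean_C κ) / sd_C κ`, where κ counts edges to
  same-community nodes; population sd; a zero-spread community maps to
  Zg = 0 by convention (avoids division blow-ups in tiny communities).
* `Kπ(i) = 1 − (k_in/k_tot)²`; isolated nodes map to 0.
* `APCC(i)` = mean Pearson correlation between *i*'s profile and its graph
  neighbours' profiles; undefined (NaN) for isolated nodes, which are
  excluded from the hub taxonomy.

Hub classes split on APCC: fight-club < 0 ≤ date < 0.5 ≤ party. The 0.5
date/party split is configurable ("low positive" vs "high positive" is a
convention, not a law). The (Kπ, Zg) plane splits into seven role regions:
non-hub rows (Zg < 2.5) at Kπ ∈ {0.05, 0.62, 0.8} into R1–R4, hub rows at
Kπ ∈ {0.30, 0.75} into R5–R7. Only the R4 cell is consequential — it is
pinned to the switch definition — and the inner boundaries are
config-exposed. Nodes with Zg > 5 are additionally flagged as network
hubs.

Switch genes are called by the strict triple `Zg < 2.5 ∧ Kπ > 0.8 ∧
APCC < 0`; boundary nodes are logged and excluded. By construction the
switch set ⊆ fight-club set ⊆ {APCC < 0}.

Switch-gene expression is biclustered for display: average linkage with
correlation distance (1 − r) on rows and Euclidean distance on per-gene
z-scored columns, leaf orders by scipy's left-before-right traversal,
dendrograms exportable as Newick text.

### Robustness

Average shortest path (ASP) is the mean breadth-first distance over
reachable unordered pairs, computed on the largest connected component
when removal disconnects the graph (the alternative — harmonic mean over
all pairs — is deliberately not used so the y-axis remains an ordinary
path length; the choice is logged per run). Removal strategies: `random`,
`degree` (descending, static order), and the class strategies `date`,
`party`, `fight_club`, `switch`, removed in seeded random order because no
canonical within-class order exists. When strategies are compared, all
curves share one fraction grid spanning [0, f_max], where f_max is the
smallest class pool fraction, so the areas under the curves are directly
comparable.

### Downstream

Over-representation is the upper-tail hypergeometric test
`p = P(X ≥ overlap)` with BH correction across sets; zero overlap reports
p = 1 (no vacuous significance). The background defaults to the genes
surviving preprocessing for the dataset — the measured-gene background is
the defensible default when no annotation-platform background is
available. Regulator ranking restricts a regulator→gene edge table to
switch-gene targets, keeps regulators present in ≥ `min_sources` distinct
source databases (the multi-database Venn consensus), and sorts by target
degree, then unnormalized betweenness on the undirected bipartite graph
(no projection is invented), then id. Cross-dataset comparison is an exact
membership table with a shared-by-exactly-n summary that partitions the
union.

No pathway, TF, miRNA or chemical database content ships with the
package; users supply GMT and edge-table snapshots.

## The synthetic generator

The generator emulates exactly the structure the pipeline assumes, with
full ground truth:

* per sample, module m has latent activity `f_m ~ N(0,1)`, mean-centred
  within each sample group so the module structure is orthogonal to the
  disease axis and the planted fold change is exact (without centring,
  chance factor/group correlation adds `loading × Δf` to the realized fold
  change and can silently delete whole modules at the filter);
* a member of module m is `loading·f_m + noise_sd·ε + de_log2fc·case`;
* a switch gene spanning modules S (|S| ≥ 2, default 2, drawn at random)
  is `−loading·mean(f_S) + noise_sd·ε − de_log2fc·case`: anti-correlated
  with the members of every module it spans — the defining fight-club
  property — while still differentially expressed with |log2FC| equal to
  the planted shift. Giving switch genes the *opposite* shift mirrors
  their biology (they move against their partners) and is what makes the
  anti-correlation survive pooling cases and controls: with the same-sign
  shift the disease axis contributes `+de²/4` to every covariance and
  overwhelms the negative loading term (`−loading²/2`) at realistic effect
  sizes;
* noise genes are pure measurement noise `noise_sd·ε` with no shift, so in
  the noiseless limit the filter retains exactly the structured genes;
* every gene gets a baseline level ~ N(8, 1) log2 units, placing the
  matrix on a realistic scale without affecting correlations or fold
  changes.

Defaults — 4 modules × 25 genes, 5 switch genes, 50 noise genes, 10+10
samples, loading 0.9, noise sd 0.3, shift 1.5 log2 units — are the
strong-signal benchmark used by the test-suite and the acceptance script;
10 samples per group matches the larger cohorts of typical post-mortem
case/control series, and loading 0.9 with noise 0.3 gives within-module
correlations ≈ 0.9, at the strong end of what co-expression modules show
in practice.

What the generator does *not* emulate: probe effects, batch structure,
count noise (no negative-binomial layer), correlated noise between
modules, or hub-degree heterogeneity inside modules. Passing the recovery
benchmarks therefore demonstrates correctness of the machinery under the
model's own assumptions, not performance on any particular real platform.

## Benchmarks computed by tests and the acceptance script

* **Switch recovery**: median F1 of called vs planted switch genes over 20
  seeds of the strong-signal benchmark at threshold 0.6, with called ⊆
  fight-club in every run.
* **Module-count recovery**: the scree elbow vs the planted module count
  over 20 seeds at loading 0.9, noise 0.2, with no switch genes planted —
  switch genes are mutually correlated and anti-correlated with every
  module, so they form a genuine (n_modules+1)-th profile cluster and
  would make "recover n_modules" the wrong oracle.
* **Robustness ordering**: mean area under the fight-club removal curve vs
  random removal over 10 seeds on a shared fraction grid.
* **Filter exactness**: monotonicity of retention over the fold-change
  grid {1.5, 1.75, 2, 2.5, 3, 4, 4.5} and retained = planted DE set in the
  low-noise limit (noise 0.05, shift 2.0).

Every network statistic (Zg, Kπ, APCC, betweenness, ASP, BH FDR,
hypergeometric tail) is additionally checked exactly against independent
brute-force implementations (loop-based formulas, pair-dependency path
counting, Floyd–Warshall, literal step-up recursion, exhaustive draw
enumeration) on 100+ random instances each.

## Numerical conventions and limitations

* Population (n) standard deviations throughout the cartography and
  z-scoring; zero-spread cases map to 0 rather than NaN.
* All randomness flows from one integer seed through named
  `SeedSequence` substreams (k-means replicates, removal order), so
  partial reruns reproduce stage-by-stage.
* k-means uses scikit-learn's Lloyd implementation with one init per
  replicate; empty clusters cannot arise (centroid relocation), so the
  retry path is never needed.
* Switch genes require ≥ 2 spanned modules; with exactly 2 modules total a
  switch gene cannot link "mostly outside" whichever community it joins
  (Kπ ≤ 0.75 when half its edges are internal), so benchmarks use ≥ 3
  modules. Detection degrades gracefully rather than failing loudly when
  communities are badly mis-estimated.
* The correlation threshold remains the user's scientific decision on real
  data; the auto rule is a density heuristic, not an inference.
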