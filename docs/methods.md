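# Methods

## The procedure

`somscreen` implements class-structure discovery on replicated protein
panels in four stages: preprocessing, SOM clustering with multi-run
selection, cluster extraction with majority-class labeling, and
discriminant-protein screening with a subset-reclustering validation
loop. The design target is the eight-class CFC study layout (genotype ×
behavior × treatment, 7–10 mice per class, 15 replicate measurements per
mouse, 77 proteins), but nothing in the code is tied to those numbers.

### Preprocessing

Missing cells are imputed with the arithmetic mean of the protein over
all non-missing replicate rows of the same class — no finer grouping, so
a mouse with a dropped spot borrows strength from its whole class.
Imputation is idempotent and never touches observed values; a
(protein, class) pair with no observed value at all is an error rather
than a silent zero.

Outlier handling is deliberately two-step: `flag_outlier_mice` is purely
advisory (a mouse is flagged when more than a threshold fraction,
default 0.5, of its protein columns contain a missing cell), and
`drop_mice` executes an explicit exclusion list. Declaring a mouse an
outlier in practice mixes a missingness criterion with a qualitative
"values look wrong" judgement that should stay a human decision.

Min–max normalization maps every protein column onto [0, 1] over the rows
*currently in the dataset*. Because each experiment clusters a different
class subset, the column minima/maxima are recomputed after subsetting
(`subset` clears the normalized flag to enforce this). A constant column
maps to all zeros; the choice is immaterial since such a column cannot
influence clustering. Normalization is required because protein columns
span heterogeneous ranges (some 0–3, others 0–0.6) and Euclidean
distances would otherwise be dominated by the large-scale columns.

### The map

The SOM is a square n × n grid with hexagonal adjacency in "odd-r" offset
coordinates (odd rows shifted half a cell right; interior nodes have six
neighbors). The neighborhood kernel measures distance between node
centers in the planar embedding x = col + 0.5·(row mod 2),
y = row·√3/2, which is consistent with that adjacency.

Grid side: the smallest n with n² ≥ number of mice, so that — absent any
real structure — every mouse's 15 measurements could occupy a private
node and no artificial grouping is forced. Callers can override (one
catalogued experiment deliberately uses 8×8 for 26 mice to spread the
data out).

Training is batch SOM by default: per epoch, every sample is assigned to
its best matching unit (BMU; Euclidean distance, ties to the row-major
earlier node) and each node weight is replaced by the
neighborhood-kernel-weighted mean of all samples. Batch dynamics are
deterministic given the seeded uniform-[0,1] initialization, which keeps
every experiment exactly reproducible from (data, params, seed). An
online Kohonen variant (per-sample updates in seeded shuffled order,
learning rate 0.5 → 0.01) is available behind `scheme="online"`.

Schedule defaults and why:

| parameter        | default            | rationale |
|------------------|--------------------|-----------|
| epochs           | 400                | slow annealing measurably improves topology preservation: same-class nodes end up adjacent, so fewer pure nodes are orphaned into sub-threshold singletons and lost to the downstream test |
| initial radius   | side / 2           | standard coarse-organization scale |
| final radius     | 0.25 grid units    | the grid is sized one-node-per-mouse, and the rank-sum screen treats node weights as per-mouse prototypes; a terminal kernel still coupling adjacent nodes (e.g. radius 1) shrinks same-class prototypes toward their class mean and inflates the test's null rejection rate several-fold (measured: ~0.3–0.5 per null protein at radius 1.0 vs ~0.04–0.05 at 0.25) |
| neighborhood     | gaussian           | smooth annealing; `bubble` available |
| decay            | exponential        | conventional; reaches the terminal scale early enough to matter |

The average quantization error ε_q is the mean over *data samples* of the
distance to their BMU weight. (Descriptions of this quantity sometimes
say "N is the number of nodes" while summing over samples; dividing by
the node count would make ε_q depend on map size rather than fit, so the
sample mean is used.)

Multi-run selection trains `n_runs` (default 10) maps from consecutive
seeds `base_seed .. base_seed+n_runs−1` and keeps the minimum-ε_q map;
exact ties break by fewest mixed-class nodes, then fewest measurements in
mixed nodes, then lowest seed. Class labels enter only here and in
labeling — never during training.

### Labeling and clusters

Each node is labeled with the majority class of its content (ties break
to the lexicographically first class code and are recorded); a node with
two or more classes is *mixed*. A class cluster is (i) a connected
component, under hex adjacency, of two or more pure same-class nodes, or
(ii) a pure singleton in which one mouse contributes at least
`ceil(0.8 × nominal_replicates)` measurements (12 of 15 by default;
additional same-class measurements from other mice do not disqualify it,
other-class measurements do). Mixed nodes never join clusters. Purity is
evaluated at the measurement level, since measurements are the clustered
unit throughout.

### Discriminant screening

For a class pair, the per-protein samples are the node-weight components
of all accepted clusters of each class, pooled across clusters (a class
split into clusters of six and five nodes contributes eleven values).
Weight vectors, not raw measurements, carry the test because each
prototype summarizes the measurements clustered in it — effectively one
value per mouse-scale unit rather than 15 correlated replicates.

The two-sided Wilcoxon rank-sum (Mann–Whitney) p-value is exact (full
enumeration via `scipy.stats.mannwhitneyu`) when the combined sample is
≤ 20 and tie-free — the typical regime for 5–15 node clusters — and
otherwise uses a moment-corrected normal approximation: continuity
correction, tie-corrected variance, plus the Edgeworth fourth-moment term
of the null U distribution. The extra term keeps the approximation within
0.02 of full enumeration down to samples of three per side, where the
plain continuity-corrected normal errs by up to 0.0375.

Significance is declared at p < 0.05 per protein with *no*
multiple-testing correction, matching how such screens are read in this
setting; a Benjamini–Hochberg option (`correction="bh"`) exists but is
off by default. Consequence worth stating plainly: with 77 proteins and
an m-protein true set, the expected false-discovery proportion of an
uncorrected α = 0.05 screen is ≈ 0.05·(77−m)/(0.05·(77−m)+m) — about 7 %
when m ≈ 28 but over 15 % when m ≈ 12. Small discriminant sets therefore
carry proportionally more false positives by construction.

If a class required by a comparison has no accepted cluster on the
selected map, the comparison fails loudly; falling back to raw
measurements would change the meaning of the test. For one-vs-rest
contrasts on multi-class maps, the default pools the other classes' nodes
into a single sample (`mode="pooled"`); a `pairwise` mode intersecting
the pairwise significant sets is also provided, and results are labeled
with the mode used.

### Validation loop

`subset_validation` reruns the full loop (subset columns →
re-normalize → multi-run selection → label → clusters → mixed-node
stats) on a protein subset and on its complement, reporting the number of
proteins used, mixed-node counts for a focus class pair, and measurements
in those nodes. A genuinely discriminant subset keeps or improves the
separation of the groups it discriminates (between-group mixed nodes stay
at or below baseline); its complement loses the separation.

## The synthetic generator

`generate` draws a panel from a factor-structured hierarchical model:

    e_mjr = mu_j + sum_f delta_jf * sigma_j * x_f(class) + b_mj + eps_mjr

- `mu_j`: per-protein baseline, log-uniform over 0.6–3.0, reproducing the
  heterogeneous column ranges of real panels;
- `sigma_j = 0.2 * mu_j`: per-protein measurement scale;
- `x_f`: {0,1} indicators for learning (CS), drug (memantine), genotype
  (trisomic), and `:`-joined interactions;
- `b_mj ~ N(0, (0.7 sigma_j)^2)`: mouse-level effect, shared by all 15
  replicates of a mouse;
- `eps_mjr ~ N(0, (0.71 sigma_j)^2)`: replicate-level technical noise;
- values clipped at zero (a mild truncation of the normal model).

The default variance split weights biological (between-mouse) and
technical components equally (intraclass correlation ≈ 0.5) and makes the
pooled per-measurement SD equal to sigma_j, so planted effect sizes
`delta` are in pooled-SD units and scale-free across proteins. The
mouse-level term is essential: without it replicates would be i.i.d., the
≥12-of-15 singleton rule would be untestable in any realistic regime, and
the rank-sum screen's effective sample size would be misrepresented.

The default effect map plants main effects of size delta = 1.5 on
disjoint blocks sized like the discriminant sets such studies report:
28 learning proteins, 12 drug, 14 genotype. Ground truth for every
catalogued comparison is derived from the effect map alone (a protein is
truly discriminant for A vs B iff its summed planted effects differ
between the classes), so truth never depends on noise seeds.
`inject_missing` blanks cells i.i.d.; `inject_outlier_mouse` blanks 60 %
of one mouse's columns and shifts the rest by +5 pooled SD, emulating a
sample with mostly failed spots.

What the generator does **not** emulate: dilution-series/spot-level
physics, correlated proteins (real panels share pathways; columns here
are independent given class and mouse), heavy-tailed noise, and
batch/slide effects. Passing tests on synthetic data therefore
demonstrate that the machinery recovers planted, well-separated,
independent effects at study scale — not that the biological conclusions
drawn from any real panel are correct.

## Measured operating characteristics

At the study conditions (delta = 1.5, 8 mice/class, 15 replicates), the
acceptance tests compute: null calibration of the weight-set rank-sum
within 0.05 ± 0.03; sensitivity ≥ 0.9 and FDR ≤ 0.1 on the learning
contrasts averaged over five generator seeds; and the reclustering
contract (planted subset: zero between-main-group mixed nodes, no-effect
subset: at least one). Problem sizes in the test suite are chosen
desk-scale where exactness is asserted (enumeration oracles up to
12 pooled samples, 3×3/4×4 maps) and study-scale (480–960 rows) where
statistical behavior is asserted.

## Known limitations

- ε_q-based selection favors quantization quality, not topology quality;
  a topographic-error criterion is not implemented.
- The rank-sum screen inherits pseudo-replication when one mouse's
  measurements split across two nodes; slow annealing reduces but does
  not eliminate this.
- Exact ties in ε_q between runs are broken as documented but are
  essentially impossible in floating point; the tie-break matters mainly
  for reproducibility of the written rule.
- The spreadsheet dialect reads `.xlsx`; legacy `.xls` workbooks must be
  converted (or exported to CSV, the canonical format) first.
- No growing architectures, toroidal topologies, U-matrix segmentation,
  or pathway-database enrichment.
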