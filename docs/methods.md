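# Methods

## The scoring model

Each IHC staining annotation is a pair of ordinal labels, transformed to
numeric values: Intensity *I* ∈ {0, 1, 2, 3} for Negative/Weak/Moderate/
Strong and Quantity *Q* ∈ {0, 5, 25, 50, 75} for Negative/Rare/<25%/25–75%/
>75%. One staining contributes the expression level *I*×*Q* ∈ [0, 225]. The
quantity spelling "75%–25%" (and hyphen/en-dash variants) is normalized to
the token `25-75%` at read time.

A *mapping* pairs a cancer type with the normal tissue and cell type it is
compared against. The packaged registry defines 27 mappings over 20 cancer
types; ovarian cancer has none (normal ovary staining is unavailable), and
hepatocellular carcinoma and cholangiocarcinoma are distinct cancer types
even though both arise in liver. A cancer type may appear in several
mappings (different normal contexts); those sibling mappings share the same
cancer patient records.

Per (antibody, mapping): *EiN* is the level of the single normal annotation
(the source atlas reports exactly one normal Intensity/Quantity pair per
cell type, however many images underlie it); *EiC* is the mean level over
the cancer type's patient annotations (n ≥ 1, at most 12 patients per
cancer); *ED* = *EiC* − *EiN*. A cell of the antibody × mapping matrix is
*tested* only when both sides exist; untested cells are excluded from every
normalization, never imputed — imputing zeros would bias the mapping means
toward the untested mass.

Significance and specificity are cumulative-normal rank statistics:
SG = Φ(z_g) with z_g the ED z-scored within the mapping's column
(μ_g, σ_g over all tested antibodies of the mapping), and SP = Φ(z_p) with
z_p z-scored within the antibody's row (μ_p, σ_p over all its tested
mappings). The final score is EiC·SG·SP ∈ [0, 225]. Φ is the exact erf-based
normal CDF, not a lookup-table discretization.

## Numerical conventions

- σ_g and σ_p are **population** standard deviations (divide by N): the set
  of all tested antibodies of a mapping (or all mappings of an antibody) is
  the population being ranked, not a sample from a larger one. The sample
  convention (N−1) is available via `ScoringConfig(ddof=1)`.
- The target cell is **included** in its own normalization; there is no
  leave-one-out correction.
- A degenerate axis (σ = 0, all EDs identical) assigns SG/SP = 0.5: an axis
  that cannot discriminate neither rewards nor punishes.
- An axis with fewer than two tested cells is unscorable; such cells are
  omitted from the score table with a logged count.
- Within a mapping, ranks order antibodies by descending score with ties
  broken by ascending antibody id — stable and reproducible.
- Scores are scored with n ≥ 1 patients; `n_patients` is reported so users
  can filter on cohort depth themselves.

## Validation statistics

`top_k` selects the k highest-scoring antibodies of a mapping (default
k = 100). `validate_topk_means` compares, per mapping, the top-k mean EiC
and mean ED against the population means over all tested antibodies with a
one-sample t-test: t = (x̄ − μ₀)/(s/√n), s the sample SD (N−1), p from
Student's t with n−1 degrees of freedom. The default alternative is
one-sided ("greater") because the claim under test is directional — top
antibodies should be *more* abundant and *more* overexpressed; the
two-sided p is available via a flag. No multiple-testing correction is
applied across mappings; raw p-values are reported.

`ed_heatmap` builds the specificity matrix: cell (i, j) is the mean ED on
mapping i of the top-k antibodies selected for mapping j, skipping
antibodies untested on i (selected antibodies need not be tested
everywhere); the final "All" column holds population ED means and is
independent of k. With 27 mappings the matrix is 27 × 28. Mapping-specific
scoring shows up as diagonal dominance with off-diagonal cells near the
"All" column.

## Candidate filtering

Genes survive Rule 1 if any of their antibodies reaches the score threshold
(default 100, inclusive) in any target mapping — the maximum over a gene's
antibodies is used because filtering operates on proteins while scoring is
antibody-oriented, and one best score per gene is what gets reported.
Rule 2 requires mean fold change ≥ 2 (inclusive), averaged over the
patients with an available value (coverage is reported via the qualifying
count). Rule 3 requires fold change ≥ 2 in **strictly more** than 14
patients — a strict majority of a 28-patient cohort; a gene qualifying in
exactly 15 patients passes, in 14 does not. The eight combinations map to
the rule subsets ∅, {1}, {2}, {3}, {1,2}, {1,3}, {2,3}, {1,2,3};
combination 1 (no rules) defines the reference population: all cohort genes
indexed in the score table. Reported proportions are taken both within the
filtered set and against that population. External biomarker/disease
knowledge enters as a user-supplied per-gene flag table; the package does
not attempt to reproduce any proprietary annotation service.

## The synthetic-data generator

Ordinal annotations are simulated from a latent-Gaussian threshold model.
Per antibody, each cancer type draws a base level ~ N(0, 1) (latent units),
shared between the cancer and its mapped normal contexts — a tumor and its
tissue of origin express a protein at related levels; each normal context
deviates from the base by a tissue effect ~ N(0, 0.3). One normal staining
and 12 cancer stainings per cancer type add observation noise ~ N(0, 0.5).
All cancer samples receive a global shift of −0.2 latent units, encoding
the empirical trend that the bulk of proteins is mildly down-regulated in
tumors, so population ED means come out negative while true markers stand
out positive. Planted markers add a mapping-specific effect (3 latent SD in
the study conditions) to the cancer samples and draw their base level
uniformly from [−1, 0]: markers are modeled as low-but-detectable in normal
tissue, because at either end of the bounded 0–225 ordinal scale the
expression difference saturates away (a protein already saturated in normal
tissue cannot show overexpression on this scale — a genuine limitation of
ordinal IHC quantification, not of the generator). Latents are cut at
(−1, 0, 1) into intensity labels and (−1.5, −0.75, 0, 0.75) into quantity
labels, roughly quartile-like splits of the latent marginal.

All draws descend from one seed; each antibody uses the sub-stream
(seed, antibody index), so output is reproducible and stable under antibody
subsetting. The fold-change cohort simulator (28 patients by default) draws
per-patient log2 fold changes ~ N(0, 0.5) for null genes and ~ N(2, 0.5)
for planted genes, giving planted genes an expected mean fold change ≥ 2
and an expected qualifying-patient count far above half the cohort.
`cohort_from_summary` deterministically reconstructs patient-level tables
from per-gene (mean fold change, qualifying count) summaries, which is how
published per-gene evidence is turned into testable input.

### Study conditions and registries

Specificity (heat map) and recovery studies use
`independent_registry(27)` — 27 mappings with one distinct synthetic cancer
type each — rather than the packaged registry. With the real registry,
sibling mappings of one cancer type share patient cohorts, so a marker
planted for one sibling is genuinely overexpressed in the other as well and
strict diagonal dominance between siblings becomes a coin flip; the
independent registry keeps mapping columns statistically independent while
preserving the 27-mapping geometry. The packaged registry remains the
default everywhere else, and the generator reproduces the shared-cohort
structure when used with it.

Problem sizes used by the test suite: 2000 antibodies × 27 mappings with 4
planted markers per mapping for the top-100 t-test and heat-map regimes;
300 antibodies × 27 mappings × 20 seeds with 2 planted markers per mapping
for recovery (precision@2 averaged over seeds); 150–300 genes × 28 patients
for cohort filtering.

### What passing simulations do and do not show

The generator emulates the *structure* of curated atlas data — one normal
pair per cell type, ≤ 12 patients per cancer, untested pairs, ordinal
discretization, shared cohorts between sibling mappings — with known ground
truth, so it can establish that the implementation ranks what it should
rank and that the statistics behave as designed. It does not model antibody
cross-reactivity or quality variation, expert-annotation disagreement,
image-level artifacts, cancer subtypes, or the correlated expression of
functionally related proteins; passing these tests therefore shows
correctness of the method's mechanics, not performance guarantees on real
atlas data. Full-atlas quantities (hundreds of thousands of scores over
~17000 antibodies, and absolute published per-gene scores) depend on a
specific atlas release and are out of scope at this problem size.

## Heat-map calibration check

The off-diagonal heat-map assertion is a calibration statement: each cell's
deviation from its row's population mean, scaled by the standard error
σ_i/√k, should behave like a standard normal. With 702 off-diagonal cells a
literal "every cell within 2 SE" would fail almost surely by chance alone
(~5% of cells are expected outside any 2-SE band), so the suite asserts the
nominal coverage instead: at least 90% of cells within 2 SE and a mean
|deviation|/SE ≤ 2 (the expected value under calibration is √(2/π) ≈ 0.8).
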