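# Methods

This note documents the models and procedures implemented in
`redoxomics`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made
where the procedure left room.

## Artifact cleaning

Electrospray in-source fragmentation produces artifact features that (i)
co-elute with a heavier parent, (ii) track the parent's intensity across
samples because ionization branching is a fixed fraction, and (iii) have
an m/z present in the parent's MS2 spectrum. The cleaner composes four
steps: retention-time binning, co-elution correlation grouping,
MS2-based parent-fragment matching, and halogen-formula removal.

Parameters (defaults): RT gap tolerance 0.005 (in the RT column's
units — the pipeline does not assume seconds vs minutes), Pearson
threshold 0.98 (strict inequality, computed on raw intensities),
MS2 mass tolerance 5 ppm (relative to the candidate m/z), halogen
removal on.

Choices where the procedure was open:

* **Binning** is single-linkage over sorted RT with an inclusive gap
  rule: a gap of exactly the tolerance joins. This is deterministic,
  order-free, and matches a tolerance-window reading of "binned".
* **Correlated groups** are connected components of the >0.98 graph
  inside a bin: if A–B and B–C correlate but A–C does not, all three
  form one co-elution cluster. The parent is the component's heaviest
  ion, ties broken by feature id.
* **Missing formulas are never halogen-removed** — the rule targets
  predicted compositions, and the absence of a prediction is not
  evidence of halogens.
* Workflows of this kind usually end with a manual inspection of the
  candidate list; here that is replaced
  by the automated MS2-match criterion plus a machine-readable report
  (fragment, parent, r, ppm error per removal) that preserves
  auditability for human review.

The report partitions the input exactly (removed-as-fragment +
removed-as-halogen + retained = input), cleaning is idempotent, and
decisions are invariant to feature order.

## Metabolite normalization and statistics

**glog.** The standard generalized logarithm
`x' = log2((x + sqrt(x^2 + a^2))/2)` with offset `a` equal to the
dataset's minimum nonzero intensity. A `literal` mode computes
`sqrt(x^2 + a^2)/2` without the logarithm; it exists because that
written variant circulates in methods texts, but it is not a log
transform and is not the default. With `a > 0` both modes are strictly
monotone and defined at zero.

**Pareto scaling** divides each feature row by the square root of its
standard deviation (n−1 denominator throughout the package). Rows with
zero variance pass through unchanged — constant features carry no
contrast information and dividing by zero is the only alternative.

**Per-feature models.** One OLS per feature in cell-means form (a
coefficient per habitat x timepoint cell, equivalent to
habitat + day + interaction with day categorical). The bog-vs-fen
contrast at each timepoint is a difference of cell means with a t test
on the pooled residual degrees of freedom. Because the two habitats'
final sampling days can differ (bog day 28, fen day 35), the last day of
each habitat is pooled into one shared "final" level; this alignment is
on by default and can be disabled. BH correction is applied across
features separately within each timepoint contrast (per-timepoint
families match how per-timepoint feature lists are reported); a pooled
family across all contrasts is available via `bh_family="pooled"`. The
fits are vectorized with a single least-squares solve across features,
which keeps 2000-feature null simulations fast; single-feature results
match statsmodels OLS `t_test` exactly (verified in the suite).

**NOSC** is computed from element counts and net charge as
`4 − (−Z + 4C + H − 3N − 2O + 5P − 2S)/C`, requiring C ≥ 1. Useful
identities: +1 O changes NOSC by +2/C, +1 H by −1/C.

## Pathway expression

The KEGG logic grammar is parsed with precedence (loosest to tightest)
whitespace < `,` < `+`, with parentheses grouping. KEGG's non-essential
markers (`-Kxxxxx`, `--`) are stripped with a warning rather than
modeled. Scoring: a leaf is its KO's expression (0 when absent — a
pathway with missing genes scores low rather than undefined), a complex
is the mean of its subunits, a step is the sum of its alternatives, the
pathway is the mean over steps, and a parenthesized subsequence is
scored as a sub-pathway (mean of its steps). KO expression is the *sum*
of normalized expression across genes sharing the KO (total transcript
output of that function), optionally restricted to a MAG subset.

**geTMM.** Counts become reads-per-kilobase (RPK = count/(length/1000));
TMM scale factors are computed on the RPK matrix and the output is RPK
per million of effective library size (RPK library size x factor).
TMM details: the reference is the sample whose upper-quartile proportion
is closest to the mean upper quartile; M-values (log2 expression ratios)
are rank-trimmed 30% two-sided and A-values (log2 mean abundance) 5%
two-sided; the factor is the weighted mean of surviving M-values with
inverse-variance weights of binomial shape, `(1−p)/p` per sample summed
over the pair, normalized to geometric mean 1 across samples. The
depth-free weight form is deliberate: with the conventional
library-size-weighted variant, rescaling one sample's counts changes its
per-gene precision weights and hence its factor, so normalized output
would not be exactly invariant to per-sample rescaling. The depth-free
form preserves that invariance to machine precision while keeping the
binomial variance structure across genes; `depth_weights=True` restores
the library-size-weighted variant. All four TMM knobs (reference, both
trims, weighting) are exposed.

## MAG curation

Activity is per sample: total transcript count over the MAG's genes
strictly greater than 15. Encoding is evaluated from the MAG's annotated
KO set (genomic potential, independent of expression): a step is encoded
when at least one alternative is satisfied, a complex only when **all**
subunits are present (incomplete complexes are non-functional;
`complex_rule="any"` relaxes this), a parenthesized subsequence only
when all its steps are satisfied; the pathway is encoded when the
encoded-step fraction is at least 0.60 (inclusive). Encoding proportions
use MAGs active in ≥1 sample as the denominator. The Wilcoxon rank-sum
test uses the exact null distribution when n ≤ 20 without ties and the
normal approximation with continuity and tie correction otherwise
(scipy's engine; an independent full-enumeration oracle cross-checks all
layouts with n ≤ 8 in the suite).

## Methane modules

Signed soft-thresholded adjacency `a_ij = ((1 + r_ij)/2)^β` with β = 14,
so anticorrelated features get near-zero adjacency. Topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij)`. Modules
come from average-linkage hierarchical clustering of 1 − TOM with a
static cut (default height 0.995) and a minimum size (default 30);
smaller clusters stay unassigned ("grey"). A static cut replaces a
dynamic tree cut: it is deterministic, has two interpretable knobs, and
recovers planted structure reliably at these problem sizes. Labels are
deterministic (ordered by size, then smallest member id). The module
eigengene is the first principal component of the standardized member
block, oriented so the mean member-eigengene correlation is positive.
For the most positively and most negatively methane-correlated modules,
the top 100 members are retained ranked by |Spearman rho| between raw
member intensity and methane (the validation statistic itself);
module-membership strength (kME) ranking is available as a flag. Features
without MS2 annotations are dropped before retention when the annotation
filter is on.

## Gas accounting

Headspace moles by the ideal gas law
(`n = ppm·1e−6 · P · V_head / (R T)`, R = 0.082057 L·atm/(mol·K));
dissolved concentration by Henry's law with van 't Hoff adjustment
`KH(T) = KH(298.15) · exp(C (1/T − 1/298.15))`. CO2's dissolved pool is
multiplied by the speciation factor `1 + K1/[H+] + K1K2/[H+]^2`
(K1 = 10^−6.35, K2 = 10^−10.33 at 25 °C; temperature correction of
K1/K2 off by default). Defaults: CO2 KH = 3.4e−2 mol/(L·atm), C = 2400 K;
CH4 KH = 1.4e−3, C = 1700 K — standard compilation values, all
overridable. A named geometry preset covers the Balch-tube incubation
setting (~15 mL headspace, 11 mL liquid, 19 °C). Ideal-gas behavior at
1 atm is assumed; fugacity corrections are out of scope. CH4 totals are
pH-invariant by construction.

## Synthetic data

The generator emulates the statistical structure each stage assumes,
with truth labels in a sidecar file (never merged into analysis inputs,
to prevent leakage into pipeline tests). Defaults are the study-like
conditions used throughout: 24 samples (2 habitats x 4 days x 3
replicates), 500 genuine LC-MS features plus 50 in-source fragments and
10 halogen artifacts, 20 MAGs x 50 genes, negative-binomial counts with
variance μ + αμ² at α = 0.1 (standard RNA-seq overdispersion), a 1 log2
fen/bog habitat effect on half the MAGs, a 30-feature planted methane
module, and a 40x fen/bog CH4 production ratio.

Specifics worth knowing:

* Fragment intensities are parent x fixed branching fraction x
  multiplicative lognormal noise (sd 0.005), which guarantees the >0.98
  correlation regime; fragment RT jitter (0.002) is below the binning
  tolerance, and genuine features sit ≥0.04 RT units apart so true
  co-elution groups are singletons. Chance false positives are therefore
  structurally excluded at the default geometry — real chromatograms are
  denser, so perfect precision on synthetic data does not promise
  perfect precision on real data.
* Inactive MAG labels are enforced by construction (≤15 transcripts
  spread multinomially in flagged samples) and active labels are
  guaranteed auditable (a deficit top-up prevents a nominally active
  MAG from landing under the threshold by chance). Encoding labels are
  computed from the realized KO set with the same all-subunit rule the
  curation stage uses, so they stay correct even when pathways share KOs.
* The gas series inverts the total-gas equation, so a noiseless series
  round-trips exactly; measurement noise is multiplicative lognormal on
  ppm with the series re-monotonized (production only accumulates).
* The planted module's latent factor is constructed in sample space to
  have *exactly* the requested Pearson correlation with the methane
  vector before noise (Gram-Schmidt against the standardized gas
  vector); member noise sd is 0.3.

What the generator does not emulate: raw spectra or chromatographic peak
shapes, adducts and isotopologues, read-level sequencing data,
compositional coupling between the metabolome and the transcriptome, and
batch effects. Green tests demonstrate the pipeline's rules and
numerics, not robustness to those real-data phenomena.

## Problem sizes

The suite and drivers run at the generator defaults above
(560-feature tables, 1000-gene count matrices, 90-feature module
networks at 12 samples, 100-seed recovery loops, 2000-feature null
simulations) — sizes chosen so planted-structure recovery is
statistically meaningful while a full run stays in seconds.

## Known limitations

* The static-height tree cut can absorb weakly correlated background
  features into a strong module; recovery guarantees are about
  containment of the planted block and the sign/size of the correlation,
  not exact membership.
* geTMM's depth-free weights differ (slightly) from the
  library-size-weighted convention; factors agree closely in practice
  but not bit-for-bit.
* The Fig-style per-MAG coupling and encoding comparisons assume the
  synthetic sample-naming convention (`habitat_dDD_rN`) when driven
  end-to-end; library functions accept explicit designs.
* Wilcoxon exact p-values are only used without ties; tied data fall
  back to the corrected normal approximation even at small n.
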