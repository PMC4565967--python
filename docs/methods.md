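# Methods

## Scope and model

`lncgba` annotates lncRNAs by guilt-by-association: a lncRNA is linked
to the biological functions over-represented among the protein-coding
genes co-expressed with it. The pipeline has four statistical stages —
expression filtering, pairwise association, set merging, and
hypergeometric enrichment — plus a bipartite network export and a
synthetic-data generator used for validation. Every stage operates on
plain text formats (expression TSV, GTF, GMT) and is deterministic given
its inputs and configuration.

## Expression filtering

Only expressed genes enter the screen. The default rule keeps a gene
when its mean expression exceeds 0.001 on the FPKM/RSEM scale; an
alternative mode requires expression above the threshold in at least
half the samples. The 0.001 default reflects the conventional
"expressed at all" cutoff for RNA-Seq abundance estimates; both the
threshold and the mode are configurable (`expression_threshold`,
`expression_filter_mode`). Input matrices are accepted as-is — the
package does not renormalise; any library-size or within-sample
normalisation is the caller's responsibility upstream.

## Association statistics

Two methods score each (lncRNA, protein-coding gene) pair over the
*n* shared samples (*n* ≥ 3 required):

**Linear regression.** The protein-coding gene is regressed on the
lncRNA — the lncRNA is framed as the putative regulator. Both vectors
are transformed by `log2(x+1)` first (default, `log_transform`), which
tames the right skew of FPKM-scale values; the transform changes the
slope's units but not CEG membership in any material way because the
slope p-value equals the Pearson correlation-test p-value for simple
OLS. The slope is b = S<sub>xy</sub>/S<sub>xx</sub>; significance is the
two-sided p of t = r·√((n−2)/(1−r²)) on n−2 df. Pairs where the
response is constant get r = 0, p = 1; a constant predictor is an
error (single-pair API) or a logged skip (matrix screen), so one flat
gene cannot abort a genome-wide run.

**Spearman rank correlation.** Mid-ranks (ties receive the mean rank)
followed by Pearson correlation, with the same t-approximation for the
p-value and p = 0 at ρ = ±1. The t-approximation is standard at
RNA-Seq sample sizes but coarse below roughly ten samples; no exact
permutation p is computed. Spearman is unaffected by the log transform
(monotone invariance) and is the robust choice when the
lncRNA–target relationship is monotone but not linear.

Both are implemented as vectorised closed forms (one predictor against
all response rows at once); the unit tests cross-check them against
`scipy.stats.spearmanr`, `pearsonr` and `linregress` and against
textbook-formula oracles to 1e−12.

**CEG thresholds.** A pair is a CEG call when every *configured*
threshold passes: p ≤ `p_threshold` and |r| ≥ `coef_threshold`. Either
may be unset (at least one must be set). The coefficient threshold is
applied to the correlation-scale effect r rather than the raw slope so
that a single τ is meaningful for both methods. Defaults: p ≤ 0.01, no
coefficient threshold. Each dataset is analysed independently; there is
no cross-dataset pooling at the association stage.

## Merging

CEG sets are combined in two strictly sequential levels: first the sets
of the queried lncRNAs are merged *within* each dataset, then the
per-dataset merged sets are merged *across* datasets. Each level is
either a union or an intersection; a flattened one-shot merge is not
offered because the two orders differ when the modes are mixed. Empty
merged sets are legal (intersections of many lncRNAs legitimately
empty), propagate with a warning, and yield empty enrichment output
rather than an error.

## Enrichment

Over-representation only, by the hypergeometric upper tail
P(X ≥ k) (evaluated via `scipy.stats.hypergeom.sf`, which works in log
space; validated against exact rational enumeration). The background
universe defaults to the expressed protein-coding genes that carry at
least one annotation in the collection under test
(`universe_mode=annotated`): genes no term could ever contain cannot be
enriched, and leaving them in deflates every p uniformly. The
alternative `all` mode uses all expressed protein-coding genes. Term
membership, K, and n are all restricted to the chosen universe before
testing; terms outside the size bounds (default 5–1000 after
restriction) are skipped as uninformative. Corrections (Bonferroni,
Benjamini–Hochberg via `statsmodels.stats.multitest`) are applied per
collection — GO BP, GO CC, GO MF and KEGG are separate test families,
matching how the result lists are reported. The significance filter
(default 0.05) applies to the adjusted p, or to the raw p when no
correction is selected; zero-overlap terms are never reported. GMT
collections are taken as-is — no GO ancestor propagation is performed.

## Network export

The lncRNA–CEG graph is strictly bipartite; each association record that
passed the thresholds becomes one edge carrying its coefficient, r,
p-value and dataset id. Multi-dataset graphs keep one edge per dataset
(the multi-edge key is the dataset id) so cross-dataset support stays
visible; `--collapse` merges parallel edges keeping the smallest p.
Bipartiteness is verified on build and on read-back. Formats: GraphML
(typed attributes), SIF with relation `coexp` plus a companion
edge-attribute TSV (isolated lncRNAs appear as lone-name SIF lines), and
a two-file node/edge TSV convention importable by desktop Cytoscape.

## Synthetic data generator

The generator emulates matched lncRNA/protein-coding profiles with known
structure. Each lncRNA is a latent standard Gaussian over samples; each
of its targets is ρ·(lnc latent) + √(1−ρ²)·ε; all latents are mapped
through `exp` to a lognormal, FPKM-like scale. Correlation is planted on
the latent scale deliberately: the monotone map preserves rank-based
association exactly, so the realised Spearman correlation concentrates
on (6/π)·asin(ρ/2) (≈ 0.786 at ρ = 0.8), while Pearson correlation is
only approximately preserved — tests therefore compare rank-scale
quantities. Defaults define the validation study: 50 samples, 2 lncRNAs
× 50 targets at ρ = 0.8, 2000 unassociated lognormal genes, and a
22-term GMT holding one planted term per lncRNA (80 % of its targets
plus non-target fillers to a term size of 50) and 10 decoy terms per
lncRNA sampled only from non-target genes, so top-rank recovery of the
planted term is unambiguous. Everything is reproducible from a single
integer seed.

What the generator does *not* emulate: count overdispersion (negative
binomial noise), library-size variation, batch effects, correlated null
genes (co-regulated modules not driven by the lncRNA), or missing
values. Passing the recovery tests therefore demonstrates that the
statistics and plumbing are correct under clean lognormal conditions; it
does not guarantee the same sensitivity/specificity on real tissue
panels, where null correlations are not independent and effect sizes
vary per target.

## Numerical and design choices

* Gene id version suffixes (".N") are stripped everywhere (GTF,
  expression tables, GMT) before joining, since annotation versions
  drift across releases.
* Symbol→id resolution never expands ambiguous symbols; they are
  reported separately and the caller must disambiguate.
* BH adjustment is the step-up running-minimum form, restored to input
  order; adjusted values are capped at 1.
* Enrichment ties are broken by term id for deterministic output order;
  association tables are written sorted, and no output embeds a
  timestamp, so identical runs are byte-identical.
* In `merge-cegsfuncs` the enrichment background is the union of the
  per-dataset expressed protein-coding genes: a gene expressed in any
  contributing dataset could have entered the integrative set, so it
  belongs to the population sampled from.
* Validation problem sizes (e.g. 2000 null genes, 50 samples, 200
  samples for the rank-correlation calibration check) were chosen as the
  smallest scales at which the binomial/KS acceptance bands are tight
  enough to be meaningful.

## Known limitations

* The Spearman p-value uses the t-approximation at all n; below ~10
  samples it is unreliable.
* No partial correlation, mutual information or module detection — a
  strong confounder (e.g. tumour purity) can induce CEG calls that
  guilt-by-association will happily annotate.
* Enrichment assumes the GMT is the complete annotation of the
  background; incomplete collections bias the annotated-universe mode.
* Only union/intersection merging is offered across datasets; there is
  no significance-aware meta-analysis.
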