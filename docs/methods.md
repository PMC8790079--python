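# Methods

## The scoring model

A variant's score is the change in mean alignment score against clusters of
homologous supporting sequences:

    score(v) = (1/|C|) Σ_{c ∈ C} [ mean_{s∈c} A(mutant, s) − mean_{s∈c} A(query, s) ]

where `A` is an optimal pairwise alignment score and `C` the selected
clusters.  Averaging is *within cluster first, then across clusters*, so a
large cluster of near-identical homologs counts once, not once per member.
A variant is classified **deleterious** when its score falls strictly below
the threshold (default −2.5); there is no beneficial category, however
positive the score.

**Alignment.**  `A` is an affine-gap alignment under a substitution matrix
(default BLOSUM62): a gap of length L costs `gap_open + (L−1)·gap_extend`
(defaults 10 and 1).  The shorter sequence of a pair is aligned end to end;
terminal overhangs of the longer sequence are free; equal-length pairs are
aligned globally.  This makes the score symmetric and gives the intuitive
closed forms used in the tests (a substitution against a support set equal to
the query scores exactly the matrix difference, e.g. W→A =
B62(A,W) − B62(W,W) = −14).  The dynamic program is a numba-compiled Gotoh
recursion; the test suite checks it against an independent path-enumeration
oracle on all small instances.

**Clustering and selection.**  Supporting sequences are clustered greedily in
order of decreasing length (ties broken lexicographically so the partition is
independent of input order): a sequence joins the first cluster whose
*representative* — the founding, longest member — shares at least
`cluster_identity` (default 0.75) identity, else founds a new cluster.
Identity is matches divided by alignment columns of the unit-cost global
alignment (computed with edlib); gaps count as columns.  Clusters are ranked
by the representative's identity to the query (ties: longer representative,
then founding order) and the top `max_clusters` (default 30) are scored.
Variants scored from fewer than 30 clusters or fewer than 50 supporting
sequences carry `few_clusters` / `few_support` flags, since scoring accuracy
is known to degrade there; an empty supporting set, or a mutant too degenerate
to align (a protein abolished by an immediate stop), yields an `unscored`
flag rather than a number, and unscored proteins are excluded from all
statistics but tallied.

**Gene-level reduction.**  When alternative transcripts of a gene are mutated
they are scored separately and the *minimum* score is reported for the gene,
with the classification recomputed from that score.

## Mutagenesis

Coding sequences are spliced from exon intervals (reverse-complemented on the
minus strand), each line's variants in a gene are applied jointly from the
highest genomic position down (so lower coordinates stay valid; exon
boundaries downstream of an indel are shifted by the length difference), and
the result is translated with the standard code.  Premature stops truncate
the protein rather than erroring; frameshifts therefore surface as long
replacement/truncation edits, which the aligner penalises heavily — the
behaviour such variants show in practice.  Edits that span an exon boundary
are rejected (splice-site effect prediction is out of scope).

Protein changes are expressed in an HGVS protein subset (no `p.` prefix):
substitution, del, ins, dup, delins.  The diff trims the longest common
prefix, then the longest common suffix, which places ambiguous indels at
their 3'-most equivalent position (the HGVS convention; chosen so repeat
regions get deterministic descriptions).  An insertion equal to the
immediately preceding run is written as a duplication.  Insertions before the
first or after the last residue, which plain `ins` notation cannot express,
are folded into a delins on the terminal residue.  A fuzz test round-trips
≥10⁴ random edit scripts through diff → parse → apply.

**Ancestor correction.**  All diffs are taken against the MA ancestor's
protein, built by folding ancestor-vs-reference variants into the reference.
Comparing against the reference instead would contaminate every score with
shared standing divergence (reference bias); the package treats the ancestor
query as the only correct baseline and provides the reference-bias analysis
to quantify what ignoring it would do.

## Per-line statistics

For each line: Ψ_tot counts scored mutant proteins (each protein once per
line); Ψ_del those with score < threshold; Ψ_abs those with |score| >
|threshold| (a +3 score enters Ψ_abs but not Ψ_del); Ψ_non_del = Ψ_tot −
Ψ_del; `*_ess` versions restrict to an essential-gene list (genes absent from
the list count as non-essential).  Σ_tot = log(1 − Σ scores) log-compresses
the raw score sum, whose distribution is extremely skewed once truncating
variants (scores in the hundreds to thousands negative) are present.  When
the score sum reaches 1 the logarithm is undefined; the statistic is then
flagged undefined, never silently dropped, and model fits drop such lines
explicitly (with a logged count) so all compared models share the same n.

## Fitness models

Relative fitness is the block-centred mean growth rate of a line minus the
block-centred mean of its matched controls (matching on ancestor and
environment by default); a constant offset added to any assay block cancels
exactly.  An absolute-value response is available for designs where fitness
moves in both directions without a mean trend.  Controls define the zero of
both axes, so single-predictor regressions run through a fixed (0, 0)
origin; a free-intercept refit is provided as the sensitivity analysis for
settings without controls (it is a different design matrix, not an origin
point appended to the data).  Multi-predictor fits (e.g. Ψ_del + Ψ_non_del)
and a relative-genome-size covariate are supported.  With several ancestral
backgrounds, a per-ancestor random slope (no intercepts anywhere) is
estimated by maximum likelihood — ML rather than REML so likelihoods are
comparable across fixed-effect structures in AICc ranking.  K counts every
estimated parameter including variance components.  The default optimizer
chain for the mixed fit can collapse to a degenerate boundary solution;
several optimizers are tried and the best finite converged ML solution kept,
with non-convergence and near-zero random-slope variance flagged.

The threshold sweep recomputes Ψ_del per line over a grid of cutoffs
(default −10 to 0 in steps of 0.25), refits the origin model at each, and
reports AICc and the pooled proportion of variants classified deleterious;
cutoffs where every line has zero deleterious proteins are recorded as
undefined rather than fitted.  Exact AICc ties across cutoffs (identical
counts) resolve to the most negative tied cutoff.

## Reference-bias analysis

Ancestral (ancestor-vs-reference) variants are scored with the reference
protein as query and compared with new MA mutations: a 2×2
deleterious/neutral table with the exact two-sided Fisher p; a two-sided
rank-sum test (exact enumeration up to combined n = 20 without ties,
tie-corrected normal approximation otherwise); percentile-bootstrap 95%
confidence intervals for median scores (seeded, default 10⁴ resamples — the
interval method is a package choice); and a logistic model of deleterious
status on variant origin with a per-ancestor random intercept, fitted by
maximum likelihood via 25-node Gauss–Hermite quadrature (statsmodels has no
ML binomial GLMM).  The pooled p-value is the likelihood-ratio (profile)
test, which stays finite under complete separation; separation in any
ancestor × origin cell is flagged, as is a collapsed random-intercept
variance (in which case a fixed-ancestor-effects logistic refit supplies the
Wald quantities).  Per-group log-odds use the Haldane–Anscombe correction.

## The synthetic-data generator

The generator emulates the *structure* of an MA study, not any particular
organism: protein families in which supporting sequences derive from the
query by per-site substitution with probability proportional to a site
tolerance (half the sites strongly conserved, tolerance 0.02, the rest 0.35 —
so conserved-site variants score systematically worse); 1–3-exon gene models
on both strands whose spliced translation reproduces the designed protein
exactly; per-line Poisson mutation counts realised as nonsynonymous codon
changes, with small probabilities (0.05 each) of an in-frame codon deletion
and of a premature stop — the truncating class that gives real variant
tables their extreme negative score tail, without which aggregate score sums
are nearly proportional to counts and the Ψ_tot/Σ_tot comparison is
uninformative.  Ancestral variants occur per protein at a configurable rate
at tolerant sites, preferring residues already present among the homologs at
that site — variation that "looks screened by selection" and accordingly
scores less deleterious than new mutations.  True line fitness is additive
over mutations (no epistasis, matching the models being tested) under one of
three effect models: a constant effect per mutant protein (default −0.02),
an effect proportional to the realized score (scaled so a −2.5 score gives
the base effect), or the proportional effect applied only below a cutoff
(default −2).  Measured growth adds a per-ancestor baseline (1.0), Gaussian
block effects (sd 0.05 over 4 blocks), and replicate noise (sd 0.1 over 10
replicates per line; ~40 control replicates per ancestor) — giving line-level
repeatability (ICC ≈ 0.2–0.3) in the range reported for replicated MA growth
assays.  Every latent quantity is kept in a truth record; identical seed and
config give byte-identical outputs.

Default study dimensions are 6 ancestors × 14 lines, 40 proteins of mean
length 120 with 12 homologs each and ~6 mutations per line.  The package's
own replicated evaluation runs (`evaluation_config`) use a reduced scale —
3 ancestors × 8 lines, 25 proteins of mean length 60, 8 homologs, ~5
mutations per line — chosen so that fifty end-to-end replicates per scenario
remain cheap while preserving the study structure.

**What passing tests do and do not show.**  The generator's homologs are
independently derived from the query (no phylogeny, no alignment-driven
gaps), proteins are length-realistic only at desk scale (real proteins
average several hundred residues), supporting sets are far smaller than a
real BLAST harvest (hence every simulated variant carries the few-support
flag), and mutation rates are homogeneous along the genome.  Passing the
qualitative tests shows the pipeline's statistics behave as designed under
known generating models; it does not certify how any real database-backed
score set will rank predictors on a particular organism.

## Numerical and design choices

- AICc = −2lnL + 2K + 2K(K+1)/(n−K−1); reported alongside AIC; n−K−1 ≤ 0
  yields +inf rather than an error.
- Deleterious classification uses a strict inequality at the threshold.
- Greedy-cluster order ties broken lexicographically; cluster-selection ties
  by representative length then founding order — all deterministic, so delta
  scores are invariant to supporting-sequence input order.
- The aligner rejects unknown residues and empty sequences outright.
- Lines whose mutations are all synonymous stay in the study with every
  count at zero.
- Exclusion lists remove lines by id with logged reasons; unknown ids warn
  and no-op.
- Environment pooling is justified by an explicit role × environment
  interaction F-test, exposed as its own function rather than hard-coded.

## Known limitations

Supporting-set acquisition (BLAST against a protein database, E-value
filtering) is out of scope — supporting sets are inputs.  Nucleotide-level
scores, splice-site and regulatory variants, mitochondrial/chloroplast
genomes, aneuploidy calling (relative genome size is accepted as a per-line
input), dominance and epistasis are not modelled.  The grouped logistic
model fits a random intercept, not a random origin-effect slope.
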