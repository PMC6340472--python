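# Methods

## The MK framework as implemented

The McDonald–Kreitman test contrasts two classes of nucleotide change at
synonymous (S) and nonsynonymous (N) sites: changes *fixed* between two
closely related species and changes *polymorphic* within either species.
Under neutrality the N:S ratio is the same in both classes; an excess of
fixed nonsynonymous changes indicates adaptive fixation, an excess of
polymorphic nonsynonymous changes indicates segregating weakly
deleterious variation. The package computes, per user-defined codon
region and for the full CDS:

- the 2×2 table (dN, dS, pN, pS);
- a two-tailed Fisher exact p-value (point-probability method: the sum of
  hypergeometric probabilities of all tables at fixed margins no more
  probable than the observed one — this is what `scipy.stats.fisher_exact`
  computes);
- α = 1 − (dS·pN)/(dN·pS), reported `NA` when dN = 0 or pS = 0;
- DoS = dN/(dN+dS) − pN/(pN+pS), reported `NA` when either denominator
  is 0.

`NA` is a first-class value (`None` in the API, the literal token `NA` in
reports); boundary tables are never coerced to a number.

## Site classification conventions

The data do not dictate every counting convention; the following choices
are fixed and tested:

- **Reference for polymorphisms.** Each segregating site is scored
  against the *species-majority codon* at that column, ties broken
  lexicographically. This makes output invariant under reordering of
  input lines. One change is emitted per non-majority allele, carrying
  its minor-allele count and the column's effective sample size.
- **Fixed differences.** A site is a fixed difference only when each
  species is monomorphic there (over its gap/N-free lines) and the two
  alleles differ. A shared allele is never a fixed difference. Fixed
  sites are weighted by pathway averaging over the two species' consensus
  codons.
- **Pathway counting.** For codons differing at k > 1 positions, all k!
  orderings of single-nucleotide steps are enumerated, orderings passing
  through a stop codon are discarded, and each site's syn/nonsyn
  assignment is averaged over the survivors. Fractional weights are kept
  exact through tabulation and rounded half-to-even only for the Fisher
  test and integer reporting.
- **Missing data.** A line with N or an alignment gap in a codon is
  dropped from that column only; a species needs ≥ 2 remaining lines for
  the column to be scored, and fixed calls require both species scorable.
- **Stop codons.** Changes to or from stop codons are excluded from all
  counts: the framework concerns amino-acid replacement.
- **Frequency filter.** A polymorphism is removed iff its minor-allele
  frequency is *strictly* below the threshold (default 0.05, i.e. "fewer
  than 5% of lines"); a variant at exactly the threshold is retained.
  Fixed differences are never filtered.
- **Both-species polymorphism.** A site segregating in both species
  yields one change per species (both pool into pN/pS in unpolarized
  mode).

## Polarization

With an outgroup, each fixed difference is assigned by parsimony: if
species B's allele equals the outgroup allele, the substitution occurred
on A's lineage (and symmetrically). Sites where the outgroup carries
N/gap or matches neither allele are unpolarizable and are dropped from
polarized divergence counts — hence polarized dN (dS) can never exceed
the unpolarized count, a tested invariant. In polarized mode the
polymorphism columns default to the focal species' polymorphisms only; a
`pooled_polymorphism` option keeps both species' polymorphisms instead.
Both conventions appear in the literature and published tables rarely say
which was used, so neither is asserted as canonical here.

## Region partitions

Configs name codon intervals in 1-based inclusive residue coordinates
(the convention of statements like "spans residues 36 to 54"); internal
arithmetic uses 0-based half-open nucleotide ranges, with codon interval
(s, e) mapping to nucleotides [3(s−1), 3e). Intervals must be
non-overlapping and within the CDS but need not tile it; changes in
spacers count only toward the implicit Full CDS row. Region boundaries
are always user-supplied, never hard-coded.

## Motif scanning

Patterns use PROSITE-like syntax (`[ST]` classes, `X(m,n)` wildcard runs,
single-letter literals, `-` separators). The matcher backtracks over the
element list directly, which keeps it independent of the regex engine the
tests use as an oracle. Decisions: every start offset that can begin a
match is reported (overlaps included); variable wildcards report the
*shortest* match per start (greedy vs. shortest changes only spans, not
the hit set, for anchored patterns like the S/TP motif); an `X` in the
subject sequence satisfies only wildcard elements, never literals or
classes. Per-region percent identity between two aligned proteins counts
a column in the denominator when at least one sequence has a residue
there (gap/residue columns score 0; columns gapped in both are excluded).

## The simulator

`synthetic.emit_dataset` emulates the data layout of a two-species
population study: an ancestral CDS of uniform-random sense codons evolves
independently into an outgroup (branch `t_out`) and into each species'
consensus (branches `t_a`, `t_b`); each consensus is copied into a
population sample into which `n_poly` segregating sites are injected.

- **Mutation.** Per codon, Poisson(t) proposals; each picks a site
  uniformly and an alternative nucleotide with transition weight κ
  (default 2, a typical coding-sequence transition bias) against
  transversion weight 1. Proposals creating stop codons are rejected.
- **Selection.** Acceptance-thinning: synonymous proposals are always
  accepted, nonsynonymous ones with probability ω of the codon's region —
  separately configurable for fixations (`omega_div`) and polymorphisms
  (`omega_poly`). This deliberately replaces a full codon-substitution
  matrix: it is sufficient to generate MK-style count structure with
  closed-form expectations, and it is *not* a model of codon usage,
  mutation-selection balance, or the site-frequency dynamics of selected
  alleles.
- **Polymorphisms.** Each takes a fresh nucleotide position, a derived
  allele by the same proposal/acceptance rules, a derived-allele count k
  from the chosen SFS over 1..n−1 (neutral: P(k) ∝ 1/k, the standard
  equilibrium spectrum; or uniform), and a uniform-random subset of k
  carrier lines.
- **Determinism and ground truth.** One seeded NumPy generator drives
  every draw; identical configs give byte-identical output. Every
  accepted event is recorded with its codon, site, lineage, syn/nonsyn
  label and derived count, so pipeline output can be reconciled exactly
  against the generator on singly-hit codons.
- **Homoplasy.** Repeat hits at a site (and multiple events in a codon)
  are allowed, not retried; they are flagged in the ground truth rather
  than prevented. At the default branch lengths they affect < 1% of
  sites.

What passing tests on simulated data do *not* show: robustness to
misalignment, indel polymorphism, sequencing error beyond N-masking,
linked selection, demography, or non-equilibrium frequency spectra —
real-data features the generator does not emulate.

## Numerical and calibration notes

- Fisher's test uses integer counts (half-to-even rounding of fractional
  pathway weights); α and DoS use the exact fractional counts. An
  all-zero table returns p = 1 by convention.
- Six tests per run (five regions + full CDS) are performed with no
  multiple-testing correction, matching standard practice of reporting
  raw per-region p-values; a log message notes the count.
- **Known counting bias at multi-hit codons.** Endpoint-based pathway
  averaging is exact for singly-hit codons but approximate when a codon
  carries events on both lineages or two events on one lineage. Measured
  with this package's own simulator: at per-codon proposal rate t = 0.3
  per branch with ω = 1 the mean DoS over 2,000 neutral replicates is
  +0.0035 (pathway averaging weights orderings uniformly, while under
  shared purifying selection the realized order is synonymous-enriched —
  at ω_div = ω_poly = 0.5 the bias grows to ≈ +0.013). At t = 0.10 per
  branch the bias is statistically indistinguishable from zero, so the
  package's neutral-calibration experiment (1,000 codons, 30+30 lines,
  150 polymorphisms per species, 2,000 replicates) runs at t = 0.10,
  where the Fisher rejection rate at the 0.05 level is ≈ 4% (slightly
  conservative, as expected for an exact test on discrete tables) and
  mean DoS is within Monte-Carlo error of 0. The regional-power
  experiment (ω_div elevated 5× in one region, 100 replicates) runs at
  t = 0.2 per branch, 750 codons, where the elevated region dominates
  rejections with positive mean DoS.
- Columns cannot be masked by alignment confidence within the package:
  all supplied columns are counted, and masking (e.g. of low-confidence
  alignment columns) is left to the user upstream.

## Known limitations

- No multiple-hit divergence correction (Jukes–Cantor etc.): the method
  targets closely related species where divergence is sparse.
- No asymptotic-MK or model-based (SnIPRE-style) estimators; α is the
  classic point estimate and inherits its sensitivity to segregating
  deleterious variants (mitigated, not removed, by the 5% filter).
- The genetic code is the standard nuclear code; alternate codes can be
  passed to the classification functions but the report pipeline does not
  expose them.
- Whether a codon segregating at two sites counts as two polymorphisms
  (as here) or one is a convention; this package counts per segregating
  site.
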