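# Methods

## Scope and model

`mappskit` analyses the downstream readouts of a MAPPs (MHC-associated
peptide proteomics) immunogenicity study: eluted-peptide tables per donor ×
construct, donor HLA genotypes, population allele frequencies, peptide ×
allele percentile-rank matrices from an MHC-II binding predictor, and
triplicate cpm tables from a proliferation assay. Identification of the
peptides themselves (mass spectrometry, database search) and the binding
predictor are upstream and out of scope; the package consumes their tabular
outputs.

Coordinates are 1-based inclusive everywhere. Each construct carries a
`numbering_offset` mapping local position 1 onto the reference numbering in
which substitutions are written; published cluster spans and mature-protein
substitution labels do not always share a consistent origin, so the offset
is user-supplied per construct rather than hard-coded. Sequences are
uppercased on ingest and restricted to the 20 canonical amino acids.

## Cluster detection

Eluted peptides are placed on their construct by exact substring search
(all occurrences reported, multi-hits flagged ambiguous; optional
I/L-equivalent matching for the isobaric mass-spectrometry ambiguity,
off by default). Clusters are the connected components of the
interval-overlap graph. `min_overlap` (default 1 residue) sets the overlap
needed to connect two peptides; `max_gap` (default 0 = disabled) switches
to gap bridging, additionally connecting intervals separated by at most
that many uncovered residues. For sorted intervals a single sweep computes
the components; a brute-force pairwise union-find oracle checks this on
random instances in the test suite. Cluster bounds are the min start / max
end of members, and the spanning sequence is read off the construct.

## Cohort statistics and the absent/zero distinction

Cluster frequency is 100 × (presenting donors ÷ total donors). A donor's
within-donor cluster percentage is 100 × (peptides overlapping the cluster
÷ total peptides for that construct); when the donor yielded *no peptides
at all* the value is absent (`None`), which is different from an observed
0%. Absent reference values exclude a donor from responder and inhibition
denominators — with the published 11-donor presentation table this yields 9
evaluable donors and responder rates of 6/9 and 7/9. A responder requires a
*strict* decrease; ties are non-responders. Percent inhibition
100 × (f_ref − f_var)/f_ref is undefined (absent) when f_ref is 0 or
missing and may be negative. Per-donor peptide-count decreases exclude
donors whose reference count is 0 from every denominator.

Report tables round percentages half away from zero to integers (45.45 →
45, 81.82 → 82); exact values are kept alongside in machine-readable
output. Whether within-donor percentages use total or unique peptide
counts is configurable; total is the default. Duplicate eluate rows count
toward totals and length statistics and collapse only in unique counts.

## Binding statistics

Percentile ranks (lower = stronger predicted binding) are held in a
peptide × allele matrix; rank < 10 is "high affinity", with strict
inequality, so ties at exactly 10 are excluded. The promiscuity score of a
peptide is the sum of population frequencies of its high-affinity alleles;
it is monotone in τ and bounded by the table's cumulative coverage.
Variant comparisons default to the two-sided Wilcoxon signed-rank test on
paired per-peptide scores (paired, non-normal, small n); a sign test is
available, the test name is recorded in the result, and all-tied inputs
are defined to give p = 1 (scipy raises on them).

Allele names are compared on locus + first two numeric fields, zero-padded
("DRB1*4:2:1" ≡ "DRB1*04:02"), because typing tables mix resolutions;
names appearing without a locus prefix inside a locus column inherit that
locus. A donor's score for a peptide is the minimum rank over its DR
alleles (DRB1/3/4/5 by default — the assay captures DR — configurable down
to DRB1). Eluted ligands vary in length while matrices cover fixed k-mers,
so variable-length peptides are scored by their best contained k-mer (the
best-binding-window convention); peptides shorter than k are reported as
unscoreable rather than guessed. Density histograms use half-open bins
with a closed final bin, so counts always conserve mass.

## Synthetic study generator

The generator emulates the study conditions: an 11-donor cohort with two
DRB1 alleles each drawn from a population table (a synthetic representative
frequency table of 28 common DRB1 alleles is the default); four homologous
~300-residue constructs sharing eight planted 9-mer binding cores, with the
central core mutated in the engineered analog and shifted upward in rank
for WT (+12, tolerized self) and the deimmunized analogs (+8, +5);
background ranks uniform on [0, 100]; presentation of a core gated at
min-rank < τ_present = 10 with logistic probability (midpoint 5, slope 2)
below the gate; presented cores spawning nested sets of 1–8 peptides
(Poisson-distributed size, mean 4) by geometric flank extension (p = 0.2
per side) around the core, clipped to lengths 10–26 so the pooled mean
lands near 17; and triplicate lognormal cpm (baseline 500 cpm, σ = 0.25 on
the log scale) with a planted effect of 4 for responders and 1 for
non-responders. The logistic presentation model and the lognormal cpm
noise are modelling choices — the data only motivate a low-rank-skewed,
roughly multiplicative-noise structure — and both are parameterized so
they can be swapped.

Randomness is split into named streams seeded by (seed, stream id, entity
keys). Donor streams are mutually independent, so enlarging a cohort never
perturbs earlier donors. Eluate draws are keyed per donor × core but *not*
per construct: homologous constructs share background rank draws, core
rank draws, and eluate draws, so paired variant-vs-reference contrasts
isolate the planted shift (common random numbers). This is what lets the
end-to-end test recover a planted deimmunization effect exactly: donors
unaffected by the shift produce identical eluates under both constructs
(ties, non-responders), affected donors lose the core (responders).

What the generator does **not** emulate: mass-spectrometry noise, missed
identifications, spectral counts, per-donor processing differences beyond
a yield multiplier, DQ/DP presentation, or linkage between the two alleles
of a haplotype. Passing tests therefore demonstrate correctness of the
downstream statistics under a clean generative model, not robustness to
identification error in real eluates.

## Problem sizes and numerics

The default simulated study uses 11 donors × 4 constructs (~470 peptides);
law-of-large-numbers checks use 5 000 donors for cohort sampling and 500
donors for end-to-end recovery and responder-call sensitivity, sizes at
which binomial error is well below the asserted tolerances and the whole
suite runs in seconds. Percentile ranks are validated into [0, 100];
frequencies into [0, 1] with table sums ≤ 1 + 1e-6 (tables may truncate
rare alleles). Degenerate inputs are errors, not silent defaults: empty
score lists, single-pair signed-rank tests, zero-mean controls, donors
with no usable alleles, and clusters referencing missing constructs all
raise typed exceptions.

## Known limitations

* Cluster counts are data-dependent; dense eluates can merge neighbouring
  cores into one cluster, which is faithful to the definition but means
  "number of clusters" is not a stable readout.
* The predictor dialect reader covers the common whitespace-tabular form
  (Peptide/Allele-or-MHC/Rank columns) only.
* Promiscuity aggregation over a region is left to the caller (per-peptide
  scores are exposed); the package does not decide between best-rank and
  averaged aggregation.
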