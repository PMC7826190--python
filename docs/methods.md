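# Methods

## The statistic

Given three populations and an outgroup related as (((P1, P2), P3), O), a
biallelic site with derived-allele frequencies p1, p2, p3 contributes

    c_ABBA = (1 − p1) · p2 · p3
    c_BABA = p1 · (1 − p2) · p3

to the two shared-derived-allele classes, under the assumption that the
outgroup is fixed for the ancestral state.  Patterson's D is the normalized
difference of the genome-wide sums,

    D = (Σ c_ABBA − Σ c_BABA) / (Σ c_ABBA + Σ c_BABA),

and is zero in expectation when the only source of non-sister allele sharing
is incomplete lineage sorting in a constant-size history.  The D frequency
spectrum partitions the same sums by the derived-allele count k ∈ {1..n}
(requiring equal haploid sample sizes n for P1 and P2): bin k collects ABBA
mass from sites with count k in P2 and BABA mass from sites with count k in
P1,

    D_k = (A_k − B_k) / (A_k + B_k),      w_k = (A_k + B_k) / Σ(A + B),

so that Σ w_k = 1 and Σ w_k·D_k = D exactly.  Bin k = 0 is structurally
weightless (c_ABBA vanishes at p2 = 0 and c_BABA at p1 = 0) and is omitted.
A bin with no mass has undefined D_k, reported as NaN with w_k = 0 — never
as 0, which would be indistinguishable from a genuinely balanced signal.
All sums run over real-valued cell masses, so hypergeometrically projected
(fractional) spectra are handled natively; division is guarded by an
explicit zero-denominator branch and the identities above are asserted in
tests at 1e-12.

Unequal P1/P2 sample sizes are reconciled by exact hypergeometric
projection of both axes to min(n1, n2) (a logged, automatic step); P3 keeps
its native size, since only its frequency enters the site contributions.

## From genotypes to a spectrum

The VCF pipeline keeps biallelic SNPs (single-base REF and ALT; indels,
spanning deletions and symbolic alleles excluded), counts allele copies
directly from GT fields (so arbitrary ploidy, including tetraploids, works
unchanged), and drops sites genotyped in fewer than 80% of mapped
individuals by default.  An optional per-genotype depth threshold
(FORMAT/DP) is off by default: depth QC is normally done upstream.
Polarization uses the outgroup: fixed REF means ALT is derived, fixed ALT
complements the ingroup counts, and a polymorphic outgroup (or one with
fewer than `min_outgroup_alleles` called copies, default 1) discards the
site.  Binning at target sizes (n1, n2, n3) either hypergeometrically
projects any site with at least the target number of called alleles per
population (`project`, the default) or keeps only exactly-matching sites
(`drop`).  Sites below target are dropped and counted; every input site is
accounted for by exactly one counter.

## The simulator

Joint spectra are simulated at unlinked sites: each site draws an
independent genealogy from the structured coalescent (via msprime) and
receives exactly one mutation, placed uniformly at random on total branch
length.  Because the statistic depends only on the joint distribution of
allele frequencies at variant sites — not on how many sites vary — one
mutation per site is equivalent in expectation to a mutation-rate model,
and the result is independent of absolute population size, generation time
and mutation rate.  Spectra are polarized by construction, so no outgroup
population is simulated; this mirrors empirical practice where an adequate
outgroup is assumed available.

Units and conventions, fixed once:

- Time is measured in units of 2·N_ref generations; a population of
  relative size ν = N/N_ref has pairwise coalescence rate 1/ν per unit.
  Internally, genealogies use haploid individuals, whose msprime pairwise
  rate is 1/Ne, so `initial_size = ν` realizes the convention (validated by
  the mean pairwise TMRCA of 1.0 in tests).
- A migration epoch with population-scaled rate M = 2Nm moves each lineage
  of the forward-time recipient back to the donor at rate M per unit time:
  forward, a fraction m of the recipient is replaced per generation, so a
  lineage traces to the donor at rate m per generation = 2Nm per 2N
  generations.  The convention is validated by the null (no-flow D = 0) and
  by the direction of the D signal under one-way flow.
- One master seed drives everything; per-replicate mutation positions and
  per-grid-cell seeds derive from numpy `SeedSequence` spawning, so results
  are bit-reproducible and independent of execution order.

An optional mutation-age window (t_min, t_max) restricts placement to
branch segments overlapping the window, enabling the decomposition of the
signal into ancient (pre-split) versus recent mutations.  A genealogy with
no eligible branch length is resampled and counted; a window no genealogy
can satisfy raises after a bounded number of rounds.

## Scenario presets

The migration rates in the presets are the published scaled rates for each
scenario (2 for recent inward flow, 3 for older and ancient flow, 2 for
outward flow, 2 and 1 for bidirectional, 3 and 0.5 for flow into both
recipients).  Split times, pulse placement, bottleneck depth and structure
parameters are not dictated by the scenarios themselves, so the presets use
round values chosen to place each scenario in the regime where its
characteristic shape appears; all are keyword-overridable:

- Generic history: P1/P2 split at t = 0.5, P3 split at t = 1.0, all sizes 1.
  "Recent" flow occupies [0, 0.1], "old" [0.2, 0.3].
- `ancient_geneflow` deepens the splits (t12 = 2.0, t123 = 2.5, flow in
  [1.6, 2.0]): concentration of the signal in the fixed bin requires the
  flow to be ancient relative to 2N, i.e. enough post-flow drift (here 1.6
  units) for introgressed variation to sort to fixation or loss.
- Bottleneck presets shrink P2 to ν = 0.05 over [0.05, 0.15] — two
  coalescent units of in-bottleneck drift, enough that gene flow placed
  before the bottleneck loses its low-frequency excess, while flow after
  the bottleneck restores it.
- `ancestral_structure` subdivides the common ancestor into two demes with
  symmetric migration M = 0.5 from t = 2.0 until a shallow P1/P2 split at
  t = 0.1 (P3 branches from P2's deme at t = 1.0).  The shallow split is
  what empties the low-frequency bins: right up to the split, migration
  keeps depositing each deme's alleles into the other at low frequency, so
  the rare end of both spectra is symmetric while common alleles remain
  deme-specific.
- `ancient_mutations_only` is the recent-flow model with the mutation
  window restricted to ages ≥ t123.

## What the synthetic data does and does not show

The simulator emulates neutral, unlinked, freely polarized biallelic sites
under piecewise-constant demography.  It does not model linkage (no
recombination or haplotype structure, so block-level noise in real genomes
is absent), selection, mutation-rate heterogeneity, polarization error from
outgroup polymorphism, or genotyping error; the VCF fixture generator draws
population frequencies independently rather than from a coalescent, so it
validates bookkeeping (parsing, filtering, polarization, projection), not
population-genetic realism.  Passing tests therefore demonstrate that the
statistic and pipeline compute what they claim on clean input, and that the
scenario shapes are genuine consequences of the stated demographies — not
that empirical spectra will be free of the confounders above.

## Problem sizes and numerical choices

Monte Carlo checks use 8 haploid genomes per population and 2×10^5 unlinked
sites per scenario — enough that every asserted sign is resolved at three
site-bootstrap standard errors — except the recent-gene-flow signature,
which runs 4×10^5 sites because its inverted fixed bin (true D_n ≈ −0.05)
is the smallest asserted effect.  Standard errors come from a multinomial
site-resampling bootstrap (200 replicates) over spectrum cells.  Exact
identities are asserted at 1e-12; spectra are stored as float64 throughout;
hypergeometric projection uses scipy's exact pmf, conserving total mass to
~1e-10 relative.

## Known limitations

- Only the fixed (((P1, P2), P3)) topology is modeled; no arbitrary
  population graphs.
- Unlinked sites only: no recombination/linked-sequence simulation and no
  tract-length statistics.
- No significance machinery for empirical genome scans (block-jackknife
  Z-scores, f-statistics) — the bootstrap here assumes independent sites
  and is intended for simulated spectra.
- The per-bin bootstrap treats the spectrum as multinomial, which is exact
  for integer site counts and approximate for fractional (projected) mass.
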