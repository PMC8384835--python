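# Methods

This note documents the models, parameter choices and numerical decisions
behind `epitopemap`, and what validation on synthetic data does and does
not establish.

## Library design

A protein of length L is tiled into `window`-mers (default 15) staggered by
`stagger` residues (default 5). Full windows start at 1, 1+5, 1+10, …;
when the last full window ends short of the C-terminus, one terminal
peptide is appended starting one stagger later and ending at residue L, so
the library covers every residue. For L = 1053 this yields 208 full
15-mers plus a terminal 13-mer (209 peptides). A configurable
`min_terminal_length` (default 7, the shortest peptide MHC-II elution data
typically contains) guards against degenerate one- or two-residue tails: if
the natural terminal fragment would be shorter, its start is pulled back to
reach that length. Pools are consecutive chunks of `pool_size` (default
10) peptides, the last pool taking the remainder; a pool's span is the
(min start, max end) over members, so consecutive pool spans overlap by
`window − stagger` residues. All coordinates are 1-based inclusive.

`locate_peptide` maps a sequence by first exact occurrence and flags
multiplicity rather than resolving it: on antigen-scale proteins repeated
7+-mers are rare, and surfacing the ambiguity is safer than guessing.
Matching is case-insensitive; sequences are normalized to uppercase.

## Cohort selection

The published algorithm this step corresponds to is not described beyond
its goal (a cohort whose allele spectrum matches a reference population),
so the objective and schedule here are this package's own design:

* **Objective**: L1 distance between the cohort's DRB1 allele frequencies
  (counts over 2n chromosomes) and the reference table, with missing
  entries read as 0 — cohort alleles absent from the reference contribute
  their full frequency, penalizing unrepresentative alleles. L1 is robust
  to the long tail of rare alleles; an L2 variant is available via
  `metric="l2"`.
* **Search**: simulated annealing over size-n subsets; a move swaps one
  selected donor for one unselected donor; Metropolis acceptance with
  geometric cooling T_k = T0·α^k, defaults T0 = 1.0, α = 0.995, 20,000
  iterations. The best-ever subset is returned and the per-iteration
  objective trace is kept for diagnostics. On 12-donor pools the default
  schedule finds the exhaustive optimum in ≥ 95% of seeded runs (tested).

Only DRB1 is modelled — the locus that dominates CD4+ responses to protein
antigens; readers ignore other loci with a logged note.

## Responder calling

Each stimulated donor × stimulus × marker count is compared with the
donor's unstimulated control for the same marker by a one-sided Fisher
exact test (alternative: stimulated positive fraction greater), computed
as the hypergeometric upper tail so it vectorizes across a donor's tests.
Degenerate tables where enrichment is impossible return p = 1, never an
error.

**Multiplicity.** The adjustment family is all stimulus × marker tests of
one donor (pools, whole proteins and controls alike), adjusted by
Holm-Bonferroni; a call is positive iff adjusted p < α (default 0.05).
This is family-wise error control per donor. (Assay write-ups sometimes
label this procedure a "false-discovery rate"; Holm controls FWER, which
is the stricter quantity, and that is what is implemented and tested.)
Adjusting per donor rather than jointly across donors matches the
per-donor control structure of the assay — each donor carries its own
unstimulated reference — and keeps donors exchangeable; a joint family
would make one donor's calls depend on another's counts.

The donor-level rule is worst-case: a donor responds to a stimulus if any
of the three cytokines is positive. Percent responders per stimulus,
positive-pool counts per donor (pool stimuli only; proteins and SEB
excluded) and log fold changes (base 2, pseudocount 0.5 — both
configurable) derive from this. SEB rows are QC'd (each donor's SEB
response should be positive) but never contribute to promiscuity or pool
counts.

## Allele association and coverage

A donor *carries* an allele if it appears in either DRB1 slot (homozygotes
count once). The *any* rule marks (allele, stimulus) true when ≥ 1 carrier
responds; the *all* rule when every carrier among the donors with calls
responds — so the strict matrix is always a cellwise subset of the lenient
one (property-tested). Promiscuity score(s) = Σ frequencies of associated
alleles; the raw associated-allele count is emitted alongside rather than
normalizing the score, so both readings are available. Cumulative
population coverage of an allele set is the plain frequency sum in percent
(no diploidy or linkage correction); a Hardy-Weinberg carrier-coverage
variant, 1 − Π(1−f)², is provided as `carrier_coverage` but is not the
default.

## MAPPs processing

Identifications are filtered at EV ≤ 0.05 (boundary inclusive), mapped by
exact substring match (mismatching peptides are dropped, counted and
logged — the search engine, not this package, owns mutation tolerance),
and merged into maximal continuous regions: two identifications join a
region iff their spans share ≥ 1 residue (configurable `min_overlap`);
adjacent-but-disjoint spans stay separate. "Unique peptides" is reported
as the cohort-scope merged region count, with the distinct-raw-sequence
count emitted alongside, since elution data consists of nested length
variants around a shared core and either notion may be wanted. Length
statistics are computed on individual identifications, not regions.

## Integration

Four steps: (1) match every MAPPs donor with every T-cell donor sharing
≥ 1 DRB1 allele (all pairs contribute independently); (2) per match, take
the union over (identification, positive pool) pairs of their residue-span
intersections — partial overlaps kept, since the subsequent step operates
on residues, not whole peptides; (3) union the matched residues across all
matches, decompose into maximal runs, and drop runs shorter than
`min_length` (default 9 — runs of exactly 9 are kept); (4) cross-reference
the surviving intervals with the distinct MAPPs regions, requiring
≥ `min_length` shared residues (stricter than ≥ 1, so the 9-residue filter
is not undone by a 1-residue graze). A candidate's span is the
region ∩ interval overlap and its sequence is read off the protein at that
span; supporting matches are those whose matched residues intersect the
span, and its associated alleles are the union of their shared alleles.
Candidate coverage is the cumulative allele frequency of all candidates'
alleles. The pool side uses per-pool spans by default; `distinct=
"sequences"` switches the cross-reference to distinct raw peptides.

The whole procedure is monotone — adding an identification or a positive
call never removes a candidate — and equals an exhaustive enumeration of
all (match, identification, pool) triples on small instances (both
tested).

## Synthetic data

The generator emulates the five input roles (reference frequencies,
genotypes, cell counts, MAPPs identifications, antigen) with planted
ground truth. Defaults follow the assay design scale: 1053-residue
antigen, 50-donor typed pool from which 21 T-cell donors are annealed, 18
MAPPs donors, 20 DRB1 alleles.

* **Population**: allele frequencies ~ symmetric Dirichlet(0.5) (a skewed
  spectrum with a few common and many rare alleles, as real DRB1 tables
  show); genotypes are two independent draws (Hardy-Weinberg, no linkage).
* **Epitopes**: 8 non-overlapping spans of 12–20 residues, ≥ 30 residues
  apart, each presented by 1–3 alleles drawn proportional to population
  frequency — epitopes restricted to vanishingly rare alleles are
  unobservable in a 21-donor cohort, so the frequency-weighted regime is
  the one the assay can see.
* **Counts**: binomial per sample. Background positive rate 1e-4 and
  totals uniform in 5e4–1e5 put a 20-fold planted effect
  (`effect_multiplier`, default 20) at near-complete Fisher power while a
  2-fold effect is mostly undetectable — a realistic dynamic range for
  ICS counts. A donor's expected positive pools are those overlapping an
  epitope presented by one of its alleles; per expected combination each
  marker responds with probability 0.7 (≥ 1 forced), mimicking
  marker-to-marker heterogeneity. SEB always responds at 50-fold;
  unstimulated rows are pure background.
* **MAPPs**: per donor and presented epitope, a ladder of 1 + Poisson(3)
  peptides with lengths ~ N(15, 3.5) clipped to 7–24 (median ≈ 15, the
  canonical MHC-II length profile) and centers jittered ±4 residues around
  the epitope center; true EVs log-uniform on [1e-4, 0.05]. Decoy (false)
  identifications arrive at Poisson(0.5) per donor at uniform positions
  with EVs log-uniform on [0.03, 3], so ≈ 11% survive the EV filter —
  consistent with EV ≤ 0.05 implying a sub-percent false share of a
  ~40-identification donor.

Recovery is scored by span overlap: an epitope is recovered (and a
candidate is true) when they share ≥ 9 residues (or the full epitope if
shorter); precision on an empty candidate list is 1 by convention. At the
default configuration, mean recall and precision over 20 seeds exceed 0.9,
and mean recall is non-increasing in the effect multiplier down to the
null (both enforced in the acceptance tests).

**What this does not show.** The generator has no MS intensity model, no
linkage disequilibrium between alleles, no donor-specific assay effects
(viability, staining efficiency), no shared-epitope cross-reactivity and
no non-DRB1 restriction. Passing the recovery tests demonstrates that the
analysis correctly inverts its own generative assumptions at realistic
signal levels — not that those assumptions exhaust real assay noise.

## Numerical choices and degenerate inputs

* Fisher on tables where enrichment is impossible returns p = 1.
* Holm via the standard step-down implementation; the unit tests pin it to
  hand-computed values, and the Fisher path is pinned to an exact
  `math.comb` tail sum at 1e-10 on margins ≤ 200.
* Annealing accepts equal-objective moves (delta = 0), which lets plateaus
  drift instead of freezing; ties between equally optimal subsets are
  resolved by the seeded random walk, and determinism is guaranteed only
  per seed.
* Empty inputs: empty peptide library, empty donor set and zero totals are
  errors; empty MAPPs lists, empty residue sets and zero candidates flow
  through as empty results.
* Pipeline problem sizes in the test suite use a reduced synthetic study
  (300-residue antigen, 6 T-cell donors) where full scale adds nothing to
  the property under test; the recovery and error-control tests run at
  full default scale.

## Known limitations

* Exact substring mapping cannot place identifications from antigen
  variants (point mutations, PTM-altered residues).
* The cohort-selection objective is a stand-in for the unpublished
  original; results about it describe this implementation only.
* The all-rule denominator is the cohort's carriers; with 1–2 carriers per
  allele the strict map is noisy, which is inherent to small typed
  cohorts, not to the implementation.
* Cumulative allele frequency sums can exceed realistic carrier fractions
  when many alleles are involved; use `carrier_coverage` for a bounded
  estimate.
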