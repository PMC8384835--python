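# epitopemap

Identification of CD4+ T-cell epitopes in a protein antigen by integrating
two complementary ex vivo assays:

1. **Overlapping-peptide T-cell activation.** The antigen is tiled into
   overlapping 15-mer peptides (staggered by 5 residues) organized into
   pools of 10. PBMCs from an HLA-DRB1-typed donor cohort — selected by
   simulated annealing so its allele spectrum matches a reference
   population — are stimulated pool by pool, and intracellular cytokine
   staining (IFN-γ, TNF-α, IL-2) yields gated positive-cell counts per
   donor × stimulus × marker.
2. **MHC-II immunopeptidomics (MAPPs).** Peptides eluted from MHC-II
   molecules on antigen-pulsed dendritic cells are identified by LC-MS/MS,
   each with an Expect Value (EV); identifications with EV ≤ 0.05 are
   retained and mapped onto the antigen.

A peptide region that T-cells respond to *and* that dendritic cells
actually process and present is a credible epitope. The package implements
the full analysis for tools of this design: library design, responder
statistics, allele-level association and population coverage, MAPPs
processing, and the cross-assay merge — plus a synthetic-data generator
that plants known epitopes so the whole workflow can be validated.

## Statistical core

For each donor × stimulus × marker, enrichment of cytokine-positive cells
over the donor's unstimulated control is tested with a one-sided Fisher
exact test on the 2×2 table

```
                positive      negative
stimulated        a             n_s − a
unstimulated      c             n_u − c
```

with p = P(X ≥ a) for hypergeometric X conditioned on both margins.
P-values are Holm-Bonferroni adjusted within each donor's family of tests;
calls with adjusted p < α (default 0.05) are positive, and a donor responds
to a stimulus if **any** of the three cytokines is positive (worst-case
rule). At the allele level, an allele–stimulus pair is associated under the
lenient *any* rule (≥ 1 carrier responds) or the strict *all* rule (every
carrier responds); the promiscuity score of a stimulus is the sum of
reference-population frequencies of its associated alleles. The final merge
matches donors across the two assays by shared DRB1 allele, intersects each
MAPPs identification with the matched donor's positive pool spans, unions
the matching residues across all matches, drops runs shorter than 9
residues (the MHC-II binding core), and cross-references survivors with the
distinct merged MAPPs regions.

## Worked example

```python
import epitopemap as em

# a complete synthetic study with 8 planted epitopes (seed-deterministic)
ds = em.simulate_dataset(em.SimulationConfig(seed=1))
print(f"library: {len(ds.peptides)} peptides in {len(ds.pools)} pools")

calls = em.call_responders(ds.counts, alpha=0.05)
print(f"positive calls: {sum(c.positive for c in calls)} of {len(calls)}")

kept = em.filter_by_expect_value(ds.mapps_peptides)        # EV <= 0.05
mapped, _ = em.map_mapps_peptides(kept, ds.protein)
regions = em.merge_regions(mapped, scope="cohort")
s = em.summarize_mapps(mapped, regions)
print(f"MAPPs: {s.n_identifications} identifications from {s.n_donors} donors"
      f" -> {s.n_unique_regions} unique regions (median length {s.median_length:.0f})")

cands = em.integrate_epitopes(calls, mapped, ds.tcell_genotypes,
                              ds.mapps_genotypes, ds.pools, ds.protein)
cov = em.epitope_population_coverage(cands, ds.allele_frequencies)
print(f"final epitopes: {len(cands)}, cumulative allele frequency {cov:.1f}%")

m = em.recovery_metrics(cands, ds.truth)
print(f"recovery vs planted truth: precision {m.precision:.2f}, recall {m.recall:.2f}")
```

prints, for seed 1:

```
library: 209 peptides in 21 pools
positive calls: 361 of 1449
MAPPs: 255 identifications from 16 donors -> 9 unique regions (median length 15)
final epitopes: 9, cumulative allele frequency 93.8%
recovery vs planted truth: precision 0.89, recall 1.00
```

The 209/21 geometry is the standard design for a 1053-residue antigen; the
nine candidates are the planted epitope regions recovered from the noisy
synthetic assays (one spurious region slips through in this seed, hence
precision 0.89), and the cumulative allele frequency is the summed
reference-population frequency of every DRB1 allele supporting a candidate
— an upper-bound estimate of the population fraction able to present and
respond to at least one epitope.

The same stages run from the shell on TSV/FASTA inputs:

```sh
epitopemap simulate --seed 1 --out-dir data/
epitopemap design --fasta data/protein.fasta --out library.tsv
epitopemap call-responders --counts data/counts.tsv --out calls.tsv
epitopemap run --config pipeline.yaml          # all stages at once
```

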