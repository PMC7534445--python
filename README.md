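# polybrix

Presence/absence allele–trait association mapping for mixed-ploidy clonal
crops, built around the workflow used to find soluble-solids-content (SSC)
loci in autopolyploid blackberry: a small clonal cohort (4x–8x) is
sequenced, every locus-allele is coded as a dominant (presence/absence)
marker, alleles are screened against the quantitative phenotype, vetted
against population structure, validated per environment, and turned into
KASP-style diagnostic assays — with cross-genus syntenic QTL intersection
to pick candidate regions in the first place.

## Who this is for

Breeders and genomicists working on high-ploidy clonal crops where allele
dosage cannot be called reliably, genetic maps are sparse, and marker
discovery has to run on a few dozen sequenced individuals plus validation
panels scored with cheap uniplex assays.

## The method

For each locus kept by the filters (< 20% missing cells, 2–4 observed
alleles), every observed allele *a* becomes a binary column
x_a(s) = 1 if sample *s* carries ≥ 1 copy (dosage discarded). Each column
is screened with Welch's two-sample t-test of SSC between carriers and
non-carriers, and p-values are corrected by Benjamini–Hochberg (α = 0.05).
Screen survivors are fitted to two nested OLS models against population
groups G (inferred DAPC-style — PCA, then k-means over candidate k with
BIC — or supplied externally):

    model 1:  SSC = G + A + G×A + ε        (interaction test)
    model 2:  SSC = G + A within G + ε     (within-group test)

An allele is selected as a diagnostic candidate iff its BH q ≤ α, its G×A
interaction is *not* significant (the effect is consistent across groups),
and its within-group allele term *is* significant (the association
survives conditioning on structure). Selected markers are re-tested per
location-year environment (Welch + BH within each environment), and
flanking consensus templates are generated for assay design: target allele
verbatim, other SNPs IUPAC-coded, flanking indels flagged.

A fully parameterized simulator generates cohorts with this exact
generative structure (group-divergent allele frequencies, planted °Brix
effects, pure-interaction "structure-confounded" effects, depth-driven
missingness, replicate phenotypes in multiple environments), so every
stage is testable without any external data.

## Worked example

`examples/discover_alleles.py` simulates 96 samples × 400 loci in two
groups, plants two structure-independent alleles (+2.0 and +1.5 °Brix) and
one structure-confounded allele (opposite sign per group), and runs the
full discovery pass:

```
loci: 400 in -> 400 kept (0 too much missing data, 0 outside 2-4 alleles)
structure: chose k=2 groups from 66 PCs
columns screened: 636, BH-significant: 5, selected: 3

selected alleles (°Brix effect = carrier mean - non-carrier mean):
                   effect_brix       q  p_interaction  p_within
locus      allele
Ro01:10685 G            2.1258  0.0000         0.6505     0.000
Ro01:15480 C            1.5834  0.0016         0.5682     0.000
Ro06:15617 T            1.9206  0.0499         0.6301     0.019
```

Both planted structure-independent alleles are recovered with effect
estimates near truth; the confounded allele is rejected by its significant
group × allele interaction. The other examples cover cohort simulation and
file round trips, per-environment marker validation, KASP template design,
the packaged reference tables (40-sample cohort summary, 13-sample
sequencing-vs-KASP concordance panel), and syntenic QTL intersection with
bait-tiling arithmetic.

A thin CLI mirrors the stages (`polybrix simulate | gtable | associate |
validate | design-kasp | concordance | synqtl | run`); `polybrix run
--config cfg.yaml --out DIR` executes the whole pipeline reproducibly,
stamping every artifact with the configuration hash.

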