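# Methods

`ssrwild` analyses dominant (presence/absence) SSR band data from a
multi-species germplasm survey: a panel of primer pairs is scored on a set
of accessions spanning several taxonomic sections of a genus, and the 0/1
band matrix drives four analyses — cross-species transferability, detection
of taxon-specific alleles and marker classes, Nei–Li-distance
neighbor-joining dendrograms with bootstrap support, and genetic-distance
ranking of candidate diploid genome donors of an allotetraploid.  Because
band-scoring matrices of this kind are rarely published, the package ships
a synthetic-data generator that reproduces the statistical structure of
such a survey with a planted ground truth, so every detector can be tested
for exact recovery.

## Scoring model

Each marker (primer pair) amplifies zero or more discrete fragment sizes
per accession.  Allele identity is the exact pair `(marker_id, size_bp)`;
sizes are assumed pre-called against a ladder, and an optional binning
tolerance is deliberately *not* applied (default 0 bp — two bands are the
same allele only at identical called size).  A cell is 1 if the band was
observed and 0 otherwise; there is no missing-data state, matching strict
0/1 dominant-marker coding.  The markers × accessions amplification matrix
is always the any-allele-present reduction of the allele matrix and is
re-derived and cross-checked after every load.

## Transferability

A marker of class *genomic* was developed from a genomic library of the
cultivated species, so cultivated accessions are excluded from every
denominator for that class; *genic* (EST/gene-derived) markers count all
accessions.  Two rates are computed and kept apart:

* **section-level** — a marker is transferable to a section iff it
  amplifies in ≥ 1 scorable accession of the section.  This is the reading
  under which the source section scores 100% even when the per-accession
  rate is lower.  The class "Mean" row is the half-up-rounded arithmetic
  mean of the per-section percentages (and, for the count column, the exact
  mean count).
* **accession-level** — for each marker, the fraction of scorable
  accessions amplifying, averaged over markers.

Percentages are rounded half-up, the convention of printed survey tables.
The genic-vs-genomic comparison is a pooled two-proportion z-test applied
to the per-class mean transferable counts over the class panel sizes, with
a two-sided normal p-value.  This basis is our own documented choice; other
bases (e.g. per-accession pooling) give different statistics, and no
attempt is made to match any particular published z value.

## Distances and trees

The distance between two band profiles is the Dice complement

    D(x, y) = 1 − 2a / (2a + b + c)

(`a` shared bands, `b`/`c` private bands), the standard binary-marker
reading of the Nei–Li coefficient.  Jointly absent bands never contribute,
and the coefficient is undefined when both profiles are empty — such input
is rejected, not imputed.  The −ln(F) variant is out of scope but isolated
in a single function for easy substitution.

Trees are built with Studier–Keppler neighbor joining: join the pair
minimizing `Q(i,j) = (n−2)·d(i,j) − R_i − R_j`, branch lengths by the
standard formulas, negative lengths clamped to zero (raw values are
logged at debug level), ties broken by the first minimum scanning the
upper triangle row-major — i.e. the smallest (row, column) position pair —
so results are deterministic.

**Identical profiles.** Two accessions at exact distance zero are
indistinguishable, yet the raw Q criterion can place them apart when a
third, equally similar neighbor intervenes.  We therefore collapse
exact-zero-distance groups to one representative before joining and
re-expand them afterwards as zero-length cherries (chains, for groups
larger than two, in sorted label order).  This guarantees that identical
accessions always sit together and that their placement never depends on
resampling accidents.

Section-level dendrograms use the mean of all inter-section accession-pair
distances (unweighted average linkage between groups); within-group
distances do not enter.

## Bootstrap support

Characters are resampled with replacement — allele columns by default, or
whole markers (`unit="marker"`), since markers are the independent loci and
both readings of character resampling are defensible.  The support of each
non-trivial bipartition of the full-data tree is the percentage of
replicate trees containing it.  A replicate that leaves an accession with
an all-absent profile has no defined distances and is redrawn (at most 100
times, then an error).  Within a replicate, accessions at exact distance
zero form an unresolved cluster: any bipartition nested inside such a
cluster is counted as supported by that replicate, because the resampled
characters cannot distinguish its members and therefore cannot contradict
any arrangement of them.  Supports are reported as integer percentages in
Newick internal-node labels (branch lengths with six decimals).

Taxon concordance is the fraction of taxa (species, sections or genome
classes with ≥ 2 leaves) whose leaf set is one side of an edge-induced
split of the unrooted tree — the unrooted analogue of monophyly.

## Donor inference

An allotetraploid (AABB) carries both diploid subgenomes, so its genome
donors should be the diploids genetically closest to the tetraploid group.
"Distance to the group" is the arithmetic mean of the pairwise Nei–Li
distances to each group member — parameter-free, unlike a consensus-profile
construction (noted as a possible extension).  Candidates are restricted to
diploid (2n=20) accessions of genome classes A and B within section
Arachis; the top-ranked accession in each class is the nominated donor.

## Synthetic-data generator

The generator emulates a genus-wide survey of 7 sections, ~35 species and
~95 accessions genotyped with 82 genomic + 19 genic markers.  Defaults are
the study conditions of the survey the package models:

| parameter | default | rationale |
| --- | --- | --- |
| `n_genomic_markers` / `n_genic_markers` | 82 / 19 | published panel composition |
| `base_transfer_prob` | 0.76 / 0.88 | published per-class mean transferability |
| `alleles_per_marker` | 4–29 | published allele-count range of the clustering subset |
| `cultivated_accessions` | 11 | cultivated accessions in the surveyed germplasm |
| `species_per_section` / `accessions_per_species` | 4–6 / 2–3 | gives ~35 species, ~95 accessions |
| `section_divergence_penalty` | 0.05 | mild transferability decay with divergence rank |
| `p_private_allele` | 0.05 | ~100+ private alleles genus-wide, the reported order |
| `donor_retention` | 0.95 | tetraploids retain almost all donor alleles |
| `p_tetraploid_locus` | 0.1 | ~10 of ~82 genomic markers show duplicated loci |
| `section_exclusive_frac` / `species_pool_frac` / `allele_presence_prob` | 0.7 / 0.7 / 0.8 | see below |

Section Arachis always receives one A-, one B- and one D-genome diploid
species plus the allotetraploid cultivated (AB) species;
`species_per_section` governs the other sections and any extra A/B species.
Sections carry a fixed divergence rank from the source section
(Arachis < Erectoides < Procumbentes < Heteranthae < Caulorrhizae <
Extranervosae < Triseminatae, configurable); a marker amplifies in a
diploid accession with probability `base_transfer_prob[class] ×
max(0, 1 − penalty·rank)`.

Alleles come from hierarchical pools: each marker draws a global pool of
distinct sizes (without replacement, so `(marker, size)` pairs are unique);
a fraction `section_exclusive_frac` of pool alleles is assigned exclusively
to one section; each species subsamples its section pool
(`species_pool_frac`), and each amplified accession carries each
species-pool allele with probability `allele_presence_prob` (at least one).
A Dice-similarity back-of-envelope with these defaults puts within-species
similarity above within-section above between-section similarity, which is
what makes simulated accessions cluster by species and section the way the
real survey's dendrogram does.  The species-pool construct itself is our
own device — the survey only notes that intraspecific variation was high
for some species, without quantifying it.

Private alleles are planted per (species, marker) with probability
`p_private_allele`, using fresh sizes, and recorded in the ground-truth
ledger.  A deterministic cleanup pass then guarantees that the
species-specific alleles of the diploid view are *exactly* the planted
ones: any non-planted allele carried by a single diploid species gains one
extra carrier from another species (pool holders first, then the same
section, then anywhere — mimicking homoplasy), or is dropped when no other
accession amplified that marker.  Without this pass, random subsampling
would create accidental singletons and no exact-recovery statement could
be made.

Tetraploid accessions carry the union of the two designated donors' final
allele sets, each allele kept with probability `donor_retention`.  A
fraction `p_tetraploid_locus` of genomic markers (among those both donors
amplify) gains a tetraploid-only fragment carried by all tetraploids; the
first tetraploid is anchored to retain one allele from each donor at those
markers so the full duplicated-locus signature (A-fragment + B-fragment +
unique fragment) is always present.  Ground truth records donors, private
alleles, section-specific alleles (computed from the emitted matrix),
tetraploid-only alleles and duplicated-locus markers.

All draws use counter-keyed RNG sub-streams (`seed` plus purpose/marker/
accession indices), so enlarging the panel or the germplasm never perturbs
earlier draws and everything is reproducible from one seed.

**What the generator does not emulate.**  Amplification is Bernoulli, not
mechanistic: there is no primer-sequence model, no section-wide marker
loss (so simulated section-level transferability saturates near 100% even
though accession-level rates calibrate to the configured 0.76/0.88), no
band-intensity or co-migration ambiguity, and no geographic structure.
Passing recovery tests therefore show the detectors are correct under the
stated generative model, not that real gels are free of scoring error.

## Numerical and degenerate-input choices

* Exact symmetry and zero diagonal are enforced on every distance matrix.
* Percentages round half-up (`floor(x + 0.5)`), never banker's rounding.
* An accession with an all-absent profile makes Nei–Li undefined; loaders
  accept such a column but distance computations reject it by name, and the
  simulator floors every accession at one band.
* NJ with fewer than 3 labels is an error; 2-leaf trees occur only as
  intermediate objects during identical-profile expansion.
* Report TSVs sort rows by all columns so reruns are byte-identical.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data at
the default survey scale (~95 accessions × 101 markers, ~1,700 allele
characters): 100 simulated datasets for donor recovery (plus 3 × 50 for the
retention monotonicity curve), 50 for transferability calibration, 20 for
private-allele recovery, 10 for section concordance, 50 random 6–10-leaf
additive matrices for the NJ oracle, and 200 bootstrap replicates for the
support checks.
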