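# Methods

## Background and scope

SVA (SINE-VNTR-Alu) elements are hominid-specific composite
retrotransposons mobilized in trans by LINE-1. Somatic SVA integrations
accumulate during development: an insertion arising in a progenitor cell
is inherited by all of that cell's descendants and by none of its
cousins, so presence/absence of an insertion across tissue samples is a
binary, effectively irreversible clade marker. `svarda` implements the
computational arm of a representational-difference-analysis (RDA)
enrichment assay for such insertions: deep-sequenced amplicons capture
the genomic 5'-flank of each SVA integration, and the pipeline turns
those reads into de novo insertion events, cross-region marker matrices,
a maximum-parsimony lineage tree of brain regions, and statistics about
where insertions land.

The package is organized as a library (`src/svarda/`) driven by numbered
analysis scripts (`analysis/01_simulate.py` … `06_evaluate.py`) and a
`svarda` CLI. All inputs are synthetic: the generator in
`svarda.synthetic_data` defines the study conditions, so every stage is
testable without external downloads.

## Read model and processing

An RDA amplicon read has the layout

```
[24-mer RDA primer] [GATC] [genomic 5'-flank] [(CCCTCT)_n] [SVA body ...]
```

The `GATC` after the primer is the reconstituted MboI site at the adapter
ligation junction and is present in every true product; it is skipped
during flank excision rather than treated as an artifact. A `GATC`
*inside* the flank, by contrast, marks a re-ligation chimera (an SVA
joined to an unrelated restriction fragment) and rejects the read.
Processing steps: optional pair merging (maximal suffix/prefix overlap,
min 10 bp, mismatch fraction <= 0.1, higher quality base wins), primer
selection with orientation normalization (reads ending in the primer's
reverse complement are flipped; matching is exact by default because RDA
products contain the literal primer), hexamer scanning (leftmost tandem
run of >= 2 exact `CCCTCT` copies; the true copy number is variable, so
the detector must not assume a specific n), flank excision with the
artifact and strict >30 bp length filters, and exact-sequence collapsing
with read support carried as multiplicity.

## Insertion calling

Candidate flanks pass a four-stage cascade:

1. **Reference-SVA subtraction.** Flanks aligning to any annotated SVA
   extended by 1 kb are discarded — these are germline leak-through or
   reference-derived sequences that escaped the experimental subtraction.
2. **Unique genome mapping.** A flank is kept only with exactly one
   qualifying alignment genome-wide, counting both strands; zero-hit and
   multi-hit flanks are tallied separately in the run report.
3. **Annotated-SVA proximity subtraction.** Hits overlapping annotated
   SVA +- 3 kb are removed (stringency re-check).
4. **Event collapsing.** Remaining hit intervals are single-linkage
   merged per region; an event carries the summed read support and the
   number of distinct flank sequences.

The built-in aligner is a 16-mer seed index with ungapped verification.
In exact mode it reports every exact occurrence (seeding at the query's
first k-mer is lossless). In near-exact mode seeds are sampled at
k-spaced offsets, so a hit can be missed only when every sampled seed
carries a mismatch; with the default thresholds (identity >= 0.95 over
coverage >= 0.90) this is adequate for the synthetic scale, and external
aligners can be substituted by importing their hit tables. Default
thresholds are a design choice — the assay itself fixes no alignment
acceptance criteria — and the evaluation experiments run in exact mode.
Hit coordinates are always reported on the forward strand. All
coordinates package-wide are 0-based half-open (BED convention); abutting
intervals do not overlap.

## Marker matrix and parsimony

Per donor, the union of all regions' event intervals is merged into
reference loci; `state(region, locus) = 1` iff any of the region's
events overlaps the locus. Characters can be serialized as two-letter
sequences (`A` = present, `T` = absent) in FASTA/relaxed PHYLIP for
cross-checking with external parsimony programs.

The tree search is exhaustive: all unrooted topologies are enumerated
(15 for 5 taxa) and scored by Fitch small parsimony, vectorized across
characters. Exhaustive enumeration is exact where heuristic search is
merely conventional; it is capped at 10 taxa (~2 x 10^6 topologies), far
above the study's 5 regions. The first minimal-length topology in the
deterministic enumeration order is reported, rooted on the cerebellum —
the developmental outgroup, since the cerebellum derives from the
metencephalon while the other four regions are telencephalic. Per-branch
steps come from a deterministic minimum-length refinement of the Fitch
state sets: each node takes its parent's state when compatible, and the
root takes the outgroup state, fixing character polarity. One
presentational consequence: the outgroup terminal edge and the adjacent
internal edge form a single unrooted edge, and all of its steps are
charged to the ingroup side, so the outgroup leaf shows length 0. The
invariant `tree length == sum of branch steps == sum of per-character
minima` is asserted on every search.

Bootstrap support resamples loci (columns) with replacement; a
replicate's co-optimal trees each contribute fractionally (1/k) to the
bipartitions they contain. The seed is a required parameter.

Two informative-site counts are reported: the lineage definition
(present in >= 2 and <= R-1 regions; singletons and fully shared loci
carry no branching signal) and the standard parsimony definition
(>= 2 taxa in each state). They differ exactly on loci present in R-1
of R regions.

## Integration landscape

* **Chromosomal density** d_c = n_c * L-bar / S_c * 10^6 ("SVA bp per
  million chromosomal bp"), with L-bar the mean annotated SVA length and
  S_c the chromosome size; the de novo profile (multi-donor arithmetic
  mean) is compared to the annotation's own profile by Pearson r with
  t = r * sqrt(n-2) / sqrt(1-r^2) and a two-tailed Student-t p-value
  (df = n-2, n = chromosomes).
* **Feature annotation** assigns each event one label at its midpoint by
  fixed precedence: Promoter (TSS -1 kb .. +100 bp, strand-aware) > 5'UTR
  > 3'UTR > Exon > TTS (-100 bp .. +1 kb) > ncRNA > SINE > LINE > LTR >
  DNA > Satellite > Intron > Intergenic. A point rule is required for a
  single-label fraction table; gene features outrank repeats, mirroring
  common annotators' behaviour.
* **TE-rich windows**: 100 kb windows with a 10 kb stagger (truncated
  trailing windows kept so every position is covered), scored by their
  SINE+LINE element count. "Above average" is strict (>); the top-25%
  set uses the linear-interpolation 75th percentile with >= at the
  threshold. The two sets are computed independently (on skewed counts
  the top-25% set need not nest inside the above-mean set). Enrichment
  is the percentage of LINE/SINE-labeled events overlapping >= 1 window.
* **Flank GC**: event spans extended +-2.5 kb (clipped at chromosome
  ends), GC% per flank with ambiguous bases excluded from the
  denominator, and a one-sample two-tailed t-test against the genome
  constant g0 = 40.9%. Testing per flank (not pooled) is what gives the
  per-sample means with p-values a within-sample variance.

## The synthetic study

Defaults are the study conditions; they are not tuned per run.

| parameter | default | rationale |
|---|---|---|
| genome | 6 chromosomes, 3.3 Mb total | large enough that 31-mers are effectively unique, small enough for seconds-scale runs |
| GC landscape | 50 kb blocks, GC ~ N(0.41, 0.06) clipped to [0.25, 0.65] | genome-like average with regional heterogeneity |
| TE annotation | 1,250 elements (SINE/LINE/LTR/DNA/Satellite), gamma-weighted 10 kb block placement, copies mutated 15% from a class consensus | clustered TE-rich windows; divergent copies keep flanks uniquely mappable |
| germline SVAs | 40, bodies start with (CCCTCT)_6, per-chromosome lognormal intensity | non-trivial reference density profile |
| lineage | (Cereb,(Bulb,(Hippo,(Pfc,Calca)))) | the developmental branching order of the five sampled regions |
| insertions/donor | 2,000 over 9 branches (5 x 340 terminal, 90/80/80 internal, 50 root) | mostly region-unique insertions, >= 20 characters per internal branch, ~50 deep coalescers |
| singleton fraction | 0.77 | within the observed 75-79% range of single-read insertions |
| support model | 1 w.p. 0.77, else 2 + Poisson(1) | singletons dominate; occasional well-supported events |
| flank length | uniform 31-150 bp | all pass the >30 bp filter unless short flanks are requested |
| hexamer copies | uniform 4-10 | detector must be copy-number robust |
| artifact / leak rate | 1% / 1% | placeholders — the assay does not quantify either rate |
| sequencing error | 0 | the filters are exact-match based; an optional uniform substitution rate exists for robustness runs |
| donors | 2, independent draws over the same topology | both donors should recover the same tree |

Placement mode defaults to `uniform` so that spike-in recovery and the
per-chromosome multinomial property hold exactly; `te_biased`
(multiplicative weights in SINE/LINE-rich and GC-rich blocks) and
`density_proportional` (per-chromosome weight proportional to the
reference SVA profile) are first-class modes used by the enrichment and
density-correlation experiments. Somatic flanks are sampled to be
GATC-free, free of tandem hexamer runs, not ending in a hexamer copy
(which would shift the detected flank boundary), >= 3.5 kb from any
germline SVA, and >= 400 bp from other somatic loci — one flank sequence
per locus, as the MboI fragment side is fixed by the nearest upstream
restriction site.

What the generator does **not** emulate: sequencing error by default, PCR
chimeras other than GATC re-ligation, hybridization kinetics and
enrichment efficiency, VNTR internal structure, reference gaps or
segmental duplications, and polymorphic (non-reference) germline SVAs.
Passing tests therefore demonstrate the correctness of the computational
contracts under the assay's idealized assumptions, not the wet-lab
performance of the enrichment on real tissue.

## Evaluation experiments and problem sizes

`analysis/06_evaluate.py` and `scripts/acceptance.py` recompute, at run
time: spike-in recall/precision on uniquely mappable truth loci
(a truth flank counts as uniquely mappable when it occurs exactly once
genome-wide, both strands); the pooled singleton fraction against its
binomial confidence band; topology recovery with 1,000 bootstrap
replicates; the density correlation under proportional placement
(20 chromosomes, 2,000 insertions, 300 reference SVAs) and its null
calibration (300 seeds, uniform placement on equal-size chromosomes,
rejection rate expected in [0.01, 0.11] at alpha = 0.05 — a 2.4-sigma
binomial band with slack for the multinomial approximation); flank-GC
null calibration (1,000 replicates of 60 disjoint 5.1 kb windows from a
fresh homogeneous-GC sequence each, so flank values are independent) and
power at a +2 percentage-point shift with m = 500 flanks. These sizes
keep each experiment in the seconds-to-one-minute range while leaving
Monte-Carlo error well inside the asserted bands.

## Known limitations

* The near-exact aligner is ungapped; indel-containing flanks would be
  lost (irrelevant for error-free synthetic data, a real limitation on
  real reads).
* Event support counts weight distinct near-duplicate flanks equally;
  how non-identical flanks at one locus should be weighted is left open.
* The exhaustive tree search does not scale beyond 10 taxa by design.
* Driver leak-through and artifact rates are placeholders, not
  estimates; conclusions about filter efficiency at other rates require
  re-simulation.
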