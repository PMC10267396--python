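# svarda

Detection and lineage analysis of somatic SVA retrotransposition from
RDA-enriched amplicon sequencing.

## The problem

SVA (SINE-VNTR-Alu) elements are hominid-specific retrotransposons that
remain mobile in the human soma, including the brain. Representational
difference analysis (RDA) enriches the genomic 5'-flanks of SVA
integrations that are present in a tissue of interest (tester) but absent
from a reference tissue of the same individual (driver), producing
amplicons of the form

```
[24-mer RDA primer][GATC][genomic 5'-flank][(CCCTCT)_n hexamer][SVA body]
```

`svarda` is the computational pipeline for such data. From amplicon reads
it (1) extracts clean genomic flanks (primer selection, SVA hexamer
scanning, removal of GATC re-ligation artifacts, strict >30 bp filter),
(2) calls de novo insertion events after two-stage germline subtraction
(alignment against annotated SVAs +- 1 kb, unique genome mapping, removal
of hits within annotated SVA +- 3 kb, single-linkage event collapsing),
(3) treats each event as a binary presence/absence clade marker across
tissue samples and reconstructs a maximum-parsimony lineage tree
(exhaustive Fitch search, branch lengths in steps, bootstrap over loci),
and (4) characterizes integration-target preferences: per-chromosome SVA
density d_c = n_c·L̄/S_c·10^6 with a Pearson/Student-t correlation test
against the germline profile, HOMER-style single-label feature
annotation, SINE+LINE-rich 100 kb window enrichment, and extended-flank
GC analysis (one-sample t-test vs the genome constant g₀ = 40.9%).

A synthetic-data module generates the toy genome, lineage-structured
ground-truth insertions and RDA reads, so the whole pipeline runs and is
tested without any downloads. It is aimed at researchers working on
somatic mosaicism, mobile-element insertion calling, and lineage tracing
with irreversible genomic markers.

## Worked example

Run the whole pipeline on the default synthetic study (5 brain regions x
2 donors, 2,000 somatic insertions per donor, 1% artifact reads, 1%
germline leak-through):

```bash
svarda run-all --seed 1 --outdir run1
```

or stage by stage via the numbered drivers:

```bash
python analysis/01_simulate.py
python analysis/02_extract_flanks.py
python analysis/03_call_insertions.py
python analysis/04_phylogeny.py
python analysis/05_landscape.py
python analysis/06_evaluate.py
```

`analysis/04_phylogeny.py` prints, for each donor:

```
D1: 2000 reference loci; 300 shared in >1 region, 50 in all 5 regions
  MP tree length 1950 steps, 250 lineage-informative sites (170 standard); 1 co-optimal topology(ies)
  tree: (Cereb:0,((Hippo:340,(Pfc:340,Calca:340)100:90)100:80,Bulb:340):420);
```

Reading this: the 2,000 insertion loci of donor 1 yield a presence/absence
matrix whose unique maximum-parsimony tree has length 1,950 steps — one
step per locus except the 50 deep-coalescing loci shared by all five
regions, which require none. Terminal branches are long (340 steps each:
most insertions are unique to one region) while internal branches are
short but decisive (90/80 steps), and both internal bipartitions,
(Pfc,Calca) and (Hippo,(Pfc,Calca)), carry 100% bootstrap support with
the cerebellum as outgroup. 250 loci are lineage-informative (present in
2-4 regions); of these, 170 also satisfy the standard
parsimony-informative definition.

`analysis/06_evaluate.py` scores the pipeline against the simulation
ground truth and prints:

```
recall_on_uniquely_mappable_loci          1
precision                                 1
events_in_sva_3kb_pad                     0
singleton_fraction                   0.7719
topology_recovered_both_donors            1
min_bootstrap_support                   100
density_r_proportional_placement     0.9924
density_p_proportional_placement  7.418e-18
density_null_rejection_rate         0.05333
gc_null_rejection_rate                0.049
gc_shift2pct_p                   3.126e-238
```

i.e. every uniquely mappable planted insertion is recovered with no false
events, the singleton fraction matches its 0.77 target, both donors yield
the planted lineage, the density-correlation test is strongly positive
when insertions track the reference SVA profile yet calibrated under the
null, and the flank-GC t-test holds its 5% level while easily detecting a
+2 percentage-point GC shift.

See `docs/methods.md` for the model, parameter choices, and limitations.

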