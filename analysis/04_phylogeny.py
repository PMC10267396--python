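#!/usr/bin/env python
"""Reconstruct the brain-region lineage from presence/absence markers.

Builds each donor's reference locus set from the per-region event BEDs,
derives the binary marker matrix, counts shared (Venn) subsets, and runs
an exhaustive maximum-parsimony search with 1,000 bootstrap replicates,
rooting on the cerebellum. Writes newick trees, PHYLIP/FASTA matrices and
Venn tables to results/phylogeny/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
EVENTS = ROOT / "results" / "events"
OUT = ROOT / "results" / "phylogeny"

from svarda.genomic_core import GenomicInterval, IntervalSet, read_bed
from svarda.mosaic_phylogeny import (
    bootstrap_support,
    build_reference_positions,
    mp_search,
    presence_absence_matrix,
    shared_set_counts,
    to_newick,
    write_character_fasta,
    write_phylip,
)

SEED = 1


def main() -> None:
    if not EVENTS.exists():
        sys.exit("run analysis/03_call_insertions.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    donors = sorted({b.stem.split("_")[0] for b in EVENTS.glob("*.bed")})
    for di, donor in enumerate(donors):
        event_sets = {}
        for bed in sorted(EVENTS.glob(f"{donor}_*.bed")):
            region = bed.stem.split("_")[1]
            event_sets[region] = IntervalSet(
                GenomicInterval(iv.chrom, iv.start, iv.end) for iv in read_bed(bed)
            )
        reference = build_reference_positions(event_sets)
        matrix = presence_absence_matrix(reference, event_sets)
        shared = shared_set_counts(matrix)
        result = mp_search(matrix, outgroup="Cereb")
        result.bootstrap = bootstrap_support(
            matrix, "Cereb", replicates=1_000, seed=SEED + di
        )
        (OUT / f"{donor}.nwk").write_text(to_newick(result) + "\n")
        write_phylip(matrix, OUT / f"{donor}_matrix.phy")
        write_character_fasta(matrix, OUT / f"{donor}_matrix.fasta")
        pd.DataFrame(
            [{"regions": ";".join(sorted(k)), "n_loci": v}
             for k, v in sorted(shared.exact.items(),
                                key=lambda kv: (len(kv[0]), sorted(kv[0])))]
        ).to_csv(OUT / f"{donor}_venn.tsv", sep="\t", index=False)
        print(f"{donor}: {matrix.n_loci} reference loci; "
              f"{shared.n_shared_multi} shared in >1 region, "
              f"{shared.n_all_regions} in all 5 regions")
        print(f"  MP tree length {result.tree_length} steps, "
              f"{result.informative_sites} lineage-informative sites "
              f"({result.informative_sites_standard} standard); "
              f"{len(result.co_optimal)} co-optimal topology(ies)")
        print(f"  tree: {to_newick(result)}")


if __name__ == "__main__":
    sys.exit(main())
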