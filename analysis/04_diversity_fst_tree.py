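#!/usr/bin/env python
"""Nucleotide diversity, FST between samples, and the strain tree.

pi within each sample, pi between sample pairs and FST are computed per
genome from the pileups; the filtered SNP table yields a consensus-allele
p-distance matrix over samples and a neighbor-joining tree.  Because
allele frequencies were drawn per individual, FST between samples of the
same individual should be near 0 and the tree should cluster the two time
points of each individual together.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from strainpi import pileup_coverage as pc
from strainpi import popgen, variants
from strainpi.pipeline import _read_fasta

COMMUNITY = Path("results/community")
OUT = Path("results")


def main() -> None:
    refs = _read_fasta(COMMUNITY / "references.fa")
    lengths = {g: len(s) for g, s in refs.items()}
    meta = pd.read_csv(COMMUNITY / "samples.tsv", sep="\t", index_col=0)
    samples = sorted(meta.index)
    by_genome: dict[str, dict] = {}
    for sample in samples:
        mats = pc.pileup_from_alignments(str(COMMUNITY / f"{sample}.sam"), lengths, references=refs)
        for g, m in mats.items():
            by_genome.setdefault(g, {})[sample] = m

    within, pairs = [], []
    for g, per_sample in sorted(by_genome.items()):
        res = popgen.diversity(per_sample, lengths[g], genome=g)
        w, p = res.to_frames()
        within.append(w)
        pairs.append(p)
    pd.concat(within).to_csv(OUT / "pi_within.tsv", sep="\t", index=False)
    pair_df = pd.concat(pairs)
    pair_df.to_csv(OUT / "pi_fst_pairs.tsv", sep="\t", index=False)

    same = pair_df[
        pair_df.apply(lambda r: meta.loc[r.sample1, "individual"] == meta.loc[r.sample2, "individual"], axis=1)
    ]["fst"]
    diff = pair_df[
        pair_df.apply(lambda r: meta.loc[r.sample1, "individual"] != meta.loc[r.sample2, "individual"], axis=1)
    ]["fst"]
    print(f"mean FST within individuals:  {same.mean():.4f} (n={len(same)})")
    print(f"mean FST between individuals: {diff.mean():.4f} (n={len(diff)})")

    # strain tree from filtered SNPs
    called = []
    for g, per_sample in sorted(by_genome.items()):
        called.extend(variants.call_variants(per_sample, refs))
    kept = variants.filter_variants(called, variants.FilterPolicy())
    snps = [r for r in kept if r.variant_class == "SNP"]
    dm = popgen.p_distance_matrix(snps, samples)
    dm.to_phylip(OUT / "p_distance.phy")
    tree = popgen.neighbor_joining(dm)
    newick = popgen.tree_to_newick(tree, OUT / "samples.nwk")
    print(f"p-distance matrix over {len(samples)} samples -> {OUT/'p_distance.phy'}")
    print("NJ tree:", newick.strip())


if __name__ == "__main__":
    main()
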