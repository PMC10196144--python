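#!/usr/bin/env python
"""Call SNPs/INDELs from the community pileups and apply the support filter.

Variants must be present in at least two samples and be supported by at
least four reads (per supporting sample).  SNP density per kilobase is
reported per genome; with 200 implanted sites on 50 kb the truth is
4 SNPs per kb before filtering losses.
"""

from pathlib import Path

from strainpi import pileup_coverage as pc
from strainpi import variants
from strainpi.pipeline import _read_fasta

COMMUNITY = Path("results/community")
OUT = Path("results")


def main() -> None:
    refs = _read_fasta(COMMUNITY / "references.fa")
    lengths = {g: len(s) for g, s in refs.items()}
    samples = sorted(p.stem for p in COMMUNITY.glob("s*.sam"))
    by_genome: dict[str, dict] = {}
    for sample in samples:
        mats = pc.pileup_from_alignments(str(COMMUNITY / f"{sample}.sam"), lengths, references=refs)
        for g, m in mats.items():
            by_genome.setdefault(g, {})[sample] = m

    called = []
    for g, per_sample in sorted(by_genome.items()):
        called.extend(variants.call_variants(per_sample, refs))
    policy = variants.FilterPolicy(min_samples=2, min_reads=4)
    kept = variants.filter_variants(called, policy)
    variants.records_to_frame(kept).to_csv(OUT / "variants.tsv", sep="\t", index=False)
    variants.write_vcf(kept, OUT / "variants.vcf", lengths)

    print(f"called {len(called)} candidate variants; retained {len(kept)} "
          f"(>=2 samples, >=4 reads per sample)")
    for g in sorted(by_genome):
        recs = [r for r in kept if r.genome == g]
        dens = variants.snp_density(recs, lengths[g])
        print(f"  {g}: {len(recs)} variants, {dens:.2f} SNPs per kb")


if __name__ == "__main__":
    main()
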