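"""End-to-end orchestration: coverage -> selection -> variants -> diversity -> tree.

The pipeline wires the analysis modules together in the order of the
strain-level workflow: build pileups per sample, compute coverage profiles,
gate reference genomes, call and filter variants, compute nucleotide
diversity and FST per genome, and build a p-distance neighbor-joining tree
over samples.  Community statistics and the HGT screen run as independent
branches when their inputs are supplied.  Every stage writes a TSV under
the output directory and is recorded in a JSON run manifest (config hash,
seed, per-stage row counts), so a rerun with the same config and inputs is
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from strainpi import pileup_coverage as pc
from strainpi import popgen, variants

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "strainpi_out"
    reference_fasta: str | None = None
    sam_paths: dict[str, str] = field(default_factory=dict)  # sample -> SAM/BAM
    pileup_paths: dict[str, str] = field(default_factory=dict)  # sample -> pileup TSV
    vcf_path: str | None = None
    breadth_min: float = 0.40
    cum_depth_min: float = 10.0
    min_alt_reads: int = 2
    min_alt_frac: float = 0.1
    min_samples: int = 2
    min_reads: int = 4
    reads_scope: str = "per_sample"
    p_distance_min_depth: int = 4
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.breadth_min <= 1.0:
            raise ValueError("breadth_min must be in [0, 1]")
        if self.cum_depth_min < 0:
            raise ValueError("cum_depth_min must be non-negative")
        if not 0.0 <= self.min_alt_frac <= 1.0:
            raise ValueError("min_alt_frac must be in [0, 1]")
        for name in ("min_alt_reads", "min_samples", "min_reads", "p_distance_min_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.reads_scope not in ("per_sample", "per_variant_total"):
            raise ValueError("invalid reads_scope")
        if not self.sam_paths and not self.pileup_paths:
            raise ValueError("no alignment or pileup inputs configured")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the strain-level workflow; returns the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    refs = _read_fasta(config.reference_fasta) if config.reference_fasta else {}
    lengths = {g: len(s) for g, s in refs.items()}

    # stage 1: pileups per sample
    pileups: dict[str, dict[str, pc.PileupMatrix]] = {}
    for sample, path in config.sam_paths.items():
        pileups[sample] = pc.pileup_from_alignments(path, lengths, references=refs)
    for sample, path in config.pileup_paths.items():
        mats = pc.PileupMatrix.from_tsv(path)
        for g, mat in mats.items():
            if g in lengths and len(mat) < lengths[g]:
                padded = pc.PileupMatrix(
                    g,
                    _pad_counts(mat.counts, lengths[g]),
                    ref=refs.get(g),
                    indels=mat.indels,
                )
                mats[g] = padded
            elif refs.get(g) is not None and mat.ref is None:
                mats[g] = pc.PileupMatrix(g, mat.counts, ref=refs[g], indels=mat.indels)
        pileups[sample] = mats
    if not lengths:
        lengths = {
            g: len(m)
            for per_genome in pileups.values()
            for g, m in per_genome.items()
        }
    _log_stage(manifest, "pileup", sum(len(v) for v in pileups.values()))

    # stage 2: coverage + reference gate
    profiles = [
        pc.coverage_profile(mat, lengths[g], sample=s)
        for s, per_genome in pileups.items()
        for g, mat in per_genome.items()
    ]
    pc.profiles_to_frame(profiles).to_csv(outdir / "coverage.tsv", sep="\t", index=False)
    selections = pc.select_references(
        profiles, breadth_min=config.breadth_min, cum_depth_min=config.cum_depth_min
    )
    pc.selection_to_frame(selections).to_csv(outdir / "selection.tsv", sep="\t", index=False)
    selected = {s.genome for s in selections if s.selected}
    _log_stage(manifest, "selection", len(selected))

    # stage 3: variants
    if config.vcf_path:
        records = variants.read_vcf(config.vcf_path)
        records = [r for r in records if r.genome in selected]
    else:
        records = []
        for genome in sorted(selected):
            per_sample = {
                s: per_genome[genome]
                for s, per_genome in pileups.items()
                if genome in per_genome
            }
            records.extend(
                variants.call_variants(
                    per_sample,
                    refs or {genome: "N" * lengths[genome]},
                    min_alt_reads=config.min_alt_reads,
                    min_alt_frac=config.min_alt_frac,
                )
            )
    policy = variants.FilterPolicy(
        min_samples=config.min_samples,
        min_reads=config.min_reads,
        reads_scope=config.reads_scope,
    )
    retained = variants.filter_variants(records, policy)
    variants.records_to_frame(retained).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    if lengths and retained:
        variants.write_vcf(
            retained, outdir / "variants.vcf", {g: lengths[g] for g in sorted(selected)}
        )
    _log_stage(manifest, "variants", len(retained), extra={"called": len(records)})

    # stage 4: diversity per selected genome
    within_frames, pair_frames = [], []
    for genome in sorted(selected):
        per_sample = {
            s: per_genome[genome]
            for s, per_genome in pileups.items()
            if genome in per_genome
        }
        if len(per_sample) < 1:
            continue
        res = popgen.diversity(per_sample, lengths[genome], genome=genome)
        w, p = res.to_frames()
        within_frames.append(w)
        pair_frames.append(p)
    if within_frames:
        pd.concat(within_frames).to_csv(outdir / "pi_within.tsv", sep="\t", index=False)
    if pair_frames:
        pd.concat(pair_frames).to_csv(outdir / "pi_fst_pairs.tsv", sep="\t", index=False)
    _log_stage(manifest, "diversity", sum(len(f) for f in within_frames))

    # stage 5: p-distance + NJ tree over samples (needs >= 3 samples and sites)
    sample_ids = sorted(pileups)
    snp_records = [r for r in retained if r.variant_class == "SNP"]
    if len(sample_ids) >= 3 and snp_records:
        try:
            dm = popgen.p_distance_matrix(
                snp_records, sample_ids, min_depth=config.p_distance_min_depth
            )
            dm.to_phylip(outdir / "p_distance.phy")
            if not dm.missing_pairs:
                tree = popgen.neighbor_joining(dm)
                popgen.tree_to_newick(tree, outdir / "samples.nwk")
                _log_stage(manifest, "tree", len(sample_ids))
        except ValueError as exc:
            logger.warning("tree stage skipped: %s", exc)
            manifest["stages"]["tree"] = {"skipped": str(exc)}

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _pad_counts(counts, length):
    import numpy as np

    out = np.zeros((length, 4), dtype=counts.dtype)
    out[: len(counts)] = counts
    return out


def _log_stage(manifest: dict, name: str, n: int, extra: dict | None = None) -> None:
    entry = {"rows": int(n)}
    if extra:
        entry.update(extra)
    manifest["stages"][name] = entry
    logger.info("stage %-10s %s", name, entry)


def make_report(outdir) -> dict[str, pd.DataFrame]:
    """Summarise a completed run into per-genome / per-pair tables.

    Missing stage outputs are listed under the ``missing`` key and the
    report is emitted for whatever is present.
    """
    outdir = Path(outdir)
    report: dict[str, pd.DataFrame] = {}
    missing: list[str] = []

    cov_path = outdir / "coverage.tsv"
    var_path = outdir / "variants.tsv"
    pi_path = outdir / "pi_within.tsv"
    pair_path = outdir / "pi_fst_pairs.tsv"

    if cov_path.exists():
        cov = pd.read_csv(cov_path, sep="\t")
        genome_summary = cov.groupby("genome").agg(
            max_breadth=("breadth", "max"), cumulative_depth=("mean_depth", "sum")
        )
    else:
        missing.append("coverage.tsv")
        genome_summary = pd.DataFrame()

    if var_path.exists():
        var = pd.read_csv(var_path, sep="\t")
        if len(var):
            counts = var.groupby(["genome", "class"]).size().unstack(fill_value=0)
            for cls in ("SNP", "INDEL"):
                if cls not in counts:
                    counts[cls] = 0
            genome_summary = genome_summary.join(
                counts.rename(columns={"SNP": "n_snps", "INDEL": "n_indels"}),
                how="outer",
            ).fillna(0)
    else:
        missing.append("variants.tsv")

    if pi_path.exists():
        pi = pd.read_csv(pi_path, sep="\t")
        genome_summary = genome_summary.join(
            pi.groupby("genome")["pi_within"].mean().rename("mean_pi_within"),
            how="outer",
        )
    else:
        missing.append("pi_within.tsv")

    report["genomes"] = genome_summary.reset_index()
    if pair_path.exists():
        report["pairs"] = pd.read_csv(pair_path, sep="\t")
    else:
        missing.append("pi_fst_pairs.tsv")

    report["missing"] = pd.DataFrame({"missing": missing})
    report["genomes"].to_csv(outdir / "report_genomes.tsv", sep="\t", index=False)
    return report
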