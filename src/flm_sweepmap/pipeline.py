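"""Stage orchestration: simulate inputs, run analyses, write outputs.

All randomness flows from the single configured seed; two runs with equal
configuration produce byte-identical outputs. Outputs are written under
``config.out_dir`` together with a JSON manifest (paths, sizes, sha256) and
a machine-readable run record.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import allele_age, bsa, expression, insertion, io, simulate
from .config import PipelineConfig

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)

_DEMO_GENE = expression.GeneModelAnnot(
    gene_id="FLM",
    chrom="chr1",
    strand="+",
    exons=((0, 200), (1200, 1350), (1500, 1650), (1900, 2000), (2200, 2300), (2500, 2600), (2800, 3000)),
)


def _write_json(path: Path, obj) -> Path:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the selected stages in dependency order; return the manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.DEBUG if config.verbose else logging.INFO)
    written: list[Path] = []
    seed = int(config.seed)

    sim_kwargs = dict(config.sim)
    cfg = simulate.F2SimConfig(seed=seed, **{k: v for k, v in sim_kwargs.items() if k != "seed"})

    snp_table = None
    if "pools" in config.stages:
        truth = simulate.simulate_f2_population(cfg)
        snp_table = simulate.pool_and_count(truth, cfg)
        written.append(io.write_snp_tsv(snp_table, out_dir / "snp_pools.tsv"))
        written.append(io.write_snp_vcf(snp_table, out_dir / "snp_pools.vcf"))
        logger.info("pools: %d SNPs, causal marker at %d bp", len(snp_table), truth.causal_pos)

    if "mapdelta" in config.stages:
        result = bsa.analyze_pools(
            snp_table,
            span=config.span,
            degree=config.degree,
            threshold=config.delta_threshold,
            n_boot=config.n_boot,
            seed=seed,
            cov_min=config.cov_min,
            cov_max=config.cov_max,
            min_freq=config.min_freq,
            parental_min=config.parental_min,
        )
        written.append(io.write_profile_tsv(result, out_dir / "delta_f_profile.tsv"))
        written.append(io.write_intervals_bed(result.intervals, out_dir / "mapping_intervals.bed"))
        logger.info(
            "mapdelta: %d/%d SNPs retained, %d interval(s)",
            result.filter_report.n_retained,
            result.filter_report.n_input,
            len(result.intervals),
        )

    readset = None
    ref_seq = insert_seq = None
    insertion_pos = 1000
    if "reads" in config.stages:
        rng = np.random.default_rng([seed, 0xFA57A])
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        ref_seq = rng.choice(bases, size=2000).tobytes().decode()
        insert_seq = rng.choice(bases, size=1000).tobytes().decode()
        readset = simulate.simulate_breakpoint_reads(
            ref_seq, insert_seq, insertion_pos, depth=20.0, error_rate=0.005, carrier=True, seed=seed
        )
        written.append(io.write_fastq(readset, out_dir / "reads.fastq"))
        written.append(io.write_fasta({"ref": ref_seq, "insert": insert_seq}, out_dir / "locus.fasta"))
        readset.truth_frame().to_csv(out_dir / "reads_truth.tsv", sep="\t", index=False)
        written.append(out_dir / "reads_truth.tsv")

    if "genotype" in config.stages:
        call = insertion.genotype_sample(
            [(r.read_id, r.sequence) for r in readset.reads],
            ref_seq,
            insert_seq,
            insertion_pos,
            flank=config.flank,
            max_diff_frac=config.max_diff,
            min_reads=config.min_reads,
            dedup=config.dedup,
            sample="sim_sample",
        )
        df = pd.DataFrame([call.__dict__])
        df.to_csv(out_dir / "insertion_calls.tsv", sep="\t", index=False)
        written.append(out_dir / "insertion_calls.tsv")
        logger.info("genotype: support L=%d R=%d present=%s", call.support_left, call.support_right, call.present)

    profiles = None
    if "coverage" in config.stages:
        profiles = simulate.simulate_coverage_profiles(_DEMO_GENE, seed=seed)
        for prof in profiles:
            written.append(io.write_bedgraph(prof, out_dir / f"coverage_{prof.replicate}.bedgraph"))
        written.append(io.write_gene_model_gff3(_DEMO_GENE, out_dir / "gene_model.gff3"))

    if "exonusage" in config.stages:
        usage = expression.exon_usage(profiles, _DEMO_GENE)
        usage.per_exon.assign(ratio_exon1=pd.Series(usage.ratios)).to_csv(
            out_dir / "exon_usage.tsv", sep="\t"
        )
        written.append(out_dir / "exon_usage.tsv")
        logger.info("exonusage: ratio %.3f ± %.3f", usage.mean_ratio, usage.sd_ratio)

    ct_table = None
    if "ct" in config.stages:
        ct_table = simulate.simulate_ct_table(
            {"Col-0": 1.0, "Kil-0_beta": 1 / 6, "Kil-0_delta": 1 / 27}, seed=seed
        )
        ct_table.to_csv(out_dir / "ct_table.tsv", sep="\t", index=False)
        written.append(out_dir / "ct_table.tsv")

    if "ddct" in config.stages:
        folds = expression.ddct_relative_expression(ct_table, "FLM", "ACT8", "Col-0")
        folds.to_csv(out_dir / "ddct_fold_changes.tsv", sep="\t", index=False)
        written.append(out_dir / "ddct_fold_changes.tsv")

    pairs = None
    if "phenotype" in config.stages:
        pairs = simulate.simulate_expression_phenotype(seed=seed)
        pairs.to_csv(out_dir / "expression_phenotype.tsv", sep="\t", index=False)
        written.append(out_dir / "expression_phenotype.tsv")

    if "correlate" in config.stages:
        reg = expression.regress_flowering_on_expression(
            pairs["expression"].to_numpy(), pairs["flowering_days"].to_numpy()
        )
        written.append(_write_json(out_dir / "regression.json", reg.__dict__))

    if "age" in config.stages:
        seq_a, seq_b = simulate.simulate_divergent_pair(5700, 15000, 6.5e-9, seed=seed)
        k, L = allele_age.pairwise_differences([seq_a, seq_b])
        est = allele_age.estimate_allele_age(
            allele_age.ClockInput(k=k, L=L, mu_lo=6e-9, mu_hi=7e-9, g_lo=1.0, g_hi=3.0)
        )
        written.append(_write_json(out_dir / "allele_age.json", {"k": k, "L": L, **est.__dict__}))

    run_info = {"seed": seed, "stages": list(config.stages)}
    manifest_path = io.write_manifest(written, out_dir, run_info=run_info)
    return json.loads(manifest_path.read_text())
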