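"""End-to-end orchestration of the multi-platform analysis on one cohort.

Stages: exon -> transcript deconvolution, differential expression and DET
selection, discretized-expression survival screening, gene-level summaries,
copy-number segmentation/calling/frequencies, amplification-expression
integration, SNP survival screening, methylation combining, miRNA DE with
target filtering, siRNA screen scoring, and the fused gene report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import copynumber as cn
from . import expression as expr
from . import integration as integ
from . import methylation_mirna as meth
from . import report as rep
from . import screen as scr
from . import survival as surv
from .synthetic import Cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    transcript_matrix: pd.DataFrame
    transcript_de: pd.DataFrame
    dets: pd.Index
    transcript_survival: pd.DataFrame
    gene_de: pd.DataFrame
    exon_gene_de: pd.DataFrame
    gene_survival: pd.DataFrame
    thresholds: cn.AberrationThresholds
    segments: pd.DataFrame
    cn_frequencies: pd.DataFrame
    integration_gain: pd.DataFrame
    amplification_driven: pd.Index
    snp_results: pd.DataFrame
    methylation_beta: pd.Series
    mirna_de: pd.DataFrame
    mirna_targets: pd.DataFrame
    screen_scores: pd.DataFrame
    report_table: pd.DataFrame
    site_index: Path | None = None
    extras: dict = field(default_factory=dict)


def run_cohort(
    cohort: Cohort,
    seed: int = 0,
    outdir=None,
    render: bool = True,
    cbs_permutations: int = 1000,
    cbs_alpha: float = 0.01,
    integration_permutations: int = 10_000,
) -> PipelineResult:
    """Run every analysis stage on a cohort and fuse the gene report."""
    rng = np.random.default_rng(seed)
    roles = cohort.sample_roles
    tumor_ids, control_ids = expr.split_roles(roles)

    # --- transcript deconvolution and differential expression
    incidences = ann.build_incidence(cohort.annotation, measured_exon_ids=cohort.exon_matrix.index)
    tmat = expr.transcript_matrix(incidences, cohort.exon_matrix)
    transcript_de = expr.differential_expression(tmat, roles)
    dets = expr.select_dets(transcript_de)
    logger.info("%d / %d transcripts differentially expressed", len(dets), len(transcript_de))

    # --- per-sample fold changes of DETs, discretized survival screen
    control_means = tmat.loc[dets, control_ids].mean(axis=1)
    fc_per_sample = tmat.loc[dets, tumor_ids].div(control_means, axis=0)
    transcript_survival = surv.expression_survival_screen(fc_per_sample, cohort.clinical)

    # --- gene level (exon-platform medians + separate gene array)
    gene_map = ann.exon_gene_map(cohort.annotation)
    exon_gene = expr.gene_level_from_exons(cohort.exon_matrix, gene_map)
    exon_gene_de = expr.differential_expression(exon_gene, roles)
    gene_de = expr.differential_expression(cohort.gene_matrix, roles)
    gene_cm = exon_gene[control_ids].mean(axis=1)
    gene_fc_per_sample = exon_gene[tumor_ids].div(gene_cm, axis=0)
    gene_survival = surv.expression_survival_screen(gene_fc_per_sample, cohort.clinical)

    # --- copy number
    thresholds = cn.estimate_thresholds(
        cohort.cn_control_probes.pivot_table(index="pos", columns="sample", values="logratio")
    )
    segments = cn.segment_profiles(
        cohort.cn_probes, alpha=cbs_alpha, n_permutations=cbs_permutations,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    called = cn.call_aberrations(segments, thresholds)
    spans = ann.gene_spans(cohort.annotation)
    status = cn.aberration_matrix(called, spans)
    freqs = cn.aberration_frequencies(called, spans)

    # --- amplification-expression integration (exon-platform gene values)
    integration_gain = integ.integrate_expression_cn(
        exon_gene.loc[:, tumor_ids], status, freqs,
        direction="gain", n_permutations=integration_permutations,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    amplification_driven = integ.select_amplification_driven(integration_gain)

    # --- SNP survival screen
    snp_results = surv.snp_survival_screen(
        cohort.genotype_calls, cohort.genotype_prob, cohort.sample_snr, cohort.clinical
    )

    # --- methylation and miRNA
    beta_matrix = meth.combine_promoter_probes(cohort.methylation)
    methylation_beta = beta_matrix.median(axis=1)
    mirna_de = expr.differential_expression(cohort.mirna_matrix, roles)
    mirna_targets = meth.filter_mirna_targets(cohort.mirna_targets)

    # --- siRNA screens
    screen_parts = []
    for plate_id, plate in cohort.plates.groupby("plate"):
        corrected = scr.loess_plate_normalize(plate)
        scores = scr.score_plate(corrected)
        scores.insert(0, "plate", plate_id)
        scores.insert(1, "assay", plate["assay"].iloc[0])
        screen_parts.append(scores)
    screen_scores = pd.concat(screen_parts) if screen_parts else pd.DataFrame()

    # --- fused gene report
    transcript_genes = (
        cohort.annotation[["transcript_id", "gene_id"]].drop_duplicates().set_index("transcript_id")["gene_id"]
    )
    table = rep.build_gene_table(
        gene_de=gene_de,
        exon_gene_de=exon_gene_de,
        transcript_de=transcript_de,
        transcript_genes=transcript_genes,
        transcript_survival=transcript_survival,
        gene_survival=gene_survival,
        snp_results=snp_results,
        marker_genes=cohort.marker_genes,
        cn_frequencies=freqs,
        methylation_beta=methylation_beta,
        integration_results=integration_gain,
    )

    site_index = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        transcript_de.to_csv(out / "transcript_de.tsv", sep="\t", index_label="transcript_id")
        transcript_survival.to_csv(out / "transcript_survival.tsv", sep="\t", index_label="transcript_id")
        called.to_csv(out / "segments.tsv", sep="\t", index=False)
        freqs.to_csv(out / "cn_frequencies.tsv", sep="\t", index_label="gene_id")
        integration_gain.assign(selected=integration_gain.index.isin(amplification_driven)).to_csv(
            out / "integration.tsv", sep="\t", index_label="gene_id"
        )
        snp_results.to_csv(out / "snp_survival.tsv", sep="\t", index_label="marker")
        mirna_de.to_csv(out / "mirna_de.tsv", sep="\t", index_label="mirna")
        screen_scores.to_csv(out / "screen_scores.tsv", sep="\t", index_label="sirna")
        if render:
            km_dir = out / "site" / "km"
            km_dir.mkdir(parents=True, exist_ok=True)
            km_plots = {}
            hits = transcript_survival.index[transcript_survival["p"] < rep.KM_GATE_P]
            for tid in hits:
                groups = pd.Series(
                    surv.discretize_fold_change(fc_per_sample.loc[tid].to_numpy()),
                    index=fc_per_sample.columns,
                )
                path = km_dir / f"{tid}.svg"
                surv.km_plot(cohort.clinical, groups, path, title=str(tid))
                km_plots[tid] = path
            transcript_pages = transcript_de[["fc"]].join(transcript_survival["p"]).assign(
                gene_id=transcript_genes.reindex(transcript_de.index)
            )
            site_index = rep.render_website(
                table, out / "site", transcript_table=transcript_pages, km_plots=km_plots
            )
    return PipelineResult(
        transcript_matrix=tmat,
        transcript_de=transcript_de,
        dets=dets,
        transcript_survival=transcript_survival,
        gene_de=gene_de,
        exon_gene_de=exon_gene_de,
        gene_survival=gene_survival,
        thresholds=thresholds,
        segments=called,
        cn_frequencies=freqs,
        integration_gain=integration_gain,
        amplification_driven=amplification_driven,
        snp_results=snp_results,
        methylation_beta=methylation_beta,
        mirna_de=mirna_de,
        mirna_targets=mirna_targets,
        screen_scores=screen_scores,
        report_table=table,
        site_index=site_index,
    )
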