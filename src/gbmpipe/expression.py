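"""Transcript deconvolution, gene summaries and differential expression.

Transcript abundances are recovered per sample from exon-array intensities by
solving the least-squares problem ``min_t ||A t - e||_2`` where ``A`` is the
gene's exon x transcript incidence matrix.  The solver uses an orthogonal
factorization (complete orthogonal decomposition via LAPACK ``gelsy``), which
returns the minimum-norm solution when ``A`` is rank-deficient.

Differential expression between tumor and control groups uses fold change
(ratio of group means on the intensity scale), a Welch two-sample t-test and
Benjamini-Hochberg FDR adjustment.  Differentially expressed transcripts
(DETs) are those with fold change > 2 or < 0.5 and adjusted P < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .annotation import ExonTranscriptIncidence

logger = logging.getLogger(__name__)

TUMOR, CONTROL = "tumor", "control"


@dataclass
class TranscriptSolution:
    """Least-squares transcript estimate for one gene in one sample."""

    gene_id: str
    transcript_ids: list[str]
    values: np.ndarray
    residual_norm: float
    rank: int
    rank_deficient: bool
    has_negative: bool


def solve_transcripts(incidence: ExonTranscriptIncidence, exon_values) -> TranscriptSolution:
    """Solve ``A t = e`` in the least-squares sense for one gene/sample.

    Negative solved values are permitted (no nonnegativity constraint) and
    flagged.  Rank-deficient systems yield the minimum-norm solution and are
    flagged rather than rejected.
    """
    e = np.asarray(exon_values, dtype=float)
    a = incidence.matrix
    if e.ndim != 1 or e.shape[0] != a.shape[0]:
        raise ValueError(
            f"{incidence.gene_id}: exon vector length {e.shape} does not match incidence rows {a.shape[0]}"
        )
    t, _, rank, _ = scipy.linalg.lstsq(a, e, lapack_driver="gelsy")
    resid = float(np.linalg.norm(a @ t - e))
    return TranscriptSolution(
        gene_id=incidence.gene_id,
        transcript_ids=list(incidence.transcript_ids),
        values=t,
        residual_norm=resid,
        rank=int(rank),
        rank_deficient=int(rank) < a.shape[1],
        has_negative=bool((t < 0).any()),
    )


def solve_transcripts_matrix(incidence: ExonTranscriptIncidence, exon_matrix: pd.DataFrame) -> pd.DataFrame:
    """Solve transcript values for all samples of one gene at once.

    ``exon_matrix`` holds the gene's exon rows (indexed by exon id) across
    samples; rows are aligned to the incidence matrix order.
    """
    e = exon_matrix.loc[incidence.exon_ids].to_numpy(dtype=float)
    t, _, rank, _ = scipy.linalg.lstsq(incidence.matrix, e, lapack_driver="gelsy")
    if int(rank) < incidence.matrix.shape[1]:
        logger.warning("gene %s: rank-deficient system, minimum-norm solution", incidence.gene_id)
    return pd.DataFrame(t, index=incidence.transcript_ids, columns=exon_matrix.columns)


def transcript_matrix(
    incidences: dict[str, ExonTranscriptIncidence], exon_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Transcript x sample matrix solved gene by gene from exon intensities."""
    blocks = [solve_transcripts_matrix(inc, exon_matrix) for inc in incidences.values()]
    if not blocks:
        return pd.DataFrame(columns=exon_matrix.columns)
    return pd.concat(blocks, axis=0)


def gene_level_from_exons(exon_matrix: pd.DataFrame, gene_map: pd.Series) -> pd.DataFrame:
    """Gene x sample matrix: per-gene median over its measured exons.

    Exons absent from ``gene_map`` (and genes with no measured exon) are
    dropped with a warning.  Even exon counts use the midpoint median.
    """
    gm = gene_map.reindex(exon_matrix.index)
    orphan = gm.isna()
    if orphan.any():
        logger.warning("%d exons without gene mapping dropped", int(orphan.sum()))
    mat = exon_matrix.loc[~orphan]
    return mat.groupby(gm.dropna()).median()


def fold_change(tumor_values, control_values) -> float:
    """Ratio of tumor group mean to control group mean.

    Returns NaN (undefined-FC) when the control mean is not positive.
    """
    tm = float(np.mean(tumor_values))
    cm = float(np.mean(control_values))
    if cm <= 0:
        logger.warning("control mean %.4g <= 0: fold change undefined", cm)
        return float("nan")
    return tm / cm


def per_sample_fold_change(values, control_mean: float):
    """Per-sample fold change: sample value divided by the control-group mean."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive for per-sample fold change")
    return np.asarray(values, dtype=float) / float(control_mean)


def split_roles(sample_roles: pd.Series) -> tuple[pd.Index, pd.Index]:
    roles = sample_roles.astype(str)
    tumor = roles.index[roles == TUMOR]
    control = roles.index[roles == CONTROL]
    if len(tumor) == 0 or len(control) == 0:
        raise ValueError("need at least one tumor and one control sample")
    return tumor, control


def differential_expression(
    matrix: pd.DataFrame, sample_roles: pd.Series, log_transform: bool = False
) -> pd.DataFrame:
    """Per-feature fold change + Welch t-test + Benjamini-Hochberg adjustment.

    Parameters
    ----------
    matrix : DataFrame
        Features x samples intensity matrix.
    sample_roles : Series
        Maps sample id -> "tumor" | "control"; each group needs >= 2 samples.
    log_transform : bool
        Run the t-test on log2 intensities (fold change stays on the
        intensity scale).

    Returns
    -------
    DataFrame with columns ``fc``, ``t``, ``p``, ``adj_p`` indexed by feature.
    Features with zero variance in both groups get missing P (flagged, not
    adjusted).
    """
    tumor_ids, control_ids = split_roles(sample_roles)
    if len(tumor_ids) < 2 or len(control_ids) < 2:
        raise ValueError("differential expression needs >= 2 samples per group")
    tum = matrix[tumor_ids].to_numpy(dtype=float)
    ctl = matrix[control_ids].to_numpy(dtype=float)
    cm = ctl.mean(axis=1)
    fc = np.where(cm > 0, tum.mean(axis=1) / np.where(cm > 0, cm, 1.0), np.nan)
    if (cm <= 0).any():
        logger.warning("%d features with non-positive control mean: FC undefined", int((cm <= 0).sum()))
    xt, xc = (np.log2(np.maximum(tum, 1e-12)), np.log2(np.maximum(ctl, 1e-12))) if log_transform else (tum, ctl)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = scipy.stats.ttest_ind(xt, xc, axis=1, equal_var=False)
    degenerate = (xt.var(axis=1) == 0) & (xc.var(axis=1) == 0)
    pval = np.where(degenerate, np.nan, pval)
    if degenerate.any():
        logger.warning("%d features with zero variance in both groups: P missing", int(degenerate.sum()))
    adj = np.full_like(pval, np.nan)
    ok = np.isfinite(pval)
    if ok.any():
        adj[ok] = multipletests(pval[ok], method="fdr_bh")[1]
    return pd.DataFrame({"fc": fc, "t": tstat, "p": pval, "adj_p": adj}, index=matrix.index)


def select_dets(
    de_records: pd.DataFrame, fc_threshold: float = 2.0, alpha: float = 0.05
) -> pd.Index:
    """Differentially expressed features: FC > 2 or FC < 0.5, adjusted P < 0.05.

    The fold-change gate is symmetric on the ratio scale (threshold and its
    reciprocal); both inequalities are strict.
    """
    fc, adj = de_records["fc"], de_records["adj_p"]
    keep = ((fc > fc_threshold) | (fc < 1.0 / fc_threshold)) & (adj < alpha)
    return de_records.index[keep.fillna(False)]
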