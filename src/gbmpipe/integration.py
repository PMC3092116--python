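"""Amplification-expression integration with a permutation weight statistic.

For each gene the tumor samples are split into amplified and non-amplified
groups by the copy-number calls, and the weight

    w = (mean_amplified - mean_non_amplified) / (SD_amplified + SD_non_amplified)

is tested by randomly permuting the group labels (group sizes fixed) and
comparing the permuted weights with the observed one.  The test is one-sided
toward overexpression-with-amplification by default (two-sided available);
the mirrored statistic with a loss mask and flipped sign screens
deletion-driven underexpression.  Candidate amplification-driven genes are
those with permutation P < 0.01 and gain frequency > 5%.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def amplification_weight(values, mask) -> float:
    """Weight statistic; NaN when a group has <2 samples or both SDs are 0."""
    x = np.asarray(values, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if x.shape != m.shape:
        raise ValueError("values and mask must have equal length")
    amp, non = x[m], x[~m]
    if amp.size < 2 or non.size < 2:
        logger.debug("group with <2 samples: weight undefined")
        return float("nan")
    denom = amp.std(ddof=1) + non.std(ddof=1)
    if denom == 0:
        logger.debug("both group SDs zero: weight undefined")
        return float("nan")
    return float((amp.mean() - non.mean()) / denom)


def _weights_for_index_matrix(x: np.ndarray, amp_idx: np.ndarray) -> np.ndarray:
    """Weights for many amplified-group index sets at once (rows of amp_idx)."""
    n = x.size
    k = amp_idx.shape[1]
    total, total_sq = x.sum(), (x**2).sum()
    s = x[amp_idx].sum(axis=1)
    s2 = (x[amp_idx] ** 2).sum(axis=1)
    mean_a = s / k
    mean_n = (total - s) / (n - k)
    var_a = (s2 - k * mean_a**2) / (k - 1)
    var_n = ((total_sq - s2) - (n - k) * mean_n**2) / (n - k - 1)
    denom = np.sqrt(np.maximum(var_a, 0)) + np.sqrt(np.maximum(var_n, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (mean_a - mean_n) / denom


def permutation_pvalue(
    values,
    mask,
    n_permutations: int = 10_000,
    seed: int = 0,
    two_sided: bool = False,
    exhaustive_limit: int = 10_000,
) -> float:
    """Permutation P-value of the amplification weight.

    All label assignments are enumerated exhaustively when C(n, k) does not
    exceed ``exhaustive_limit`` (P = fraction of assignments with permuted w
    at least the observed); otherwise ``n_permutations`` random assignments
    are drawn and the add-one estimator P = (1 + #{w_perm >= w_obs}) /
    (n_permutations + 1) is used.  ``two_sided`` compares |w| instead.
    """
    x = np.asarray(values, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if x.size and np.ptp(x) == 0:
        # constant expression: every permuted assignment looks like the
        # observed one, nothing to detect
        return 1.0
    w_obs = amplification_weight(x, m)
    if not np.isfinite(w_obs):
        return float("nan")
    n, k = x.size, int(m.sum())

    def effect(w):
        return np.abs(w) if two_sided else w

    if comb(n, k) <= exhaustive_limit:
        idx = np.array(list(combinations(range(n), k)))
        w_all = _weights_for_index_matrix(x, idx)
        w_all = w_all[np.isfinite(w_all)]
        return float((effect(w_all) >= effect(w_obs) - 1e-12).sum() / comb(n, k))
    rng = np.random.default_rng(seed)
    order = rng.permuted(np.broadcast_to(np.arange(n), (n_permutations, n)), axis=1)
    w_perm = _weights_for_index_matrix(x, order[:, :k])
    exceed = int((effect(w_perm[np.isfinite(w_perm)]) >= effect(w_obs) - 1e-12).sum())
    return float((1 + exceed) / (n_permutations + 1))


def integrate_expression_cn(
    expression: pd.DataFrame,
    aberration_status: pd.DataFrame,
    frequencies: pd.DataFrame,
    direction: str = "gain",
    n_permutations: int = 10_000,
    seed: int = 0,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Per-gene weight + permutation P over a cohort.

    Parameters
    ----------
    expression : DataFrame
        Gene x tumor-sample expression values.
    aberration_status : DataFrame
        Gene x sample status from :func:`gbmpipe.copynumber.aberration_matrix`.
    frequencies : DataFrame
        Gain/loss frequencies per gene (columns ``gain_freq``/``loss_freq``).
    direction : {"gain", "loss"}
        ``gain`` tests amplification-driven overexpression; ``loss`` runs the
        mirrored deletion-underexpression statistic (sign-flipped values,
        loss mask).

    Returns
    -------
    DataFrame indexed by gene: ``w``, ``p_perm``, ``n_aberrant``,
    ``n_normal``, ``gain_freq``, ``loss_freq``.  Genes whose aberrant or
    normal group has <2 samples are skipped (missing w/P).
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    genes = expression.index.intersection(aberration_status.index)
    samples = expression.columns.intersection(aberration_status.columns)
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        vals = expression.loc[gene, samples].to_numpy(dtype=float)
        status = aberration_status.loc[gene, samples]
        usable = (status != "ambiguous").to_numpy()
        mask = (status == direction).to_numpy() & usable
        x = vals[usable] if direction == "gain" else -vals[usable]
        m = mask[usable]
        w = amplification_weight(x, m)
        p = (
            permutation_pvalue(
                x, m, n_permutations=n_permutations,
                seed=int(rng.integers(0, 2**31 - 1)), two_sided=two_sided,
            )
            if np.isfinite(w)
            else float("nan")
        )
        rows.append(
            pd.Series(
                {
                    "w": w,
                    "p_perm": p,
                    "n_aberrant": int(m.sum()),
                    "n_normal": int((~m).sum()),
                    "gain_freq": frequencies.loc[gene, "gain_freq"] if gene in frequencies.index else np.nan,
                    "loss_freq": frequencies.loc[gene, "loss_freq"] if gene in frequencies.index else np.nan,
                },
                name=gene,
            )
        )
    return pd.DataFrame(rows)


def select_amplification_driven(
    results: pd.DataFrame, p_threshold: float = 0.01, gain_threshold: float = 0.05
) -> pd.Index:
    """Genes whose overexpression is explained by amplification.

    Keeps genes with permutation P < 0.01 and gain frequency > 5%.
    """
    keep = (results["p_perm"] < p_threshold) & (results["gain_freq"] > gain_threshold)
    return results.index[keep.fillna(False)]
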