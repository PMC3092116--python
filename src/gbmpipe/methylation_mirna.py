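"""Methylation beta values, promoter-level combining, miRNA target filtering.

The beta value of a methylation probe is M/(M+U), where M and U are the
methylated and unmethylated signal levels; beta ranges from 0
(hypomethylated) to 1 (hypermethylated).  Probes targeting the same gene
promoter are combined by the median so each gene has a unique combined beta.

miRNA differential expression reuses :func:`gbmpipe.expression.differential_expression`
verbatim; target-site annotations are filtered at P < 1e-5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def beta_value(m, u):
    """Methylation fraction beta = M/(M+U); missing where M+U = 0.

    Accepts scalars or arrays; negative signals raise.
    """
    m_arr = np.asarray(m, dtype=float)
    u_arr = np.asarray(u, dtype=float)
    if (m_arr < 0).any() or (u_arr < 0).any():
        raise ValueError("negative methylation signal")
    total = m_arr + u_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m_arr / np.where(total > 0, total, 1.0), np.nan)
    return float(beta) if np.isscalar(m) and np.isscalar(u) else beta


def combine_promoter_probes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene median beta per sample.

    ``records`` is a long table with columns ``probe``, ``gene``, ``sample``
    and either ``beta`` or the raw ``M``/``U`` signals.  The median is taken
    over non-missing probe betas; a gene/sample cell with all probes missing
    stays missing.  Returns a gene x sample matrix.
    """
    df = records.copy()
    if "beta" not in df.columns:
        if not {"M", "U"}.issubset(df.columns):
            raise ValueError("records need a 'beta' column or raw 'M'/'U' signals")
        df["beta"] = beta_value(df["M"].to_numpy(), df["U"].to_numpy())
    out = df.pivot_table(index="gene", columns="sample", values="beta", aggfunc="median")
    missing = out.isna().all(axis=1)
    if missing.any():
        logger.warning("%d genes with all probes missing", int(missing.sum()))
    return out


def filter_mirna_targets(annotation: pd.DataFrame, p_threshold: float = 1e-5) -> pd.DataFrame:
    """Retain miRNA-target pairs with target-site P below ``p_threshold``.

    ``annotation`` has columns ``mirna``, ``gene``, ``p``.
    """
    if annotation.empty:
        return annotation.copy()
    for col in ("mirna", "gene", "p"):
        if col not in annotation.columns:
            raise ValueError(f"target annotation missing column {col!r}")
    return annotation[annotation["p"] < p_threshold].reset_index(drop=True)
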