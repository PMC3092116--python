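"""siRNA screen scoring: plate background correction and robust z-scores.

Plate-level systematic background is removed by fitting a robust
locally-weighted polynomial surface (degree 2, span 0.35, tricube distance
weights, iterated bisquare down-weighting of outliers) over well coordinates
and subtracting the fit, after which per-siRNA robust z-scores
(median / scaled MAD) and Welch t-tests against negative-control wells are
computed.  A gene is a consistent hit when at least two distinct siRNAs
reach the z cutoff in the effect direction in every tested cell line.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

#: consistency constant making the MAD match the SD under normality
MAD_SCALE = 1.4826

PLATE_COLUMNS = ["plate", "row", "col", "signal", "role", "sirna", "gene"]

ROLE_SAMPLE = "sample"
ROLE_NEGATIVE = "negative"
ROLE_POSITIVE = "positive"
ROLE_DEATH = "death"
ROLE_EMPTY = "empty"


def _loess_surface(
    coords: np.ndarray, y: np.ndarray, span: float, degree: int, iterations: int
) -> np.ndarray:
    """Fitted values of a robust local polynomial regression on 2-D coordinates."""
    n = y.size
    n_terms = 6 if degree == 2 else 3
    k = max(int(math.ceil(span * n)), n_terms + 2)
    k = min(k, n)
    # pairwise distances between wells
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    robust = np.ones(n)

    def design(xy: np.ndarray) -> np.ndarray:
        r, c = xy[:, 0], xy[:, 1]
        cols = [np.ones_like(r), r, c]
        if degree == 2:
            cols += [r * r, r * c, c * c]
        return np.column_stack(cols)

    x_full = design(coords)
    fit = np.empty(n)
    for _ in range(iterations + 1):
        for i in range(n):
            nbr = np.argpartition(d[i], k - 1)[:k]
            dmax = d[i, nbr].max()
            if dmax == 0:
                fit[i] = np.average(y[nbr], weights=robust[nbr]) if robust[nbr].sum() else y[nbr].mean()
                continue
            w = (1 - (d[i, nbr] / dmax) ** 3) ** 3
            w = np.maximum(w, 0) * robust[nbr]
            if w.sum() <= 0:
                w = np.maximum((1 - (d[i, nbr] / dmax) ** 3) ** 3, 0)
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(x_full[nbr] * sw[:, None], y[nbr] * sw, rcond=None)
            fit[i] = x_full[i] @ beta
        resid = y - fit
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = np.clip(resid / (6 * s), -1, 1)
        robust = (1 - u**2) ** 2
    return fit


def loess_plate_normalize(
    plate: pd.DataFrame,
    span: float = 0.35,
    degree: int = 2,
    iterations: int = 2,
    min_wells: int = 20,
) -> pd.DataFrame:
    """Subtract a robust local-regression background surface from one plate.

    The surface is fitted over (row, col) of non-empty wells; statistical
    outliers (hits) are down-weighted by bisquare reweighting so the fit
    stays robust even when plates differ in hit rate.  Returns a copy of the
    plate with corrected ``signal`` and the fitted ``background`` column.
    """
    for col in ("row", "col", "signal"):
        if col not in plate.columns:
            raise ValueError(f"plate table missing column {col!r}")
    roles = plate["role"] if "role" in plate.columns else pd.Series(ROLE_SAMPLE, index=plate.index)
    use = (roles != ROLE_EMPTY) & plate["signal"].notna()
    if int(use.sum()) < min_wells:
        raise ValueError(f"too few non-empty wells ({int(use.sum())} < {min_wells}) for surface fit")
    coords = plate.loc[use, ["row", "col"]].to_numpy(dtype=float)
    y = plate.loc[use, "signal"].to_numpy(dtype=float)
    fit = _loess_surface(coords, y, span=span, degree=degree, iterations=iterations)
    out = plate.copy()
    out["background"] = np.nan
    out.loc[use, "background"] = fit
    out.loc[use, "signal"] = y - fit
    return out


def robust_z(values, ref_median: float | None = None, ref_mad: float | None = None):
    """Robust z-scores: (x - median) / (1.4826 * MAD).

    The reference median/raw MAD default to those of ``values`` themselves.
    A zero MAD yields missing z (flagged).
    """
    x = np.asarray(values, dtype=float)
    med = float(np.nanmedian(x)) if ref_median is None else float(ref_median)
    mad = float(np.nanmedian(np.abs(x - med))) if ref_mad is None else float(ref_mad)
    if mad <= 0:
        logger.warning("MAD = 0: robust z undefined")
        return np.full_like(x, np.nan) if x.ndim else float("nan")
    return (x - med) / (MAD_SCALE * mad)


def normalize_to_negative_controls(plate: pd.DataFrame) -> pd.DataFrame:
    """Express signals relative to the mean of negative-control wells (== 1)."""
    neg = plate.loc[plate["role"] == ROLE_NEGATIVE, "signal"]
    if neg.empty:
        raise ValueError("plate has no negative-control wells")
    ref = float(neg.mean())
    if ref == 0:
        raise ValueError("negative-control mean is zero")
    out = plate.copy()
    out["signal"] = out["signal"] / ref
    return out


def significance_tier(p: float) -> str:
    """Map a P-value to the significance tiers ns / * / ** / ***."""
    if not np.isfinite(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def sirna_significance(replicate_signals, negative_signals) -> tuple[float, str]:
    """Welch two-tailed t-test of siRNA replicates vs negative controls."""
    x = np.asarray(replicate_signals, dtype=float)
    y = np.asarray(negative_signals, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 replicates on each side")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        logger.warning("zero variance on both sides: P missing")
        return float("nan"), "ns"
    p = float(scipy.stats.ttest_ind(x, y, equal_var=False).pvalue)
    return p, significance_tier(p)


def score_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-siRNA scores for one corrected plate.

    Robust z of each siRNA's replicate median relative to the plate's sample
    wells, plus the Welch t-test against negative controls.  Returns a frame
    indexed by siRNA with columns ``median_signal``, ``z``, ``p``, ``tier``.
    """
    samples = plate[plate["role"] == ROLE_SAMPLE]
    neg = plate.loc[plate["role"] == ROLE_NEGATIVE, "signal"].to_numpy(dtype=float)
    ref = samples["signal"].to_numpy(dtype=float)
    med = float(np.median(ref))
    mad = float(np.median(np.abs(ref - med)))
    rows = []
    for sirna, grp in samples.groupby("sirna"):
        vals = grp["signal"].to_numpy(dtype=float)
        z = robust_z(np.median(vals), ref_median=med, ref_mad=mad)
        p, tier = sirna_significance(vals, neg) if vals.size >= 2 and neg.size >= 2 else (float("nan"), "ns")
        rows.append(
            pd.Series(
                {"gene": grp["gene"].iloc[0], "median_signal": float(np.median(vals)), "z": z, "p": p, "tier": tier},
                name=sirna,
            )
        )
    return pd.DataFrame(rows)


def gene_consistency_call(
    z_table: pd.DataFrame, z_min: float = 2.0, min_sirnas: int = 2, direction: int = -1
) -> bool:
    """Consistent-hit call for one gene across cell lines.

    ``z_table`` holds per-siRNA z-scores (rows) per cell line (columns).  The
    gene is a hit when at least ``min_sirnas`` distinct siRNAs reach
    ``|z| >= z_min`` in the effect direction (default: inhibition, z <= -2)
    in every tested cell line.
    """
    if z_table.shape[0] < min_sirnas:
        return False
    qualifying = (direction * z_table >= z_min).all(axis=1)
    return int(qualifying.sum()) >= min_sirnas
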