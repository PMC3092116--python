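"""aCGH segmentation, aberration calling and per-gene gain/loss frequencies.

Profiles of normalized log-ratios are segmented per chromosome with circular
binary segmentation: the test statistic is the maximum over all arc
boundaries (i, j) of the standardized difference between the mean inside the
arc and the mean outside it, and a split is accepted when a permutation test
of that maximum is significant at ``alpha``; the search recurses into the
resulting pieces until no significant split remains.

A segment is called gained when its mean log-ratio exceeds the upper
threshold and lost when below the lower threshold (defaults +/-0.632); the
thresholds can be estimated from control (blood vs blood) arrays as the mean
of pooled control probe log-ratios plus/minus two standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_UPPER = 0.632
DEFAULT_LOWER = -0.632

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "n_probes", "seg_mean"]

_PAIR_CACHE: dict[tuple[int, int], tuple[np.ndarray, ...]] = {}


@dataclass
class AberrationThresholds:
    """Gain/loss calling thresholds on segment mean log-ratios."""

    upper: float = DEFAULT_UPPER
    lower: float = DEFAULT_LOWER

    def __post_init__(self) -> None:
        if not (self.lower < 0 < self.upper):
            raise ValueError(f"need lower < 0 < upper, got ({self.lower}, {self.upper})")


def estimate_thresholds(control_logratios=None, per_array: bool = False) -> AberrationThresholds:
    """Thresholds = mean +/- 2 SD of control probe log-ratios.

    ``control_logratios`` may be a probes x arrays DataFrame/2-D array or a
    pooled 1-D array.  By default the SD is pooled over all control probes;
    ``per_array=True`` averages per-array SDs instead.  Missing or degenerate
    controls (fewer than 2 values, zero SD) fall back to the +/-0.632
    defaults with a warning.
    """
    if control_logratios is None:
        logger.warning("no control arrays: using default thresholds +/-%.3f", DEFAULT_UPPER)
        return AberrationThresholds()
    arr = np.asarray(control_logratios, dtype=float)
    vals = arr[np.isfinite(arr)]
    if vals.size < 2:
        logger.warning("not enough control probes: using default thresholds")
        return AberrationThresholds()
    mean = float(vals.mean())
    if per_array and arr.ndim == 2:
        sds = np.nanstd(arr, axis=0, ddof=1)
        sd = float(np.nanmean(sds))
    else:
        sd = float(vals.std(ddof=1))
    if sd <= 0:
        logger.warning("degenerate control SD = 0: using default thresholds")
        return AberrationThresholds()
    return AberrationThresholds(upper=mean + 2 * sd, lower=mean - 2 * sd)


def _pairs(n: int, min_width: int):
    """Arc boundary index pairs (i, j), segment x[i:j], both sides >= min_width."""
    key = (n, min_width)
    if key not in _PAIR_CACHE:
        i_all, j_all = [], []
        for width in range(min_width, n - min_width + 1):
            i = np.arange(0, n - width + 1)
            i_all.append(i)
            j_all.append(i + width)
        i_arr = np.concatenate(i_all) if i_all else np.empty(0, dtype=int)
        j_arr = np.concatenate(j_all) if j_all else np.empty(0, dtype=int)
        k = (j_arr - i_arr).astype(float)
        m = n - k
        denom = np.sqrt(1.0 / k + 1.0 / m)
        _PAIR_CACHE[key] = (i_arr, j_arr, k, m, denom)
    return _PAIR_CACHE[key]


def _max_arc_stat(x: np.ndarray, min_width: int):
    """Maximum standardized arc mean difference and its boundaries (i, j)."""
    n = x.size
    i_arr, j_arr, k, m, denom = _pairs(n, min_width)
    if i_arr.size == 0:
        return 0.0, None
    sigma = x.std(ddof=1)
    if sigma == 0:
        return 0.0, None
    s = np.concatenate(([0.0], np.cumsum(x)))
    inside = s[j_arr] - s[i_arr]
    diff = inside / k - (s[n] - inside) / m
    z = np.abs(diff) / (sigma * denom)
    best = int(np.argmax(z))
    return float(z[best]), (int(i_arr[best]), int(j_arr[best]))


def _perm_max_stats(x: np.ndarray, min_width: int, rng: np.random.Generator, count: int) -> np.ndarray:
    """Max arc statistics for ``count`` random permutations of ``x`` (vectorized)."""
    n = x.size
    i_arr, j_arr, k, m, denom = _pairs(n, min_width)
    sigma = x.std(ddof=1)
    perm = rng.permuted(np.broadcast_to(x, (count, n)), axis=1)
    s = np.concatenate([np.zeros((count, 1)), np.cumsum(perm, axis=1)], axis=1)
    inside = s[:, j_arr] - s[:, i_arr]
    diff = inside / k - (s[:, [n]] - inside) / m
    z = np.abs(diff) / (sigma * denom)
    return z.max(axis=1)


def _split_significant(
    x: np.ndarray,
    stat: float,
    alpha: float,
    n_permutations: int,
    min_width: int,
    rng: np.random.Generator,
    chunk: int = 100,
) -> bool:
    """Permutation acceptance of a candidate split with early rejection.

    Add-one estimator P = (1 + #{perm >= observed}) / (B + 1); evaluation
    stops as soon as P >= alpha is certain.
    """
    limit = alpha * (n_permutations + 1) - 1  # exceedances allowed while still significant
    exceed = 0
    done = 0
    while done < n_permutations:
        take = min(chunk, n_permutations - done)
        exceed += int((_perm_max_stats(x, min_width, rng, take) >= stat).sum())
        done += take
        if exceed > limit:
            return False
    return (1 + exceed) / (n_permutations + 1) < alpha


def _segment_chromosome(
    x: np.ndarray,
    alpha: float,
    n_permutations: int,
    min_width: int,
    rng: np.random.Generator,
) -> list[int]:
    """Recursive change-point search; returns sorted interior breakpoints."""
    breakpoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if seg.size < 2 * min_width:
            return
        stat, bounds = _max_arc_stat(seg, min_width)
        if bounds is None or stat <= 0:
            return
        if not _split_significant(seg, stat, alpha, n_permutations, min_width, rng):
            return
        i, j = bounds
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            return
        breakpoints.extend(cuts)
        edges = [lo, *cuts, hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b)

    recurse(0, x.size)
    return sorted(breakpoints)


def segment_profile(
    profile: pd.DataFrame,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    min_width: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Segment one sample's probe profile into constant-mean segments.

    Parameters
    ----------
    profile : DataFrame
        Columns ``sample``, ``chrom``, ``pos``, ``logratio``; positions must
        be sorted within each chromosome.
    alpha, n_permutations, min_width :
        Permutation acceptance level, permutations per candidate split, and
        the minimum number of probes on each side of a split.
    seed : int
        Seed for the permutation stream (segmentation is deterministic given
        the seed).

    Returns
    -------
    DataFrame with columns :data:`SEGMENT_COLUMNS`; every probe is covered by
    exactly one segment and ``seg_mean`` is the mean of member probes.
    Genomic ``start``/``end`` are half-open probe-position bounds.
    """
    required = {"sample", "chrom", "pos", "logratio"}
    if not required.issubset(profile.columns):
        raise ValueError(f"profile needs columns {sorted(required)}")
    samples = profile["sample"].unique()
    if len(samples) != 1:
        raise ValueError("segment_profile expects a single sample; see segment_profiles")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in profile.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        if (np.diff(pos) < 0).any():
            raise ValueError(f"probe positions not sorted on {chrom}")
        x = grp["logratio"].to_numpy(dtype=float)
        cuts = _segment_chromosome(x, alpha, n_permutations, min_width, rng) if x.size >= 2 else []
        edges = [0, *cuts, x.size]
        for a, b in zip(edges[:-1], edges[1:]):
            rows.append(
                {
                    "sample": samples[0],
                    "chrom": chrom,
                    "start": int(pos[a]),
                    "end": int(pos[b - 1]) + 1,
                    "n_probes": b - a,
                    "seg_mean": float(x[a:b].mean()),
                }
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def segment_profiles(
    probes: pd.DataFrame,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    min_width: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Segment every sample in a long probe table (see :func:`segment_profile`)."""
    parts = []
    for idx, (_, grp) in enumerate(probes.groupby("sample", sort=True)):
        parts.append(
            segment_profile(
                grp, alpha=alpha, n_permutations=n_permutations, min_width=min_width, seed=seed + idx
            )
        )
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=SEGMENT_COLUMNS)


def call_aberrations(segments: pd.DataFrame, thresholds: AberrationThresholds) -> pd.DataFrame:
    """Label segments gain/loss/neutral by strict threshold comparison."""
    out = segments.copy()
    mean = out["seg_mean"]
    out["call"] = np.where(mean > thresholds.upper, "gain", np.where(mean < thresholds.lower, "loss", "neutral"))
    return out


def aberration_matrix(called_segments: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Per-feature per-sample aberration status.

    ``features`` is indexed by feature id with columns chrom/start/end
    (half-open).  A feature overlapping any gained segment in a sample is
    ``gain``; any lost segment, ``loss``; both present, ``ambiguous``
    (excluded from frequencies); otherwise ``neutral``.  Features with no
    covering segment in a sample count as neutral (logged).
    """
    samples = sorted(called_segments["sample"].unique())
    out = pd.DataFrame("neutral", index=features.index, columns=samples)
    uncovered = 0
    by_sample = dict(tuple(called_segments.groupby("sample")))
    for sample in samples:
        segs = by_sample[sample]
        for fid, feat in features.iterrows():
            hit = segs[
                (segs["chrom"] == feat["chrom"])
                & (segs["start"] < feat["end"])
                & (segs["end"] > feat["start"])
            ]
            if hit.empty:
                uncovered += 1
                continue
            calls = set(hit["call"])
            if "gain" in calls and "loss" in calls:
                out.loc[fid, sample] = "ambiguous"
            elif "gain" in calls:
                out.loc[fid, sample] = "gain"
            elif "loss" in calls:
                out.loc[fid, sample] = "loss"
    if uncovered:
        logger.info("%d feature/sample pairs without covering segment counted neutral", uncovered)
    return out


def aberration_frequencies(called_segments: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Fraction of samples in which each feature is gained / lost.

    Ambiguous feature/sample pairs (both gain and loss overlap) are excluded
    from both numerators; the denominator is the total number of samples.
    """
    status = aberration_matrix(called_segments, features)
    n = status.shape[1]
    return pd.DataFrame(
        {
            "gain_freq": (status == "gain").sum(axis=1) / n,
            "loss_freq": (status == "loss").sum(axis=1) / n,
            "n_ambiguous": (status == "ambiguous").sum(axis=1),
        }
    )
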