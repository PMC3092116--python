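"""Kaplan-Meier estimation, log-rank testing and survival screens.

Two screens are provided.  The transcriptome screen discretizes per-sample
fold changes of differentially expressed transcripts into underexpression
(FC < 0.5, class -1), overexpression (FC > 2, class 1) and stable expression
(class 0), drops classes with fewer than 20 patients, and runs a log-rank
test over the remaining classes.  The germline SNP screen applies sample and
call quality control, a minor-allele-frequency filter, a 36-month study
horizon with administrative censoring, rare-homozygote merging, and reports
markers with uncorrected log-rank P below 1e-4.

The log-rank statistic is computed internally with the standard O-E /
hypergeometric-variance formulation (all tied events at a time handled with
the hypergeometric variance); Kaplan-Meier estimates and Greenwood-based
confidence intervals come from :mod:`lifelines`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import KaplanMeierFitter

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ["months", "event"]


def _check_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    for c in CLINICAL_COLUMNS:
        if c not in clinical.columns:
            raise ValueError(f"clinical table missing column {c!r}")
    if clinical["months"].isna().all():
        raise ValueError("all survival times missing")
    if (clinical["months"] < 0).any():
        raise ValueError("negative survival times")
    if not clinical["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (death)")
    return clinical


def kaplan_meier(clinical: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood-based 95% CI.

    Returns a step-function table indexed by time with columns ``S``,
    ``ci_lower``, ``ci_upper``.
    """
    clinical = _check_clinical(clinical)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(clinical["months"], clinical["event"])
    out = pd.DataFrame(
        {
            "S": kmf.survival_function_.iloc[:, 0],
            "ci_lower": kmf.confidence_interval_.iloc[:, 0],
            "ci_upper": kmf.confidence_interval_.iloc[:, 1],
        }
    )
    out.index.name = "time"
    return out


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    df: int
    group_sizes: dict


def logrank_test(times, events, groups) -> LogrankResult:
    """K-sample log-rank test (chi-square with k-1 df).

    Observed-minus-expected death counts per group accumulated over ordered
    distinct event times, with the hypergeometric (co)variance; ties at a
    time are handled by the multivariate hypergeometric formula.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if t.shape != e.shape or t.shape != g.shape:
        raise ValueError("times, events and groups must have equal length")
    labels, gidx = np.unique(g, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank test needs >= 2 nonempty groups")
    sizes = {lab: int(n) for lab, n in zip(labels, np.bincount(gidx, minlength=k))}

    event_times = np.unique(t[e == 1])
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n = int(at_risk.sum())
        if n < 1:
            continue
        dying = at_risk & (e == 1) & (t == et)
        d = int(dying.sum())
        n_i = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_i = np.bincount(gidx[dying], minlength=k).astype(float)
        frac = n_i / n
        o_minus_e += d_i - d * frac
        if n > 1:
            c = d * (n - d) / (n - 1)
            cov += c * (np.diag(frac) - np.outer(frac, frac))
    v = cov[: k - 1, : k - 1]
    u = o_minus_e[: k - 1]
    try:
        stat = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(v) @ u)
    stat = max(stat, 0.0)
    p = float(scipy.stats.chi2.sf(stat, df=k - 1))
    return LogrankResult(statistic=stat, p_value=p, df=k - 1, group_sizes=sizes)


def discretize_fold_change(fc, lower: float = 0.5, upper: float = 2.0) -> np.ndarray:
    """Map per-sample fold changes to classes -1 (FC<0.5), 1 (FC>2), 0 (else)."""
    fc = np.asarray(fc, dtype=float)
    cls = np.zeros(fc.shape, dtype=int)
    cls[fc < lower] = -1
    cls[fc > upper] = 1
    return cls


def expression_survival_screen(
    per_sample_fc: pd.DataFrame,
    clinical: pd.DataFrame,
    min_group_size: int = 20,
) -> pd.DataFrame:
    """Discretized-expression Kaplan-Meier/log-rank screen over features.

    Parameters
    ----------
    per_sample_fc : DataFrame
        Features x patients per-sample fold changes (patients must appear in
        ``clinical``); normally restricted to pre-selected DETs.
    clinical : DataFrame
        Indexed by patient id, columns ``months`` and ``event``.
    min_group_size : int
        Expression classes with fewer patients are excluded; features left
        with fewer than two classes are skipped.

    Returns
    -------
    DataFrame indexed by feature with columns ``chisq``, ``p``, ``n_groups``
    and per-class counts ``n_under``/``n_stable``/``n_over``.  Skipped
    features carry missing P.
    """
    clinical = _check_clinical(clinical)
    patients = per_sample_fc.columns.intersection(clinical.index)
    if len(patients) < len(per_sample_fc.columns):
        logger.warning(
            "%d samples without clinical records dropped from survival screen",
            len(per_sample_fc.columns) - len(patients),
        )
    times = clinical.loc[patients, "months"].to_numpy()
    events = clinical.loc[patients, "event"].to_numpy()
    rows = []
    for feature, fc in per_sample_fc.loc[:, patients].iterrows():
        cls = discretize_fold_change(fc.to_numpy())
        counts = {c: int((cls == c).sum()) for c in (-1, 0, 1)}
        keep_classes = [c for c, n in counts.items() if n >= min_group_size]
        mask = np.isin(cls, keep_classes)
        row = {
            "n_under": counts[-1],
            "n_stable": counts[0],
            "n_over": counts[1],
            "n_groups": len(keep_classes),
            "chisq": np.nan,
            "p": np.nan,
        }
        if len(keep_classes) >= 2:
            res = logrank_test(times[mask], events[mask], cls[mask])
            row["chisq"], row["p"] = res.statistic, res.p_value
        else:
            logger.debug("feature %s skipped: %d class(es) after size filter", feature, len(keep_classes))
        rows.append(pd.Series(row, name=feature))
    return pd.DataFrame(rows)


def administrative_censor(clinical: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Truncate follow-up at the study horizon (events after it become censored)."""
    out = clinical.copy()
    late = out["months"] > horizon
    out.loc[late, "months"] = horizon
    out.loc[late, "event"] = 0
    return out


def minor_allele_frequency(calls: pd.Series) -> float:
    """MAF from called genotypes only, counting alleles (AA/AB/BB coding)."""
    counts = calls.value_counts()
    n_called = int(counts.reindex(["AA", "AB", "BB"]).fillna(0).sum())
    if n_called == 0:
        return float("nan")
    b = 2 * counts.get("BB", 0) + counts.get("AB", 0)
    freq_b = b / (2 * n_called)
    return float(min(freq_b, 1.0 - freq_b))


def snp_survival_screen(
    calls: pd.DataFrame,
    call_prob: pd.DataFrame,
    sample_snr: pd.Series,
    clinical: pd.DataFrame,
    study_time: float = 36.0,
    snr_min: float = 5.0,
    call_prob_min: float = 0.95,
    maf_min: float = 0.1,
    rare_homozygote_min_count: int = 15,
    rare_homozygote_min_freq: float = 0.1,
    p_limit: float = 1e-4,
) -> pd.DataFrame:
    """Genotype-group survival screen over SNP markers.

    Quality control drops samples with signal-to-noise ratio below 5 and sets
    calls with probability below 0.95 to missing.  Markers with minor allele
    frequency below 0.1 are excluded.  Survival times are administratively
    censored at 36 months.  The rare-homozygote group is merged into the
    heterozygote group when it has fewer than 15 patients or frequency below
    0.1 among called patients; a log-rank test is run across the remaining
    genotype groups.  Markers with raw P below ``p_limit`` are flagged.

    Returns a DataFrame indexed by marker with columns ``maf``, ``n_groups``,
    ``merged``, ``chisq``, ``p``, ``selected`` and a ``status`` note for
    excluded/skipped markers.
    """
    clinical = administrative_censor(_check_clinical(clinical), study_time)
    good_samples = sample_snr.index[sample_snr >= snr_min]
    dropped = len(sample_snr) - len(good_samples)
    if dropped:
        logger.info("%d samples dropped by SNR < %g", dropped, snr_min)
    patients = calls.columns.intersection(good_samples).intersection(clinical.index)
    calls = calls.loc[:, patients].where(call_prob.loc[:, patients] >= call_prob_min)
    times = clinical.loc[patients, "months"].to_numpy()
    events = clinical.loc[patients, "event"].to_numpy()

    rows = []
    for marker, geno in calls.iterrows():
        row = {
            "maf": np.nan, "n_groups": 0, "merged": False,
            "chisq": np.nan, "p": np.nan, "selected": False, "status": "ok",
        }
        maf = minor_allele_frequency(geno)
        row["maf"] = maf
        if not np.isfinite(maf) or maf < maf_min:
            row["status"] = "maf_excluded"
            rows.append(pd.Series(row, name=marker))
            continue
        counts = geno.value_counts()
        n_called = int(counts.reindex(["AA", "AB", "BB"]).fillna(0).sum())
        freq_b = (2 * counts.get("BB", 0) + counts.get("AB", 0)) / (2 * n_called)
        rare_homo = "BB" if freq_b <= 0.5 else "AA"
        groups = geno.copy()
        n_rare = int(counts.get(rare_homo, 0))
        if n_rare > 0 and (n_rare < rare_homozygote_min_count or n_rare / n_called < rare_homozygote_min_freq):
            groups = groups.replace(rare_homo, "AB")
            row["merged"] = True
        called = groups.notna().to_numpy()
        g = groups[called].to_numpy()
        labels = np.unique(g)
        row["n_groups"] = len(labels)
        if len(labels) < 2:
            row["status"] = "one_group"
            rows.append(pd.Series(row, name=marker))
            continue
        res = logrank_test(times[called], events[called], g)
        row["chisq"], row["p"] = res.statistic, res.p_value
        row["selected"] = bool(res.p_value < p_limit)
        rows.append(pd.Series(row, name=marker))
    out = pd.DataFrame(rows)
    out["selected"] = out["selected"].astype(bool)
    out["merged"] = out["merged"].astype(bool)
    return out


def km_plot(
    clinical: pd.DataFrame, groups: pd.Series, path, title: str = "", alpha: float = 0.05
) -> None:
    """Kaplan-Meier curves per group with 95% CI bands, written as SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clinical = _check_clinical(clinical)
    fig, ax = plt.subplots(figsize=(5, 4))
    for label in sorted(groups.dropna().unique()):
        ids = groups.index[groups == label].intersection(clinical.index)
        if len(ids) == 0:
            continue
        kmf = KaplanMeierFitter(alpha=alpha)
        kmf.fit(clinical.loc[ids, "months"], clinical.loc[ids, "event"], label=f"class {label} (n={len(ids)})")
        kmf.plot_survival_function(ax=ax, ci_show=True)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
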