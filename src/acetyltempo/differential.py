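"""Pseudocount log transform, per-site pairwise contrasts, and QC.

The differential test is the classical equal-variance two-sample Student
t-test applied per site to log2(x + pseudocount) values, with significance
called at an unadjusted p < alpha — no fold-change filter and no multiple
testing correction in the main path (a Benjamini-Hochberg mode exists for
users who want adjusted calls).  Missing values are dropped per site; a
site with fewer than two remaining replicates in either group is flagged
untestable and excluded with a logged count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import QuantTable

logger = logging.getLogger("acetyltempo")


@dataclass(frozen=True)
class ContrastOutcome:
    """One site's result for one pairwise contrast (b vs a)."""

    site_id: str
    contrast: str
    log2fc: float
    t: float
    p_value: float
    significant: bool
    direction: str  # "up" | "down" | "none"
    exact_separation: bool = False


def transform(
    table: QuantTable, pseudocount: float = 1.0, log_base: float = 2.0
) -> QuantTable:
    """Return log_base(x + pseudocount) with shape and metadata preserved."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (table.data == 0).any().any():
        raise ValueError("zero intensities require pseudocount > 0")
    logged = np.log(table.data + pseudocount) / np.log(log_base)
    return QuantTable(logged, table.sample_meta.copy(), log_scale=True)


def contrast(
    logtable: QuantTable,
    condition_a: str,
    condition_b: str,
    alpha: float = 0.05,
    adjust: bool = False,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-site Student t-test of condition_b vs condition_a.

    Returns a DataFrame indexed by site_id with columns contrast, log2fc,
    t, p_value, significant, direction, exact_separation.  log2fc is
    mean(b) - mean(a) on the (already log-scale) values.  Sites with a zero
    pooled variance get p = 1 when the means agree, else p = 0 with the
    exact_separation flag.  With ``adjust`` the significance call uses
    Benjamini-Hochberg adjusted p-values (the raw p column is unchanged).
    """
    a = logtable.data[logtable.samples_for(condition_a)].to_numpy(float)
    b = logtable.data[logtable.samples_for(condition_b)].to_numpy(float)
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError(
            f"condition missing from table: {condition_a!r} or {condition_b!r}"
        )
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    testable = (na >= 2) & (nb >= 2)
    n_drop = int((~testable).sum())
    if n_drop:
        logger.warning(
            "%s_vs_%s: %d sites untestable (<2 replicates), excluded",
            condition_b, condition_a, n_drop,
        )

    # compute group means only on testable rows (nanmean warns on empty rows)
    mean_a = np.full(a.shape[0], np.nan)
    mean_b = np.full(a.shape[0], np.nan)
    mean_a[testable] = np.nanmean(a[testable], axis=1)
    mean_b[testable] = np.nanmean(b[testable], axis=1)
    lfc = mean_b - mean_a

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance sites make scipy warn; they are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(
            b.T, a.T, axis=0, equal_var=not welch, nan_policy="omit"
        )
    t = np.asarray(t, float)
    p = np.asarray(p, float)

    # zero pooled variance: t-test undefined; equal means -> p=1, else p=0
    var_a = np.full(a.shape[0], np.nan)
    var_b = np.full(a.shape[0], np.nan)
    var_a[testable] = np.nanvar(a[testable], axis=1, ddof=1)
    var_b[testable] = np.nanvar(b[testable], axis=1, ddof=1)
    zero_var = testable & (var_a == 0) & (var_b == 0)
    sep = zero_var & (lfc != 0)
    t[zero_var & ~sep] = 0.0
    p[zero_var & ~sep] = 1.0
    t[sep] = np.sign(lfc[sep]) * np.inf
    p[sep] = 0.0

    label = f"{condition_b}_vs_{condition_a}"
    df = pd.DataFrame(
        {
            "contrast": label,
            "log2fc": lfc,
            "t": t,
            "p_value": p,
            "exact_separation": sep,
        },
        index=logtable.data.index,
    )
    df = df[testable]
    p_call = df["p_value"].to_numpy()
    if adjust:
        p_call = multipletests(p_call, method="fdr_bh")[1]
        df["p_adjusted"] = p_call
    df["significant"] = p_call < alpha
    df["direction"] = np.where(
        ~df["significant"], "none", np.where(df["log2fc"] > 0, "up", "down")
    )
    return df


def contrast_all(
    logtable: QuantTable,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Stack ``contrast`` over several (a, b) condition pairs."""
    frames = [contrast(logtable, a, b, alpha, **kwargs) for a, b in pairs]
    out = pd.concat(frames)
    out.index.name = "site_id"
    return out


@dataclass
class QCSummary:
    """PCA sample scores / variance fractions and per-contrast MA tables."""

    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray
    ma: dict[str, pd.DataFrame]  # contrast label -> columns A, M


def qc(logtable: QuantTable, pairs: list[tuple[str, str]] | None = None
       ) -> QCSummary:
    """PCA (SVD of the site-mean-centered matrix) and MA coordinates.

    Sample scores are the projections of samples on the principal axes of
    the sites x samples matrix after centering each site; a constant matrix
    yields all-zero variance fractions.  For each contrast (a, b), A is the
    mean of the two group means and M their difference, per site.
    """
    x = logtable.data.to_numpy(float)
    centered = x - np.nanmean(x, axis=1, keepdims=True)
    centered = np.nan_to_num(centered)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    varfrac = s**2 / total if total > 0 else np.zeros_like(s)
    scores = pd.DataFrame(
        (vt * s[:, None]).T,
        index=logtable.data.columns,
        columns=[f"PC{i+1}" for i in range(len(s))],
    )
    ma = {}
    if pairs is None:
        conds = logtable.conditions
        pairs = [(conds[0], c) for c in conds[1:]]
    for a, b in pairs:
        ma_mean_a = logtable.data[logtable.samples_for(a)].mean(axis=1)
        ma_mean_b = logtable.data[logtable.samples_for(b)].mean(axis=1)
        ma[f"{b}_vs_{a}"] = pd.DataFrame(
            {"A": (ma_mean_a + ma_mean_b) / 2, "M": ma_mean_b - ma_mean_a}
        )
    return QCSummary(scores, varfrac, ma)
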