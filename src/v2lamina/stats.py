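"""Group statistics: repeated-measures ANOVA, paired t, bootstrap null,
Fisher z, Benjamini-Hochberg FDR, and a Bonferroni helper for ANOVA families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateDataWarning, InputError


@dataclass
class RMAnovaResult:
    """One-way repeated-measures ANOVA (condition within subject)."""

    f: float
    df_effect: int
    df_error: int
    p: float
    degenerate: bool = False


def rm_anova_oneway(data) -> RMAnovaResult:
    """Classical within-subject decomposition of a subject x condition table.

    F = MS_condition / MS_(condition x subject); df = (k-1), (k-1)(n-1).
    A zero interaction mean square (perfectly consistent effects) is flagged
    degenerate with F = inf.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise InputError("data must be a 2D subject x condition table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InputError("need >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(x)):
        raise InputError("missing cells are not supported (no imputation)")
    grand = x.mean()
    subj = x.mean(axis=1, keepdims=True)
    cond = x.mean(axis=0, keepdims=True)
    ss_cond = n * ((cond - grand) ** 2).sum()
    ss_err = ((x - subj - cond + grand) ** 2).sum()
    df_e, df_r = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df_e
    ms_err = ss_err / df_r
    if ms_err == 0:
        if ms_cond == 0:
            return RMAnovaResult(0.0, df_e, df_r, 1.0)
        warnings.warn(
            "zero condition-by-subject variance; F is unbounded", DegenerateDataWarning
        )
        return RMAnovaResult(np.inf, df_e, df_r, 0.0, degenerate=True)
    f = ms_cond / ms_err
    return RMAnovaResult(float(f), df_e, df_r, float(sps.f.sf(f, df_e, df_r)))


def paired_t(x, y):
    """Paired t-test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise InputError("paired samples must have equal length >= 2")
    d = x - y
    if d.std(ddof=1) == 0:
        raise InputError("zero-variance differences; paired t undefined")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), x.size - 1, float(res.pvalue)


@dataclass
class BootstrapNull:
    """Bootstrap distribution of pairwise compartment differences."""

    pairs: list
    samples: dict  # pair -> ndarray of n_iter differences
    p: dict  # pair -> two-sided p against 0
    n_iter: int
    seed: int


def bootstrap_compartment_null(si, labels=None, n_iter=10000, seed=0) -> BootstrapNull:
    """Bootstrap test of pairwise differences in mean SI between compartments.

    Each iteration resamples subjects with replacement, computes each
    compartment's mean SI, and records every pairwise difference; the
    two-sided p for a pair is 2 * min(frac >= 0, frac <= 0) with add-one
    smoothing, i.e. the critical value is 0.

    Parameters
    ----------
    si : ndarray, shape (n_subjects, n_compartments)
    labels : sequence of compartment names, optional
    """
    x = np.asarray(si, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InputError("need a 2D subject x compartment table with >= 2 subjects")
    n, k = x.shape
    labels = list(labels) if labels is not None else [f"c{i}" for i in range(k)]
    rng = np.random.default_rng([int(seed) % (2**31), 91])
    idx = rng.integers(0, n, size=(n_iter, n))
    means = x[idx].mean(axis=1)  # (n_iter, k)
    pairs, samples, pvals = [], {}, {}
    for i in range(k):
        for j in range(i + 1, k):
            pair = (labels[i], labels[j])
            d = means[:, i] - means[:, j]
            ge = (1 + np.sum(d >= 0)) / (1 + n_iter)
            le = (1 + np.sum(d <= 0)) / (1 + n_iter)
            pairs.append(pair)
            samples[pair] = d
            pvals[pair] = float(min(1.0, 2.0 * min(ge, le)))
    return BootstrapNull(pairs, samples, pvals, n_iter, seed)


def fisher_z(r):
    """Fisher z-transform, z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise InputError("|r| must be < 1 for the Fisher transform")
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def fisher_z_inverse(z):
    """Inverse Fisher transform, r = tanh(z)."""
    z = np.asarray(z, dtype=float)
    r = np.tanh(z)
    return float(r) if r.ndim == 0 else r


def fdr_bh(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_family(p_values, alpha=0.05):
    """Bonferroni-corrected p-values and the survival flags for an ANOVA family.

    Post hoc tests are gated on the family-corrected ANOVA surviving
    ``alpha`` (corrected p < alpha), per the usual gatekeeping rule.
    """
    p = np.asarray(p_values, dtype=float)
    corr = np.minimum(p * p.size, 1.0)
    return corr, corr < alpha


@dataclass
class GroupTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def one_sample_t(values, popmean=0.0) -> GroupTestResult:
    """Two-sided one-sample t against ``popmean``; all-equal input is degenerate."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InputError("need >= 3 observations")
    if x.std(ddof=1) == 0:
        if np.allclose(x, popmean):
            warnings.warn("all values equal the null mean; t = 0", DegenerateDataWarning)
            return GroupTestResult(0.0, x.size - 1, 1.0, degenerate=True)
        raise InputError("zero variance with nonzero effect; t undefined")
    res = sps.ttest_1samp(x, popmean)
    return GroupTestResult(float(res.statistic), x.size - 1, float(res.pvalue))
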