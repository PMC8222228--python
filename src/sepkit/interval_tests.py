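"""Exact negative-binomial tests between neighboring time points.

For each gene and each of the n-1 neighboring time intervals we test
H0: mu_j = mu_{j+1} with a conditional exact test in the style of the
classical two-group NB exact test: libraries are first scaled to a common
(geometric-mean) size, the per-group sums A and B are formed, and the test
conditions on the total T = A + B.  With a common dispersion phi the
conditional law of A given T is negative hypergeometric (the unknown mean
cancels), collapsing to Binomial(T, n_a/(n_a+n_b)) in the Poisson limit
phi = 0.  The p-value sums the probabilities of all splits no more likely
than the observed one.

BH (Benjamini-Hochberg) adjustment turns the per-interval p-values into
q-values; ternary model calling downstream rejects at q below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .data_model import CountMatrix

__all__ = [
    "DispersionFit",
    "estimate_common_dispersion",
    "nb_exact_test",
    "test_neighbor_intervals",
    "bh_adjust",
    "equalize_lib_sizes",
]

#: totals above this are handled with a normal approximation instead of
#: exact enumeration of all splits
ENUMERATION_LIMIT = 10_000


@dataclass(frozen=True)
class DispersionFit:
    """Common NB dispersion phi (variance = mu + phi*mu^2) shared by all genes."""

    common_dispersion: float
    n_genes_used: int
    loglik: float

    def __post_init__(self) -> None:
        if self.common_dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not np.isfinite(self.loglik):
            raise ValueError("non-finite log-likelihood")


def equalize_lib_sizes(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """Scale each library's counts to the geometric-mean library size.

    Returns integer pseudo-counts (round-half-even for determinism).
    """
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise ValueError("library sizes must be positive")
    geo = float(np.exp(np.mean(np.log(lib_sizes))))
    scaled = np.asarray(counts, dtype=float) * (geo / lib_sizes)
    return np.round(scaled).astype(np.int64)


def _log_nbinom_sum_pmf(a: np.ndarray, r: float) -> np.ndarray:
    """log of the combinatorial factor C(a + r - 1, a) for NB-sum masses."""
    a = np.asarray(a, dtype=float)
    return gammaln(a + r) - gammaln(r) - gammaln(a + 1)


def _conditional_split_logpmf(T: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log-pmf of A given A + B = T over a = 0..T under H0.

    With equalized library sizes and common dispersion, A is the sum of
    n_a iid NB variables and B of n_b; conditionally on T the mean cancels
    and the law is negative hypergeometric with shapes n_a/phi, n_b/phi.
    phi = 0 is the binomial limit.
    """
    a = np.arange(T + 1)
    if phi == 0.0:
        p = n_a / (n_a + n_b)
        logpmf = (
            gammaln(T + 1)
            - gammaln(a + 1)
            - gammaln(T - a + 1)
            + a * np.log(p)
            + (T - a) * np.log1p(-p)
        )
        return logpmf
    r_a = n_a / phi
    r_b = n_b / phi
    logw = _log_nbinom_sum_pmf(a, r_a) + _log_nbinom_sum_pmf(T - a, r_b)
    # normalize: subtract log C(T + r_a + r_b - 1, T)
    logw -= gammaln(T + r_a + r_b) - gammaln(r_a + r_b) - gammaln(T + 1)
    return logw


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_sizes_a: np.ndarray,
    lib_sizes_b: np.ndarray,
    phi: float,
) -> float:
    """Exact conditional NB test of equal means between two groups.

    Libraries are scaled to the geometric mean of all library sizes; the
    test conditions on the total pseudo-count T and sums the conditional
    probabilities of every split (a, T - a) no more likely than the
    observed one.  Symmetric in the two groups.
    """
    counts_a = np.atleast_1d(np.asarray(counts_a))
    counts_b = np.atleast_1d(np.asarray(counts_b))
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise ValueError("negative counts")
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    lib_sizes = np.concatenate([np.atleast_1d(lib_sizes_a), np.atleast_1d(lib_sizes_b)]).astype(float)
    if np.any(lib_sizes <= 0):
        raise ValueError("library sizes must be positive")
    pseudo = equalize_lib_sizes(np.concatenate([counts_a, counts_b]), lib_sizes)
    n_a, n_b = counts_a.size, counts_b.size
    A = int(pseudo[:n_a].sum())
    B = int(pseudo[n_a:].sum())
    T = A + B
    if T == 0:
        return 1.0
    if T <= ENUMERATION_LIMIT:
        logpmf = _conditional_split_logpmf(T, n_a, n_b, phi)
        obs = logpmf[A]
        # tolerance guards equal-probability ties against fp noise
        keep = logpmf <= obs + 1e-12
        p = float(np.exp(logpmf[keep]).sum())
        return min(1.0, p)
    return _normal_approx_p(T, A, n_a, n_b, phi)


def _normal_approx_p(T: int, A: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided normal approximation to the conditional split law.

    Mean and variance are those of the (negative) hypergeometric
    conditional distribution; continuity-corrected, both tails folded by
    distance from the mean to mirror the minimum-likelihood rule.
    """
    if phi == 0.0:
        p = n_a / (n_a + n_b)
        mean = T * p
        var = T * p * (1 - p)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        r = r_a + r_b
        mean = T * r_a / r
        var = T * (r_a / r) * (r_b / r) * (T + r) / (r + 1)
    if var <= 0:
        return 1.0
    z = (abs(A - mean) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * norm.sf(z)))


# ---------------------------------------------------------------------------
# common dispersion


def _group_conditional_loglik(pseudo: np.ndarray, groups: np.ndarray, phi: float) -> float:
    """Summed conditional log-likelihood of within-group splits given sums.

    For one gene in one group of n libraries with equal sizes, the
    probability of the observed counts y_1..y_n given their sum z is
    prod_i C(y_i + r - 1, y_i) / C(z + n*r - 1, z) with r = 1/phi.
    """
    r = 1.0 / phi
    total = 0.0
    for g in np.unique(groups):
        cols = groups == g
        n = int(cols.sum())
        if n < 2:
            continue
        y = pseudo[:, cols]
        z = y.sum(axis=1)
        ll = _log_nbinom_sum_pmf(y, r).sum(axis=1)
        ll -= _log_nbinom_sum_pmf(z, n * r)
        total += float(ll.sum())
    return total


def estimate_common_dispersion(
    cm_or_counts: CountMatrix | np.ndarray,
    group_labels: np.ndarray | list,
    lib_sizes: np.ndarray | None = None,
    lo: float = 1e-6,
    hi: float = 10.0,
    tol: float = 1e-4,
) -> DispersionFit:
    """Maximize the conditional log-likelihood over a common phi.

    Counts are first equalized to the geometric-mean library size.  The
    search is golden-section on log(phi) in [1e-6, 10] to a tolerance of
    1e-4 in log-phi.  At least one group must have two or more libraries.
    """
    if isinstance(cm_or_counts, CountMatrix):
        counts = cm_or_counts.counts.to_numpy()
        if lib_sizes is None:
            lib_sizes = cm_or_counts.lib_sizes().to_numpy()
    else:
        counts = np.asarray(cm_or_counts)
        if lib_sizes is None:
            lib_sizes = counts.sum(axis=0).astype(float)
    groups = np.asarray(group_labels)
    if groups.size != counts.shape[1]:
        raise ValueError("one group label per library is required")
    _, sizes = np.unique(groups, return_counts=True)
    if (sizes < 2).all():
        raise ValueError("cannot estimate dispersion without replication")
    pseudo = np.vstack(
        [equalize_lib_sizes(counts[i], lib_sizes) for i in range(counts.shape[0])]
    )
    # drop all-zero genes: they carry no dispersion information
    keep = pseudo.sum(axis=1) > 0
    pseudo = pseudo[keep]
    if pseudo.shape[0] == 0:
        raise ValueError("no expressed genes to estimate dispersion from")

    def nll(logphi: float) -> float:
        return -_group_conditional_loglik(pseudo, groups, float(np.exp(logphi)))

    a, b = np.log(lo), np.log(hi)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = nll(c), nll(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = nll(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = nll(d)
    logphi = (a + b) / 2.0
    phi = float(np.exp(logphi))
    return DispersionFit(
        common_dispersion=phi, n_genes_used=int(pseudo.shape[0]), loglik=-nll(logphi)
    )


# ---------------------------------------------------------------------------
# per-interval testing


def test_neighbor_intervals(
    cm: CountMatrix,
    acc_key: str,
    phi: DispersionFit | float | None = None,
    external_pvalues: pd.DataFrame | None = None,
    bh_scope: str = "per-interval",
) -> pd.DataFrame:
    """Test every gene at every neighboring time interval of one accession.

    Returns a tidy table with one row per gene x interval: p, BH q, and
    the library-size-normalized mean counts at the low and high time of
    the interval.  An externally computed gene x interval p-value table
    (columns = 1-based interval indices) can replace internal testing.
    """
    if acc_key not in cm.design.acc_keys:
        raise KeyError(f"unknown accession key {acc_key!r}")
    times = cm.design.times
    lib_sizes = cm.lib_sizes()
    cols_by_time = {}
    for t in times:
        libs = cm.libraries_for(acc_key, t)
        if len(libs) < 2:
            raise ValueError(
                f"accession {acc_key!r} needs >= 2 replicates at time {t}"
            )
        cols_by_time[t] = [l.library_id for l in libs]

    if external_pvalues is not None:
        missing = [g for g in cm.gene_ids if g not in external_pvalues.index]
        if missing:
            raise ValueError(f"p-value table incomplete: missing {missing[:10]}")
        if external_pvalues.shape[1] < cm.design.n_intervals:
            raise ValueError("p-value table incomplete: too few intervals")

    if phi is None and external_pvalues is None:
        labels = []
        cols = []
        for t in times:
            for c in cols_by_time[t]:
                cols.append(c)
                labels.append(t)
        fit = estimate_common_dispersion(
            cm.counts[cols].to_numpy(), labels, lib_sizes[cols].to_numpy()
        )
        phi_val = fit.common_dispersion
    elif isinstance(phi, DispersionFit):
        phi_val = phi.common_dispersion
    else:
        phi_val = float(phi) if phi is not None else 0.0

    # normalized per-time means (counts per library scaled to geometric mean)
    acc_cols = [c for t in times for c in cols_by_time[t]]
    geo = float(np.exp(np.mean(np.log(lib_sizes[acc_cols].to_numpy()))))
    norm_counts = cm.counts[acc_cols] * (geo / lib_sizes[acc_cols])
    time_means = {
        t: norm_counts[cols_by_time[t]].mean(axis=1) for t in times
    }

    rows = []
    for j in range(cm.design.n_intervals):
        t_lo, t_hi = times[j], times[j + 1]
        if external_pvalues is not None:
            pvals = external_pvalues.loc[cm.gene_ids].iloc[:, j].to_numpy(dtype=float)
        else:
            cols_lo, cols_hi = cols_by_time[t_lo], cols_by_time[t_hi]
            sizes_lo = lib_sizes[cols_lo].to_numpy()
            sizes_hi = lib_sizes[cols_hi].to_numpy()
            cnt_lo = cm.counts[cols_lo].to_numpy()
            cnt_hi = cm.counts[cols_hi].to_numpy()
            pvals = np.array(
                [
                    nb_exact_test(cnt_lo[i], cnt_hi[i], sizes_lo, sizes_hi, phi_val)
                    for i in range(cm.n_genes)
                ]
            )
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": cm.gene_ids,
                    "interval": j + 1,
                    "p_value": pvals,
                    "mean_low": time_means[t_lo].to_numpy(),
                    "mean_high": time_means[t_hi].to_numpy(),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    if bh_scope == "per-interval":
        table["q_value"] = table.groupby("interval")["p_value"].transform(
            lambda p: bh_adjust(p.to_numpy())
        )
    elif bh_scope == "global":
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    else:
        raise ValueError("bh_scope must be 'per-interval' or 'global'")
    return table[["gene_id", "interval", "p_value", "q_value", "mean_low", "mean_high"]]


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values, capped at 1,
    returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
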