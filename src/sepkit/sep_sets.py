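"""Query, summarize and compare sets of standardized expression profiles.

Two SEP sets S_A (size k) and S_B (size r) are compared through Euclidean
distances: D_B collects the k*r between-set pair distances and D_W the
k(k-1)/2 + r(r-1)/2 within-set distances pooled over both sets.  Sets
whose members share a common average profile give mean(D_B) close to
mean(D_W); a one-tailed two-sample t-test of mean(D_B) > mean(D_W)
quantifies divergence.  The joint peak-time matrix tabulates, over genes
expressed in two accessions, the times at which each gene's SEP peaks in
each — a times x times table of percentages whose off-diagonal cells hold
out-of-phase gene sets.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GeneAnnotation
from .sep_core import SEP

__all__ = [
    "SEPQuery",
    "SEPSet",
    "DistanceVectors",
    "SEPComparison",
    "PeakMatrix",
    "get_sep",
    "sep_set_summary",
    "distances_between_within",
    "analyze_2_seps",
    "peak_matrix",
]


@dataclass(frozen=True)
class SEPQuery:
    """Conjunctive filter over a SEP store.

    Every field is optional; supplied fields are ANDed.  ``descr`` is a
    case-sensitive substring match against the protein description;
    ``model`` accepts an exact model string or a pattern with ``.`` as a
    one-symbol wildcard; ``exist_in_all`` keeps only genes having a SEP in
    every accession present in the store.
    """

    ids: tuple[str, ...] | None = None
    descr: str | None = None
    acc_key: str | None = None
    acc_type: str | None = None
    model: str | None = None
    exist_in_all: bool = False
    time_max_exp: float | None = None
    is_tf: bool | None = None
    coded_expr_level: str | None = None


@dataclass
class SEPSet:
    """An ordered, labelled collection of SEPs on one time grid."""

    label: str
    members: list[SEP]

    def __post_init__(self) -> None:
        grids = {s.times for s in self.members}
        if len(grids) > 1:
            raise ValueError("SEPSet members mix different time grids")

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def times(self) -> tuple[float, ...]:
        if not self.members:
            raise ValueError("empty SEP set has no time grid")
        return self.members[0].times

    def value_matrix(self) -> np.ndarray:
        return np.vstack([s.values for s in self.members])


@dataclass(frozen=True)
class DistanceVectors:
    d_between: np.ndarray
    d_within: np.ndarray


@dataclass(frozen=True)
class SEPComparison:
    mean_d_between: float
    mean_d_within: float
    t_statistic: float
    df: float
    p_value: float
    test_variant: str
    wilcoxon_p: float | None = None


@dataclass
class PeakMatrix:
    """Joint peak-time tabulation for genes shared by two accessions."""

    acc_a: str
    acc_b: str
    times: tuple[float, ...]
    counts: pd.DataFrame  # index = time in A, columns = time in B
    gene_sets: dict[tuple[float, float], list[str]]
    total_genes: int

    @property
    def percentages(self) -> pd.DataFrame:
        """Exact cell percentages of the joint total (sum to 100)."""
        return 100.0 * self.counts / self.total_genes

    @staticmethod
    def percent_of(counts, total: int):
        """Cell percentage(s) of the joint total, rounded to 2 decimals."""
        if total <= 0:
            raise ValueError("total must be positive")
        return np.round(100.0 * counts / total, 2)

    def cell_label(self, t_a: float, t_b: float) -> str:
        """Gene-set name for a cell, e.g. ASm0_SRm60."""
        return f"{self.acc_a}m{t_a:g}_{self.acc_b}m{t_b:g}"


# ---------------------------------------------------------------------------
# querying


def _model_matches(pattern: str, model: str) -> bool:
    if len(pattern) != len(model):
        return False
    if "." not in pattern:
        return pattern == model
    return re.fullmatch(pattern.replace(".", "[SID]"), model) is not None


def get_sep(
    store: list[SEP],
    query: SEPQuery,
    annot: GeneAnnotation | None = None,
    label: str = "query",
    include_degenerate: bool = False,
) -> SEPSet:
    """Select the SEPs matching every supplied query field.

    Description, TF and expression-level filters need the annotation
    table.  Degenerate (constant) profiles are excluded unless asked for.
    An empty result is allowed but warned about.
    """
    if not store:
        raise ValueError("empty SEP store")
    members = [s for s in store if include_degenerate or not s.degenerate]
    if query.ids is not None:
        wanted = set(query.ids)
        members = [s for s in members if s.gene_id in wanted]
    if query.acc_key is not None:
        members = [s for s in members if s.acc_key == query.acc_key]
    if query.acc_type is not None:
        members = [s for s in members if s.acc_type == query.acc_type]
    if query.model is not None:
        members = [s for s in members if _model_matches(query.model, s.model)]
    if query.time_max_exp is not None:
        members = [s for s in members if s.time_max_exp == float(query.time_max_exp)]
    if query.exist_in_all:
        all_keys = {s.acc_key for s in store}
        by_gene: dict[str, set[str]] = {}
        for s in store:
            if include_degenerate or not s.degenerate:
                by_gene.setdefault(s.gene_id, set()).add(s.acc_key)
        members = [s for s in members if by_gene.get(s.gene_id) == all_keys]
    needs_annot = (
        query.descr is not None
        or query.is_tf is not None
        or query.coded_expr_level is not None
    )
    if needs_annot:
        if annot is None:
            raise ValueError("query uses annotation fields but no annotation given")
        tab = annot.table
        if query.descr is not None:
            ok = set(tab.index[tab["descr"].str.contains(query.descr, regex=False)])
            members = [s for s in members if s.gene_id in ok]
        if query.is_tf is not None:
            ok = set(tab.index[tab["is_tf"] == query.is_tf])
            members = [s for s in members if s.gene_id in ok]
        if query.coded_expr_level is not None:
            if "coded_expr_level" not in tab.columns:
                raise ValueError("annotation lacks a coded_expr_level column")
            ok = set(tab.index[tab["coded_expr_level"] == query.coded_expr_level])
            members = [s for s in members if s.gene_id in ok]
    if not members:
        warnings.warn("query matched no SEPs", stacklevel=2)
    return SEPSet(label=label, members=members)


# ---------------------------------------------------------------------------
# summaries


def sep_set_summary(s: SEPSet, alpha: float = 0.05) -> pd.DataFrame:
    """Per-time mean and Student-t confidence interval of a SEP set.

    CI = mean +/- t_{1-alpha/2, k-1} * sd / sqrt(k).  Also attaches the
    set's model and peak-time tabulations as frame attrs.
    """
    if s.k < 2:
        raise ValueError("need at least 2 SEPs to summarize")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    vals = s.value_matrix()
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    half = stats.t.ppf(1 - alpha / 2, df=s.k - 1) * sd / np.sqrt(s.k)
    out = pd.DataFrame(
        {"time": s.times, "mean": mean, "ci_low": mean - half, "ci_high": mean + half}
    )
    out.attrs["models"] = pd.Series([m.model for m in s.members]).value_counts()
    out.attrs["peaks"] = pd.Series([m.time_max_exp for m in s.members]).value_counts().sort_index()
    out.attrs["k"] = s.k
    return out


# ---------------------------------------------------------------------------
# between/within distance comparison


def distances_between_within(a: SEPSet, b: SEPSet) -> DistanceVectors:
    """Euclidean distances between and within two SEP sets.

    d_between has k*r entries (all cross pairs); d_within pools the
    k(k-1)/2 within-A with the r(r-1)/2 within-B unordered pairs.
    """
    if a.k < 2 or b.k < 2:
        raise ValueError("both sets need at least 2 members")
    if a.times != b.times:
        raise ValueError("sets are on different time grids")
    va, vb = a.value_matrix(), b.value_matrix()
    diff = va[:, None, :] - vb[None, :, :]
    d_b = np.sqrt((diff**2).sum(axis=2)).ravel()
    d_w = np.concatenate([_pairwise(va), _pairwise(vb)])
    return DistanceVectors(d_between=d_b, d_within=d_w)


def _pairwise(v: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(v.shape[0], k=1)
    diff = v[iu[0]] - v[iu[1]]
    return np.sqrt((diff**2).sum(axis=1))


def analyze_2_seps(
    a: SEPSet,
    b: SEPSet,
    variant: str = "welch",
    with_wilcoxon: bool = False,
) -> SEPComparison:
    """One-tailed t-test that two SEP sets differ on average.

    Tests H0: mean(D_B) = mean(D_W) against mean(D_B) > mean(D_W) — a set
    pair whose members are interchangeable shows no excess between-set
    distance.  Both sets must have more than two members.  Welch degrees
    of freedom by default; a pooled-variance variant and a one-tailed
    Wilcoxon rank-sum corroboration are available.  Symmetric in a and b.
    """
    if a.k <= 2 or b.k <= 2:
        raise ValueError("both SEP sets must be larger than two members")
    if variant not in {"welch", "pooled"}:
        raise ValueError("variant must be 'welch' or 'pooled'")
    d = distances_between_within(a, b)
    # sorted copies make the statistic bitwise identical under set swap
    d_b, d_w = np.sort(d.d_between), np.sort(d.d_within)
    res = stats.ttest_ind(
        d_b, d_w, equal_var=(variant == "pooled"), alternative="greater"
    )
    wilcox = None
    if with_wilcoxon:
        wilcox = float(stats.mannwhitneyu(d_b, d_w, alternative="greater").pvalue)
    return SEPComparison(
        mean_d_between=float(d.d_between.mean()),
        mean_d_within=float(d.d_within.mean()),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        test_variant=variant,
        wilcoxon_p=wilcox,
    )


# ---------------------------------------------------------------------------
# joint peak-time matrix


def peak_matrix(store: list[SEP], acc_a: str, acc_b: str) -> PeakMatrix:
    """Tabulate joint SEP peak times for genes shared by two accessions.

    Only genes with a non-degenerate SEP in both accessions count; each
    cell holds the genes peaking at (t in acc_a, t' in acc_b) with the
    percentage of the joint total.  For n times the matrix has n^2 cells
    and the percentages sum to 100.
    """
    by_acc: dict[str, dict[str, SEP]] = {acc_a: {}, acc_b: {}}
    times = None
    for s in store:
        if s.acc_key in by_acc and not s.degenerate:
            by_acc[s.acc_key][s.gene_id] = s
            times = s.times
    shared = sorted(set(by_acc[acc_a]) & set(by_acc[acc_b]))
    if not shared:
        raise ValueError(f"no genes shared between {acc_a!r} and {acc_b!r}")
    counts = pd.DataFrame(0, index=list(times), columns=list(times))
    gene_sets: dict[tuple[float, float], list[str]] = {
        (ta, tb): [] for ta in times for tb in times
    }
    for g in shared:
        ta = by_acc[acc_a][g].time_max_exp
        tb = by_acc[acc_b][g].time_max_exp
        counts.loc[ta, tb] += 1
        gene_sets[(ta, tb)].append(g)
    return PeakMatrix(
        acc_a=acc_a,
        acc_b=acc_b,
        times=times,
        counts=counts,
        gene_sets=gene_sets,
        total_genes=len(shared),
    )
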