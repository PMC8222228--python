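"""GO term enrichment of a target gene set against a background.

Each term is a 2x2 table — (in/out of target) x (annotated/not annotated)
— tested one-sided with Fisher's exact test in the enrichment direction.
Reported per term: observed count O, expected count under independence
E = n_target * K / N, and the sample (cross-product) odds ratio with a
Haldane 0.5 continuity correction when a cell is empty.  BH correction is
applied within each GO aspect (BP, CC, MF) separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GOMap
from .interval_tests import bh_adjust

__all__ = ["EnrichmentRow", "analyze_go_term", "analyze_all_go"]


@dataclass(frozen=True)
class EnrichmentRow:
    aspect: str
    go_id: str
    description: str
    observed: int
    expected: float
    odds: float
    p_value: float
    q_value: float | None = None


def _two_by_two(target: set, background: set, term_genes: set) -> tuple[int, int, int, int]:
    term_in_bg = term_genes & background
    a = len(target & term_in_bg)                    # target, annotated
    b = len(target) - a                             # target, not annotated
    c = len(term_in_bg) - a                         # non-target, annotated
    d = len(background) - len(target) - c           # non-target, not annotated
    return a, b, c, d


def _sample_odds(a: int, b: int, c: int, d: int) -> float:
    # a zero margin (e.g. a term annotating every gene) carries no
    # association information: the odds ratio is 1 by convention
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def analyze_go_term(
    target: set[str],
    background: set[str],
    gomap: GOMap,
    term: str,
) -> EnrichmentRow:
    """Enrichment of one GO term in the target set.

    One-sided Fisher exact p (alternative: over-representation in the
    target).  The target must be a subset of the background.
    """
    target, background = set(target), set(background)
    if not target <= background:
        raise ValueError("target gene set is not a subset of the background")
    rows = gomap.table[gomap.table["go_id"] == term]
    if rows.empty:
        raise KeyError(f"term {term!r} not in GO map")
    a, b, c, d = _two_by_two(target, background, set(rows["gene_id"]))
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
    K = a + c
    expected = len(target) * K / len(background)
    return EnrichmentRow(
        aspect=str(rows["aspect"].iloc[0]),
        go_id=term,
        description=str(rows["descr"].iloc[0]),
        observed=a,
        expected=expected,
        odds=_sample_odds(a, b, c, d),
        p_value=p,
    )


def analyze_all_go(
    target: set[str],
    background: set[str],
    gomap: GOMap,
    fdr: float = 0.10,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Test every sufficiently annotated term; keep rows with q <= fdr.

    BH adjustment runs within each aspect separately (the three
    ontologies are analyzed as separate families).  Sorted by q then
    term id.
    """
    if gomap.table.empty:
        raise ValueError("empty GO map")
    target, background = set(target), set(background)
    if not target <= background:
        raise ValueError("target gene set is not a subset of the background")
    tab = gomap.table[gomap.table["gene_id"].isin(background)]
    term_sizes = tab.groupby("go_id")["gene_id"].nunique()
    testable = term_sizes[term_sizes >= min_term_size].index
    rows = []
    for go_id, sub in tab[tab["go_id"].isin(testable)].groupby("go_id"):
        a, b, c, d = _two_by_two(target, background, set(sub["gene_id"]))
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
        K = a + c
        rows.append(
            {
                "aspect": sub["aspect"].iloc[0],
                "go_id": go_id,
                "description": sub["descr"].iloc[0],
                "odds": _sample_odds(a, b, c, d),
                "O": a,
                "E": len(target) * K / len(background),
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q_value=pd.Series(dtype=float))
    df["q_value"] = np.nan
    for aspect, idx in df.groupby("aspect").groups.items():
        df.loc[idx, "q_value"] = bh_adjust(df.loc[idx, "p_value"].to_numpy())
    df = df[df["q_value"] <= fdr]
    return df.sort_values(["q_value", "go_id"]).reset_index(drop=True)
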