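"""Ternary models and standardized expression profiles (SEPs).

A gene's time-course in one accession is summarized twice over:

* a *ternary model*: a string of length n-1 over {S, I, D}, one symbol per
  neighboring time interval — Steady when the interval's null hypothesis of
  equal means is not rejected, Increasing/Decreasing by the direction of
  the estimated FPKM means when it is;
* a *SEP*: the mean FPKM profile standardized to mean 0 and SD 1, making
  profiles scale-free and directly comparable across genes and accessions.

With n time points the model space has 3^(n-1) elements (729 for n = 7).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountMatrix, GeneAnnotation

TERNARY_ALPHABET = ("S", "I", "D")

__all__ = [
    "TERNARY_ALPHABET",
    "SEP",
    "fpkm_mean_profile",
    "call_ternary_model",
    "estimate_sep",
    "model_frequencies",
    "ternary_model_space",
    "build_seps",
    "seps_to_frame",
    "write_sep_table",
    "read_sep_table",
]


def ternary_model_space(n_times: int):
    """Yield every possible ternary model for a design with n_times points."""
    if n_times < 2:
        raise ValueError("need at least 2 time points")
    for combo in itertools.product(TERNARY_ALPHABET, repeat=n_times - 1):
        yield "".join(combo)


def _validate_model(model: str, n_times: int) -> str:
    if len(model) != n_times - 1:
        raise ValueError(
            f"model length {len(model)} != n_times - 1 = {n_times - 1}"
        )
    bad = set(model) - set(TERNARY_ALPHABET)
    if bad:
        raise ValueError(f"invalid model symbols: {sorted(bad)}")
    return model


@dataclass
class SEP:
    """One gene's standardized expression profile in one accession.

    ``values`` sums to 0 with (sample) SD 1 unless the profile is
    degenerate (constant after smoothing), in which case it is all zeros
    and flagged.  ``time_max_exp`` is the design time of the maximum
    standardized value, earliest time on ties.
    """

    gene_id: str
    acc_key: str
    acc_type: str
    model: str
    times: tuple[float, ...]
    values: np.ndarray
    time_max_exp: float = field(init=False)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.times):
            raise ValueError("values length != number of times")
        _validate_model(self.model, len(self.times))
        self.time_max_exp = float(self.times[int(np.argmax(self.values))])


def fpkm_mean_profile(
    cm: CountMatrix, annot: GeneAnnotation, acc_key: str
) -> pd.DataFrame:
    """Mean FPKM per gene per time for one accession.

    FPKM = count * 1e9 / (gene length in bp * mapped reads of the
    library); the per-time value is the arithmetic mean over replicates.
    Returns a genes x times DataFrame (columns = design times).
    """
    libs = cm.libraries_for(acc_key)
    lengths = annot.lengths_for(cm.gene_ids).to_numpy()
    lib_sizes = cm.lib_sizes()
    out = {}
    for t in cm.design.times:
        cols = [l.library_id for l in cm.libraries_for(acc_key, t)]
        fpkm = (
            cm.counts[cols].to_numpy()
            * 1e9
            / (lengths[:, None] * lib_sizes[cols].to_numpy()[None, :])
        )
        out[t] = fpkm.mean(axis=1)
    return pd.DataFrame(out, index=cm.gene_ids)


def call_ternary_model(
    gene_tests: pd.DataFrame, fdr_threshold: float = 0.01
) -> str:
    """Classify each interval of one gene as S, I or D.

    ``gene_tests`` holds that gene's rows of the interval-test table
    (columns interval, q_value, mean_low, mean_high).  An interval whose
    q-value is at or above the threshold is Steady; otherwise the call
    follows the direction of the estimated means (ties fall back to S).
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must lie in (0, 1)")
    t = gene_tests.sort_values("interval")
    intervals = t["interval"].to_numpy()
    expected = np.arange(1, intervals.size + 1)
    if intervals.size == 0 or not np.array_equal(intervals, expected):
        raise ValueError(f"missing or duplicated intervals: have {list(intervals)}")
    symbols = []
    for _, row in t.iterrows():
        if row["q_value"] >= fdr_threshold:
            symbols.append("S")
        elif row["mean_low"] < row["mean_high"]:
            symbols.append("I")
        elif row["mean_low"] > row["mean_high"]:
            symbols.append("D")
        else:
            symbols.append("S")
    return "".join(symbols)


def _smooth_by_model(mu: np.ndarray, model: str) -> np.ndarray:
    """Average the profile over maximal runs of times joined by S intervals."""
    out = np.empty_like(mu, dtype=float)
    start = 0
    for j, sym in enumerate(model + "#"):  # sentinel closes the last run
        if sym != "S":
            out[start : j + 1] = mu[start : j + 1].mean()
            start = j + 1
    return out


def estimate_sep(
    gene_id: str,
    acc_key: str,
    acc_type: str,
    times: tuple[float, ...],
    mu_hat: np.ndarray,
    model: str,
    mode: str = "smoothed",
    ddof: int = 1,
) -> SEP:
    """Standardize a mean FPKM profile into a SEP using its ternary model.

    mode="smoothed" (default) first replaces each maximal run of times
    connected by S symbols with the run mean, so the model shapes the
    profile; mode="raw" z-scores the means directly.  Either way the
    result has mean 0 and SD 1 (sample SD by default), is invariant to
    positive affine transforms of the input, and collapses to a flagged
    all-zero profile when constant.
    """
    mu = np.asarray(mu_hat, dtype=float)
    if mu.size != len(times):
        raise ValueError("profile length != number of times")
    _validate_model(model, len(times))
    if mode == "smoothed":
        x = _smooth_by_model(mu, model)
    elif mode == "raw":
        x = mu.astype(float)
    else:
        raise ValueError("mode must be 'smoothed' or 'raw'")
    sd = float(np.std(x, ddof=ddof))
    if sd < 1e-12 * max(1.0, float(np.abs(x).max())) or sd == 0.0:
        return SEP(gene_id, acc_key, acc_type, model, tuple(times), np.zeros(mu.size), degenerate=True)
    values = (x - x.mean()) / sd
    return SEP(gene_id, acc_key, acc_type, model, tuple(times), values)


def build_seps(
    cm: CountMatrix,
    annot: GeneAnnotation,
    tests: pd.DataFrame,
    acc_key: str,
    fdr_threshold: float = 0.01,
    mode: str = "smoothed",
    ddof: int = 1,
) -> list[SEP]:
    """Full per-accession pipeline: FPKM means -> models -> SEPs."""
    profiles = fpkm_mean_profile(cm, annot, acc_key)
    acc_type = cm.design.acc_type(acc_key)
    times = cm.design.times
    seps = []
    grouped = dict(tuple(tests.groupby("gene_id")))
    for gene in cm.gene_ids:
        if gene not in grouped:
            raise ValueError(f"no interval tests for gene {gene!r}")
        model = call_ternary_model(grouped[gene], fdr_threshold)
        seps.append(
            estimate_sep(
                gene, acc_key, acc_type, times,
                profiles.loc[gene].to_numpy(), model, mode=mode, ddof=ddof,
            )
        )
    return seps


def model_frequencies(seps: list[SEP]) -> pd.DataFrame:
    """Tabulate ternary-model usage over a SEP collection.

    Sorted by descending count then model string; fractions sum to one.
    """
    if not seps:
        raise ValueError("empty SEP collection")
    counts = pd.Series([s.model for s in seps]).value_counts()
    df = counts.rename_axis("model").reset_index(name="count")
    df = df.sort_values(["count", "model"], ascending=[False, True]).reset_index(drop=True)
    df["fraction"] = df["count"] / df["count"].sum()
    return df


# ---------------------------------------------------------------------------
# serialization


def seps_to_frame(seps: list[SEP]) -> pd.DataFrame:
    if not seps:
        raise ValueError("empty SEP collection")
    times = seps[0].times
    rows = []
    for s in seps:
        if s.times != times:
            raise ValueError("SEPs mix different time grids")
        row = {"gene_id": s.gene_id, "acc_key": s.acc_key, "acc_type": s.acc_type, "model": s.model}
        for t, v in zip(times, s.values):
            row[f"s_{t:g}"] = v
        row["time_max_exp"] = s.time_max_exp
        row["degenerate"] = s.degenerate
        rows.append(row)
    return pd.DataFrame(rows)


def write_sep_table(seps: list[SEP], path) -> None:
    seps_to_frame(seps).to_csv(path, sep="\t", index=False)


def read_sep_table(path) -> list[SEP]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    value_cols = [c for c in df.columns if c.startswith("s_")]
    times = tuple(float(c[2:]) for c in value_cols)
    seps = []
    for _, row in df.iterrows():
        s = SEP(
            gene_id=str(row["gene_id"]),
            acc_key=row["acc_key"],
            acc_type=row["acc_type"],
            model=row["model"],
            times=times,
            values=row[value_cols].to_numpy(dtype=float),
            degenerate=bool(row["degenerate"]),
        )
        seps.append(s)
    return seps
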