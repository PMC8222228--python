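"""Negative-binomial time-course simulator with known ternary models.

Emulates a replicated RNA-seq fruit-development experiment: for each gene
a true mean path is built by walking its ternary model from a base mean
(I multiplies by the fold change, D divides, S keeps), and counts are
drawn NB(mean = path * library size factor, variance = mu + phi*mu^2);
phi = 0 draws Poisson.  Defaults mirror the study design: 7 times (0-60
in steps of 10 days after anthesis), 2 replicates per time, domesticated
and wild accessions.  Everything is reproducible from a single root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountMatrix, Design, GeneAnnotation, LibraryInfo
from .interval_tests import test_neighbor_intervals
from .sep_core import TERNARY_ALPHABET, call_ternary_model

__all__ = [
    "SimulationSpec",
    "default_design",
    "simulate_time_course",
    "true_mean_path",
    "sample_sep_set",
    "ternary_recovery_rate",
]


def default_design(n_accessions: int = 2) -> Design:
    """7 times 0..60 step 10, 2 replicates, alternating D/W accession types."""
    if n_accessions < 1:
        raise ValueError("need at least one accession")
    accs = []
    for i in range(n_accessions):
        typ = "D" if i % 2 == 0 else "W"
        accs.append((f"A{i}", typ, f"synthetic accession {i}"))
    return Design(times=tuple(range(0, 70, 10)), accessions=tuple(accs), replicates_per_point=2)


@dataclass
class SimulationSpec:
    """Ground truth for a simulated NB time course.

    ``true_models`` is a list of ternary model strings (one per gene) or
    the string ``"random"`` to draw them uniformly from the model space.
    ``fold_change`` is the multiplicative step per I (x f) or D (/ f)
    interval; ``phi`` the NB dispersion (0 = Poisson).
    """

    n_genes: int = 200
    design: Design = field(default_factory=default_design)
    true_models: list[str] | str = "random"
    base_mean: float = 500.0
    fold_change: float = 8.0
    phi: float = 0.05
    lib_size_factors: np.ndarray | None = None
    gene_length_bp: int = 1000
    nominal_depth: float = 1e7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_mean <= 0:
            raise ValueError("base_mean must be positive")
        if self.fold_change <= 1 and self.true_models == "random":
            raise ValueError("fold_change must exceed 1")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")


def true_mean_path(model: str, base_mean: float, fold_change: float) -> np.ndarray:
    """Walk a ternary model from the base mean: I multiplies, D divides."""
    mu = [float(base_mean)]
    for sym in model:
        if sym == "I":
            mu.append(mu[-1] * fold_change)
        elif sym == "D":
            mu.append(mu[-1] / fold_change)
        elif sym == "S":
            mu.append(mu[-1])
        else:
            raise ValueError(f"invalid model symbol {sym!r}")
    return np.array(mu)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0.0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_time_course(
    spec: SimulationSpec,
) -> tuple[CountMatrix, GeneAnnotation, pd.DataFrame]:
    """Simulate counts, annotation and the gene-level truth table.

    Returns a CountMatrix over all accessions in the design (each
    accession shares the gene's true model and mean path), a minimal
    GeneAnnotation, and a truth table (gene_id, true_model, base_mean).
    Identical seeds give identical matrices.
    """
    rng = np.random.default_rng(spec.seed)
    design = spec.design
    n_int = design.n_intervals
    if spec.true_models == "random":
        models = [
            "".join(rng.choice(TERNARY_ALPHABET, size=n_int)) for _ in range(spec.n_genes)
        ]
    else:
        models = list(spec.true_models)
        if len(models) != spec.n_genes:
            raise ValueError("one true model per gene is required")
        for m in models:
            if len(m) != n_int or set(m) - set(TERNARY_ALPHABET):
                raise ValueError(f"invalid model {m!r}")
    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    paths = np.vstack(
        [true_mean_path(m, spec.base_mean, spec.fold_change) for m in models]
    )

    lib_keys = [
        (acc_key, t, rep)
        for acc_key, _typ, _name in design.accessions
        for t in design.times
        for rep in range(1, design.replicates_per_point + 1)
    ]
    n_libs = len(lib_keys)
    if spec.lib_size_factors is None:
        factors = np.ones(n_libs)
    else:
        factors = np.asarray(spec.lib_size_factors, dtype=float)
        if factors.size != n_libs or (factors <= 0).any():
            raise ValueError("lib_size_factors must be positive, one per library")
    # record the true sequencing depth so normalization sees the simulated
    # factors, not the expression-driven column sums
    libraries = [
        LibraryInfo(
            library_id=f"{acc}_t{t:g}_r{rep}",
            acc_key=acc,
            time=t,
            replicate=rep,
            mapped_reads=float(np.round(spec.nominal_depth * factors[i])),
        )
        for i, (acc, t, rep) in enumerate(lib_keys)
    ]

    time_index = {t: j for j, t in enumerate(design.times)}
    counts = np.empty((spec.n_genes, n_libs), dtype=np.int64)
    for li, lib in enumerate(libraries):
        mu = paths[:, time_index[lib.time]] * factors[li]
        counts[:, li] = _draw_counts(rng, mu, spec.phi)
    cm = CountMatrix(
        design=design,
        libraries=libraries,
        counts=pd.DataFrame(counts, index=gene_ids, columns=[l.library_id for l in libraries]),
    )
    annot = GeneAnnotation(
        pd.DataFrame(
            {
                "descr": [f"synthetic gene {g}" for g in gene_ids],
                "length_bp": spec.gene_length_bp,
                "is_tf": False,
            },
            index=pd.Index(gene_ids, name="id"),
        )
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "true_model": models, "base_mean": spec.base_mean}
    )
    return cm, annot, truth


def sample_sep_set(
    model: str,
    k: int,
    label: str = "set",
    base_mean: float = 100.0,
    fold_change: float = 4.0,
    noise_sd: float = 0.5,
    times: tuple[float, ...] | None = None,
    rng: np.random.Generator | int | None = None,
    acc_key: str = "A0",
    acc_type: str = "D",
):
    """Draw a SEP set around one ternary profile family.

    The family's mean path walks ``model`` from ``base_mean``; each member
    multiplies the path by log-normal noise (sigma = ``noise_sd`` on the
    log scale) before standardizing to mean 0, SD 1.  Two sets drawn from
    the same family are exchangeable — the null configuration of the
    between/within distance test; sets from different models probe power.
    """
    from .sep_core import SEP
    from .sep_sets import SEPSet

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if times is None:
        times = tuple(range(0, 10 * (len(model) + 1), 10))
    base = true_mean_path(model, base_mean, fold_change)
    members = []
    for i in range(k):
        x = base * np.exp(rng.normal(0.0, noise_sd, size=base.size))
        v = (x - x.mean()) / x.std(ddof=1)
        members.append(SEP(f"{label}_g{i}", acc_key, acc_type, model, times, v))
    return SEPSet(label=label, members=members)


def ternary_recovery_rate(
    spec: SimulationSpec,
    fdr_threshold: float = 0.01,
    acc_key: str | None = None,
    phi: float | None = None,
) -> dict:
    """Simulate, run the interval tests and score model recovery.

    Runs the full calling pipeline (common-dispersion estimate unless a
    known phi is passed, exact interval tests, BH, ternary calls) on one
    accession and reports the fraction of per-interval symbols and of
    whole models matching the simulation truth.
    """
    if spec.n_genes < 100:
        raise ValueError("recovery experiments need at least 100 genes")
    cm, _annot, truth = simulate_time_course(spec)
    acc = acc_key or spec.design.acc_keys[0]
    tests = test_neighbor_intervals(cm, acc, phi=phi)
    truth_models = dict(zip(truth["gene_id"], truth["true_model"]))
    n_sym = 0
    n_sym_ok = 0
    n_model_ok = 0
    for gene, sub in tests.groupby("gene_id"):
        called = call_ternary_model(sub, fdr_threshold)
        true = truth_models[gene]
        n_sym += len(true)
        n_sym_ok += sum(c == t for c, t in zip(called, true))
        n_model_ok += called == true
    return {
        "per_interval_accuracy": n_sym_ok / n_sym,
        "per_model_accuracy": n_model_ok / spec.n_genes,
        "n_genes": spec.n_genes,
    }
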