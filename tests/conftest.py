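import numpy as np
import pandas as pd
import pytest

from sepkit.data_model import CountMatrix, Design, GeneAnnotation, LibraryInfo
from sepkit.sep_core import SEP

TIMES7 = tuple(range(0, 70, 10))


@pytest.fixture
def two_acc_design():
    return Design(
        times=(0.0, 10.0),
        accessions=(("AA", "D", "acc A"), ("BB", "W", "acc B")),
        replicates_per_point=2,
    )


def make_count_matrix(design, counts_by_gene, mapped_reads=1e6):
    """Build a CountMatrix from {gene: [counts in canonical library order]}."""
    libs = []
    for acc, _t, _n in design.accessions:
        for t in design.times:
            for rep in (1, 2):
                libs.append(
                    LibraryInfo(f"{acc}_t{t:g}_r{rep}", acc, t, rep, mapped_reads)
                )
    df = pd.DataFrame(
        counts_by_gene, index=[l.library_id for l in libs]
    ).T.astype(np.int64)
    return CountMatrix(design=design, libraries=libs, counts=df)


@pytest.fixture
def toy_cm(two_acc_design):
    # 5 genes x (2 accessions x 2 times x 2 reps) = 8 libraries;
    # g4 is silent in accession BB only, g5 silent everywhere
    counts = {
        "g1": [10, 12, 20, 18, 9, 11, 21, 19],
        "g2": [5, 7, 5, 6, 4, 6, 5, 5],
        "g3": [100, 90, 50, 60, 95, 105, 55, 45],
        "g4": [8, 9, 10, 11, 0, 0, 0, 0],
        "g5": [0, 0, 0, 0, 0, 0, 0, 0],
    }
    return make_count_matrix(two_acc_design, counts)


@pytest.fixture
def annot5():
    ids = ["g1", "g2", "g3", "g4", "g5"]
    return GeneAnnotation(
        pd.DataFrame(
            {
                "descr": [
                    "protein kinase 1",
                    "MYB transcription factor",
                    "receptor kinase",
                    "unknown protein",
                    "MYB-like protein",
                ],
                "length_bp": [2000, 1500, 3000, 1000, 1200],
                "is_tf": [False, True, False, False, True],
            },
            index=pd.Index(ids, name="id"),
        )
    )


def make_sep(gene, acc, acc_type, model, values, times=TIMES7):
    values = np.asarray(values, dtype=float)
    return SEP(gene, acc, acc_type, model, times, values)


def standardized(x):
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std(ddof=1)


@pytest.fixture
def sep_store():
    """Six genes x two accessions with varied models and peak times."""
    store = []
    profiles = {
        "g1": ("ISSSSS", [1, 5, 5, 5, 5, 5, 5]),
        "g2": ("DSSSSS", [9, 2, 2, 2, 2, 2, 2]),
        "g3": ("SSSIII", [1, 1, 1, 1, 2, 4, 8]),
        "g4": ("IDIDID", [1, 4, 1, 4, 1, 4, 1]),
        "g5": ("SSSSSI", [3, 3, 3, 3, 3, 3, 9]),
        "g6": ("ISSDSS", [1, 6, 6, 6, 2, 2, 2]),
    }
    for acc, typ in (("AA", "D"), ("BB", "W")):
        for gene, (model, prof) in profiles.items():
            store.append(make_sep(gene, acc, typ, model, standardized(prof)))
    return store
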