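"""Packaged benchmark fixtures for regression tests of the comparison harness.

Two small versioned TSVs ship with the package: per-dataset sample/truth
counts for the eleven public benchmark datasets, and the published AUCs of
three rankers on those datasets under two preprocessing pipelines.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_benchmark_counts", "load_benchmark_aucs", "auc_matrix"]

METHODS = ("t_test", "shrink_t", "dfc")
PREPROCESSINGS = ("mas5", "rma")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("dfctest.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_benchmark_counts() -> pd.DataFrame:
    """Per-dataset class sizes and confirmed-DEG counts (11 rows)."""
    return _read("benchmark_counts.tsv")


def load_benchmark_aucs() -> pd.DataFrame:
    """Tidy AUC table: dataset, n_samples, preprocessing, method, auc (66 rows)."""
    return _read("benchmark_aucs.tsv")


def auc_matrix(preprocessing: str) -> pd.DataFrame:
    """AUCs for one preprocessing as a datasets x methods matrix."""
    tidy = load_benchmark_aucs()
    sub = tidy[tidy["preprocessing"] == preprocessing]
    if sub.empty:
        raise KeyError(f"unknown preprocessing {preprocessing!r}")
    wide = sub.pivot(index="dataset", columns="method", values="auc")
    order = [d for d in tidy["dataset"].unique() if d in wide.index]
    return wide.loc[order, list(METHODS)]
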