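"""Shared builders for signatures and matrices used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from sigoverlap import ExpressionMatrix, GeneSignature


def make_signature(
    genes,
    directions=None,
    p_values=None,
    background_n=None,
    background_genes=None,
    name="sig",
):
    """Signature with given directions ('up'/'down'); stats default to a rank ramp."""
    genes = list(genes)
    n = len(genes)
    if directions is None:
        directions = ["up"] * n
    if p_values is None:
        p_values = [0.001 * (i + 1) / max(n, 1) for i in range(n)]
    linear = [2.0 if d == "up" else 0.5 for d in directions]
    return GeneSignature.from_stats(
        genes,
        linear,
        p_values,
        background_n=background_n if background_n is not None else max(10 * n, 100),
        background_genes=background_genes,
        name=name,
    )


def make_matrix(values, gene_ids=None, n_group1=None):
    """ExpressionMatrix from a 2-D array; first n_group1 columns are group1."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if n_group1 is None:
        n_group1 = n_samples // 2
    samples = [f"s{i}" for i in range(n_samples)]
    labels = {s: ("group1" if i < n_group1 else "group2") for i, s in enumerate(samples)}
    return ExpressionMatrix(
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(samples),
        values=values,
        group_labels=labels,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
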