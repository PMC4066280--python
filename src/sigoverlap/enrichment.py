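"""Gene-set over-representation with Benjamini-Hochberg adjustment.

For each set in a collection, a one-sided Fisher exact test asks whether the
bioset is enriched for the set's members relative to the measured background
(the genes actually assayed, not the genome).  Raw P-values are adjusted
across the whole collection by the Benjamini-Hochberg step-up procedure,
implemented here as the literal definition: sort ascending, multiply by
n/rank, enforce monotonicity from the largest P downwards, cap at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneSetCollection, GeneSignature, warn


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """BH step-up adjusted P-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set enrichment table plus the background it was computed against."""

    table: pd.DataFrame  # set_name, set_size, overlap, p_value, p_adjusted
    background_n: int
    bioset_n: int

    def __len__(self) -> int:
        return len(self.table)

    def significant(self, q: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adjusted"] < q]


def enrich(
    bioset: GeneSignature,
    collection: GeneSetCollection,
    background: int | Iterable[str],
) -> EnrichmentResult:
    """One-sided Fisher enrichment of ``bioset`` against every set.

    ``background`` is either the measured background size (sets are then
    assumed to lie within it) or the background gene membership, in which
    case each set is first restricted to the background and sets with no
    background members are skipped with a warning.
    """
    if len(collection) == 0:
        raise ValueError("gene-set collection is empty")
    if isinstance(background, int):
        background_n = background
        bg_genes: frozenset[str] | None = None
    else:
        bg_genes = frozenset(background)
        background_n = len(bg_genes)
    bio = bioset.gene_set if bg_genes is None else bioset.gene_set & bg_genes
    n_bio = len(bio)
    if background_n < n_bio:
        raise ValueError(
            f"background_n={background_n} smaller than bioset size {n_bio}"
        )

    rows = []
    for name, members in sorted(collection.sets.items()):
        if bg_genes is not None:
            members = members & bg_genes
            if not members:
                warn(f"set {name!r} has no background members; skipped")
                continue
        k = len(members & bio)
        in_set = len(members)
        table = [
            [k, n_bio - k],
            [in_set - k, background_n - n_bio - (in_set - k)],
        ]
        if min(min(r) for r in table) < 0:
            raise ValueError(
                f"set {name!r} (size {in_set}) inconsistent with background_n={background_n}"
            )
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append({"set_name": name, "set_size": in_set, "overlap": k, "p_value": float(p)})

    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_value"])
    df["p_adjusted"] = benjamini_hochberg(df["p_value"]) if len(df) else []
    df = df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    return EnrichmentResult(table=df, background_n=background_n, bioset_n=n_bio)
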