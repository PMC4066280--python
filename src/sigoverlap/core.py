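"""Core containers for two-group expression studies and gene signatures.

A *signature* (a "bioset" in meta-analysis parlance) is a ranked list of
differentially expressed genes, each carrying a fold change, a direction and a
P-value, together with the size of the measured background (every gene the
platform assayed) from which it was drawn.  Fold changes are kept internally as
linear ratios (group1 / group2 on the natural scale); the signed *display*
convention maps a ratio r < 1 to -1/r so that down-regulation reads as a
negative magnitude (a ratio of 0.5 displays as -2.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GROUP1 = "group1"
GROUP2 = "group2"

#: Columns every GeneSignature entries frame carries, in order.
SIGNATURE_COLUMNS = (
    "gene_id",
    "linear_fc",
    "display_fc",
    "p_value",
    "direction",
    "rank",
)


class FormatError(ValueError):
    """Malformed tabular input (duplicate ids, bad cells, missing labels)."""


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


def display_fold_change(linear_fc: float) -> float:
    """Signed display convention: r if r >= 1 else -1/r."""
    if linear_fc <= 0:
        raise ValueError(f"linear fold change must be positive, got {linear_fc}")
    return linear_fc if linear_fc >= 1.0 else -1.0 / linear_fc


def linear_fold_change(display_fc: float) -> float:
    """Inverse of :func:`display_fold_change`."""
    if display_fc == 0 or -1.0 < display_fc < 1.0:
        raise ValueError(f"display fold change must have magnitude >= 1, got {display_fc}")
    return display_fc if display_fc >= 1.0 else -1.0 / display_fc


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2-scale gene-by-sample expression values with a two-group labelling."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples), log2 units
    group_labels: Mapping[str, str]  # sample_id -> GROUP1 | GROUP2

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise FormatError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        groups = set()
        for sid in self.sample_ids:
            lab = self.group_labels.get(sid)
            if lab is None:
                raise FormatError(f"sample {sid!r} has no group label")
            if lab not in (GROUP1, GROUP2):
                raise FormatError(f"sample {sid!r} has label {lab!r}, expected group1/group2")
            groups.add(lab)
        if groups != {GROUP1, GROUP2}:
            raise FormatError(f"both groups must be non-empty, found only {sorted(groups)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of samples belonging to ``group``."""
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group_labels[s] == group],
            dtype=int,
        )

    def swap_groups(self) -> "ExpressionMatrix":
        """Relabel group1 <-> group2 (used to test antisymmetry of fold changes)."""
        swapped = {
            s: (GROUP2 if g == GROUP1 else GROUP1) for s, g in self.group_labels.items()
        }
        return replace(self, group_labels=swapped)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise ValueError("no duplicate present")


def rank_entries(entries: pd.DataFrame) -> pd.DataFrame:
    """Apply the signature ranking policy and assign ranks 1..n.

    Entries are ordered by ascending P-value, ties broken by descending
    absolute display fold change, then lexicographic gene id.  The policy is
    fixed so that the rank-based overlap scan is deterministic.
    """
    entries = entries.copy()
    entries["_absfc"] = entries["display_fc"].abs()
    entries = entries.sort_values(
        by=["p_value", "_absfc", "gene_id"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_absfc")
    entries["rank"] = np.arange(1, len(entries) + 1)
    return entries.reset_index(drop=True)


@dataclass(frozen=True)
class GeneSignature:
    """Ranked differential-expression gene list with its measured background.

    ``entries`` has columns gene_id, linear_fc, display_fc, p_value, direction
    ('up'/'down'), rank (1..n per the ranking policy).  ``background_n`` is the
    number of genes tested to produce the signature; ``background_genes`` keeps
    the actual background membership when known (signatures extracted from a
    matrix always know it; signatures read from bare tables may not).
    """

    entries: pd.DataFrame
    background_n: int
    thresholds: tuple[float, float] | None = None  # (fc_cut, p_cut)
    background_genes: tuple[str, ...] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        e = self.entries
        missing = [c for c in SIGNATURE_COLUMNS if c not in e.columns]
        if missing:
            raise FormatError(f"signature entries missing columns {missing}")
        if e["gene_id"].duplicated().any():
            dup = e.loc[e["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene id {dup!r} in signature")
        if len(e) and not (
            ((e["p_value"] > 0) & (e["p_value"] <= 1)).all() and (e["linear_fc"] > 0).all()
        ):
            raise FormatError("signature entries contain invalid p_value or fold change")
        if self.background_n < len(e):
            raise FormatError(
                f"background_n={self.background_n} smaller than signature size {len(e)}"
            )
        if self.background_genes is not None and len(e):
            extra = set(e["gene_id"]) - set(self.background_genes)
            if extra:
                raise FormatError(f"signature gene {sorted(extra)[0]!r} not in background")

    @classmethod
    def from_stats(
        cls,
        gene_ids: Iterable[str],
        linear_fc: Iterable[float],
        p_value: Iterable[float],
        background_n: int,
        *,
        thresholds: tuple[float, float] | None = None,
        background_genes: Iterable[str] | None = None,
        name: str = "",
    ) -> "GeneSignature":
        """Build a ranked signature from per-gene statistics."""
        fc = np.asarray(list(linear_fc), dtype=float)
        entries = pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "linear_fc": fc,
                "display_fc": np.where(fc >= 1.0, fc, -1.0 / fc),
                "p_value": np.asarray(list(p_value), dtype=float),
            }
        )
        entries["direction"] = np.where(entries["linear_fc"] > 1.0, "up", "down")
        entries = rank_entries(entries)
        bg = tuple(background_genes) if background_genes is not None else None
        return cls(
            entries=entries,
            background_n=background_n,
            thresholds=thresholds,
            background_genes=bg,
            name=name,
        )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> tuple[str, ...]:
        """Gene ids in rank order."""
        return tuple(self.entries["gene_id"])

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.entries["gene_id"])

    @property
    def directions(self) -> dict[str, str]:
        return dict(zip(self.entries["gene_id"], self.entries["direction"]))

    @property
    def n_up(self) -> int:
        return int((self.entries["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.entries["direction"] == "down").sum())

    def top(self, k: int) -> frozenset[str]:
        """Genes at ranks 1..k."""
        e = self.entries
        return frozenset(e.loc[e["rank"] <= k, "gene_id"])

    def restrict(self, genes: Iterable[str], background_n: int | None = None) -> "GeneSignature":
        """Keep only entries whose gene id is in ``genes``; re-rank."""
        keep = set(genes)
        entries = self.entries[self.entries["gene_id"].isin(keep)]
        entries = rank_entries(entries.drop(columns="rank"))
        bg_genes = None
        if self.background_genes is not None:
            bg_genes = tuple(g for g in self.background_genes if g in keep)
        n = background_n
        if n is None:
            n = len(bg_genes) if bg_genes is not None else self.background_n
        return GeneSignature(
            entries=entries,
            background_n=n,
            thresholds=self.thresholds,
            background_genes=bg_genes,
            name=self.name,
        )

    def subset_by_direction(self, direction: str) -> "GeneSignature":
        """Direction-restricted sub-signature ('up' or 'down'), re-ranked."""
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        entries = self.entries[self.entries["direction"] == direction]
        entries = rank_entries(entries.drop(columns="rank"))
        return replace(self, entries=entries)


@dataclass(frozen=True)
class OrthologMap:
    """Set of (source_gene, target_gene) identifier pairs across species."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for p in self.pairs:
            if len(p) != 2:
                raise FormatError(f"ortholog pair {p!r} is not a 2-tuple")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologMap":
        return cls(pairs=frozenset((str(a), str(b)) for a, b in pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(a for a, _ in self.pairs)

    def targets(self, source: str) -> tuple[str, ...]:
        """All targets of ``source`` in deterministic (lexicographic) order."""
        return tuple(sorted(b for a, b in self.pairs if a == source))

    def inverse(self) -> "OrthologMap":
        return OrthologMap(pairs=frozenset((b, a) for a, b in self.pairs))

    def target_lookup(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a, b in sorted(self.pairs):
            out.setdefault(a, []).append(b)
        return out


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT-style), e.g. pathways or curated biogroups."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def warn(message: str) -> None:
    """Single funnel for data-quality warnings."""
    warnings.warn(message, UserWarning, stacklevel=3)
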