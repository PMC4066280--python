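"""Venn decomposition of a bioset across cell-type reference signatures.

Given a concordant bioset (e.g. genes sharing a juvenile-like expression
pattern across two studies) and up to three cell-type developmental reference
signatures, every bioset gene is assigned to exactly one membership region of
the Venn diagram over the references — or to the *unexplained* remainder.
Membership uses gene identity only; per-reference direction agreement is
tallied alongside but does not gate membership, mirroring the distinction
between a Venn of shared genes and bar graphs of direction-matched subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Sequence

from .core import GeneSignature, OrthologMap, warn
from .io import translate_signature

MAX_REFERENCES = 3


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding, matching conventional report formatting."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int) -> float:
    """100 * count / total, half-up rounded to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, 1)


@dataclass(frozen=True)
class VennPartition:
    """Counts of a bioset's genes across all nonempty reference regions.

    ``region_counts`` keys are tuples of reference names (in the order the
    references were supplied) naming the exact membership pattern; every
    bioset gene sits in exactly one region or in ``unexplained``.
    ``agreement`` maps each reference to its (concordant, discordant)
    direction tallies over all genes shared with the bioset.
    """

    bioset_n: int
    ref_names: tuple[str, ...]
    region_counts: Mapping[tuple[str, ...], int]
    region_genes: Mapping[tuple[str, ...], tuple[str, ...]]
    unexplained: int
    agreement: Mapping[str, tuple[int, int]]

    @property
    def explained(self) -> int:
        return self.bioset_n - self.unexplained

    @property
    def explained_percent(self) -> float:
        return percent(self.explained, self.bioset_n)

    def reference_total(self, name: str) -> int:
        """Total bioset overlap with one reference (regions summed)."""
        return sum(c for patt, c in self.region_counts.items() if name in patt)

    def reference_percent(self, name: str) -> float:
        return percent(self.reference_total(name), self.bioset_n)


def _region_patterns(names: Sequence[str]) -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = []
    for k in range(1, len(names) + 1):
        out.extend(combinations(names, k))
    return out


def partition_bioset(
    bioset: GeneSignature,
    refs: Sequence[GeneSignature],
    ortholog_map: OrthologMap | None = None,
    *,
    ref_names: Sequence[str] | None = None,
) -> VennPartition:
    """Assign every bioset gene to its Venn membership region.

    When the references live in another species' namespace, supply an
    ``ortholog_map`` from the reference namespace to the bioset namespace;
    each reference is translated before membership is evaluated.
    """
    if len(bioset) == 0:
        raise ValueError("bioset is empty")
    if not 1 <= len(refs) <= MAX_REFERENCES:
        raise ValueError(f"need 1..{MAX_REFERENCES} references, got {len(refs)}")
    names = tuple(ref_names) if ref_names is not None else tuple(
        r.name or f"ref{i+1}" for i, r in enumerate(refs)
    )
    if len(set(names)) != len(names):
        raise ValueError(f"reference names must be unique, got {names}")

    translated = []
    for r in refs:
        if ortholog_map is not None:
            r, _ = translate_signature(r, ortholog_map)
        if len(r) == 0:
            warn(f"reference {r.name!r} is empty; it contributes only empty regions")
        translated.append(r)

    bio_dir = bioset.directions
    ref_sets = [r.gene_set for r in translated]
    ref_dirs = [r.directions for r in translated]

    region_genes: dict[tuple[str, ...], list[str]] = {
        patt: [] for patt in _region_patterns(names)
    }
    unexplained = 0
    for g in bioset.genes:
        patt = tuple(n for n, s in zip(names, ref_sets) if g in s)
        if patt:
            region_genes[patt].append(g)
        else:
            unexplained += 1

    agreement = {}
    for name, s, dirs in zip(names, ref_sets, ref_dirs):
        shared = [g for g in bioset.genes if g in s]
        conc = sum(1 for g in shared if dirs[g] == bio_dir[g])
        agreement[name] = (conc, len(shared) - conc)

    return VennPartition(
        bioset_n=len(bioset),
        ref_names=names,
        region_counts={p: len(gs) for p, gs in region_genes.items()},
        region_genes={p: tuple(gs) for p, gs in region_genes.items()},
        unexplained=unexplained,
        agreement=agreement,
    )


def contribution_percentages(partition: VennPartition) -> list[dict]:
    """Report rows: per-reference totals, each Venn region, explained total.

    Percentages are of the bioset size, half-up rounded to one decimal; the
    per-reference direction agreement is reported as a percentage of that
    reference's total overlap.
    """
    rows: list[dict] = []
    for name in partition.ref_names:
        total = partition.reference_total(name)
        conc, disc = partition.agreement[name]
        rows.append(
            {
                "kind": "reference_total",
                "label": name,
                "count": total,
                "percent": partition.reference_percent(name),
                "direction_concordant": conc,
                "direction_discordant": disc,
                "direction_concordant_percent": (
                    percent(conc, total) if total else 0.0
                ),
                "direction_concordant_percent_of_bioset": percent(
                    conc, partition.bioset_n
                ),
            }
        )
    for patt, count in partition.region_counts.items():
        rows.append(
            {
                "kind": "region",
                "label": "+".join(patt),
                "count": count,
                "percent": percent(count, partition.bioset_n),
            }
        )
    rows.append(
        {
            "kind": "explained",
            "label": "explained",
            "count": partition.explained,
            "percent": partition.explained_percent,
        }
    )
    rows.append(
        {
            "kind": "unexplained",
            "label": "unexplained",
            "count": partition.unexplained,
            "percent": percent(partition.unexplained, partition.bioset_n),
        }
    )
    return rows
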