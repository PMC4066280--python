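"""Tabular input/output and cross-species signature translation.

Formats are deliberately plain: tab-separated UTF-8 text with ``#`` comment
lines, GMT per the Broad convention, ortholog maps as two-column TSV.  Gene
identifier matching everywhere is exact, case-sensitive string equality —
symbol aliasing belongs in the ortholog/alias map input, not in silent
normalisation.

Signature tables accept either fold-change dialect: a ``fold_change_linear``
column of positive ratios, or a ``fold_change_display`` column in the signed
negative-reciprocal display convention (-1/r for ratios below 1).  The
internal canonical form is always the linear ratio plus a direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    GROUP1,
    GROUP2,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    GeneSignature,
    OrthologMap,
    linear_fold_change,
    warn,
)

LINEAR_COLUMN = "fold_change_linear"
DISPLAY_COLUMN = "fold_change_display"


def _read_metadata(path: Path) -> dict[str, str]:
    """Parse '# key: value' comment lines at the top of a TSV."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_expression_matrix(path: str | Path, labels_path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-sample log2 TSV plus its two-column sample-label TSV."""
    path, labels_path = Path(path), Path(labels_path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated gene row {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicated sample column {dup!r}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(values))
    if len(bad):
        g, s = bad[0]
        raise FormatError(
            f"{path}: non-numeric cell at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    labels_df = pd.read_csv(
        labels_path, sep="\t", comment="#", header=None, names=["sample_id", "group"], dtype=str
    )
    labels = dict(zip(labels_df["sample_id"], labels_df["group"]))
    for s in df.columns:
        if s not in labels:
            raise FormatError(f"{labels_path}: sample {s!r} has no group label")
    return ExpressionMatrix(
        gene_ids=tuple(df.index),
        sample_ids=tuple(df.columns),
        values=values,
        group_labels={s: labels[s] for s in df.columns},
    )


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, labels_path: str | Path
) -> None:
    matrix.to_frame().to_csv(Path(path), sep="\t", float_format="%.17g", index_label="gene_id")
    with open(labels_path, "w", encoding="utf-8") as fh:
        for s in matrix.sample_ids:
            fh.write(f"{s}\t{matrix.group_labels[s]}\n")


def read_signature_table(path: str | Path, *, name: str = "") -> GeneSignature:
    """Read a signature TSV (gene_id, fold change in either dialect, p_value).

    The column name declares the dialect.  Optional comment metadata:
    ``# background_n: N`` (defaults to the number of rows) and
    ``# thresholds: fc_cut,p_cut``.
    """
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str},
                     float_precision="round_trip")
    if "gene_id" not in df.columns or "p_value" not in df.columns:
        raise FormatError(f"{path}: signature table needs gene_id and p_value columns")
    if LINEAR_COLUMN in df.columns:
        fc = pd.to_numeric(df[LINEAR_COLUMN], errors="coerce")
        if len(df) and not (fc > 0).all():
            raise FormatError(f"{path}: linear fold changes must be positive")
        linear = fc.to_numpy(dtype=float)
    elif DISPLAY_COLUMN in df.columns:
        fc = pd.to_numeric(df[DISPLAY_COLUMN], errors="coerce")
        if fc.isna().any() or (len(df) and (fc.abs() < 1).any()):
            raise FormatError(f"{path}: display fold changes must have magnitude >= 1")
        linear = np.array([linear_fold_change(v) for v in fc])
    else:
        raise FormatError(
            f"{path}: need a {LINEAR_COLUMN} or {DISPLAY_COLUMN} column to declare the dialect"
        )
    p = pd.to_numeric(df["p_value"], errors="coerce")
    if len(df) and not ((p > 0) & (p <= 1)).all():
        raise FormatError(f"{path}: p_value outside (0, 1]")
    background_n = int(meta.get("background_n", len(df)))
    thresholds = None
    if "thresholds" in meta:
        fc_cut, p_cut = meta["thresholds"].split(",")
        thresholds = (float(fc_cut), float(p_cut))
    return GeneSignature.from_stats(
        df["gene_id"],
        linear,
        p.to_numpy(dtype=float),
        background_n=background_n,
        thresholds=thresholds,
        name=name or path.stem,
    )


def write_signature_table(
    sig: GeneSignature, path: str | Path, *, dialect: str = "display"
) -> None:
    """Write a signature TSV in the requested fold-change dialect."""
    if dialect not in ("linear", "display"):
        raise ValueError(f"dialect must be 'linear' or 'display', got {dialect!r}")
    e = sig.entries
    col = LINEAR_COLUMN if dialect == "linear" else DISPLAY_COLUMN
    src = "linear_fc" if dialect == "linear" else "display_fc"
    out = pd.DataFrame(
        {"gene_id": e["gene_id"], col: e[src], "p_value": e["p_value"], "rank": e["rank"]}
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# background_n: {sig.background_n}\n")
        if sig.thresholds is not None:
            fh.write(f"# thresholds: {sig.thresholds[0]},{sig.thresholds[1]}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.17g")


@dataclass(frozen=True)
class TranslationLog:
    """Bookkeeping for one ortholog translation pass."""

    n_input: int
    n_unmapped: int
    n_fanout_collapsed: int
    n_collision_dropped: int
    unmapped: tuple[str, ...]

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_unmapped - self.n_collision_dropped


def translate_signature(
    sig: GeneSignature, omap: OrthologMap
) -> tuple[GeneSignature, TranslationLog]:
    """Re-express a signature in the target species' identifier namespace.

    Collapse policy for ambiguous mappings, applied deterministically:

    * 1:many fan-out (one source, several targets): keep the single pairing
      whose source gene has the smallest P (within one source the statistics
      tie, so the lexicographically first target is kept).
    * many:1 collision (several sources, one target): keep the source with
      the smallest P; ties broken by larger |display FC|, then lexicographic
      source id.

    Unmapped genes are dropped and recorded in the translation log.  The
    measured background is recomputed as the number of background genes with
    at least one mapping when the membership is known; otherwise the mappable
    universe (distinct map sources) bounded by the previous background size.
    """
    if len(omap) == 0:
        raise ValueError("ortholog map is empty")
    lookup = omap.target_lookup()
    rows = []
    unmapped: list[str] = []
    n_fanout = 0
    for _, row in sig.entries.iterrows():
        targets = lookup.get(row["gene_id"])
        if not targets:
            unmapped.append(row["gene_id"])
            continue
        if len(targets) > 1:
            n_fanout += 1
        rows.append((targets[0], row))  # lexicographically first target
    # many:1 collisions: best evidence wins.
    by_target: dict[str, list] = {}
    for tgt, row in rows:
        by_target.setdefault(tgt, []).append(row)
    kept = []
    n_collision = 0
    for tgt in sorted(by_target):
        cands = sorted(
            by_target[tgt],
            key=lambda r: (r["p_value"], -abs(r["display_fc"]), r["gene_id"]),
        )
        n_collision += len(cands) - 1
        kept.append((tgt, cands[0]))

    if sig.background_genes is not None:
        # Background in the target namespace: distinct first-targets of the
        # background genes that have a mapping (collisions collapse, exactly
        # as signature entries do), so entries stay within the background.
        mapped_bg = sorted(
            {lookup[g][0] for g in sig.background_genes if g in lookup}
            | {t for t, _ in kept}
        )
        background_genes: tuple[str, ...] | None = tuple(mapped_bg)
        background_n = len(mapped_bg)
    else:
        background_n = min(sig.background_n, len(omap.sources))
        background_genes = None

    out = GeneSignature.from_stats(
        [t for t, _ in kept],
        [r["linear_fc"] for _, r in kept],
        [r["p_value"] for _, r in kept],
        background_n=background_n,
        thresholds=sig.thresholds,
        background_genes=background_genes,
        name=sig.name,
    )
    log = TranslationLog(
        n_input=len(sig),
        n_unmapped=len(unmapped),
        n_fanout_collapsed=n_fanout,
        n_collision_dropped=n_collision,
        unmapped=tuple(unmapped),
    )
    if unmapped:
        warn(f"translation dropped {len(unmapped)} unmapped genes")
    return out, log


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Two-column TSV: source gene, target gene."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
            pairs.append((parts[0], parts[1]))
    return OrthologMap.from_pairs(pairs)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(omap.pairs):
            fh.write(f"{a}\t{b}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-convention GMT file (name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{i}: GMT line needs name, description, members")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise FormatError(f"{path}:{i}: duplicate set name {name!r}")
            if not members:
                raise FormatError(f"{path}:{i}: set {name!r} has no members")
            if len(set(members)) < len(members):
                warn(f"{path}:{i}: duplicated members in set {name!r} were de-duplicated")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def write_ground_truth(truth, path: str | Path) -> None:
    """Serialize a GroundTruth table as TSV."""
    truth.table.to_csv(Path(path), sep="\t", index=False, float_format="%.10g")


def read_ground_truth(path: str | Path):
    from .synthetic import GroundTruth

    return GroundTruth(table=pd.read_csv(Path(path), sep="\t", dtype={"gene_id": str}))
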