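"""Synthetic paired two-group expression studies sharing a maturation axis.

The generator emulates the statistical structure of a cross-study
transcriptome comparison: two independent two-group studies (e.g. a
developmental contrast and a disease-vs-control contrast) whose true
differential-expression effects share a latent component.  A controllable
fraction of study-A DE genes carries a same-direction effect in study B
(*concordant*); the remainder carry an opposite-direction effect
(*discordant*).  Effect magnitudes are Gamma-distributed around the nominal
effect size, signs are down-biased to mirror the preferential
down-regulation of maturation markers seen in real cortical data, and
per-sample noise is i.i.d. Gaussian on the log2 scale.

Also provided: reference signatures with a controllable gene-content overlap
against a designated bioset (standing in for cell-type developmental
signatures) and deterministic mouse-style ortholog maps, so the cross-species
translation path is exercisable without real nomenclature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GROUP1,
    GROUP2,
    ConfigError,
    ExpressionMatrix,
    GeneSignature,
    OrthologMap,
)

# Shape of the Gamma magnitude distribution (scale = effect_size / shape, so the
# mean absolute effect equals effect_size and the CV is 0.5): magnitudes
# concentrate near the nominal effect rather than piling up at zero.
GAMMA_SHAPE = 4.0

LABEL_CONCORDANT = "concordant"
LABEL_DISCORDANT = "discordant"
LABEL_A_ONLY = "A-only"
LABEL_B_ONLY = "B-only"
LABEL_NULL = "null"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a paired synthetic comparison.

    Defaults describe a moderately powered microarray-scale design: 2000
    genes, 10 samples per group, 20% of genes truly differential in study A
    with 80% of those concordant in study B, mean absolute log2 effect 1.0,
    per-sample noise SD 0.5 log2 units, and 60% of true effects negative.
    """

    n_genes: int = 2000
    n_per_group: int = 10
    frac_de: float = 0.2
    concordance: float = 0.8
    effect_size: float = 1.0
    noise_sd: float = 0.5
    down_bias: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ConfigError(f"n_genes must be >= 10, got {self.n_genes}")
        if self.n_per_group < 3:
            raise ConfigError(f"n_per_group must be >= 3, got {self.n_per_group}")
        for fld in ("frac_de", "concordance", "down_bias"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{fld} must be in [0, 1], got {v}")
        if self.effect_size <= 0:
            raise ConfigError(f"effect_size must be positive, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be positive, got {self.noise_sd}")


@dataclass(frozen=True)
class GroundTruth:
    """Per-gene true effects (signed log2 units) and concordance labels."""

    table: pd.DataFrame  # columns: gene_id, effect_a, effect_b, label

    @property
    def labels(self) -> dict[str, str]:
        return dict(zip(self.table["gene_id"], self.table["label"]))

    def genes_with_label(self, label: str) -> frozenset[str]:
        t = self.table
        return frozenset(t.loc[t["label"] == label, "gene_id"])

    @property
    def a_de_genes(self) -> frozenset[str]:
        """Genes truly differential in study A."""
        t = self.table
        return frozenset(t.loc[t["effect_a"] != 0.0, "gene_id"])

    @property
    def b_de_genes(self) -> frozenset[str]:
        t = self.table
        return frozenset(t.loc[t["effect_b"] != 0.0, "gene_id"])


def gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n_genes + 1)]


def mouse_id(gene: str) -> str:
    """Deterministic mouse-style transform of a synthetic gene id."""
    return "m" + gene


def _signed_magnitudes(rng: np.random.Generator, n: int, effect_size: float, down_bias: float) -> np.ndarray:
    mag = rng.gamma(GAMMA_SHAPE, effect_size / GAMMA_SHAPE, size=n)
    sign = np.where(rng.random(n) < down_bias, -1.0, 1.0)
    return mag * sign


def _study_matrix(
    rng: np.random.Generator,
    ids: list[str],
    effects: np.ndarray,
    n_per_group: int,
    noise_sd: float,
    prefix: str,
) -> ExpressionMatrix:
    n_genes = len(ids)
    baseline = rng.normal(8.0, 1.5, size=n_genes)
    samples = [f"{prefix}_g1_{i+1:02d}" for i in range(n_per_group)] + [
        f"{prefix}_g2_{i+1:02d}" for i in range(n_per_group)
    ]
    labels = {s: (GROUP1 if i < n_per_group else GROUP2) for i, s in enumerate(samples)}
    values = np.tile(baseline[:, None], (1, 2 * n_per_group))
    values[:, :n_per_group] += effects[:, None]  # group1 carries the effect
    values += rng.normal(0.0, noise_sd, size=values.shape)
    return ExpressionMatrix(
        gene_ids=tuple(ids),
        sample_ids=tuple(samples),
        values=values,
        group_labels=labels,
    )


def generate_paired_studies(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate two studies over one gene universe with shared latent effects.

    Study-A DE genes are drawn per ``frac_de``; of those, a ``concordance``
    fraction carries a same-sign effect in study B and the rest an
    opposite-sign effect (so the concordant fraction among genes recovered in
    both studies estimates ``concordance`` directly).  Both matrices are log2
    scale with group1 as the young/disease-style numerator group.
    """
    rng = np.random.default_rng(config.seed)
    ids = gene_ids(config.n_genes)
    n_de = round(config.frac_de * config.n_genes)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    n_conc = round(config.concordance * n_de)
    conc_idx = de_idx[:n_conc]
    disc_idx = de_idx[n_conc:]

    effect_a = np.zeros(config.n_genes)
    effect_b = np.zeros(config.n_genes)
    effect_a[de_idx] = _signed_magnitudes(rng, n_de, config.effect_size, config.down_bias)
    # Study-B magnitudes are redrawn (effects share direction, not size).
    mag_b = rng.gamma(GAMMA_SHAPE, config.effect_size / GAMMA_SHAPE, size=n_de)
    effect_b[conc_idx] = np.sign(effect_a[conc_idx]) * mag_b[:n_conc]
    effect_b[disc_idx] = -np.sign(effect_a[disc_idx]) * mag_b[n_conc:]

    labels = np.full(config.n_genes, LABEL_NULL, dtype=object)
    labels[conc_idx] = LABEL_CONCORDANT
    labels[disc_idx] = LABEL_DISCORDANT

    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "gene_id": ids,
                "effect_a": effect_a,
                "effect_b": effect_b,
                "label": labels,
            }
        )
    )
    mat_a = _study_matrix(rng, ids, effect_a, config.n_per_group, config.noise_sd, "A")
    mat_b = _study_matrix(rng, ids, effect_b, config.n_per_group, config.noise_sd, "B")
    return mat_a, mat_b, truth


def generate_reference_signature(
    config: SyntheticConfig,
    bioset: GeneSignature,
    overlap_frac: float,
    *,
    direction_agreement: float = 1.0,
    size: int | None = None,
    target_ids: bool = False,
    seed_offset: int = 0,
) -> GeneSignature:
    """Reference signature overlapping ``bioset`` at a requested fraction.

    ``overlap_frac`` of the bioset's genes are included; the remainder of the
    signature (up to ``size``, default the bioset's size) is filled with genes
    disjoint from the bioset.  Overlapping genes agree in direction with the
    bioset with probability ``direction_agreement``.  With ``target_ids`` the
    output carries mouse-style identifiers consistent with
    :func:`generate_ortholog_map` over the same gene universe.
    """
    if not 0.0 <= overlap_frac <= 1.0:
        raise ConfigError(f"overlap_frac must be in [0, 1], got {overlap_frac}")
    if not 0.0 <= direction_agreement <= 1.0:
        raise ConfigError(
            f"direction_agreement must be in [0, 1], got {direction_agreement}"
        )
    rng = np.random.default_rng(config.seed + 104729 * (seed_offset + 1))
    n_overlap = round(overlap_frac * len(bioset))
    size = len(bioset) if size is None else size
    if size < n_overlap:
        raise ConfigError(f"size={size} smaller than requested overlap {n_overlap}")

    bioset_genes = list(bioset.genes)
    chosen = list(rng.choice(bioset_genes, size=n_overlap, replace=False)) if n_overlap else []
    n_filler = size - n_overlap
    filler = [f"R{seed_offset:02d}_{i:06d}" for i in range(1, n_filler + 1)]
    genes = chosen + filler

    bio_dir = bioset.directions
    agree = rng.random(n_overlap) < direction_agreement
    directions = [
        bio_dir[g] if agree[i] else ("down" if bio_dir[g] == "up" else "up")
        for i, g in enumerate(chosen)
    ]
    directions += list(rng.choice(["up", "down"], size=n_filler))

    # Statistics comfortably inside typical signature thresholds.
    p = rng.uniform(1e-8, 0.049, size=size)
    mag = 1.6 + rng.gamma(2.0, 0.5, size=size)
    linear = np.where(np.array(directions) == "up", mag, 1.0 / mag)

    background_genes = sorted(set(bioset.background_genes or bioset.genes) | set(genes))
    if target_ids:
        genes = [mouse_id(g) for g in genes]
        background_genes = [mouse_id(g) for g in background_genes]
    return GeneSignature.from_stats(
        genes,
        linear,
        p,
        background_n=len(background_genes),
        background_genes=background_genes,
        name=f"reference{seed_offset}",
    )


def generate_ortholog_map(
    genes: list[str] | tuple[str, ...],
    *,
    drop_frac: float = 0.0,
    fanout_frac: float = 0.0,
    seed: int = 0,
) -> OrthologMap:
    """Mouse-style -> source-id ortholog map over ``genes``.

    Each gene maps from its deterministic mouse-style id back to itself; a
    ``drop_frac`` fraction of genes is left unmapped and a ``fanout_frac``
    fraction gains a second (1:2) target, for exercising collapse policies.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    for g in genes:
        if drop_frac and rng.random() < drop_frac:
            continue
        pairs.append((mouse_id(g), g))
        if fanout_frac and rng.random() < fanout_frac:
            pairs.append((mouse_id(g), g + "_alt"))
    return OrthologMap.from_pairs(pairs)
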