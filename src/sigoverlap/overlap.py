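"""Rank-based signature overlap statistics.

The central test is a running (rank-scanned) Fisher overlap: scan cumulative
cutoffs down the ranked query signature, compute an upper-tail hypergeometric
overlap P-value at each cutoff against the reference signature over the common
measured background, and summarise by the minimum P multiplied by the number
of cutoffs (a Bonferroni correction over the scan).  The scan uses decile
boundaries for signatures of 50+ genes and every rank below that, so a
brute-force exhaustive oracle is exact for small signatures.

Hypergeometric tails are evaluated in exact big-integer arithmetic
(numerators summed over a single shared denominator C(M, N)), which keeps
extreme tails — real cross-study overlaps reach 1e-75 and below — meaningful:
P-values that underflow double precision are reported via their log10.

Direction handling: each shared gene falls in one of four quadrants (up-up,
down-down, up-down, down-up).  Genes changing in the same direction in both
signatures show a *positive correlation*; the Pearson chi-square against an
expected 50/50 split tests whether concordance exceeds chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

from scipy import stats

from .core import GeneSignature, warn

QUADRANTS = ("uu", "dd", "ud", "du")
_LOG10_2 = math.log10(2.0)
#: Direction Bonferroni: four direction pairings (up,up) (down,down) (up,down) (down,up).
N_DIRECTION_PAIRS = 4


def _log10_int(n: int) -> float:
    """log10 of a positive (possibly huge) integer."""
    if n <= 0:
        raise ValueError("n must be positive")
    bl = n.bit_length()
    if bl <= 53:
        return math.log10(n)
    shift = bl - 53
    return math.log10(n >> shift) + shift * _LOG10_2


def log10_fraction(frac: Fraction) -> float:
    """log10 of a positive rational, immune to float underflow."""
    if frac <= 0:
        raise ValueError("fraction must be positive")
    return _log10_int(frac.numerator) - _log10_int(frac.denominator)


def fraction_to_float(frac: Fraction) -> float:
    """Rational -> float, floored at the smallest subnormal instead of 0."""
    f = float(frac)
    if f == 0.0 and frac > 0:
        return 5e-324
    return f


def hypergeom_upper_exact(
    overlap_k: int, draws: int, successes: int, population: int
) -> Fraction:
    """P(X >= overlap_k) for X ~ Hypergeometric(population, successes, draws).

    Exact rational: sum of C(successes, i) * C(population - successes,
    draws - i) over the upper tail, divided by C(population, draws).
    """
    if not (0 <= overlap_k <= min(draws, successes) <= population):
        raise ValueError(
            f"inconsistent hypergeometric arguments k={overlap_k}, draws={draws}, "
            f"successes={successes}, population={population}"
        )
    if draws > population:
        raise ValueError(f"draws={draws} exceeds population={population}")
    lo = max(overlap_k, draws + successes - population)
    hi = min(draws, successes)
    num = sum(
        math.comb(successes, i) * math.comb(population - successes, draws - i)
        for i in range(lo, hi + 1)
    )
    return Fraction(num, math.comb(population, draws))


def hypergeom_upper(overlap_k: int, draws: int, successes: int, population: int) -> float:
    """Float upper-tail hypergeometric P; exact up to the final conversion."""
    return fraction_to_float(hypergeom_upper_exact(overlap_k, draws, successes, population))


def hypergeom_upper_log10(overlap_k: int, draws: int, successes: int, population: int) -> float:
    """log10 of the upper-tail P, usable far below double-precision underflow."""
    return log10_fraction(hypergeom_upper_exact(overlap_k, draws, successes, population))


def scan_cutoffs(n_a: int) -> list[int]:
    """Cutoff grid over the ranked query: every rank below 50, else deciles."""
    if n_a < 50:
        return list(range(1, n_a + 1))
    return sorted({math.ceil(n_a * j / 10) for j in range(1, 11)})


@dataclass(frozen=True)
class RunningFisherScan:
    """Full scan detail: cutoffs, per-cutoff exact P, corrected minimum."""

    cutoffs: tuple[int, ...]
    cutoff_p: tuple[Fraction, ...]
    p: float
    log10_p: float

    @property
    def min_cutoff(self) -> int:
        i = min(range(len(self.cutoff_p)), key=lambda j: self.cutoff_p[j])
        return self.cutoffs[i]


def running_fisher_scan(
    sig_a: GeneSignature, sig_b: GeneSignature, background_n: int
) -> RunningFisherScan:
    """Scan the ranked ``sig_a`` against ``sig_b``'s gene content."""
    n_a, n_b = len(sig_a), len(sig_b)
    if n_a == 0 or n_b == 0:
        warn("running Fisher on an empty signature; P = 1")
        return RunningFisherScan(cutoffs=(), cutoff_p=(), p=1.0, log10_p=0.0)
    union = len(sig_a.gene_set | sig_b.gene_set)
    if background_n < union:
        raise ValueError(
            f"background_n={background_n} smaller than signature union {union}"
        )
    b_genes = sig_b.gene_set
    ranked = list(sig_a.genes)  # rank order
    cutoffs = scan_cutoffs(n_a)
    ps: list[Fraction] = []
    hits = 0
    next_idx = 0
    for k in cutoffs:
        while next_idx < k:
            if ranked[next_idx] in b_genes:
                hits += 1
            next_idx += 1
        ps.append(hypergeom_upper_exact(hits, k, n_b, background_n))
    corrected = min(ps) * len(cutoffs)
    capped = min(corrected, Fraction(1))
    return RunningFisherScan(
        cutoffs=tuple(cutoffs),
        cutoff_p=tuple(ps),
        p=fraction_to_float(capped),
        log10_p=log10_fraction(capped) if capped > 0 else 0.0,
    )


def running_fisher(sig_a: GeneSignature, sig_b: GeneSignature, background_n: int) -> float:
    """Corrected minimum over the cutoff scan (see :func:`running_fisher_scan`)."""
    return running_fisher_scan(sig_a, sig_b, background_n).p


def restrict_to_background(
    sig_a: GeneSignature, sig_b: GeneSignature, background: Iterable[str]
) -> tuple[GeneSignature, GeneSignature, int]:
    """Filter both signatures to a common measured background."""
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    missing = (sig_a.gene_set | sig_b.gene_set) - bg
    if missing:
        warn(f"{len(missing)} signature genes outside the common background were dropped")
    return (
        sig_a.restrict(bg, background_n=len(bg)),
        sig_b.restrict(bg, background_n=len(bg)),
        len(bg),
    )


def common_background(sig_a: GeneSignature, sig_b: GeneSignature) -> frozenset[str] | None:
    """Intersection of the two measured backgrounds, when both are known."""
    if sig_a.background_genes is None or sig_b.background_genes is None:
        return None
    return frozenset(sig_a.background_genes) & frozenset(sig_b.background_genes)


@dataclass(frozen=True)
class QuadrantCounts:
    """Shared genes split by direction pair across the two signatures."""

    uu: int
    dd: int
    ud: int
    du: int
    genes: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def overlap(self) -> int:
        return self.uu + self.dd + self.ud + self.du

    @property
    def concordant(self) -> int:
        """Positive-correlation genes: same direction in both signatures."""
        return self.uu + self.dd

    @property
    def discordant(self) -> int:
        return self.ud + self.du

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.uu, self.dd, self.ud, self.du)


def quadrant_partition(sig_a: GeneSignature, sig_b: GeneSignature) -> QuadrantCounts:
    """Assign every shared gene to exactly one of uu/dd/ud/du."""
    dir_a = sig_a.directions
    dir_b = sig_b.directions
    buckets: dict[str, list[str]] = {q: [] for q in QUADRANTS}
    for g in sorted(sig_a.gene_set & sig_b.gene_set):
        key = ("u" if dir_a[g] == "up" else "d") + ("u" if dir_b[g] == "up" else "d")
        buckets[key].append(g)
    return QuadrantCounts(
        uu=len(buckets["uu"]),
        dd=len(buckets["dd"]),
        ud=len(buckets["ud"]),
        du=len(buckets["du"]),
        genes={q: tuple(v) for q, v in buckets.items()},
    )


def directional_overlap_p(
    sig_a: GeneSignature,
    sig_b: GeneSignature,
    direction_a: str,
    direction_b: str,
    background_n: int,
) -> float:
    """Running Fisher on the direction-restricted sub-signatures."""
    sub_a = sig_a.subset_by_direction(direction_a)
    sub_b = sig_b.subset_by_direction(direction_b)
    if len(sub_a) == 0 or len(sub_b) == 0:
        warn(
            f"empty direction-restricted signature ({direction_a}/{direction_b}); P = 1"
        )
        return 1.0
    return running_fisher(sub_a, sub_b, background_n)


def concordance_chi_square(concordant: int, discordant: int) -> tuple[float, float]:
    """Pearson chi-square of the concordant/discordant split against 50/50.

    One degree of freedom, no continuity correction:
    chi2 = sum (obs - exp)^2 / exp with exp = total/2 in each cell.
    """
    if concordant < 0 or discordant < 0:
        raise ValueError("counts must be non-negative")
    total = concordant + discordant
    if total == 0:
        raise ValueError("concordance chi-square undefined for zero overlap")
    exp = total / 2.0
    chi2 = (concordant - exp) ** 2 / exp + (discordant - exp) ** 2 / exp
    return chi2, float(stats.chi2.sf(chi2, df=1))


def bonferroni_ledger(n_dataset_pairs: int) -> tuple[float, float]:
    """Significance levels in force: per dataset pair and per direction pair.

    The pairwise level divides 0.05 by the number of dataset combinations
    compared in the run; the directional level divides by the four possible
    direction pairings (0.05 / 4 = 0.0125).
    """
    if n_dataset_pairs < 1:
        raise ValueError(f"n_dataset_pairs must be >= 1, got {n_dataset_pairs}")
    return 0.05 / n_dataset_pairs, 0.05 / N_DIRECTION_PAIRS


@dataclass(frozen=True)
class OverlapResult:
    """Complete pairwise comparison of two signatures.

    ``quadrant_p`` carries the four direction-restricted running-Fisher
    P-values in uu/dd/ud/du order; ``running_p`` is the joint (direction-
    agnostic) scan.  ``running_log10_p`` stays informative when ``running_p``
    underflows double precision.
    """

    name_a: str
    name_b: str
    n_a: int
    n_b: int
    background_n: int
    quadrants: QuadrantCounts
    quadrant_p: tuple[float, float, float, float]
    running_p: float
    running_log10_p: float
    chi2: float
    chi2_p: float
    alpha_pairs: float
    alpha_directions: float
    sig_a: GeneSignature = field(repr=False, compare=False)
    sig_b: GeneSignature = field(repr=False, compare=False)

    @property
    def overlap(self) -> int:
        return self.quadrants.overlap

    @property
    def concordant(self) -> int:
        return self.quadrants.concordant

    @property
    def discordant(self) -> int:
        return self.quadrants.discordant

    def to_dict(self) -> dict:
        return {
            "name_a": self.name_a,
            "name_b": self.name_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "background_n": self.background_n,
            "overlap": self.overlap,
            "quadrants": dict(zip(QUADRANTS, self.quadrants.as_tuple())),
            "quadrant_p": dict(zip(QUADRANTS, self.quadrant_p)),
            "running_p": self.running_p,
            "running_log10_p": self.running_log10_p,
            "concordant": self.concordant,
            "discordant": self.discordant,
            "chi2": self.chi2,
            "chi2_p": self.chi2_p,
            "alpha_pairs": self.alpha_pairs,
            "alpha_directions": self.alpha_directions,
        }


def compare_signatures(
    sig_a: GeneSignature,
    sig_b: GeneSignature,
    *,
    background: Iterable[str] | None = None,
    n_dataset_pairs: int = 1,
) -> OverlapResult:
    """Full pairwise comparison over a common measured background.

    When ``background`` is not given it defaults to the intersection of the
    two signatures' recorded backgrounds; with neither available, the smaller
    recorded background size is used without membership filtering.
    """
    if background is None:
        bg = common_background(sig_a, sig_b)
    else:
        bg = frozenset(background)
    if bg is not None:
        sig_a, sig_b, background_n = restrict_to_background(sig_a, sig_b, bg)
    else:
        background_n = min(sig_a.background_n, sig_b.background_n)
    quad = quadrant_partition(sig_a, sig_b)
    if quad.overlap > 0:
        chi2, chi2_p = concordance_chi_square(quad.concordant, quad.discordant)
    else:
        chi2, chi2_p = 0.0, 1.0
    scan = running_fisher_scan(sig_a, sig_b, background_n)
    qp = tuple(
        directional_overlap_p(
            sig_a,
            sig_b,
            "up" if q[0] == "u" else "down",
            "up" if q[1] == "u" else "down",
            background_n,
        )
        for q in QUADRANTS
    )
    alpha_pairs, alpha_directions = bonferroni_ledger(n_dataset_pairs)
    return OverlapResult(
        name_a=sig_a.name,
        name_b=sig_b.name,
        n_a=len(sig_a),
        n_b=len(sig_b),
        background_n=background_n,
        quadrants=quad,
        quadrant_p=qp,  # type: ignore[arg-type]
        running_p=scan.p,
        running_log10_p=scan.log10_p,
        chi2=chi2,
        chi2_p=chi2_p,
        alpha_pairs=alpha_pairs,
        alpha_directions=alpha_directions,
        sig_a=sig_a,
        sig_b=sig_b,
    )
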