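"""End-to-end orchestration: extract -> translate -> overlap -> contribute -> enrich.

A run is declared in a YAML config naming the study inputs (expression
matrices with labels, or precomputed signature tables), per-study thresholds,
the comparison pairs, and optional ortholog map / cell-type reference /
gene-set collection paths.  Every comparison produces an OverlapResult and
its positive-correlation *bioset* (the genes changing in the same direction
in both studies), which feeds the cell-type contribution and enrichment
stages.  The report is deterministic JSON: rerunning the echoed config on the
same inputs reproduces it byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .contribution import VennPartition, contribution_percentages, partition_bioset
from .core import ConfigError, GeneSignature, warn
from .diffexpr import extract_signature
from .enrichment import EnrichmentResult, enrich
from .io import (
    read_expression_matrix,
    read_gmt,
    read_ortholog_map,
    read_signature_table,
    write_signature_table,
)
from .overlap import OverlapResult, bonferroni_ledger, compare_signatures

logger = logging.getLogger("sigoverlap")


def _log(msg: str) -> None:
    logger.info("%s %s", _dt.datetime.now().isoformat(timespec="seconds"), msg)


@dataclass(frozen=True)
class StudyInput:
    """One study: either a matrix+labels to extract from, or a signature table."""

    name: str
    matrix: str | None = None
    labels: str | None = None
    signature: str | None = None
    fc_cut: float = 1.2
    p_cut: float = 0.05

    def __post_init__(self) -> None:
        has_matrix = self.matrix is not None and self.labels is not None
        has_sig = self.signature is not None
        if has_matrix == has_sig:
            raise ConfigError(
                f"study {self.name!r}: give either matrix+labels or signature"
            )


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of a full comparison run."""

    studies: tuple[StudyInput, ...]
    pairs: tuple[tuple[str, str], ...]
    out_dir: str
    ortholog_map: str | None = None
    references: tuple[str, ...] = ()
    gmt: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ConfigError("pairs: at least one comparison pair is required")
        names = {s.name for s in self.studies}
        if len(names) != len(self.studies):
            raise ConfigError("studies: names must be unique")
        for a, b in self.pairs:
            for n in (a, b):
                if n not in names:
                    raise ConfigError(f"pairs: study {n!r} is not declared")
        if len(self.references) > 3:
            raise ConfigError("references: at most 3 reference signatures")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        def _resolve(p):
            if p is None:
                return None
            p = str(p)
            return str((base / p)) if base is not None and not Path(p).is_absolute() else p

        studies = tuple(
            StudyInput(
                name=s["name"],
                matrix=_resolve(s.get("matrix")),
                labels=_resolve(s.get("labels")),
                signature=_resolve(s.get("signature")),
                fc_cut=float(s.get("fc_cut", 1.2)),
                p_cut=float(s.get("p_cut", 0.05)),
            )
            for s in raw.get("studies", [])
        )
        pairs = tuple((a, b) for a, b in raw.get("pairs", []))
        return cls(
            studies=studies,
            pairs=pairs,
            out_dir=_resolve(raw.get("out_dir", "sigoverlap_out")),
            ortholog_map=_resolve(raw.get("ortholog_map")),
            references=tuple(_resolve(r) for r in raw.get("references", [])),
            gmt=_resolve(raw.get("gmt")),
            seed=int(raw.get("seed", 0)),
        )

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["studies"] = [dataclasses.asdict(s) for s in self.studies]
        d["pairs"] = [list(p) for p in self.pairs]
        d["references"] = list(self.references)
        return d

    def validate_paths(self) -> None:
        paths = []
        for s in self.studies:
            paths += [p for p in (s.matrix, s.labels, s.signature) if p]
        paths += [p for p in (self.ortholog_map, self.gmt) if p]
        paths += list(self.references)
        for p in paths:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")


def make_bioset(overlap: OverlapResult, *, name: str = "") -> GeneSignature:
    """Positive-correlation bioset: the uu and dd genes of an overlap.

    Entries carry the study-A statistics (the signature whose ranking drove
    the scan) plus the study-B fold change and P as extra columns.
    """
    conc = sorted(
        set(overlap.quadrants.genes.get("uu", ()))
        | set(overlap.quadrants.genes.get("dd", ()))
    )
    if not conc:
        warn("overlap has no positive-correlation genes; bioset is empty")
    ea = overlap.sig_a.entries.set_index("gene_id")
    eb = overlap.sig_b.entries.set_index("gene_id")
    sig = GeneSignature.from_stats(
        conc,
        [ea.loc[g, "linear_fc"] for g in conc],
        [ea.loc[g, "p_value"] for g in conc],
        background_n=overlap.background_n,
        background_genes=overlap.sig_a.background_genes,
        name=name or f"bioset_{overlap.name_a}_vs_{overlap.name_b}",
    )
    entries = sig.entries.copy()
    entries["linear_fc_b"] = [eb.loc[g, "linear_fc"] for g in entries["gene_id"]]
    entries["p_value_b"] = [eb.loc[g, "p_value"] for g in entries["gene_id"]]
    return dataclasses.replace(sig, entries=entries)


@dataclass(frozen=True)
class PairReport:
    overlap: OverlapResult
    bioset: GeneSignature
    partition: VennPartition | None
    enrichment: EnrichmentResult | None


@dataclass(frozen=True)
class RunReport:
    """Self-contained result of one pipeline run."""

    config: dict
    version: str
    n_dataset_pairs: int
    alpha_pairs: float
    alpha_directions: float
    pairs: dict[str, PairReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict[str, Any] = {
            "version": self.version,
            "config": self.config,
            "n_dataset_pairs": self.n_dataset_pairs,
            "alpha_pairs": self.alpha_pairs,
            "alpha_directions": self.alpha_directions,
            "pairs": {},
        }
        for key, pr in self.pairs.items():
            d: dict[str, Any] = {"overlap": pr.overlap.to_dict(), "bioset_n": len(pr.bioset)}
            if pr.partition is not None:
                d["contribution"] = contribution_percentages(pr.partition)
            if pr.enrichment is not None:
                d["enrichment"] = pr.enrichment.table.to_dict(orient="records")
            out["pairs"][key] = d
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _load_signatures(config: RunConfig) -> dict[str, GeneSignature]:
    sigs: dict[str, GeneSignature] = {}
    for s in config.studies:
        if s.signature is not None:
            sig = read_signature_table(s.signature, name=s.name)
            _log(f"study {s.name}: loaded signature of {len(sig)} genes")
        else:
            mat = read_expression_matrix(s.matrix, s.labels)
            sig = extract_signature(mat, s.fc_cut, s.p_cut, name=s.name)
            n_dropped = mat.n_genes - len(sig)
            assert len(sig) + n_dropped == mat.n_genes  # filter-count conservation
            _log(
                f"study {s.name}: extracted {len(sig)} of {mat.n_genes} genes "
                f"({sig.n_up} up, {sig.n_down} down, {n_dropped} filtered)"
            )
        sigs[s.name] = sig
    return sigs


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all declared comparisons and write artifacts to ``out_dir``.

    Any stage failure aborts with a stage-tagged message and removes partial
    outputs created by this run.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        stage = "load"
        omap = read_ortholog_map(config.ortholog_map) if config.ortholog_map else None
        refs = [read_signature_table(p) for p in config.references]
        collection = read_gmt(config.gmt) if config.gmt else None
        sigs = _load_signatures(config)

        n_pairs = len(config.pairs)
        alpha_pairs, alpha_directions = bonferroni_ledger(n_pairs)
        report = RunReport(
            config=config.echo(),
            version=__version__,
            n_dataset_pairs=n_pairs,
            alpha_pairs=alpha_pairs,
            alpha_directions=alpha_directions,
            pairs={},
        )
        for a, b in config.pairs:
            stage = f"overlap:{a}~{b}"
            ov = compare_signatures(sigs[a], sigs[b], n_dataset_pairs=n_pairs)
            _log(
                f"pair {a}~{b}: overlap {ov.overlap} "
                f"(uu={ov.quadrants.uu} dd={ov.quadrants.dd} "
                f"ud={ov.quadrants.ud} du={ov.quadrants.du}), "
                f"running log10 P {ov.running_log10_p:.2f}, chi2 {ov.chi2:.2f}"
            )
            bioset = make_bioset(ov)
            bioset_path = out_dir / f"bioset_{a}_vs_{b}.tsv"
            write_signature_table(bioset, bioset_path)
            created.append(bioset_path)

            partition = None
            if refs and len(bioset):
                stage = f"contribution:{a}~{b}"
                partition = partition_bioset(bioset, refs, omap)
                _log(
                    f"pair {a}~{b}: explained {partition.explained} of "
                    f"{partition.bioset_n} ({partition.explained_percent}%)"
                )
            enrichment = None
            if collection is not None and len(bioset):
                stage = f"enrichment:{a}~{b}"
                enrichment = enrich(bioset, collection, bioset.background_n)
                _log(f"pair {a}~{b}: enrichment over {len(enrichment)} sets")
            report.pairs[f"{a}~{b}"] = PairReport(
                overlap=ov, bioset=bioset, partition=partition, enrichment=enrichment
            )

        stage = "report"
        report_path = out_dir / "report.json"
        report_path.write_text(report.to_json(), encoding="utf-8")
        created.append(report_path)
        _log(f"report written to {report_path}")
        return report
    except Exception as exc:
        for p in created:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
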