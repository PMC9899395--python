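"""End-to-end protocol-design run: digest -> select -> predict -> budget.

One declarative :class:`RunConfig` drives the whole pipeline so a design
comparison (e.g. a three-enzyme protocol against a single frequent cutter)
is reproducible from a single file.  All randomness is seeded explicitly;
the emitted JSON report conforms to the schema shipped in
``gbs3d/data/design_report.schema.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .digestion import (
    Genome,
    MethylationTrack,
    digest,
    evaluate_combinations,
    find_cut_sites,
    write_cut_sites_bed,
    write_fragments_bed,
)
from .enzymes import EnzymeRegistry, builtin_registry
from .library import LibraryDesign, budget, predict_library, select_fragments

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_design", "load_schema", "validate_report"]


@dataclass
class RunConfig:
    """Declarative configuration for one design run."""

    genome_fasta: Union[str, Path]
    enzymes: tuple[str, ...] = ("PstI", "NsiI", "MspI")
    rare_set: tuple[str, ...] = ("PstI", "NsiI")
    frequent_cutter: str = "MspI"
    size_window: tuple[int, int] = (50, 350)
    adapter_extension: int = 0
    methylation_bed: Optional[Union[str, Path]] = None
    partial_block_probability: float = 0.5
    reads_per_sample: int = 100_000
    min_depth: int = 2
    run_capacity: Optional[int] = None
    enzyme_registry_tsv: Optional[Union[str, Path]] = None
    seed: int = 0
    output_dir: Union[str, Path] = "gbs3d_out"

    def validate(self) -> None:
        if not Path(self.genome_fasta).exists():
            raise FileNotFoundError(f"genome FASTA not found: {self.genome_fasta}")
        if self.methylation_bed and not Path(self.methylation_bed).exists():
            raise FileNotFoundError(
                f"methylation BED not found: {self.methylation_bed}"
            )
        if self.enzyme_registry_tsv and not Path(self.enzyme_registry_tsv).exists():
            raise FileNotFoundError(
                f"enzyme registry not found: {self.enzyme_registry_tsv}"
            )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        for key in ("enzymes", "rare_set", "size_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in dataclasses.asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_design(config: RunConfig) -> dict:
    """Execute the full design pipeline and write the JSON report.

    Stages: load genome (and methylation track), digest with the configured
    enzyme combination, apply the library selection rule, predict coverage
    and end-pair composition, and evaluate the read budget.  Intermediate
    BED files and the report are written under ``config.output_dir`` with
    stable names.
    """
    config.validate()
    logger.info("run_design config %s: %s", config.config_hash(), config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    registry = (
        EnzymeRegistry.from_tsv(config.enzyme_registry_tsv)
        if config.enzyme_registry_tsv
        else builtin_registry()
    )
    enzymes = registry.resolve(config.enzymes)

    genome = Genome.from_fasta(config.genome_fasta)
    methylation = (
        MethylationTrack.from_bed(config.methylation_bed, genome)
        if config.methylation_bed
        else None
    )

    sites = find_cut_sites(
        genome, enzymes, methylation, config.partial_block_probability, config.seed
    )
    fragments = digest(genome, sites)
    write_cut_sites_bed(sites, outdir / "cut_sites.bed")
    write_fragments_bed(fragments, outdir / "fragments.bed")

    design = LibraryDesign(
        rare_set=frozenset(config.rare_set),
        frequent_cutter=config.frequent_cutter,
        size_window=tuple(config.size_window),
        adapter_extension=config.adapter_extension,
    )
    selected = select_fragments(fragments, design)
    write_fragments_bed(selected, outdir / "selected_fragments.bed")
    prediction = predict_library(fragments, design, genome.total_length)

    per_enzyme = {e.name: 0 for e in enzymes}
    for cs in sites:
        per_enzyme[cs.enzyme_name] += 1

    if prediction.fragment_count > 0:
        budget_result = budget(
            prediction.fragment_count,
            config.reads_per_sample,
            config.min_depth,
            config.run_capacity,
        )
        budget_dict = dataclasses.asdict(budget_result)
    else:
        budget_dict = None

    report = {
        "config": {
            "genome_fasta": str(config.genome_fasta),
            "enzymes": list(config.enzymes),
            "rare_set": sorted(config.rare_set),
            "frequent_cutter": config.frequent_cutter,
            "size_window": list(config.size_window),
            "adapter_extension": config.adapter_extension,
            "partial_block_probability": config.partial_block_probability,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        },
        "digest": {
            "cut_sites_total": len(sites),
            "cut_sites_per_enzyme": per_enzyme,
            "fragment_count": len(fragments),
            "mean_fragment_length": genome.total_length / len(fragments),
        },
        "prediction": {
            "fragment_count": prediction.fragment_count,
            "captured_bases": prediction.captured_bases,
            "genome_length": prediction.genome_length,
            "coverage_fraction": prediction.coverage_fraction,
            "pair_counts": prediction.pair_counts,
            "per_sequence": prediction.per_sequence,
        },
        "budget": budget_dict,
        "pair_proportions": prediction.pair_proportions,
    }
    if budget_dict is None:
        raise RuntimeError(
            "no fragments selected under this design; budget undefined"
        )
    with open(outdir / "design_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    validate_report(report)
    return report


def load_schema() -> dict:
    with resources.as_file(
        resources.files("gbs3d.data") / "design_report.schema.json"
    ) as p:
        with open(p) as fh:
            return json.load(fh)


_TYPE_MAP = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}


def _check(value, schema: dict, path: str, errors: list[str]) -> None:
    """Minimal structural validator (required keys + types) for the report
    schema; covers the subset of JSON Schema the shipped schema uses."""
    stype = schema.get("type")
    if stype is not None:
        types = stype if isinstance(stype, list) else [stype]
        pytypes = tuple(
            t for name in types for t in (
                _TYPE_MAP[name] if isinstance(_TYPE_MAP[name], tuple) else (_TYPE_MAP[name],)
            )
        )
        if not isinstance(value, pytypes) or (
            isinstance(value, bool) and "boolean" not in types
        ):
            errors.append(f"{path}: expected {types}, got {type(value).__name__}")
            return
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _check(value[key], sub, f"{path}.{key}", errors)
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _check(item, schema["items"], f"{path}[{i}]", errors)


def validate_report(report: dict, schema: Optional[dict] = None) -> None:
    """Raise ValueError if the report does not conform to the design-report
    schema (required keys and types)."""
    errors: list[str] = []
    _check(report, schema or load_schema(), "$", errors)
    if errors:
        raise ValueError("report schema violations: " + "; ".join(errors))
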