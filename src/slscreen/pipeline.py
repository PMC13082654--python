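"""End-to-end orchestration: discretize → context → enumerate → screen → report.

A run is described by a :class:`RunConfig` (usually parsed from YAML) naming
the base model, one cancer expression matrix, an ordered list of protected
non-tumor expression matrices, and the thresholds.  ``run_pipeline`` chains
the stages, writes every intermediate artifact as a TSV and a JSON manifest
(config hash, seed, per-stage counts), and is deterministic: the same config
and seed produce byte-identical outputs.  No stage mutates an upstream
artifact, so a run can be resumed from any stage given its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import expr_discretize as xd
from .context_build import ContextModel, build_context, map_scores_to_reactions
from .errors import ConfigurationError
from .model_core import MetabolicNetwork, read_model
from .select_screen import (
    cooccurrence_edges,
    gene_frequency,
    percentage_selective,
    protection_curve,
    screen,
    selectivity_table,
)
from .sl_enum import SLSet, enumerate_sl, essential_genes, sl_table

log = logging.getLogger("slscreen")

FLOAT_FORMAT = "%.6f"


@dataclass
class ContextSpec:
    label: str
    expression_path: Path


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    model_path: Path
    model_dialect: str | None
    cancer: ContextSpec
    protected: list[ContextSpec]  # order defines the protection sequence
    lethal_threshold: float = 0.5
    safe_threshold: float = 0.1
    zfpkm_floor: float = -3.0
    expression_threshold_z: float = 0.0
    active_fraction: float = 0.9
    inactive_fraction: float = 0.9
    max_order: int = 4
    seed: int = 0
    outdir: Path = Path("slscreen_out")

    def validate(self) -> None:
        if self.max_order not in (1, 2, 3, 4):
            raise ConfigurationError(f"max_order must be in 1..4, got {self.max_order}")
        for name, value in (
            ("lethal_threshold", self.lethal_threshold),
            ("safe_threshold", self.safe_threshold),
        ):
            if not 0.0 < value < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {value}")
        if not self.zfpkm_floor <= self.expression_threshold_z:
            raise ConfigurationError("zfpkm_floor must not exceed the expression threshold")
        for name, frac in (
            ("active_fraction", self.active_fraction),
            ("inactive_fraction", self.inactive_fraction),
        ):
            if not 0.5 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0.5, 1], got {frac}")
        if not self.protected:
            raise ConfigurationError("at least one protected context is required")
        for path in [self.model_path, self.cancer.expression_path] + [
            c.expression_path for c in self.protected
        ]:
            if not Path(path).exists():
                raise ConfigurationError(f"input path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        try:
            model = doc["model"]
            cancer = doc["cancer"]
            protected = doc["protected"]
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"{path.name}: missing section {exc}") from exc
        base = path.parent

        def resolve(p: str) -> Path:
            candidate = Path(p)
            return candidate if candidate.is_absolute() else base / candidate

        thresholds = doc.get("thresholds", {})
        consensus = doc.get("consensus", {})
        config = cls(
            model_path=resolve(model["path"]),
            model_dialect=model.get("dialect"),
            cancer=ContextSpec(cancer["label"], resolve(cancer["expression"])),
            protected=[
                ContextSpec(entry["label"], resolve(entry["expression"]))
                for entry in protected
            ],
            lethal_threshold=float(thresholds.get("lethal", 0.5)),
            safe_threshold=float(thresholds.get("safe", 0.1)),
            zfpkm_floor=float(thresholds.get("zfpkm_floor", -3.0)),
            expression_threshold_z=float(thresholds.get("expression_threshold", 0.0)),
            active_fraction=float(consensus.get("active_fraction", 0.9)),
            inactive_fraction=float(consensus.get("inactive_fraction", 0.9)),
            max_order=int(doc.get("max_order", 4)),
            seed=int(doc.get("seed", 0)),
            outdir=Path(doc.get("outdir", "slscreen_out")),
        )
        config.validate()
        return config

    def canonical(self) -> dict[str, Any]:
        return {
            "model_path": str(self.model_path),
            "model_dialect": self.model_dialect,
            "cancer": {"label": self.cancer.label, "expression": str(self.cancer.expression_path)},
            "protected": [
                {"label": c.label, "expression": str(c.expression_path)}
                for c in self.protected
            ],
            "lethal_threshold": self.lethal_threshold,
            "safe_threshold": self.safe_threshold,
            "zfpkm_floor": self.zfpkm_floor,
            "expression_threshold_z": self.expression_threshold_z,
            "active_fraction": self.active_fraction,
            "inactive_fraction": self.inactive_fraction,
            "max_order": self.max_order,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def _discretize_context(
    config: RunConfig, spec: ContextSpec, outdir: Path
) -> pd.Series:
    expression = xd.load_expression(spec.expression_path)
    scores, _ = xd.discretize_matrix(expression, floor_z=config.zfpkm_floor)
    consensus = xd.consensus_scores(
        scores, config.active_fraction, config.inactive_fraction
    )
    _write_tsv(scores, outdir / f"scores_{spec.label}.tsv")
    _write_tsv(consensus.to_frame(), outdir / f"consensus_{spec.label}.tsv")
    return consensus


def _build_one_context(
    network: MetabolicNetwork, consensus: pd.Series, label: str, condition: str
) -> ContextModel:
    reaction_scores = map_scores_to_reactions(network, consensus.to_dict())
    return build_context(network, reaction_scores, label, condition)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage in order and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }

    def stage(name: str, **counts) -> None:
        log.info("stage %-12s %s", name, counts)
        manifest["stages"].append({"name": name, **counts})

    t0 = time.monotonic()
    network = read_model(config.model_path, config.model_dialect)
    stage(
        "load_model",
        reactions=len(network.reaction_ids),
        genes=len(network.gene_ids),
        seconds=round(time.monotonic() - t0, 3),
    )

    contexts: dict[str, ContextModel] = {}
    for spec, condition in [(config.cancer, "cancer")] + [
        (c, "non_tumor") for c in config.protected
    ]:
        t0 = time.monotonic()
        consensus = _discretize_context(config, spec, outdir)
        model_genes = set(network.gene_ids)
        consensus = consensus[consensus.index.isin(model_genes)]
        contexts[spec.label] = _build_one_context(
            network, consensus, spec.label, condition
        )
        stage(
            f"context:{spec.label}",
            inactive_reactions=len(contexts[spec.label].deactivated_reactions),
            blocked=len(contexts[spec.label].blocked_removed),
            wild_type_growth=round(contexts[spec.label].wild_type_growth, 6),
            seconds=round(time.monotonic() - t0, 3),
        )

    summary = pd.DataFrame(
        [
            {
                "label": c.label,
                "condition": c.condition,
                "wild_type_growth": c.wild_type_growth,
                "n_inactive": len(c.deactivated_reactions),
                "n_blocked": len(c.blocked_removed),
            }
            for c in contexts.values()
        ]
    )
    _write_tsv(summary, outdir / "context_summary.tsv", index=False)

    cancer = contexts[config.cancer.label]
    protected = [contexts[c.label] for c in config.protected]

    t0 = time.monotonic()
    candidates: list[SLSet] = essential_genes(cancer, config.lethal_threshold)
    if config.max_order >= 2:
        candidates = candidates + enumerate_sl(
            cancer, config.max_order, config.lethal_threshold
        )
    _write_tsv(sl_table(candidates), outdir / "sl_sets.tsv", index=False)
    stage(
        "enumerate_sl",
        candidates=len(candidates),
        seconds=round(time.monotonic() - t0, 3),
    )

    t0 = time.monotonic()
    records = screen(
        candidates, cancer, protected, config.lethal_threshold, config.safe_threshold
    )
    _write_tsv(selectivity_table(records), outdir / "selectivity.tsv", index=False)
    n_selective = sum(r.strictly_selective for r in records)
    stage(
        "screen",
        candidates=len(records),
        strictly_selective=n_selective,
        seconds=round(time.monotonic() - t0, 3),
    )

    curve = protection_curve(
        candidates, cancer, protected, config.lethal_threshold, config.safe_threshold
    )
    _write_tsv(curve.to_frame(), outdir / "protection_curve.tsv")

    per_order = pd.DataFrame(
        [
            {
                "order": order,
                "lethal": sum(1 for r in records if r.order == order),
                "strictly_selective": sum(
                    1 for r in records if r.order == order and r.strictly_selective
                ),
                "percent_selective": _format_percent(
                    sum(1 for r in records if r.order == order),
                    sum(1 for r in records if r.order == order and r.strictly_selective),
                ),
            }
            for order in range(1, config.max_order + 1)
        ]
    )
    _write_tsv(per_order, outdir / "selectivity_summary.tsv", index=False)

    frequency = gene_frequency(records)
    _write_tsv(frequency.to_frame(), outdir / "gene_frequency.tsv")
    edges = pd.DataFrame(
        cooccurrence_edges(records),
        columns=["gene_a", "gene_b", "order", "cancer"],
    )
    _write_tsv(edges, outdir / "cooccurrence.tsv", index=False)
    stage("report", genes=len(frequency), edges=len(edges))

    manifest["outputs"] = sorted(p.name for p in outdir.glob("*.tsv"))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def _format_percent(lethal: int, selective: int) -> str:
    percent = percentage_selective(lethal, selective)
    return "NA" if percent is None else f"{percent:.1f}"
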