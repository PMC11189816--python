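"""End-to-end orchestration: read -> filter -> map -> call -> signatures -> quant.

Every run writes its tables plus a manifest (input hashes, config snapshot,
package version, output hashes) and a run log, so reruns with identical
inputs are byte-comparable.  Any stage failure removes partial outputs and
re-raises with a located diagnostic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .filtering import (
    fdr_filter,
    quality_filter,
    rt_reliability_filter,
    write_filter_report,
)
from .io import read_observations, read_precursors
from .mapping import map_observations, write_mapping_table
from .presence import build_presence_matrix
from .quant import quantify
from .signatures import build_signature_report
from .types import ConfigError, FilterConfig, StudyDesign, default_design

logger = logging.getLogger("neuropep")


@dataclass
class PipelineConfig:
    observations: Path
    precursors: Path
    out_dir: Path
    filters: FilterConfig = field(default_factory=FilterConfig)
    design: StudyDesign = field(default_factory=default_design)
    enable_fdr: bool = False
    paired: bool = False
    bh: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.observations = Path(self.observations)
        self.precursors = Path(self.precursors)
        self.out_dir = Path(self.out_dir)

    def validate_paths(self) -> None:
        if not self.observations.exists():
            raise ConfigError(f"observation table not found: {self.observations}")
        if not self.precursors.exists():
            raise ConfigError(f"precursor FASTA not found: {self.precursors}")

    def snapshot(self) -> dict:
        return {
            "observations": str(self.observations),
            "precursors": str(self.precursors),
            "out_dir": str(self.out_dir),
            "filters": dataclasses.asdict(self.filters),
            "design": {
                "groups": self.design.groups,
                "n_culture_reps": self.design.n_culture_reps,
                "n_tech_reps": self.design.n_tech_reps,
                "conditions": list(self.design.conditions),
                "group_presence_threshold": self.design.group_presence_threshold,
                "tech_threshold": self.design.tech_threshold,
                "culture_threshold": self.design.culture_threshold,
            },
            "enable_fdr": self.enable_fdr,
            "paired": self.paired,
            "bh": self.bh,
            "seed": self.seed,
        }


def config_from_yaml(path: str | Path, **overrides) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file; keyword overrides win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    filters = FilterConfig(**raw.pop("filters", {}))
    design_raw = raw.pop("design", None)
    design = StudyDesign(**design_raw) if design_raw else default_design()
    try:
        return PipelineConfig(filters=filters, design=design, **raw)
    except TypeError as exc:
        raise ConfigError(f"bad pipeline configuration: {exc}") from None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages and return the output directory."""
    config.validate_paths()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    created.append(log_path)

    try:
        input_hashes = {
            "observations": _sha256(config.observations),
            "precursors": _sha256(config.precursors),
        }
        report = read_observations(config.observations, design=config.design)
        observations = report.observations
        logger.info("read %d observations", len(observations))
        precursors = read_precursors(config.precursors)
        logger.info("read %d precursors", len(precursors))

        stage_reports = []
        if config.enable_fdr:
            observations, cutoff, fdr_report = fdr_filter(
                observations, config.filters.fdr_max
            )
            stage_reports.append(fdr_report)
            logger.info("FDR gate: cutoff %.4g, %d rows retained", cutoff, len(observations))
        else:
            # decoys (if labelled) never pass downstream even without the gate
            n0 = len(observations)
            observations = [o for o in observations if not o.is_decoy]
            if len(observations) != n0:
                logger.info("dropped %d labelled decoy rows", n0 - len(observations))

        observations, q_report = quality_filter(observations, config.filters)
        stage_reports.append(q_report)
        logger.info("quality gate: %d rows retained", len(observations))
        observations, rt_report = rt_reliability_filter(observations, config.filters)
        stage_reports.append(rt_report)
        logger.info("RT reliability gate: %d rows retained", len(observations))

        filter_path = out / "filter_report.tsv"
        write_filter_report(stage_reports, filter_path)
        created.append(filter_path)

        mapping, unmapped = map_observations(observations, precursors)
        logger.info("mapped %d distinct peptides (%d unmapped)", len(mapping), len(unmapped))
        mapping_path = out / "mapping.tsv"
        write_mapping_table(sorted(mapping.values(), key=lambda m: m.key), mapping_path)
        created.append(mapping_path)
        if unmapped:
            unmapped_path = out / "unmapped.txt"
            unmapped_path.write_text("\n".join(sorted(unmapped)) + "\n")
            created.append(unmapped_path)

        matrix = build_presence_matrix(observations, mapping, config.design)
        matrix.check()
        logger.info("presence matrix: %d peptides", len(matrix.peptides))
        matrix_path = out / "presence_matrix.tsv"
        matrix.to_tsv(matrix_path)
        created.append(matrix_path)
        detail_path = out / "subject_detail.tsv"
        matrix.subject_detail_frame().to_csv(detail_path, sep="\t", index=False)
        created.append(detail_path)

        signatures = build_signature_report(matrix)
        sig_path = out / "signature_report.json"
        signatures.to_json(sig_path)
        created.append(sig_path)
        for condition, tally in signatures.tallies.items():
            tally_path = out / f"tally_{condition}.tsv"
            tally.to_csv(tally_path, sep="\t", index=False)
            created.append(tally_path)

        quant = quantify(
            observations,
            mapping,
            matrix,
            config.design,
            paired=config.paired,
            bh=config.bh,
        )
        quant_path = out / "quant.tsv"
        quant.to_csv(quant_path, sep="\t", index=False)
        created.append(quant_path)

        manifest = {
            "version": __version__,
            "config": config.snapshot(),
            "inputs": input_hashes,
            "outputs": {
                p.name: _sha256(p) for p in created if p != log_path
            },
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("wrote %d outputs to %s", len(created), out)
        return out
    except Exception:
        for p in created:
            if p.exists() and p != log_path:
                p.unlink()
        logger.exception("pipeline failed; partial outputs removed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
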