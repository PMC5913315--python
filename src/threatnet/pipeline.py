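"""Config-driven end-to-end runs.

One pipeline run: load or simulate records -> map threat codes -> partition
into extinct / threatened -> region-eligibility screen -> optional
harsh-impact screen -> build the three network kinds per partition ->
summaries, association tallies, top-N combinations, and per-group
breakdowns -> export networks and tables, plus a manifest listing every
artifact with its row/node/edge counts. Runs are deterministic: identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import filtering, io, stats, synthetic
from .model import SpeciesRecord, ThreatClassScheme, ValidationError
from .networks import build_group_threat_network, build_species_threat_network, export_network

log = logging.getLogger("threatnet")


@dataclass
class PipelineConfig:
    """Settings of one run; exactly one of ``input_path`` / ``synthetic``
    must be present."""

    output_dir: str | Path
    input_path: str | Path | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    scheme_path: str | Path | None = None
    min_assessed: int = 50
    harsh_filter: bool = False
    harsh_retain_all_threats: bool = True
    current_timing_only: bool = False
    export_formats: tuple[str, ...] = ("edgelist_csv", "gexf")
    top_n: int = 10
    rounding: int = 1

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValidationError("config needs exactly one of input_path / synthetic")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        cfg = cls(**{**raw, "synthetic": synthetic.SyntheticConfig(**syn) if syn else None})
        cfg.export_formats = tuple(cfg.export_formats)
        return cfg


def _round_or_none(x: float | None, nd: int) -> float | None:
    return None if x is None else round(x, nd)


def _partition_outputs(
    name: str,
    records: list[SpeciesRecord],
    scheme: ThreatClassScheme,
    cfg: PipelineConfig,
    outdir: Path,
    manifest: dict,
    region_coords: dict,
) -> None:
    nets = {
        "species": build_species_threat_network(records, scheme),
        "taxa": build_group_threat_network(records, scheme, "taxon"),
        "regions": build_group_threat_network(records, scheme, "region", region_coords),
    }
    for label, net in nets.items():
        for fmt in cfg.export_formats:
            ext = {"edgelist_csv": "csv", "gexf": "gexf", "graphml": "graphml"}[fmt]
            path = outdir / f"{name}_{label}_network.{ext}"
            export_network(net, path, fmt, scheme)
            manifest["artifacts"].append(
                {"path": path.name, "partition": name, "network": label, "format": fmt,
                 "n_nodes": net.n_nodes, "n_entity_nodes": len(net.entity_nodes),
                 "n_edges": net.n_edges}
            )
    summary = stats.summarize_network(nets["species"])
    tally = stats.association_tally(records, scheme)
    top = stats.top_combinations(tally, cfg.top_n)
    report = {
        "summary": stats.summary_as_dict(summary, scheme),
        "single_share": tally.single_share,
        "association_share": tally.association_share,
        "n_single_combos": tally.n_single_combos,
        "n_association_combos": tally.n_association_combos,
        "top_combinations": [
            {"classes": [scheme.class_name(c) for c in combo], "count": count, "share": share}
            for combo, count, share in top
        ],
    }
    (outdir / f"{name}_report.json").write_text(json.dumps(report, indent=1) + "\n")
    manifest["artifacts"].append({"path": f"{name}_report.json", "partition": name, "format": "json"})
    for group_by in ("taxon", "region", "status"):
        table = stats.breakdown_table(stats.group_breakdown(records, scheme, group_by), scheme)
        path = outdir / f"{name}_by_{group_by}.csv"
        table.round(6).to_csv(path, index=False)
        manifest["artifacts"].append(
            {"path": path.name, "partition": name, "format": "csv", "rows": len(table)}
        )
    log.info(
        "partition %s: %d species, %d edges, mean threats/species %s",
        name, summary.n_entity_nodes, summary.n_edges,
        _round_or_none(summary.mean_threats_per_species, cfg.rounding),
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute a full run; returns the manifest (also written to
    ``manifest.json`` in the output directory). Any stage error removes
    partial outputs and re-raises."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = io.load_scheme(cfg.scheme_path) if cfg.scheme_path else io.default_scheme()
    region_coords = io.default_region_coords()
    manifest: dict = {"artifacts": [], "filters": []}
    try:
        if cfg.synthetic is not None:
            records = synthetic.simulate_dataset(cfg.synthetic, scheme)
            canonical = outdir / "records.csv"
            io.write_species_table(records, canonical)
            manifest["artifacts"].append({"path": "records.csv", "format": "csv", "rows": len(records)})
        else:
            records = io.load_species_table(cfg.input_path)
        manifest["n_records"] = len(records)

        regions = filtering.eligible_regions(records, cfg.min_assessed)
        records, report = filtering.restrict_to_regions(records, regions)
        manifest["filters"].append(report.as_row())

        if cfg.current_timing_only:
            n0 = len(records)
            records = filtering.filter_current_timing(records)
            manifest["filters"].append(
                {"rule": "current_timing_only", "input_count": n0, "output_count": len(records)}
            )
        if cfg.harsh_filter:
            n0 = len(records)
            records = filtering.filter_harsh_impact(records, cfg.harsh_retain_all_threats)
            manifest["filters"].append(
                {"rule": "harsh_impact", "input_count": n0, "output_count": len(records)}
            )

        extinct, threatened = filtering.partition_by_status(records)
        manifest["n_extinct"] = len(extinct)
        manifest["n_threatened"] = len(threatened)
        for name, part in (("extinct", extinct), ("threatened", threatened)):
            _partition_outputs(name, part, scheme, cfg, outdir, manifest, region_coords)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
        return manifest
    except Exception:
        # remove partial outputs so a failed run leaves no half-written state
        for entry in manifest["artifacts"]:
            (outdir / entry["path"]).unlink(missing_ok=True)
        raise
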