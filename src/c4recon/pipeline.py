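"""Pipeline orchestration: reconstruct -> overlay -> consolidated report.

The report bundle ties together the reconstruction summary statistics, the
omics coverage table, per-panel color summaries, and the transcript-protein
correlation, with full config provenance.  All outputs land inside the
configured output directory; the timestamp is isolated to a single report
field so determinism checks can mask it.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .homology import (
    DEFAULT_MAX_EVALUE,
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_IDENTITY,
    best_hits,
    lift_model,
    read_hit_table,
)
from .model import (
    build_stoich_matrix,
    collapse_entries,
    read_core_model,
    reconstruction_stats,
    write_core_model,
    write_mtx,
    write_sbml,
)
from .omics import read_expression_table, read_metabolite_table, read_protein_table
from .overlay import (
    DEFAULT_ALPHA,
    DEFAULT_LFC_THRESHOLD,
    assemble_pathway_report,
    coverage_stats,
    load_panels,
    map_omics_to_network,
    matched_lfc_pairs,
    mrna_protein_correlation,
    write_overlay_tsv,
)

SCHEMA_VERSION = "1.0"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for error reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    core: str | None = None
    hits: str | None = None
    expression: str | None = None
    proteome: str | None = None
    metabolome: str | None = None
    panels: str | None = None
    outdir: str = "report"
    max_evalue: float = DEFAULT_MAX_EVALUE
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_coverage: float = DEFAULT_MIN_COVERAGE
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    moderated: bool = True  # proteome test mode
    n_coding_genes: int | None = None
    require_proteome: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.lfc_threshold < 0 or self.min_identity < 0 or self.min_coverage < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(stage: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:  # surface with the stage tag
            raise StageError(stage, str(exc)) from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute reconstruct -> overlay -> stats and write the report bundle."""
    if not config.core:
        raise StageError("core", "no core model provided")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    entries = _stage("core")(read_core_model, config.core)
    provenance = f"core model {config.core}"

    lift_info = None
    if config.hits:
        def _homology():
            rows = read_hit_table(config.hits)
            gmap = best_hits(
                rows,
                max_evalue=config.max_evalue,
                min_identity=config.min_identity,
                min_coverage=config.min_coverage,
            )
            return lift_model(entries, gmap), gmap

        lift, gmap = _stage("homology")(_homology)
        lift_info = {
            "n_hit_rows": None,
            "n_mapped_target_genes": len(gmap),
            "dropped_entries": lift.dropped_entries,
            "n_unmapped_reference_genes": len(lift.unmapped_reference_genes),
        }
        model_entries = lift.entries
        provenance += (
            f"; lifted via {config.hits} (max_evalue={config.max_evalue:g}, "
            f"min_identity={config.min_identity:g}, min_coverage={config.min_coverage:g})"
        )
    else:
        model_entries = entries

    def _reconstruct():
        recon = collapse_entries(model_entries, provenance=provenance)
        sm = build_stoich_matrix(recon)
        stats = reconstruction_stats(recon, model_entries)
        write_core_model(model_entries, outdir / "lifted.tsv")
        write_sbml(recon, outdir / "model.xml")
        write_mtx(sm, outdir / "S.mtx")
        (outdir / "reconstruction_stats.json").write_text(
            json.dumps(stats, indent=2) + "\n", encoding="utf-8"
        )
        return recon, sm, stats

    recon, sm, recon_stats = _stage("reconstruct")(_reconstruct)

    expression, proteins, metabolites = [], [], []
    if config.expression:
        expression = _stage("omics")(read_expression_table, config.expression)
    if config.proteome:
        proteins = _stage("omics")(
            read_protein_table,
            config.proteome,
            test="moderated" if config.moderated else "welch",
        )
    elif config.require_proteome:
        raise StageError("omics", "proteome input required but not provided")
    if config.metabolome:
        metabolites = _stage("omics")(read_metabolite_table, config.metabolome)

    def _overlay():
        overlays = map_omics_to_network(
            recon,
            expression,
            proteins,
            metabolites,
            lfc_threshold=config.lfc_threshold,
            alpha=config.alpha,
        )
        write_overlay_tsv(overlays, outdir / "overlay.tsv")
        return overlays

    overlays = _stage("overlay")(_overlay)

    n_coding = config.n_coding_genes if config.n_coding_genes else len(expression)
    coverage = _stage("stats")(
        coverage_stats, recon, expression, proteins, metabolites, n_coding, config.alpha
    )
    (outdir / "coverage_stats.json").write_text(
        json.dumps(coverage.as_dict(), indent=2) + "\n", encoding="utf-8"
    )

    panel_summaries = {}
    if config.panels:
        def _panels():
            panels = load_panels(config.panels)
            rows, summaries = assemble_pathway_report(panels, overlays, recon)
            import csv

            with open(outdir / "pathway_report.tsv", "w", encoding="utf-8", newline="") as fh:
                writer = csv.DictWriter(
                    fh,
                    fieldnames=[
                        "panel", "step", "step_name", "reaction_id", "compartment",
                        "cell_type", "color", "display", "contributors",
                    ],
                    delimiter="\t",
                    lineterminator="\n",
                )
                writer.writeheader()
                writer.writerows(rows)
            return summaries

        panel_summaries = _stage("panels")(_panels)

    correlation = None
    if expression and proteins:
        pairs = matched_lfc_pairs(expression, proteins)
        if len(pairs) >= 3:
            r, rho, n = _stage("correlation")(mrna_protein_correlation, pairs)
            correlation = {"pearson_r": r, "spearman_rho": rho, "n_pairs": n}

    report = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "config": config.as_dict(),
        "seed": config.seed,
        "reconstruction_stats": recon_stats,
        "stoich_matrix": {"shape": list(sm.shape), "nnz": sm.nnz},
        "homology_lift": lift_info,
        "coverage_stats": coverage.as_dict(),
        "overlay_color_counts": overlays.color_counts(),
        "n_unmapped": {
            "genes": len(overlays.unmapped_genes),
            "proteins": len(overlays.unmapped_proteins),
            "metabolites": len(overlays.unmapped_metabolites),
        },
        "panel_summaries": panel_summaries,
        "mrna_protein_correlation": correlation,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report


def validate_inputs(config: RunConfig) -> list[dict]:
    """Per-file pass/fail with diagnostics; never mutates anything."""
    checks = []

    def check(name, path, reader):
        if path is None:
            return
        try:
            reader(path)
            checks.append({"file": str(path), "kind": name, "status": "pass", "error": None})
        except Exception as exc:
            checks.append({"file": str(path), "kind": name, "status": "fail", "error": str(exc)})

    check("core_model", config.core, read_core_model)
    check("hit_table", config.hits, read_hit_table)
    check("expression", config.expression, read_expression_table)
    check("proteome", config.proteome, read_protein_table)
    check("metabolome", config.metabolome, read_metabolite_table)
    check("panels", config.panels, load_panels)
    return checks
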