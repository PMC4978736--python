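"""Mapping differential omics contrasts onto the reconstruction.

Every reaction inherits the transcript and protein contrasts of its GPR
genes and is classified with the four-color scheme used for pathway maps:

* green  — all significant contributors up in mature tissue,
* red    — all significant contributors down in mature tissue,
* yellow — significant contributors disagree in sign (isoforms regulated in
  opposite directions in different tissues/organelles),
* gray   — no statistically significant contributor.

A contributor is significant when its adjusted p is below ``alpha`` and its
|log2FC| exceeds the display threshold (0.5 by default); a reaction is
displayed when any contributor passes the fold-change threshold, whichever
omics layer it comes from.  Measured metabolites are colored by their linear
concentration fold change.  The module also computes the omics coverage
summary and the transcript-protein fold-change correlation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import scipy.stats
import yaml

from .model import Reconstruction, ModelValidationError
from .omics import ExpressionRecord, InsufficientDataError, MetaboliteRecord, ProteinRecord

DEFAULT_LFC_THRESHOLD = 0.5
DEFAULT_ALPHA = 0.05

COLORS = ("green", "red", "yellow", "gray")


@dataclass(frozen=True)
class Contributor:
    feature_id: str
    layer: str  # "transcript" | "protein"
    log2fc: float
    q_value: float | None

    def significant(self, lfc_threshold: float, alpha: float) -> bool:
        return (
            self.q_value is not None
            and self.q_value < alpha
            and abs(self.log2fc) > lfc_threshold
        )


def classify_reaction(
    gene_stats: Sequence[Contributor],
    protein_stats: Sequence[Contributor],
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[str, bool]:
    """Four-color call for one reaction; returns (color, display flag).

    Transcript and protein evidence are treated jointly: the union of
    significant contributors decides the color, and the display flag is set
    when either layer moved by more than the fold-change threshold.
    """
    contributors = list(gene_stats) + list(protein_stats)
    display = any(abs(c.log2fc) > lfc_threshold for c in contributors)
    sig = [c for c in contributors if c.significant(lfc_threshold, alpha)]
    if not sig:
        return "gray", display
    signs = {1 if c.log2fc > 0 else -1 for c in sig}
    if signs == {1}:
        return "green", display
    if signs == {-1}:
        return "red", display
    return "yellow", display


def classify_metabolite(
    fold_change: float, q_value: float | None, alpha: float = DEFAULT_ALPHA
) -> str:
    """Green/red/gray call for a measured metabolite (linear fold change)."""
    if q_value is None or q_value >= alpha or fold_change == 1:
        return "gray"
    return "green" if fold_change > 1 else "red"


@dataclass
class ReactionOverlay:
    reaction_key: tuple[str, str, str]
    gene_contributors: list[Contributor]
    protein_contributors: list[Contributor]
    color: str
    display: bool


@dataclass
class MetaboliteOverlay:
    metabolite_id: str
    fold_change: float
    q_value: float | None
    color: str


@dataclass
class OverlayResult:
    reactions: dict[tuple[str, str, str], ReactionOverlay]
    metabolites: dict[str, MetaboliteOverlay]
    unmapped_genes: list[str]
    unmapped_proteins: list[str]
    unmapped_metabolites: list[str]
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD
    alpha: float = DEFAULT_ALPHA

    def color_counts(self) -> dict[str, int]:
        out = {c: 0 for c in COLORS}
        for ov in self.reactions.values():
            out[ov.color] += 1
        return out


def map_omics_to_network(
    recon: Reconstruction,
    expression: Sequence[ExpressionRecord] = (),
    proteins: Sequence[ProteinRecord] = (),
    metabolites: Sequence[MetaboliteRecord] = (),
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> OverlayResult:
    """Attach omics records to reactions/metabolites and classify everything.

    Gene ids are expected pre-normalized (the readers already strip
    transcript-model suffixes).  Measured features that hit nothing in the
    network are returned in the unmapped lists.
    """
    network_genes = set(recon.genes)
    expr_by_gene = {r.gene_id: r for r in expression}
    prots_by_gene: dict[str, list[ProteinRecord]] = {}
    for p in proteins:
        prots_by_gene.setdefault(p.gene_id, []).append(p)

    overlays: dict[tuple[str, str, str], ReactionOverlay] = {}
    for r in recon.reactions:
        gene_stats, protein_stats = [], []
        for g in sorted(r.genes):
            er = expr_by_gene.get(g)
            if er is not None:
                gene_stats.append(Contributor(g, "transcript", er.log2fc, er.q_value))
            for pr in prots_by_gene.get(g, []):
                protein_stats.append(
                    Contributor(pr.protein_id, "protein", pr.log2fc, pr.q_value)
                )
        if gene_stats or protein_stats:
            color, display = classify_reaction(
                gene_stats, protein_stats, lfc_threshold, alpha
            )
        else:
            color, display = "gray", False
        overlays[r.key] = ReactionOverlay(r.key, gene_stats, protein_stats, color, display)

    network_met_ids = recon.metabolite_ids()
    met_overlays: dict[str, MetaboliteOverlay] = {}
    unmapped_mets = []
    for m in metabolites:
        if m.metabolite_id in network_met_ids:
            met_overlays[m.metabolite_id] = MetaboliteOverlay(
                m.metabolite_id,
                m.fold_change,
                m.q_value,
                classify_metabolite(m.fold_change, m.q_value, alpha),
            )
        else:
            unmapped_mets.append(m.metabolite_id)

    return OverlayResult(
        reactions=overlays,
        metabolites=met_overlays,
        unmapped_genes=sorted(g for g in expr_by_gene if g not in network_genes),
        unmapped_proteins=sorted(
            p.protein_id for p in proteins if p.gene_id not in network_genes
        ),
        unmapped_metabolites=sorted(unmapped_mets),
        lfc_threshold=lfc_threshold,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# coverage statistics


def _pct(num: int, den: int) -> int | None:
    """Integer percentage, round-half-up, exact in integer arithmetic."""
    if den == 0:
        return None
    return (200 * num + den) // (2 * den)


@dataclass
class CoverageStats:
    """Omics mapping summary: counts with integer percentages.

    Denominators: the genome's coding-gene count for "expressed"; expressed
    genes for "differentially expressed" and for both "mapped" statistics;
    identified proteins and measured metabolites for their layers.
    """

    n_coding_genes: int
    n_expressed: int
    n_de: int
    n_expressed_mapped: int
    n_de_mapped: int
    n_proteins_identified: int
    n_proteins_de: int
    n_proteins_mapped: int
    n_metabolites: int
    n_metabolites_de: int
    n_metabolites_mapped: int

    def __post_init__(self):
        pairs = [
            (self.n_expressed, self.n_coding_genes),
            (self.n_de, self.n_expressed),
            (self.n_expressed_mapped, self.n_expressed),
            (self.n_de_mapped, self.n_expressed),
            (self.n_proteins_de, self.n_proteins_identified),
            (self.n_proteins_mapped, self.n_proteins_identified),
            (self.n_metabolites_de, self.n_metabolites),
            (self.n_metabolites_mapped, self.n_metabolites),
        ]
        for num, den in pairs:
            if num < 0 or num > den:
                raise ValueError(f"count pair ({num}, {den}) violates numerator <= denominator")

    @property
    def pct_expressed(self) -> int | None:
        return _pct(self.n_expressed, self.n_coding_genes)

    @property
    def pct_de(self) -> int | None:
        return _pct(self.n_de, self.n_expressed)

    @property
    def pct_expressed_mapped(self) -> int | None:
        return _pct(self.n_expressed_mapped, self.n_expressed)

    @property
    def pct_de_mapped(self) -> int | None:
        return _pct(self.n_de_mapped, self.n_expressed)

    @property
    def pct_proteins_de(self) -> int | None:
        return _pct(self.n_proteins_de, self.n_proteins_identified)

    @property
    def pct_metabolites_de(self) -> int | None:
        return _pct(self.n_metabolites_de, self.n_metabolites)

    def as_dict(self) -> dict:
        return {
            "transcriptome": {
                "protein_coding_genes": self.n_coding_genes,
                "genes_expressed": self.n_expressed,
                "pct_expressed": self.pct_expressed,
                "genes_differentially_expressed": self.n_de,
                "pct_differentially_expressed": self.pct_de,
                "genes_expressed_mapped": self.n_expressed_mapped,
                "pct_expressed_mapped": self.pct_expressed_mapped,
                "genes_de_mapped": self.n_de_mapped,
                "pct_de_mapped": self.pct_de_mapped,
            },
            "proteome": {
                "proteins_identified": self.n_proteins_identified,
                "proteins_differentially_abundant": self.n_proteins_de,
                "pct_differentially_abundant": self.pct_proteins_de,
                "proteins_mapped": self.n_proteins_mapped,
            },
            "metabolome": {
                "metabolites_measured": self.n_metabolites,
                "metabolites_differentially_abundant": self.n_metabolites_de,
                "pct_differentially_abundant": self.pct_metabolites_de,
                "metabolites_mapped": self.n_metabolites_mapped,
            },
        }


def coverage_stats(
    recon: Reconstruction,
    expression: Sequence[ExpressionRecord],
    proteins: Sequence[ProteinRecord],
    metabolites: Sequence[MetaboliteRecord],
    n_coding_genes: int,
    alpha: float = DEFAULT_ALPHA,
) -> CoverageStats:
    """Compute the omics-mapping summary against the reconstruction.

    A gene counts as expressed when any FPKM replicate is positive (or
    unconditionally for externally computed records without replicate
    values); differential calls require adjusted p < ``alpha``.
    """
    network_genes = set(recon.genes)
    network_mets = recon.metabolite_ids()

    def _expressed(r: ExpressionRecord) -> bool:
        reps = r.fpkm_mature + r.fpkm_immature
        return (max(reps) > 0) if reps else True

    expressed = [r for r in expression if _expressed(r)]
    if n_coding_genes < len(expressed):
        raise ValueError("n_coding_genes must be >= number of expressed genes")
    de = [r for r in expressed if r.q_value is not None and r.q_value < alpha]
    prot_de = [p for p in proteins if p.q_value is not None and p.q_value < alpha]
    met_de = [m for m in metabolites if m.q_value is not None and m.q_value < alpha]
    return CoverageStats(
        n_coding_genes=n_coding_genes,
        n_expressed=len(expressed),
        n_de=len(de),
        n_expressed_mapped=sum(r.gene_id in network_genes for r in expressed),
        n_de_mapped=sum(r.gene_id in network_genes for r in de),
        n_proteins_identified=len(proteins),
        n_proteins_de=len(prot_de),
        n_proteins_mapped=sum(p.gene_id in network_genes for p in proteins),
        n_metabolites=len(metabolites),
        n_metabolites_de=len(met_de),
        n_metabolites_mapped=sum(m.metabolite_id in network_mets for m in metabolites),
    )


# ---------------------------------------------------------------------------
# transcript-protein correlation


def mrna_protein_correlation(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float, float, int]:
    """Pearson r and Spearman rho over matched (transcript, protein) log2FCs."""
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"need >= 3 matched transcript/protein pairs, got {len(pairs)}"
        )
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    r = scipy.stats.pearsonr(x, y).statistic
    rho = scipy.stats.spearmanr(x, y).statistic
    return float(r), float(rho), len(pairs)


def matched_lfc_pairs(
    expression: Sequence[ExpressionRecord], proteins: Sequence[ProteinRecord]
) -> list[tuple[float, float]]:
    """Gene-matched (transcript log2FC, protein log2FC) pairs, sorted by gene."""
    expr = {r.gene_id: r.log2fc for r in expression}
    pairs = []
    for p in sorted(proteins, key=lambda p: (p.gene_id, p.protein_id)):
        if p.gene_id in expr:
            pairs.append((expr[p.gene_id], p.log2fc))
    return pairs


# ---------------------------------------------------------------------------
# pathway panels


@dataclass
class PanelStep:
    step: int
    name: str
    reaction_ids: list[str]


@dataclass
class PathwayPanel:
    """A numbered enzyme-step listing for one pathway map panel."""

    name: str
    steps: list[PanelStep] = field(default_factory=list)


def load_panels(path) -> list[PathwayPanel]:
    """Read pathway panel definitions from YAML (panels are data, not code)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    panels = []
    for p in doc.get("panels", []):
        steps = [
            PanelStep(
                step=int(s["step"]),
                name=str(s.get("name", "")),
                reaction_ids=[str(r) for r in s["reactions"]],
            )
            for s in p.get("steps", [])
        ]
        panels.append(PathwayPanel(name=str(p["name"]), steps=steps))
    return panels


def validate_panels(panels: Iterable[PathwayPanel], recon: Reconstruction) -> None:
    known = {r.reaction_id for r in recon.reactions}
    for panel in panels:
        for s in panel.steps:
            missing = [rid for rid in s.reaction_ids if rid not in known]
            if missing:
                raise ModelValidationError(
                    f"panel {panel.name!r} step {s.step}: unknown reaction(s) "
                    f"{', '.join(missing)}"
                )


def assemble_pathway_report(
    panels: Sequence[PathwayPanel],
    overlays: OverlayResult,
    recon: Reconstruction,
) -> tuple[list[dict], dict[str, dict[str, int]]]:
    """Tabular pathway report: ordered step rows plus per-panel color counts."""
    validate_panels(panels, recon)
    by_rid: dict[str, list] = {}
    for key, ov in overlays.reactions.items():
        by_rid.setdefault(key[0], []).append(ov)

    rows = []
    summaries: dict[str, dict[str, int]] = {}
    for panel in panels:
        counts = {c: 0 for c in COLORS}
        for s in panel.steps:
            for rid in s.reaction_ids:
                for ov in sorted(by_rid.get(rid, []), key=lambda o: o.reaction_key):
                    contribs = ov.gene_contributors + ov.protein_contributors
                    rows.append(
                        {
                            "panel": panel.name,
                            "step": s.step,
                            "step_name": s.name,
                            "reaction_id": ov.reaction_key[0],
                            "compartment": ov.reaction_key[1],
                            "cell_type": ov.reaction_key[2],
                            "color": ov.color,
                            "display": ov.display,
                            "contributors": ";".join(
                                f"{c.layer}:{c.feature_id}:{c.log2fc:.3f}"
                                + (f":q={c.q_value:.3g}" if c.q_value is not None else "")
                                for c in contribs
                            ),
                        }
                    )
                    counts[ov.color] += 1
        summaries[panel.name] = counts
    return rows, summaries


def write_overlay_tsv(overlays: OverlayResult, path) -> None:
    """One row per reaction with its color, display flag, and contributors."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["reaction_id", "compartment", "cell_type", "color", "display", "contributors"]
        )
        for key in sorted(overlays.reactions):
            ov = overlays.reactions[key]
            contribs = ov.gene_contributors + ov.protein_contributors
            writer.writerow(
                [
                    key[0],
                    key[1],
                    key[2],
                    ov.color,
                    "true" if ov.display else "false",
                    ";".join(
                        f"{c.layer}:{c.feature_id}:{c.log2fc:.3f}"
                        + (f":q={c.q_value:.3g}" if c.q_value is not None else "")
                        for c in contribs
                    ),
                ]
            )
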