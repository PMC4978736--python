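"""Synthetic study universes with planted ground truth.

Every pipeline input can be generated offline with a known answer sheet: a
toy gene-centric core model (with a recognizable C4 carbon-shuttle backbone
plus generic pathway chains), a best-hit table deriving a target genome from
the reference genes, and mature-vs-immature omics tables with planted
differential structure.  The ledger/truth objects record exactly what was
planted so recovery is checkable.

Noise models are the simplest ones matching each platform's scale
conventions: multiplicative log-normal replicate noise for FPKM and
metabolite concentrations, additive Gaussian noise on log2 isobaric-label
ratios.  All randomness flows from explicit seeds; regeneration with the
same seed is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .homology import GeneMap, HitRow, best_hits, write_hit_table
from .model import (
    AssociationEntry,
    Reconstruction,
    StoichTerm,
    RECON_SUMMARY_FIELDS,
    collapse_entries,
    write_core_model,
)

#: canonical C4 carbon-shuttle reactions used as the head of every toy model,
#: so that shipped pathway-panel definitions resolve against generated models
_C4_BACKBONE = [
    # (reaction_id, name, ec, compartment, stoich terms, reversible, step enzyme)
    ("R_PEPC", "PEP carboxylase", "4.1.1.31", "cytosol",
     [("pep", -1), ("hco3", -1), ("oaa", 1), ("pi", 1)], False),
    ("R_NADP_MDH", "NADP-malate dehydrogenase", "1.1.1.82", "plastid",
     [("oaa", -1), ("nadph", -1), ("mal", 1), ("nadp", 1)], True),
    ("R_NADP_ME", "NADP-malic enzyme", "1.1.1.40", "plastid",
     [("mal", -1), ("nadp", -1), ("pyr", 1), ("co2", 1), ("nadph", 1)], False),
    ("R_PPDK", "pyruvate,Pi dikinase", "2.7.9.1", "plastid",
     [("pyr", -1), ("atp", -1), ("pi", -1), ("pep", 1), ("amp", 1), ("ppi", 1)], False),
    ("R_RUBISCO", "Rubisco (carboxylation)", "4.1.1.39", "plastid",
     [("co2", -1), ("rubp", -1), ("pga", 2)], False),
    ("R_NAD_MDH", "NAD-malate dehydrogenase", "1.1.1.37", "mitochondrion",
     [("oaa", -1), ("nadh", -1), ("mal", 1), ("nad", 1)], True),
    ("R_NAD_ME", "NAD-malic enzyme", "1.1.1.39", "mitochondrion",
     [("mal", -1), ("nad", -1), ("pyr", 1), ("co2", 1), ("nadh", 1)], False),
    ("R_AAT", "aspartate aminotransferase", "2.6.1.1", "cytosol",
     [("oaa", -1), ("glu", -1), ("asp", 1), ("akg", 1)], True),
    ("R_ALAAT", "alanine aminotransferase", "2.6.1.2", "cytosol",
     [("pyr", -1), ("glu", -1), ("ala", 1), ("akg", 1)], True),
]

DEFAULT_PANELS_YAML = """\
# Pathway panel definitions: numbered enzyme steps per C4 subtype panel.
panels:
  - name: "C4 NADP-ME"
    steps:
      - {step: 1, name: "PEP carboxylase", reactions: [R_PEPC]}
      - {step: 2, name: "NADP-malate dehydrogenase", reactions: [R_NADP_MDH]}
      - {step: 3, name: "NADP-malic enzyme", reactions: [R_NADP_ME]}
      - {step: 4, name: "Pyruvate-Pi dikinase", reactions: [R_PPDK]}
      - {step: 5, name: "Rubisco (carboxylation)", reactions: [R_RUBISCO]}
  - name: "C4 NAD-ME"
    steps:
      - {step: 1, name: "PEP carboxylase", reactions: [R_PEPC]}
      - {step: 10, name: "aspartate aminotransferase", reactions: [R_AAT]}
      - {step: 11, name: "NAD-malate dehydrogenase", reactions: [R_NAD_MDH]}
      - {step: 12, name: "NAD-malic enzyme", reactions: [R_NAD_ME]}
      - {step: 13, name: "alanine aminotransferase", reactions: [R_ALAAT]}
"""


@dataclass
class CoreModelLedger:
    """What the generator planted, in the six summary-statistic fields."""

    stats: dict[str, int] = field(default_factory=dict)


def make_core_model(
    n_reactions: int = 20,
    n_genes: int = 14,
    compartments: Sequence[str] = ("cytosol", "plastid", "mitochondrion", "peroxisome"),
    transporter_counts: tuple[int, int, int] = (1, 1, 1),
    seed: int = 0,
    isozyme_rate: float = 0.3,
    gene_prefix: str = "REF_G",
) -> tuple[list[AssociationEntry], CoreModelLedger]:
    """Generate a connected toy gene-enzyme-reaction table plus its ledger.

    The first reactions are the canonical C4 shuttle; the rest are linear
    pathway chains with occasional branch points, plus the requested number
    of (extracellular, plasmodesmata, interorganelle) transporters.  Each
    reaction gets one gene; extra isozyme entries are added at
    ``isozyme_rate`` per reaction, cycling through the gene pool.
    """
    n_extra, n_plasmo, n_organelle = transporter_counts
    n_transport = n_extra + n_plasmo + n_organelle
    if min(transporter_counts) < 0 or n_transport > n_reactions:
        raise ValueError(
            f"infeasible counts: {n_transport} transporters > {n_reactions} reactions"
        )
    if n_reactions <= 0 or n_genes <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"{gene_prefix}{i:05d}" for i in range(1, n_genes + 1)]
    next_gene = iter(genes * (10 * (n_reactions // n_genes + 2)))

    entries: list[AssociationEntry] = []
    n_normal = n_reactions - n_transport

    def add_entry(rid, name, ec, comp, cell, terms, rev, tclass):
        entries.append(
            AssociationEntry(
                gene_id=next(next_gene),
                reaction_id=rid,
                reaction_name=name,
                ec_number=ec,
                compartment=comp,
                cell_type=cell,
                stoichiometry=tuple(terms),
                reversible=rev,
                transporter_class=tclass,
            )
        )
        n_iso = 0
        while rng.random() < isozyme_rate and n_iso < 3:
            e = entries[-1]
            entries.append(
                AssociationEntry(
                    gene_id=next(next_gene),
                    reaction_id=e.reaction_id,
                    reaction_name=e.reaction_name,
                    ec_number=e.ec_number,
                    compartment=e.compartment,
                    cell_type=e.cell_type,
                    stoichiometry=e.stoichiometry,
                    reversible=e.reversible,
                    transporter_class=e.transporter_class,
                )
            )
            n_iso += 1

    for rid, name, ec, comp, terms, rev in _C4_BACKBONE[:n_normal]:
        stoich = [StoichTerm(m, float(c), comp, "generic") for m, c in terms]
        add_entry(rid, name, ec, comp, "generic", stoich, rev, "none")

    # generic linear chains with branch points every 5 steps
    n_chain = max(0, n_normal - len(_C4_BACKBONE))
    for i in range(n_chain):
        comp = compartments[i % len(compartments)]
        src = f"X{i:03d}" if i % 5 else "pyr"  # branch back into the backbone
        dst = f"X{i + 1:03d}"
        stoich = [StoichTerm(src, -1.0, comp, "generic"), StoichTerm(dst, 1.0, comp, "generic")]
        add_entry(f"R_S{i + 1:03d}", f"synthetic step {i + 1}", "", comp, "generic",
                  stoich, bool(rng.random() < 0.2), "none")

    for j in range(n_extra):
        met = f"ext{j:02d}"
        terms = [StoichTerm(met, -1.0, "extracellular", "generic"),
                 StoichTerm(met, 1.0, "cytosol", "generic")]
        add_entry(f"R_TEX{j + 1:02d}", f"{met} uptake", "", "cytosol", "generic",
                  terms, True, "extracellular")
    for j in range(n_plasmo):
        met = ["pep", "pyr", "mal", "asp", "ala"][j % 5]
        terms = [StoichTerm(met, -1.0, "cytosol", "mesophyll"),
                 StoichTerm(met, 1.0, "cytosol", "bundle_sheath")]
        add_entry(f"R_TPD{j + 1:02d}", f"{met} plasmodesmata flux", "", "cytosol",
                  "generic", terms, True, "plasmodesmata")
    for j in range(n_organelle):
        met = ["mal", "oaa", "pyr", "pep", "pga"][j % 5]
        comp = ["plastid", "mitochondrion", "peroxisome"][j % 3]
        terms = [StoichTerm(met, -1.0, "cytosol", "generic"),
                 StoichTerm(met, 1.0, comp, "generic")]
        add_entry(f"R_TOR{j + 1:03d}", f"{met} {comp} shuttle", "", "cytosol",
                  "generic", terms, True, "interorganelle")

    # ledger by construction (independent bookkeeping, not reconstruction_stats)
    met_keys = {t.met_key for e in entries for t in e.stoichiometry}
    ledger = CoreModelLedger(
        stats={
            RECON_SUMMARY_FIELDS[0]: len(entries),
            RECON_SUMMARY_FIELDS[1]: len({e.gene_id for e in entries}),
            RECON_SUMMARY_FIELDS[2]: len(met_keys),
            RECON_SUMMARY_FIELDS[3]: n_extra,
            RECON_SUMMARY_FIELDS[4]: n_plasmo,
            RECON_SUMMARY_FIELDS[5]: n_organelle,
        }
    )
    return entries, ledger


def make_hit_table(
    core_genes: Sequence[str],
    n_target_genes: int,
    mutation_rate: float = 0.02,
    decoy_rate: float = 0.0,
    seed: int = 0,
    gene_length: int = 300,
    target_prefix: str = "T",
) -> tuple[list[HitRow], GeneMap, dict]:
    """Hit table deriving each target gene from one reference gene.

    Simulated identity is ``100 * (1 - mutation_rate)`` plus per-target
    Gaussian noise; crucially the noise is drawn from the seed *before* the
    mutation rate is applied (common random numbers), and the e-value is a
    deterministic monotone function of identity — so recall as a function of
    mutation rate is exactly monotone within a seed family.  Decoy rows are
    spurious cross-hits with low identity and high e-values.

    Returns (rows, planted gene map, ledger with row count and bitscore sum).
    """
    if not 0 <= mutation_rate <= 1 or not 0 <= decoy_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_ref = len(core_genes)
    eps = rng.normal(0.0, 3.0, size=n_target_genes)
    decoy_flags = rng.random(n_target_genes) < decoy_rate
    decoy_partner = rng.integers(0, max(n_ref, 1), size=n_target_genes)
    decoy_identity = rng.uniform(15.0, 28.0, size=n_target_genes)
    decoy_evalue_exp = rng.uniform(0.0, 8.0, size=n_target_genes)

    rows: list[HitRow] = []
    mapping: dict[str, str] = {}
    for i in range(n_target_genes):
        tgt = f"{target_prefix}{i + 1:06d}"
        ref = core_genes[i % n_ref]
        mapping[tgt] = ref
        identity = float(np.clip(100.0 * (1.0 - mutation_rate) + eps[i], 1.0, 100.0))
        evalue = 10.0 ** (-min(max(0.45 * identity - 12.0, 0.0), 180.0))
        mismatches = int(round(gene_length * (100.0 - identity) / 100.0))
        rows.append(
            HitRow(
                query_id=tgt,
                subject_id=ref,
                percent_identity=round(identity, 2),
                alignment_length=gene_length,
                mismatches=mismatches,
                gap_opens=0,
                qstart=1,
                qend=gene_length,
                sstart=1,
                send=gene_length,
                evalue=evalue,
                bitscore=round(2.0 * gene_length * identity / 100.0, 1),
            )
        )
        if decoy_flags[i] and n_ref > 1:
            wrong = core_genes[int(decoy_partner[i]) % n_ref]
            if wrong == ref:
                wrong = core_genes[(int(decoy_partner[i]) + 1) % n_ref]
            d_id = float(decoy_identity[i])
            rows.append(
                HitRow(
                    query_id=tgt,
                    subject_id=wrong,
                    percent_identity=round(d_id, 2),
                    alignment_length=gene_length // 2,
                    mismatches=int(round(gene_length / 2 * (100 - d_id) / 100)),
                    gap_opens=1,
                    qstart=1,
                    qend=gene_length // 2,
                    sstart=1,
                    send=gene_length // 2,
                    evalue=10.0 ** (-float(decoy_evalue_exp[i])),
                    bitscore=round(gene_length * d_id / 100.0, 1),
                )
            )
    ledger = {
        "n_rows": len(rows),
        "bitscore_sum": round(float(sum(r.bitscore for r in rows)), 1),
    }
    return rows, GeneMap(mapping=mapping), ledger


# ---------------------------------------------------------------------------
# omics tables


@dataclass
class SyntheticTruth:
    """The answer sheet for one generated omics universe."""

    seed: int
    de_fraction: float
    gene_log2fc: dict[str, float]  # planted effect; 0.0 for non-DE genes
    protein_log2fc: dict[str, float]  # keyed by gene id
    metabolite_fold_change: dict[str, float]  # linear scale
    reaction_colors: dict[str, str]  # "rid@compartment/cell" -> color
    gene_map: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "de_fraction": self.de_fraction,
                "gene_log2fc": self.gene_log2fc,
                "protein_log2fc": self.protein_log2fc,
                "metabolite_fold_change": self.metabolite_fold_change,
                "reaction_colors": self.reaction_colors,
                "gene_map": self.gene_map,
                "params": self.params,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            de_fraction=d["de_fraction"],
            gene_log2fc=d["gene_log2fc"],
            protein_log2fc=d["protein_log2fc"],
            metabolite_fold_change=d["metabolite_fold_change"],
            reaction_colors=d["reaction_colors"],
            gene_map=d.get("gene_map", {}),
            params=d.get("params", {}),
        )


def _reaction_key_str(key: tuple[str, str, str]) -> str:
    return f"{key[0]}@{key[1]}/{key[2]}"


def planted_reaction_color(
    reaction_genes: Sequence[str],
    gene_log2fc: dict[str, float],
    protein_log2fc: dict[str, float],
    lfc_threshold: float = 0.5,
) -> str:
    """Ground-truth color from planted effects (a planted effect is always
    statistically detectable in the separation regime, so significance
    reduces to |planted lfc| exceeding the display threshold)."""
    signs = set()
    for g in reaction_genes:
        for source in (gene_log2fc, protein_log2fc):
            lfc = source.get(g, 0.0)
            if abs(lfc) > lfc_threshold:
                signs.add(1 if lfc > 0 else -1)
    if not signs:
        return "gray"
    if signs == {1}:
        return "green"
    if signs == {-1}:
        return "red"
    return "yellow"


def make_omics_tables(
    recon: Reconstruction,
    de_fraction: float = 0.3,
    effect_range: tuple[float, float] = (0.75, 3.0),
    n_reps_expr: int = 3,
    n_reps_prot: int = 4,
    sigma: float = 0.25,
    sigma_prot: float = 0.2,
    protein_subset_fraction: float = 0.5,
    concordance: float = 0.9,
    metabolite_panel: Sequence[str] | None = None,
    metabolite_de_fraction: float | None = None,
    n_extra_genes: int = 0,
    seed: int = 0,
) -> tuple["pd.DataFrame", "pd.DataFrame", "pd.DataFrame", SyntheticTruth]:
    """Generate expression, protein, and metabolite tables with planted truth.

    Expression covers every network gene plus ``n_extra_genes`` off-network
    genes (so coverage statistics have something to not map).  FPKM
    replicates are log-normal around planted means with log2-scale noise sd
    ``sigma``; DE genes (a ``de_fraction`` sample) are shifted by log2 fold
    changes drawn from +/- Uniform(*effect_range*).  Proteins exist for a
    subset of network genes and agree in sign with their transcript with
    probability ``concordance``.  Metabolite concentrations get planted
    linear fold changes on the panel (default: every network metabolite id).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    network_genes = sorted(recon.genes)
    extra_genes = [f"E{i + 1:05d}" for i in range(n_extra_genes)]
    genes = network_genes + extra_genes

    n_de = int(round(de_fraction * len(genes)))
    de_idx = rng.choice(len(genes), size=n_de, replace=False)
    gene_lfc = {g: 0.0 for g in genes}
    lo, hi = effect_range
    for i in sorted(de_idx):
        mag = rng.uniform(lo, hi)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        gene_lfc[genes[i]] = round(float(sign * mag), 4)

    base = 2.0 ** rng.uniform(4.0, 8.0, size=len(genes))
    expr_rows = {}
    for i, g in enumerate(genes):
        lfc = gene_lfc[g]
        mean_m = base[i] * 2.0 ** (lfc / 2.0)
        mean_i = base[i] * 2.0 ** (-lfc / 2.0)
        reps_m = mean_m * 2.0 ** rng.normal(0.0, sigma, n_reps_expr)
        reps_i = mean_i * 2.0 ** rng.normal(0.0, sigma, n_reps_expr)
        expr_rows[g] = np.concatenate([reps_m, reps_i])
    expr_df = pd.DataFrame.from_dict(expr_rows, orient="index").round(4)
    expr_df.columns = [f"fpkm_mature_{j + 1}" for j in range(n_reps_expr)] + [
        f"fpkm_immature_{j + 1}" for j in range(n_reps_expr)
    ]
    expr_df.insert(0, "gene_id", expr_df.index)
    expr_df = expr_df.reset_index(drop=True)

    n_prot = int(round(protein_subset_fraction * len(network_genes)))
    prot_gene_idx = sorted(rng.choice(len(network_genes), size=n_prot, replace=False))
    prot_lfc: dict[str, float] = {}
    prot_rows = []
    for i in prot_gene_idx:
        g = network_genes[i]
        lfc = gene_lfc[g]
        if lfc != 0.0 and rng.random() >= concordance:
            lfc = -lfc  # discordant isoform: regulated in the opposite direction
        prot_lfc[g] = lfc
        reps_m = lfc / 2.0 + rng.normal(0.0, sigma_prot, n_reps_prot)
        reps_i = -lfc / 2.0 + rng.normal(0.0, sigma_prot, n_reps_prot)
        prot_rows.append([f"P_{g}", g] + list(np.round(reps_m, 4)) + list(np.round(reps_i, 4)))
    prot_df = pd.DataFrame(
        prot_rows,
        columns=["protein_id", "gene_id"]
        + [f"log2ratio_mature_{j + 1}" for j in range(n_reps_prot)]
        + [f"log2ratio_immature_{j + 1}" for j in range(n_reps_prot)],
    )

    if metabolite_panel is None:
        metabolite_panel = sorted(recon.metabolite_ids())
    met_de_frac = de_fraction if metabolite_de_fraction is None else metabolite_de_fraction
    n_met_de = int(round(met_de_frac * len(metabolite_panel)))
    met_de_idx = set(
        int(i) for i in rng.choice(len(metabolite_panel), size=n_met_de, replace=False)
    )
    met_fc: dict[str, float] = {}
    met_rows = []
    for i, m in enumerate(metabolite_panel):
        if i in met_de_idx:
            mag = rng.uniform(lo, hi)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            fc = 2.0 ** (sign * mag)
        else:
            fc = 1.0
        met_fc[m] = round(float(fc), 4)
        conc = rng.uniform(10.0, 100.0)
        mean_m = conc * math.sqrt(fc)
        mean_i = conc / math.sqrt(fc)
        reps_m = mean_m * 2.0 ** rng.normal(0.0, sigma, n_reps_expr)
        reps_i = mean_i * 2.0 ** rng.normal(0.0, sigma, n_reps_expr)
        met_rows.append([m] + list(np.round(reps_m, 4)) + list(np.round(reps_i, 4)))
    met_df = pd.DataFrame(
        met_rows,
        columns=["metabolite_id"]
        + [f"conc_mature_{j + 1}" for j in range(n_reps_expr)]
        + [f"conc_immature_{j + 1}" for j in range(n_reps_expr)],
    )

    reaction_colors = {
        _reaction_key_str(r.key): planted_reaction_color(
            sorted(r.genes), gene_lfc, prot_lfc
        )
        for r in recon.reactions
    }
    truth = SyntheticTruth(
        seed=seed,
        de_fraction=de_fraction,
        gene_log2fc=gene_lfc,
        protein_log2fc=prot_lfc,
        metabolite_fold_change=met_fc,
        reaction_colors=reaction_colors,
        params={
            "effect_range": list(effect_range),
            "n_reps_expr": n_reps_expr,
            "n_reps_prot": n_reps_prot,
            "sigma": sigma,
            "sigma_prot": sigma_prot,
            "protein_subset_fraction": protein_subset_fraction,
            "concordance": concordance,
            "metabolite_de_fraction": met_de_frac,
            "n_extra_genes": n_extra_genes,
        },
    )
    return expr_df, prot_df, met_df, truth


# ---------------------------------------------------------------------------
# fixture presets

PRESETS = {
    "small": {
        "n_reactions": 20,
        "n_genes": 14,
        "transporter_counts": (1, 1, 1),
        "isozyme_rate": 0.4,
        "n_target_genes": 30,
        "mutation_rate": 0.02,
        "n_extra_genes": 60,
        "metabolite_panel_size": None,  # all network metabolites
    },
    # echoes the reference reconstruction's proportions at desk scale:
    # ~300 reactions with the (18, 11, 83) transporter-class split, ~2000
    # expressed genes against ~360 network genes
    "fullscale": {
        "n_reactions": 300,
        "n_genes": 220,
        "transporter_counts": (18, 11, 83),
        "isozyme_rate": 0.4,
        "n_target_genes": 300,
        "mutation_rate": 0.02,
        "n_extra_genes": 1700,
        "metabolite_panel_size": 100,
    },
}


def write_fixtures(outdir, preset: str = "small", seed: int = 42) -> dict:
    """Write core.tsv, hits.tsv, expr.tsv, prot.tsv, metab.tsv, truth.json,
    panels.yaml for one preset universe; returns the combined ledger."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    entries, core_ledger = make_core_model(
        n_reactions=cfg["n_reactions"],
        n_genes=cfg["n_genes"],
        transporter_counts=cfg["transporter_counts"],
        isozyme_rate=cfg["isozyme_rate"],
        seed=seed,
    )
    write_core_model(entries, outdir / "core.tsv")

    core_genes = sorted({e.gene_id for e in entries})
    hits, planted_map, hit_ledger = make_hit_table(
        core_genes,
        n_target_genes=cfg["n_target_genes"],
        mutation_rate=cfg["mutation_rate"],
        seed=seed + 1,
    )
    write_hit_table(hits, outdir / "hits.tsv")

    gmap = best_hits(hits)
    from .homology import lift_model

    lift = lift_model(entries, gmap)
    recon = collapse_entries(lift.entries, provenance=f"synthetic preset {preset}")

    panel_size = cfg["metabolite_panel_size"]
    panel = sorted(recon.metabolite_ids())
    if panel_size is not None:
        panel = panel[:panel_size]
    expr_df, prot_df, met_df, truth = make_omics_tables(
        recon,
        metabolite_panel=panel,
        n_extra_genes=cfg["n_extra_genes"],
        metabolite_de_fraction=0.67,
        seed=seed + 2,
    )
    truth.gene_map = dict(planted_map.mapping)
    for df, name in ((expr_df, "expr.tsv"), (prot_df, "prot.tsv"), (met_df, "metab.tsv")):
        df.to_csv(outdir / name, sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json() + "\n", encoding="utf-8")
    (outdir / "panels.yaml").write_text(DEFAULT_PANELS_YAML, encoding="utf-8")

    ledger = {
        "core_model": core_ledger.stats,
        "hit_table": hit_ledger,
        "n_expression_records": len(expr_df),
        "n_protein_records": len(prot_df),
        "n_metabolite_records": len(met_df),
    }
    (outdir / "ledger.json").write_text(
        json.dumps(ledger, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return ledger
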