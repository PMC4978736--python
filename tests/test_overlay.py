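"""Reaction color classification, coverage statistics, panels, correlation."""

import itertools

import numpy as np
import pytest

from c4recon.model import ModelValidationError, collapse_entries
from c4recon.omics import (
    ExpressionRecord,
    InsufficientDataError,
    MetaboliteRecord,
    ProteinRecord,
)
from c4recon.overlay import (
    Contributor,
    CoverageStats,
    PanelStep,
    PathwayPanel,
    assemble_pathway_report,
    classify_metabolite,
    classify_reaction,
    coverage_stats,
    map_omics_to_network,
    matched_lfc_pairs,
    mrna_protein_correlation,
)


def _c(lfc, q, layer="transcript", fid="x"):
    return Contributor(fid, layer, lfc, q)


def oracle_classify(contributors, lfc_threshold=0.5, alpha=0.05):
    """Independent re-statement of the color rule for the truth table."""
    sig_up = sig_down = 0
    display = False
    for lfc, q in contributors:
        if abs(lfc) > lfc_threshold:
            display = True
            if q is not None and q < alpha:
                if lfc > 0:
                    sig_up += 1
                else:
                    sig_down += 1
    if sig_up and sig_down:
        color = "yellow"
    elif sig_up:
        color = "green"
    elif sig_down:
        color = "red"
    else:
        color = "gray"
    return color, display


class TestClassifyReaction:
    def test_single_up_gene_is_green_and_displayed(self):
        assert classify_reaction([_c(1.2, 0.01)], []) == ("green", True)

    def test_opposite_isoforms_are_yellow(self):
        color, _ = classify_reaction([_c(1.0, 0.01), _c(-1.0, 0.01)], [])
        assert color == "yellow"

    def test_below_threshold_is_gray_and_hidden(self):
        assert classify_reaction([_c(0.3, 0.01)], []) == ("gray", False)

    def test_protein_evidence_joins_transcript_evidence(self):
        color, display = classify_reaction(
            [_c(0.2, 0.9)], [_c(-1.5, 0.001, layer="protein")]
        )
        assert (color, display) == ("red", True)

    def test_truth_table_small_patterns(self):
        lfc_values = (1.2, 0.3, -0.3, -1.2)
        q_values = (0.01, 0.2, None)
        options = list(itertools.product(lfc_values, q_values))
        for n in (1, 2):
            for combo in itertools.product(options, repeat=n):
                for split in range(n + 1):
                    genes = [_c(l, q) for l, q in combo[:split]]
                    prots = [_c(l, q, layer="protein") for l, q in combo[split:]]
                    assert classify_reaction(genes, prots) == oracle_classify(combo)

    def test_relabeling_symmetry_and_sign_antisymmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(1, 4)
            contribs = [
                _c(float(rng.normal(0, 1.5)), float(rng.uniform(0, 0.2)))
                for _ in range(n)
            ]
            color, disp = classify_reaction(contribs, [])
            perm = [contribs[i] for i in rng.permutation(n)]
            assert classify_reaction(perm, []) == (color, disp)
            flipped = [_c(-c.log2fc, c.q_value) for c in contribs]
            fcolor, fdisp = classify_reaction(flipped, [])
            assert fdisp == disp
            assert fcolor == {"green": "red", "red": "green"}.get(color, color)

    def test_alpha_relaxation_only_moves_out_of_gray(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = rng.integers(1, 4)
            contribs = [
                _c(float(rng.normal(0, 1.0)), float(rng.uniform(0, 1)))
                for _ in range(n)
            ]
            strict, _ = classify_reaction(contribs, [], alpha=0.05)
            loose, _ = classify_reaction(contribs, [], alpha=1.0)
            if loose == "gray":
                assert strict == "gray"


class TestClassifyMetabolite:
    @pytest.mark.parametrize(
        "fc,q,expected",
        [(2.5, 0.01, "green"), (0.4, 0.01, "red"), (2.5, 0.2, "gray"),
         (1.0, 0.01, "gray"), (2.5, None, "gray")],
    )
    def test_rule(self, fc, q, expected):
        assert classify_metabolite(fc, q) == expected


def _expr(gene, lfc, q):
    return ExpressionRecord(gene, (), (), lfc, q, q)


def _prot(gene, lfc, q, pid=None):
    return ProteinRecord(pid or f"P_{gene}", gene, (), (), lfc, q, q)


def _met(mid, fc, q):
    return MetaboliteRecord(mid, (), (), fc, q, q)


class TestMapOmics:
    def test_partial_gpr_coverage(self, toy_recon):
        result = map_omics_to_network(toy_recon, [_expr("g1", 1.2, 0.01)])
        r1 = result.reactions[("R1", "plastid", "mesophyll")]
        assert [c.feature_id for c in r1.gene_contributors] == ["g1"]
        assert r1.color == "green"
        assert result.unmapped_genes == []

    def test_unmeasured_reaction_is_gray(self, toy_recon):
        result = map_omics_to_network(toy_recon, [_expr("g1", 1.2, 0.01)])
        r2 = result.reactions[("R2", "plastid", "bundle_sheath")]
        assert r2.color == "gray" and not r2.display

    def test_unknown_metabolite_reported_unmapped(self, toy_recon):
        result = map_omics_to_network(toy_recon, [], [], [_met("sucrose", 2.0, 0.01)])
        assert result.unmapped_metabolites == ["sucrose"]

    def test_network_metabolite_gets_color(self, toy_recon):
        result = map_omics_to_network(toy_recon, [], [], [_met("A", 3.0, 0.001)])
        assert result.metabolites["A"].color == "green"

    def test_off_network_gene_listed_unmapped(self, toy_recon):
        result = map_omics_to_network(toy_recon, [_expr("nowhere", 1.0, 0.01)])
        assert result.unmapped_genes == ["nowhere"]


class TestCoverageStats:
    def test_counts_and_percentages(self, toy_recon):
        expression = [
            ExpressionRecord("g1", (5.0,), (3.0,), 1.0, 0.01, 0.02),
            ExpressionRecord("g2", (2.0,), (2.0,), 0.0, 0.9, 0.9),
            ExpressionRecord("off1", (1.0,), (4.0,), -2.0, 0.001, 0.004),
            ExpressionRecord("silent", (0.0,), (0.0,), 0.0, None, None),
        ]
        proteins = [_prot("g1", 1.0, 0.01), _prot("off2", 0.1, 0.8)]
        mets = [_met("A", 2.0, 0.01), _met("unknown", 1.0, 0.9)]
        cov = coverage_stats(toy_recon, expression, proteins, mets,
                             n_coding_genes=10)
        assert cov.n_expressed == 3 and cov.pct_expressed == 30
        assert cov.n_de == 2 and cov.pct_de == 67
        assert cov.n_expressed_mapped == 2
        assert cov.n_de_mapped == 1
        assert cov.n_proteins_identified == 2 and cov.n_proteins_de == 1
        assert cov.n_proteins_mapped == 1
        assert cov.n_metabolites == 2 and cov.n_metabolites_de == 1
        assert cov.n_metabolites_mapped == 1

    def test_zero_denominator_reports_absent(self):
        cov = CoverageStats(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
        assert cov.pct_expressed is None

    def test_zero_numerator_is_zero_percent(self):
        cov = CoverageStats(100, 50, 0, 0, 0, 10, 0, 0, 5, 0, 0)
        assert cov.pct_de == 0

    def test_numerator_exceeding_denominator_rejected(self):
        with pytest.raises(ValueError):
            CoverageStats(10, 20, 0, 0, 0, 0, 0, 0, 0, 0, 0)

    def test_percentages_self_consistent(self):
        cov = CoverageStats(35424, 29423, 15788, 8361, 5242, 570, 125, 128, 100, 67, 100)
        d = cov.as_dict()
        t = d["transcriptome"]
        assert t["pct_expressed"] == (200 * 29423 + 35424) // (2 * 35424)
        assert t["pct_differentially_expressed"] == (200 * 15788 + 29423) // (2 * 29423)


class TestCorrelation:
    def test_identical_vectors(self):
        pairs = [(0.1, 0.1), (1.0, 1.0), (-2.0, -2.0), (0.5, 0.5)]
        r, rho, n = mrna_protein_correlation(pairs)
        assert r == pytest.approx(1.0) and rho == pytest.approx(1.0) and n == 4

    def test_exact_negation(self):
        pairs = [(0.1, -0.1), (1.0, -1.0), (-2.0, 2.0)]
        r, rho, _ = mrna_protein_correlation(pairs)
        assert r == pytest.approx(-1.0) and rho == pytest.approx(-1.0)

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            mrna_protein_correlation([(1.0, 1.0), (2.0, 2.0)])

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(3)
        cov = [[1.0, 0.6], [0.6, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=500)
        r, rho, n = mrna_protein_correlation([tuple(p) for p in xy])
        assert n == 500
        assert abs(r - 0.6) < 0.1 and abs(rho - 0.58) < 0.12

    def test_matched_pairs_join_on_gene(self):
        expression = [_expr("g1", 1.0, 0.01), _expr("g2", -1.0, 0.01)]
        proteins = [_prot("g2", -0.8, 0.02), _prot("g9", 0.0, 0.9)]
        assert matched_lfc_pairs(expression, proteins) == [(-1.0, -0.8)]


class TestPathwayReport:
    def _panel(self, rids, name="toy"):
        return PathwayPanel(
            name=name,
            steps=[PanelStep(step=i + 1, name=f"s{i + 1}", reaction_ids=[rid])
                   for i, rid in enumerate(rids)],
        )

    def test_all_up_panel_is_green(self, toy_recon):
        overlays = map_omics_to_network(
            toy_recon,
            [_expr(g, 1.5, 0.001) for g in ("g1", "g2", "g3", "g4")],
        )
        panel = self._panel(["R1", "R2", "R_TEX", "R_TPD"])
        rows, summaries = assemble_pathway_report([panel], overlays, toy_recon)
        assert len(rows) == 4
        assert summaries["toy"] == {"green": 4, "red": 0, "yellow": 0, "gray": 0}

    def test_empty_overlay_all_gray(self, toy_recon):
        overlays = map_omics_to_network(toy_recon, [])
        panel = self._panel(["R1", "R2"])
        _, summaries = assemble_pathway_report([panel], overlays, toy_recon)
        assert summaries["toy"]["gray"] == 2

    def test_unknown_reaction_names_the_step(self, toy_recon):
        overlays = map_omics_to_network(toy_recon, [])
        panel = self._panel(["R1", "R_MISSING"])
        with pytest.raises(ModelValidationError, match="step 2.*R_MISSING"):
            assemble_pathway_report([panel], overlays, toy_recon)
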