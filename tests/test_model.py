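"""Core model data structures: TSV I/O, collapsing, S matrix, exports."""

import random

import numpy as np
import pytest

from c4recon.model import (
    AssociationEntry,
    ConflictError,
    Reconstruction,
    RowError,
    SchemaError,
    StoichTerm,
    build_stoich_matrix,
    collapse_entries,
    expand_reconstruction,
    read_core_model,
    read_mtx,
    read_sbml,
    reconstruction_stats,
    write_core_model,
    write_mtx,
    write_sbml,
)
from c4recon.simulate import make_core_model


class TestCoreModelTSV:
    def test_roundtrip_identity(self, toy_entries, tmp_path):
        p = tmp_path / "core.tsv"
        write_core_model(toy_entries, p)
        back = read_core_model(p)
        assert back == toy_entries
        # serialization is stable: a second write is byte-identical
        p2 = tmp_path / "core2.tsv"
        write_core_model(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_stoichiometry_two_signed_terms(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "gene_id\treaction_id\treaction_name\tec_number\tcompartment\tcell_type"
            "\tstoichiometry\treversible\ttransporter_class\n"
            "g1\tPGI\tisomerase\t5.3.1.9\tcytosol\tgeneric\tg6p:-1;f6p:1\ttrue\tnone\n"
        )
        (entry,) = read_core_model(p)
        assert entry.stoichiometry == (
            StoichTerm("g6p", -1.0, "cytosol", "generic"),
            StoichTerm("f6p", 1.0, "cytosol", "generic"),
        )

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene_id\treaction_id\n g\tR\n")
        with pytest.raises(SchemaError, match="stoichiometry"):
            read_core_model(p)

    def test_unparsable_coefficient_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "gene_id\treaction_id\treaction_name\tec_number\tcompartment\tcell_type"
            "\tstoichiometry\treversible\ttransporter_class\n"
            "g1\tR1\t\t\tcytosol\tgeneric\tA:xyz\tfalse\tnone\n"
        )
        with pytest.raises(RowError, match="line 2"):
            read_core_model(p)

    def test_duplicate_rows_accepted_with_warning(self, tmp_path, caplog):
        p = tmp_path / "dup.tsv"
        row = "g1\tR1\t\t\tcytosol\tgeneric\tA:-1;B:1\tfalse\tnone\n"
        p.write_text(
            "gene_id\treaction_id\treaction_name\tec_number\tcompartment\tcell_type"
            "\tstoichiometry\treversible\ttransporter_class\n" + row + row
        )
        with caplog.at_level("WARNING"):
            entries = read_core_model(p)
        assert len(entries) == 2
        assert any("duplicate" in r.message for r in caplog.records)

    def test_glyoxysome_alias_normalizes_to_peroxisome(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "gene_id\treaction_id\treaction_name\tec_number\tcompartment\tcell_type"
            "\tstoichiometry\treversible\ttransporter_class\n"
            "g1\tCS\tcitrate synthase\t\tglyoxysome\tgeneric\toaa:-1;cit:1\tfalse\tnone\n"
        )
        (entry,) = read_core_model(p)
        assert entry.compartment == "peroxisome"


class TestCollapse:
    def test_isozymes_collapse_to_or(self):
        terms = (StoichTerm("A", -1.0, "plastid"), StoichTerm("B", 1.0, "plastid"))
        entries = [
            AssociationEntry(gene_id=g, reaction_id="R1", compartment="plastid",
                             stoichiometry=terms)
            for g in ("g1", "g2", "g3")
        ]
        recon = collapse_entries(entries)
        assert len(recon.reactions) == 1
        assert recon.reactions[0].gpr == (("g1",), ("g2",), ("g3",))

    def test_distinct_compartments_stay_distinct(self):
        entries = [
            AssociationEntry(gene_id="g1", reaction_id="R1", compartment=c,
                             stoichiometry=(StoichTerm("A", -1.0, c), StoichTerm("B", 1.0, c)))
            for c in ("plastid", "mitochondrion")
        ]
        recon = collapse_entries(entries)
        assert len(recon.reactions) == 2

    def test_empty_table(self):
        recon = collapse_entries([])
        assert recon.reactions == [] and recon.genes == []

    def test_conflicting_stoichiometry_is_hard_error(self):
        e1 = AssociationEntry(gene_id="g1", reaction_id="R1", compartment="cytosol",
                              stoichiometry=(StoichTerm("A", -1.0, "cytosol"),
                                             StoichTerm("B", 1.0, "cytosol")))
        e2 = AssociationEntry(gene_id="g2", reaction_id="R1", compartment="cytosol",
                              stoichiometry=(StoichTerm("A", -2.0, "cytosol"),
                                             StoichTerm("B", 1.0, "cytosol")))
        with pytest.raises(ConflictError, match="rows 0 and 1"):
            collapse_entries([e1, e2])

    def test_complex_group_forms_conjunction(self):
        terms = (StoichTerm("A", -1.0, "cytosol"), StoichTerm("B", 1.0, "cytosol"))
        entries = [
            AssociationEntry(gene_id="s1", reaction_id="PDH", compartment="cytosol",
                             stoichiometry=terms, complex_group="cx1"),
            AssociationEntry(gene_id="s2", reaction_id="PDH", compartment="cytosol",
                             stoichiometry=terms, complex_group="cx1"),
            AssociationEntry(gene_id="iso", reaction_id="PDH", compartment="cytosol",
                             stoichiometry=terms),
        ]
        recon = collapse_entries(entries)
        assert recon.reactions[0].gpr == (("iso",), ("s1", "s2"))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_collapse_is_idempotent(self, seed):
        entries, _ = make_core_model(n_reactions=15, n_genes=9, seed=seed,
                                     isozyme_rate=0.5)
        recon = collapse_entries(entries)
        again = collapse_entries(expand_reconstruction(recon))
        assert again == recon

    def test_collapse_never_exceeds_entry_count(self, toy_entries):
        recon = collapse_entries(toy_entries)
        assert len(recon.reactions) <= len(toy_entries)


class TestStoichMatrix:
    def test_toy_linear_chain(self):
        entries = [
            AssociationEntry(gene_id="g1", reaction_id="R1", compartment="cytosol",
                             stoichiometry=(StoichTerm("A", -1.0, "cytosol"),
                                            StoichTerm("B", 1.0, "cytosol"))),
            AssociationEntry(gene_id="g2", reaction_id="R2", compartment="cytosol",
                             stoichiometry=(StoichTerm("B", -1.0, "cytosol"),
                                            StoichTerm("C", 1.0, "cytosol"))),
        ]
        sm = build_stoich_matrix(collapse_entries(entries))
        assert sm.shape == (3, 2)
        dense = sm.matrix.toarray()
        # rows sorted A, B, C; columns R1, R2
        assert dense.tolist() == [[-1, 0], [1, -1], [0, 1]]

    def test_empty_reconstruction(self):
        sm = build_stoich_matrix(collapse_entries([]))
        assert sm.shape == (0, 0)

    def test_invariant_to_entry_order(self, toy_entries):
        ref = build_stoich_matrix(collapse_entries(toy_entries))
        rng = random.Random(5)
        for _ in range(5):
            shuffled = list(toy_entries)
            rng.shuffle(shuffled)
            sm = build_stoich_matrix(collapse_entries(shuffled))
            assert sm.row_index == ref.row_index
            assert sm.col_index == ref.col_index
            assert (sm.matrix != ref.matrix).nnz == 0

    @pytest.mark.parametrize("seed", [0, 3])
    def test_non_transporter_columns_have_both_signs(self, seed):
        entries, _ = make_core_model(n_reactions=25, n_genes=12, seed=seed)
        recon = collapse_entries(entries)
        sm = build_stoich_matrix(recon)
        tclass = {r.key: r.transporter_class for r in recon.reactions}
        for j, key in enumerate(sm.col_index):
            if tclass[key] != "none":
                continue
            col = sm.matrix[:, j].toarray().ravel()
            assert (col > 0).any() and (col < 0).any()


class TestReconstructionStats:
    def test_toy_hand_count(self, toy_entries, toy_recon, toy_ledger):
        assert reconstruction_stats(toy_recon, toy_entries) == toy_ledger

    def test_empty_model_all_zero(self):
        stats = reconstruction_stats(collapse_entries([]), [])
        assert all(v == 0 for v in stats.values())

    def test_unique_genes_bounded_by_entries(self):
        for seed in range(4):
            entries, _ = make_core_model(n_reactions=12, n_genes=8, seed=seed,
                                         isozyme_rate=0.6)
            recon = collapse_entries(entries)
            stats = reconstruction_stats(recon, entries)
            assert 0 < stats["Unique genes (ORFs)"] <= stats["ORF-reaction association entries"]
            assert all(isinstance(v, int) and v >= 0 for v in stats.values())


class TestExports:
    def test_sbml_roundtrip(self, toy_entries, toy_recon, tmp_path):
        p = tmp_path / "model.xml"
        write_sbml(toy_recon, p)
        assert read_sbml(p) == toy_recon

    def test_sbml_plasmodesmata_spans_cell_suffixed_compartments(self, toy_recon, tmp_path):
        p = tmp_path / "model.xml"
        write_sbml(toy_recon, p)
        text = p.read_text()
        assert 'compartment id="plastid_M"' in text
        assert 'compartment id="plastid_BS"' in text

    def test_mtx_roundtrip_and_nnz(self, toy_recon, tmp_path):
        sm = build_stoich_matrix(toy_recon)
        n_nonzero = sum(
            len({t.met_key for t in r.stoichiometry}) for r in toy_recon.reactions
        )
        assert sm.nnz == n_nonzero
        p = tmp_path / "S.mtx"
        write_mtx(sm, p)
        back = read_mtx(p)
        assert back.row_index == sm.row_index
        assert back.col_index == sm.col_index
        assert np.allclose(back.matrix.toarray(), sm.matrix.toarray())


class TestValidation:
    def test_gpr_gene_must_exist(self):
        from c4recon.model import Metabolite, ModelValidationError, Reaction

        r = Reaction(
            reaction_id="R1", compartment="cytosol", cell_type="generic",
            stoichiometry=(StoichTerm("A", -1.0, "cytosol"), StoichTerm("B", 1.0, "cytosol")),
            reversible=False, gpr=(("ghost",),),
        )
        mets = [Metabolite("A", "", "cytosol"), Metabolite("B", "", "cytosol")]
        with pytest.raises(ModelValidationError, match="ghost"):
            Reconstruction(reactions=[r], metabolites=mets, genes=[])

    def test_transporter_must_span_locations(self):
        with pytest.raises(ValueError, match="distinct compartments"):
            AssociationEntry(
                gene_id="g1", reaction_id="T1", compartment="cytosol",
                stoichiometry=(StoichTerm("A", -1.0, "cytosol"),
                               StoichTerm("B", 1.0, "cytosol")),
                transporter_class="extracellular",
            )
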