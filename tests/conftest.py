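import pytest

from c4recon.model import AssociationEntry, StoichTerm, collapse_entries


def _term(met, coeff, comp, cell="generic"):
    return StoichTerm(met, float(coeff), comp, cell)


@pytest.fixture
def toy_entries():
    """Hand-written 6-entry toy core model.

    Hand-computed ledger: 6 association entries, 4 unique genes,
    6 localized metabolites, 5 reactions after collapse (R1 carries two
    isozymes), one transporter of each class.
    """
    return [
        AssociationEntry(
            gene_id="g1", reaction_id="R1", reaction_name="A to B", ec_number="1.1.1.1",
            compartment="plastid", cell_type="mesophyll",
            stoichiometry=(_term("A", -1, "plastid", "mesophyll"),
                           _term("B", 1, "plastid", "mesophyll")),
            reversible=False,
        ),
        AssociationEntry(
            gene_id="g2", reaction_id="R1", reaction_name="A to B", ec_number="1.1.1.1",
            compartment="plastid", cell_type="mesophyll",
            stoichiometry=(_term("A", -1, "plastid", "mesophyll"),
                           _term("B", 1, "plastid", "mesophyll")),
            reversible=False,
        ),
        AssociationEntry(
            gene_id="g3", reaction_id="R2", reaction_name="A to B (BS)",
            compartment="plastid", cell_type="bundle_sheath",
            stoichiometry=(_term("A", -1, "plastid", "bundle_sheath"),
                           _term("B", 1, "plastid", "bundle_sheath")),
            reversible=True,
        ),
        AssociationEntry(
            gene_id="g4", reaction_id="R_TPD", reaction_name="A plasmodesmata flux",
            compartment="cytosol", cell_type="generic",
            stoichiometry=(_term("A", -1, "plastid", "mesophyll"),
                           _term("A", 1, "plastid", "bundle_sheath")),
            reversible=True, transporter_class="plasmodesmata",
        ),
        AssociationEntry(
            gene_id="g1", reaction_id="R_TEX", reaction_name="A uptake",
            compartment="plastid", cell_type="mesophyll",
            stoichiometry=(_term("A", -1, "extracellular", "mesophyll"),
                           _term("A", 1, "plastid", "mesophyll")),
            reversible=True, transporter_class="extracellular",
        ),
        AssociationEntry(
            gene_id="g2", reaction_id="R_TOR", reaction_name="B cytosol shuttle",
            compartment="plastid", cell_type="mesophyll",
            stoichiometry=(_term("B", -1, "plastid", "mesophyll"),
                           _term("B", 1, "cytosol", "mesophyll")),
            reversible=True, transporter_class="interorganelle",
        ),
    ]


#: the hand count for the toy model above
TOY_LEDGER = {
    "ORF-reaction association entries": 6,
    "Unique genes (ORFs)": 4,
    "Metabolites": 6,
    "Extracellular transporters": 1,
    "Transporters (intercellular-plasmodesmata)": 1,
    "Transporters (interorganelle)": 1,
}


@pytest.fixture
def toy_ledger():
    return dict(TOY_LEDGER)


@pytest.fixture
def toy_recon(toy_entries):
    return collapse_entries(toy_entries)
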