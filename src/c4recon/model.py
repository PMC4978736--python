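"""Gene-centric metabolic reconstruction: data model, collapsing, and I/O.

The reconstruction follows the gene-centric convention of C4 genome-scale
frameworks: the primary artifact is a gene-enzyme-reaction association table
in which each metabolic gene is mapped to one or several reactions, each
localized to a compartment and (optionally) a leaf cell type (mesophyll or
bundle sheath).  Multiple association entries for the same reaction in the
same compartment/cell type are collapsed to a single reaction whose
gene-protein-reaction (GPR) rule is the OR over the contributing genes
(isozymes).  The collapsed network is exported as a stoichiometric matrix S
(metabolites x reactions, signed coefficients) and as SBML.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

COMPARTMENTS = (
    "cytosol",
    "plastid",
    "mitochondrion",
    "peroxisome",
    "vacuole",
    "extracellular",
)
#: naming synonyms normalized on input (the glyoxysome is the
#: specialized peroxisome of germinating/fatty tissues)
COMPARTMENT_ALIASES = {"glyoxysome": "peroxisome"}

CELL_TYPES = ("generic", "mesophyll", "bundle_sheath")
CELL_TYPE_SUFFIX = {"generic": "", "mesophyll": "_M", "bundle_sheath": "_BS"}
_SUFFIX_CELL_TYPE = {"_M": "mesophyll", "_BS": "bundle_sheath"}

TRANSPORTER_CLASSES = ("none", "extracellular", "plasmodesmata", "interorganelle")

#: the six reconstruction summary statistics, in canonical order
RECON_SUMMARY_FIELDS = (
    "ORF-reaction association entries",
    "Unique genes (ORFs)",
    "Metabolites",
    "Extracellular transporters",
    "Transporters (intercellular-plasmodesmata)",
    "Transporters (interorganelle)",
)

CORE_MODEL_COLUMNS = (
    "gene_id",
    "reaction_id",
    "reaction_name",
    "ec_number",
    "compartment",
    "cell_type",
    "stoichiometry",
    "reversible",
    "transporter_class",
)


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed layout."""


class RowError(ValueError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ConflictError(ValueError):
    """Entries that collapse to one reaction disagree on its chemistry."""


class ModelValidationError(ValueError):
    """A reconstruction violates a structural invariant."""


def normalize_compartment(raw: str) -> str:
    c = raw.strip().lower()
    c = COMPARTMENT_ALIASES.get(c, c)
    if c not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {raw!r}")
    return c


def normalize_cell_type(raw: str) -> str:
    c = raw.strip().lower() or "generic"
    if c in ("m", "mesophyll"):
        return "mesophyll"
    if c in ("bs", "bundle_sheath"):
        return "bundle_sheath"
    if c == "generic":
        return "generic"
    raise ValueError(f"unknown cell type {raw!r}")


@dataclass(frozen=True, order=True)
class StoichTerm:
    """One signed term of a reaction: coefficient of a localized metabolite.

    Compartment/cell type default to the owning entry's location; transporter
    entries override them per term (serialized ``met@compartment/cell``).
    """

    met_id: str
    coeff: float
    compartment: str
    cell_type: str = "generic"

    @property
    def met_key(self) -> tuple[str, str, str]:
        return (self.met_id, self.compartment, self.cell_type)


def _parse_stoich(
    text: str, default_compartment: str, default_cell: str
) -> tuple[StoichTerm, ...]:
    terms = []
    for raw in text.split(";"):
        raw = raw.strip()
        if not raw:
            continue
        if ":" not in raw:
            raise ValueError(f"stoichiometry term {raw!r} lacks a coefficient")
        met_part, coeff_part = raw.rsplit(":", 1)
        coeff = float(coeff_part)  # may raise ValueError
        if coeff == 0:
            raise ValueError(f"zero coefficient for {met_part!r}")
        comp, cell = default_compartment, default_cell
        if "@" in met_part:
            met_id, loc = met_part.split("@", 1)
            if "/" in loc:
                comp_raw, cell_raw = loc.split("/", 1)
                comp = normalize_compartment(comp_raw)
                cell = normalize_cell_type(cell_raw)
            else:
                comp = normalize_compartment(loc)
        else:
            met_id = met_part
        met_id = met_id.strip()
        if not met_id:
            raise ValueError(f"empty metabolite id in term {raw!r}")
        terms.append(StoichTerm(met_id, coeff, comp, cell))
    return tuple(terms)


def _format_stoich(
    terms: Sequence[StoichTerm], default_compartment: str, default_cell: str
) -> str:
    parts = []
    for t in terms:
        met = t.met_id
        if t.compartment != default_compartment or t.cell_type != default_cell:
            met = f"{t.met_id}@{t.compartment}"
            if t.cell_type != default_cell:
                met += f"/{t.cell_type}"
        coeff = f"{t.coeff:g}"
        parts.append(f"{met}:{coeff}")
    return ";".join(parts)


@dataclass(frozen=True)
class AssociationEntry:
    """One row of the gene-enzyme-reaction table: one gene, one reaction."""

    gene_id: str
    reaction_id: str
    reaction_name: str = ""
    ec_number: str = ""
    compartment: str = "cytosol"
    cell_type: str = "generic"
    stoichiometry: tuple[StoichTerm, ...] = ()
    reversible: bool = False
    transporter_class: str = "none"
    complex_group: str = ""

    def __post_init__(self):
        if not self.reaction_id:
            raise ValueError("reaction_id must be nonempty")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if self.transporter_class not in TRANSPORTER_CLASSES:
            raise ValueError(f"unknown transporter class {self.transporter_class!r}")
        for t in self.stoichiometry:
            if t.coeff == 0:
                raise ValueError(f"zero coefficient on {t.met_id}")
        if self.transporter_class != "none" and self.stoichiometry:
            locations = {(t.compartment, t.cell_type) for t in self.stoichiometry}
            if len(locations) < 2:
                raise ValueError(
                    f"transporter entry {self.reaction_id} must move a metabolite "
                    "between two distinct compartments or cell types"
                )

    @property
    def reaction_key(self) -> tuple[str, str, str]:
        return (self.reaction_id, self.compartment, self.cell_type)


@dataclass(frozen=True)
class Metabolite:
    metabolite_id: str
    name: str = ""
    compartment: str = "cytosol"
    cell_type: str = "generic"

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.metabolite_id, self.compartment, self.cell_type)


@dataclass(frozen=True)
class Reaction:
    """A collapsed reaction: unique per (reaction_id, compartment, cell_type).

    ``gpr`` is a disjunction of conjunctions over gene ids: each inner tuple
    is an enzyme (complex), the outer tuple the isozyme alternatives.
    """

    reaction_id: str
    compartment: str
    cell_type: str
    stoichiometry: tuple[StoichTerm, ...]
    reversible: bool
    gpr: tuple[tuple[str, ...], ...]
    transporter_class: str = "none"
    reaction_name: str = ""
    ec_number: str = ""

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.reaction_id, self.compartment, self.cell_type)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for conj in self.gpr for g in conj)

    def gpr_string(self) -> str:
        parts = []
        for conj in self.gpr:
            inner = " and ".join(conj)
            parts.append(f"({inner})" if len(conj) > 1 else inner)
        return " or ".join(parts)


@dataclass
class Reconstruction:
    """Collapsed reaction set with metabolites, gene universe, and provenance."""

    reactions: list[Reaction] = field(default_factory=list)
    metabolites: list[Metabolite] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        self.reactions = sorted(self.reactions, key=lambda r: r.key)
        self.metabolites = sorted(self.metabolites, key=lambda m: m.key)
        self.genes = sorted(set(self.genes))
        self.validate()

    def validate(self) -> None:
        keys = [r.key for r in self.reactions]
        if len(keys) != len(set(keys)):
            raise ModelValidationError("duplicate (reaction, compartment, cell) keys")
        met_keys = {m.key for m in self.metabolites}
        if len(met_keys) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite keys")
        gene_set = set(self.genes)
        for r in self.reactions:
            missing = r.genes - gene_set
            if missing:
                raise ModelValidationError(
                    f"reaction {r.reaction_id}: GPR genes {sorted(missing)} "
                    "not in reconstruction gene set"
                )
            for t in r.stoichiometry:
                if t.met_key not in met_keys:
                    raise ModelValidationError(
                        f"reaction {r.reaction_id} references unknown "
                        f"metabolite {t.met_key}"
                    )

    def reactions_by_gene(self) -> dict[str, list[Reaction]]:
        out: dict[str, list[Reaction]] = {}
        for r in self.reactions:
            for g in r.genes:
                out.setdefault(g, []).append(r)
        return out

    def metabolite_ids(self) -> set[str]:
        return {m.metabolite_id for m in self.metabolites}

    def __eq__(self, other) -> bool:  # provenance is metadata, not identity
        if not isinstance(other, Reconstruction):
            return NotImplemented
        return (
            self.reactions == other.reactions
            and self.metabolites == other.metabolites
            and self.genes == other.genes
        )


# ---------------------------------------------------------------------------
# core-model TSV I/O


def read_core_model(path) -> list[AssociationEntry]:
    """Read a gene-enzyme-reaction TSV into association entries.

    The file is tab-delimited with a header row naming all of
    ``CORE_MODEL_COLUMNS`` (an optional ``complex_group`` column marks
    subunits of one enzyme complex); ``#`` lines are comments.  Stoichiometry
    is serialized as ``metA:-1;metB:1`` with optional per-term
    ``@compartment/cell_type`` overrides for transporters.
    """
    entries: list[AssociationEntry] = []
    seen_rows: set[tuple] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if header is None:
                header = [h.strip() for h in row]
                missing = [c for c in CORE_MODEL_COLUMNS if c not in header]
                if missing:
                    raise SchemaError(
                        f"{path}: missing required column(s) {', '.join(missing)}"
                    )
                idx = {c: header.index(c) for c in header}
                continue
            if len(row) < len(header):
                raise RowError(f"expected {len(header)} columns, got {len(row)}", lineno)
            rec = {c: row[idx[c]].strip() for c in header}
            try:
                compartment = normalize_compartment(rec["compartment"])
                cell_type = normalize_cell_type(rec["cell_type"])
                stoich = _parse_stoich(rec["stoichiometry"], compartment, cell_type)
                entry = AssociationEntry(
                    gene_id=rec["gene_id"],
                    reaction_id=rec["reaction_id"],
                    reaction_name=rec["reaction_name"],
                    ec_number=rec["ec_number"],
                    compartment=compartment,
                    cell_type=cell_type,
                    stoichiometry=stoich,
                    reversible=_parse_bool(rec["reversible"]),
                    transporter_class=rec["transporter_class"].strip().lower() or "none",
                    complex_group=rec.get("complex_group", ""),
                )
            except ValueError as exc:
                raise RowError(str(exc), lineno) from exc
            row_key = tuple(row)
            if row_key in seen_rows:
                logger.warning("%s line %d: duplicate row accepted", path, lineno)
            seen_rows.add(row_key)
            entries.append(entry)
        if header is None:
            raise SchemaError(f"{path}: empty file, no header row")
    return entries


def _parse_bool(raw: str) -> bool:
    v = raw.strip().lower()
    if v in ("1", "true", "yes", "reversible"):
        return True
    if v in ("0", "false", "no", "irreversible", ""):
        return False
    raise ValueError(f"unparsable boolean {raw!r}")


def write_core_model(entries: Iterable[AssociationEntry], path) -> None:
    columns = CORE_MODEL_COLUMNS + ("complex_group",)
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(columns)
            for e in entries:
                writer.writerow(
                    [
                        e.gene_id,
                        e.reaction_id,
                        e.reaction_name,
                        e.ec_number,
                        e.compartment,
                        e.cell_type,
                        _format_stoich(e.stoichiometry, e.compartment, e.cell_type),
                        "true" if e.reversible else "false",
                        e.transporter_class,
                        e.complex_group,
                    ]
                )
    except OSError as exc:
        raise OSError(f"writing core model to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# collapsing and the stoichiometric matrix


def collapse_entries(
    entries: Sequence[AssociationEntry], provenance: str = ""
) -> Reconstruction:
    """Collapse association entries to one reaction per (id, compartment, cell).

    The GPR of each collapsed reaction is the OR over the genes of the
    grouped entries (entries sharing a nonempty ``complex_group`` form one
    AND conjunction); duplicates are removed.  Stoichiometry and
    reversibility must agree across the group; a disagreement raises
    :class:`ConflictError` naming both rows.
    """
    groups: dict[tuple[str, str, str], list[tuple[int, AssociationEntry]]] = {}
    for i, e in enumerate(entries):
        groups.setdefault(e.reaction_key, []).append((i, e))

    reactions = []
    met_keys: dict[tuple[str, str, str], Metabolite] = {}
    genes: set[str] = set()
    for key in sorted(groups):
        rows = groups[key]
        first_i, first = rows[0]
        ref_stoich = _canonical_stoich(first.stoichiometry)
        for i, e in rows[1:]:
            if _canonical_stoich(e.stoichiometry) != ref_stoich:
                raise ConflictError(
                    f"reaction {key}: conflicting stoichiometry between entry "
                    f"rows {first_i} and {i}"
                )
            if e.reversible != first.reversible:
                raise ConflictError(
                    f"reaction {key}: conflicting reversibility between entry "
                    f"rows {first_i} and {i}"
                )
        conjunctions: dict[str, list[str]] = {}
        singletons: set[tuple[str, ...]] = set()
        for _, e in rows:
            if e.complex_group:
                conjunctions.setdefault(e.complex_group, []).append(e.gene_id)
            elif e.gene_id:
                singletons.add((e.gene_id,))
        gpr_terms = set(singletons)
        for members in conjunctions.values():
            gpr_terms.add(tuple(sorted(set(members))))
        gpr = tuple(sorted(gpr_terms))
        genes.update(g for conj in gpr for g in conj)
        stoich = tuple(sorted(first.stoichiometry))
        for t in stoich:
            met_keys.setdefault(
                t.met_key, Metabolite(t.met_id, t.met_id, t.compartment, t.cell_type)
            )
        reactions.append(
            Reaction(
                reaction_id=first.reaction_id,
                compartment=first.compartment,
                cell_type=first.cell_type,
                stoichiometry=stoich,
                reversible=first.reversible,
                gpr=gpr,
                transporter_class=first.transporter_class,
                reaction_name=first.reaction_name,
                ec_number=first.ec_number,
            )
        )
    return Reconstruction(
        reactions=reactions,
        metabolites=sorted(met_keys.values(), key=lambda m: m.key),
        genes=sorted(genes),
        provenance=provenance,
    )


def _canonical_stoich(terms: Sequence[StoichTerm]) -> dict:
    out: dict[tuple, float] = {}
    for t in terms:
        out[t.met_key] = out.get(t.met_key, 0.0) + t.coeff
    return out


def expand_reconstruction(recon: Reconstruction) -> list[AssociationEntry]:
    """Inverse of :func:`collapse_entries`: one entry per GPR gene.

    Complex conjunctions expand to one entry per subunit sharing a
    ``complex_group`` label; used for round-trip/idempotence checks.
    """
    entries = []
    for r in recon.reactions:
        for j, conj in enumerate(r.gpr) if r.gpr else [(0, ("",))]:
            group = f"{r.reaction_id}_cx{j}" if len(conj) > 1 else ""
            for g in conj:
                entries.append(
                    AssociationEntry(
                        gene_id=g,
                        reaction_id=r.reaction_id,
                        reaction_name=r.reaction_name,
                        ec_number=r.ec_number,
                        compartment=r.compartment,
                        cell_type=r.cell_type,
                        stoichiometry=r.stoichiometry,
                        reversible=r.reversible,
                        transporter_class=r.transporter_class,
                        complex_group=group,
                    )
                )
    return entries


@dataclass
class StoichMatrix:
    """Sparse S matrix with deterministic (lexicographic) orderings."""

    row_index: list[tuple[str, str, str]]
    col_index: list[tuple[str, str, str]]
    matrix: scipy.sparse.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def nnz(self) -> int:
        return self.matrix.nnz


def build_stoich_matrix(recon: Reconstruction) -> StoichMatrix:
    """Extract S: entry (i, j) is the coefficient of metabolite i in reaction j.

    Rows cover metabolites participating in at least one reaction, sorted
    lexicographically by (id, compartment, cell type); columns likewise by
    reaction key.  Zeros are never stored.
    """
    used_mets = sorted({t.met_key for r in recon.reactions for t in r.stoichiometry})
    row_pos = {k: i for i, k in enumerate(used_mets)}
    col_keys = sorted(r.key for r in recon.reactions)
    col_pos = {k: j for j, k in enumerate(col_keys)}
    by_key = {r.key: r for r in recon.reactions}

    rows, cols, vals = [], [], []
    for key in col_keys:
        r = by_key[key]
        canon = _canonical_stoich(r.stoichiometry)
        for met_key in sorted(canon):
            coeff = canon[met_key]
            if coeff == 0:
                continue
            rows.append(row_pos[met_key])
            cols.append(col_pos[key])
            vals.append(coeff)
    mat = scipy.sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(used_mets), len(col_keys))
    )
    return StoichMatrix(row_index=used_mets, col_index=col_keys, matrix=mat)


def write_mtx(sm: StoichMatrix, path) -> None:
    """Write S in MatrixMarket coordinate format, plus .rows/.cols key files."""
    path = str(path)
    try:
        scipy.io.mmwrite(path, sm.matrix.tocoo())
        for suffix, keys in ((".rows", sm.row_index), (".cols", sm.col_index)):
            with open(path + suffix, "w", encoding="utf-8") as fh:
                for k in keys:
                    fh.write("\t".join(k) + "\n")
    except OSError as exc:
        raise OSError(f"writing matrix to {path}: {exc}") from exc


def read_mtx(path) -> StoichMatrix:
    path = str(path)
    mat = scipy.sparse.csr_matrix(scipy.io.mmread(path))

    def _keys(suffix):
        with open(path + suffix, encoding="utf-8") as fh:
            return [tuple(line.rstrip("\n").split("\t")) for line in fh if line.strip()]

    return StoichMatrix(row_index=_keys(".rows"), col_index=_keys(".cols"), matrix=mat)


# ---------------------------------------------------------------------------
# reconstruction statistics


def reconstruction_stats(
    recon: Reconstruction, entries: Sequence[AssociationEntry]
) -> dict[str, int]:
    """The six reconstruction summary statistics.

    Entry and unique-gene counts come from the uncollapsed association table;
    metabolite and transporter counts from the collapsed reconstruction.
    """
    met_keys = {t.met_key for e in entries for t in e.stoichiometry}
    by_class = {c: 0 for c in TRANSPORTER_CLASSES}
    for r in recon.reactions:
        by_class[r.transporter_class] += 1
    return {
        RECON_SUMMARY_FIELDS[0]: len(entries),
        RECON_SUMMARY_FIELDS[1]: len({e.gene_id for e in entries if e.gene_id}),
        RECON_SUMMARY_FIELDS[2]: len(met_keys),
        RECON_SUMMARY_FIELDS[3]: by_class["extracellular"],
        RECON_SUMMARY_FIELDS[4]: by_class["plasmodesmata"],
        RECON_SUMMARY_FIELDS[5]: by_class["interorganelle"],
    }


# ---------------------------------------------------------------------------
# SBML export/import (delegated to cobra; no objective — annotation use only)


def _sanitize(sid: str) -> str:
    out = re.sub(r"[^0-9a-zA-Z_]", "_", sid)
    if not out or out[0].isdigit():
        out = "x" + out
    return out


def _loc_code(compartment: str, cell_type: str) -> str:
    return _sanitize(compartment) + CELL_TYPE_SUFFIX[cell_type]


def write_sbml(recon: Reconstruction, path) -> None:
    """Export as SBML L3; cell types flatten into _M/_BS compartment suffixes."""
    import cobra

    model = cobra.Model("reconstruction")
    mets = {}
    for m in recon.metabolites:
        cm = cobra.Metabolite(
            id=_sanitize(m.metabolite_id) + "__" + _loc_code(m.compartment, m.cell_type),
            name=m.name or m.metabolite_id,
            compartment=_loc_code(m.compartment, m.cell_type),
        )
        cm.notes["metabolite_id"] = m.metabolite_id
        cm.notes["base_compartment"] = m.compartment
        cm.notes["cell_type"] = m.cell_type
        mets[m.key] = cm
    model.add_metabolites(list(mets.values()))

    reactions = []
    for r in recon.reactions:
        cr = cobra.Reaction(
            id=_sanitize(r.reaction_id) + "__" + _loc_code(r.compartment, r.cell_type),
            name=r.reaction_name or r.reaction_id,
            lower_bound=-1000.0 if r.reversible else 0.0,
            upper_bound=1000.0,
        )
        cr.add_metabolites(
            {mets[k]: c for k, c in _canonical_stoich(r.stoichiometry).items()}
        )
        cr.gene_reaction_rule = r.gpr_string()
        cr.notes["reaction_id"] = r.reaction_id
        cr.notes["base_compartment"] = r.compartment
        cr.notes["cell_type"] = r.cell_type
        cr.notes["transporter_class"] = r.transporter_class
        if r.ec_number:
            cr.notes["ec_number"] = r.ec_number
        reactions.append(cr)
    model.add_reactions(reactions)
    try:
        cobra.io.write_sbml_model(model, str(path))
    except OSError as exc:
        raise OSError(f"writing SBML to {path}: {exc}") from exc


def _parse_gpr_string(rule: str) -> tuple[tuple[str, ...], ...]:
    rule = rule.strip()
    if not rule:
        return ()
    terms = []
    for disjunct in re.split(r"\s+or\s+", rule):
        disjunct = disjunct.strip().strip("()")
        genes = tuple(sorted(g.strip() for g in re.split(r"\s+and\s+", disjunct) if g.strip()))
        if genes:
            terms.append(genes)
    return tuple(sorted(set(terms)))


def read_sbml(path) -> Reconstruction:
    import cobra

    model = cobra.io.read_sbml_model(str(path))
    met_info = {}
    for cm in model.metabolites:
        met_info[cm.id] = Metabolite(
            metabolite_id=str(cm.notes.get("metabolite_id", cm.id)),
            name=cm.name or "",
            compartment=str(cm.notes.get("base_compartment", cm.compartment)),
            cell_type=str(cm.notes.get("cell_type", "generic")),
        )
    reactions = []
    genes: set[str] = set()
    for cr in model.reactions:
        terms = []
        for cm, coeff in cr.metabolites.items():
            m = met_info[cm.id]
            terms.append(StoichTerm(m.metabolite_id, float(coeff), m.compartment, m.cell_type))
        gpr = _parse_gpr_string(cr.gene_reaction_rule)
        genes.update(g for conj in gpr for g in conj)
        reactions.append(
            Reaction(
                reaction_id=str(cr.notes.get("reaction_id", cr.id)),
                compartment=str(cr.notes.get("base_compartment", "cytosol")),
                cell_type=str(cr.notes.get("cell_type", "generic")),
                stoichiometry=tuple(sorted(terms)),
                reversible=cr.lower_bound < 0,
                gpr=gpr,
                transporter_class=str(cr.notes.get("transporter_class", "none")),
                reaction_name=cr.name or "",
                ec_number=str(cr.notes.get("ec_number", "")),
            )
        )
    return Reconstruction(
        reactions=reactions,
        metabolites=sorted(set(met_info.values()), key=lambda m: m.key),
        genes=sorted(genes),
        provenance=f"imported from SBML {path}",
    )
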