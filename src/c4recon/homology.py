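"""Best-hit homology lifting of a target genome onto the reference core model.

The reconstruction for a new grass genome is obtained by mapping its genes
onto the reference genes of the core model through a standard 12-column
alignment hit table (query, subject, percent identity, alignment length,
mismatches, gap opens, qstart, qend, sstart, send, e-value, bitscore).
Each target gene keeps its single best passing hit; the reference
gene-enzyme-reaction table is then rewritten in the target namespace and fed
to the collapser.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import AssociationEntry, RowError

HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

DEFAULT_MAX_EVALUE = 1e-10
DEFAULT_MIN_IDENTITY = 30.0
DEFAULT_MIN_COVERAGE = 50.0


@dataclass(frozen=True)
class HitRow:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"percent identity {self.percent_identity} outside [0, 100]")


@dataclass
class GeneMap:
    """target gene -> reference gene, with the thresholds that produced it."""

    mapping: dict[str, str] = field(default_factory=dict)
    max_evalue: float = DEFAULT_MAX_EVALUE
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_coverage: float = DEFAULT_MIN_COVERAGE

    def __len__(self) -> int:
        return len(self.mapping)

    def inverse(self) -> dict[str, list[str]]:
        """reference gene -> sorted list of target genes mapping to it."""
        inv: dict[str, list[str]] = {}
        for tgt in sorted(self.mapping):
            inv.setdefault(self.mapping[tgt], []).append(tgt)
        return inv


def read_hit_table(path) -> list[HitRow]:
    """Parse a 12-column tabular alignment file; order preserved."""
    rows: list[HitRow] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 12:
                raise RowError(f"expected 12 columns, got {len(fields)}", lineno)
            try:
                rows.append(
                    HitRow(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise RowError(str(exc), lineno) from exc
    return rows


def write_hit_table(rows: Iterable[HitRow], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        f"{r.percent_identity:.2f}",
                        str(r.alignment_length),
                        str(r.mismatches),
                        str(r.gap_opens),
                        str(r.qstart),
                        str(r.qend),
                        str(r.sstart),
                        str(r.send),
                        f"{r.evalue:.3g}",
                        f"{r.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


def _query_coverage(row: HitRow, qlen: int | None) -> float:
    span = abs(row.qend - row.qstart) + 1
    if qlen is None or qlen <= 0:
        return 100.0
    return 100.0 * span / qlen


def best_hits(
    rows: Sequence[HitRow],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    query_lengths: Mapping[str, int] | None = None,
) -> GeneMap:
    """Single best passing hit per query.

    A row passes when e-value <= ``max_evalue``, identity >= ``min_identity``
    and query coverage >= ``min_coverage`` percent.  Coverage is the aligned
    query span over the query length; lengths come from ``query_lengths``
    when given, otherwise the per-query maximum ``qend`` stands in (exact for
    full-length alignment coordinates).  Among passing rows the lowest
    e-value wins, ties broken by highest bitscore, then lexicographically
    smallest subject id — so the result depends only on the row multiset,
    never on input order.
    """
    qlens: dict[str, int] = dict(query_lengths) if query_lengths else {}
    if not query_lengths:
        for r in rows:
            qlens[r.query_id] = max(qlens.get(r.query_id, 0), r.qend)

    best: dict[str, HitRow] = {}
    for r in rows:
        if r.evalue > max_evalue or r.percent_identity < min_identity:
            continue
        if _query_coverage(r, qlens.get(r.query_id)) < min_coverage:
            continue
        cur = best.get(r.query_id)
        if cur is None or _hit_rank(r) < _hit_rank(cur):
            best[r.query_id] = r
    mapping = {q: best[q].subject_id for q in sorted(best)}
    return GeneMap(
        mapping=mapping,
        max_evalue=max_evalue,
        min_identity=min_identity,
        min_coverage=min_coverage,
    )


def _hit_rank(r: HitRow) -> tuple:
    return (r.evalue, -r.bitscore, r.subject_id)


def reciprocal_best_hits(
    forward: Sequence[HitRow],
    backward: Sequence[HitRow],
    **thresholds,
) -> GeneMap:
    """Stricter mode: keep target->reference pairs that are mutual best hits."""
    fwd = best_hits(forward, **thresholds)
    bwd = best_hits(backward, **thresholds)
    mapping = {
        t: ref for t, ref in fwd.mapping.items() if bwd.mapping.get(ref) == t
    }
    return GeneMap(
        mapping=mapping,
        max_evalue=fwd.max_evalue,
        min_identity=fwd.min_identity,
        min_coverage=fwd.min_coverage,
    )


@dataclass
class LiftResult:
    entries: list[AssociationEntry]
    dropped_entries: int
    unmapped_reference_genes: list[str]


def lift_model(core: Sequence[AssociationEntry], gmap: GeneMap) -> LiftResult:
    """Rewrite the reference gene-enzyme-reaction table in the target namespace.

    Every entry whose reference gene has at least one inverse image under the
    gene map is replicated once per mapping target gene; entries whose
    reference gene attracted no target hit are dropped (and counted, so the
    shrinkage of the lifted model relative to the reference is explainable).
    """
    inv = gmap.inverse()
    lifted: list[AssociationEntry] = []
    dropped = 0
    unmapped: set[str] = set()
    for e in core:
        targets = inv.get(e.gene_id)
        if not targets:
            dropped += 1
            unmapped.add(e.gene_id)
            continue
        for t in targets:
            lifted.append(
                AssociationEntry(
                    gene_id=t,
                    reaction_id=e.reaction_id,
                    reaction_name=e.reaction_name,
                    ec_number=e.ec_number,
                    compartment=e.compartment,
                    cell_type=e.cell_type,
                    stoichiometry=e.stoichiometry,
                    reversible=e.reversible,
                    transporter_class=e.transporter_class,
                    complex_group=e.complex_group,
                )
            )
    return LiftResult(
        entries=lifted, dropped_entries=dropped, unmapped_reference_genes=sorted(unmapped)
    )


_VERSION_SUFFIX = re.compile(r"\.\d+$")
_TRANSCRIPT_SUFFIX = re.compile(r"(?<=\d)m$")


def normalize_gene_id(raw: str) -> str:
    """Strip transcript-model suffixes so gene- and transcript-level ids join.

    Millet/foxtail locus identifiers appear both as ``Si000645`` (gene) and
    ``Si000645m`` / ``Si000645m.2`` (transcript model, optional version);
    the trailing ``m`` after the numeric body and any ``.N`` version are
    removed.  Idempotent.
    """
    out = _VERSION_SUFFIX.sub("", raw.strip())
    return _TRANSCRIPT_SUFFIX.sub("", out)
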