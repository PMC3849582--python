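"""Phenotype gene sets and non-redundant gene-set collections.

A *gene set* is a single phenotype term together with the unique genes that
have been genetically associated with that phenotype (RNAi knockdowns or
curated variants in WormBase, allele-level phenotypic records in FlyBase).
A *collection* maps phenotype terms to gene sets and is non-redundant: each
term appears once and each gene appears at most once within a set.

Gene identifiers are compared case-insensitively after stripping any
parenthesized symbol (worm annotation files print ``locus_tag(symbol)``, and
the same gene can appear as ``B0035.8(HIS-48)`` and ``B0035.8(his-48)``).
The first-seen casing is preserved for output.
"""

from __future__ import annotations

import csv
import io
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, TextIO

from .errors import (
    DialectError,
    EmptyCollectionError,
    InvalidLabelError,
    ConfigurationError,
    NonRedundancyError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenePhenotypePair",
    "GeneSet",
    "GeneSetCollection",
    "CollectionOverlap",
    "normalize_gene_label",
    "normalize_phenotype_term",
    "parse_association_table",
    "build_collection",
    "merge_collections",
    "collection_overlap",
    "filter_by_size",
    "read_gmt",
    "write_gmt",
    "write_summary_tsv",
]

_LABEL_RE = re.compile(r"^([^()\s]+)\s*(?:\(\s*([^()]*?)\s*\))?$")


def normalize_gene_label(raw: str) -> tuple[str, str | None]:
    """Split a printed gene label into (gene_id, optional symbol).

    ``"AC7.1(tag-49)"`` -> ``("AC7.1", "tag-49")``; ``"arm"`` -> ``("arm",
    None)``. Casing is preserved; callers compare identifiers case-
    insensitively.
    """
    if raw is None:
        raise InvalidLabelError("gene label is None")
    text = raw.strip()
    if not text:
        raise InvalidLabelError("gene label is empty")
    m = _LABEL_RE.match(text)
    if m is None:
        # fall back: primary token before whitespace or '('
        token = re.split(r"[\s(]", text, maxsplit=1)[0]
        if not token:
            raise InvalidLabelError(f"cannot parse gene label {raw!r}")
        return token, None
    gene_id, symbol = m.group(1), m.group(2)
    return gene_id, (symbol or None)


def normalize_phenotype_term(raw: str) -> str:
    """Trim and collapse internal whitespace/underscores to single underscores.

    ``"life span variant"`` and ``"life_span_variant"`` normalize to the same
    term.
    """
    return "_".join(raw.replace("_", " ").split())


@dataclass(frozen=True)
class GenePhenotypePair:
    """One curated association between a phenotype term and a gene."""

    phenotype_term: str
    gene_id: str
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if not self.phenotype_term:
            raise InvalidLabelError("phenotype term is empty")
        if not self.gene_id or re.search(r"\s", self.gene_id):
            raise InvalidLabelError(f"bad gene id {self.gene_id!r}")


class GeneSet:
    """A phenotype term plus its unique annotated gene identifiers."""

    __slots__ = ("name", "_genes", "symbols")

    def __init__(self, name: str, genes: Iterable[str] = (),
                 symbols: Mapping[str, str] | None = None):
        self.name = name
        # casefolded id -> first-seen casing
        self._genes: dict[str, str] = {}
        self.symbols: dict[str, str] = dict(symbols or {})
        for g in genes:
            self.add(g)

    def add(self, gene_id: str, symbol: str | None = None) -> bool:
        """Add a gene; returns False if it was already present."""
        key = gene_id.casefold()
        if key in self._genes:
            return False
        self._genes[key] = gene_id
        if symbol:
            self.symbols.setdefault(key, symbol)
        return True

    @property
    def genes(self) -> tuple[str, ...]:
        """Stored gene identifiers, sorted, first-seen casing."""
        return tuple(sorted(self._genes.values(), key=str.casefold))

    @property
    def gene_keys(self) -> frozenset[str]:
        """Casefolded identifiers used for membership and overlap."""
        return frozenset(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id.casefold() in self._genes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSet):
            return NotImplemented
        return self.name == other.name and self.gene_keys == other.gene_keys

    def __hash__(self) -> int:
        return hash((self.name, self.gene_keys))

    def __repr__(self) -> str:
        return f"GeneSet({self.name!r}, n={len(self)})"


class GeneSetCollection:
    """Named, non-redundant map of phenotype term -> :class:`GeneSet`."""

    def __init__(self, label: str, sets: Iterable[GeneSet] = (),
                 provenance: str = ""):
        self.label = label
        self.provenance = provenance
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise NonRedundancyError(
                    f"duplicate phenotype term {s.name!r} in {label!r}")
            self._sets[s.name] = s

    @property
    def sets(self) -> dict[str, GeneSet]:
        return self._sets

    def terms(self) -> list[str]:
        return sorted(self._sets)

    def all_gene_keys(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self._sets.values():
            out |= s.gene_keys
        return frozenset(out)

    def __len__(self) -> int:
        return len(self._sets)

    def __getitem__(self, term: str) -> GeneSet:
        return self._sets[term]

    def __contains__(self, term: str) -> bool:
        return term in self._sets

    def __iter__(self) -> Iterator[GeneSet]:
        for term in self.terms():
            yield self._sets[term]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return (self.terms() == other.terms()
                and all(self[t].gene_keys == other[t].gene_keys
                        for t in self.terms()))

    def __repr__(self) -> str:
        return f"GeneSetCollection({self.label!r}, sets={len(self)})"


@dataclass(frozen=True)
class CollectionOverlap:
    """Counts of genes and phenotype terms shared by two collections."""

    shared_genes: int
    shared_phenotypes: int


# ---------------------------------------------------------------------------
# association-table parsing

DIALECTS = ("worm_pairs", "fly_alleles")

_ALLELE_SUFFIX_RE = re.compile(r"\[[^\]]*\]\s*$")


def default_allele_to_gene(allele: str) -> str:
    """Strip a FlyBase-style bracketed allele designator: arm[4] -> arm."""
    return _ALLELE_SUFFIX_RE.sub("", allele.strip())


def _open_source(source) -> tuple[TextIO, bool]:
    if hasattr(source, "read"):
        return source, False
    return open(os.fspath(source), "r", encoding="utf-8"), True


def _sniff_delimiter(line: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if "\t" in line else ","


def parse_association_table(
    source,
    dialect: str,
    *,
    delimiter: str | None = None,
    allele_to_gene: Callable[[str], str] | None = None,
) -> list[GenePhenotypePair]:
    """Parse a delimited gene–phenotype table into association pairs.

    ``worm_pairs`` rows are ``gene<sep>phenotype``; ``fly_alleles`` rows are
    ``allele<sep>phenotypic description`` and the allele is mapped to its
    gene (default: strip the bracketed allele designator; pass
    ``allele_to_gene`` to override, e.g. with a FlyBase lookup). Malformed
    rows are skipped with a logged warning.
    """
    if dialect not in DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}; expected {DIALECTS}")
    mapper = allele_to_gene or default_allele_to_gene
    stream, close = _open_source(source)
    pairs: list[GenePhenotypePair] = []
    skipped = 0
    try:
        sep: str | None = None if delimiter is None else delimiter
        for lineno, line in enumerate(stream, start=1):
            stripped = line.strip()
            if not stripped:
                skipped += 1
                logger.warning("skipping blank row %d", lineno)
                continue
            if stripped.startswith("#"):
                continue
            if sep is None:
                sep = _sniff_delimiter(line, delimiter)
            fields = next(csv.reader([line], delimiter=sep))
            fields = [f.strip() for f in fields]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                skipped += 1
                logger.warning("skipping malformed row %d: %r", lineno,
                               line.rstrip("\n"))
                continue
            raw_gene, raw_phen = fields[0], fields[1]
            try:
                if dialect == "fly_alleles":
                    raw_gene = mapper(raw_gene)
                gene_id, symbol = normalize_gene_label(raw_gene)
                term = normalize_phenotype_term(raw_phen)
                pairs.append(GenePhenotypePair(term, gene_id, symbol))
            except InvalidLabelError as exc:
                skipped += 1
                logger.warning("skipping row %d (%s)", lineno, exc)
    finally:
        if close:
            stream.close()
    if skipped:
        logger.warning("parse_association_table: skipped %d malformed rows",
                       skipped)
    return pairs


# ---------------------------------------------------------------------------
# collection construction and algebra

def build_collection(pairs: Iterable[GenePhenotypePair],
                     label: str,
                     provenance: str = "") -> GeneSetCollection:
    """Collapse association pairs into a non-redundant collection.

    Duplicate (phenotype, gene) combinations are removed; one gene set is
    produced per unique phenotype term.
    """
    coll = GeneSetCollection(label, provenance=provenance)
    n = 0
    for p in pairs:
        n += 1
        gs = coll.sets.get(p.phenotype_term)
        if gs is None:
            gs = GeneSet(p.phenotype_term)
            coll.sets[p.phenotype_term] = gs
        gs.add(p.gene_id, p.gene_symbol)
    if n == 0:
        raise EmptyCollectionError("no association pairs supplied")
    return coll


def merge_collections(a: GeneSetCollection, b: GeneSetCollection,
                      label: str) -> GeneSetCollection:
    """Union of two collections: shared terms get the union of their genes."""
    merged = GeneSetCollection(
        label, provenance=f"merge of {a.label!r} and {b.label!r}")
    for src in (a, b):
        for s in src:
            tgt = merged.sets.get(s.name)
            if tgt is None:
                tgt = GeneSet(s.name)
                merged.sets[s.name] = tgt
            for key, stored in s._genes.items():
                tgt.add(stored, s.symbols.get(key))
    return merged


def collection_overlap(a: GeneSetCollection,
                       b: GeneSetCollection) -> CollectionOverlap:
    """Count genes and phenotype terms present in both collections."""
    shared_genes = len(a.all_gene_keys() & b.all_gene_keys())
    shared_terms = len(set(a.terms()) & set(b.terms()))
    return CollectionOverlap(shared_genes, shared_terms)


def filter_by_size(coll: GeneSetCollection, min_genes: int,
                   max_genes: int | None = None) -> GeneSetCollection:
    """Retain sets with min_genes <= size <= max_genes (inclusive bounds)."""
    if min_genes < 1:
        raise ConfigurationError("min_genes must be >= 1")
    if max_genes is not None and max_genes < min_genes:
        raise ConfigurationError("max_genes must be >= min_genes")
    kept = [s for s in coll
            if len(s) >= min_genes
            and (max_genes is None or len(s) <= max_genes)]
    return GeneSetCollection(
        coll.label, kept,
        provenance=(coll.provenance +
                    f" | size filter [{min_genes}, {max_genes or 'inf'}]"))


# ---------------------------------------------------------------------------
# GMT serialization (one set per line: name, description, genes...)

def read_gmt(source, label: str | None = None) -> GeneSetCollection:
    """Read a GMT stream/path into a collection.

    Duplicate set names raise a non-redundancy error naming the offenders;
    a duplicated gene within a line is stored once with a warning. Lines
    starting with ``#`` are treated as comments.
    """
    stream, close = _open_source(source)
    try:
        sets: list[GeneSet] = []
        seen: dict[str, int] = {}
        dupes: list[str] = []
        for line in stream:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                logger.warning("skipping short GMT line: %r", line[:60])
                continue
            name = normalize_phenotype_term(fields[0])
            if name in seen:
                dupes.append(name)
                continue
            seen[name] = 1
            gs = GeneSet(name)
            for raw in fields[2:]:
                if not raw.strip():
                    continue
                gene_id, symbol = normalize_gene_label(raw)
                if not gs.add(gene_id, symbol):
                    logger.warning("duplicate gene %r in set %r stored once",
                                   gene_id, name)
            sets.append(gs)
        if dupes:
            raise NonRedundancyError(
                f"duplicate set names in GMT: {sorted(set(dupes))}")
        inferred = label or getattr(source, "name", "gmt")
        return GeneSetCollection(str(inferred), sets)
    finally:
        if close:
            stream.close()


def write_gmt(coll: GeneSetCollection, target,
              description: str | None = None) -> None:
    """Write a collection as GMT; description column defaults to provenance."""
    desc = description if description is not None else (coll.provenance or "na")
    stream, close = (target, False) if hasattr(target, "write") else (
        open(os.fspath(target), "w", encoding="utf-8"), True)
    try:
        for s in coll:
            stream.write("\t".join([s.name, desc, *s.genes]) + "\n")
    finally:
        if close:
            stream.close()


def write_summary_tsv(coll: GeneSetCollection, target) -> None:
    """Write a two-column (term, size) summary of a collection."""
    stream, close = (target, False) if hasattr(target, "write") else (
        open(os.fspath(target), "w", encoding="utf-8"), True)
    try:
        stream.write("term\tsize\n")
        for s in coll:
            stream.write(f"{s.name}\t{len(s)}\n")
    finally:
        if close:
            stream.close()
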