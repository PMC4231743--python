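"""Proteome and gene-set IO.

A proteome here is a multi-isoform protein FASTA keyed by gene symbol: each
gene contributes one *non-redundant* counting unit no matter how many
isoforms it has, which is the unit all enrichment counts use.  Gene symbols
are compared case-insensitively after trimming (mouse symbol capitalisation
varies across resources).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "Proteome",
    "GeneSet",
    "read_fasta_proteome",
    "read_gene_set",
    "read_id_map",
    "genes_with_motif",
]

_GENE_TAG_RE = re.compile(r"(?:gene|GN)[=:]\s*([^\s|;]+)")


def _norm_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class ProteinRecord:
    """One protein isoform: accession, owning gene symbol, sequence."""

    protein_id: str
    gene_symbol: str
    sequence: str


class Proteome:
    """Gene-symbol-keyed collection of protein isoform sequences.

    Parameters
    ----------
    records:
        Iterable of :class:`ProteinRecord` (or ``(protein_id, gene_symbol,
        sequence)`` tuples).  Sequences are uppercased with trailing ``*``
        stripped; gene symbols are case-normalised.
    unmapped:
        Number of source records whose header yielded no gene symbol; these
        are excluded from the non-redundant gene universe but the count is
        kept so nothing is dropped without trace.
    """

    def __init__(self, records: Iterable, unmapped: int = 0):
        recs: list[ProteinRecord] = []
        for r in records:
            if not isinstance(r, ProteinRecord):
                r = ProteinRecord(*r)
            recs.append(
                ProteinRecord(
                    r.protein_id,
                    _norm_symbol(r.gene_symbol),
                    r.sequence.upper().rstrip("*"),
                )
            )
        self.records: tuple[ProteinRecord, ...] = tuple(recs)
        self.unmapped = int(unmapped)
        index: dict[str, list[int]] = {}
        for i, r in enumerate(self.records):
            index.setdefault(r.gene_symbol, []).append(i)
        self.index: dict[str, list[int]] = index

    @property
    def n_genes(self) -> int:
        """Number of distinct (non-redundant) gene symbols."""
        return len(self.index)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.index)

    def isoforms(self, gene_symbol: str) -> list[ProteinRecord]:
        return [self.records[i] for i in self.index[_norm_symbol(gene_symbol)]]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def write_fasta(self, path) -> None:
        """Write as FASTA with ``>protein_id gene=SYMBOL`` headers."""
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.protein_id} gene={r.gene_symbol}\n")
                for i in range(0, len(r.sequence), 60):
                    fh.write(r.sequence[i : i + 60] + "\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<Proteome: {len(self.records)} isoforms, "
                f"{self.n_genes} genes, {self.unmapped} unmapped>")


@dataclass
class GeneSet:
    """A named set of gene symbols (e.g. the circadian genes).

    ``universe_size`` optionally records the total gene count of the
    originating expression dataset, which may differ from the proteome's.
    """

    name: str
    symbols: frozenset[str]
    universe_size: int | None = None

    def __post_init__(self) -> None:
        self.symbols = frozenset(_norm_symbol(s) for s in self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return _norm_symbol(symbol) in self.symbols


def _make_header_rule(header_rule) -> Callable:
    """Build a ``record -> gene symbol or None`` extractor.

    Accepts ``"gene_tag"`` (a ``gene=SYMBOL`` / ``GN=SYMBOL`` tag in the
    description), a ``(delimiter, index)`` field selector applied to the ID
    token, a mapping ``protein_id -> gene symbol``, or any callable taking a
    Biopython ``SeqRecord``.
    """
    if header_rule == "gene_tag":

        def rule(rec):
            m = _GENE_TAG_RE.search(rec.description)
            return m.group(1) if m else None

        return rule
    if isinstance(header_rule, tuple) and len(header_rule) == 2:
        delim, idx = header_rule

        def rule(rec):
            parts = rec.id.split(delim)
            return parts[idx] if idx < len(parts) else None

        return rule
    if isinstance(header_rule, Mapping):

        def rule(rec):
            return header_rule.get(rec.id)

        return rule
    if callable(header_rule):
        return header_rule
    raise TypeError(f"unsupported header_rule {header_rule!r}")


def read_fasta_proteome(path, header_rule="gene_tag") -> Proteome:
    """Read a multi-isoform protein FASTA into a :class:`Proteome`.

    Records whose header yields no gene symbol go to the ``unmapped``
    counter rather than being silently dropped.  Raises ``ValueError`` on an
    empty file or if no record maps to a gene symbol.
    """
    rule = _make_header_rule(header_rule)
    records: list[ProteinRecord] = []
    unmapped = 0
    n_seen = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        symbol = rule(rec)
        if symbol is None or not str(symbol).strip():
            unmapped += 1
            continue
        records.append(ProteinRecord(rec.id, str(symbol), str(rec.seq)))
    if n_seen == 0:
        raise ValueError(f"no FASTA records in {path}")
    if not records:
        raise ValueError(f"no records in {path} mapped to a gene symbol")
    return Proteome(records, unmapped=unmapped)


def read_id_map(path) -> dict[str, str]:
    """Read a two-column ``protein_id<TAB>gene_symbol`` mapping table."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pid, _, sym = line.partition("\t")
        if sym:
            mapping[pid.strip()] = sym.strip()
    if not mapping:
        raise ValueError(f"no id mappings in {path}")
    return mapping


def read_gene_set(path, name: str | None = None,
                  universe_size: int | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list (``#`` comments, blanks ignored).

    Symbols are deduplicated after case normalisation; an empty set is an
    error.
    """
    symbols = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbols.add(_norm_symbol(line))
    if not symbols:
        raise ValueError(f"gene set {path} is empty")
    return GeneSet(name=name or Path(path).stem, symbols=frozenset(symbols),
                   universe_size=universe_size)


def genes_with_motif(proteome: Proteome, hits: pd.DataFrame,
                     pattern_name: str) -> frozenset[str]:
    """Genes of ``proteome`` with >= 1 hit of ``pattern_name`` on any isoform.

    ``hits`` must be a hit table from :func:`~slimscreen.patterns.scan_proteome`
    over this proteome.  A pattern that was scanned but hit nothing yields
    the empty set; a pattern that was never scanned raises ``KeyError``.
    """
    scanned = hits.attrs.get("patterns")
    if scanned is None:
        scanned = list(hits["pattern"].unique())
    if pattern_name not in scanned:
        raise KeyError(f"pattern {pattern_name!r} was not scanned")
    if len(hits) == 0:
        return frozenset()
    sub = hits.loc[hits["pattern"] == pattern_name, "gene"]
    return frozenset(sub) & proteome.genes
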