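"""Motif presence/position across ortholog sequences.

Reduces "is the motif evolutionarily conserved?" to a per-species report:
for each ortholog sequence, is the motif present, where, and matching which
pattern.  For the PXDLS family the scan uses a broad-to-stringent variant
cascade (broadest pattern first); the *anchor* of an instance is its first
residue — conventionally the leading proline — which is how point mutants
such as P72A are named.

No multiple sequence alignment is performed: the report states presence and
position, not alignment statistics.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .patterns import (
    PXDLS_FAMILY,
    MotifPattern,
    registry_pattern,
    scan_sequence,
)

__all__ = [
    "ConservationRecord",
    "AnchorResult",
    "pxdls_family_patterns",
    "conservation_report",
    "motif_anchor_position",
    "fetch_accession",
]


@dataclass(frozen=True)
class ConservationRecord:
    """Motif status of one species' ortholog sequence."""

    species_label: str
    accession: str
    pattern_name: str
    hits: tuple[tuple[int, int, str], ...]  # (start, end, peptide)

    @property
    def motif_present(self) -> bool:
        return len(self.hits) > 0


@dataclass(frozen=True)
class AnchorResult:
    """Position of the first motif instance in a sequence (or absence)."""

    present: bool
    position: int | None = None
    variant_name: str | None = None
    peptide: str | None = None


def pxdls_family_patterns() -> list[MotifPattern]:
    """The five PXDLS variants in broad-to-stringent cascade order."""
    return [registry_pattern(name) for name in PXDLS_FAMILY]


def _resolve_patterns(pattern) -> list[MotifPattern]:
    if isinstance(pattern, MotifPattern):
        return [pattern]
    if isinstance(pattern, str) and pattern.upper().replace("-FAMILY", "") == "PXDLS":
        return pxdls_family_patterns()
    raise TypeError(
        "pattern must be a MotifPattern or the family label 'PXDLS-family'"
    )


def _scan_cascade(sequence: str, patterns: Sequence[MotifPattern]):
    """First pattern in cascade order with >= 1 hit, with its hits."""
    for pat in patterns:
        hits = scan_sequence(pat, sequence)
        if hits:
            return pat, hits
    return patterns[0], []


def conservation_report(ortholog_fastas, pattern) -> list[ConservationRecord]:
    """Per-species motif presence/position report.

    Parameters
    ----------
    ortholog_fastas:
        List of ``(species_label, fasta_path)``; the first record of each
        file is used and its ID taken as the accession.
    pattern:
        A single :class:`MotifPattern`, or ``"PXDLS-family"`` to scan the
        five-variant cascade broadest-first.

    Records come back in input order; each species is scanned independently
    (no cross-sequence state).
    """
    patterns = _resolve_patterns(pattern)
    records: list[ConservationRecord] = []
    for label, path in ortholog_fastas:
        try:
            rec = next(SeqIO.parse(str(path), "fasta"))
        except StopIteration:
            raise ValueError(f"no FASTA records in {path}") from None
        pat, hits = _scan_cascade(str(rec.seq), patterns)
        records.append(
            ConservationRecord(
                species_label=label,
                accession=rec.id,
                pattern_name=pat.name,
                hits=tuple((h.start, h.end, h.peptide) for h in hits),
            )
        )
    return records


def motif_anchor_position(sequence: str, pattern_family="PXDLS") -> AnchorResult:
    """1-based start of the first motif-family instance in ``sequence``.

    Scans every family variant and reports the smallest hit start; ties go
    to the broadest variant (cascade order).  Absence is a typed result,
    not an exception, so callers can tabulate missing motifs.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    patterns = _resolve_patterns(pattern_family)
    best: tuple[int, int] | None = None  # (start, cascade index)
    best_hit = None
    for idx, pat in enumerate(patterns):
        for h in scan_sequence(pat, sequence):
            key = (h.start, idx)
            if best is None or key < best:
                best = key
                best_hit = (pat.name, h)
            break  # hits are sorted; only the first start matters
    if best is None:
        return AnchorResult(present=False)
    name, hit = best_hit
    return AnchorResult(present=True, position=hit.start,
                        variant_name=name, peptide=hit.peptide)


_EFETCH_URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=protein&rettype=fasta&retmode=text&id={acc}"
)


def fetch_accession(accession: str, out_path=None, timeout: float = 30.0) -> str:
    """Download one protein accession as FASTA text (requires network).

    Optional convenience for assembling ortholog panels from RefSeq
    accessions; nothing in the screen or the tests depends on it.
    """
    with urllib.request.urlopen(_EFETCH_URL.format(acc=accession),
                                timeout=timeout) as resp:
        text = resp.read().decode()
    if not text.startswith(">"):
        raise ValueError(f"unexpected response for accession {accession!r}")
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
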