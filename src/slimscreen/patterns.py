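"""PROSITE/fuzzpro-style motif patterns: parsing, the built-in registry and
exhaustive protein-sequence scanning.

Short linear motifs (SLiMs) are 3-11 residue elements, typically in
disordered regions, that mediate transient protein-protein interactions.
They are conventionally written in a small PROSITE-like dialect:

* a plain letter is that residue (``P`` matches proline only);
* ``[NDS]`` is a fixed class (any one of N, D or S);
* ``[^P]`` is a negated class (any standard residue except P; the
  typographic wedge ``∧`` is accepted and normalised to ``^``);
* ``X`` is a wildcard over the 20 standard residues;
* ``X(1,2)`` is a wildcard repeated one or two times — the only place a
  repeat count may appear.

Scanning is exhaustive: every distinct ``(start, end)`` span at which the
element list can be satisfied is reported, so a variable-length pattern may
yield two hits sharing a start.  A wildcard at either end of a pattern must
be satisfied by a real residue (no matching past the sequence boundary),
mirroring fuzzpro.  Coordinates are 1-based inclusive so that a hit's first
residue agrees with mutant nomenclature such as ``P72A``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "STANDARD_AA",
    "PatternSyntaxError",
    "PatternElement",
    "MotifPattern",
    "MotifHit",
    "parse_pattern",
    "builtin_registry",
    "registry_pattern",
    "scan_sequence",
    "scan_proteome",
    "read_patterns_file",
    "write_patterns_file",
]

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

# Nonstandard/ambiguity letters (B, J, O, U, X, Z) are deliberately matched
# by nothing: neither classes nor the wildcard.  This keeps ambiguity codes
# from inflating motif counts.

_HIT_COLUMNS = ["pattern", "gene", "protein", "start", "end", "peptide"]


class PatternSyntaxError(ValueError):
    """A motif pattern string that cannot be parsed in the dialect."""


@dataclass(frozen=True)
class PatternElement:
    """One position (or wildcard run) of a motif pattern.

    ``kind`` is ``"fixed"``, ``"negated"`` or ``"wildcard"``.  ``residues``
    preserves the order in which letters were written (used for canonical
    re-serialisation); matching treats it as a set.  Repeats other than
    (1, 1) are only legal on wildcards — the dialect only writes ``X(m,n)``.
    """

    kind: str
    residues: tuple[str, ...] = ()
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "negated", "wildcard"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "wildcard":
            if self.residues:
                raise ValueError("wildcard elements carry no residue set")
        else:
            if not self.residues:
                raise PatternSyntaxError("empty residue class")
            bad = set(self.residues) - _STANDARD_SET
            if bad:
                raise PatternSyntaxError(
                    f"non-standard residue letters in class: {sorted(bad)}"
                )
        if not (1 <= self.min_repeat <= self.max_repeat):
            raise PatternSyntaxError(
                f"invalid repeat range ({self.min_repeat},{self.max_repeat})"
            )
        if self.kind != "wildcard" and (self.min_repeat, self.max_repeat) != (1, 1):
            raise PatternSyntaxError("repeat counts are only allowed on wildcard X")

    @property
    def match_set(self) -> frozenset[str]:
        """Residues this element accepts (for one repeat)."""
        if self.kind == "wildcard":
            return _STANDARD_SET
        if self.kind == "fixed":
            return frozenset(self.residues)
        return _STANDARD_SET - frozenset(self.residues)

    def matches(self, letter: str) -> bool:
        return letter in self.match_set

    def serialize(self) -> str:
        """Canonical dialect text for this element."""
        if self.kind == "wildcard":
            body = "X"
        elif self.kind == "fixed" and len(self.residues) == 1:
            body = self.residues[0]
        elif self.kind == "fixed":
            body = "[" + "".join(self.residues) + "]"
        else:
            body = "[^" + "".join(self.residues) + "]"
        if (self.min_repeat, self.max_repeat) != (1, 1):
            body += f"({self.min_repeat},{self.max_repeat})"
        return body

    def _regex_chunk(self) -> str:
        """Regex character class for a single repeat of this element."""
        allowed = sorted(self.match_set)
        if len(allowed) == 1:
            return allowed[0]
        return "[" + "".join(allowed) + "]"


@dataclass(frozen=True)
class MotifPattern:
    """A named, compiled motif pattern.

    ``raw`` is the pattern string as supplied (wedge-normalised);
    ``canonical`` re-serialises the element list and must round-trip.
    ``min_len``/``max_len`` are the sums of element min/max repeats.
    """

    name: str
    raw: str
    elements: tuple[PatternElement, ...]

    @property
    def min_len(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_len(self) -> int:
        return sum(e.max_repeat for e in self.elements)

    @property
    def canonical(self) -> str:
        return "".join(e.serialize() for e in self.elements)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}: {self.raw}"


@dataclass(frozen=True)
class MotifHit:
    """One match of one pattern on one protein, 1-based inclusive."""

    pattern_name: str
    protein_id: str
    gene_symbol: str
    start: int
    end: int
    peptide: str


def _normalize(raw: str) -> str:
    # U+2227 LOGICAL AND and U+02C4 are typographic stand-ins for the caret.
    return raw.replace("∧", "^").replace("˄", "^")


def parse_pattern(raw: str, name: str | None = None) -> MotifPattern:
    """Parse a pattern string in the SLiM dialect into a :class:`MotifPattern`.

    Parameters
    ----------
    raw:
        Pattern text, e.g. ``"PX[NDS]LSX(1,2)[KR]"``.  Both ``^`` and the
        typographic ``∧`` mark negation.
    name:
        Label for the pattern; defaults to the normalised text itself.

    Raises
    ------
    PatternSyntaxError
        On unbalanced brackets/parentheses, empty classes, repeats attached
        to non-wildcard elements, or letters outside the 20 standard codes.
    """
    if not raw:
        raise PatternSyntaxError("empty pattern")
    text = _normalize(raw)
    elements: list[PatternElement] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise PatternSyntaxError(f"unbalanced '[' in {text!r}")
            body = text[i + 1 : j]
            negated = body.startswith("^")
            if negated:
                body = body[1:]
            if not body:
                raise PatternSyntaxError(f"empty residue class in {text!r}")
            seen: list[str] = []
            for letter in body:
                if letter not in seen:
                    seen.append(letter)
            elements.append(
                PatternElement("negated" if negated else "fixed", tuple(seen))
            )
            i = j + 1
        elif ch == "(":
            j = text.find(")", i)
            if j < 0:
                raise PatternSyntaxError(f"unbalanced '(' in {text!r}")
            body = text[i + 1 : j]
            m = re.fullmatch(r"(\d+)(?:,(\d+))?", body)
            if not m:
                raise PatternSyntaxError(f"malformed repeat {body!r} in {text!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            if lo < 1 or hi < lo:
                raise PatternSyntaxError(f"invalid repeat range ({lo},{hi})")
            if not elements or elements[-1].kind != "wildcard":
                raise PatternSyntaxError(
                    f"repeat {body!r} attached to a non-wildcard element"
                )
            if (elements[-1].min_repeat, elements[-1].max_repeat) != (1, 1):
                raise PatternSyntaxError("element already carries a repeat")
            elements[-1] = PatternElement("wildcard", (), lo, hi)
            i = j + 1
        elif ch in ("]", ")"):
            raise PatternSyntaxError(f"unbalanced {ch!r} in {text!r}")
        elif ch == "X":
            elements.append(PatternElement("wildcard"))
            i += 1
        elif ch in _STANDARD_SET:
            elements.append(PatternElement("fixed", (ch,)))
            i += 1
        else:
            raise PatternSyntaxError(f"unexpected character {ch!r} in {text!r}")
    if not elements:
        raise PatternSyntaxError("pattern has no elements")
    return MotifPattern(name=name if name is not None else text,
                        raw=text, elements=tuple(elements))


# --- compilation -----------------------------------------------------------

_MAX_ALLOCATIONS = 10_000


@lru_cache(maxsize=512)
def _compiled_by_length(pattern: MotifPattern) -> tuple[tuple[int, re.Pattern], ...]:
    """Compile a pattern to one overlap-aware regex per total match length.

    Each wildcard-repeat allocation fixes the length of every element, so
    the pattern expands into a handful of fixed-length concrete regexes.
    Allocations of equal total length are OR-ed inside a lookahead, which
    lets ``finditer`` report every match start while spans of different
    length are kept apart.
    """
    ranges = [range(e.min_repeat, e.max_repeat + 1) for e in pattern.elements]
    total = 1
    for r in ranges:
        total *= len(r)
        if total > _MAX_ALLOCATIONS:
            raise PatternSyntaxError(
                f"pattern {pattern.name!r} expands to too many repeat allocations"
            )
    by_length: dict[int, list[str]] = {}
    for counts in itertools.product(*ranges):
        body = "".join(
            e._regex_chunk() * c for e, c in zip(pattern.elements, counts)
        )
        by_length.setdefault(sum(counts), []).append(body)
    compiled = []
    for length in sorted(by_length):
        alts = sorted(set(by_length[length]))
        rx = re.compile("(?=" + ("|".join(alts) if len(alts) > 1 else alts[0]) + ")")
        compiled.append((length, rx))
    return tuple(compiled)


def scan_sequence(
    pattern: MotifPattern,
    sequence: str,
    protein_id: str = "",
    gene_symbol: str = "",
) -> list[MotifHit]:
    """Find every match span of ``pattern`` in ``sequence``.

    The sequence is uppercased and a trailing stop ``*`` is stripped.  All
    distinct ``(start, end)`` spans are returned, sorted by (start, end);
    an empty sequence yields an empty list.
    """
    seq = sequence.upper().rstrip("*")
    hits: list[MotifHit] = []
    for length, rx in _compiled_by_length(pattern):
        for m in rx.finditer(seq):
            s = m.start()
            if s + length > len(seq):
                continue
            hits.append(
                MotifHit(pattern.name, protein_id, gene_symbol,
                         s + 1, s + length, seq[s : s + length])
            )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def scan_proteome(patterns: Sequence[MotifPattern], proteome) -> pd.DataFrame:
    """Scan every isoform of ``proteome`` with every pattern.

    Returns a hit table with columns ``pattern, gene, protein, start, end,
    peptide`` in deterministic (pattern, gene, protein, start, end) order.
    The list of scanned pattern names travels in ``df.attrs["patterns"]`` so
    that downstream per-gene counting can distinguish "pattern scanned, no
    hits" from "pattern never scanned".
    """
    records = sorted(proteome.records, key=lambda r: (r.gene_symbol, r.protein_id))
    rows: list[tuple] = []
    for pat in patterns:
        for rec in records:
            for h in scan_sequence(pat, rec.sequence, rec.protein_id, rec.gene_symbol):
                rows.append((pat.name, rec.gene_symbol, rec.protein_id,
                             h.start, h.end, h.peptide))
    df = pd.DataFrame(rows, columns=_HIT_COLUMNS)
    df["start"] = df["start"].astype(int) if len(df) else df["start"]
    df["end"] = df["end"].astype(int) if len(df) else df["end"]
    df.attrs["patterns"] = [p.name for p in patterns]
    return df


# --- built-in registry -----------------------------------------------------

# The twelve protein-interaction motifs of the screen followed by the five
# PXDLS-family variants, raw strings exactly as printed (wedge-normalised).
_REGISTRY_SPECS: tuple[tuple[str, str], ...] = (
    ("WRPW", "[WFY]RP[WFY]"),
    ("TRAF6", "PX[QE]XX[DFYWE]"),
    ("RGD", "RGD"),
    ("PXDLS_screen", "PX[NDS]LSX(1,2)[KR]"),
    ("PTAP", "XP[TS]APX"),
    ("PPXY", "PPXY"),
    ("PDZ", "X[ST]X[LV]"),
    ("PAM2", "SX[LFP]NXXAXXF"),
    ("NPF", "XNPFX"),
    ("LXXLL", "[^P]L[^P][^P]LL[^P]"),
    ("LXCXE", "[LI]XCX[DE]"),
    ("CaM", "[ILV]QXXXRXXXX[RK]XX[FILVWY]"),
    ("PXDLS_broad", "PX[NDS]L[VTSAC]X(1,2)[KR]"),
    ("PXNDSLS", "PX[NDS]LS"),
    ("PXDLS_core", "PXDLS"),
    ("PXDLS_KR", "PX[NDS]LSX(1,2)[KR]"),
    ("PXDLS_strict", "PXDLSX(1,2)[KR]"),
)

#: PXDLS-family variant names in broad-to-stringent cascade order.
PXDLS_FAMILY: tuple[str, ...] = (
    "PXDLS_broad", "PXDLS_KR", "PXDLS_strict", "PXNDSLS", "PXDLS_core",
)


def builtin_registry() -> list[MotifPattern]:
    """The 17 built-in patterns: 12 screen motifs + 5 PXDLS variants."""
    return [parse_pattern(raw, name) for name, raw in _REGISTRY_SPECS]


def registry_pattern(name: str) -> MotifPattern:
    """Look up a single built-in pattern by name."""
    for pat_name, raw in _REGISTRY_SPECS:
        if pat_name == name:
            return parse_pattern(raw, pat_name)
    raise KeyError(f"no built-in pattern named {name!r}")


def write_patterns_file(patterns: Iterable[MotifPattern], path) -> None:
    """Write patterns as ``name<TAB>pattern`` lines."""
    with open(path, "w") as fh:
        for p in patterns:
            fh.write(f"{p.name}\t{p.raw}\n")


def read_patterns_file(path) -> list[MotifPattern]:
    """Read a ``name<TAB>pattern`` file (blank lines and ``#`` comments ok)."""
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, raw = line.partition("\t")
        if not raw:
            raise PatternSyntaxError(f"malformed patterns line: {line!r}")
        patterns.append(parse_pattern(raw.strip(), name.strip()))
    if not patterns:
        raise PatternSyntaxError(f"no patterns found in {path}")
    return patterns
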