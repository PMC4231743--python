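"""Shared fixtures and the independent brute-force matching oracle.

The oracle checks every substring of candidate length element-by-element
over all wildcard repeat allocations.  It shares no code with the compiled
regex scanner it validates.
"""

from __future__ import annotations

import numpy as np
import pytest

from slimscreen.patterns import (
    STANDARD_AA,
    MotifPattern,
    PatternElement,
    parse_pattern,
)
from slimscreen.proteome import GeneSet, ProteinRecord, Proteome

_STANDARD = set(STANDARD_AA)


def _element_accepts(el: PatternElement, letter: str) -> bool:
    if letter not in _STANDARD:
        return False  # nonstandard/ambiguity codes match nothing
    if el.kind == "wildcard":
        return True
    if el.kind == "fixed":
        return letter in el.residues
    return letter not in el.residues


def _ends_from(elements, seq: str, i: int):
    """Yield every end index (exclusive) reachable matching elements at i."""
    if not elements:
        yield i
        return
    el = elements[0]
    for r in range(el.min_repeat, el.max_repeat + 1):
        if i + r > len(seq):
            break
        if all(_element_accepts(el, seq[i + j]) for j in range(r)):
            yield from _ends_from(elements[1:], seq, i + r)


def brute_force_hits(pattern: MotifPattern, sequence: str) -> set[tuple[int, int]]:
    """All distinct 1-based inclusive (start, end) spans matching pattern."""
    seq = sequence.upper().rstrip("*")
    spans = set()
    for start in range(len(seq)):
        for end in _ends_from(list(pattern.elements), seq, start):
            spans.add((start + 1, end))
    return spans


def random_pattern(rng: np.random.Generator, max_elements: int = 8) -> MotifPattern:
    """A random dialect pattern with <= 2 repeat wildcards."""
    n = int(rng.integers(1, max_elements + 1))
    parts = []
    n_repeats = 0
    for _ in range(n):
        kind = rng.choice(["letter", "class", "negated", "wild"],
                          p=[0.35, 0.2, 0.15, 0.3])
        if kind == "letter":
            parts.append(STANDARD_AA[rng.integers(20)])
        elif kind == "class":
            size = int(rng.integers(2, 6))
            letters = rng.choice(list(STANDARD_AA), size=size, replace=False)
            parts.append("[" + "".join(letters) + "]")
        elif kind == "negated":
            size = int(rng.integers(1, 4))
            letters = rng.choice(list(STANDARD_AA), size=size, replace=False)
            parts.append("[^" + "".join(letters) + "]")
        else:
            if n_repeats < 2 and rng.random() < 0.4:
                lo = int(rng.integers(1, 3))
                hi = lo + int(rng.integers(0, 3))
                parts.append(f"X({lo},{hi})")
                n_repeats += 1
            else:
                parts.append("X")
    return parse_pattern("".join(parts), "random")


def random_sequence(rng: np.random.Generator, max_len: int = 200) -> str:
    """Random protein-like sequence with occasional nonstandard letters."""
    n = int(rng.integers(0, max_len + 1))
    letters = list(STANDARD_AA) + ["B", "Z", "X", "U"]
    p = np.array([1.0] * 20 + [0.15] * 4)
    return "".join(rng.choice(letters, size=n, p=p / p.sum()))


@pytest.fixture
def toy_proteome() -> Proteome:
    """Three genes; GENE1 has two isoforms, GENE2 carries a PXDLS instance."""
    return Proteome(
        [
            ProteinRecord("P1.1", "GENE1", "MKTAYIAKQRQISFVK"),
            ProteinRecord("P1.2", "GENE1", "MKTAYIAKQR"),
            ProteinRecord("P2.1", "GENE2", "MAAPIDLSLKAAAAAA"),
            ProteinRecord("P3.1", "GENE3", "GGGGGGGGGGGG"),
        ]
    )


@pytest.fixture
def toy_gene_set() -> GeneSet:
    return GeneSet(name="circadian", symbols=frozenset({"GENE2", "GENE3"}))
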