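"""Synthetic proteomes with planted motif enrichment.

The generator emulates the inputs of the screen — a multi-isoform proteome
and a "circadian" gene label set — with *known* structure: background
sequences are drawn i.i.d. from a residue distribution, and a concrete
instantiation of a chosen motif pattern is spliced into one isoform of each
"planted" gene.  Planting probabilities differ by class
(``p_motif_circadian`` vs ``p_motif_noncircadian``), so the true forward
enrichment is known by construction::

    expected_forward_pct = (p_c - p_n) / p_n * 100     (ignoring chance)

Background sequences can also match the pattern by chance at a small rate
``q``; with it the expected measured enrichment is slightly *diluted*::

    E[forward] = (p_c' - p_n') / p_n' * 100,   p' = p + (1 - p) * q

(:func:`expected_forward_pct_with_background`).  Everything is
deterministic given the mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .patterns import (
    STANDARD_AA,
    MotifPattern,
    registry_pattern,
    scan_sequence,
)
from .proteome import GeneSet, ProteinRecord, Proteome

__all__ = [
    "SWISSPROT_FREQS",
    "SyntheticConfig",
    "SyntheticTruth",
    "instantiate_pattern",
    "splice_motif_instance",
    "generate",
    "synthetic_ortholog_sequence",
    "expected_forward_pct_with_background",
]

#: Swiss-Prot-like background residue frequencies (UniProtKB/Swiss-Prot
#: release statistics, renormalised over the 20 standard letters).
SWISSPROT_FREQS: dict[str, float] = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0664, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

_ALPHABET = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)


def _freq_vector(background) -> np.ndarray:
    if background == "uniform" or background is None:
        p = np.full(20, 1 / 20)
    elif background == "swissprot":
        p = np.array([SWISSPROT_FREQS[a] for a in STANDARD_AA])
    elif isinstance(background, Mapping):
        p = np.array([float(background.get(a, 0.0)) for a in STANDARD_AA])
    else:
        raise ValueError(f"unsupported background {background!r}")
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("background frequencies must be non-negative, sum > 0")
    return p / p.sum()


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the scale of the real screen: a 20,000-gene proteome
    with ~12.5% of genes labelled circadian, 1-2 isoforms of 200-400
    residues per gene, and the stringent PXDLS variant planted in 25% of
    circadian vs 20% of non-circadian genes (a true +25% forward
    enrichment).  The seed is mandatory.
    """

    seed: int
    n_genes: int = 20_000
    frac_circadian: float = 0.125
    isoforms_per_gene: tuple[int, int] = (1, 2)
    seq_len: tuple[int, int] = (200, 400)
    background: object = "uniform"
    p_motif_circadian: float = 0.25
    p_motif_noncircadian: float = 0.20
    planted_pattern: MotifPattern | None = None

    def __post_init__(self) -> None:
        if self.planted_pattern is None:
            self.planted_pattern = registry_pattern("PXDLS_strict")
        if not (0 < self.frac_circadian < 1):
            raise ValueError("frac_circadian must be in (0,1)")
        for p in (self.p_motif_circadian, self.p_motif_noncircadian):
            if not (0 <= p <= 1):
                raise ValueError("planting probabilities must be in [0,1]")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        lo, hi = self.isoforms_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("invalid isoforms_per_gene range")
        lo, hi = self.seq_len
        if not (1 <= lo <= hi):
            raise ValueError("invalid seq_len range")
        if lo < self.planted_pattern.max_len:
            raise ValueError(
                "seq_len minimum is shorter than the planted pattern"
            )
        _freq_vector(self.background)  # validate eagerly

    @property
    def expected_forward_pct(self) -> float:
        """Planted forward enrichment, ignoring chance background matches."""
        if self.p_motif_noncircadian == 0:
            raise ValueError("undefined for p_motif_noncircadian = 0")
        return (
            (self.p_motif_circadian - self.p_motif_noncircadian)
            / self.p_motif_noncircadian * 100.0
        )


@dataclass
class SyntheticTruth:
    """Planted parameters and realized per-gene outcomes of one dataset."""

    config: SyntheticConfig
    gene_symbols: list[str]
    circadian: np.ndarray  # bool per gene
    planted: np.ndarray  # bool per gene
    expected_forward_pct: float

    @property
    def n_planted_circadian(self) -> int:
        return int((self.planted & self.circadian).sum())

    @property
    def n_planted_noncircadian(self) -> int:
        return int((self.planted & ~self.circadian).sum())

    def to_json(self, path) -> None:
        payload = {
            "seed": self.config.seed,
            "n_genes": self.config.n_genes,
            "p_motif_circadian": self.config.p_motif_circadian,
            "p_motif_noncircadian": self.config.p_motif_noncircadian,
            "planted_pattern": self.config.planted_pattern.raw,
            "expected_forward_pct": self.expected_forward_pct,
            "n_circadian": int(self.circadian.sum()),
            "n_planted_circadian": self.n_planted_circadian,
            "n_planted_noncircadian": self.n_planted_noncircadian,
            "planted_genes": [
                g for g, p in zip(self.gene_symbols, self.planted) if p
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def instantiate_pattern(pattern: MotifPattern, rng: np.random.Generator) -> str:
    """Sample one concrete peptide matching ``pattern``.

    Wildcards and classes are sampled uniformly from their permitted
    residues; repeat counts uniformly from their range.  Raises on an
    element with an empty permitted set (e.g. a negation of all residues).
    """
    out = []
    for el in pattern.elements:
        allowed = sorted(el.match_set)
        if not allowed:
            raise ValueError(f"element {el.serialize()} permits no residue")
        count = int(rng.integers(el.min_repeat, el.max_repeat + 1))
        for _ in range(count):
            out.append(allowed[int(rng.integers(len(allowed)))])
    return "".join(out)


def splice_motif_instance(
    sequence: str,
    pattern: MotifPattern,
    position: int,
    rng: np.random.Generator,
) -> str:
    """Overwrite ``sequence`` at 0-based ``position`` with a pattern instance.

    The returned sequence has the same length and is guaranteed to match
    ``pattern`` at exactly the spliced location (verified by a post-hoc
    scan; construction makes failure impossible, the check is cheap
    insurance).
    """
    inst = instantiate_pattern(pattern, rng)
    if position < 0 or position + len(inst) > len(sequence):
        raise ValueError(
            f"instance of length {len(inst)} does not fit at {position} "
            f"in a {len(sequence)}-mer"
        )
    spliced = sequence[:position] + inst + sequence[position + len(inst):]
    starts = {h.start for h in scan_sequence(pattern, spliced)}
    assert position + 1 in starts, "spliced instance failed to scan"
    return spliced


def _random_sequences(rng, lengths: np.ndarray, freqs: np.ndarray) -> list[str]:
    """Draw i.i.d. background sequences of the given lengths."""
    total = int(lengths.sum())
    flat = _ALPHABET[rng.choice(20, size=total, p=freqs)]
    big = flat.tobytes().decode("ascii")
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return [big[offsets[i]: offsets[i + 1]] for i in range(len(lengths))]


def generate(config: SyntheticConfig) -> tuple[Proteome, GeneSet, SyntheticTruth]:
    """Generate a synthetic proteome, circadian gene list and ground truth.

    The circadian set is an exact-size uniform draw of
    ``round(frac_circadian * n_genes)`` genes.  Each planted gene receives
    one pattern instance spliced at a uniform interior position of one
    uniformly chosen isoform.  Byte-identical outputs for equal seeds.
    """
    rng = np.random.default_rng(config.seed)
    freqs = _freq_vector(config.background)
    ng = config.n_genes
    genes = [f"G{i:05d}" for i in range(ng)]

    m = int(round(config.frac_circadian * ng))
    m = min(max(m, 1), ng - 1)
    circadian = np.zeros(ng, dtype=bool)
    circadian[rng.choice(ng, size=m, replace=False)] = True

    p_gene = np.where(circadian, config.p_motif_circadian,
                      config.p_motif_noncircadian)
    planted = rng.random(ng) < p_gene

    iso_lo, iso_hi = config.isoforms_per_gene
    n_iso = rng.integers(iso_lo, iso_hi + 1, size=ng)
    len_lo, len_hi = config.seq_len
    lengths = rng.integers(len_lo, len_hi + 1, size=int(n_iso.sum()))
    seqs = _random_sequences(rng, lengths, freqs)

    offsets = np.concatenate([[0], np.cumsum(n_iso)])
    pat = config.planted_pattern
    records: list[ProteinRecord] = []
    for g in range(ng):
        gene_seqs = seqs[offsets[g]: offsets[g + 1]]
        if planted[g]:
            j = int(rng.integers(len(gene_seqs)))
            target = gene_seqs[j]
            # interior: keep at least one background residue on each side
            hi = len(target) - pat.max_len - 1
            pos = int(rng.integers(1, hi + 1)) if hi >= 1 else 0
            gene_seqs[j] = splice_motif_instance(target, pat, pos, rng)
        for j, s in enumerate(gene_seqs, start=1):
            records.append(ProteinRecord(f"{genes[g]}.{j}", genes[g], s))

    proteome = Proteome(records)
    gene_set = GeneSet(
        name="circadian",
        symbols=frozenset(g for g, c in zip(genes, circadian) if c),
        universe_size=ng,
    )
    truth = SyntheticTruth(
        config=config,
        gene_symbols=genes,
        circadian=circadian,
        planted=planted,
        expected_forward_pct=config.expected_forward_pct,
    )
    return proteome, gene_set, truth


def expected_forward_pct_with_background(
    p_circadian: float, p_noncircadian: float, chance_rate: float
) -> float:
    """Planted class contrast adjusted for chance background matches.

    ``chance_rate`` is the per-gene probability that an *unplanted* gene
    carries a chance instance of the pattern; it dilutes the planted
    contrast toward zero.
    """
    pc = p_circadian + (1 - p_circadian) * chance_rate
    pn = p_noncircadian + (1 - p_noncircadian) * chance_rate
    if pn == 0:
        raise ValueError("undefined when no non-circadian gene can be positive")
    return (pc - pn) / pn * 100.0


def expected_forward_statistic_pct(
    config: SyntheticConfig, chance_rate: float = 0.0
) -> float:
    """Exact expectation of the *measured* forward-enrichment statistic.

    The forward statistic compares the circadian motif rate ``k/M`` with
    the whole-universe rate ``n/N`` — and circadian genes are part of the
    universe, so the denominator is the mixture rate
    ``p̄ = frac·p_c + (1−frac)·p_n``, not ``p_n``.  With the per-gene
    chance-match rate ``q`` each class rate becomes ``p' = p + (1−p)q``::

        E[forward] ≈ (p_c' − p̄') / p̄' · 100

    This is strictly below the class contrast ``(p_c−p_n)/p_n·100``
    whenever the circadian fraction or the chance rate is non-zero (both
    dilute the contrast).
    """
    q = chance_rate
    pc = config.p_motif_circadian + (1 - config.p_motif_circadian) * q
    pn = (config.p_motif_noncircadian
          + (1 - config.p_motif_noncircadian) * q)
    mix = config.frac_circadian * pc + (1 - config.frac_circadian) * pn
    if mix == 0:
        raise ValueError("no gene can be motif-positive under this config")
    return (pc - mix) / mix * 100.0


def synthetic_ortholog_sequence(
    anchor: int,
    length: int,
    seed: int,
    pattern: MotifPattern | None = None,
    background: object = "uniform",
    max_tries: int = 200,
) -> str:
    """SYNTHETIC stand-in for an ortholog protein with a motif at ``anchor``.

    Builds a random background sequence of ``length`` residues and splices
    a PXDLS-family instance so that the *first* family hit starts exactly at
    the 1-based ``anchor`` (backgrounds that happen to contain an earlier
    family hit are redrawn).  Used to exercise anchor-position reporting at
    biologically motivated coordinates without shipping database sequences;
    these are not the real RefSeq proteins.
    """
    from .conservation import motif_anchor_position, pxdls_family_patterns

    pat = pattern if pattern is not None else registry_pattern("PXDLS_KR")
    if not (1 <= anchor <= length - pat.max_len + 1):
        raise ValueError("anchor does not fit in the sequence")
    rng = np.random.default_rng(seed)
    freqs = _freq_vector(background)
    for _ in range(max_tries):
        seq = _random_sequences(rng, np.array([length]), freqs)[0]
        seq = splice_motif_instance(seq, pat, anchor - 1, rng)
        res = motif_anchor_position(seq, "PXDLS")
        if res.present and res.position == anchor:
            return seq
    raise RuntimeError("could not place a clean first-anchor instance")
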