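"""Bidirectional percent-enrichment of motif-bearing genes in a gene set.

All statistics are functions of four non-redundant gene counts:

* ``N`` — genes in the universe,
* ``n`` — motif-positive genes in the universe,
* ``M`` — set (circadian) genes in the universe,
* ``k`` — motif-positive set genes.

Forward enrichment compares the motif-positive fraction among set genes to
that in the whole universe::

    forward = (k/M - n/N) / (n/N) * 100

Reciprocal enrichment swaps the roles — the set-member fraction among
motif-positive genes against the set fraction overall::

    reciprocal = (k/n - M/N) / (M/N) * 100

Both are signed percentages: positive for over-representation, negative for
depletion, 0 exactly at independence (k = nM/N), and they always share a
sign when both are defined.  When ``n`` (or ``M``) is zero the statistic is
*undefined* and raising :class:`UndefinedEnrichmentError` is deliberate: 0
would falsely claim "exactly at expectation".

The percent statistics are the headline outputs; the hypergeometric and
permutation p-values are an added significance layer on the same counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "UndefinedEnrichmentError",
    "EnrichmentResult",
    "forward_enrichment",
    "reciprocal_enrichment",
    "hypergeometric_overrepresentation_p",
    "permutation_enrichment_p",
    "benjamini_hochberg",
    "evaluate_counts",
]


class UndefinedEnrichmentError(ZeroDivisionError):
    """Enrichment is undefined (no motif-positive genes, or empty set)."""


def _validate_counts(N: int, n: int, M: int, k: int) -> None:
    if not all(isinstance(v, (int, np.integer)) for v in (N, n, M, k)):
        raise ValueError("counts must be integers")
    if N <= 0:
        raise ValueError(f"universe size N must be positive, got {N}")
    if not (0 <= n <= N and 0 <= M <= N):
        raise ValueError(f"need 0 <= n,M <= N; got N={N}, n={n}, M={M}")
    if not (0 <= k <= min(n, M)):
        raise ValueError(f"need 0 <= k <= min(n,M); got n={n}, M={M}, k={k}")


def forward_enrichment(N: int, n: int, M: int, k: int) -> float:
    """Percent enrichment of the motif among set genes.

    ``(circadian ratio - general population ratio) / general population
    ratio * 100`` where the circadian ratio is k/M and the general
    population ratio is n/N.
    """
    _validate_counts(N, n, M, k)
    if n == 0 or M == 0:
        raise UndefinedEnrichmentError(
            f"forward enrichment undefined for n={n}, M={M}"
        )
    general = n / N
    circadian = k / M
    return (circadian - general) / general * 100.0


def reciprocal_enrichment(N: int, n: int, M: int, k: int) -> float:
    """Percent enrichment of set genes among motif-positive genes.

    ``(motif ratio - general circadian ratio) / general circadian ratio *
    100`` where the motif ratio is k/n and the general circadian ratio is
    M/N.
    """
    _validate_counts(N, n, M, k)
    if n == 0 or M == 0:
        raise UndefinedEnrichmentError(
            f"reciprocal enrichment undefined for n={n}, M={M}"
        )
    general = M / N
    motif = k / n
    return (motif - general) / general * 100.0


def hypergeometric_overrepresentation_p(N: int, n: int, M: int, k: int) -> float:
    """One-sided upper-tail P(K >= k) for K ~ Hypergeom(N, n, M).

    The probability of observing at least ``k`` motif-positive genes in a
    uniformly drawn size-``M`` subset of the universe.
    """
    _validate_counts(N, n, M, k)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, n, M))


def permutation_enrichment_p(
    N: int, n: int, M: int, k: int, n_perm: int = 999, seed: int | None = None
) -> float:
    """Permutation p-value by resampling size-``M`` gene sets.

    Draws ``n_perm`` uniform size-``M`` subsets of the universe, counts how
    often the resampled overlap ``k*`` reaches the observed ``k``, and
    returns the add-one estimate ``(1 + #{k* >= k}) / (1 + n_perm)``.  The
    seed is mandatory so screens are reproducible.
    """
    _validate_counts(N, n, M, k)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    is_positive = np.zeros(N, dtype=bool)
    is_positive[:n] = True  # labels are exchangeable under the null
    exceed = 0
    for _ in range(n_perm):
        draw = rng.choice(N, size=M, replace=False)
        if int(is_positive[draw].sum()) >= k:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional output column)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float))


@dataclass(frozen=True)
class EnrichmentResult:
    """Counts plus bidirectional enrichment for one pattern.

    ``forward_enrichment_pct`` / ``reciprocal_enrichment_pct`` are ``None``
    when undefined (``n == 0`` or ``M == 0``); ``undefined`` flags that
    state so screens can carry the row rather than drop it.
    """

    pattern_name: str
    N: int
    n: int
    M: int
    k: int
    forward_enrichment_pct: float | None
    reciprocal_enrichment_pct: float | None
    p_hypergeom: float | None = None
    p_perm: float | None = None

    @property
    def undefined(self) -> bool:
        return self.forward_enrichment_pct is None

    @property
    def general_population_ratio(self) -> float:
        return self.n / self.N

    @property
    def circadian_ratio(self) -> float | None:
        return self.k / self.M if self.M else None

    @property
    def motif_ratio(self) -> float | None:
        return self.k / self.n if self.n else None

    @property
    def general_circadian_ratio(self) -> float:
        return self.M / self.N

    def as_dict(self) -> dict:
        return {
            "pattern": self.pattern_name,
            "N": self.N,
            "n": self.n,
            "M": self.M,
            "k": self.k,
            "forward_pct": self.forward_enrichment_pct,
            "reciprocal_pct": self.reciprocal_enrichment_pct,
            "p_hypergeom": self.p_hypergeom,
            "p_perm": self.p_perm,
        }


def evaluate_counts(
    pattern_name: str,
    N: int,
    n: int,
    M: int,
    k: int,
    p_values: bool = False,
    n_perm: int = 0,
    seed: int | None = None,
) -> EnrichmentResult:
    """Build an :class:`EnrichmentResult` from the four counts.

    Undefined enrichment (``n == 0`` or ``M == 0``) is flagged, not raised,
    so whole-screen callers can apply their own policy.
    """
    _validate_counts(N, n, M, k)
    if n == 0 or M == 0:
        fwd = rec = None
    else:
        fwd = forward_enrichment(N, n, M, k)
        rec = reciprocal_enrichment(N, n, M, k)
    p_h = hypergeometric_overrepresentation_p(N, n, M, k) if p_values else None
    p_p = (
        permutation_enrichment_p(N, n, M, k, n_perm=n_perm, seed=seed)
        if p_values and n_perm
        else None
    )
    return EnrichmentResult(pattern_name, N, n, M, k, fwd, rec, p_h, p_p)
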