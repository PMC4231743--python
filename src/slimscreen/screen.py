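"""The motif-enrichment screen as a model/results pair.

:class:`MotifScreen` binds a proteome, a gene set and a pattern list (the
data and design); :meth:`MotifScreen.fit` scans the proteome, collapses
hits to non-redundant genes, computes both percent-enrichment statistics
per pattern and returns a :class:`ScreenResults` carrying the counts, the
statistics, optional p-values and a ``summary()`` table.

The universe over which all counts are taken is configurable because the
two obvious choices (all proteome genes vs. proteome genes also present in
the expression dataset that defined the gene set) give different ``N``:

* ``universe=None`` (default) — every gene in the proteome;
* ``universe=<iterable of symbols>`` — proteome genes intersected with the
  supplied list.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import (
    EnrichmentResult,
    UndefinedEnrichmentError,
    benjamini_hochberg,
    evaluate_counts,
)
from .patterns import MotifPattern, builtin_registry, scan_proteome
from .proteome import GeneSet, Proteome, genes_with_motif

__all__ = ["MotifScreen", "ScreenResults", "run_screen"]


class MotifScreen:
    """Over-representation screen of motif-bearing genes in a gene set.

    Parameters
    ----------
    proteome:
        Multi-isoform :class:`~slimscreen.proteome.Proteome`.
    gene_set:
        The label set (e.g. circadian genes).  Must intersect the universe.
    patterns:
        Patterns to screen; defaults to the 17-entry built-in registry.
    universe:
        Optional gene-symbol list restricting the counting universe (see
        module docstring).
    """

    def __init__(
        self,
        proteome: Proteome,
        gene_set: GeneSet,
        patterns: Sequence[MotifPattern] | None = None,
        universe: Iterable[str] | None = None,
    ):
        self.proteome = proteome
        self.gene_set = gene_set
        self.patterns = list(patterns) if patterns is not None else builtin_registry()
        if universe is not None:
            self.universe_genes = proteome.genes & {
                s.strip().upper() for s in universe
            }
        else:
            self.universe_genes = proteome.genes
        if not self.universe_genes:
            raise ValueError("universe is empty")
        self.set_genes = gene_set.symbols & self.universe_genes
        if not self.set_genes:
            raise ValueError("gene set is disjoint from the universe")

    def fit(
        self,
        p_values: bool = False,
        n_perm: int = 0,
        seed: int | None = None,
        undefined_policy: str = "flag",
    ) -> "ScreenResults":
        """Scan, count and score every pattern.

        ``undefined_policy`` is ``"flag"`` (carry undefined rows, default)
        or ``"error"`` (raise on a pattern with zero motif-positive genes).
        Permutation p-values are computed when ``p_values`` is true and
        ``n_perm > 0``; they need an explicit ``seed``.
        """
        if undefined_policy not in ("flag", "error"):
            raise ValueError(f"unknown undefined_policy {undefined_policy!r}")
        hits = scan_proteome(self.patterns, self.proteome)
        N = len(self.universe_genes)
        M = len(self.set_genes)
        results: list[EnrichmentResult] = []
        seeds = _pattern_seeds(seed, len(self.patterns)) if seed is not None else None
        for i, pat in enumerate(self.patterns):
            positive = genes_with_motif(self.proteome, hits, pat.name)
            positive &= self.universe_genes
            n = len(positive)
            k = len(positive & self.set_genes)
            if n == 0 and undefined_policy == "error":
                raise UndefinedEnrichmentError(
                    f"pattern {pat.name!r} has no motif-positive genes"
                )
            results.append(
                evaluate_counts(
                    pat.name, N, n, M, k,
                    p_values=p_values,
                    n_perm=n_perm if n > 0 else 0,
                    seed=seeds[i] if seeds is not None else None,
                )
            )
        return ScreenResults(self, results, hits)


def _pattern_seeds(seed: int, n: int) -> list[int]:
    """Independent sub-seeds (< 2**31) for per-pattern permutation tests."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


class ScreenResults(Sequence):
    """Fitted screen: one :class:`EnrichmentResult` per pattern.

    Sequence-like (iterating yields results in pattern order); the raw hit
    table is available as ``.hits``.
    """

    def __init__(self, model: MotifScreen, results: list[EnrichmentResult],
                 hits: pd.DataFrame):
        self.model = model
        self.results = results
        self.hits = hits

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, i):
        return self.results[i]

    def by_name(self, pattern_name: str) -> EnrichmentResult:
        for r in self.results:
            if r.pattern_name == pattern_name:
                return r
        raise KeyError(pattern_name)

    def to_frame(self, fdr: bool = False) -> pd.DataFrame:
        """Counts and statistics as a DataFrame, one row per pattern.

        With ``fdr=True`` a Benjamini-Hochberg column over the
        hypergeometric p-values is appended (an optional extension; the
        screen applies no multiple-testing correction by default).
        """
        df = pd.DataFrame([r.as_dict() for r in self.results])
        df["undefined"] = [r.undefined for r in self.results]
        if fdr:
            if df["p_hypergeom"].isna().any():
                raise ValueError("fit with p_values=True before requesting FDR")
            df["bh_fdr"] = benjamini_hochberg(df["p_hypergeom"].to_numpy())
        return df

    def to_tsv(self, path, fdr: bool = False) -> None:
        self.to_frame(fdr=fdr).to_csv(path, sep="\t", index=False,
                                      float_format="%.6g")

    def summary(self) -> str:
        """Plain-text summary table (percentages to 1 decimal)."""
        df = self.to_frame().copy()
        for col in ("forward_pct", "reciprocal_pct"):
            df[col] = df[col].map(lambda v: "undef" if pd.isna(v) else f"{v:.1f}")
        for col in ("p_hypergeom", "p_perm"):
            if df[col].isna().all():
                df = df.drop(columns=col)
            else:
                df[col] = df[col].map(
                    lambda v: "" if pd.isna(v) else f"{v:.3g}")
        df = df.drop(columns="undefined")
        header = [
            "Motif enrichment screen".center(64),
            "=" * 64,
            f"Universe genes (N): {len(self.model.universe_genes)}",
            f"Set genes (M):      {len(self.model.set_genes)}",
            f"Patterns screened:  {len(self.results)}",
            "-" * 64,
        ]
        return "\n".join(header) + "\n" + df.to_string(index=False)

    def plot_enrichment(self, which: str = "forward", ax=None):
        """Bar chart of percent enrichment per pattern (optional output)."""
        import matplotlib.pyplot as plt

        col = {"forward": "forward_pct", "reciprocal": "reciprocal_pct"}[which]
        df = self.to_frame()
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        ax.bar(df["pattern"], df[col].fillna(0.0))
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_ylabel(f"{which} enrichment (%)")
        ax.set_xticklabels(df["pattern"], rotation=60, ha="right")
        ax.figure.tight_layout()
        return ax


def run_screen(
    proteome: Proteome,
    gene_set: GeneSet,
    patterns: Sequence[MotifPattern] | None = None,
    universe: Iterable[str] | None = None,
    **fit_kwargs,
) -> ScreenResults:
    """One-call screen: build a :class:`MotifScreen` and fit it."""
    return MotifScreen(proteome, gene_set, patterns, universe).fit(**fit_kwargs)
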