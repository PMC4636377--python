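"""Tests for genes hit by more mutations than their length predicts.

Under the null, each of the n coding mutations lands in a gene of coding
length L with probability L/G, where G is the total coding content of the
genome; a gene's hit count is Binomial(n, L/G) and enrichment is assessed by
the upper-tail probability P(X >= k). An aggregate Monte-Carlo test asks how
often random placement produces as many multiply-hit genes as observed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAnnotation

__all__ = ["gene_hit_pvalue", "multihit_census", "census_significance",
           "gene_hit_table"]


def gene_hit_pvalue(k: int, n: int, L: int, G: int,
                    point_mass: bool = False) -> float:
    """Binomial probability that a gene of coding length ``L`` collects at
    least ``k`` of ``n`` coding mutations by chance (``P(X >= k)`` with
    ``X ~ Binomial(n, L/G)``); ``point_mass`` returns ``P(X = k)`` instead.
    """
    if not (0 < L <= G):
        raise ValueError("need 0 < L <= G")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    p = L / G
    if point_mass:
        return float(stats.binom.pmf(k, n, p))
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def multihit_census(table: pd.DataFrame,
                    annotation: GenomeAnnotation | None = None
                    ) -> tuple[dict[int, int], pd.DataFrame]:
    """Count genes by number of distinct mutated coding positions.

    Hits identical at the nucleotide level (same chromosome and position)
    are counted once even when seen in several reactors or generations.
    Returns ``(census, per-gene hits)`` where census maps m -> number of
    genes hit at exactly m distinct positions, for m >= 2.
    """
    coding = table[table["gene"].astype(str).ne("")]
    hits = (coding.drop_duplicates(subset=["chromosome", "position"])
            .groupby("gene").size().rename("k").reset_index())
    census: dict[int, int] = {}
    for m, cnt in hits["k"].value_counts().items():
        if m >= 2:
            census[int(m)] = int(cnt)
    return census, hits


def gene_hit_table(table: pd.DataFrame, annotation: GenomeAnnotation,
                   adjust: str = "BH") -> pd.DataFrame:
    """Per-gene enrichment table: gene, L, k, p and (optionally) BH-adjusted
    p across all genes with at least one hit; draws n = total distinct
    coding mutations, G = total coding content."""
    _, hits = multihit_census(table)
    n = int(hits["k"].sum())
    G = annotation.coding_length
    lengths = annotation.gene_lengths()
    rows = []
    for _, r in hits.iterrows():
        L = int(lengths.get(r["gene"], 0))
        if L == 0:
            continue
        rows.append({"gene": r["gene"], "L": L, "k": int(r["k"]),
                     "p": gene_hit_pvalue(int(r["k"]), n, L, G)})
    out = pd.DataFrame(rows, columns=["gene", "L", "k", "p"])
    if adjust == "BH" and not out.empty:
        from statsmodels.stats.multitest import multipletests
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    elif not out.empty:
        out["p_adj"] = out["p"]
    return out.sort_values("p").reset_index(drop=True)


def census_significance(observed_census: dict[int, int], n: int,
                        annotation: GenomeAnnotation,
                        n_sim: int = 10_000,
                        seed: int | None = None) -> dict[int, float]:
    """Monte-Carlo aggregate test: drop ``n`` mutations on the coding genome
    with per-gene probability L/G and, for each multiplicity m, report the
    fraction of simulations with at least as many genes hit >= m times as
    observed (the observed exact-m census is accumulated into >= m counts,
    so the statistic is monotone and saturates to p = 1 as n grows large)."""
    rng = np.random.default_rng(seed)
    lengths = annotation.gene_lengths().to_numpy(dtype=float)
    probs = lengths / lengths.sum()
    ms = sorted(observed_census)
    if not ms:
        return {}
    observed_cum = {m: sum(v for mm, v in observed_census.items() if mm >= m)
                    for m in ms}
    exceed = {m: 0 for m in ms}
    for _ in range(n_sim):
        counts = rng.multinomial(n, probs)
        for m in ms:
            if int((counts >= m).sum()) >= observed_cum[m]:
                exceed[m] += 1
    return {m: exceed[m] / n_sim for m in ms}
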