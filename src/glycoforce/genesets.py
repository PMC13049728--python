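"""Differential-expression filtering, top-k fold-change ranking, and exact
hypergeometric overlap of gene sets.

Gene/protein tables are pandas DataFrames with columns

    gene_id, measure ("rna" | "protein"), and per contrast
    log2fc_<contrast>, padj_<contrast> (rna) or p_<contrast> (protein)

Fold-change thresholds are applied to |FC| = 2^|log2fc| symmetrically
(both up- and down-regulation count).  The RNA default adjusted-p cutoff is
0.105 and the protein filter is p < 0.05 with a 1.2-fold change, matching
the upstream study design these tables emulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GlycoforceError

__all__ = [
    "OverlapResult",
    "filter_degs",
    "filter_deps",
    "hypergeometric_overlap",
    "rank_top_migration",
]


def _require_columns(table: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise GlycoforceError(f"table is missing columns: {missing}")


def filter_degs(table: pd.DataFrame, contrast: str = "bac",
                padj_max: float = 0.105, fc_min: float = 1.5) -> set[str]:
    """Differentially expressed genes of one contrast: adjusted p <= padj_max
    and |fold change| strictly above fc_min."""
    lcol, pcol = f"log2fc_{contrast}", f"padj_{contrast}"
    _require_columns(table, ["gene_id", lcol, pcol])
    rna = table[table["measure"] == "rna"] if "measure" in table.columns else table
    fc = np.exp2(np.abs(rna[lcol].to_numpy(dtype=float)))
    p = rna[pcol].to_numpy(dtype=float)
    keep = (p <= padj_max) & (fc > fc_min)
    return set(rna.loc[keep, "gene_id"])


def filter_deps(table: pd.DataFrame, contrast: str = "bac",
                fc_min: float = 1.2, alpha: float = 0.05) -> set[str]:
    """Differentially expressed proteins: per-row p < alpha (t-test performed
    upstream on replicate intensities) and |fold change| >= fc_min."""
    lcol, pcol = f"log2fc_{contrast}", f"p_{contrast}"
    _require_columns(table, ["gene_id", lcol, pcol])
    prot = table[table["measure"] == "protein"] if "measure" in table.columns else table
    fc = np.exp2(np.abs(prot[lcol].to_numpy(dtype=float)))
    p = prot[pcol].to_numpy(dtype=float)
    keep = (p < alpha) & (fc >= fc_min)
    return set(prot.loc[keep, "gene_id"])


@dataclass(frozen=True)
class OverlapResult:
    """Exact upper-tail hypergeometric overlap of two gene sets in a stated
    universe."""

    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap_size: int
    p_value: float
    overlap_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.overlap_size > min(self.set_a_size, self.set_b_size):
            raise GlycoforceError("overlap exceeds the smaller set")
        if not (0 < self.p_value <= 1):
            raise GlycoforceError("p must be in (0, 1]")

    def __str__(self) -> str:
        return (f"overlap {self.overlap_size} of |A|={self.set_a_size}, "
                f"|B|={self.set_b_size} in universe {self.universe_size}: "
                f"P(X >= {self.overlap_size}) = {self.p_value:.6g}")


def hypergeometric_overlap(set_a, set_b, universe) -> OverlapResult:
    """Exact tail probability P(X >= k) of observing at least the realised
    overlap between ``set_a`` and ``set_b`` drawn from ``universe``.

    Computed by exact summation of the hypergeometric pmf (scipy's survival
    function; no normal approximation).  Symmetric in (set_a, set_b).
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u:
        raise GlycoforceError("set_a is not a subset of the universe")
    if not b <= u:
        raise GlycoforceError("set_b is not a subset of the universe")
    common = a & b
    k = len(common)
    # P(X >= k), X ~ Hypergeom(M=|U|, n=|A|, N=|B|)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return OverlapResult(universe_size=len(u), set_a_size=len(a),
                         set_b_size=len(b), overlap_size=k, p_value=p,
                         overlap_ids=frozenset(common))


def rank_top_migration(table: pd.DataFrame, gene_subset,
                       contrasts: tuple[str, str] = ("mac", "bac"),
                       k: int = 25) -> tuple[list[str], list[str], bool]:
    """Top-k up- and down-regulated genes of a subset, ranked by the mean of
    the two contrasts' log2 fold changes (ties broken lexicographically by
    gene id).

    Returns ``(up, down, truncated)``; ``truncated`` is True when fewer than
    ``k`` genes were available and everything was returned.
    """
    cols = [f"log2fc_{c}" for c in contrasts]
    _require_columns(table, ["gene_id", *cols])
    sub = table[table["gene_id"].isin(set(gene_subset))]
    if sub[cols].isna().any().any():
        raise GlycoforceError("both contrasts must be present for every gene "
                              "in the subset")
    score = sub[cols].mean(axis=1)
    ranked = pd.DataFrame({"gene_id": sub["gene_id"].to_numpy(),
                           "score": score.to_numpy()})
    up = ranked.sort_values(["score", "gene_id"],
                            ascending=[False, True])["gene_id"].tolist()
    down = ranked.sort_values(["score", "gene_id"],
                              ascending=[True, True])["gene_id"].tolist()
    truncated = len(ranked) < k
    return up[:k], down[:k], truncated
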