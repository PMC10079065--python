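"""Gene-set overlap testing.

Overlap between an extracted set and a reference list (Braak-correlated
genes, cell-type markers, candidate risk genes, ...) is scored by a
one-sided Fisher's exact test — the upper-tail hypergeometric probability
of drawing at least the observed intersection — against a fixed gene
universe (default 25,000, the assumed named-gene genome size), together
with the Jaccard index |A ∩ B| / |A ∪ B|. Families of pairwise tests are
BH-adjusted over all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

DEFAULT_UNIVERSE = 25_000


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self):
        # deduplicate, preserving first-seen order
        object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))

    def __len__(self):
        return len(self.genes)


@dataclass(frozen=True)
class OverlapResult:
    set_a: str
    set_b: str
    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    jaccard: float
    p: float
    q: float | None = None


def overlap_test(
    a: GeneSet,
    b: GeneSet,
    universe: int = DEFAULT_UNIVERSE,
    universe_genes: tuple[str, ...] | None = None,
) -> OverlapResult:
    """One-sided enrichment test of the overlap between two gene sets.

    p is the probability of >= n_overlap successes when drawing |B| genes
    without replacement from a universe containing |A| marked genes. In
    strict mode (``universe_genes`` given) both sets are first restricted
    to that list and the universe is its size.
    """
    genes_a, genes_b = set(a.genes), set(b.genes)
    if universe_genes is not None:
        allowed = set(universe_genes)
        genes_a &= allowed
        genes_b &= allowed
        universe = len(allowed)
    n_a, n_b = len(genes_a), len(genes_b)
    if n_a > universe or n_b > universe:
        raise ValueError("gene set larger than the universe")
    k = len(genes_a & genes_b)
    union = len(genes_a | genes_b)
    jaccard = k / union if union else 0.0
    p = float(stats.hypergeom.sf(k - 1, universe, n_a, n_b))
    return OverlapResult(
        set_a=a.name, set_b=b.name, n_a=n_a, n_b=n_b, n_overlap=k,
        n_universe=universe, jaccard=jaccard, p=min(p, 1.0),
    )


def overlap_matrix(
    rows: list[GeneSet],
    cols: list[GeneSet],
    universe: int = DEFAULT_UNIVERSE,
    universe_genes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """All pairwise overlaps with BH q over the full family of tests."""
    if not rows or not cols:
        raise ValueError("empty gene-set list")
    for sets in (rows, cols):
        names = [s.name for s in sets]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate set names: {names}")
    results = [
        overlap_test(a, b, universe, universe_genes) for a in rows for b in cols
    ]
    table = pd.DataFrame([vars(r) for r in results]).drop(columns="q")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table


def genesets_from_gmt(gmt: dict[str, dict], source: str = "gmt") -> list[GeneSet]:
    return [
        GeneSet(name=name, genes=tuple(entry["genes"]), source=source)
        for name, entry in gmt.items()
    ]
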