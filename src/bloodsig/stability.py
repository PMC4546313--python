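"""Cross-cohort module stability: Fisher overlap, stable-module calling,
and balancing of the up/down lists.

Modules detected independently in two reference cohorts are compared by the
one-sided Fisher's exact (hypergeometric enrichment) test on their gene
overlap within the shared candidate universe.  A cohort-1 module whose best
cohort-2 partner overlaps at p < alpha (default 0.01) is called *stable*;
stable modules are ranked by descending −log(p), and the longer of the
up-/down-regulated lists is truncated from the bottom so both directions
contribute the same number of modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .coexpression import GREY, ModuleAssignment
from .exceptions import ValidationError


@dataclass
class ModuleOverlap:
    """Overlap evidence between one cohort-1 and one cohort-2 module."""

    module_a: str
    module_b: str
    overlap_count: int
    size_a: int
    size_b: int
    universe_size: int
    fisher_p: float
    genes: list[str] = field(default_factory=list)


@dataclass
class StableModule:
    """A cohort-1 module with a significantly overlapping cohort-2 partner."""

    direction: str
    gene_set: list[str]
    module_a: str
    module_b: str
    best_p: float
    rank: int


def fisher_overlap(k: int, size_a: int, size_b: int, universe: int) -> float:
    """One-sided enrichment p: P(X >= k), X ~ Hypergeom(universe, size_a, size_b)."""
    if min(k, size_a, size_b) < 0 or universe <= 0:
        raise ValidationError("counts must be nonnegative, universe positive")
    if size_a > universe or size_b > universe:
        raise ValidationError("set sizes cannot exceed the universe")
    if k > min(size_a, size_b):
        raise ValidationError("overlap cannot exceed either set size")
    if k < size_a + size_b - universe:
        raise ValidationError("overlap below the feasible minimum")
    return float(hypergeom.sf(k - 1, universe, size_a, size_b))


def overlap_table(assign_1: ModuleAssignment, assign_2: ModuleAssignment
                  ) -> list[ModuleOverlap]:
    """All non-grey × non-grey module overlaps within the shared universe.

    The universe is the set of genes present in both assignments (grey genes
    included); grey itself never forms a pair.
    """
    genes_1 = set(assign_1.genes)
    genes_2 = set(assign_2.genes)
    universe = genes_1 & genes_2
    if not universe:
        raise ValidationError("assignments have disjoint gene universes")
    n = len(universe)
    out: list[ModuleOverlap] = []
    for ma in assign_1.module_names():
        set_a = set(assign_1.module_genes(ma)) & universe
        for mb in assign_2.module_names():
            set_b = set(assign_2.module_genes(mb)) & universe
            inter = sorted(set_a & set_b)
            p = fisher_overlap(len(inter), len(set_a), len(set_b), n)
            out.append(ModuleOverlap(ma, mb, len(inter), len(set_a),
                                     len(set_b), n, p, inter))
    return out


def call_stable_modules(overlaps: list[ModuleOverlap], alpha: float = 0.01,
                        core_rule: str = "intersection",
                        direction: str = "") -> list[StableModule]:
    """Call stable modules from one direction's overlap table.

    Each cohort-1 module is matched to its best cohort-2 partner (smallest
    fisher_p; ties by larger overlap, then label order).  Matches with
    p < alpha become stable modules, ranked 1.. by descending −log(p).  The
    stable gene set is the intersection of the matched pair (the only
    ``core_rule`` currently supported): genes co-clustered in both cohorts.
    """
    if not overlaps:
        raise ValidationError("no overlaps supplied")
    if core_rule != "intersection":
        raise ValidationError(f"unknown core_rule {core_rule!r}")
    best: dict[str, ModuleOverlap] = {}
    for ov in overlaps:
        cur = best.get(ov.module_a)
        if cur is None or (ov.fisher_p, -ov.overlap_count, ov.module_b) < \
                (cur.fisher_p, -cur.overlap_count, cur.module_b):
            best[ov.module_a] = ov
    called = [ov for ov in best.values() if ov.fisher_p < alpha and ov.genes]
    called.sort(key=lambda ov: (ov.fisher_p, -ov.overlap_count, ov.module_a))
    return [StableModule(direction, list(ov.genes), ov.module_a, ov.module_b,
                         ov.fisher_p, rank)
            for rank, ov in enumerate(called, start=1)]


def balance_directions(up: list[StableModule], down: list[StableModule]
                       ) -> tuple[list[StableModule], list[StableModule]]:
    """Truncate the longer list from the bottom so both directions match.

    Lists must arrive ranked; the worst-ranked (largest best_p) modules of
    the longer list are discarded.  If either direction has no stable module
    both lists come back empty (with a warning) — no paired model exists.
    """
    if not up or not down:
        warnings.warn("one direction has no stable modules; both lists emptied")
        return [], []
    k = min(len(up), len(down))
    up_sorted = sorted(up, key=lambda m: m.rank)
    down_sorted = sorted(down, key=lambda m: m.rank)
    return up_sorted[:k], down_sorted[:k]


def overlap_matrix(overlaps: list[ModuleOverlap]):
    """Overlap counts and −log10 p as DataFrames (cohort-1 rows × cohort-2 cols),
    ordered by each module's maximum −log(p) with the other cohort's modules."""
    import pandas as pd
    rows = sorted({ov.module_a for ov in overlaps})
    cols = sorted({ov.module_b for ov in overlaps})
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    logp = pd.DataFrame(0.0, index=rows, columns=cols)
    for ov in overlaps:
        counts.loc[ov.module_a, ov.module_b] = ov.overlap_count
        logp.loc[ov.module_a, ov.module_b] = -np.log10(max(ov.fisher_p, 1e-300))
    row_order = logp.max(axis=1).sort_values(ascending=False).index
    col_order = logp.max(axis=0).sort_values(ascending=False).index
    return counts.loc[row_order, col_order], logp.loc[row_order, col_order]
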