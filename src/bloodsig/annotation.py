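"""Functional annotation of stable modules.

Each stable module is tested for enrichment against two GMT collections —
canonical pathways and hematopoietic cell-type overexpression signatures —
by the same one-sided Fisher test used for module overlaps.  The module's
*functional core* is its intersection with the most significantly enriched
canonical pathway when that pathway reaches p < 1e-4 (a Bonferroni-style
family-wise threshold); otherwise the intersection with the best cell-type
signature, accepted without a second threshold.

The enrichment universe is all genes measured in the training cohort: a
module's enrichment is judged against the assay background, not merely the
candidate pool.  No multiplicity adjustment is applied inside ``enrich`` —
the 1e-4 core threshold already plays that role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import GeneSetCollection
from .stability import StableModule, fisher_overlap

CANONICAL_PATHWAY = "canonical_pathway"
CELLTYPE = "celltype_overexpression"

#: Pathway-core significance threshold (family-wise 0.1 after Bonferroni).
CORE_P_THRESHOLD = 1e-4


@dataclass
class FunctionalCore:
    """Module ∩ best enriched gene set, with provenance of that set."""

    parent: StableModule
    core_genes: list[str]
    source_set_name: str
    source_collection: str
    p: float


def enrich(module_genes, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """One-sided Fisher enrichment of a module against every set.

    Sets are intersected with the universe before testing.  Returns a
    DataFrame ranked by ascending p (ties: smaller effective set, then
    name) with columns overlap_count, set_size, module_size, universe_size,
    fisher_p.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty enrichment universe")
    module = set(module_genes)
    if not module <= universe:
        raise ValidationError("module genes must lie within the universe")
    n, m = len(universe), len(module)
    rows = []
    for name in collection.names():
        s = set(collection[name]) & universe
        if not s:
            continue
        k = len(module & s)
        rows.append((name, k, len(s), m, n, fisher_overlap(k, m, len(s), n)))
    res = pd.DataFrame(rows, columns=["set_name", "overlap_count", "set_size",
                                      "module_size", "universe_size",
                                      "fisher_p"]).set_index("set_name")
    res["_name"] = res.index
    res = res.sort_values(["fisher_p", "set_size", "_name"]).drop(columns="_name")
    return res


def functional_core(module: StableModule, pathways: GeneSetCollection,
                    celltypes: GeneSetCollection, universe,
                    p_threshold: float = CORE_P_THRESHOLD) -> FunctionalCore:
    """Extract the functional core of a stable module.

    Branch 1: best canonical pathway with p < p_threshold → core = module ∩
    that pathway.  Branch 2 (fallback): no pathway reaches the threshold →
    core = module ∩ best cell-type signature, regardless of its p.
    """
    if len(pathways) == 0 and len(celltypes) == 0:
        raise ValidationError("both gene-set collections are empty")
    module_set = set(module.gene_set)
    universe = set(universe)

    def _best(collection, source):
        res = enrich(module_set, collection, universe)
        if res.empty:
            return None
        name = res.index[0]
        p = float(res["fisher_p"].iloc[0])
        core = sorted(module_set & set(collection[name]) & universe)
        return FunctionalCore(module, core, name, source, p)

    best_pathway = _best(pathways, CANONICAL_PATHWAY) if len(pathways) else None
    if best_pathway is not None and best_pathway.p < p_threshold:
        return best_pathway
    best_cell = _best(celltypes, CELLTYPE) if len(celltypes) else None
    if best_cell is not None:
        return best_cell
    if best_pathway is not None:  # no cell-type sets available at all
        return best_pathway
    raise ValidationError("no gene set intersects the universe")


def celltype_profile(modules: list[StableModule],
                     celltypes: GeneSetCollection, universe) -> pd.DataFrame:
    """−log10 enrichment p per (module, cell-type set); heatmap-ready."""
    universe = set(universe)
    names = celltypes.names()
    rows = {}
    for mod in modules:
        res = enrich(set(mod.gene_set) & universe, celltypes, universe)
        logp = -np.log10(res["fisher_p"].clip(lower=1e-300))
        label = f"{mod.direction}_{mod.module_a}" if mod.direction else mod.module_a
        rows[label] = logp.reindex(names)
    return pd.DataFrame(rows).T.fillna(0.0)
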