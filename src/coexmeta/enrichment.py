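"""Over-representation analysis of gene lists against GMT collections.

Each term is tested with a one-sided Fisher's exact test (hypergeometric
upper tail) for over-representation of the query inside the analysis gene
universe — the post-intersection gene set, not the whole genome, so genes
that were never testable cannot inflate enrichment.  BH correction is
applied across the tested terms and terms pass at corrected p < ora_alpha.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .gene_meta import bh_adjust
from .io import GeneSetCollection

__all__ = ["ora"]

RESULT_COLUMNS = ["term", "description", "overlap", "term_size",
                  "query_size", "universe_size", "p", "q", "enriched"]


def ora(query: set[str], universe: set[str],
        collection: GeneSetCollection,
        config: PipelineConfig) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``query`` in each term.

    Terms are intersected with the universe first; terms with an empty
    intersection are skipped.  The query must be a subset of the universe.
    Results are sorted by p then term ID, so term order in the GMT cannot
    change the output.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        warnings.warn("empty query gene set; returning no enrichments")
        return pd.DataFrame(columns=RESULT_COLUMNS)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    n_universe = len(universe)
    rows = []
    for term, (desc, genes) in collection:
        term_genes = set(genes) & universe
        if not term_genes:
            continue
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(term_genes),
                                     len(query)))
        rows.append({"term": term, "description": desc, "overlap": k,
                     "term_size": len(term_genes), "query_size": len(query),
                     "universe_size": n_universe, "p": p})
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.DataFrame(rows).sort_values(["p", "term"]).reset_index(drop=True)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["q"] < config.ora_alpha
    return out[RESULT_COLUMNS]
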