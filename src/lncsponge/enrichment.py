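"""Over-representation analysis against user-supplied gene-set collections.

A plain hypergeometric-tail ORA: for each set, the overlap between the query
and the set (both intersected with the universe) is tested against random
draws from the universe, with BH correction across sets. The universe
defaults to all genes of the expression matrix the query came from, which
avoids detection bias relative to a whole-genome universe.
"""

from __future__ import annotations

import pandas as pd

from .cerna import hypergeometric_upper_p
from .diffexpr import benjamini_hochberg
from .types import GeneSetCollection, ValidationError


def ora(query, sets: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Returns one row per tested set with overlap counts, the upper-tail
    hypergeometric p (N = |universe|, K = |set ∩ universe|, n = |query|,
    m = |overlap|), BH FDR across sets, and the overlapping ids; sorted by
    p then set name. Sets with no member in the universe are skipped.
    """
    query = set(query)
    universe = set(universe)
    outside = query - universe
    if outside:
        raise ValidationError(f"query genes outside the universe: {sorted(outside)[:10]}")
    N = len(universe)
    n = len(query)
    rows = []
    for name in sorted(sets.sets):
        members = sets.sets[name] & universe
        if not members:
            continue
        overlap = sorted(members & query)
        rows.append(
            {
                "set_name": name,
                "k": len(overlap),
                "K": len(members),
                "n": n,
                "N": N,
                "p": hypergeometric_upper_p(N, len(members), n, len(overlap)),
                "overlap_genes": ";".join(overlap),
            }
        )
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p", "overlap_genes"])
    if len(df):
        df["fdr"] = benjamini_hochberg(df["p"].to_numpy())
        df = df.sort_values(["p", "set_name"]).reset_index(drop=True)
    else:
        df["fdr"] = []
    return df[["set_name", "k", "K", "n", "N", "p", "fdr", "overlap_genes"]]
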