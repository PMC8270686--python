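"""Supercluster/subcluster gene-set over-representation.

Terms are grouped into a two-level manual taxonomy (supercluster ->
subcluster); each subcluster's reference list is the union of its member
terms' gene sets.  A query list is tested against every subcluster
reference with the one-sided (over-representation) Fisher exact test --
i.e. the hypergeometric upper tail P(X >= overlap) with population =
universe, successes = reference, draws = query -- and Benjamini-Hochberg
adjustment across the tested subclusters.  Two query lists can then be
contrasted: subclusters significant in both are "common", in one only
"specific" to that query.

The universe defaults to the genes represented on the array after
collapsing, not the genome.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh
from .io import SuperclusterMap, TermCollection

logger = logging.getLogger("thydex")

SubclusterKey = tuple[str, str]  # (supercluster, subcluster)


def build_subcluster_references(
    terms: TermCollection,
    scmap: SuperclusterMap,
) -> dict[SubclusterKey, frozenset[str]]:
    """Union-of-member-terms reference gene list per (supercluster, subcluster).

    A term assigned to two superclusters contributes its genes to both;
    subclusters that end up empty are dropped with a warning.
    """
    scmap.validate(terms)
    refs: dict[SubclusterKey, set[str]] = {}
    for tid, pairs in scmap.assignments.items():
        genes = terms.genes_of(tid)
        for pair in pairs:
            refs.setdefault(pair, set()).update(genes)
    out = {}
    for key, genes in refs.items():
        if genes:
            out[key] = frozenset(genes)
        else:
            logger.warning("subcluster %s has no genes; dropped", key)
    return out


def fisher_overlap(
    query: Iterable[str],
    reference: Iterable[str],
    universe: Iterable[str],
) -> tuple[int, float, float]:
    """One-sided over-representation test of query x reference overlap.

    Returns (overlap, odds ratio, raw p) where p is the hypergeometric
    upper tail P(X >= overlap).  Query/reference members outside the
    universe are dropped (and counted in the log).  The odds ratio is the
    sample odds ratio of the 2x2 table; 0.5 is added to every cell for
    reporting only when some cell is zero.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    r = set(reference) & uni
    n_outside = len(set(query) - uni) + len(set(reference) - uni)
    if n_outside:
        logger.info("fisher_overlap: dropped %d genes outside the universe", n_outside)
    if not q:
        raise ValueError("empty query after restriction to the universe")
    k = len(q & r)
    M, K, n = len(uni), len(r), len(q)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    a = k
    b = n - k
    c = K - k
    d = M - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return k, float(odds), min(1.0, p)


def subcluster_enrichment(
    query: Iterable[str],
    references: Mapping[SubclusterKey, frozenset[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test a query list against every subcluster reference; BH-adjust.

    One row per subcluster with counts, odds ratio, raw and adjusted p, and
    a ``significant`` flag at adjusted p < alpha.
    """
    if not references:
        raise ValueError("no subcluster references supplied")
    uni = set(universe)
    q = set(query) & uni
    rows = []
    for (supercluster, subcluster), ref in sorted(references.items()):
        k, odds, p = fisher_overlap(q, ref, uni)
        rows.append((supercluster, subcluster, len(set(ref) & uni), k,
                     len(uni), len(q), odds, p))
    df = pd.DataFrame(
        rows,
        columns=["supercluster", "subcluster", "reference_size", "overlap",
                 "universe_size", "query_size", "odds_ratio", "p"],
    )
    df["adj_p"] = adjust_bh(df["p"].to_numpy())
    df["significant"] = df["adj_p"] < alpha
    return df


def differential_enrichment(
    rows_a: pd.DataFrame,
    rows_b: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify subclusters as common / a_specific / b_specific.

    Both inputs must cover the same subcluster set (as produced by
    :func:`subcluster_enrichment` on the same references).  Subclusters
    significant in neither query are omitted.
    """
    key = ["supercluster", "subcluster"]
    a = rows_a.set_index(key)
    b = rows_b.set_index(key)
    if set(a.index) != set(b.index):
        diff = sorted(set(a.index).symmetric_difference(b.index))
        raise ValueError(f"mismatched subcluster sets: {diff[:5]}")
    b = b.loc[a.index]
    sig_a = a["adj_p"] < alpha
    sig_b = b["adj_p"] < alpha
    out = pd.DataFrame(
        {
            "adj_p_a": a["adj_p"],
            "adj_p_b": b["adj_p"],
        },
        index=a.index,
    )
    label = np.where(sig_a & sig_b, "common",
                     np.where(sig_a, "a_specific",
                              np.where(sig_b, "b_specific", "")))
    out["classification"] = label
    return out[out["classification"] != ""].reset_index()
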