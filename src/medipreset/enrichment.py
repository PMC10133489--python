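"""Hypergeometric gene-set over-representation with −log10(p) scores.

Queries (e.g. hyper- or hypomethylated gene lists) are tested against GMT
gene sets with the one-tailed hypergeometric test; the Enrichment Score is
−log10 of the raw p-value and ``significant`` means raw p < 0.05. A
Benjamini–Hochberg column is reported for context but does not drive the
flag. The default universe is the set of genes represented on the array.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    universe: set[str]

    @classmethod
    def from_gmt(
        cls, path: str | Path, universe: Iterable[str]
    ) -> "GeneSetCollection":
        """Parse GMT (set_name TAB description TAB gene...) against a universe.

        Set members outside the universe are dropped; sets left empty are
        discarded with a warning.
        """
        universe = set(universe)
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                name, _desc, *genes = parts
                members = sorted({g for g in genes if g} & universe)
                if not members:
                    logger.warning("gene set %r empty after universe filter; dropped", name)
                    continue
                sets[name] = members
        return cls(sets, universe)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int       # overlap
    K: int       # set size in universe
    n: int       # query size in universe
    N: int       # universe size
    p_value: float
    enrichment_score: float
    significant: bool
    fdr_bh: float = float("nan")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X ≥ k) for overlap k of a size-n query with a size-K set."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query: Sequence[str], collection: GeneSetCollection
) -> list[EnrichmentResult]:
    """Score every set; results sorted by Enrichment Score, ties by name."""
    q = set(query) & collection.universe
    if not q:
        raise ValueError("query has no genes in the universe")
    N = len(collection.universe)
    n = len(q)
    raw = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(q.intersection(members))
        p = hypergeom_pvalue(k, K, n, N)
        raw.append((name, k, K, p))

    # BH over all tested sets (informational)
    order = sorted(range(len(raw)), key=lambda i: raw[i][3])
    m = len(raw)
    fdr = [0.0] * m
    prev = 1.0
    for rank_from_last, i in enumerate(reversed(order)):
        rank = m - rank_from_last
        prev = min(prev, raw[i][3] * m / rank)
        fdr[i] = prev

    results = [
        EnrichmentResult(
            set_name=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            enrichment_score=-math.log10(p) if p > 0 else 300.0,
            significant=p < 0.05,
            fdr_bh=fdr[i],
        )
        for i, (name, k, K, p) in enumerate(raw)
    ]
    results.sort(key=lambda r: (-r.enrichment_score, r.set_name))
    return results


def top_n(results: Sequence[EnrichmentResult], n: int = 10) -> list[EnrichmentResult]:
    """The n best-scoring sets (all of them if fewer)."""
    return list(results[:n])


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.set_name, r.k, r.K, r.n, r.N, r.p_value, r.enrichment_score,
             r.significant, r.fdr_bh)
            for r in results
        ],
        columns=["set_name", "k", "K", "n", "N", "p_value",
                 "enrichment_score", "significant", "fdr_bh"],
    )
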