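"""Compartment partitioning, gene-set matrices, and Fisher over-representation.

Over-representation uses the right-tailed Fisher exact (hypergeometric
upper-tail) test; a set is called enriched when -log10(p) >= 1.3, the
log-threshold form equivalent to p <= 10^-1.3.  The default universe is the
set of proteins quantified in the input table — a detection-bias-correct
background — overridable by a GMT universe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .io_core import GeneSetCollection

logger = logging.getLogger("acetyltempo")

#: enrichment threshold on -log10(p), as commonly printed for pathway tools
NEG_LOG10_P_THRESHOLD = 1.3


@dataclass
class CompartmentPartition:
    """Per-compartment DAP membership; multi-membership counts in each."""

    members: dict[str, frozenset[str]]
    unassigned: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(m) for name, m in self.members.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"compartment": name, "count": len(m)}
            for name, m in self.members.items()
        ]
        rows.append({"compartment": "unassigned", "count": len(self.unassigned)})
        return pd.DataFrame(rows)


def partition_by_compartment(
    daps: set[str] | frozenset[str], compartments: GeneSetCollection
) -> CompartmentPartition:
    """Overlay differentially acetylated proteins onto compartment sets.

    Identifier matching is case-insensitive; a protein belonging to k
    compartment sets contributes to all k counts, and proteins in no set
    are counted as unassigned.
    """
    if not compartments.sets:
        raise ValueError("empty compartment collection")
    norm = compartments.case_normalized()
    daps_norm = {d.lower(): d for d in daps}
    members = {
        name: frozenset(
            daps_norm[d] for d in daps_norm if d in norm.sets[name]
        )
        for name in compartments.sets
    }
    assigned = frozenset().union(*members.values()) if members else frozenset()
    unassigned = frozenset(daps) - assigned
    return CompartmentPartition(members, unassigned)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # hits in set
    K: int  # set size within universe
    n: int  # hits in universe
    N: int  # universe size
    p_value: float
    neg_log10_p: float
    enriched: bool


def fisher_right_tail(k: int, K: int, n: int, N: int,
                      set_name: str = "") -> EnrichmentResult:
    """Right-tailed Fisher exact test P(X >= k) for X ~ Hypergeom(N, K, n).

    k = hits in the set, K = set size, n = total hits, N = universe size.
    Enrichment is called on the printed-threshold form -log10(p) >= 1.3.
    """
    if not (0 <= k <= K <= N and k <= n <= N):
        raise ValueError(f"inconsistent margins k={k} K={K} n={n} N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)")
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(p, 1.0)
    neg = -math.log10(p) if p > 0 else math.inf
    return EnrichmentResult(
        set_name, k, K, n, N, p, neg, neg >= NEG_LOG10_P_THRESHOLD
    )


def enrich(
    hits: set[str] | frozenset[str],
    gene_sets: GeneSetCollection,
    universe: set[str] | frozenset[str] | None = None,
) -> pd.DataFrame:
    """Run the right-tailed Fisher test on every gene set.

    `universe` defaults to the collection's own universe; hits and set
    members are restricted to it.  Matching is case-insensitive.
    """
    if universe is None:
        universe = gene_sets.universe
    if universe is None:
        raise ValueError("no universe supplied and collection carries none")
    uni = frozenset(u.lower() for u in universe)
    hits_u = frozenset(h.lower() for h in hits) & uni
    rows = []
    for name, members in gene_sets.sets.items():
        mem = frozenset(m.lower() for m in members) & uni
        res = fisher_right_tail(
            len(hits_u & mem), len(mem), len(hits_u), len(uni), set_name=name
        )
        rows.append(res.__dict__)
    df = pd.DataFrame(rows).set_index("set_name")
    return df.sort_values("p_value")


def extract_gene_set_matrix(
    values: pd.DataFrame,
    gene_set: frozenset[str] | set[str],
    site_proteins: pd.Series,
    order: pd.Index | None = None,
) -> pd.DataFrame:
    """Restrict a site-indexed value table to sites on gene-set proteins.

    `values` rows are sites (log2 intensities or per-contrast log2fc),
    `site_proteins` maps site_id -> protein_id, and `order` optionally
    imposes a supervised row order (class then p).  An empty overlap
    returns an empty matrix with a logged warning.
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    members = {g.lower() for g in gene_set}
    keep = [
        s for s in values.index
        if str(site_proteins.get(s, "")).lower() in members
    ]
    if not keep:
        logger.warning("gene set has no overlap with the data")
        return values.iloc[0:0]
    out = values.loc[keep]
    if order is not None:
        out = out.loc[[s for s in order if s in out.index]]
    return out
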