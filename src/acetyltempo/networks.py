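"""Co-acetylation correlation matrices and interaction-edge concordance.

Pairwise Pearson correlations across sample profiles identify co-regulated
acetylation sites; supplied protein-protein interaction edges are colored
by whether both endpoints move in the same direction (the orange/purple/
gray convention of interaction circle plots: both up, both down, or
discordant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import EdgeList

logger = logging.getLogger("acetyltempo")


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson r, two-tailed p, and an alpha significance mask."""

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    degenerate: pd.Index  # constant features (r set to 0, p to 1)


def correlation_matrix(
    profiles: pd.DataFrame, alpha: float = 0.05
) -> CorrelationMatrix:
    """All-pairs Pearson correlation of feature rows across samples.

    p-values come from the t transform t = r*sqrt((m-2)/(1-r^2)) with m the
    number of shared non-missing samples per pair (two-tailed).  Constant
    features are degenerate: their r is set to 0 and p to 1.  Pairs with
    fewer than 3 shared samples get r = 0, p = 1.
    """
    x = profiles.to_numpy(float)
    n_feat = x.shape[0]
    valid = ~np.isnan(x)
    xz = np.nan_to_num(x)

    # pairwise counts and sufficient statistics under pairwise deletion
    m = valid.astype(float) @ valid.T.astype(float)
    s1 = xz @ valid.T.astype(float)          # sum of x over shared samples
    s1t = valid.astype(float) @ xz.T         # sum of y over shared samples
    s2 = (xz**2) @ valid.T.astype(float)
    s2t = valid.astype(float) @ (xz.T**2)
    sxy = xz @ xz.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - s1 * s1t / m
        vx = s2 - s1**2 / m
        vy = s2t - s1t**2 / m
        r = cov / np.sqrt(vx * vy)
    degenerate_pair = (vx <= 1e-300) | (vy <= 1e-300) | (m < 3)
    r = np.where(degenerate_pair, 0.0, np.clip(r, -1.0, 1.0))
    r = (r + r.T) / 2  # exact symmetry
    np.fill_diagonal(r, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((m - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), np.maximum(m - 2, 1))
    p = np.where(degenerate_pair, 1.0, np.where(np.abs(r) >= 1.0, 0.0, p))
    p = np.minimum((p + p.T) / 2, 1.0)
    np.fill_diagonal(p, 0.0)

    idx = profiles.index
    row_const = np.nanvar(x, axis=1) <= 1e-300
    degen = idx[row_const]
    if len(degen):
        logger.warning("%d constant (degenerate) features", len(degen))
    rdf = pd.DataFrame(r, index=idx, columns=idx)
    pdf = pd.DataFrame(p, index=idx, columns=idx)
    sig = pdf < alpha
    np.fill_diagonal(sig.values, True)
    return CorrelationMatrix(rdf, pdf, sig, degen)


@dataclass(frozen=True)
class ColoredEdge:
    a: str
    b: str
    concordance: str  # both_up | both_down | discordant | unclassified


def color_edges(
    edges: EdgeList, directions: dict[str, str] | pd.Series
) -> list[ColoredEdge]:
    """Color interaction edges by endpoint differential direction.

    Both endpoints up -> both_up (drawn orange); both down -> both_down
    (purple); opposite directions or exactly one unchanged endpoint ->
    discordant (gray); both unchanged -> unclassified.  An endpoint absent
    from the mapping makes the edge unclassified with a warning.
    """
    if isinstance(directions, pd.Series):
        directions = directions.to_dict()
    out = []
    n_missing = 0
    for a, b in edges.edges:
        da, db = directions.get(a), directions.get(b)
        if da is None or db is None:
            n_missing += 1
            out.append(ColoredEdge(a, b, "unclassified"))
            continue
        # any status other than a clean up/down (e.g. "mixed") counts as none
        da = da if da in ("up", "down") else "none"
        db = db if db in ("up", "down") else "none"
        if da == "up" and db == "up":
            c = "both_up"
        elif da == "down" and db == "down":
            c = "both_down"
        elif da == "none" and db == "none":
            c = "unclassified"
        else:
            c = "discordant"
        out.append(ColoredEdge(a, b, c))
    if n_missing:
        logger.warning("%d edges with endpoints missing from the direction "
                       "mapping", n_missing)
    return out


def colored_edges_frame(colored: list[ColoredEdge]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in colored])
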