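"""Nine-way temporal classification of acetylation sites and protein rollup.

Each site is tested in three pairwise contrasts — 6 h vs untreated, 24 h vs
untreated, and 24 h vs 6 h — and assigned exactly one temporal class from
the joint significance/direction pattern:

=====================  =======================================================
class                  pattern (vs untreated unless noted)
=====================  =======================================================
PERSISTENT_UP/DOWN     significant at 6 h and 24 h, same direction
EARLY_DOWN_LATE_UP     significant down at 6 h, significant up at 24 h
EARLY_UP_LATE_DOWN     mirror of the above (kept for exhaustiveness)
LATE_UP/DOWN           not significant at 6 h, significant at 24 h
EARLY_TRANSIENT_*      significant at 6 h, not significant at 24 h
PSEUDOSILENT_UP/DOWN   neither vs-untreated contrast significant, but the
                       24h-vs-6h contrast is; direction from its sign
UNCHANGED              nothing significant
=====================  =======================================================

The 24h-vs-6h contrast is consulted only when neither vs-untreated contrast
is significant, so the eleven classes partition the outcome space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .differential import ContrastOutcome

logger = logging.getLogger("acetyltempo")


class TemporalClass(Enum):
    PERSISTENT_UP = "persistent_up"
    PERSISTENT_DOWN = "persistent_down"
    LATE_UP = "late_up"
    LATE_DOWN = "late_down"
    EARLY_TRANSIENT_UP = "early_transient_up"
    EARLY_TRANSIENT_DOWN = "early_transient_down"
    EARLY_DOWN_LATE_UP = "early_down_late_up"
    EARLY_UP_LATE_DOWN = "early_up_late_down"
    PSEUDOSILENT_UP = "pseudosilent_up"
    PSEUDOSILENT_DOWN = "pseudosilent_down"
    UNCHANGED = "unchanged"


def classify_directions(d6: str, d24: str, d24v6: str) -> TemporalClass:
    """Map a (direction6, direction24, direction24v6) triple to its class.

    Directions are "up", "down" or "none" (= not significant).  The triple
    space (27 combinations) is partitioned exhaustively.
    """
    for d in (d6, d24, d24v6):
        if d not in ("up", "down", "none"):
            raise ValueError(f"invalid direction {d!r}")
    if d6 != "none" and d24 != "none":
        if d6 == d24:
            return (TemporalClass.PERSISTENT_UP if d6 == "up"
                    else TemporalClass.PERSISTENT_DOWN)
        return (TemporalClass.EARLY_DOWN_LATE_UP if d6 == "down"
                else TemporalClass.EARLY_UP_LATE_DOWN)
    if d6 == "none" and d24 != "none":
        return TemporalClass.LATE_UP if d24 == "up" else TemporalClass.LATE_DOWN
    if d6 != "none" and d24 == "none":
        return (TemporalClass.EARLY_TRANSIENT_UP if d6 == "up"
                else TemporalClass.EARLY_TRANSIENT_DOWN)
    if d24v6 != "none":
        return (TemporalClass.PSEUDOSILENT_UP if d24v6 == "up"
                else TemporalClass.PSEUDOSILENT_DOWN)
    return TemporalClass.UNCHANGED


def classify_site(
    c6: ContrastOutcome, c24: ContrastOutcome, c24v6: ContrastOutcome
) -> TemporalClass:
    """Classify one site from its three contrast outcomes."""
    if not (c6.site_id == c24.site_id == c24v6.site_id):
        raise ValueError("contrast outcomes belong to different sites")
    return classify_directions(c6.direction, c24.direction, c24v6.direction)


def classify_table(
    contrasts: pd.DataFrame,
    contrast_6: str,
    contrast_24: str,
    contrast_24v6: str,
) -> pd.DataFrame:
    """Classify every site in a stacked contrast table.

    `contrasts` is the output of ``differential.contrast_all`` (index
    site_id, column ``contrast``).  Only sites testable in all three
    contrasts are classified.  Returns a DataFrame indexed by site_id with
    the class plus per-contrast p and log2fc columns.
    """
    wide = {}
    for label, tag in [(contrast_6, "6h"), (contrast_24, "24h"),
                       (contrast_24v6, "24v6")]:
        sub = contrasts[contrasts["contrast"] == label]
        if sub.empty:
            raise ValueError(f"contrast {label!r} absent from table")
        wide[tag] = sub[["direction", "p_value", "log2fc"]].rename(
            columns=lambda c: f"{c}_{tag}"
        )
    merged = wide["6h"].join(wide["24h"], how="inner").join(
        wide["24v6"], how="inner"
    )
    classes = [
        classify_directions(r.direction_6h, r.direction_24h, r.direction_24v6)
        for r in merged.itertuples()
    ]
    merged.insert(0, "temporal_class", [c.name for c in classes])
    merged.index.name = "site_id"
    return merged


@dataclass
class ProteinCall:
    """Protein-level rollup of site calls for the three contrasts."""

    protein_id: str
    n_sites: int
    dap_status: dict[str, str]  # contrast tag -> up|down|mixed|none
    temporal_class: str
    n_up: dict[str, int]
    n_down: dict[str, int]


def _dap_status(n_up: int, n_down: int) -> str:
    if n_up and n_down:
        return "mixed"
    if n_up:
        return "up"
    if n_down:
        return "down"
    return "none"


def aggregate_to_proteins(
    site_classes: pd.DataFrame,
    site_proteins: pd.Series | None = None,
) -> pd.DataFrame:
    """Roll site classes up to proteins.

    Per contrast a protein is "up" if at least one site is up and none down,
    symmetrically "down", "mixed" if both, else "none".  The protein's
    temporal class is the class of its most significant site by the 24 h
    contrast p-value, ties broken by ascending residue position.

    ``site_proteins`` maps site_id -> protein_id; by default protein ids
    are parsed from the ``<protein>_K<pos>`` site-id convention.
    """
    from .io_core import parse_site_id

    df = site_classes.copy()
    if site_proteins is None:
        parsed = [parse_site_id(s) for s in df.index]
        df["protein_id"] = [p for p, _ in parsed]
        df["position"] = [pos for _, pos in parsed]
    else:
        orphans = [s for s in df.index if s not in site_proteins.index]
        if orphans:
            raise ValueError(f"sites with unknown protein: {orphans}")
        df["protein_id"] = site_proteins.loc[df.index].to_numpy()
        df["position"] = [parse_site_id(s)[1] for s in df.index]

    rows = []
    for pid, grp in df.groupby("protein_id", sort=True):
        rec: dict = {"protein_id": pid, "n_sites": len(grp)}
        for tag in ("6h", "24h", "24v6"):
            d = grp[f"direction_{tag}"]
            up = int((d == "up").sum())
            down = int((d == "down").sum())
            rec[f"n_up_{tag}"] = up
            rec[f"n_down_{tag}"] = down
            rec[f"dap_{tag}"] = _dap_status(up, down)
        best = grp.sort_values(["p_value_24h", "position"]).iloc[0]
        rec["temporal_class"] = best["temporal_class"]
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("protein_id")
    return out


def shared_unique(
    set_a: set[str] | frozenset[str], set_b: set[str] | frozenset[str]
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Venn partition: (shared, only in a, only in b)."""
    a, b = frozenset(set_a), frozenset(set_b)
    return a & b, a - b, b - a


_CLASS_ORDER = [c.name for c in TemporalClass]


def ordered_matrix(
    site_classes: pd.DataFrame, logtable_or_contrasts: pd.DataFrame
) -> pd.DataFrame:
    """Heatmap-ready matrix: rows ordered by temporal class then by the
    24 h contrast p-value (the supervised ordering used for temporal
    heatmaps), columns taken from the supplied value table."""
    order = site_classes.assign(
        _rank=[_CLASS_ORDER.index(c) for c in site_classes["temporal_class"]]
    ).sort_values(["_rank", "p_value_24h"]).index
    keep = [s for s in order if s in logtable_or_contrasts.index]
    return logtable_or_contrasts.loc[keep]
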