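"""Iterative flanking-motif discovery around acetylated lysines.

Implements the motif-x strategy: within fixed-length K-centered windows,
repeatedly find the (offset, residue) pair whose foreground count is most
surprising under a binomial model with positional background frequencies,
fix it, restrict both window sets to matches, and recurse; when no
candidate passes the p cutoff and minimum-occurrence filter, the
accumulated constraint set is emitted as one motif, its matching foreground
windows are removed, and the search restarts.  The procedure is fully
deterministic: candidate ties are broken lexicographically by
(offset, residue).

Discovered motifs are summarized as position-frequency matrices (PFMs) and
can be scored against a library of known-motif PFMs by the best mean
per-column Pearson correlation over ungapped alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .io_core import AMINO_ACIDS, PAD

logger = logging.getLogger("acetyltempo")


@dataclass(frozen=True)
class MotifStep:
    """One fixed constraint with the binomial statistics of its step."""

    offset: int
    residue: str
    k: int          # foreground count of the residue at the offset
    n: int          # foreground size when the step was taken
    p0: float       # positional background frequency at that step
    p_value: float  # binomial right-tail p of the step


@dataclass
class Motif:
    """One discovered motif: fixed (offset, residue) constraints plus the
    enrichment statistics.  The headline p-value and (k, n, p0) refer to the
    seeding (first-fixed, most significant) constraint; per-step statistics
    for extensions live in ``steps``."""

    constraints: tuple[tuple[int, str], ...]
    k: int                      # final foreground matches of the full motif
    n: int                      # foreground size when the search started
    p0: float                   # product of per-step background frequencies
    p_value: float              # binomial right-tail p of the seeding step
    fold_enrichment: float
    steps: tuple[MotifStep, ...]
    pfm: pd.DataFrame = field(repr=False)

    @property
    def pattern(self) -> str:
        """Human-readable pattern, e.g. ``......EK.......`` for E at -1."""
        half = (self.pfm.shape[1] - 1) // 2
        chars = ["."] * (2 * half + 1)
        chars[half] = "K"
        for off, res in self.constraints:
            chars[half + off] = res
        return "".join(chars)


def window_matrix(windows: list[str]) -> np.ndarray:
    return np.array([list(w) for w in windows])


def positional_frequencies(windows: list[str]) -> pd.DataFrame:
    """Per-position residue frequencies (pad symbols excluded from the
    denominator), rows = residues, columns = offsets."""
    mat = window_matrix(windows)
    half = (mat.shape[1] - 1) // 2
    offsets = list(range(-half, half + 1))
    freq = np.zeros((len(AMINO_ACIDS), mat.shape[1]))
    for j in range(mat.shape[1]):
        col = mat[:, j]
        col = col[col != PAD]
        denom = max(len(col), 1)
        for i, a in enumerate(AMINO_ACIDS):
            freq[i, j] = np.sum(col == a) / denom
    return pd.DataFrame(freq, index=list(AMINO_ACIDS), columns=offsets)


def binomial_right_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0)."""
    if k <= 0:
        return 1.0
    return float(binom.sf(k - 1, n, p0))


def pfm(windows: list[str]) -> pd.DataFrame:
    """Position-frequency matrix of a window set (synonym wrapper)."""
    return positional_frequencies(windows)


def discover_motifs(
    foreground: list[str],
    background: list[str],
    p_cutoff: float = 1e-6,
    min_occurrences: int = 20,
    max_motifs: int = 10,
) -> list[Motif]:
    """motif-x-style iterative binomial motif discovery.

    Background frequencies are computed positionally from the supplied
    background windows and re-computed after every restriction.  Each
    emitted motif satisfies p < p_cutoff and k >= min_occurrences for every
    fixed constraint.
    """
    if not 0 < p_cutoff < 1:
        raise ValueError("p_cutoff must be in (0,1)")
    if not foreground:
        return []
    width = len(foreground[0])
    if any(len(w) != width for w in foreground + background):
        raise ValueError("all windows must have equal length")
    half = (width - 1) // 2

    fg = window_matrix(foreground)
    bg = window_matrix(background)
    motifs: list[Motif] = []

    while len(motifs) < max_motifs and len(fg) >= min_occurrences:
        constraints: list[tuple[int, str]] = []
        steps: list[MotifStep] = []
        cur_fg, cur_bg = fg, bg
        cum_p0 = 1.0
        while True:
            best = None  # (p, offset, residue, k, n, p0)
            n = len(cur_fg)
            for j in range(width):
                off = j - half
                if off == 0:
                    continue
                if any(c[0] == off for c in constraints):
                    continue
                bg_col = cur_bg[:, j]
                bg_col = bg_col[bg_col != PAD]
                if len(bg_col) == 0:
                    continue
                fg_col = cur_fg[:, j]
                for res in AMINO_ACIDS:
                    k = int(np.sum(fg_col == res))
                    if k < min_occurrences:
                        continue
                    p0 = float(np.sum(bg_col == res)) / len(bg_col)
                    if p0 <= 0.0:
                        p0 = 1.0 / (2 * len(bg_col))  # unseen-residue floor
                    p = binomial_right_tail(k, n, p0)
                    cand = (p, off, res, k, n, p0)
                    if best is None or (p, off, res) < (best[0], best[1],
                                                        best[2]):
                        best = cand
            if best is None or best[0] >= p_cutoff:
                break
            p, off, res, k, n, p0 = best
            constraints.append((off, res))
            steps.append(MotifStep(off, res, k, n, p0, p))
            cum_p0 *= p0
            j = off + half
            cur_fg = cur_fg[cur_fg[:, j] == res]
            cur_bg = cur_bg[cur_bg[:, j] == res]
            if len(cur_bg) == 0:
                break
        if not constraints:
            break
        k_final = len(cur_fg)
        n0 = len(fg)
        matched = ["".join(row) for row in cur_fg]
        fold = (k_final / n0) / cum_p0 if cum_p0 > 0 else np.inf
        motifs.append(
            Motif(
                constraints=tuple(constraints),
                k=k_final,
                n=n0,
                p0=cum_p0,
                p_value=steps[0].p_value,
                fold_enrichment=fold,
                steps=tuple(steps),
                pfm=positional_frequencies(matched),
            )
        )
        # remove matched windows and restart
        mask = np.ones(len(fg), dtype=bool)
        for off, res in constraints:
            mask &= fg[:, off + half] == res
        fg = fg[~mask]
    return motifs


def motifs_frame(motifs: list[Motif]) -> pd.DataFrame:
    rows = []
    for m in motifs:
        rows.append(
            {
                "pattern": m.pattern,
                "constraints": ";".join(f"{o}:{r}" for o, r in m.constraints),
                "k": m.k,
                "n": m.n,
                "p0": m.p0,
                "p_value": m.p_value,
                "fold_enrichment": m.fold_enrichment,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# known-motif matching


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two frequency columns; 0 if either is
    zero-variance (e.g. a uniform column)."""
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def pfm_similarity(query: pd.DataFrame, reference: pd.DataFrame,
                   min_overlap: int = 4) -> float:
    """Best mean per-column Pearson correlation over ungapped offsets."""
    q = query.to_numpy(float)
    r = reference.to_numpy(float)
    nq, nr = q.shape[1], r.shape[1]
    best = -1.0
    for shift in range(-(nq - min_overlap), nr - min_overlap + 1):
        cols = []
        for jq in range(nq):
            jr = jq + shift
            if 0 <= jr < nr:
                cols.append(_column_correlation(q[:, jq], r[:, jr]))
        if len(cols) >= min_overlap:
            best = max(best, float(np.mean(cols)))
    return best


def match_known_motifs(
    query: pd.DataFrame, library: dict[str, pd.DataFrame],
    min_overlap: int = 4,
) -> tuple[str, float]:
    """Best-scoring library PFM for a query PFM."""
    if not library:
        raise ValueError("empty motif library")
    scored = {
        name: pfm_similarity(query, ref, min_overlap)
        for name, ref in library.items()
    }
    best = max(scored, key=lambda k: (scored[k], k))
    return best, scored[best]


def read_pfm(path: str | Path) -> pd.DataFrame:
    """Read a PFM TSV (rows = residues, columns = offsets)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [int(c) for c in df.columns]
    return df


def write_pfm(pfm_df: pd.DataFrame, path: str | Path) -> None:
    out = pfm_df.copy()
    out.index.name = "residue"
    out.to_csv(path, sep="\t", float_format="%.10g")


def load_pfm_library(directory: str | Path) -> dict[str, pd.DataFrame]:
    return {
        p.stem: read_pfm(p) for p in sorted(Path(directory).glob("*.tsv"))
    }
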