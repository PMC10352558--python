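"""Seeded generator for acetylome datasets with known planted structure.

Emulates a 3-condition (UnT, 6hAmAc, 24hAmAc) x 3-replicate site-intensity
experiment: every site gets a temporal class that prescribes its log2 shift
at 6 h and 24 h relative to untreated, replicate noise is additive Gaussian
on the log2 scale (log-normal on the raw scale, the standard model for MS
intensities), proteins carry compartment labels, and a configurable fraction
of flanking windows carry a planted motif residue.  Because the ground truth
is recorded, every downstream stage can be scored against it.

A note on the pseudosilent class: it is defined observationally (6 h and
24 h differ from each other, neither differs from untreated), which no pair
of fixed shifts can realize exactly at high power.  Pseudosilent sites are
therefore planted with shifts of -effect/2 and +effect/2 around untreated
(so the 24h-vs-6h difference equals the full effect) and with replicate
noise inflated by a factor of 2, which de-powers the vs-untreated contrasts
much more than the twice-as-large 24h-vs-6h contrast.  Recovery of this
class is intrinsically partial and is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import AMINO_ACIDS, EdgeList, GeneSetCollection, QuantTable
from .temporal_classify import TemporalClass

#: noise-sd multiplier applied to pseudosilent sites (see module docstring)
PSEUDOSILENT_NOISE_FACTOR = 2.0

DEFAULT_CONDITIONS = ("UnT", "6hAmAc", "24hAmAc")

#: default temporal-class mix: most quantified sites unchanged, persistent /
#: late / early-transient classes dominating the changed fraction, mirror
#: classes at half weight, and the never-observed early-up-late-down empty.
DEFAULT_CLASS_PROPORTIONS: dict[TemporalClass, float] = {
    TemporalClass.UNCHANGED: 0.40,
    TemporalClass.PERSISTENT_UP: 0.10,
    TemporalClass.PERSISTENT_DOWN: 0.05,
    TemporalClass.LATE_UP: 0.10,
    TemporalClass.LATE_DOWN: 0.05,
    TemporalClass.EARLY_TRANSIENT_UP: 0.10,
    TemporalClass.EARLY_TRANSIENT_DOWN: 0.05,
    TemporalClass.EARLY_DOWN_LATE_UP: 0.05,
    TemporalClass.PSEUDOSILENT_UP: 0.05,
    TemporalClass.PSEUDOSILENT_DOWN: 0.05,
}

DEFAULT_COMPARTMENTS: dict[str, float] = {
    "mitochondrion": 0.40,
    "nucleus": 0.25,
    "cytosol": 0.25,
    "plasma_membrane": 0.10,
}


def class_shifts(cls: TemporalClass, effect: float) -> tuple[float, float]:
    """Planted log2 shifts (at 6 h, at 24 h) vs untreated for one class."""
    e = effect
    return {
        TemporalClass.PERSISTENT_UP: (e, e),
        TemporalClass.PERSISTENT_DOWN: (-e, -e),
        TemporalClass.LATE_UP: (0.0, e),
        TemporalClass.LATE_DOWN: (0.0, -e),
        TemporalClass.EARLY_TRANSIENT_UP: (e, 0.0),
        TemporalClass.EARLY_TRANSIENT_DOWN: (-e, 0.0),
        TemporalClass.EARLY_DOWN_LATE_UP: (-e, e),
        TemporalClass.EARLY_UP_LATE_DOWN: (e, -e),
        TemporalClass.PSEUDOSILENT_UP: (-e / 2, e / 2),
        TemporalClass.PSEUDOSILENT_DOWN: (e / 2, -e / 2),
        TemporalClass.UNCHANGED: (0.0, 0.0),
    }[cls]


@dataclass
class MotifPlant:
    """Planted flanking-motif spec: `residue` at `offset` (center = 0) in a
    `foreground_fraction` of changed-site windows; elsewhere residues are
    drawn from the background frequency table."""

    residue: str = "E"
    offset: int = -1
    foreground_fraction: float = 0.4
    background_fraction: float = 0.05


@dataclass
class SimulationDesign:
    n_proteins: int = 400
    sites_per_protein: tuple[int, int] = (1, 3)
    n_replicates: int = 3
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    class_proportions: dict[TemporalClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_size: float = 2.0
    noise_sd: float = 0.3
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    compartment_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENTS)
    )
    motif: MotifPlant = field(default_factory=MotifPlant)
    dropout: float = 0.0
    half_width: int = 7
    edge_density: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if self.sites_per_protein[1] < self.sites_per_protein[0]:
            raise ValueError("sites_per_protein max < min")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class GroundTruth:
    """Planted per-site classes, per-protein compartments, motif carriers."""

    site_class: pd.Series  # index site_id -> TemporalClass name
    protein_compartment: pd.Series  # index protein_id -> compartment name
    motif_carrier: pd.Series  # index site_id -> bool

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"true_class": self.site_class, "motif_carrier": self.motif_carrier}
        )
        df.index.name = "site_id"
        return df


def apportion(proportions: dict, n: int) -> dict:
    """Largest-remainder apportionment of n items to the given proportions."""
    quotas = {k: p * n for k, p in proportions.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    by_rem = sorted(
        proportions, key=lambda k: (-(quotas[k] - counts[k]), str(k))
    )
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def plant_motif(
    windows: list[str],
    residue: str,
    offset: int,
    fraction: float,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], np.ndarray]:
    """Force `residue` at `offset` in exactly round(fraction*n) windows.

    Returns the modified windows and a boolean carrier mask.  Offset 0 is the
    acetyl-K itself and may only be "planted" with K.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0,1]")
    if offset == 0 and residue != "K":
        raise ValueError("offset 0 is the central acetyl-K; cannot plant "
                         f"{residue!r} there")
    n = len(windows)
    if n == 0:
        return [], np.zeros(0, dtype=bool)
    half = (len(windows[0]) - 1) // 2
    if abs(offset) > half:
        raise ValueError(f"|offset| {abs(offset)} exceeds half-width {half}")
    k = round(fraction * n)
    if rng is None:
        carriers = np.zeros(n, dtype=bool)
        carriers[:k] = True
    else:
        carriers = np.zeros(n, dtype=bool)
        carriers[rng.choice(n, size=k, replace=False)] = True
    col = half + offset
    out = []
    for w, hit in zip(windows, carriers):
        out.append(w[:col] + residue + w[col + 1 :] if hit else w)
    return out, carriers


def simulate_dataset(
    design: SimulationDesign,
) -> tuple[QuantTable, dict[str, str], GeneSetCollection, EdgeList, GroundTruth]:
    """Generate one seeded dataset with planted structure.

    Returns the quant table, protein sequences, gene sets (compartments),
    an interaction edge list, and the ground truth.  Identical designs
    (including the seed) produce bit-identical outputs.
    """
    rng = np.random.default_rng(design.seed)
    hw = design.half_width

    # --- proteins, site positions, sequences -------------------------------
    n_sites_per = rng.integers(
        design.sites_per_protein[0], design.sites_per_protein[1] + 1,
        size=design.n_proteins,
    )
    proteins = [f"P{i:04d}" for i in range(design.n_proteins)]
    aa = np.array(list(AMINO_ACIDS))
    bg = np.full(20, 1 / 20)  # uniform background keeps binomial oracles exact
    sequences: dict[str, str] = {}
    site_index: list[tuple[str, int]] = []
    for pid, k in zip(proteins, n_sites_per):
        # sites spaced 2*hw+1 apart so windows never collide
        length = int(k) * (2 * hw + 1) + 2 * hw
        seq = rng.choice(aa, size=length, p=bg)
        positions = [hw + 1 + j * (2 * hw + 1) for j in range(int(k))]
        for pos in positions:
            seq[pos - 1] = "K"
            site_index.append((pid, pos))
        sequences[pid] = "".join(seq)

    site_ids = [f"{pid}_K{pos}" for pid, pos in site_index]
    n_sites = len(site_ids)

    # --- temporal classes (largest-remainder exact counts) -----------------
    counts = apportion(design.class_proportions, n_sites)
    labels: list[TemporalClass] = []
    for cls, c in counts.items():
        labels.extend([cls] * c)
    order = rng.permutation(n_sites)
    labels = [labels[i] for i in order]

    # --- intensities --------------------------------------------------------
    n_rep = design.n_replicates
    cond_unt, cond_6, cond_24 = design.conditions
    samples = [
        f"{cond}_r{r}" for cond in design.conditions for r in range(1, n_rep + 1)
    ]
    baseline = rng.normal(design.baseline_mean, design.baseline_sd, n_sites)
    shifts = np.array(
        [class_shifts(c, design.effect_size) for c in labels]
    )  # (n_sites, 2)
    mean_log2 = np.column_stack(
        [baseline, baseline + shifts[:, 0], baseline + shifts[:, 1]]
    )  # per condition
    sd = np.where(
        [c.name.startswith("PSEUDOSILENT") for c in labels],
        design.noise_sd * PSEUDOSILENT_NOISE_FACTOR,
        design.noise_sd,
    )
    log2 = np.repeat(mean_log2, n_rep, axis=1) + rng.normal(
        0.0, sd[:, None], (n_sites, 3 * n_rep)
    )
    intensities = np.maximum(np.exp2(log2), 0.0)
    if design.dropout > 0:
        mask = rng.random(intensities.shape) < design.dropout
        intensities = np.where(mask, np.nan, intensities)

    data = pd.DataFrame(intensities, index=pd.Index(site_ids, name="site_id"),
                        columns=samples)
    meta = pd.DataFrame(
        {
            "condition": [c for c in design.conditions for _ in range(n_rep)],
            "replicate": list(range(1, n_rep + 1)) * 3,
        },
        index=pd.Index(samples, name="sample"),
    )
    table = QuantTable(data, meta)

    # --- compartments -------------------------------------------------------
    comp_counts = apportion(design.compartment_proportions, design.n_proteins)
    comp_labels: list[str] = []
    for comp, c in comp_counts.items():
        comp_labels.extend([comp] * c)
    comp_order = rng.permutation(design.n_proteins)
    comp_labels = [comp_labels[i] for i in comp_order]
    comp_sets = {
        comp: frozenset(
            p for p, lab in zip(proteins, comp_labels) if lab == comp
        )
        for comp in design.compartment_proportions
    }
    gene_sets = GeneSetCollection(comp_sets, universe=frozenset(proteins))

    # --- planted motif on changed-site windows ------------------------------
    changed = np.array(
        [c is not TemporalClass.UNCHANGED for c in labels], dtype=bool
    )
    carriers = np.zeros(n_sites, dtype=bool)
    m = design.motif
    changed_idx = np.flatnonzero(changed)
    k_carry = round(m.foreground_fraction * len(changed_idx))
    chosen = rng.choice(len(changed_idx), size=k_carry, replace=False)
    carriers[changed_idx[chosen]] = True
    col = m.offset  # position relative to the K
    for i in np.flatnonzero(carriers):
        pid, pos = site_index[i]
        seq = sequences[pid]
        j = pos - 1 + col
        if 0 <= j < len(seq):
            sequences[pid] = seq[:j] + m.residue + seq[j + 1 :]

    # --- edges --------------------------------------------------------------
    ii, jj = np.triu_indices(design.n_proteins, k=1)
    n_pairs = len(ii)
    n_edges = min(int(round(design.edge_density * n_pairs)), n_pairs)
    pair_idx = np.sort(rng.choice(n_pairs, size=n_edges, replace=False))
    edge_list = EdgeList(
        [(proteins[ii[k]], proteins[jj[k]]) for k in pair_idx]
    )

    truth = GroundTruth(
        site_class=pd.Series(
            [c.name for c in labels], index=site_ids, name="true_class"
        ),
        protein_compartment=pd.Series(
            comp_labels, index=proteins, name="compartment"
        ),
        motif_carrier=pd.Series(carriers, index=site_ids, name="motif_carrier"),
    )
    return table, sequences, gene_sets, edge_list, truth


def random_windows(
    n: int,
    half_width: int = 7,
    rng: np.random.Generator | None = None,
    background: np.ndarray | None = None,
) -> list[str]:
    """K-centered windows with flank residues drawn from `background`
    (uniform over the 20 amino acids by default)."""
    rng = rng or np.random.default_rng()
    aa = np.array(list(AMINO_ACIDS))
    p = background if background is not None else np.full(20, 1 / 20)
    w = 2 * half_width + 1
    flanks = rng.choice(aa, size=(n, w), p=p)
    flanks[:, half_width] = "K"
    return ["".join(row) for row in flanks]
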