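"""Reproducible simulation experiments scoring the pipeline against its
planted ground truth.

These are the package's calibration/validation workloads: planted-class
recovery of the temporal classifier, type-I calibration of the per-site
t-test under an all-unchanged simulation, and recovery of a planted
flanking motif.  Each takes a base seed and derives per-replicate seeds
deterministically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import contrast_all, transform
from .motifs import discover_motifs
from .synthetic_data import (
    SimulationDesign,
    plant_motif,
    random_windows,
    simulate_dataset,
)
from .temporal_classify import TemporalClass, classify_table

CONTRAST_PAIRS = [("UnT", "6hAmAc"), ("UnT", "24hAmAc"), ("6hAmAc", "24hAmAc")]
CONTRAST_6H = "6hAmAc_vs_UnT"
CONTRAST_24H = "24hAmAc_vs_UnT"
CONTRAST_24V6 = "24hAmAc_vs_6hAmAc"


def child_seeds(base_seed: int, n: int) -> list[int]:
    """n deterministic 31-bit seeds derived from one base seed."""
    return [
        int(s) for s in
        np.random.SeedSequence(base_seed).generate_state(n) % (2**31)
    ]


def classify_dataset(table) -> pd.DataFrame:
    """Transform -> three contrasts -> temporal classes for one quant table."""
    logt = transform(table)
    cons = contrast_all(logt, CONTRAST_PAIRS)
    return classify_table(cons, CONTRAST_6H, CONTRAST_24H, CONTRAST_24V6)


def class_recovery(
    base_seed: int = 0,
    n_seeds: int = 20,
    n_proteins: int = 1000,
    sites_per_protein: tuple[int, int] = (2, 2),
    effect_size: float = 2.0,
    noise_sd: float = 0.3,
) -> dict:
    """Planted-class recovery of the temporal classifier.

    Defaults give exactly 2,000 sites per replicate.  Returns per-class
    recovery rates plus three summaries: the unweighted mean of per-class
    recovery over the non-pseudosilent classes (macro), the site-weighted
    agreement over non-pseudosilent sites (micro), and the pseudosilent
    recovery reported separately (expected much lower by construction; see
    the synthetic-data module).
    """
    per_class_hits: dict[str, int] = {}
    per_class_n: dict[str, int] = {}
    for seed in child_seeds(base_seed, n_seeds):
        design = SimulationDesign(
            n_proteins=n_proteins, sites_per_protein=sites_per_protein,
            effect_size=effect_size, noise_sd=noise_sd, seed=seed,
        )
        table, _, _, _, truth = simulate_dataset(design)
        called = classify_dataset(table)["temporal_class"]
        truth_cls = truth.site_class.loc[called.index]
        for cls in truth_cls.unique():
            mask = truth_cls == cls
            per_class_hits[cls] = per_class_hits.get(cls, 0) + int(
                (called[mask] == cls).sum()
            )
            per_class_n[cls] = per_class_n.get(cls, 0) + int(mask.sum())
    per_class = {
        cls: per_class_hits[cls] / per_class_n[cls] for cls in per_class_n
    }
    non_ps = [c for c in per_class if not c.startswith("PSEUDOSILENT")]
    ps = [c for c in per_class if c.startswith("PSEUDOSILENT")]
    macro = float(np.mean([per_class[c] for c in non_ps]))
    micro = sum(per_class_hits[c] for c in non_ps) / sum(
        per_class_n[c] for c in non_ps
    )
    ps_rate = (
        sum(per_class_hits[c] for c in ps) / sum(per_class_n[c] for c in ps)
        if ps else float("nan")
    )
    return {
        "per_class": per_class,
        "macro_recovery": macro,
        "micro_recovery": float(micro),
        "pseudosilent_recovery": float(ps_rate),
        "n_sites_per_seed": sum(per_class_n.values()) // max(len(
            child_seeds(base_seed, n_seeds)), 1),
    }


def type_i_calibration(
    base_seed: int = 0,
    n_seeds: int = 20,
    n_proteins: int = 1000,
    alpha: float = 0.05,
) -> dict[str, float]:
    """False-positive rate per contrast under an all-unchanged simulation."""
    fractions: dict[str, list[float]] = {}
    for seed in child_seeds(base_seed, n_seeds):
        design = SimulationDesign(
            n_proteins=n_proteins, sites_per_protein=(2, 2),
            class_proportions={TemporalClass.UNCHANGED: 1.0}, seed=seed,
        )
        table = simulate_dataset(design)[0]
        cons = contrast_all(transform(table), CONTRAST_PAIRS, alpha=alpha)
        for label, grp in cons.groupby("contrast"):
            fractions.setdefault(label, []).append(
                float((grp["p_value"] < alpha).mean())
            )
    return {label: float(np.mean(v)) for label, v in fractions.items()}


def motif_recovery(
    base_seed: int = 0,
    n_seeds: int = 20,
    n_windows: int = 500,
    fraction: float = 0.4,
    residue: str = "E",
    offset: int = -1,
) -> dict:
    """Fraction of seeds in which the planted motif is the first discovered.

    Background residue frequencies are uniform (1/20 = 0.05 per residue per
    position), so the planted constraint competes against a 5% background.
    """
    hits = 0
    for seed in child_seeds(base_seed, n_seeds):
        rng = np.random.default_rng(seed)
        fg = random_windows(n_windows, half_width=7, rng=rng)
        fg, _ = plant_motif(fg, residue, offset, fraction, rng=rng)
        bg = random_windows(10 * n_windows, half_width=7, rng=rng)
        motifs = discover_motifs(fg, bg)
        if motifs and motifs[0].constraints[0] == (offset, residue):
            hits += 1
    return {"hits": hits, "n_seeds": n_seeds, "fraction": hits / n_seeds}
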