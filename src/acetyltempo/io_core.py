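"""File formats, core containers, and run configuration.

The pipeline's on-disk currency is plain text: site-level intensity tables
and sample sheets as TSV, gene sets as GMT, protein sequences as FASTA,
interaction edges as two-column TSV.  Acetylation sites are named
``<protein_id>_K<position>`` with a 1-based residue position, the common
convention for acetyl-lysine site identifiers.
"""

from __future__ import annotations

import logging
import re
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("acetyltempo")

#: pad symbol used when a sequence window overflows a protein terminus;
#: deliberately distinct from the 20 amino-acid letters and from X.
PAD = "_"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_SITE_RE = re.compile(r"^(?P<protein>.+)_K(?P<pos>\d+)$")


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


def parse_site_id(site_id: str) -> tuple[str, int]:
    """Split ``PROT_K123`` into ``("PROT", 123)``; raise on malformed ids."""
    m = _SITE_RE.match(site_id)
    if m is None or int(m.group("pos")) < 1:
        raise ValidationError(f"unparsable site id {site_id!r}")
    return m.group("protein"), int(m.group("pos"))


@dataclass
class QuantTable:
    """Site-level acetylation intensities over condition x replicate samples.

    Parameters
    ----------
    data
        Non-negative intensity matrix, rows indexed by ``site_id``,
        columns by sample name.
    sample_meta
        One row per sample (index = sample name) with columns
        ``condition`` and ``replicate`` (1-based integer).
    log_scale
        True once the table holds log-transformed values, which may be
        negative; raw intensity tables must be non-negative.
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site ids: {dups}")
        missing = [c for c in self.data.columns if c not in self.sample_meta.index]
        if missing:
            raise ValidationError(
                f"samples missing from sample sheet: {missing}"
            )
        if not self.log_scale:
            neg = self.data.lt(0)
            if neg.any().any():
                site = self.data.index[neg.any(axis=1)][0]
                col = self.data.columns[neg.loc[site].to_numpy().nonzero()[0][0]]
                raise ValidationError(
                    f"negative intensity at site {site!r}, sample {col!r}"
                )
        self.sample_meta = self.sample_meta.loc[list(self.data.columns)]

    @property
    def site_ids(self) -> pd.Index:
        return self.data.index

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["condition"]))

    def site_info(self) -> pd.DataFrame:
        """Protein id and lysine position parsed from each site id."""
        parsed = [parse_site_id(s) for s in self.data.index]
        return pd.DataFrame(
            parsed, index=self.data.index, columns=["protein_id", "position"]
        )

    def samples_for(self, condition: str) -> list[str]:
        mask = self.sample_meta["condition"] == condition
        return list(self.sample_meta.index[mask])


@dataclass
class GeneSetCollection:
    """Named identifier sets (compartments, pathways) with optional universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if any(m == "" for m in members):
                raise ValidationError(f"empty member identifier in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def case_normalized(self) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: frozenset(m.lower() for m in s) for n, s in self.sets.items()},
            None if self.universe is None
            else frozenset(m.lower() for m in self.universe),
        )


@dataclass
class EdgeList:
    """Undirected, de-duplicated interaction edges without self-loops."""

    edges: list[tuple[str, str]]
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], None] = {}
        weights: dict[tuple[str, str], float] = {}
        for e in self.edges:
            a, b = e
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen[key] = None
            if e in self.weights:
                weights[key] = self.weights[e]
        self.edges = list(seen)
        self.weights = weights

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class RunConfig:
    """Numeric knobs shared across the pipeline.

    ``alpha`` is the unadjusted per-contrast significance cutoff;
    ``pseudocount`` is added to every intensity before the log transform;
    motif parameters follow the usual motif-x defaults (15-mer windows,
    binomial p cutoff 1e-6, at least 20 foreground occurrences).
    """

    alpha: float = 0.05
    pseudocount: float = 1.0
    log_base: float = 2.0
    motif_half_width: int = 7
    motif_p_cutoff: float = 1e-6
    motif_min_occurrences: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.motif_half_width < 1:
            raise ValidationError("motif_half_width must be >= 1")
        if not 0 < self.motif_p_cutoff < 1:
            raise ValidationError("motif_p_cutoff must be in (0,1)")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a TOML key/value config; keyword arguments win over the file."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        known.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**known)
        logger.info("effective config: %s", cfg)
        return cfg


# ---------------------------------------------------------------------------
# readers / writers


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    for col in ("sample", "condition", "replicate"):
        if col not in sheet.columns:
            raise ValidationError(f"sample sheet missing column {col!r}")
    if sheet["sample"].duplicated().any():
        raise ValidationError("duplicate sample names in sample sheet")
    sheet = sheet.set_index("sample")
    sheet["replicate"] = sheet["replicate"].astype(int)
    if (sheet["replicate"] < 1).any():
        raise ValidationError("replicate indices must be >= 1")
    return sheet


def read_quant_table(path: str | Path, sample_sheet: str | Path,
                     log_scale: bool = False) -> QuantTable:
    """Read a site x sample intensity TSV plus its sample sheet.

    The TSV's first column holds site ids; every other column must appear in
    the sample sheet.  Rows whose site id does not parse as
    ``<protein>_K<pos>`` are dropped with a logged count.
    """
    meta = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    unknown = [c for c in df.columns if c not in meta.index]
    if unknown:
        raise ValidationError(
            f"columns absent from sample sheet: {unknown}"
        )
    bad = []
    for sid in df.index:
        try:
            parse_site_id(str(sid))
        except ValidationError:
            bad.append(sid)
    if bad:
        logger.warning("dropping %d rows with unparsable site ids", len(bad))
        df = df.drop(index=bad)
    return QuantTable(df.astype(float), meta, log_scale=log_scale)


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    """Write intensities at full precision; round-trips through read exactly."""
    df = table.data.copy()
    df.index.name = "site_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_sample_sheet(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member ... per line."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate set name {name!r}"
                )
            sets[name] = frozenset(m for m in fields[2:] if m)
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_edge_list(path: str | Path) -> EdgeList:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: edge list needs >= 2 columns")
    edges = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    weights = {}
    if df.shape[1] >= 3:
        weights = {
            e: float(w) for e, w in zip(edges, df.iloc[:, 2]) if pd.notna(w)
        }
    return EdgeList(edges, weights)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b in edges.edges:
            w = edges.weights.get((a, b), "")
            fh.write(f"{a}\t{b}\t{w}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def extract_windows(
    sequences: Mapping[str, str] | str | Path,
    sites: Iterable[tuple[str, int]],
    half_width: int,
    allow_noncanonical: bool = False,
) -> list[str]:
    """Cut fixed-length windows centered on each acetylated lysine.

    Every window has exactly ``2*half_width + 1`` residues; positions past a
    protein terminus are padded with ``PAD``.  Positions are 1-based.  The
    central residue must be K unless ``allow_noncanonical`` is set.
    """
    if not isinstance(sequences, Mapping):
        sequences = read_fasta(sequences)
    sites = list(sites)
    missing = sorted({p for p, _ in sites if p not in sequences})
    if missing:
        raise ValidationError(f"proteins missing from FASTA: {missing}")
    windows = []
    for protein_id, pos in sites:
        seq = sequences[protein_id]
        if not 1 <= pos <= len(seq):
            raise ValidationError(
                f"position {pos} outside protein {protein_id!r} (len {len(seq)})"
            )
        center = seq[pos - 1]
        if center != "K" and not allow_noncanonical:
            raise ValidationError(
                f"central residue at {protein_id}_{pos} is {center!r}, not K"
            )
        i0 = pos - 1 - half_width
        chars = [
            seq[i] if 0 <= i < len(seq) else PAD
            for i in range(i0, i0 + 2 * half_width + 1)
        ]
        windows.append("".join(chars))
    return windows
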