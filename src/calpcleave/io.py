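"""Table I/O, decoy-database construction, and synthetic data generation.

Readers and writers for the plain-text formats the package exchanges:
tab-separated cleavage-site tables, generic 20-residue descriptor TSVs,
AAindex1 flat files, FASTA (via Biopython), and multiplexed-intensity
tables.  Also houses the decoy-database construction procedure
(C-terminal proteome tails filtered by shared 4-residue blocks with a
core database), control-peptide scrambling, and the seeded synthetic
library generator that makes every other module testable without any
download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import kinetics as _kinetics
from .descriptors import (
    AMINO_ACIDS,
    STANDARD_COMPOSITION,
    DescriptorTable,
    Peptide,
    SiteWindow,
    enumerate_windows,
    position_labels,
)
from .pls_qsar import PlsFeature, _as_feature, design_matrix

__all__ = [
    "SequenceDb",
    "DecoyResult",
    "SyntheticConfig",
    "read_fasta",
    "write_fasta",
    "read_aaindex",
    "read_descriptor_tsv",
    "write_descriptor_tsv",
    "read_site_table",
    "write_site_table",
    "read_intensity_table",
    "write_intensity_table",
    "build_decoy_db",
    "scramble_peptide",
    "generate_synthetic_library",
]

# AAindex1 lists its 20 values on two lines in this fixed residue order.
_AAINDEX_ORDER = ("A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
                  "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V")


@dataclass
class SequenceDb:
    """A named collection of protein/peptide sequences."""

    entries: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        for sid, seq in self.entries.items():
            bad = set(seq.upper()) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(
                    f"entry {sid!r}: non-canonical residues {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Sequence and descriptor formats
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceDb:
    entries = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in entries:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        entries[rec.id] = str(rec.seq).upper()
    return SequenceDb(entries=entries, provenance=str(path))


def write_fasta(db: SequenceDb, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in db.entries.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_aaindex(path: str | Path) -> dict[str, DescriptorTable]:
    """Parse an AAindex1 flat file into descriptor tables.

    Records are keyed by the ``H`` accession line; the ``I`` block
    carries 20 values on two lines in the canonical
    A/R/N/D/C/Q/E/G/H/I // L/K/M/F/P/S/T/W/Y/V order.  Records with
    ``NA`` values are skipped.
    """
    tables: dict[str, DescriptorTable] = {}
    accession, description, values, in_values = None, "", [], False
    with open(path) as fh:
        for line in fh:
            tag, rest = line[:2], line[2:].strip()
            if tag == "H ":
                accession, description, values = rest, "", []
                in_values = False
            elif tag == "D ":
                description = rest
            elif tag == "I ":
                in_values = True
            elif in_values and tag == "  ":
                values.extend(rest.split())
            elif tag == "//":
                if accession and len(values) == 20 and "NA" not in values:
                    tables[accession] = DescriptorTable(
                        id=accession,
                        values={aa: float(v)
                                for aa, v in zip(_AAINDEX_ORDER, values)},
                        kind="aaindex",
                        description=description,
                    )
                accession, values, in_values = None, [], False
    return tables


def read_descriptor_tsv(path: str | Path, kind: str = "molecular"
                        ) -> dict[str, DescriptorTable]:
    """Generic descriptor TSV: descriptor_id column + 20 residue columns."""
    df = pd.read_csv(path, sep="\t")
    missing = set(AMINO_ACIDS) - set(df.columns)
    if missing:
        raise ValueError(f"descriptor TSV lacks residue columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        tid = str(row["descriptor_id"])
        out[tid] = DescriptorTable(
            id=tid,
            values={a: float(row[a]) for a in AMINO_ACIDS},
            kind=kind,
            description=str(row.get("description", "")),
        )
    return out


def write_descriptor_tsv(tables: Mapping[str, DescriptorTable],
                         path: str | Path) -> None:
    rows = []
    for tid in sorted(tables):
        t = tables[tid]
        row = {"descriptor_id": tid, "description": t.description}
        row.update({a: t.values[a] for a in AMINO_ACIDS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Site and intensity tables
# ---------------------------------------------------------------------------

_SITE_COLUMNS = ["peptide_id", "sequence", "bond_after", "enzyme", "status",
                 "kcat_km", "kcat_km_se"]


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a cleavage-site TSV with strict schema validation.

    Columns: peptide_id, sequence, bond_after (1-based), enzyme
    (C1/C2/both or empty), status (Rp/Nv/Lit/uncleaved or empty),
    optional kcat_km and kcat_km_se.  Malformed rows raise with their
    line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "sequence": str})
    required = {"peptide_id", "sequence", "bond_after"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table lacks columns {sorted(missing)}")
    for i, row in df.iterrows():
        line = i + 2  # header on line 1
        seq = str(row["sequence"])
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"line {line}: non-canonical residues {sorted(bad)}"
            )
        bond = row["bond_after"]
        if not (1 <= int(bond) <= len(seq) - 1):
            raise ValueError(
                f"line {line}: bond_after={bond} outside [1, {len(seq) - 1}]"
            )
        enzyme = row.get("enzyme")
        if isinstance(enzyme, str) and enzyme and enzyme not in ("C1", "C2", "both"):
            raise ValueError(f"line {line}: bad enzyme {enzyme!r}")
        status = row.get("status")
        if (isinstance(status, str) and status
                and status not in ("Rp", "Nv", "Lit", "uncleaved")):
            raise ValueError(f"line {line}: bad status {status!r}")
    return df


def write_site_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _SITE_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_intensity_table(path: str | Path) -> list[_kinetics.IntensityRecord]:
    """Read a long-format intensity TSV: peptide_id, species, channel,
    intensity; one record per (peptide, species)."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide_id", "species", "channel", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"intensity table lacks columns {sorted(missing)}")
    records = []
    for (pid, species), grp in df.groupby(["peptide_id", "species"], sort=True):
        if species not in ("full_length", "fragment"):
            raise ValueError(f"bad species {species!r} for peptide {pid!r}")
        records.append(_kinetics.IntensityRecord(
            peptide_id=str(pid), species=species,
            intensities={int(c): float(v)
                         for c, v in zip(grp["channel"], grp["intensity"])},
        ))
    return records


def write_intensity_table(records: Sequence[_kinetics.IntensityRecord],
                          path: str | Path) -> None:
    rows = []
    for rec in records:
        for ch, v in sorted(rec.intensities.items()):
            rows.append((rec.peptide_id, rec.species, ch, v))
    pd.DataFrame(rows, columns=["peptide_id", "species", "channel",
                                "intensity"]).to_csv(path, sep="\t",
                                                     index=False)


# ---------------------------------------------------------------------------
# Decoy database construction
# ---------------------------------------------------------------------------

@dataclass
class DecoyResult:
    """Decoy sets and the per-stage survivor counts."""

    hs_large: SequenceDb
    hs_small: SequenceDb
    counts: dict[str, int]


def _blocks(seq: str, block: int) -> set[str]:
    return {seq[i:i + block] for i in range(len(seq) - block + 1)}


def build_decoy_db(
    proteome: SequenceDb,
    core: SequenceDb,
    tail_len: int = 20,
    block: int = 4,
    sample_n: int = 4000,
    seed: int = 0,
) -> DecoyResult:
    """C-terminal-tail decoy construction with 4-mer block filtering.

    Stage 1 takes the C-terminal ``tail_len`` residues of every
    proteome entry at least that long.  Stage 2 (the large set) drops
    tails whose reversal shares any contiguous ``block``-length
    substring with any core sequence; stage 3 additionally drops tails
    whose forward sequence shares such a block; stage 4 samples
    ``sample_n`` survivors uniformly without replacement (the small
    set).  Matching is exact and case-insensitive.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    if not proteome.entries:
        raise ValueError("empty proteome")
    core_blocks: set[str] = set()
    for seq in core.entries.values():
        core_blocks |= _blocks(seq.upper(), block)

    tails = {sid: seq[-tail_len:].upper()
             for sid, seq in proteome.entries.items()
             if len(seq) >= tail_len}
    large = {sid: seq for sid, seq in tails.items()
             if not (_blocks(seq[::-1], block) & core_blocks)}
    forward = {sid: seq for sid, seq in large.items()
               if not (_blocks(seq, block) & core_blocks)}
    if sample_n > len(forward):
        raise ValueError(
            f"cannot sample {sample_n} from {len(forward)} surviving entries "
            f"(stages: {len(tails)} -> {len(large)} -> {len(forward)})"
        )
    rng = np.random.default_rng(seed)
    ids = sorted(forward)
    chosen = sorted(rng.choice(len(ids), size=sample_n, replace=False))
    small = {ids[i]: forward[ids[i]] for i in chosen}
    return DecoyResult(
        hs_large=SequenceDb(large, provenance="decoy reverse-filtered tails"),
        hs_small=SequenceDb(small, provenance="decoy sampled tails"),
        counts={
            "tails": len(tails),
            "after_reverse_filter": len(large),
            "after_forward_filter": len(forward),
            "sampled": sample_n,
        },
    )


def scramble_peptide(sequence: str,
                     seed: int | np.random.Generator = 0) -> str:
    """Uniform seeded permutation of a sequence (control peptides)."""
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    idx = rng.permutation(len(sequence))
    return "".join(sequence[i] for i in idx)


# ---------------------------------------------------------------------------
# Synthetic library generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Parameters of the synthetic oligopeptide library.

    Defaults mimic the study library: 87 20-mer peptides drawn from the
    Swiss-Prot background composition.  ``planted_features`` and
    ``planted_coefficients`` define the linear model generating the
    true per-window kcat/Km (M^-1 s^-1); multiplicative log-normal
    noise of coefficient of variation ``noise_cv`` is applied, and the
    binary cleaved label is kcat/Km > ``cleavage_threshold``.
    """

    n_peptides: int = 87
    peptide_length: int = 20
    planted_features: list[PlsFeature] = field(default_factory=list)
    planted_coefficients: list[float] = field(default_factory=list)
    planted_intercept: float = 100.0
    noise_cv: float = 0.1
    cleavage_threshold: float = 100.0
    window_positions: tuple[str, ...] = tuple(position_labels(6))
    seed: int = 0


def generate_synthetic_library(
    config: SyntheticConfig,
    tables: Mapping[str, DescriptorTable],
    with_kinetics: bool = False,
) -> dict[str, object]:
    """Generate a labelled synthetic library, fully seeded.

    Returns a dict with ``peptides``, ``windows`` (complete over
    ``config.window_positions``), ``kcat_km`` (pandas Series of true
    efficiencies, clipped at zero), ``labels`` (0/1 Series), the
    ``design_matrix`` over the planted features, and, when requested,
    per-window simulated ``intensity`` records.
    """
    if len(config.planted_features) != len(config.planted_coefficients):
        raise ValueError("planted features/coefficients length mismatch")
    rng = np.random.default_rng(config.seed)
    residues = list(AMINO_ACIDS)
    probs = np.array([STANDARD_COMPOSITION[a] for a in residues])
    probs = probs / probs.sum()

    peptides = []
    for i in range(config.n_peptides):
        seq = "".join(rng.choice(residues, size=config.peptide_length, p=probs))
        peptides.append(Peptide(id=f"SYN{i + 1:04d}", sequence=seq))

    windows: list[SiteWindow] = []
    for pep in peptides:
        windows.extend(
            enumerate_windows(pep, flank=10,
                              require_complete=config.window_positions)
        )

    feats = [_as_feature(f) for f in config.planted_features]
    kcat = pd.Series(config.planted_intercept, index=[w.id for w in windows],
                     dtype=float)
    if feats:
        dm = design_matrix(windows, feats, tables)
        lin = dm.values.to_numpy() @ np.asarray(config.planted_coefficients)
        kcat = pd.Series(lin + config.planted_intercept,
                         index=[w.id for w in windows])
    else:
        dm = design_matrix(windows, [], tables)
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        kcat = kcat * np.exp(rng.normal(0.0, sigma, size=len(kcat)))
    kcat = kcat.clip(lower=0.0)
    labels = (kcat > config.cleavage_threshold).astype(int)

    out: dict[str, object] = {
        "peptides": peptides,
        "windows": windows,
        "kcat_km": kcat,
        "labels": labels,
        "design_matrix": dm,
    }
    if with_kinetics:
        design = _kinetics.ChannelDesign()
        out["intensity"] = {
            w.id: _kinetics.simulate_digestion(
                float(kcat[w.id]), design, noise_cv=config.noise_cv,
                seed=rng, peptide_id=w.id,
            )
            for w in windows
        }
    return out
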