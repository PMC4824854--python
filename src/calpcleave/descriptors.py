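"""Cleavage-site windows and per-position descriptor featurization.

A protease cleavage event is described by the residues flanking the
scissile bond: P1, P2, ... count N-terminally from the bond and P1',
P2', ... C-terminally (Schechter-Berger nomenclature).  This module
extracts fixed-width P10-P10' windows from peptides or proteins, maps
each occupied position onto numeric amino-acid scales (AAindex entries,
molecular-property tables, or externally supplied secondary-structure
probabilities), and provides the descriptor pre-selection procedures
used upstream of the QSAR models: per-position best-r^2 selection
against measured kcat/Km, and rank-sum ranking of scales against a
per-residue contribution profile.

Positions are labelled ``P10`` ... ``P1`` and ``P1p`` ... ``P10p`` (the
ASCII ``p`` stands for the prime).  Internal ordering is always
N-terminal to C-terminal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AMINO_ACIDS",
    "STANDARD_COMPOSITION",
    "MISSING",
    "Peptide",
    "SiteWindow",
    "DescriptorTable",
    "FeatureMatrix",
    "position_labels",
    "position_offset",
    "build_window",
    "enumerate_windows",
    "featurize",
    "select_best_descriptor_per_position",
    "rank_descriptor_by_r_and_rho",
]

#: The 20 canonical residues, alphabetical by one-letter code.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Background amino-acid composition (proportions) of Swiss-Prot
#: release 2012_9, used to standardize observed frequencies.
STANDARD_COMPOSITION: dict[str, float] = {
    "A": 0.0867, "C": 0.0126, "D": 0.0532, "E": 0.0617, "F": 0.0401,
    "G": 0.0710, "H": 0.0221, "I": 0.0596, "K": 0.0525, "L": 0.0992,
    "M": 0.0246, "N": 0.0409, "P": 0.0471, "Q": 0.0395, "R": 0.0546,
    "S": 0.0666, "T": 0.0557, "V": 0.0677, "W": 0.0130, "Y": 0.0303,
}

#: Sentinel for a window position that falls outside the sequence.
MISSING = None


def position_labels(flank: int = 10) -> list[str]:
    """Return the 2*flank position labels in N->C order.

    >>> position_labels(2)
    ['P2', 'P1', 'P1p', 'P2p']
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    p_side = [f"P{k}" for k in range(flank, 0, -1)]
    pp_side = [f"P{k}p" for k in range(1, flank + 1)]
    return p_side + pp_side


def position_offset(label: str) -> int:
    """0-based offset of a position label relative to the scissile bond.

    For a cleavage after 1-based residue ``i``, the residue at ``label``
    sits at 0-based index ``(i - 1) + position_offset(label)``.
    P1 has offset 0, P2 offset -1, P1p offset +1, and so on.
    """
    if not label.startswith("P"):
        raise ValueError(f"bad position label {label!r}")
    if label.endswith("p"):
        return int(label[1:-1])
    return 1 - int(label[1:])


@dataclass(frozen=True)
class Peptide:
    """A peptide or protein sequence with terminal-modification metadata.

    Terminal modifications (N-acetyl, C-diketopiperazine) mark
    library peptides whose termini are capped; they are carried as
    metadata only and never featurized as residues.
    """

    id: str
    sequence: str
    n_terminal_mod: str = "free"
    c_terminal_mod: str = "free"
    source_protein: str | None = None
    source_offset: int | None = None  # 1-based position in source protein

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError(f"peptide {self.id!r}: sequence shorter than 2")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"peptide {self.id!r}: non-canonical residues {sorted(bad)}"
            )
        if self.n_terminal_mod not in ("free", "acetyl"):
            raise ValueError(f"bad n_terminal_mod {self.n_terminal_mod!r}")
        if self.c_terminal_mod not in ("free", "diketopiperazine"):
            raise ValueError(f"bad c_terminal_mod {self.c_terminal_mod!r}")


@dataclass(frozen=True)
class SiteWindow:
    """A P-flank...P'-flank alignment of one scissile bond.

    ``residues`` maps each position label to a one-letter residue code,
    or to :data:`MISSING` when the position falls outside the sequence.
    ``bond_after`` is the 1-based index of the P1 residue; the bond is
    cleaved between residues ``bond_after`` and ``bond_after + 1``.
    """

    peptide_id: str
    bond_after: int
    residues: Mapping[str, str | None]
    enzyme: str | None = None      # "C1", "C2", or "both"
    status: str | None = None      # "Rp", "Nv", "Lit", or "uncleaved"

    @property
    def id(self) -> str:
        return f"{self.peptide_id}@{self.bond_after}"

    def missing_positions(self) -> list[str]:
        return [lab for lab, res in self.residues.items() if res is MISSING]

    def is_complete(self, positions: Iterable[str]) -> bool:
        """True when every requested position carries a residue."""
        return all(self.residues.get(lab) is not MISSING for lab in positions)


@dataclass(frozen=True)
class DescriptorTable:
    """One named amino-acid scale: residue -> real value.

    ``kind`` distinguishes residue-keyed scales (``aaindex``,
    ``molecular``) from ``secondary_structure`` descriptors, whose
    values are per-position probabilities supplied alongside each
    window rather than looked up by residue identity.
    """

    id: str
    values: Mapping[str, float]
    kind: str = "aaindex"
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("aaindex", "molecular", "secondary_structure"):
            raise ValueError(f"bad descriptor kind {self.kind!r}")
        if self.kind != "secondary_structure":
            if set(self.values) != set(AMINO_ACIDS):
                raise ValueError(
                    f"descriptor {self.id!r}: must provide exactly the 20 "
                    "canonical residues"
                )

    @property
    def residue_keyed(self) -> bool:
        return self.kind != "secondary_structure"

    def mean(self) -> float:
        """Unweighted mean over the 20 residues (residue-keyed only)."""
        return float(np.mean([self.values[a] for a in AMINO_ACIDS]))


@dataclass
class FeatureMatrix:
    """Windows x (position, descriptor) feature values.

    ``values`` has the window ids as index and a two-level column index
    ``(position, descriptor_id)``; a cell is NaN exactly when the
    window's residue at that position is missing and the descriptor is
    residue-keyed.  ``labels`` (binary cleaved/uncleaved) and
    ``response`` (kcat/Km, M^-1 s^-1) are optional row annotations.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None
    response: pd.Series | None = None

    def complete_rows(self) -> "FeatureMatrix":
        """Restrict to rows without any missing cell."""
        keep = ~self.values.isna().any(axis=1)
        return FeatureMatrix(
            values=self.values.loc[keep],
            labels=None if self.labels is None else self.labels.loc[keep],
            response=None if self.response is None else self.response.loc[keep],
        )


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------

def build_window(
    peptide: Peptide,
    bond_after: int,
    flank: int = 10,
    enzyme: str | None = None,
    status: str | None = None,
) -> SiteWindow:
    """Align a P-flank...P'-flank window on one scissile bond.

    ``bond_after`` is 1-based: the bond between residues ``bond_after``
    and ``bond_after + 1`` is the cleaved one, so valid values run from
    1 to ``len(sequence) - 1``.  Positions that fall outside the
    sequence are set to :data:`MISSING`.
    """
    n = len(peptide.sequence)
    if not 1 <= bond_after <= n - 1:
        raise ValueError(
            f"no scissile bond after residue {bond_after} in "
            f"{peptide.id!r} (length {n})"
        )
    residues: dict[str, str | None] = {}
    for lab in position_labels(flank):
        idx = (bond_after - 1) + position_offset(lab)
        residues[lab] = peptide.sequence[idx] if 0 <= idx < n else MISSING
    return SiteWindow(
        peptide_id=peptide.id,
        bond_after=bond_after,
        residues=residues,
        enzyme=enzyme,
        status=status,
    )


def enumerate_windows(
    peptide: Peptide,
    flank: int = 10,
    require_complete: Sequence[str] | None = None,
) -> list[SiteWindow]:
    """One window per internal peptide bond, in N->C order.

    A length-L sequence yields L-1 windows.  When ``require_complete``
    is given (a list of position labels), only windows with a residue
    at every listed position are returned -- e.g. requiring P6-P6'
    keeps 9 of the 19 bonds of a 20-mer.
    """
    out = []
    for bond in range(1, len(peptide.sequence)):
        w = build_window(peptide, bond, flank)
        if require_complete is not None and not w.is_complete(require_complete):
            continue
        out.append(w)
    return out


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

SsInput = Mapping[str, Mapping[tuple[str, str], float]]


def featurize(
    windows: Sequence[SiteWindow],
    tables: Sequence[DescriptorTable],
    positions: Sequence[str],
    ss: SsInput | None = None,
    labels: Mapping[str, int] | pd.Series | None = None,
    response: Mapping[str, float] | pd.Series | None = None,
) -> FeatureMatrix:
    """Look up descriptor values per window position.

    Residue-keyed descriptors are looked up by residue identity;
    secondary-structure descriptors take their value from ``ss``, a
    mapping ``table_id -> {(window_id, position): probability}``.
    Missing window positions propagate as NaN for residue-keyed
    descriptors.  Column order is deterministic: positions in the given
    (N->C) order, descriptor ids lexicographic within each position.

    Optional ``labels``/``response`` are aligned to the window ids.
    """
    table_ids = sorted(t.id for t in tables)
    if len(table_ids) != len(set(table_ids)):
        raise ValueError("duplicate descriptor ids")
    by_id = {t.id: t for t in tables}
    columns = pd.MultiIndex.from_tuples(
        [(pos, tid) for pos in positions for tid in table_ids],
        names=["position", "descriptor"],
    )
    index = [w.id for w in windows]
    data = np.empty((len(windows), len(columns)))
    for i, w in enumerate(windows):
        j = 0
        for pos in positions:
            res = w.residues.get(pos, MISSING)
            for tid in table_ids:
                table = by_id[tid]
                if table.residue_keyed:
                    if res is MISSING:
                        data[i, j] = np.nan
                    else:
                        try:
                            data[i, j] = table.values[res]
                        except KeyError:
                            raise ValueError(
                                f"unknown residue {res!r} at {pos} of "
                                f"window {w.id}"
                            ) from None
                else:
                    if ss is None or (w.id, pos) not in ss.get(tid, {}):
                        raise ValueError(
                            f"secondary-structure descriptor {tid!r} needs a "
                            f"per-window probability for window {w.id} at {pos}"
                        )
                    data[i, j] = ss[tid][(w.id, pos)]
                j += 1
    values = pd.DataFrame(data, index=index, columns=columns)
    lab = None if labels is None else pd.Series(labels).reindex(index)
    resp = None if response is None else pd.Series(response).reindex(index)
    return FeatureMatrix(values=values, labels=lab, response=resp)


# ---------------------------------------------------------------------------
# Descriptor pre-selection
# ---------------------------------------------------------------------------

def select_best_descriptor_per_position(
    matrix: FeatureMatrix,
    response: Sequence[float] | pd.Series | None = None,
    min_pairs: int = 3,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Pick, per position, the descriptor most r^2-correlated with kcat/Km.

    For every candidate (position, descriptor) column the squared
    Pearson correlation with the response is computed over the rows
    where both are present; the descriptor with the largest r^2 wins at
    each position, ties broken lexicographically by descriptor id.
    Zero-variance columns are excluded with a warning.

    Returns ``(mapping position -> descriptor id, score table)`` where
    the score table has columns ``position, descriptor, r2, n``.
    """
    if response is None:
        response = matrix.response
    if response is None:
        raise ValueError("a kcat/Km response is required")
    if isinstance(response, pd.Series) or isinstance(response, Mapping):
        y = pd.Series(response).reindex(matrix.values.index).astype(float)
    else:
        y = pd.Series(np.asarray(response, dtype=float),
                      index=matrix.values.index)

    rows = []
    for (pos, tid) in matrix.values.columns:
        x = matrix.values[(pos, tid)].astype(float)
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < min_pairs:
            continue
        xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
        if np.ptp(xv) == 0:
            warnings.warn(
                f"descriptor {tid!r} at {pos} has zero variance; excluded",
                stacklevel=2,
            )
            continue
        if np.ptp(yv) == 0:
            r2 = 0.0
        else:
            r2 = float(stats.pearsonr(xv, yv)[0] ** 2)
        rows.append({"position": pos, "descriptor": tid, "r2": r2, "n": n})
    scores = pd.DataFrame(rows, columns=["position", "descriptor", "r2", "n"])
    best: dict[str, str] = {}
    for pos, grp in scores.groupby("position", sort=False):
        grp = grp.sort_values(["r2", "descriptor"], ascending=[False, True])
        best[pos] = grp.iloc[0]["descriptor"]
    return best, scores


def rank_descriptor_by_r_and_rho(
    per_aar_scores: Mapping[str, float],
    tables: Sequence[DescriptorTable],
) -> pd.DataFrame:
    """Rank scales against a 20-residue score profile by r + rho rank sum.

    Pearson r and Spearman rho are computed between the profile and
    each residue-keyed table over the 20 residues; tables are ranked
    independently for r and for rho (descending), and the sum of the
    two ranks is ranked again (ascending; ties broken by descriptor
    id).  Constant tables are assigned the worst rank.

    Returns a DataFrame sorted best-first with columns
    ``descriptor, r, rho, rank_r, rank_rho, rank_sum``.
    """
    if set(per_aar_scores) != set(AMINO_ACIDS):
        raise ValueError("per_aar_scores must cover exactly the 20 residues")
    y = np.array([per_aar_scores[a] for a in AMINO_ACIDS], dtype=float)
    ids, rs, rhos = [], [], []
    for t in tables:
        if not t.residue_keyed:
            continue
        x = np.array([t.values[a] for a in AMINO_ACIDS], dtype=float)
        ids.append(t.id)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rs.append(np.nan)
            rhos.append(np.nan)
        else:
            rs.append(float(stats.pearsonr(x, y)[0]))
            rhos.append(float(stats.spearmanr(x, y)[0]))
    df = pd.DataFrame({"descriptor": ids, "r": rs, "rho": rhos})
    worst = len(df)
    # descending rank on the statistic; NaN (constant table) -> worst
    df["rank_r"] = (-df["r"]).rank(method="average", na_option="bottom")
    df["rank_rho"] = (-df["rho"]).rank(method="average", na_option="bottom")
    df.loc[df["r"].isna(), ["rank_r", "rank_rho"]] = worst
    df["rank_sum"] = df["rank_r"] + df["rank_rho"]
    df = df.sort_values(["rank_sum", "descriptor"]).reset_index(drop=True)
    return df
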