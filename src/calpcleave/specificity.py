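"""Descriptive and inferential statistics on cleavage-site sets.

Covers the specificity analyses surrounding the QSAR models:
standardized log-ratio frequency profiles (sequence-logo input),
profile correlations with the t-test for a correlation coefficient,
pooled two-proportion and one-proportion Z-tests, the binomial
probability of a residue's complete absence, Welch's unequal-variance
t-test, paired kcat/Km correlation between the two enzymes, and the
cleavage-position bias analysis against the uniform-cleavage null.

No multiple-testing correction is applied by default; a Bonferroni
helper is provided for callers who want one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import AMINO_ACIDS, MISSING, DescriptorTable, SiteWindow

__all__ = [
    "FrequencyProfile",
    "frequency_profile",
    "profile_correlation",
    "two_proportion_z",
    "one_proportion_z",
    "absent_residue_binomial",
    "welch_t_test",
    "kcat_correlation",
    "cleavage_position_bias",
    "descriptor_contrast",
    "bonferroni",
]


@dataclass
class FrequencyProfile:
    """Position x residue counts with background-standardized log-ratios.

    ``log_ratio`` is log10(observed proportion / background proportion);
    a residue absent at a position carries the -inf sentinel (drawn
    "not to scale" in logos, excluded pairwise from correlations).
    """

    counts: pd.DataFrame            # positions x 20 residues, ints
    n_per_position: pd.Series
    standard_composition: dict[str, float]
    proportions: pd.DataFrame
    log_ratio: pd.DataFrame

    def to_logo_table(self, floor: float | None = None) -> pd.DataFrame:
        """Long-format export (position, residue, count, proportion, r)
        for logo-rendering tools; -inf optionally floored for display."""
        rows = []
        for pos in self.counts.index:
            for res in AMINO_ACIDS:
                r = self.log_ratio.loc[pos, res]
                if floor is not None and np.isneginf(r):
                    r = floor
                rows.append((pos, res, int(self.counts.loc[pos, res]),
                             self.proportions.loc[pos, res], r))
        return pd.DataFrame(
            rows, columns=["position", "residue", "count", "proportion", "r"]
        )


def frequency_profile(
    windows: Sequence[SiteWindow],
    standard_composition: Mapping[str, float],
    positions: Sequence[str] | None = None,
) -> FrequencyProfile:
    """Tally residues per position and standardize by the background.

    Missing positions are excluded from that position's denominator, so
    per-position totals differ near sequence termini.
    """
    if not windows:
        raise ValueError("empty window set")
    if positions is None:
        positions = list(windows[0].residues)
    comp = {a: standard_composition[a] for a in AMINO_ACIDS}
    total = sum(comp.values())
    comp = {a: v / total for a, v in comp.items()}

    counts = pd.DataFrame(0, index=list(positions), columns=list(AMINO_ACIDS))
    for w in windows:
        for pos in positions:
            res = w.residues.get(pos, MISSING)
            if res is not MISSING:
                counts.loc[pos, res] += 1
    n_per = counts.sum(axis=1)
    if (n_per == 0).any():
        raise ValueError("a position has no observed residues")
    props = counts.div(n_per, axis=0)
    with np.errstate(divide="ignore"):
        log_ratio = np.log10(props / pd.Series(comp))
    return FrequencyProfile(
        counts=counts,
        n_per_position=n_per,
        standard_composition=comp,
        proportions=props,
        log_ratio=log_ratio,
    )


def profile_correlation(
    profile_a: FrequencyProfile, profile_b: FrequencyProfile
) -> dict[str, float]:
    """Pearson correlation of two log-ratio profiles over shared cells.

    Cells at -inf in either profile (residue absent) are excluded
    pairwise and counted.  The p-value comes from the t-test for a
    correlation coefficient, t = r sqrt((n-2)/(1-r^2)) on n-2 df.
    """
    a = profile_a.log_ratio
    b = profile_b.log_ratio.reindex(index=a.index, columns=a.columns)
    av, bv = a.to_numpy().ravel(), b.to_numpy().ravel()
    ok = np.isfinite(av) & np.isfinite(bv)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("fewer than 3 shared finite cells")
    r = float(stats.pearsonr(av[ok], bv[ok])[0])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return {"r": r, "p": p, "n": n, "n_excluded": int((~ok).sum())}


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> dict[str, float]:
    """Pooled-variance Z-test for the equality of two proportions.

    Two-sided normal p-value; antisymmetric under swapping the two
    samples.  No continuity correction.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return {"z": 0.0, "p": 1.0}
    z = (p1 - p2) / np.sqrt(var)
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}


def one_proportion_z(x: int, n: int, p0: float) -> dict[str, float]:
    """Z-test of an observed proportion against a null value p0.

    Z = (x/n - p0) / sqrt(p0 (1 - p0) / n), two-sided p.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be strictly between 0 and 1")
    z = (x / n - p0) / np.sqrt(p0 * (1 - p0) / n)
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}


def absent_residue_binomial(n_sites: int, expected_p: float) -> float:
    """Probability of a residue never occurring in n_sites draws.

    P(zero occurrences) = (1 - expected_p)^n_sites, the binomial
    point probability at zero.
    """
    if not 0 < expected_p < 1:
        raise ValueError("expected_p must be strictly between 0 and 1")
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    return float((1.0 - expected_p) ** n_sites)


def welch_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> dict[str, float]:
    """Welch's t-test (unknown, unequal variances), Satterthwaite df."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df),
            "p": float(res.pvalue)}


def kcat_correlation(
    estimates_a: Mapping[str, float], estimates_b: Mapping[str, float]
) -> dict[str, object]:
    """Pearson r over sites measured for both enzymes.

    Returns the correlation and the paired table actually used.
    """
    shared = sorted(set(estimates_a) & set(estimates_b))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared sites")
    table = pd.DataFrame({
        "site": shared,
        "a": [estimates_a[s] for s in shared],
        "b": [estimates_b[s] for s in shared],
    }).set_index("site")
    r = float(stats.pearsonr(table["a"], table["b"])[0])
    return {"r": r, "n": len(shared), "table": table}


def cleavage_position_bias(
    bond_positions: Sequence[int],
    peptide_length: int = 20,
) -> pd.DataFrame:
    """Per-bond cleavage frequency against the uniform-cleavage null.

    Under random cleavage every one of the L-1 bonds of an L-mer is
    equally likely (expected proportion 1/(L-1), about 5% for 20-mers).
    Returns one row per bond with the observed count and proportion and
    the one-proportion Z statistic and p-value.
    """
    bonds = np.asarray(bond_positions, dtype=int)
    if bonds.size == 0:
        raise ValueError("no cleavage positions supplied")
    n_bonds = peptide_length - 1
    if np.any((bonds < 1) | (bonds > n_bonds)):
        raise ValueError("bond position outside [1, L-1]")
    n = len(bonds)
    p0 = 1.0 / n_bonds
    rows = []
    for bond in range(1, n_bonds + 1):
        x = int(np.sum(bonds == bond))
        zt = one_proportion_z(x, n, p0)
        rows.append((bond, x, x / n, p0, zt["z"], zt["p"]))
    return pd.DataFrame(
        rows, columns=["bond_after", "count", "proportion", "expected",
                       "z", "p"]
    )


def descriptor_contrast(
    windows_a: Sequence[SiteWindow],
    windows_b: Sequence[SiteWindow],
    table: DescriptorTable,
    position: str,
) -> dict[str, float]:
    """Welch contrast of a descriptor's values at one position.

    Compares the distribution of the scale's values over the residues
    observed at ``position`` in two site sets -- a generic way to ask
    whether two enzymes prefer, say, larger residues at P8.
    """
    def vals(windows):
        out = []
        for w in windows:
            res = w.residues.get(position, MISSING)
            if res is not MISSING:
                out.append(table.values[res])
        return out

    a, b = vals(windows_a), vals(windows_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("fewer than 2 observed residues in a group")
    result = welch_t_test(a, b)
    result.update({
        "mean_a": float(np.mean(a)), "mean_b": float(np.mean(b)),
        "n_a": len(a), "n_b": len(b),
    })
    return result


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values (off by default everywhere)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
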