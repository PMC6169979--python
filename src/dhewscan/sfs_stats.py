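"""Per-gene polymorphism statistics.

Computes Watterson's theta, nucleotide diversity pi, Tajima's D, the
normalised Fay & Wu H (Zeng et al. 2006 parameterisation via theta_L) and
the Ewens-Watterson haplotype homozygosity F for one gene alignment, with
outgroup polarization by strict parsimony (no reverse or convergent
mutation assumed).

Scale conventions
-----------------
pi and theta_w are reported per gene (summed over sites), not per site.
Statistics that are undefined for a gene (S = 0, or no polarizable site)
are returned as ``nan`` — never silently as 0.

Only complete-case columns enter any statistic: a column carrying an N or
a gap in any retained in-group sample is excluded from S, pi, theta_w, H
and haplotype construction, so the sample size n is constant across sites.
Multiallelic segregating sites contribute to S and pi but are excluded
from polarization (parsimony is ambiguous there).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import Alignment, GAP, N

__all__ = [
    "SiteColumn",
    "PolymorphismSummary",
    "segregating_sites",
    "watterson_theta",
    "tajimas_d",
    "tajimas_d_from_parts",
    "polarize_derived",
    "fay_wu_h_normalized",
    "fay_wu_h_from_counts",
    "ew_homozygosity",
    "summarize_alignment",
]


@dataclass
class SiteColumn:
    """Allele counts of the in-group at one alignment column."""

    position: int
    alleles: dict[int, int]  # base code -> count
    n_called: int


@dataclass
class PolymorphismSummary:
    gene_id: str
    n: int
    S: int
    pi: float
    theta_w: float
    derived_counts: list[int] = field(default_factory=list)
    n_unpolarized: int = 0
    hap_freqs: list[float] = field(default_factory=list)
    F_ew: float = float("nan")


def _complete_columns(aln: Alignment) -> np.ndarray:
    """Boolean mask of columns free of N/gaps and not otherwise excluded."""
    missing = (aln.matrix == N) | (aln.matrix == GAP)
    return ~missing.any(axis=0) & ~aln.excluded_columns


def segregating_sites(aln: Alignment) -> list[SiteColumn]:
    """Variable complete-case columns among the in-group samples.

    A column with missing data in any retained sample is never counted as
    segregating.  Multiallelic columns are included.
    """
    ok = _complete_columns(aln)
    m = aln.matrix
    variable = ok & (m != m[0]).any(axis=0)
    out = []
    for pos in np.flatnonzero(variable):
        col = m[:, pos]
        bases, counts = np.unique(col, return_counts=True)
        out.append(
            SiteColumn(int(pos), dict(zip(map(int, bases), map(int, counts))), int(col.size))
        )
    return out


def _harmonic(n: int) -> tuple[float, float]:
    """a1 = sum 1/i, a2 = sum 1/i^2 for i in 1..n-1."""
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator S/a1, on the per-gene scale."""
    if n < 2:
        raise ValueError("Watterson's theta requires n >= 2")
    if S == 0:
        return 0.0
    a1, _ = _harmonic(n)
    return S / a1


def _pi_from_sites(sites: list[SiteColumn], n: int) -> float:
    """Mean pairwise differences summed over sites (handles multiallelics)."""
    total = 0.0
    for site in sites:
        sq = sum(c * c for c in site.alleles.values())
        total += (n * n - sq) / (n * (n - 1))
    return total


def tajimas_d_from_parts(pi: float, S: int, n: int) -> float:
    """Tajima's D from (pi, S, n) using the 1989 constants; nan if S = 0."""
    if S == 0:
        return float("nan")
    a1, a2 = _harmonic(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi - S / a1) / math.sqrt(var)


def tajimas_d(summary: PolymorphismSummary) -> float:
    return tajimas_d_from_parts(summary.pi, summary.S, summary.n)


def polarize_derived(
    aln: Alignment, outgroup_names: list[str]
) -> tuple[list[int], int]:
    """Derived-allele counts by strict parsimony against the outgroup(s).

    For each biallelic segregating site the ancestral state is the
    outgroup base iff every named outgroup carries the same, unambiguous
    base and that base is one of the two in-group alleles.  Sites failing
    any condition (including multiallelic sites) count as unpolarized.

    Returns ``(derived_counts, n_unpolarized)``.
    """
    for name in outgroup_names:
        if name not in aln.outgroups:
            raise KeyError(f"outgroup {name!r} not attached to {aln.gene_id}")
    if not outgroup_names:
        raise ValueError("at least one outgroup required for polarization")
    derived, unpolarized = [], 0
    for site in segregating_sites(aln):
        out_bases = {int(aln.outgroups[o][site.position]) for o in outgroup_names}
        if len(site.alleles) != 2:
            unpolarized += 1
            continue
        if len(out_bases) != 1:
            unpolarized += 1
            continue
        anc = next(iter(out_bases))
        if anc not in site.alleles:  # includes N/gap in the outgroup
            unpolarized += 1
            continue
        derived.append(site.n_called - site.alleles[anc])
    return derived, unpolarized


def fay_wu_h_from_counts(derived_counts: list[int], n: int) -> float:
    """Normalised Fay & Wu H from derived-allele counts.

    Uses theta_L = sum(i * xi_i) / (n - 1) and the Zeng et al. (2006)
    variance with theta estimated by Watterson's theta and theta^2 by
    S(S-1)/(a1^2 + a2).  Negative values indicate an excess of
    high-frequency derived alleles (the sweep signature); nan when no
    polarizable site exists.
    """
    S = len(derived_counts)
    if S == 0 or n < 2:
        return float("nan")
    counts = np.asarray(derived_counts, dtype=float)
    pi = float(np.sum(2.0 * counts * (n - counts) / (n * (n - 1))))
    theta_l = float(np.sum(counts)) / (n - 1)
    a1, a2 = _harmonic(n)
    bn1 = a2 + 1.0 / n**2  # sum_{i=1}^{n} 1/i^2
    theta_w = S / a1
    theta_sq = S * (S - 1) / (a1**2 + a2)
    var = theta_w * (n - 2) / (6.0 * (n - 1)) + theta_sq * (
        18.0 * n * n * (3 * n + 2) * bn1 - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
    ) / (9.0 * n * (n - 1) ** 2)
    if var <= 0:
        return float("nan")
    return (pi - theta_l) / math.sqrt(var)


def fay_wu_h_normalized(summary: PolymorphismSummary) -> float:
    return fay_wu_h_from_counts(summary.derived_counts, summary.n)


def _haplotype_counts(aln: Alignment) -> np.ndarray:
    """Counts of distinct haplotypes over segregating complete-case columns."""
    ok = _complete_columns(aln)
    m = aln.matrix
    variable = ok & (m != m[0]).any(axis=0)
    if not variable.any():
        return np.array([aln.n_samples])
    sub = np.ascontiguousarray(m[:, variable])
    _, counts = np.unique(sub, axis=0, return_counts=True)
    return counts


def ew_homozygosity(aln: Alignment) -> float:
    """Haplotype homozygosity F = sum of squared haplotype frequencies.

    Haplotypes are built over segregating, non-excluded columns only;
    invariant columns cannot change homozygosity.
    """
    counts = _haplotype_counts(aln)
    freqs = counts / counts.sum()
    return float(np.sum(freqs**2))


def summarize_alignment(
    aln: Alignment, outgroup_names: list[str] | None = None
) -> PolymorphismSummary:
    """Full per-gene polymorphism summary.

    Polarization runs only when ``outgroup_names`` is given; otherwise
    ``derived_counts`` stays empty and nFWH will be nan.
    """
    n = aln.n_samples
    sites = segregating_sites(aln)
    S = len(sites)
    pi = _pi_from_sites(sites, n)
    theta = watterson_theta(S, n) if n >= 2 else float("nan")
    derived: list[int] = []
    n_unpol = 0
    if outgroup_names:
        derived, n_unpol = polarize_derived(aln, outgroup_names)
    hap_counts = _haplotype_counts(aln)
    freqs = (hap_counts / hap_counts.sum()).tolist()
    return PolymorphismSummary(
        gene_id=aln.gene_id,
        n=n,
        S=S,
        pi=pi,
        theta_w=theta,
        derived_counts=derived,
        n_unpolarized=n_unpol,
        hap_freqs=freqs,
        F_ew=float(np.sum((hap_counts / hap_counts.sum()) ** 2)),
    )
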