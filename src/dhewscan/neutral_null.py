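"""Neutral coalescent nulls and the DHEW compound test.

Simulates the standard (no-recombination) Kingman coalescent, places a
fixed number of mutations S on the genealogy with probability proportional
to branch length (fixed-S conditioning, the standard practice for the D /
H / Ewens-Watterson test family), and computes the joint null distribution
of (Tajima's D, normalised Fay & Wu H, haplotype homozygosity F).  The
root state is ancestral, so every simulated mutation is perfectly
polarized.

Observed statistics are converted to one-sided Monte-Carlo p-values with a
+1 pseudocount.  Sweep-signal tails: lower for D and H (very negative),
upper for F (high homozygosity).

The DHEW compound test scores the observed p-vector (p_D, p_H, p_F)
against the p-vectors of the null replicates themselves (each computed
against the leave-one-out null): the compound p is the pseudocounted
fraction of replicates whose p-vector is component-wise <= the observed
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sfs_stats import fay_wu_h_from_counts, tajimas_d_from_parts

__all__ = [
    "StatVector",
    "NullDistribution",
    "sample_genealogy",
    "simulate_neutral",
    "simulate_neutral_theta",
    "pvalue_from_null",
    "gene_pvalues",
    "dhew_compound",
    "get_null",
    "clear_null_cache",
]


@dataclass(frozen=True)
class StatVector:
    D: float
    H_norm: float
    F_ew: float


@dataclass
class NullDistribution:
    """Joint neutral null of (D, H_norm, F_ew) at fixed (n, S)."""

    n: int
    S_cond: int
    reps: int
    seed: int
    D: np.ndarray
    H: np.ndarray
    F: np.ndarray
    _null_pvecs: np.ndarray | None = field(default=None, repr=False)
    _dom_counts: np.ndarray | None = field(default=None, repr=False)

    def draws(self) -> list[StatVector]:
        return [StatVector(float(d), float(h), float(f)) for d, h, f in zip(self.D, self.H, self.F)]

    def replicate_pvalues(self) -> np.ndarray:
        """(reps, 3) leave-one-out p-vectors (p_D, p_H, p_F) of the null draws.

        For replicate j, p_D(j) = (1 + #{k != j: D_k <= D_j}) / reps, which
        equals rank_<= / reps; analogously upper-tailed for F.  Cached.
        """
        if self._null_pvecs is None:
            pvecs = np.empty((self.reps, 3))
            pvecs[:, 0] = _loo_lower(self.D)
            pvecs[:, 1] = _loo_lower(self.H)
            pvecs[:, 2] = _loo_upper(self.F)
            self._null_pvecs = pvecs
        return self._null_pvecs

    def dominance_counts(self) -> np.ndarray:
        """Null distribution of the DHEW dominance statistic.

        For each replicate j, the number of other replicates whose
        p-vector is component-wise <= replicate j's p-vector.  Computed in
        chunks (O(reps^2) comparisons) and cached.
        """
        if self._dom_counts is None:
            pvecs = self.replicate_pvalues()
            counts = np.empty(self.reps, dtype=np.int64)
            chunk = max(1, 2_000_000 // max(self.reps, 1))
            for start in range(0, self.reps, chunk):
                block = pvecs[start : start + chunk]
                dom = np.all(pvecs[None, :, :] <= block[:, None, :], axis=2)
                counts[start : start + chunk] = dom.sum(axis=1) - 1  # exclude self
            self._dom_counts = np.sort(counts)
        return self._dom_counts


def _loo_lower(x: np.ndarray) -> np.ndarray:
    s = np.sort(x)
    return np.searchsorted(s, x, side="right") / x.size


def _loo_upper(x: np.ndarray) -> np.ndarray:
    s = np.sort(x)
    return (x.size - np.searchsorted(s, x, side="left")) / x.size


# ---------------------------------------------------------------------------
# Genealogy sampling
# ---------------------------------------------------------------------------

def sample_genealogy(
    n: int,
    rng: np.random.Generator,
    sweep_fraction: float = 0.0,
    sweep_time: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a Kingman genealogy for ``n`` lineages.

    Returns ``(member, lengths)`` where ``member`` is a boolean matrix with
    one row per branch (the root branch is excluded) marking the leaves
    each branch subtends, and ``lengths`` the branch lengths in coalescent
    units (time scaled so k lineages coalesce at rate k(k-1)/2).

    With ``sweep_fraction`` f > 0, a fraction f of the lineages is forced
    to merge into a single ancestor at time ``sweep_time`` (star-like
    partial coalescence, the hard-sweep caricature); the remaining history
    is standard Kingman.  No coalescence is allowed before ``sweep_time``
    in that mode, which is the intended approximation for sweep_time << 1.
    """
    if n < 2:
        raise ValueError("need at least two lineages")
    m_forced = int(round(sweep_fraction * n)) if sweep_fraction > 0 else 0
    max_nodes = 2 * n  # n leaves + at most n internal nodes
    member = np.zeros((max_nodes, n), dtype=bool)
    member[np.arange(n), np.arange(n)] = True
    birth = np.zeros(max_nodes)
    death = np.zeros(max_nodes)
    active = list(range(n))
    nxt = n
    t = 0.0

    if m_forced >= 2:
        t = sweep_time
        picked = rng.choice(n, size=m_forced, replace=False)
        member[nxt] = member[picked].any(axis=0)
        birth[nxt] = t
        for p in picked:
            death[p] = t
        active = [i for i in active if i not in set(picked.tolist())]
        active.append(nxt)
        nxt += 1

    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        member[nxt] = member[a] | member[b]
        birth[nxt] = t
        death[a] = death[b] = t
        active = [x for idx, x in enumerate(active) if idx not in (i, j)]
        active.append(nxt)
        nxt += 1

    root = active[0]
    idx = np.array([v for v in range(nxt) if v != root])
    return member[idx], (death - birth)[idx]


def _stats_from_counts(counts: np.ndarray, n: int, S: int) -> tuple[float, float]:
    """(D, H_norm) from the derived-allele counts of S polarized sites."""
    counts = counts.astype(float)
    pi = float(np.sum(2.0 * counts * (n - counts) / (n * (n - 1))))
    D = tajimas_d_from_parts(pi, S, n)
    H = fay_wu_h_from_counts(counts.astype(int).tolist(), n)
    return D, H


def _f_ew_from_branches(member: np.ndarray, branch_idx: np.ndarray, n: int) -> float:
    mutated = np.unique(branch_idx)
    if mutated.size == 0:
        return 1.0
    hap = np.ascontiguousarray(member[mutated].T)  # (n, m) bool
    _, counts = np.unique(hap, axis=0, return_counts=True)
    freqs = counts / n
    return float(np.sum(freqs**2))


def simulate_neutral(n: int, S_cond: int, reps: int, seed: int) -> NullDistribution:
    """Null distribution of (D, H_norm, F_ew) at fixed (n, S).

    Each replicate draws a genealogy and multinomially places exactly
    ``S_cond`` mutations on branches with probability proportional to
    branch length.
    """
    if S_cond < 1:
        raise ValueError("S_cond must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    D = np.empty(reps)
    H = np.empty(reps)
    F = np.empty(reps)
    for r in range(reps):
        member, lengths = sample_genealogy(n, rng)
        probs = lengths / lengths.sum()
        branch_idx = rng.choice(lengths.size, size=S_cond, p=probs)
        counts = member[branch_idx].sum(axis=1)
        D[r], H[r] = _stats_from_counts(counts, n, S_cond)
        F[r] = _f_ew_from_branches(member, branch_idx, n)
    return NullDistribution(n, S_cond, reps, seed, D, H, F)


def simulate_neutral_theta(
    n: int, theta: float, reps: int, seed: int
) -> tuple[np.ndarray, NullDistribution]:
    """Unconditioned variant: mutations ~ Poisson(theta/2 * tree length).

    Returns the realised S per replicate together with the statistics
    (replicates with S = 0 yield nan D/H and F = 1).
    """
    rng = np.random.default_rng(seed)
    S_out = np.empty(reps, dtype=int)
    D = np.empty(reps)
    H = np.empty(reps)
    F = np.empty(reps)
    for r in range(reps):
        member, lengths = sample_genealogy(n, rng)
        total = lengths.sum()
        S = int(rng.poisson(theta / 2.0 * total))
        S_out[r] = S
        if S == 0:
            D[r] = H[r] = float("nan")
            F[r] = 1.0
            continue
        probs = lengths / total
        branch_idx = rng.choice(lengths.size, size=S, p=probs)
        counts = member[branch_idx].sum(axis=1)
        D[r], H[r] = _stats_from_counts(counts, n, S)
        F[r] = _f_ew_from_branches(member, branch_idx, n)
    return S_out, NullDistribution(n, 0, reps, seed, D, H, F)


# ---------------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------------

def pvalue_from_null(obs: float, null_draws: np.ndarray, tail: str) -> float:
    """Pseudocounted one-sided Monte-Carlo p-value.

    p = (1 + #{draws at least as extreme}) / (reps + 1); ``tail`` is
    ``"lower"`` (D, H) or ``"upper"`` (F).  nan observations give nan.
    """
    draws = np.asarray(null_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty null distribution")
    if np.isnan(obs):
        return float("nan")
    if tail == "lower":
        count = int(np.sum(draws <= obs))
    elif tail == "upper":
        count = int(np.sum(draws >= obs))
    else:
        raise ValueError("tail must be 'lower' or 'upper'")
    return (1 + count) / (draws.size + 1)


def dhew_compound(obs: StatVector, null: NullDistribution) -> float:
    """Compound DHEW p-value for one observed (D, H, F) triple.

    Two-stage empirical calibration.  The dominance statistic of a
    p-vector v is the number of null replicates whose own p-vector is
    component-wise <= v (small when v is jointly extreme towards the
    sweep tails).  The compound p-value is the pseudocounted fraction of
    null replicates whose dominance statistic is <= the observed one —
    i.e. the percentile of the joint-extremeness statistic within its own
    null, which makes the compound test calibrated (a raw dominance
    fraction would behave like a product of uniform p-values and reject
    far too often).  nan if any component of the observed triple is
    undefined.
    """
    if any(np.isnan(v) for v in (obs.D, obs.H_norm, obs.F_ew)):
        return float("nan")
    p_obs = np.array(
        [
            pvalue_from_null(obs.D, null.D, "lower"),
            pvalue_from_null(obs.H_norm, null.H, "lower"),
            pvalue_from_null(obs.F_ew, null.F, "upper"),
        ]
    )
    pvecs = null.replicate_pvalues()
    t_obs = int(np.sum(np.all(pvecs <= p_obs, axis=1)))
    t_null = null.dominance_counts()
    count = int(np.searchsorted(t_null, t_obs, side="right"))
    return (1 + count) / (null.reps + 1)


def gene_pvalues(obs: StatVector, null: NullDistribution) -> dict[str, float]:
    """One-sided p-values for D, H, EW plus the DHEW compound p."""
    return {
        "p_D": pvalue_from_null(obs.D, null.D, "lower") if not np.isnan(obs.D) else float("nan"),
        "p_H": pvalue_from_null(obs.H_norm, null.H, "lower")
        if not np.isnan(obs.H_norm)
        else float("nan"),
        "p_EW": pvalue_from_null(obs.F_ew, null.F, "upper")
        if not np.isnan(obs.F_ew)
        else float("nan"),
        "p_DHEW": dhew_compound(obs, null),
    }


# ---------------------------------------------------------------------------
# Null cache (one simulation per (n, S, reps, seed) cell)
# ---------------------------------------------------------------------------

_NULL_CACHE: dict[tuple[int, int, int, int], NullDistribution] = {}


def get_null(n: int, S_cond: int, reps: int = 10_000, seed: int = 0) -> NullDistribution:
    """Cached null distribution; the cell seed is derived from
    (seed, n, S_cond) so results do not depend on gene iteration order."""
    key = (n, S_cond, reps, seed)
    if key not in _NULL_CACHE:
        cell_seed = int(np.random.SeedSequence([seed, n, S_cond]).generate_state(1)[0] % (2**31))
        _NULL_CACHE[key] = simulate_neutral(n, S_cond, reps, cell_seed)
    return _NULL_CACHE[key]


def clear_null_cache() -> None:
    _NULL_CACHE.clear()
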