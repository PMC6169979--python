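"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the defining formulas or by
exhaustive enumeration, deliberately sharing no code with the package:
pairwise Hamming distances for pi, literal harmonic-sum constants for
Tajima's D and the normalised H, Counter-based haplotype homozygosity,
hypergeometric enumeration for Fisher's exact test, and the literal
step-up formula for Benjamini-Hochberg.
"""

from collections import Counter
from math import comb, sqrt


def pairwise_pi(seqs: list[str]) -> float:
    """Mean pairwise Hamming distance over all sample pairs."""
    n = len(seqs)
    total = sum(
        sum(a != b for a, b in zip(seqs[i], seqs[j]))
        for i in range(n)
        for j in range(i + 1, n)
    )
    return total / comb(n, 2)


def segregating_columns(seqs: list[str]) -> list[int]:
    return [k for k in range(len(seqs[0])) if len({s[k] for s in seqs}) > 1]


def tajimas_d_oracle(seqs: list[str]) -> float:
    """Tajima (1989) D from raw sequences (no missing data expected)."""
    n = len(seqs)
    S = len(segregating_columns(seqs))
    if S == 0:
        return float("nan")
    pi = pairwise_pi(seqs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))


def polarize_oracle(seqs: list[str], outgroup_seqs: list[str]) -> list[int]:
    """Derived counts under strict parsimony (biallelic sites only)."""
    counts = []
    n = len(seqs)
    for k in segregating_columns(seqs):
        alleles = Counter(s[k] for s in seqs)
        if len(alleles) != 2:
            continue
        out = {o[k] for o in outgroup_seqs}
        if len(out) != 1:
            continue
        anc = next(iter(out))
        if anc not in alleles:
            continue
        counts.append(n - alleles[anc])
    return counts


def fay_wu_h_oracle(derived_counts: list[int], n: int) -> float:
    """Normalised Fay & Wu H (Zeng et al. 2006) by literal evaluation."""
    S = len(derived_counts)
    if S == 0:
        return float("nan")
    pi = sum(2.0 * i * (n - i) / (n * (n - 1)) for i in derived_counts)
    theta_l = sum(derived_counts) / (n - 1.0)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    bn1 = sum(1.0 / i**2 for i in range(1, n + 1))
    tw = S / a1
    tsq = S * (S - 1.0) / (a1**2 + a2)
    var = tw * (n - 2.0) / (6.0 * (n - 1.0)) + tsq * (
        18.0 * n**2 * (3.0 * n + 2.0) * bn1 - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
    ) / (9.0 * n * (n - 1.0) ** 2)
    return (pi - theta_l) / sqrt(var)


def ew_oracle(seqs: list[str]) -> float:
    """Haplotype homozygosity from segregating columns via Counter."""
    cols = segregating_columns(seqs)
    haps = Counter("".join(s[k] for k in cols) for s in seqs)
    n = len(seqs)
    return sum((c / n) ** 2 for c in haps.values())


def fisher_exact_oracle(dn: int, ds: int, pn: int, ps: int) -> float:
    """Two-sided Fisher's exact p by hypergeometric point-probability
    enumeration over all tables with the observed margins."""
    r1 = dn + ds
    c1 = dn + pn
    n = dn + ds + pn + ps

    def prob(a):
        return comb(r1, a) * comb(n - r1, c1 - a) / comb(n, c1)

    p_obs = prob(dn)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    return sum(prob(a) for a in range(lo, hi + 1) if prob(a) <= p_obs * (1 + 1e-9))


def bh_oracle(pvals: list[float]) -> list[float]:
    """Literal BH step-up: p(i) * m / i with running minimum from the top."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = min(running, 1.0)
    return adj
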