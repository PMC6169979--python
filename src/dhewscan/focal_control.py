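"""Focal-vs-matched-control comparison framework.

Each focal gene is paired with >=3 neighbouring control genes of similar
CDS length (0.5-2x) lying within 60 kb of its start.  For every statistic
the "comparison score" is the focal value minus the median of the control
values.  Group-level departures are tested with a one-sample t-test and a
one-sample Wilcoxon signed-rank test (pseudomedian + CI, as R's
``wilcox.test(conf.int=TRUE)``).  Per-gene extremeness is quantified by
(a) the rank of the true score among all focal scores and (b) its
percentile within a permutation null built by letting control genes act
as pseudo-focals.  Sweep and adaptive-divergence calls combine these with
the neutrality-test p-values.

Orientation: ranks and percentiles are computed so that *more extreme in
the sweep/adaptive direction* means a higher percentile (most negative
for D and H scores, most positive for DoS); percentile 100 is the most
extreme gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GenePairing",
    "ComparisonRecord",
    "validate_controls",
    "comparison_score",
    "group_test",
    "rank_scores",
    "rank_against_null",
    "call_sweep",
    "call_adaptive_divergence",
]


@dataclass
class GenePairing:
    focal_id: str
    control_ids: list[str]
    focal_cds_length: int = 0
    control_cds_lengths: list[int] = field(default_factory=list)
    distances: list[int] = field(default_factory=list)


@dataclass
class ComparisonRecord:
    focal_id: str
    statistic: str
    focal_value: float
    control_values: list[float]
    comparison_score: float
    rank: int | None = None
    percentile: float | None = None
    rank_against_null_percentile: float | None = None


def validate_controls(
    focal: dict,
    candidates: list[dict],
    min_controls: int = 3,
    length_ratio: tuple[float, float] = (0.5, 2.0),
    max_distance: int = 60_000,
) -> GenePairing | None:
    """Keep candidate controls passing the length-ratio and distance rules.

    ``focal`` and each candidate are mappings with keys ``gene_id``,
    ``cds_length`` and ``start``.  Returns ``None`` (focal gene dropped)
    when fewer than ``min_controls`` candidates survive.
    """
    lo, hi = length_ratio
    flen, fstart = focal["cds_length"], focal["start"]
    kept, lens, dists = [], [], []
    for cand in candidates:
        ratio = cand["cds_length"] / flen
        dist = abs(cand["start"] - fstart)
        if lo <= ratio <= hi and dist <= max_distance:
            kept.append(cand["gene_id"])
            lens.append(cand["cds_length"])
            dists.append(dist)
    if len(kept) < min_controls:
        return None
    return GenePairing(focal["gene_id"], kept, flen, lens, dists)


def comparison_score(focal_value: float, control_values) -> float:
    """focal value minus the median of the defined control values.

    nan control values are dropped; if none remain (or the focal value is
    undefined) the score is nan.  Even-count medians average the two
    central values.
    """
    vals = np.asarray([v for v in control_values if not np.isnan(v)], dtype=float)
    if vals.size == 0 or np.isnan(focal_value):
        return float("nan")
    return float(focal_value - np.median(vals))


# ---------------------------------------------------------------------------
# Group-level tests
# ---------------------------------------------------------------------------

def _signrank_cdf(n: int) -> np.ndarray:
    """Exact CDF of the Wilcoxon signed-rank statistic W for sample size n."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for i in range(1, n + 1):
        counts[i:] += counts[:-i].copy()
    probs = counts / 2.0**n
    return np.cumsum(probs)


def _qsignrank(p: float, n: int) -> int:
    """Smallest w with P(W <= w) >= p (exact for n <= 300, else normal)."""
    if n <= 300:
        cdf = _signrank_cdf(n)
        return int(np.searchsorted(cdf, p - 1e-12))
    mean = n * (n + 1) / 4.0
    sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    return max(0, int(math.floor(mean + sd * sps.norm.ppf(p))))


def group_test(scores, conf_level: float = 0.95) -> dict:
    """One-sample tests of mean/pseudomedian comparison score = 0.

    Returns mean, t-based CI and p (``p_t``), the Hodges-Lehmann
    pseudomedian with signed-rank CI and p (``p_wilcoxon``), and ``n``.
    Degenerate inputs (all scores identical) yield nan test results with
    ``degenerate=True``.  Significance is conventionally read as the CI
    excluding 0.
    """
    x = np.asarray([s for s in scores if not np.isnan(s)], dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("group_test needs at least two defined scores")
    out: dict = {"n": int(n), "mean": float(np.mean(x)), "degenerate": False}
    if np.ptp(x) == 0:
        out.update(
            ci_t=(float("nan"), float("nan")),
            p_t=float("nan"),
            pseudomedian=float(x[0]),
            ci_w=(float("nan"), float("nan")),
            p_wilcoxon=float("nan"),
            degenerate=True,
        )
        return out
    res = sps.ttest_1samp(x, 0.0)
    ci = res.confidence_interval(conf_level)
    out["ci_t"] = (float(ci.low), float(ci.high))
    out["p_t"] = float(res.pvalue)

    # Walsh averages (i <= j) for the Hodges-Lehmann estimate and CI
    walsh = np.sort(((x[:, None] + x[None, :]) / 2.0)[np.triu_indices(n)])
    out["pseudomedian"] = float(np.median(walsh))
    alpha = 1.0 - conf_level
    qu = _qsignrank(alpha / 2.0, n)
    if qu == 0:
        qu = 1
    m = n * (n + 1) // 2
    out["ci_w"] = (float(walsh[qu - 1]), float(walsh[m - qu]))
    nonzero = x[x != 0]
    if nonzero.size >= 1 and np.ptp(nonzero) > 0 or nonzero.size > 1:
        out["p_wilcoxon"] = float(sps.wilcoxon(x, alternative="two-sided").pvalue)
    else:
        out["p_wilcoxon"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# Ranks and the permutation null
# ---------------------------------------------------------------------------

def rank_scores(
    scores: dict[str, float], higher_is_extreme: bool = True
) -> dict[str, tuple[int, float]]:
    """Rank comparison scores; the most extreme gene gets percentile 100.

    ``higher_is_extreme=False`` flips the orientation (used for D and H,
    where very negative scores are the sweep signal).  Ties share the
    smaller rank; percentile = rank / count * 100.  nan scores are
    excluded from the ranking.
    """
    items = [(g, v) for g, v in scores.items() if not np.isnan(v)]
    if not items:
        return {}
    vals = np.array([v for _, v in items], dtype=float)
    oriented = vals if higher_is_extreme else -vals
    ranks = sps.rankdata(oriented, method="min").astype(int)
    count = len(items)
    return {
        g: (int(r), 100.0 * r / count) for (g, _), r in zip(items, ranks)
    }


def _pairing_scores(
    values: dict[str, float], pairing: GenePairing
) -> tuple[float, list[float]]:
    """(true score, enumerated pseudo-scores) for one pairing."""
    ctrl = [values.get(c, float("nan")) for c in pairing.control_ids]
    true = comparison_score(values.get(pairing.focal_id, float("nan")), ctrl)
    pseudo = []
    for i, c in enumerate(pairing.control_ids):
        rest = [v for j, v in enumerate(ctrl) if j != i and not np.isnan(v)]
        if len(rest) < 2:
            continue
        pseudo.append(comparison_score(ctrl[i], rest))
    return true, pseudo


def rank_against_null(
    values: dict[str, float],
    pairings: list[GenePairing],
    mode: str = "enumerate",
    n_perm: int = 1000,
    seed: int = 0,
    higher_is_extreme: bool = True,
) -> dict[str, float]:
    """Percentile of each true comparison score within the permutation null.

    The null pools pseudo-scores obtained by letting controls act as
    "focal" genes against the remaining controls of their pairing.  In the
    default ``enumerate`` mode every control takes a turn exactly once
    (≈3-4 pseudo-scores per pairing); ``montecarlo`` draws one random
    control per pairing for each of ``n_perm`` replicates.  Percentiles
    use the extremeness orientation: 100 means more extreme than every
    pooled pseudo-score.
    """
    true_scores: dict[str, float] = {}
    pooled: list[float] = []
    rng = np.random.default_rng(seed)
    for pairing in pairings:
        true, pseudo = _pairing_scores(values, pairing)
        true_scores[pairing.focal_id] = true
        if mode == "enumerate":
            pooled.extend(pseudo)
        elif mode == "montecarlo":
            ctrl = [values.get(c, float("nan")) for c in pairing.control_ids]
            k = len(ctrl)
            for _ in range(n_perm):
                i = int(rng.integers(k))
                rest = [v for j, v in enumerate(ctrl) if j != i and not np.isnan(v)]
                if len(rest) < 2:
                    continue
                pooled.append(comparison_score(ctrl[i], rest))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    pool = np.asarray([p for p in pooled if not np.isnan(p)], dtype=float)
    if pool.size == 0:
        raise ValueError("permutation null is empty")
    if not higher_is_extreme:
        pool = -pool
    pool.sort()
    out = {}
    for gene, true in true_scores.items():
        if np.isnan(true):
            out[gene] = float("nan")
            continue
        t = true if higher_is_extreme else -true
        out[gene] = 100.0 * np.searchsorted(pool, t, side="right") / pool.size
    return out


# ---------------------------------------------------------------------------
# Calling criteria
# ---------------------------------------------------------------------------

def call_sweep(
    p_dhew: float,
    corrected_pvals: dict[str, float],
    rank_percentiles: dict[str, float],
    null_percentiles: dict[str, float],
    alpha: float = 0.05,
    rank_top_pct: float = 10.0,
    null_top_pct: float = 5.0,
) -> bool | None:
    """Three-criterion sweep call for one gene.

    1. the DHEW compound p is significant (< ``alpha``);
    2. corrected p-values are significant for at least two of the
       individual test statistics (D, H, EW);
    3. at least one of the D, H or DoS comparison scores sits in the top
       ``rank_top_pct`` of the rank distribution *and* the top
       ``null_top_pct`` of the rank-against-null distribution (oriented
       percentiles, so "top 10%" means percentile >= 90).

    Returns ``None`` (not callable, distinct from False) when the DHEW
    component is missing.
    """
    if p_dhew is None or np.isnan(p_dhew):
        return None
    c1 = p_dhew < alpha
    avail = [p for p in corrected_pvals.values() if p is not None and not np.isnan(p)]
    c2 = sum(p < alpha for p in avail) >= 2
    c3 = False
    for stat, pct in rank_percentiles.items():
        npct = null_percentiles.get(stat, float("nan"))
        if pct is None or npct is None or np.isnan(pct) or np.isnan(npct):
            continue
        if pct >= 100.0 - rank_top_pct and npct >= 100.0 - null_top_pct:
            c3 = True
            break
    return bool(c1 and c2 and c3)


def call_adaptive_divergence(
    p_fet_corrected: float, dos_value: float, alpha: float = 0.05
) -> bool | None:
    """Adaptive-divergence call: significant corrected MK p AND DoS > 0.

    ``None`` (not callable) when DoS is undefined.
    """
    if dos_value is None or np.isnan(dos_value):
        return None
    if p_fet_corrected is None or np.isnan(p_fet_corrected):
        return None
    return bool(p_fet_corrected < alpha and dos_value > 0)
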