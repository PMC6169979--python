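"""Synthetic study bundles: focal/control CDS alignments with known truth.

The generator emulates the kind of data the screen is designed for:
per-gene in-frame CDS alignments of ~150 population haplotypes (or 14 in
the second-species mode), a single aligned sister-species sequence and an
outgroup, with per-gene theta, missing data, and optionally planted
selection signals:

* **sweeps** — a fraction f of the sampled lineages is forced to coalesce
  at a very recent time tau (star-like partial coalescence), producing the
  hard-sweep signal triad: negative Tajima's D, negative normalised H and
  elevated haplotype homozygosity;
* **adaptive divergence** — extra non-synonymous substitutions planted on
  the focal lineage so that a fraction ``alpha_adaptive`` of its
  non-synonymous fixed differences is adaptive.

Mutations are codon-aware: synonymous changes are always accepted,
non-synonymous changes with probability ``omega`` (purifying selection),
stop-creating changes never.  Because accepted events are i.i.d.
synonymous/non-synonymous draws from the same site distribution for both
polymorphism and divergence, the expected DoS is exactly 0 when no
adaptive substitutions are planted.

Each gene uses at most one event per codon (single-hit codons), which
keeps the planted counts identical to what the MK classifier recovers.
Truth tables are a mandatory output so downstream tests never re-derive
planted signals from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .alignment_io import Alignment, BASES, N, array_to_seq, write_fasta_alignment
from .focal_control import GenePairing
from .mk_dos import CODON_TO_AA
from .neutral_null import sample_genealogy

__all__ = [
    "SimConfig",
    "Bundle",
    "random_cds",
    "generate_neutral_gene",
    "generate_sweep_gene",
    "generate_divergence_gene",
    "generate_study_bundle",
]

SISTER = "sister"
OUTGROUP = "outgroup"
_BASE_STR = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle.

    Defaults mirror the screen's primary design: 149 subsampled lines
    (14 in the second-species mode), 68 focal genes with 3-4 matched
    controls each, CDS lengths 0.3-3 kb, per-gene theta drawn uniformly,
    sister-species divergence of a few coalescent units, ~1% missing
    data, and no planted signal unless asked for.
    """

    n_lines: int = 149
    n_focal: int = 68
    controls_per_focal: tuple[int, int] = (3, 4)
    cds_length_range: tuple[int, int] = (300, 3000)
    theta_per_gene: float | tuple[float, float] | None = None
    theta_site: float = 0.004
    sweep_fraction: float = 0.0
    sweep_intensity: float = 0.9
    sweep_tau: float = 0.005
    divergence_time: float = 6.0
    outgroup_divergence_time: float = 18.0
    omega: float = 0.1
    alpha_adaptive: float = 0.0
    missing_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.sweep_fraction, self.sweep_intensity, self.alpha_adaptive, self.missing_rate):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        lo, hi = self.cds_length_range
        if lo % 3 or hi % 3:
            raise ValueError("cds_length_range bounds must be divisible by 3")

    def draw_theta(self, rng: np.random.Generator, length: int) -> float:
        """Per-gene theta: explicit value/range, or theta_site * length."""
        if self.theta_per_gene is None:
            return self.theta_site * length
        if isinstance(self.theta_per_gene, (int, float)):
            return float(self.theta_per_gene)
        lo, hi = self.theta_per_gene
        return float(rng.uniform(lo, hi))


def random_cds(length: int, rng: np.random.Generator) -> np.ndarray:
    """Random in-frame CDS backbone with no internal stop codons."""
    if length % 3:
        raise ValueError("CDS length must be divisible by 3")
    arr = rng.choice(BASES, size=length)
    for c in range(length // 3):
        while CODON_TO_AA[_codon_of(arr, c)] == "*":
            arr[3 * c : 3 * c + 3] = rng.choice(BASES, size=3)
    return arr.astype(np.uint8)


def _codon_of(arr: np.ndarray, c: int) -> str:
    return "".join(chr(b) for b in arr[3 * c : 3 * c + 3])


def _mutation_effect(backbone: np.ndarray, site: int, new_base: int) -> str:
    """'syn', 'nonsyn' or 'stop' for swapping ``site`` to ``new_base``."""
    c = site // 3
    old = _codon_of(backbone, c)
    pos = site % 3
    new = old[:pos] + chr(new_base) + old[pos + 1 :]
    if CODON_TO_AA[new] == "*" or CODON_TO_AA[old] == "*":
        return "stop"
    return "syn" if CODON_TO_AA[new] == CODON_TO_AA[old] else "nonsyn"


def _draw_mutation(
    backbone: np.ndarray,
    used_codons: set[int],
    omega: float,
    rng: np.random.Generator,
    force_nonsyn: bool = False,
    max_tries: int = 500,
) -> tuple[int, int, str] | None:
    """Draw one substitution in a previously unhit codon.

    A random position of a random unused codon is chosen and the new base
    is drawn among its three alternatives with purifying weights:
    synonymous 1, non-synonymous ``omega``, stop 0.  Every successful draw
    yields exactly one substitution, so the mutation supply theta sets the
    expected number of segregating events directly while the accepted
    non-synonymous fraction is suppressed identically for polymorphism and
    divergence.  Returns ``(site, new_base, effect)``; ``None`` only on
    codon exhaustion.
    """
    n_codons = backbone.size // 3
    for _ in range(max_tries):
        c = int(rng.integers(n_codons))
        if c in used_codons:
            continue
        site = 3 * c + int(rng.integers(3))
        alts = BASES[BASES != backbone[site]]
        effects = [_mutation_effect(backbone, site, int(b)) for b in alts]
        if force_nonsyn:
            weights = np.array([1.0 if e == "nonsyn" else 0.0 for e in effects])
        else:
            weights = np.array(
                [1.0 if e == "syn" else omega if e == "nonsyn" else 0.0 for e in effects]
            )
        total = weights.sum()
        if total == 0:
            continue
        k = int(rng.choice(3, p=weights / total))
        return site, int(alts[k]), effects[k]
    return None


def _mean_nonsyn_fraction(backbone: np.ndarray, omega: float) -> float:
    """Expected non-synonymous fraction of accepted substitutions, averaged
    over all sites of the backbone under the purifying weighting."""
    fracs = []
    for site in range(backbone.size):
        alts = BASES[BASES != backbone[site]]
        w_syn = w_non = 0.0
        for b in alts:
            e = _mutation_effect(backbone, site, int(b))
            if e == "syn":
                w_syn += 1.0
            elif e == "nonsyn":
                w_non += omega
        if w_syn + w_non > 0:
            fracs.append(w_non / (w_syn + w_non))
    return float(np.mean(fracs)) if fracs else 0.0


def _simulate_gene(
    cfg: SimConfig,
    rng: np.random.Generator,
    gene_id: str,
    length: int | None = None,
    theta: float | None = None,
    sweep: bool = False,
    with_sister: bool = True,
    alpha_adaptive: float | None = None,
) -> tuple[Alignment, dict]:
    """One synthetic gene: alignment (+sister/outgroup) and its truth record."""
    if length is None:
        lo, hi = cfg.cds_length_range
        length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
    if theta is None:
        theta = cfg.draw_theta(rng, length)
    if alpha_adaptive is None:
        alpha_adaptive = cfg.alpha_adaptive
    n = cfg.n_lines
    backbone = random_cds(length, rng)
    used: set[int] = set()
    truth = {
        "gene_id": gene_id,
        "length": length,
        "theta": theta,
        "swept": bool(sweep),
        "Pn": 0,
        "Ps": 0,
        "Dn_focal": 0,
        "Ds_focal": 0,
        "Dn_sister": 0,
        "Ds_sister": 0,
        "n_adaptive": 0,
    }

    # within-species polymorphism on a (possibly swept) genealogy
    member, lengths = sample_genealogy(
        n,
        rng,
        sweep_fraction=cfg.sweep_intensity if sweep else 0.0,
        sweep_time=cfg.sweep_tau,
    )
    total = lengths.sum()
    matrix = np.tile(backbone, (n, 1))
    n_prop = int(rng.poisson(theta / 2.0 * total))
    probs = lengths / total
    branches = rng.choice(lengths.size, size=n_prop, p=probs)
    for b in branches:
        hit = _draw_mutation(backbone, used, cfg.omega, rng)
        if hit is None:
            continue
        site, new, effect = hit
        used.add(site // 3)
        matrix[member[b], site] = new
        truth["Pn" if effect == "nonsyn" else "Ps"] += 1

    outgroups: dict[str, np.ndarray] = {}
    if with_sister:
        sister = backbone.copy()
        out = backbone.copy()
        # fixed differences on each lineage; outgroup gets its own branch
        for target, branch_time, dn_key, ds_key in (
            (matrix, cfg.divergence_time, "Dn_focal", "Ds_focal"),
            (sister, cfg.divergence_time, "Dn_sister", "Ds_sister"),
            (out, cfg.outgroup_divergence_time, None, None),
        ):
            n_sub = int(rng.poisson(theta / 2.0 * branch_time))
            for _ in range(n_sub):
                hit = _draw_mutation(backbone, used, cfg.omega, rng)
                if hit is None:
                    continue
                site, new, effect = hit
                used.add(site // 3)
                if target is matrix:
                    matrix[:, site] = new
                else:
                    target[site] = new
                if dn_key is not None:
                    truth[dn_key if effect == "nonsyn" else ds_key] += 1
        # planted adaptive non-synonymous substitutions on the focal lineage
        if alpha_adaptive > 0:
            base_dn = theta / 2.0 * cfg.divergence_time * _mean_nonsyn_fraction(backbone, cfg.omega)
            lam = alpha_adaptive / (1.0 - alpha_adaptive) * base_dn
            for _ in range(int(rng.poisson(lam))):
                hit = _draw_mutation(backbone, used, cfg.omega, rng, force_nonsyn=True)
                if hit is None:
                    continue
                site, new, _ = hit
                used.add(site // 3)
                matrix[:, site] = new
                truth["Dn_focal"] += 1
                truth["n_adaptive"] += 1
        outgroups[SISTER] = sister
        outgroups[OUTGROUP] = out

    # missing data: iid N calls in the in-group only
    if cfg.missing_rate > 0:
        n_missing = int(rng.poisson(cfg.missing_rate * matrix.size))
        if n_missing:
            idx = rng.integers(0, matrix.size, size=n_missing)
            matrix.flat[idx] = N

    ids = [f"line_{i:03d}" for i in range(n)]
    return Alignment(gene_id, ids, matrix, outgroups), truth


def generate_neutral_gene(cfg: SimConfig, gene_seed: int, **kw) -> tuple[Alignment, dict]:
    """Neutral gene: coalescent polymorphism, no planted signal."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, gene_seed]))
    return _simulate_gene(cfg, rng, f"gene_{gene_seed}", sweep=False, alpha_adaptive=0.0, **kw)


def generate_sweep_gene(cfg: SimConfig, gene_seed: int, **kw) -> tuple[Alignment, dict]:
    """Gene carrying a planted partial hard sweep (forced recent coalescence).

    With ``sweep_intensity`` 0 this reduces to the neutral generator.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, gene_seed]))
    return _simulate_gene(cfg, rng, f"gene_{gene_seed}", sweep=True, alpha_adaptive=0.0, **kw)


def generate_divergence_gene(cfg: SimConfig, gene_seed: int, **kw) -> tuple[Alignment, dict]:
    """Gene with (possibly adaptive) lineage divergence for the MK test."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, gene_seed]))
    return _simulate_gene(cfg, rng, f"gene_{gene_seed}", sweep=False, with_sister=True, **kw)


# ---------------------------------------------------------------------------
# Full study bundles
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """In-memory study bundle: genes, pairings, gene metadata and truth."""

    config: SimConfig
    genes: dict[str, Alignment]
    pairings: list[GenePairing]
    meta: pd.DataFrame  # gene_id, role, focal_id, chrom, start, cds_length
    truth: pd.DataFrame

    def write(self, out_dir) -> None:
        """Serialise the bundle to FASTA + pairings.tsv + truth.tsv + config.yaml."""
        import os

        import yaml

        os.makedirs(out_dir, exist_ok=True)
        for gid, aln in self.genes.items():
            write_fasta_alignment(aln, os.path.join(out_dir, f"{gid}.fasta"))
        self.meta.to_csv(os.path.join(out_dir, "pairings.tsv"), sep="\t", index=False)
        self.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
            yaml.safe_dump(asdict(self.config), fh, sort_keys=True)


def generate_study_bundle(cfg: SimConfig, out_dir=None) -> Bundle:
    """Generate a complete focal/control study.

    Focal genes sit on one synthetic chromosome at widely spaced starts;
    each receives 3-4 neutral controls with the same per-site mutation
    rate, CDS lengths
    within 0.5-2x and starts within +-60 kb, so every pairing passes the
    control validator by construction.  ``sweep_fraction`` of the focal
    genes (an exact count, assigned at random) carry a planted sweep.
    Deterministic given ``cfg.seed``; byte-identical when written twice.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 987_001]))
    n_swept = int(round(cfg.sweep_fraction * cfg.n_focal))
    swept_idx = set(rng.choice(cfg.n_focal, size=n_swept, replace=False).tolist())

    genes: dict[str, Alignment] = {}
    pairings: list[GenePairing] = []
    meta_rows, truth_rows = [], []
    lo, hi = cfg.cds_length_range
    k_lo, k_hi = cfg.controls_per_focal

    for i in range(cfg.n_focal):
        focal_id = f"focal_{i:03d}"
        focal_start = 100_000 + 200_000 * i
        flen = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        gene_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, i]))
        aln, truth = _simulate_gene(
            cfg, gene_rng, focal_id, length=flen, sweep=i in swept_idx
        )
        genes[focal_id] = aln
        meta_rows.append(
            dict(gene_id=focal_id, role="focal", focal_id=focal_id, chrom="chrSim",
                 start=focal_start, cds_length=flen)
        )
        truth_rows.append(truth)

        n_ctrl = int(rng.integers(k_lo, k_hi + 1))
        ctrl_ids, ctrl_lens, dists = [], [], []
        for j in range(n_ctrl):
            cid = f"{focal_id}_ctrl{j}"
            # the 0.5-2x matching band is symmetric on the log scale, so
            # control lengths are drawn log-uniformly around the focal length
            ratio = float(np.exp(rng.uniform(np.log(0.55), np.log(1 / 0.55))))
            clen = 3 * max(min(int(round(flen * ratio / 3)), hi // 3), lo // 3)
            offset = int(rng.integers(5_000, 55_000)) * (1 if rng.random() < 0.5 else -1)
            ctrl_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3, i, j]))
            caln, _ = _simulate_gene(
                cfg, ctrl_rng, cid, length=clen, sweep=False, alpha_adaptive=0.0
            )
            genes[cid] = caln
            meta_rows.append(
                dict(gene_id=cid, role="control", focal_id=focal_id, chrom="chrSim",
                     start=focal_start + offset, cds_length=clen)
            )
            ctrl_ids.append(cid)
            ctrl_lens.append(clen)
            dists.append(abs(offset))
        pairings.append(GenePairing(focal_id, ctrl_ids, flen, ctrl_lens, dists))

    bundle = Bundle(
        cfg,
        genes,
        pairings,
        pd.DataFrame(meta_rows),
        pd.DataFrame(truth_rows),
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
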