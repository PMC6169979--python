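"""End-to-end screen: filter -> subsample -> statistics -> nulls -> MK ->
comparison framework -> sweep/divergence calls.

The pipeline consumes a directory (or in-memory bundle) of per-gene FASTA
alignments plus a pairing table, and produces four result artefacts:

* ``group_summary.tsv`` — pathway-level t-test / Wilcoxon summaries of the
  comparison scores per statistic;
* ``sweep_table.tsv``   — per focal gene: theta_w, D, nFWH, EW, raw and
  BH-corrected p-values, DHEW p, oriented rank and rank-against-null
  percentiles, and the sweep call;
* ``divergence_table.tsv`` — per focal gene: the MK table, FET p-values,
  DoS, DoS rank columns and the adaptive-divergence call;
* ``calls.json``        — machine-readable calls plus every seed and
  threshold used.

A single global seed is expanded into per-stage, per-cell seeds through
``numpy.random.SeedSequence`` so results do not depend on gene iteration
order.  A missing sister/outgroup only disables the statistics that need
it (H, MK) for that gene; genuine errors abort with the stage and gene id.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import alignment_io as aio
from . import focal_control as fc
from . import mk_dos as mk
from . import sfs_stats as sfs
from .neutral_null import StatVector, gene_pvalues, get_null
from .synthetic_data import Bundle

__all__ = ["RunConfig", "PipelineError", "run_full_screen", "load_bundle_dir"]

log = logging.getLogger("dhewscan")

# statistics entering the comparison-score framework, with the direction in
# which extreme values signal selection (False: most negative is extreme)
COMPARISON_STATS: dict[str, bool] = {
    "theta_w": False,
    "TajD": False,
    "nFWH": False,
    "EW": True,
    "DoS": True,
}
RANKED_STATS = ("TajD", "nFWH", "DoS")  # stats entering the sweep rank criterion


class PipelineError(RuntimeError):
    def __init__(self, stage: str, gene_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for gene {gene_id!r}: {cause}")
        self.stage = stage
        self.gene_id = gene_id


@dataclass
class RunConfig:
    """Thresholds, sizes and seeds for one screen run."""

    n_subsample: int = 149
    reps: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    rank_top_pct: float = 10.0
    null_top_pct: float = 5.0
    max_missing: float = 0.10
    perm_mode: str = "enumerate"
    n_perm: int = 1000
    sister_name: str = "sister"
    outgroup_name: str = "outgroup"
    polarize_with: tuple[str, ...] | None = None  # None -> all attached outgroups

    def __post_init__(self) -> None:
        for t in (self.alpha,):
            if not 0 < t < 1:
                raise ValueError("alpha must be in (0, 1)")


def load_bundle_dir(path) -> tuple[dict[str, aio.Alignment], list[fc.GenePairing], pd.DataFrame]:
    """Read per-gene FASTA files and the pairing table from a bundle directory."""
    meta = pd.read_csv(os.path.join(path, "pairings.tsv"), sep="\t")
    genes: dict[str, aio.Alignment] = {}
    for gid in meta["gene_id"]:
        genes[gid] = aio.read_fasta_alignment(
            os.path.join(path, f"{gid}.fasta"),
            gene_id=gid,
            outgroup_ids=["sister", "outgroup"],
        )
    pairings = []
    for focal_id, grp in meta.groupby("focal_id", sort=True):
        focal = grp[grp.role == "focal"].iloc[0]
        ctrl = grp[grp.role == "control"]
        pairings.append(
            fc.GenePairing(
                focal_id,
                ctrl["gene_id"].tolist(),
                int(focal["cds_length"]),
                ctrl["cds_length"].astype(int).tolist(),
                (ctrl["start"] - focal["start"]).abs().astype(int).tolist(),
            )
        )
    return genes, pairings, meta


def _gene_stats(aln: aio.Alignment, config: RunConfig) -> dict:
    """Filter, subsample and summarise one gene; attach null p-values."""
    gid = aln.gene_id
    try:
        aln = aio.filter_missing(aln, config.max_missing)
        k = min(config.n_subsample, aln.n_samples)
        sub_seed = int(np.random.SeedSequence([config.seed, 11, abs(hash(gid)) % 2**31]).generate_state(1)[0] % 2**31)
        aln = aio.subsample_lines(aln, k, sub_seed)
    except aio.AlignmentError as exc:
        raise PipelineError("preprocess", gid, exc)
    out_names = (
        list(config.polarize_with)
        if config.polarize_with is not None
        else sorted(aln.outgroups)
    )
    out_names = [o for o in out_names if o in aln.outgroups]
    summary = sfs.summarize_alignment(aln, out_names or None)
    row = {
        "gene_id": gid,
        "n": summary.n,
        "S": summary.S,
        "theta_w": summary.theta_w,
        "pi": summary.pi,
        "TajD": sfs.tajimas_d(summary),
        "nFWH": sfs.fay_wu_h_normalized(summary),
        "EW": summary.F_ew,
        "n_unpolarized": summary.n_unpolarized,
    }
    if summary.S >= 1:
        null = get_null(summary.n, summary.S, reps=config.reps, seed=config.seed)
        obs = StatVector(row["TajD"], row["nFWH"], row["EW"])
        row.update(gene_pvalues(obs, null))
    else:
        row.update(p_D=np.nan, p_H=np.nan, p_EW=np.nan, p_DHEW=np.nan)

    # MK / DoS: needs sister + outgroup
    if config.sister_name in aln.outgroups and config.outgroup_name in aln.outgroups:
        try:
            table = mk.classify_codon_changes(aln, [config.sister_name], config.outgroup_name)
        except (ValueError, KeyError) as exc:
            raise PipelineError("mk", gid, exc)
        row.update(
            Pn=table.Pn, Ps=table.Ps, Dn=table.Dn, Ds=table.Ds,
            MKcodons=table.mk_codons, FETpval=mk.mk_test(table), DoS=mk.dos(table),
        )
    else:
        row.update(Pn=np.nan, Ps=np.nan, Dn=np.nan, Ds=np.nan, MKcodons=np.nan,
                   FETpval=np.nan, DoS=np.nan)
    return row


def run_full_screen(
    source,
    out_dir=None,
    config: RunConfig | None = None,
) -> dict:
    """Run the complete screen on a bundle directory or in-memory Bundle.

    Returns a dict with the per-gene statistics table (``stats``), the
    group summary (``group``), the sweep table (``sweep``), the divergence
    table (``divergence``) and the calls (``calls``); written as TSV/JSON
    under ``out_dir`` when given.
    """
    config = config or RunConfig()
    if isinstance(source, Bundle):
        genes, pairings = source.genes, source.pairings
    elif isinstance(source, (str, os.PathLike)):
        genes, pairings, _ = load_bundle_dir(source)
    else:
        genes, pairings = source  # (genes dict, pairings list)

    log.info(
        "screen: %d genes, %d pairings; seed=%d reps=%d alpha=%.3g rank_top=%g%% null_top=%g%%",
        len(genes), len(pairings), config.seed, config.reps, config.alpha,
        config.rank_top_pct, config.null_top_pct,
    )

    stats = pd.DataFrame([_gene_stats(aln, config) for aln in genes.values()])
    stats = stats.set_index("gene_id", drop=False)
    focal_ids = [p.focal_id for p in pairings]

    # BH correction per statistic across the focal gene set
    focal = stats.loc[focal_ids]
    for col in ("p_D", "p_H", "p_EW", "p_DHEW"):
        stats.loc[focal_ids, col + "_corrected"] = mk.bh_correct(focal[col].tolist())
    stats.loc[focal_ids, "FET_corrected"] = mk.bh_correct(focal["FETpval"].tolist())

    # comparison scores, group tests, ranks, permutation ranks
    values = {s: stats[s].to_dict() for s in COMPARISON_STATS}
    scores: dict[str, dict[str, float]] = {s: {} for s in COMPARISON_STATS}
    for p in pairings:
        for s in COMPARISON_STATS:
            scores[s][p.focal_id] = fc.comparison_score(
                values[s].get(p.focal_id, np.nan),
                [values[s].get(c, np.nan) for c in p.control_ids],
            )
    group_rows = []
    for s in COMPARISON_STATS:
        defined = [v for v in scores[s].values() if not np.isnan(v)]
        if len(defined) < 2:
            continue
        res = fc.group_test(defined)
        group_rows.append({"statistic": s, **{k: v for k, v in res.items()}})
    group = pd.DataFrame(group_rows)

    ranks: dict[str, dict[str, tuple[int, float]]] = {}
    null_pct: dict[str, dict[str, float]] = {}
    for s in RANKED_STATS:
        extreme_high = COMPARISON_STATS[s]
        ranks[s] = fc.rank_scores(scores[s], higher_is_extreme=extreme_high)
        perm_seed = int(np.random.SeedSequence([config.seed, 13]).generate_state(1)[0] % 2**31)
        null_pct[s] = fc.rank_against_null(
            values[s], pairings, mode=config.perm_mode, n_perm=config.n_perm,
            seed=perm_seed, higher_is_extreme=extreme_high,
        )

    sweep_rows, div_rows, calls = [], [], {}
    for p in pairings:
        gid = p.focal_id
        g = stats.loc[gid]
        rank_p = {s: ranks[s].get(gid, (None, np.nan))[1] for s in RANKED_STATS}
        nullp = {s: null_pct[s].get(gid, np.nan) for s in RANKED_STATS}
        sweep_call = fc.call_sweep(
            g["p_DHEW"],
            {"D": g["p_D_corrected"], "H": g["p_H_corrected"], "EW": g["p_EW_corrected"]},
            rank_p,
            nullp,
            alpha=config.alpha,
            rank_top_pct=config.rank_top_pct,
            null_top_pct=config.null_top_pct,
        )
        div_call = fc.call_adaptive_divergence(g["FET_corrected"], g["DoS"], config.alpha)
        calls[gid] = {
            "candidate_sweep": sweep_call,
            "adaptive_divergence": div_call,
        }
        sweep_rows.append({
            "gene_id": gid, "n": g["n"], "S": g["S"], "theta_w": g["theta_w"],
            "TajD": g["TajD"], "TajD_pval": g["p_D"], "TajD_pval_corrected": g["p_D_corrected"],
            "nFWH": g["nFWH"], "nFWH_pval": g["p_H"], "nFWH_pval_corrected": g["p_H_corrected"],
            "EW": g["EW"], "EW_pval": g["p_EW"], "EW_pval_corrected": g["p_EW_corrected"],
            "DHEW_pval": g["p_DHEW"], "DHEW_pval_corrected": g["p_DHEW_corrected"],
            "TajD_score": scores["TajD"][gid], "TajD_rank_pct": rank_p["TajD"],
            "TajD_rank_against_null": nullp["TajD"],
            "nFWH_score": scores["nFWH"][gid], "nFWH_rank_pct": rank_p["nFWH"],
            "nFWH_rank_against_null": nullp["nFWH"],
            "candidate_sweep": sweep_call,
        })
        div_rows.append({
            "gene_id": gid, "Pn": g["Pn"], "Dn": g["Dn"], "Ps": g["Ps"], "Ds": g["Ds"],
            "MKcodons": g["MKcodons"], "FETpval": g["FETpval"],
            "FET_corrected": g["FET_corrected"], "DoS": g["DoS"],
            "DoS_score": scores["DoS"][gid], "DoS_rank_pct": rank_p["DoS"],
            "DoS_rank_against_null": nullp["DoS"],
            "adaptive_divergence": div_call,
        })
    sweep = pd.DataFrame(sweep_rows)
    divergence = pd.DataFrame(div_rows)

    results = {
        "stats": stats.reset_index(drop=True),
        "group": group,
        "sweep": sweep,
        "divergence": divergence,
        "calls": calls,
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        results["stats"].to_csv(os.path.join(out_dir, "stats.tsv"), sep="\t", index=False)
        group.to_csv(os.path.join(out_dir, "group_summary.tsv"), sep="\t", index=False)
        sweep.to_csv(os.path.join(out_dir, "sweep_table.tsv"), sep="\t", index=False)
        divergence.to_csv(os.path.join(out_dir, "divergence_table.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "calls.json"), "w") as fh:
            json.dump({"config": asdict(config), "calls": calls}, fh, indent=2, default=str)
        log.info("results written to %s", out_dir)
    return results
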