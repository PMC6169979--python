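"""Lineage-polarized McDonald-Kreitman test and Direction of Selection.

Counts, per gene, non-synonymous and synonymous polymorphisms within the
focal species (Pn, Ps) and fixed differences assigned to the focal lineage
(Dn, Ds) from an in-frame codon alignment of focal samples, one or more
sister-species sequences, and an outgroup.  Fixed differences are
polarized by strict parsimony: the lineage carrying the allele that
differs from the outgroup base is charged with the substitution; if the
outgroup matches neither allele the substitution is left unassigned.

Codon-level filtering: a codon is "analyzable" (counted in MKcodons) only
when every sequence is unambiguous there and at most one of its three
positions varies in any way (within focal, within sister, or between the
species).  Codons with two or more variable/divergent positions — where
the mutational pathway is ambiguous — are excluded from all counts.
Variants creating a stop codon are excluded from Pn/Dn.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .alignment_io import Alignment, GAP, N

__all__ = [
    "MKTable",
    "assign_lineage_fixed_difference",
    "classify_codon_changes",
    "mk_test",
    "dos",
    "bh_correct",
]

_CODE = {65: "A", 67: "C", 71: "G", 84: "T"}


def _codon_table() -> dict[str, str]:
    from Bio.Seq import Seq

    return {
        "".join(c): str(Seq("".join(c)).translate())
        for c in product("ACGT", repeat=3)
    }


CODON_TO_AA = _codon_table()


@dataclass
class MKTable:
    """Per-gene MK counts and derived quantities for the focal lineage."""

    gene_id: str
    Pn: int = 0
    Ps: int = 0
    Dn: int = 0
    Ds: int = 0
    mk_codons: int = 0
    p_fet: float = float("nan")
    p_fet_corrected: float = float("nan")
    dos: float = float("nan")


def assign_lineage_fixed_difference(
    focal_base: int | str, sister_base: int | str, outgroup_base: int | str
) -> str:
    """Polarize one fixed inter-species difference by strict parsimony.

    Returns ``"focal"``, ``"sister"`` or ``"unassigned"``.  The lineage
    whose allele differs from the outgroup base carries the substitution;
    an outgroup base matching neither allele leaves it unassigned.
    """
    f, s, o = (b if isinstance(b, str) else _CODE.get(int(b), "N") for b in (focal_base, sister_base, outgroup_base))
    if f == s:
        raise ValueError("not a fixed difference: focal and sister agree")
    if o == s:
        return "focal"
    if o == f:
        return "sister"
    return "unassigned"


def _is_stop(codon: str) -> bool:
    return CODON_TO_AA[codon] == "*"


def classify_codon_changes(
    aln: Alignment, sister_names: list[str], outgroup_name: str
) -> MKTable:
    """Codon-by-codon MK classification for one gene.

    ``aln`` holds the focal samples as in-group; sister sequences and the
    outgroup must be attached as outgroups of the alignment.  Requires an
    in-frame alignment and the standard genetic code.
    """
    if not aln.in_frame:
        raise ValueError(f"{aln.gene_id}: alignment length not divisible by 3")
    for name in [*sister_names, outgroup_name]:
        if name not in aln.outgroups:
            raise KeyError(f"sequence {name!r} not attached to {aln.gene_id}")
    focal = aln.matrix
    sister = np.vstack([aln.outgroups[s] for s in sister_names])
    out = aln.outgroups[outgroup_name]
    table = MKTable(aln.gene_id)
    ambiguous = np.array([N, GAP], dtype=np.uint8)

    for c in range(aln.length // 3):
        sl = slice(3 * c, 3 * c + 3)
        fc = focal[:, sl]
        sc = sister[:, sl]
        oc = out[sl]
        if (
            np.isin(fc, ambiguous).any()
            or np.isin(sc, ambiguous).any()
            or np.isin(oc, ambiguous).any()
        ):
            continue  # not analyzable
        # positions where focal or sister vary, or the species differ
        hits = []
        for p in range(3):
            alleles = set(fc[:, p].tolist()) | set(sc[:, p].tolist())
            if len(alleles) > 1:
                hits.append(p)
        if len(hits) > 1:
            continue  # multi-hit codon: pathway ambiguous, excluded
        table.mk_codons += 1
        if not hits:
            continue
        p = hits[0]
        f_alleles = sorted(set(fc[:, p].tolist()))
        s_alleles = sorted(set(sc[:, p].tolist()))
        if len(set(f_alleles) | set(s_alleles)) > 2:
            continue  # triallelic single position: parsimony ambiguous
        ref = fc[0].copy()

        if len(f_alleles) == 2:
            # polymorphism within the focal species (sister may share one allele)
            cod = [_codon_str(ref, p, b) for b in f_alleles]
            if any(_is_stop(x) for x in cod):
                continue  # nonsense variants are not counted
            if CODON_TO_AA[cod[0]] == CODON_TO_AA[cod[1]]:
                table.Ps += 1
            else:
                table.Pn += 1
            continue

        if len(s_alleles) == 1 and f_alleles[0] != s_alleles[0]:
            # fixed difference between the species
            lineage = assign_lineage_fixed_difference(
                f_alleles[0], s_alleles[0], int(oc[p])
            )
            if lineage != "focal":
                continue
            cod_f = _codon_str(ref, p, f_alleles[0])
            cod_s = _codon_str(ref, p, s_alleles[0])
            if _is_stop(cod_f) or _is_stop(cod_s):
                continue
            if CODON_TO_AA[cod_f] == CODON_TO_AA[cod_s]:
                table.Ds += 1
            else:
                table.Dn += 1
        # remaining case: polymorphism only within the sister species — not counted

    return table


def _codon_str(ref: np.ndarray, pos: int, base: int) -> str:
    cod = ref.copy()
    cod[pos] = base
    return "".join(_CODE[int(b)] for b in cod)


def mk_test(table: MKTable) -> float:
    """Two-sided Fisher's exact p for [[Dn, Ds], [Pn, Ps]].

    nan when either row margin (all divergence or all polymorphism) is
    empty, where the test is undefined.
    """
    if table.Dn + table.Ds == 0 or table.Pn + table.Ps == 0:
        return float("nan")
    _, p = sps.fisher_exact([[table.Dn, table.Ds], [table.Pn, table.Ps]])
    return float(p)


def dos(table: MKTable) -> float:
    """Direction of Selection: Dn/(Dn+Ds) - Pn/(Pn+Ps).

    Positive values indicate adaptive divergence, negative values
    segregating (slightly) deleterious variants.  nan if a margin is zero.
    """
    if table.Dn + table.Ds == 0 or table.Pn + table.Ps == 0:
        return float("nan")
    return table.Dn / (table.Dn + table.Ds) - table.Pn / (table.Pn + table.Ps)


def bh_correct(pvals) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (nan-aware, capped at 1)."""
    arr = np.asarray(pvals, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return out.tolist()
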