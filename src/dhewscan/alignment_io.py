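"""Reading, filtering and subsampling of per-gene CDS haplotype alignments.

Alignments are in-frame, one per gene, with many in-group haplotypes (e.g.
population resequencing lines) and optionally one or more aligned outgroup
sequences used for polarization.  Sequences are stored internally as a
numpy uint8 matrix of ASCII codes over the alphabet ``A C G T N -`` so that
column-wise operations on thousands of simulated genes stay cheap.

Conventions
-----------
* GFF3 coordinates are 1-based inclusive; internal column indices are
  0-based half-open.
* Gaps (``-``) are treated as missing data for all downstream statistics,
  never as a fifth allele.
* Any character outside the alphabet is normalised to ``N`` on input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Alignment",
    "AlignmentError",
    "EmptyAlignmentError",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "extract_cds",
    "filter_missing",
    "subsample_lines",
]

# byte codes for the alignment alphabet
A, C, G, T, N, GAP = (ord(x) for x in "ACGTN-")
_VALID = frozenset((A, C, G, T, N, GAP))
BASES = np.array([A, C, G, T], dtype=np.uint8)


class AlignmentError(ValueError):
    """Malformed alignment (unequal lengths, bad ids, frame violations)."""


class EmptyAlignmentError(AlignmentError):
    """An operation removed every in-group sequence."""


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a sequence string as uint8 codes, mapping unknowns to N."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    bad = ~np.isin(arr, np.fromiter(_VALID, dtype=np.uint8))
    arr[bad] = N
    return arr


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass
class Alignment:
    """A per-gene in-frame haplotype alignment with optional outgroups.

    Attributes
    ----------
    gene_id : str
    sample_ids : list of str
        Unique in-group sample identifiers, input order preserved.
    matrix : (n_samples, length) uint8 array
        ASCII codes over ``A C G T N -``.
    outgroups : dict
        Outgroup name -> aligned uint8 vector of the same length.
    excluded_columns : bool array of shape (length,)
        Columns flagged for exclusion from all statistics (set by
        :func:`filter_missing` for residual N/gap columns).
    """

    gene_id: str
    sample_ids: list[str]
    matrix: np.ndarray
    outgroups: dict[str, np.ndarray] = field(default_factory=dict)
    excluded_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise AlignmentError("sample_ids and matrix rows disagree")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("duplicate sample ids")
        for name, row in self.outgroups.items():
            if row.shape != (self.matrix.shape[1],):
                raise AlignmentError(f"outgroup {name!r} length mismatch")
        if self.excluded_columns is None:
            self.excluded_columns = np.zeros(self.matrix.shape[1], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def in_frame(self) -> bool:
        return self.length % 3 == 0

    @property
    def sequences(self) -> list[str]:
        return [array_to_seq(row) for row in self.matrix]

    def copy(self) -> "Alignment":
        return Alignment(
            self.gene_id,
            list(self.sample_ids),
            self.matrix.copy(),
            {k: v.copy() for k, v in self.outgroups.items()},
            self.excluded_columns.copy(),
        )


def read_fasta_alignment(
    path,
    gene_id: str | None = None,
    outgroup_ids: list[str] | None = None,
    outgroup_prefix: str | None = None,
) -> Alignment:
    """Read an aligned FASTA into an :class:`Alignment`.

    Records named in ``outgroup_ids`` (or whose id starts with
    ``outgroup_prefix``) become outgroups; all others are in-group samples.
    Input order is preserved, bases are uppercased, and any character other
    than ``ACGTN-`` is stored as ``N``.  Readers tolerate CRLF line endings
    and wrapped sequence lines (Biopython handles both).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal record lengths in {path}: {sorted(lengths)}")
    outgroup_ids = set(outgroup_ids or ())
    ids, rows, outgroups = [], [], {}
    for rec in records:
        arr = seq_to_array(str(rec.seq))
        is_out = rec.id in outgroup_ids or (
            outgroup_prefix is not None and rec.id.startswith(outgroup_prefix)
        )
        if is_out:
            outgroups[rec.id] = arr
        else:
            ids.append(rec.id)
            rows.append(arr)
    if not rows:
        raise EmptyAlignmentError(f"no in-group records in {path}")
    if gene_id is None:
        import os

        gene_id = os.path.splitext(os.path.basename(str(path)))[0]
    return Alignment(gene_id, ids, np.vstack(rows), outgroups)


def write_fasta_alignment(aln: Alignment, path, width: int = 70) -> None:
    """Serialise an alignment (in-group then outgroups) back to FASTA."""
    with open(path, "w") as fh:
        for sid, row in zip(aln.sample_ids, aln.matrix):
            _write_record(fh, sid, array_to_seq(row), width)
        for name, row in aln.outgroups.items():
            _write_record(fh, name, array_to_seq(row), width)


def _write_record(fh, name: str, seq: str, width: int) -> None:
    fh.write(f">{name}\n")
    for i in range(0, len(seq), width):
        fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CDS extraction from genome + GFF3
# ---------------------------------------------------------------------------

def extract_cds(genome_fasta, gff3_path, gene_id: str) -> str:
    """Extract the CDS of the longest isoform of ``gene_id``.

    CDS segments of the chosen isoform are concatenated in transcription
    order; minus-strand genes are reverse-complemented.  When several
    isoforms exist the one with the greatest total CDS length is used, ties
    broken by lexicographically smallest transcript id.  A CDS length not
    divisible by three triggers a warning but is still returned.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    try:
        gene = db[gene_id]
    except gffutils.FeatureNotFoundError:
        raise KeyError(f"gene {gene_id!r} not found in {gff3_path}") from None

    transcripts = {}
    for mrna in db.children(gene, level=1):
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if cds:
            transcripts[mrna.id] = cds
    if not transcripts:
        raise KeyError(f"gene {gene_id!r} has no mRNA with CDS features")

    def total_len(segs):
        return sum(f.end - f.start + 1 for f in segs)

    best = min(transcripts, key=lambda tid: (-total_len(transcripts[tid]), tid))
    segs = transcripts[best]

    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    chrom = genome[segs[0].seqid]
    # GFF3 is 1-based inclusive
    pieces = [chrom[f.start - 1 : f.end] for f in segs]
    seq = "".join(pieces)
    if segs[0].strand == "-":
        seq = str(Seq(seq).reverse_complement())
    if len(seq) % 3 != 0:
        warnings.warn(
            f"CDS of {gene_id} (isoform {best}) has length {len(seq)} not divisible by 3",
            stacklevel=2,
        )
    return seq


# ---------------------------------------------------------------------------
# Missing-data filter and line subsampling
# ---------------------------------------------------------------------------

def filter_missing(aln: Alignment, max_missing: float = 0.10) -> Alignment:
    """Drop in-group sequences with more than ``max_missing`` missing data.

    Missing means ``N`` or a gap.  Columns that still contain missing data
    in any retained sequence are flagged in ``excluded_columns`` so that
    downstream statistics operate on complete-case columns only (keeping
    the per-site sample size constant).  Idempotent.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    missing = (aln.matrix == N) | (aln.matrix == GAP)
    frac = missing.mean(axis=1)
    keep = frac <= max_missing
    if not keep.any():
        raise EmptyAlignmentError(
            f"{aln.gene_id}: every sequence exceeds {max_missing:.0%} missing data"
        )
    matrix = aln.matrix[keep]
    ids = [s for s, k in zip(aln.sample_ids, keep) if k]
    col_missing = ((matrix == N) | (matrix == GAP)).any(axis=0)
    excluded = aln.excluded_columns | col_missing
    return Alignment(aln.gene_id, ids, matrix, dict(aln.outgroups), excluded)


def subsample_lines(aln: Alignment, k: int, seed: int) -> Alignment:
    """Uniform random subsample of ``k`` in-group lines, without replacement.

    Deterministic given ``seed``; preserves the original sample order and
    leaves outgroups untouched.
    """
    if k > aln.n_samples:
        raise ValueError(f"cannot subsample {k} of {aln.n_samples} lines")
    if k == aln.n_samples:
        return aln.copy()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(aln.n_samples, size=k, replace=False))
    return Alignment(
        aln.gene_id,
        [aln.sample_ids[i] for i in idx],
        aln.matrix[idx],
        dict(aln.outgroups),
        aln.excluded_columns.copy(),
    )
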