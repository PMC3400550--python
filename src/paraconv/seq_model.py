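"""Alignment data model, FASTA IO, pseudogene flagging and sequence typing.

Coordinates are 1-based and inclusive on the alignment, with intronic
columns counted (so nucleotide positions printed for the gene, e.g. site
692 for the N194D replacement, line up with protein residue numbers only
when the intron is included).  Gaps (``-``) and ``N`` are missing data:
gap columns are never called as SNPs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "AlleleRecord",
    "SNPMatrix",
    "AlignmentError",
    "read_fasta_alignment",
    "write_fasta",
    "flag_pseudogenes",
    "assign_sequence_types",
    "snp_table",
]

MISSING = {"-", "N"}


class AlignmentError(ValueError):
    """Raised for ragged, empty or otherwise malformed alignments."""


@dataclass
class Alignment:
    """A set of aligned nucleotide sequences over {A, C, G, T, -, N}."""

    names: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if not self.seqs:
            raise AlignmentError("alignment has no sequences")
        L = len(self.seqs[0])
        if L < 1:
            raise AlignmentError("alignment length must be >= 1")
        if any(len(s) != L for s in self.seqs):
            raise AlignmentError("sequences have unequal lengths")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("sequence names are not unique")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def L(self) -> int:
        return len(self.seqs[0])

    @property
    def matrix(self) -> np.ndarray:
        """n x L array of single characters."""
        return np.array([list(s) for s in self.seqs])

    def subset(self, names: list[str]) -> "Alignment":
        idx = {nm: i for i, nm in enumerate(self.names)}
        return Alignment([nm for nm in names], [self.seqs[idx[nm]] for nm in names])

    def columns(self, start: int, end: int) -> "Alignment":
        """Sub-alignment of 1-based inclusive column interval [start, end]."""
        if not (1 <= start <= end <= self.L):
            raise AlignmentError(f"column interval [{start}, {end}] outside 1..{self.L}")
        return Alignment(list(self.names), [s[start - 1 : end] for s in self.seqs])


@dataclass
class AlleleRecord:
    """Metadata for one sampled allele."""

    allele_id: str
    species: str = ""
    locus: str = "unassigned"  # A, B, C or unassigned
    seq_type: str = "unassigned"  # 1, 2 or unassigned
    pseudogene: bool = False
    phenotype_class: str = ""


@dataclass
class SNPMatrix:
    """Biallelic segregating columns coded 0 = major, 1 = minor, -1 = missing."""

    names: list[str]
    positions: np.ndarray  # 1-based alignment columns, ascending
    codes: np.ndarray  # n x m int8, -1 missing
    maf: np.ndarray  # minor-allele frequency per column, in (0, 0.5]
    major: list[str] = field(default_factory=list)
    minor: list[str] = field(default_factory=list)


def read_fasta_alignment(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(aln: Alignment, path) -> None:
    if not aln.seqs:
        raise AlignmentError("refusing to write an empty alignment")
    recs = [SeqRecord(Seq(s), id=nm, description="") for nm, s in zip(aln.names, aln.seqs)]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def _coding_sequence(seq: str, orf_start: int, intron: tuple[int, int] | None) -> str:
    """Degapped coding sequence from orf_start, with the intron removed."""
    keep = []
    for pos0, base in enumerate(seq):
        pos = pos0 + 1
        if pos < orf_start:
            continue
        if intron is not None and intron[0] <= pos <= intron[1]:
            continue
        if base == "-":
            continue
        keep.append(base)
    return "".join(keep)


def flag_pseudogenes(
    aln: Alignment, orf_start: int = 1, intron: tuple[int, int] | None = None
) -> dict[str, tuple[bool, str]]:
    """Flag alleles whose reading frame is broken.

    An allele is a putative pseudogene if, after removing gaps and the
    intron, translation from ``orf_start`` hits a stop codon before the
    terminal one ("premature stop") or the coding length is not a
    multiple of three ("frameshift").  Returns ``{name: (flag, reason)}``.
    """
    if not (1 <= orf_start <= aln.L):
        raise AlignmentError(f"orf_start {orf_start} outside alignment")
    if intron is not None and not (1 <= intron[0] <= intron[1] <= aln.L):
        raise AlignmentError(f"intron interval {intron} outside alignment")
    out: dict[str, tuple[bool, str]] = {}
    stops = {"TAA", "TAG", "TGA"}
    for nm, seq in zip(aln.names, aln.seqs):
        cds = _coding_sequence(seq, orf_start, intron)
        if len(cds) % 3 != 0:
            out[nm] = (True, "frameshift")
            continue
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        internal_stop = any(c in stops for c in codons[:-1])
        out[nm] = (True, "premature stop") if internal_stop else (False, "")
    return out


def _pairwise_distance(mat: np.ndarray) -> np.ndarray:
    """Pairwise nucleotide distance with pairwise deletion of missing data."""
    n = mat.shape[0]
    valid = ~np.isin(mat, list(MISSING))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nv = both.sum()
            d = np.sum((mat[i] != mat[j]) & both) / nv if nv else 0.0
            D[i, j] = D[j, i] = d
    return D


def assign_sequence_types(
    aln: Alignment, intron: tuple[int, int]
) -> dict[str, str]:
    """Partition alleles into the two intron-defined sequence types.

    Complete-linkage 2-clustering of pairwise nucleotide distance restricted
    to intronic columns.  Label "1" is the larger group (ties broken by the
    group holding the lexicographically smallest allele id); a monomorphic
    intron yields "untyped" for every allele.  Deterministic.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    if aln.n < 2:
        raise AlignmentError("need at least two alleles to assign types")
    sub = aln.columns(*intron)
    mat = sub.matrix
    valid = ~np.isin(mat, list(MISSING))
    segregating = False
    for c in range(mat.shape[1]):
        states = set(mat[valid[:, c], c])
        if len(states) > 1:
            segregating = True
            break
    if not segregating:
        return {nm: "untyped" for nm in aln.names}
    D = _pairwise_distance(mat)
    Z = linkage(squareform(D, checks=False), method="complete")
    groups = fcluster(Z, t=2, criterion="maxclust")
    members = {g: [nm for nm, gg in zip(aln.names, groups) if gg == g] for g in set(groups)}
    ordered = sorted(members.values(), key=lambda ms: (-len(ms), min(ms)))
    labels: dict[str, str] = {}
    for lab, ms in zip(("1", "2"), ordered):
        for nm in ms:
            labels[nm] = lab
    return labels


def snp_table(aln: Alignment) -> SNPMatrix:
    """Biallelic segregating columns as a 0/1-coded SNP matrix.

    Gaps and Ns are missing; columns with more than two observed states are
    excluded; MAF is computed over non-missing alleles.  A frequency tie is
    resolved by calling the alphabetically first base the major allele.
    """
    mat = aln.matrix
    positions, codes, mafs, majors, minors = [], [], [], [], []
    for c in range(aln.L):
        col = mat[:, c]
        valid = ~np.isin(col, list(MISSING))
        counts = Counter(col[valid])
        if len(counts) != 2:
            continue
        (b1, c1), (b2, c2) = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        nv = c1 + c2
        code = np.full(aln.n, -1, dtype=np.int8)
        code[valid & (col == b1)] = 0
        code[valid & (col == b2)] = 1
        positions.append(c + 1)
        codes.append(code)
        mafs.append(c2 / nv)
        majors.append(str(b1))
        minors.append(str(b2))
    if positions:
        codes_arr = np.stack(codes, axis=1)
    else:
        codes_arr = np.zeros((aln.n, 0), dtype=np.int8)
    return SNPMatrix(
        names=list(aln.names),
        positions=np.array(positions, dtype=np.int64),
        codes=codes_arr,
        maf=np.array(mafs),
        major=majors,
        minor=minors,
    )
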