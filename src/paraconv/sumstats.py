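"""Population-genetic summary statistics for alignments and simulated data.

Diversity (pi, Watterson's theta), neutrality statistics (Tajima's D,
Fu & Li's D with outgroup polarization), Hudson's F_ST between two groups,
cross-locus classification of polymorphisms into shared / private / fixed
classes for a pair of paralogous loci, sliding windows, and the summary
vector bundle consumed by the ABC machinery.

Missing data (gaps, N) are handled by pairwise deletion, the DnaSP
convention: per column, pair differences are averaged over the pairs with
both members non-missing, and the per-site denominator counts columns with
at least two non-missing alleles.  pi is reported uncorrected (no
multiple-hit correction).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .coalsim import SimReplicate
from .seq_model import MISSING, Alignment, AlignmentError

__all__ = [
    "SummaryVector",
    "SharedPrivateSpectrum",
    "pi",
    "watterson",
    "tajimas_d",
    "tajimas_d_from_counts",
    "fu_li_d",
    "fst_two_groups",
    "classify_cross_locus",
    "sliding",
    "summary_vector",
    "DEFAULT_ABC_STATS",
]

#: statistic set fed to the ABC distance by default; the shared/fixed counts
#: carry most of the information about interlocus conversion
DEFAULT_ABC_STATS = (
    "S_A",
    "S_B",
    "pi_A",
    "pi_B",
    "D_A",
    "D_B",
    "n_shared",
    "n_fixed",
    "n_private",
)


@dataclass
class SummaryVector:
    """Per-locus diversity statistics plus cross-locus polymorphism counts."""

    S_A: float = 0.0
    S_B: float = 0.0
    pi_A: float = 0.0  # per site
    pi_B: float = 0.0
    pi_total_A: float = 0.0  # mean pairwise differences
    pi_total_B: float = 0.0
    theta_W_A: float = 0.0  # per site
    theta_W_B: float = 0.0
    D_A: float = math.nan
    D_B: float = math.nan
    n_shared: float = 0.0
    n_private_A: float = 0.0
    n_private_B: float = 0.0
    n_fixed: float = 0.0

    @property
    def n_private(self) -> float:
        return self.n_private_A + self.n_private_B

    def to_array(self, names=DEFAULT_ABC_STATS) -> np.ndarray:
        return np.array([getattr(self, nm) for nm in names], dtype=float)


@dataclass
class SharedPrivateSpectrum:
    """Derived-allele frequency spectra of shared and private polymorphisms."""

    n_shared: int = 0
    n_private_A: int = 0
    n_private_B: int = 0
    n_fixed: int = 0
    spectrum_shared: Counter = field(default_factory=Counter)
    spectrum_private_A: Counter = field(default_factory=Counter)
    spectrum_private_B: Counter = field(default_factory=Counter)


def _column_counts(mat: np.ndarray):
    """Yield (n_valid, Counter of states) per column, missing removed."""
    miss = list(MISSING)
    for c in range(mat.shape[1]):
        col = mat[:, c]
        valid = ~np.isin(col, miss)
        yield int(valid.sum()), Counter(col[valid])


def pi(aln: Alignment) -> tuple[float, float]:
    """Nucleotide diversity: (mean pairwise differences, per-site value).

    Per column, the fraction of differing pairs among pairs with both
    members non-missing; summed over columns, this equals the mean number
    of pairwise differences when no data are missing.  The per-site value
    divides by the number of columns with >= 2 non-missing alleles.
    """
    if aln.n < 2:
        raise AlignmentError("pi requires at least two sequences")
    total = 0.0
    L_eff = 0
    for nv, counts in _column_counts(aln.matrix):
        if nv < 2:
            continue
        L_eff += 1
        pairs = nv * (nv - 1) / 2
        same = sum(c * (c - 1) / 2 for c in counts.values())
        total += (pairs - same) / pairs
    return total, (total / L_eff if L_eff else 0.0)


def _effective_length(mat: np.ndarray) -> int:
    return sum(1 for nv, _ in _column_counts(mat) if nv >= 2)


def _segregating(mat: np.ndarray) -> int:
    return sum(1 for nv, counts in _column_counts(mat) if nv >= 2 and len(counts) > 1)


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def watterson(aln: Alignment) -> float:
    """Watterson's theta per site: S / (a_n * L_eff)."""
    if aln.n < 2:
        raise AlignmentError("watterson requires at least two sequences")
    S = _segregating(aln.matrix)
    L_eff = _effective_length(aln.matrix)
    if S == 0 or L_eff == 0:
        return 0.0
    return S / (_harmonic(aln.n) * L_eff)


def tajimas_d_from_counts(n: int, S: int, pi_total: float) -> float:
    """Tajima (1989) D from sample size, segregating sites and mean pairwise
    differences; NaN when S = 0 (undefined, DnaSP behaviour)."""
    if S == 0 or n < 2:
        return math.nan
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:  # n = 2 has zero variance; D undefined
        return math.nan
    return (pi_total - S / a1) / math.sqrt(var)


def tajimas_d(aln: Alignment) -> float:
    pi_total, _ = pi(aln)
    return tajimas_d_from_counts(aln.n, _segregating(aln.matrix), pi_total)


def fu_li_d(aln: Alignment, outgroup: str) -> float:
    """Fu & Li (1993) D, polarized by an outgroup sequence.

    eta counts all mutations (multi-allelic columns contribute one per
    extra state, plus one when the outgroup state is absent from the
    ingroup); eta_e counts derived singletons.  Columns where the outgroup
    is missing are excluded.
    """
    n = aln.n
    if n < 3:
        raise AlignmentError("fu_li_d requires at least three sequences")
    if len(outgroup) != aln.L:
        raise AlignmentError("outgroup length does not match the alignment")
    outgroup = outgroup.upper()
    eta = 0
    eta_e = 0
    mat = aln.matrix
    for c, (nv, counts) in enumerate(_column_counts(mat)):
        anc = outgroup[c]
        if anc in MISSING or nv < 2:
            continue
        if len(counts) < 2:
            # monomorphic ingroup columns carry no within-sample mutation
            continue
        eta += len(counts) - 1 if anc in counts else len(counts)
        eta_e += sum(1 for state, cnt in counts.items() if cnt == 1 and state != anc)
    if eta == 0:
        return math.nan
    a_n = _harmonic(n)
    b_n = _harmonic(n, 2)
    c_n = 2 * (n * a_n - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v_D = 1 + (a_n**2 / (b_n + a_n**2)) * (c_n - (n + 1) / (n - 1))
    u_D = a_n - 1 - v_D
    return (eta - a_n * eta_e) / math.sqrt(u_D * eta + v_D * eta**2)


def fst_two_groups(aln: Alignment, labels: dict[str, str] | list[str]) -> float:
    """Hudson, Slatkin & Maddison (1992) F_ST = 1 - Hw/Hb for two groups.

    Hw is the mean pairwise difference count within groups (pooled over
    both groups' pairs), Hb the mean between groups; pairwise deletion.
    """
    if isinstance(labels, dict):
        lab = [labels[nm] for nm in aln.names]
    else:
        lab = list(labels)
    groups = sorted(set(lab))
    if len(groups) != 2:
        raise AlignmentError(f"need exactly two groups, got {groups}")
    idx = {g: [i for i, l in enumerate(lab) if l == g] for g in groups}
    if min(len(v) for v in idx.values()) < 1:
        raise AlignmentError("each group needs at least one member")
    mat = aln.matrix
    valid = ~np.isin(mat, list(MISSING))

    def dist(i, j):
        both = valid[i] & valid[j]
        return float(np.sum((mat[i] != mat[j]) & both))

    g1, g2 = idx[groups[0]], idx[groups[1]]
    within = [dist(i, j) for g in (g1, g2) for a, i in enumerate(g) for j in g[a + 1 :]]
    between = [dist(i, j) for i in g1 for j in g2]
    if not between:
        raise AlignmentError("no between-group pairs")
    Hb = float(np.mean(between))
    if not within:
        raise AlignmentError("no within-group pairs; need a group of size >= 2")
    Hw = float(np.mean(within))
    if Hb == 0:
        return 0.0
    return 1.0 - Hw / Hb


def classify_cross_locus(
    aln_A: Alignment, aln_B: Alignment, outgroup: str
) -> SharedPrivateSpectrum:
    """Classify homologous columns as shared / private / fixed polymorphisms.

    Shared: segregating in both loci; private: segregating in exactly one;
    fixed: monomorphic in both for different states.  Derived states
    (relative to the outgroup) populate the frequency spectra -- pooled
    derived counts for shared columns, per-locus counts for private ones.
    Columns with a missing outgroup state or fewer than two non-missing
    alleles in either locus are excluded.
    """
    if aln_A.L != aln_B.L or len(outgroup) != aln_A.L:
        raise AlignmentError("loci and outgroup must share homologous coordinates")
    outgroup = outgroup.upper()
    res = SharedPrivateSpectrum()
    it = zip(_column_counts(aln_A.matrix), _column_counts(aln_B.matrix))
    for c, ((nvA, cntA), (nvB, cntB)) in enumerate(it):
        if nvA < 2 or nvB < 2:
            continue
        anc = outgroup[c]
        if anc in MISSING:
            continue
        segA = len(cntA) > 1
        segB = len(cntB) > 1
        derived_A = sum(v for s, v in cntA.items() if s != anc)
        derived_B = sum(v for s, v in cntB.items() if s != anc)
        if segA and segB:
            res.n_shared += 1
            res.spectrum_shared[derived_A + derived_B] += 1
        elif segA:
            res.n_private_A += 1
            res.spectrum_private_A[derived_A] += 1
        elif segB:
            res.n_private_B += 1
            res.spectrum_private_B[derived_B] += 1
        else:
            stateA = next(iter(cntA))
            stateB = next(iter(cntB))
            if stateA != stateB:
                res.n_fixed += 1
    return res


def sliding(aln: Alignment, stat, window: int, step: int):
    """Evaluate ``stat`` on windows [start, start+window-1] advancing by step.

    Returns a list of (midpoint, value); undefined windows carry NaN.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if window > aln.L:
        raise ValueError("window exceeds alignment length")
    out = []
    start = 1
    while start + window - 1 <= aln.L:
        sub = aln.columns(start, start + window - 1)
        try:
            val = stat(sub)
        except AlignmentError:
            val = math.nan
        out.append((start + (window - 1) / 2.0, float(val)))
        start += step
    return out


# ---------------------------------------------------------------------------
# binary (simulated-replicate) fast path


def _binary_locus_stats(mat: np.ndarray, L: int):
    """(S, pi_total, pi_site, theta_W_site, D) for a 0/1 haplotype matrix."""
    n = mat.shape[0]
    if n < 2:
        return 0, 0.0, 0.0, 0.0, math.nan
    counts = mat.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    pairs = n * (n - 1) / 2
    pi_total = float(np.sum(counts * (n - counts)) / pairs)
    a_n = _harmonic(n)
    return (
        S,
        pi_total,
        pi_total / L,
        S / (a_n * L),
        tajimas_d_from_counts(n, S, pi_total),
    )


def summary_vector(
    data: SimReplicate | tuple[Alignment, Alignment],
    outgroup: str | None = None,
) -> SummaryVector:
    """Bundle the per-locus and cross-locus statistics for ABC.

    Accepts either a simulated replicate (binary fast path; the ancestral
    state is known, so no outgroup is needed) or a pair of observed
    alignments plus an outgroup sequence for the cross-locus classes.
    """
    if isinstance(data, SimReplicate):
        rep = data
        A, B = rep.haplotypes_A, rep.haplotypes_B
        S_A, pit_A, pis_A, tw_A, D_A = _binary_locus_stats(A, rep.L)
        S_B, pit_B, pis_B, tw_B, D_B = _binary_locus_stats(B, rep.L)
        cA = A.sum(axis=0)
        cB = B.sum(axis=0)
        nA, nB = A.shape[0], B.shape[0]
        segA = (cA > 0) & (cA < nA)
        segB = (cB > 0) & (cB < nB)
        monoA = ~segA
        monoB = ~segB
        fixed = monoA & monoB & ((cA == nA) != (cB == nB))
        return SummaryVector(
            S_A=S_A,
            S_B=S_B,
            pi_A=pis_A,
            pi_B=pis_B,
            pi_total_A=pit_A,
            pi_total_B=pit_B,
            theta_W_A=tw_A,
            theta_W_B=tw_B,
            D_A=D_A,
            D_B=D_B,
            n_shared=float(np.sum(segA & segB)),
            n_private_A=float(np.sum(segA & monoB)),
            n_private_B=float(np.sum(segB & monoA)),
            n_fixed=float(np.sum(fixed)),
        )
    aln_A, aln_B = data
    pit_A, pis_A = pi(aln_A)
    pit_B, pis_B = pi(aln_B)
    sv = SummaryVector(
        S_A=_segregating(aln_A.matrix),
        S_B=_segregating(aln_B.matrix),
        pi_A=pis_A,
        pi_B=pis_B,
        pi_total_A=pit_A,
        pi_total_B=pit_B,
        theta_W_A=watterson(aln_A),
        theta_W_B=watterson(aln_B),
        D_A=tajimas_d(aln_A),
        D_B=tajimas_d(aln_B),
    )
    if outgroup is not None:
        cls = classify_cross_locus(aln_A, aln_B, outgroup)
        sv.n_shared = float(cls.n_shared)
        sv.n_private_A = float(cls.n_private_A)
        sv.n_private_B = float(cls.n_private_B)
        sv.n_fixed = float(cls.n_fixed)
    return sv
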