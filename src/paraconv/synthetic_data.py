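"""Synthetic gene-family datasets with the structure the analysis assumes.

The generator emulates the observed panel: two paralogous loci sampled
with 14 and 9 alleles, a ~1 kb gene (900 bp coding, one 100 bp intron),
two deeply
differentiated intron-linked "sequence types" segregating at both loci at
intermediate frequency, a few pseudogene alleles carrying frameshifts or
premature stops, an outgroup sequence carrying the ancestral states, and
four phenotype classes driven by designated causal SNPs (an
AVR2-insensitivity site and a weak-HR site).

Haplotypes come from the neutral duplicated-locus coalescent
(:mod:`paraconv.coalsim`); the sequence-type dimorphism is overlaid
deterministically on the simulated genealogies rather than arising from
simulated selection -- the downstream analysis needs data *shaped like*
the observation, and forward simulation of balancing selection is out of
scope.  Default rates are the observed ones: theta = 0.0085 per site and
a conversion rate C = 1.08 per site with 500 bp mean tracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalsim import SimParams, simulate
from .seq_model import Alignment
from .sumstats import _binary_locus_stats

__all__ = [
    "SyntheticTruth",
    "generate_gene_family",
    "generate_phenotypes",
    "combine_loci",
    "split_loci",
    "reference_panel",
    "metadata_table",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate and grade a synthetic dataset."""

    params: SimParams
    seed: int | None
    orf_start: int
    intron: tuple[int, int]
    base_seq: str
    locus: dict = field(default_factory=dict)  # allele id -> "A"/"B"
    seq_type: dict = field(default_factory=dict)  # allele id -> "1"/"2"
    pseudogenes: dict = field(default_factory=dict)  # allele id -> reason
    type_columns: list = field(default_factory=list)
    causal_sites: dict = field(default_factory=dict)  # contrast -> position


def _random_orf_with_intron(rng, exon1_codons=100, intron_len=100, exon2_codons=200):
    """Random valid reading frame with one intron between two exons.

    Coding sequence ends in a single terminal TAA; the intron starts GT
    and ends AG.  Returns (sequence, orf_start, intron_interval).
    """
    codons = []
    n_codons = exon1_codons + exon2_codons
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    coding = "".join(codons)
    intron = "GT" + "".join(rng.choice(list(_BASES), size=intron_len - 4)) + "AG"
    cut = exon1_codons * 3
    seq = coding[:cut] + intron + coding[cut:]
    return seq, 1, (cut + 1, cut + intron_len)


def _codon_of(pos: int, orf_start: int, intron: tuple[int, int]) -> tuple[int, int] | None:
    """(codon index, offset) of a 1-based alignment position, or None if
    the position is intronic / upstream of the ORF."""
    if pos < orf_start or intron[0] <= pos <= intron[1]:
        return None
    cds_pos = pos - orf_start
    if pos > intron[1]:
        cds_pos -= intron[1] - intron[0] + 1
    return cds_pos // 3, cds_pos % 3


def _safe_alt(base_seq: str, pos: int, orf_start, intron, rng, n_codons: int) -> str:
    """Alternative base at a position that does not create a stop codon in
    the base-sequence context (terminal codon excluded from the check)."""
    ref = base_seq[pos - 1]
    loc = _codon_of(pos, orf_start, intron)
    choices = [b for b in _BASES if b != ref]
    rng.shuffle(choices)
    if loc is None or loc[0] >= n_codons - 1:
        return choices[0]
    ci, off = loc
    codon_start = pos - off  # 1-based position of the codon's first base
    # reconstruct the codon in alignment coordinates (codons never span the intron)
    codon = list(base_seq[codon_start - 1 : codon_start + 2])
    for b in choices:
        codon[off] = b
        if "".join(codon) not in _STOPS:
            return b
    return choices[0]


def generate_gene_family(
    n_A: int = 14,
    n_B: int = 9,
    theta: float = 0.0085,
    C: float = 1.08,
    lambda_tract: float = 500.0,
    t_dup: float = 1.0,
    growth_factor: float = 1.0,
    t_exp: float = 0.0,
    type_divergence: float = 0.05,
    type_freq: float = 0.5,
    pseudogene_count: int = 2,
    seed=None,
):
    """Generate one synthetic gene-family dataset.

    Returns (aln_A, aln_B, outgroup_seq, truth).  ``type_divergence`` is the
    per-site divergence between the two intron haplotypes; ``type_freq``
    the sequence-type-2 frequency within each locus; pseudogene alleles
    receive alternating premature-stop / frameshift lesions.
    """
    rng = np.random.default_rng(seed)
    base, orf_start, intron = _random_orf_with_intron(rng)
    L = len(base)
    n_codons = (L - (intron[1] - intron[0] + 1)) // 3
    params = SimParams(
        n_A=n_A,
        n_B=n_B,
        L=L,
        theta=theta,
        C=C,
        lambda_tract=lambda_tract,
        t_dup=t_dup,
        growth_factor=growth_factor,
        t_exp=t_exp,
    )
    if pseudogene_count < 0 or pseudogene_count > n_A + n_B:
        raise ValueError("pseudogene_count outside 0..n_A+n_B")
    rep = simulate(params, rng=rng)
    n = n_A + n_B
    names = [f"A{i + 1:02d}" for i in range(n_A)] + [f"B{i + 1:02d}" for i in range(n_B)]
    seqs = np.array([list(base) for _ in range(n)])

    # map the 0/1 haplotypes onto nucleotides: 0 = base, 1 = alternative
    alt_of: dict[int, str] = {}
    for j, pos in enumerate(rep.positions):
        alt = _safe_alt(base, int(pos), orf_start, intron, rng, n_codons)
        alt_of[int(pos)] = alt
        carriers = rep.genotypes[:, j] == 1
        seqs[carriers, pos - 1] = alt

    # repair rare premature stops created by two hits in the same codon
    from .seq_model import flag_pseudogenes  # local import avoids a cycle

    for _ in range(20):
        aln_tmp = Alignment(list(names), ["".join(row) for row in seqs])
        flags = flag_pseudogenes(aln_tmp, orf_start, intron)
        bad = [nm for nm, (fl, _) in flags.items() if fl]
        if not bad:
            break
        row = names.index(bad[0])
        redone = False
        for j, pos in enumerate(rep.positions):
            pos = int(pos)
            loc = _codon_of(pos, orf_start, intron)
            if loc is None or loc[0] >= n_codons - 1:
                continue
            if rep.genotypes[row, j] != 1:
                continue
            ci, off = loc
            codon_start = pos - off
            codon = "".join(seqs[row, codon_start - 1 : codon_start + 2])
            if codon in _STOPS:
                new_alt = _safe_alt(base, pos, orf_start, intron, rng, n_codons)
                carriers = rep.genotypes[:, j] == 1
                seqs[carriers, pos - 1] = new_alt
                alt_of[pos] = new_alt
                redone = True
                break
        if not redone:
            break

    truth = SyntheticTruth(
        params=params,
        seed=seed,
        orf_start=orf_start,
        intron=intron,
        base_seq=base,
        locus={nm: ("A" if i < n_A else "B") for i, nm in enumerate(names)},
    )

    # sequence-type overlay: a divergent intron haplotype at intermediate
    # frequency within each locus, deterministic at the type columns
    intron_cols = np.arange(intron[0], intron[1] + 1)
    ndiff = max(1, round(type_divergence * len(intron_cols)))
    type_cols = sorted(rng.choice(intron_cols, size=min(ndiff, len(intron_cols)), replace=False))
    truth.type_columns = [int(c) for c in type_cols]
    type2: set[str] = set()
    for lo, nm_range in (("A", names[:n_A]), ("B", names[n_A:])):
        k = round(type_freq * len(nm_range))
        chosen = rng.choice(len(nm_range), size=k, replace=False) if k else []
        type2.update(nm_range[i] for i in chosen)
    truth.seq_type = {nm: ("2" if nm in type2 else "1") for nm in names}
    if ndiff > 0 and type_divergence > 0:
        for pos in type_cols:
            alt = _safe_alt(base, int(pos), orf_start, intron, rng, n_codons)
            for i, nm in enumerate(names):
                seqs[i, pos - 1] = alt if nm in type2 else base[pos - 1]

    # pseudogene lesions
    pseudo_idx = rng.choice(n, size=pseudogene_count, replace=False) if pseudogene_count else []
    for j, i in enumerate(sorted(int(x) for x in np.atleast_1d(pseudo_idx))):
        nm = names[i]
        if j % 2 == 0:
            ci = int(rng.integers(10, n_codons - 10))
            # position of the codon's first base in alignment coordinates
            cds_start = ci * 3
            pos0 = orf_start + cds_start
            if pos0 >= intron[0]:
                pos0 += intron[1] - intron[0] + 1
            seqs[i, pos0 - 1 : pos0 + 2] = list("TAA")
            truth.pseudogenes[nm] = "premature stop"
        else:
            while True:
                pos = int(rng.integers(orf_start + 15, L - 15))
                if not (intron[0] <= pos <= intron[1]) and seqs[i, pos - 1] != "-":
                    break
            seqs[i, pos - 1] = "-"
            truth.pseudogenes[nm] = "frameshift"

    aln = Alignment(list(names), ["".join(row) for row in seqs])
    aln_A = Alignment(names[:n_A], aln.seqs[:n_A])
    aln_B = Alignment(names[n_A:], aln.seqs[n_A:])
    return aln_A, aln_B, base, truth


def combine_loci(aln_A: Alignment, aln_B: Alignment) -> Alignment:
    return Alignment(list(aln_A.names) + list(aln_B.names), list(aln_A.seqs) + list(aln_B.seqs))


def split_loci(aln: Alignment, truth: SyntheticTruth) -> tuple[Alignment, Alignment]:
    names_A = [nm for nm in aln.names if truth.locus.get(nm) == "A"]
    names_B = [nm for nm in aln.names if truth.locus.get(nm) == "B"]
    return aln.subset(names_A), aln.subset(names_B)


def generate_phenotypes(
    aln: Alignment,
    truth: SyntheticTruth,
    causal_sites: dict | None = None,
    penetrance: float = 1.0,
    misclassification_rate: float = 0.0,
    causal_freq: float = 0.35,
    seed=None,
) -> tuple[pd.DataFrame, Alignment]:
    """Assign the four phenotype classes, optionally planting causal SNPs.

    Class I (no protein) goes to pseudogene alleles; class II to carriers
    of the designated AVR2-insensitivity allele; carriers of the weak-HR
    allele among the remainder become class III, the rest class IV --
    each causal effect applies with probability ``penetrance``.  With
    ``causal_sites`` omitted, two fresh biallelic sites are planted at
    monomorphic exonic columns with carrier frequency ``causal_freq``
    (drawn among expressed alleles), so the causal pattern is unlinked to
    the genealogy.  Labels of expressed alleles are then randomized with
    probability ``misclassification_rate``.  Returns (phenotype table,
    alignment including any planted sites).
    """
    if not (0.0 <= penetrance <= 1.0 and 0.0 <= misclassification_rate <= 1.0):
        raise ValueError("penetrance and misclassification_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = list(aln.names)
    expressed = [nm for nm in names if nm not in truth.pseudogenes]
    seqs = np.array([list(s) for s in aln.seqs])
    L = aln.L
    n_codons = (L - (truth.intron[1] - truth.intron[0] + 1)) // 3

    if causal_sites is None:
        causal_sites = {}
        mono = [
            p
            for p in range(1, L + 1)
            if _codon_of(p, truth.orf_start, truth.intron) is not None
            and len(set(seqs[:, p - 1])) == 1
            and seqs[0, p - 1] != "-"
        ]
        picks = rng.choice(len(mono), size=2, replace=False)
        k = max(2, round(causal_freq * len(names)))
        for contrast, pi in zip(("avr2", "hr"), picks):
            pos = mono[int(pi)]
            alt = _safe_alt(truth.base_seq, pos, truth.orf_start, truth.intron, rng, n_codons)
            carriers = rng.choice(len(expressed), size=min(k, len(expressed)), replace=False)
            for ci in carriers:
                seqs[names.index(expressed[int(ci)]), pos - 1] = alt
            causal_sites[contrast] = pos
    truth.causal_sites = dict(causal_sites)

    def carries_minor(nm: str, pos: int) -> bool:
        col = seqs[:, pos - 1]
        states, counts = np.unique(col[col != "-"], return_counts=True)
        if len(states) < 2:
            return False
        minor = states[np.argmin(counts)]
        return seqs[names.index(nm), pos - 1] == minor

    classes = {}
    for nm in names:
        if nm in truth.pseudogenes:
            classes[nm] = "I"
            continue
        if carries_minor(nm, causal_sites["avr2"]) and rng.random() < penetrance:
            classes[nm] = "II"
        elif carries_minor(nm, causal_sites["hr"]) and rng.random() < penetrance:
            classes[nm] = "III"
        else:
            classes[nm] = "IV"
    for nm in names:
        if classes[nm] != "I" and rng.random() < misclassification_rate:
            classes[nm] = str(rng.choice(["II", "III", "IV"]))

    table = pd.DataFrame(
        {"allele_id": names, "phenotype_class": [classes[nm] for nm in names]}
    )
    new_aln = Alignment(names, ["".join(row) for row in seqs])
    return table, new_aln


def reference_panel(
    theta: float,
    growth_factor: float,
    t_exp: float,
    n: int = 10,
    L: int = 1200,
    n_loci: int = 14,
    seed=None,
) -> list[tuple[float, float, float]]:
    """(S, pi per site, Tajima's D) for a panel of independent single-copy
    loci under the stepwise-expansion demography -- the synthetic analogue
    of the 14 sequenced reference loci."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_loci):
        rep = simulate(
            SimParams(
                n_A=n, n_B=0, L=L, theta=theta, growth_factor=growth_factor,
                t_exp=t_exp, t_dup=1.0,
            ),
            rng=rng,
        )
        S, _, pi_site, _, D = _binary_locus_stats(rep.haplotypes_A, L)
        out.append((float(S), float(pi_site), float(D)))
    return out


def metadata_table(truth: SyntheticTruth, phenotypes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Allele metadata TSV contents (allele_id, species, locus, seq_type,
    pseudogene, phenotype_class)."""
    names = list(truth.locus)
    pheno = (
        dict(zip(phenotypes["allele_id"], phenotypes["phenotype_class"]))
        if phenotypes is not None
        else {}
    )
    return pd.DataFrame(
        {
            "allele_id": names,
            "species": ["synthetic"] * len(names),
            "locus": [truth.locus[nm] for nm in names],
            "seq_type": [truth.seq_type.get(nm, "unassigned") for nm in names],
            "pseudogene": [nm in truth.pseudogenes for nm in names],
            "phenotype_class": [pheno.get(nm, "") for nm in names],
        }
    )
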