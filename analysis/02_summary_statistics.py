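"""Summary statistics of the allele panel.

Excludes pseudogenes, assigns intron-based sequence types, and computes:
per-locus diversity and neutrality statistics, per-type diversity, the
fixation index between sequence types, the shared/private/fixed
classification of polymorphisms across the two paralogs, and a sliding
window of Tajima's D.  Writes results/summary_stats.tsv and
results/cross_locus_spectrum.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from paraconv.seq_model import assign_sequence_types, read_fasta_alignment
from paraconv.sumstats import (
    classify_cross_locus,
    fst_two_groups,
    fu_li_d,
    pi,
    sliding,
    tajimas_d,
    watterson,
)
from paraconv.synthetic_data import combine_loci


def main(out_dir: Path) -> None:
    data = out_dir / "data"
    truth = json.loads((data / "truth.json").read_text())
    aln_A = read_fasta_alignment(data / "locus_A.fasta")
    aln_B = read_fasta_alignment(data / "locus_B.fasta")
    og = read_fasta_alignment(data / "outgroup.fasta").seqs[0]
    pseudo = set(truth["pseudogenes"])

    aln_A = aln_A.subset([nm for nm in aln_A.names if nm not in pseudo])
    aln_B = aln_B.subset([nm for nm in aln_B.names if nm not in pseudo])
    comb = combine_loci(aln_A, aln_B)

    rows = []
    for label, aln in (("locus_A", aln_A), ("locus_B", aln_B)):
        pi_total, pi_site = pi(aln)
        rows.append(
            dict(unit=label, n=aln.n, pi_site=pi_site, theta_W=watterson(aln),
                 tajimas_D=tajimas_d(aln), fu_li_D=fu_li_d(aln, og))
        )

    types = assign_sequence_types(comb, tuple(truth["intron"]))
    for t in ("1", "2"):
        members = [nm for nm, lab in types.items() if lab == t]
        sub = comb.subset(members)
        rows.append(dict(unit=f"seq_type_{t}", n=sub.n, pi_site=pi(sub)[1],
                         theta_W=watterson(sub), tajimas_D=tajimas_d(sub)))
    fst = fst_two_groups(comb, types)
    rows.append(dict(unit="between_types", n=comb.n, fst=fst))

    stats = pd.DataFrame(rows)
    stats.to_csv(out_dir / "summary_stats.tsv", sep="\t", index=False)

    cls = classify_cross_locus(aln_A, aln_B, og)
    spec_rows = []
    for name, counter in (
        ("shared", cls.spectrum_shared),
        ("private_A", cls.spectrum_private_A),
        ("private_B", cls.spectrum_private_B),
    ):
        for freq, count in sorted(counter.items()):
            spec_rows.append(dict(cls=name, derived_count=freq, n_columns=count))
    spec_rows.append(dict(cls="fixed", derived_count=-1, n_columns=cls.n_fixed))
    pd.DataFrame(spec_rows).to_csv(out_dir / "cross_locus_spectrum.tsv", sep="\t", index=False)

    windows = sliding(comb, tajimas_d, window=100, step=25)
    pd.DataFrame(windows, columns=["midpoint", "tajimas_D"]).to_csv(
        out_dir / "sliding_tajimas_d.tsv", sep="\t", index=False
    )

    print(stats.to_string(index=False))
    print(f"\nF_ST between sequence types: {fst:.3f}")
    print(f"cross-locus classes: shared={cls.n_shared} private_A={cls.n_private_A} "
          f"private_B={cls.n_private_B} fixed={cls.n_fixed}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    main(ap.parse_args().out)
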