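"""Generate the synthetic allele panel the downstream analyses run on.

Emulates the observed data: 14 locus-A and 9 locus-B alleles of a ~1 kb
gene with one intron, two intron-linked sequence types at intermediate
frequency, two pseudogene alleles, an outgroup carrying ancestral states,
four phenotype classes driven by two planted causal SNPs, and a panel of
14 single-copy reference loci sequenced in the same population (used for
demographic calibration).  Writes FASTA/TSV/JSON under results/data/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from paraconv.seq_model import Alignment, write_fasta
from paraconv.synthetic_data import (
    combine_loci,
    generate_gene_family,
    generate_phenotypes,
    metadata_table,
    reference_panel,
    split_loci,
)

# generating conditions: observed mutation and conversion rates at the gene
# (theta = 0.0085/site, C = 1.08/site), 500 bp mean tracts; reference-locus
# panel at theta = 0.014/site under a five-fold stepwise expansion
GENE_PARAMS = dict(n_A=14, n_B=9, theta=0.0085, C=1.08, lambda_tract=500.0, t_dup=1.0)
REF_PARAMS = dict(theta=0.014, growth_factor=5.0, t_exp=0.5, n=10, L=1200, n_loci=14)


def main(seed: int, out_dir: Path) -> None:
    out = out_dir / "data"
    out.mkdir(parents=True, exist_ok=True)

    aln_A, aln_B, og, truth = generate_gene_family(seed=seed, pseudogene_count=2, **GENE_PARAMS)
    pheno, combined = generate_phenotypes(combine_loci(aln_A, aln_B), truth, seed=seed + 1)
    aln_A, aln_B = split_loci(combined, truth)

    write_fasta(aln_A, out / "locus_A.fasta")
    write_fasta(aln_B, out / "locus_B.fasta")
    write_fasta(Alignment(["outgroup"], [og]), out / "outgroup.fasta")
    metadata_table(truth, pheno).to_csv(out / "metadata.tsv", sep="\t", index=False)
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)

    ref = reference_panel(seed=seed + 2, **REF_PARAMS)
    pd.DataFrame(ref, columns=["S", "pi_site", "tajimas_D"]).to_csv(
        out / "reference_loci.tsv", sep="\t", index=False
    )

    config = {
        "seed": seed,
        "gene": GENE_PARAMS,
        "reference_panel": REF_PARAMS,
        "orf_start": truth.orf_start,
        "intron": list(truth.intron),
        "pseudogenes": truth.pseudogenes,
        "seq_type_truth": truth.seq_type,
        "causal_sites": truth.causal_sites,
        "type_columns": truth.type_columns,
    }
    (out / "truth.json").write_text(json.dumps(config, indent=2))
    print(f"wrote {aln_A.n}+{aln_B.n} alleles (L={aln_A.L}), "
          f"{len(truth.pseudogenes)} pseudogenes, causal sites {truth.causal_sites}")
    print(f"reference panel: {len(ref)} loci -> {out}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.seed, args.out)
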