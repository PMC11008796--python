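"""Export of simulated cohorts: phased VCF, pedigree table, per-locus TSV."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_map import LinkageMap
from .pop_sim import Population

__all__ = ["export_vcf", "export_pedigree", "gwas_result_tsv"]


def export_vcf(pop: Population, gmap: LinkageMap, path, sample_prefix: str = "ind") -> None:
    """Write the cohort's phased genotypes as a minimal VCFv4.2 text file.

    One biallelic record per locus (REF=A for the non-focal allele, ALT=T for
    the focal allele), phased GT fields, contig headers from the map.
    """
    n, _, L = pop.haps.shape
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    gt = np.char.add(np.char.add(pop.haps[:, 0, :].astype("U1"), "|"),
                     pop.haps[:, 1, :].astype("U1"))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gwasconf\n")
        for c in np.unique(gmap.chrom):
            length = int(gmap.bp[gmap.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for l in range(L):
            row = [str(gmap.chrom[l]), str(int(gmap.bp[l])), f"locus{l}",
                   "A", "T", ".", "PASS", ".", "GT"]
            fh.write("\t".join(row) + "\t" + "\t".join(gt[:, l]) + "\n")


def export_pedigree(pop: Population, path, id_prefix: str = "ind",
                    parent_prefix: str = "par") -> None:
    """Three-column text pedigree: id, mother, father (0 for founders)."""
    rows = []
    for i in range(pop.n):
        m = f"{parent_prefix}{pop.mother[i]}" if pop.mother[i] >= 0 else "0"
        f = f"{parent_prefix}{pop.father[i]}" if pop.father[i] >= 0 else "0"
        rows.append((f"{id_prefix}{i}", m, f))
    pd.DataFrame(rows, columns=["id", "mother", "father"]).to_csv(
        path, sep="\t", index=False)


def gwas_result_tsv(result, path, gmap=None, alpha_true=None) -> None:
    """Per-locus GWAS result table (locus, chrom, p_hat, estimates, mask)."""
    result.to_frame(gmap=gmap, alpha_true=alpha_true).to_csv(path, sep="\t", index=False)
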