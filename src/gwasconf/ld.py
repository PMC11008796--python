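"""Cis- and trans-linkage disequilibrium from phased population data.

Two alleles at different loci are in *cis*-LD when they covary within the
haploid genome inherited from one parent, and in *trans*-LD when an allele
inherited from one parent covaries with an allele at the other locus
inherited from the other parent.  All covariances here are population
covariances (divisor n) across individuals, matching infinite-population
theory; at simulated sample sizes the n vs n-1 distinction is immaterial.

Monomorphic loci yield undefined correlations/inbreeding coefficients; LD
entries involving them are reported as 0 and flagged in ``mask`` rather than
dropped, so matrix shapes stay stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "LDSummary",
    "cis_ld",
    "trans_ld",
    "allelic_correlations",
    "double_het_fractions",
    "inbreeding_F",
    "het_fraction",
    "ld_summary",
]


def _check_phased(haps: np.ndarray) -> np.ndarray:
    haps = np.asarray(haps)
    if haps.ndim != 3 or haps.shape[1] != 2:
        raise ValueError("phased haplotypes required: shape (n, 2, loci)")
    return haps.astype(float)


def _cov_pooled(x: np.ndarray, y: np.ndarray, p: np.ndarray) -> np.ndarray:
    # second moments about the pooled allele frequency, not the per-origin
    # mean: allele frequency is a property of the locus, and only with this
    # centering does D - D~ = (H_coup - H_rep)/2 hold exactly on finite data
    xc = x - p
    yc = y - p
    return xc.T @ yc / x.shape[0]


def cis_ld(haps: np.ndarray) -> np.ndarray:
    """Within-origin allelic covariance matrix D.

    Mean over the two parental origins of the covariance, across individuals,
    between allele indicators at each locus pair within one haploid genome
    (centred on the pooled allele frequency).  Diagonal entries equal the
    Bernoulli variances p(1-p) of the pooled frequencies exactly.
    """
    h = _check_phased(haps)
    p = h.mean(axis=(0, 1))
    return 0.5 * (_cov_pooled(h[:, 0], h[:, 0], p) + _cov_pooled(h[:, 1], h[:, 1], p))


def trans_ld(haps: np.ndarray) -> np.ndarray:
    """Across-origin allelic covariance matrix D-tilde (symmetrised).

    Mean over the two orderings of the covariance between the maternal allele
    at one locus and the paternal allele at the other, centred on the pooled
    allele frequency.
    """
    h = _check_phased(haps)
    p = h.mean(axis=(0, 1))
    c = _cov_pooled(h[:, 0], h[:, 1], p)
    return 0.5 * (c + c.T)


def allelic_correlations(D: np.ndarray) -> np.ndarray:
    """Correlation version of an allelic covariance matrix (0 where undefined)."""
    v = np.sqrt(np.abs(np.diag(D)))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = D / np.outer(v, v)
    return np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)


def double_het_fractions(haps: np.ndarray):
    """Coupling and repulsion double-heterozygote fractions per locus pair.

    A parent heterozygous at both loci is *coupling* if the focal alleles sit
    on the same haploid genome and *repulsion* if on opposite genomes.  On any
    phased data, (H_coup - H_rep) / 2 equals D' - D-tilde' exactly.
    """
    h = _check_phased(haps)
    het = h[:, 0] != h[:, 1]
    m1 = het * h[:, 0]          # heterozygous, focal allele on haplotype 0
    m0 = het * h[:, 1]          # heterozygous, focal allele on haplotype 1
    n = h.shape[0]
    coup = (m1.T @ m1 + m0.T @ m0) / n
    rep = (m1.T @ m0 + m0.T @ m1) / n
    return coup, rep


def het_fraction(haps: np.ndarray) -> np.ndarray:
    """Per-locus fraction of heterozygous individuals."""
    h = _check_phased(haps)
    return (h[:, 0] != h[:, 1]).mean(axis=0)


def inbreeding_F(genotypes: np.ndarray):
    """Wright's inbreeding coefficient per locus, F = 1 - H_obs / (2 p (1-p)).

    Returns (F, defined_mask); F is 0 where the locus is monomorphic (flagged
    False in the mask).
    """
    g = np.asarray(genotypes, dtype=float)
    p = g.mean(axis=0) / 2.0
    het = (g == 1).mean(axis=0)
    denom = 2.0 * p * (1.0 - p)
    ok = denom > 0
    F = np.zeros(p.size)
    F[ok] = 1.0 - het[ok] / denom[ok]
    return F, ok


@dataclass
class LDSummary:
    """LD state of a GWAS sample and of its parents."""

    D: np.ndarray
    D_tilde: np.ndarray
    D_prime_parents: np.ndarray
    D_tilde_prime_parents: np.ndarray
    r: np.ndarray
    r_tilde: np.ndarray
    F: np.ndarray
    H: np.ndarray
    H_coup: np.ndarray
    H_rep: np.ndarray
    mask: np.ndarray  # True where the locus is polymorphic in the sample

    def to_frame(self, threshold: float = 0.0) -> pd.DataFrame:
        """Long-format table of locus pairs with |D| or |D~| above threshold."""
        L = self.D.shape[0]
        iu, ju = np.triu_indices(L, 1)
        keep = (np.abs(self.D[iu, ju]) >= threshold) | (np.abs(self.D_tilde[iu, ju]) >= threshold)
        return pd.DataFrame({
            "locus_i": iu[keep],
            "locus_j": ju[keep],
            "D": self.D[iu, ju][keep],
            "D_tilde": self.D_tilde[iu, ju][keep],
            "r": self.r[iu, ju][keep],
            "r_tilde": self.r_tilde[iu, ju][keep],
        })

    def to_tsv(self, path, threshold: float = 0.0) -> None:
        self.to_frame(threshold).to_csv(path, sep="\t", index=False)


def _mask_fixed(D: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = D.copy()
    out[~mask, :] = 0.0
    out[:, ~mask] = 0.0
    return out


def ld_summary(sample_haps: np.ndarray, parent_haps: Optional[np.ndarray] = None) -> LDSummary:
    """Full LD summary of a phased sample (and, if given, of its parents)."""
    D = cis_ld(sample_haps)
    Dt = trans_ld(sample_haps)
    g = np.asarray(sample_haps).sum(axis=1)
    F, okF = inbreeding_F(g)
    mask = np.diag(D) + np.diag(Dt) > 0
    mask &= okF
    if parent_haps is None:
        parent_haps = sample_haps
    Dp = cis_ld(parent_haps)
    Dtp = trans_ld(parent_haps)
    coup, rep = double_het_fractions(parent_haps)
    return LDSummary(
        D=_mask_fixed(D, mask),
        D_tilde=_mask_fixed(Dt, mask),
        D_prime_parents=Dp,
        D_tilde_prime_parents=Dtp,
        r=allelic_correlations(D),
        r_tilde=allelic_correlations(Dt),
        F=F,
        H=het_fraction(parent_haps),
        H_coup=coup,
        H_rep=rep,
        mask=mask,
    )
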