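"""The three association-study designs and their summary metrics.

Per-locus estimates are simple (marginal) regressions with no covariates,
matching how effect sizes are read off in the simulations: the population
design regresses trait values on genotypes; the sibling design regresses
sibling differences in trait on sibling differences in genotype; the
parent-offspring design regresses the trait jointly on the transmitted and
untransmitted genotypes and reports the difference of the two coefficients
as the direct-effect estimate.

Zero-variance (monomorphic or uninformative) loci are masked, never silently
set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .pop_sim import Population, TraitArchitecture, sib_pairs

__all__ = [
    "GWASResult",
    "population_gwas",
    "sibling_gwas",
    "parent_offspring_gwas",
    "transmitted_untransmitted",
    "build_pgs",
    "sibling_pgs_regression",
    "summary_metrics",
    "one_sib_per_family",
]


@dataclass
class GWASResult:
    """Per-locus estimates from one design."""

    design: str
    alpha_hat: np.ndarray
    p_hat: np.ndarray
    mask: np.ndarray  # True where the estimate is defined
    alpha_hat_T: Optional[np.ndarray] = None
    alpha_hat_U: Optional[np.ndarray] = None

    def to_frame(self, gmap=None, alpha_true=None) -> pd.DataFrame:
        d = {
            "locus": np.arange(self.alpha_hat.size),
            "p_hat": self.p_hat,
            "alpha_hat": self.alpha_hat,
            "defined": self.mask,
        }
        if gmap is not None:
            d["chrom"] = gmap.chrom
        if alpha_true is not None:
            d["alpha_true"] = alpha_true
        if self.alpha_hat_T is not None:
            d["alpha_hat_T"] = self.alpha_hat_T
            d["alpha_hat_U"] = self.alpha_hat_U
        return pd.DataFrame(d)


def _marginal_slopes(x: np.ndarray, y: np.ndarray):
    """Per-column OLS slope of y on x (with intercept): Cov(x,y)/Var(x)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    vx = (xc * xc).mean(axis=0)
    cxy = xc.T @ yc / x.shape[0]
    ok = vx > 0
    slopes = np.zeros(x.shape[1])
    slopes[ok] = cxy[ok] / vx[ok]
    return slopes, ok


def population_gwas(genotypes: np.ndarray, phenotypes: np.ndarray) -> GWASResult:
    """Marginal regression of trait values on per-locus genotype counts."""
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    slopes, ok = _marginal_slopes(g, y)
    return GWASResult("population", slopes, g.mean(axis=0) / 2.0, ok)


def sibling_gwas(g_a, g_b, y_a, y_b) -> GWASResult:
    """Regression of sibling trait differences on sibling genotype differences."""
    dg = np.asarray(g_a, dtype=float) - np.asarray(g_b, dtype=float)
    dy = np.asarray(y_a, dtype=float) - np.asarray(y_b, dtype=float)
    slopes, ok = _marginal_slopes(dg, dy)
    p = (np.asarray(g_a, dtype=float) + np.asarray(g_b, dtype=float)).mean(axis=0) / 4.0
    return GWASResult("sibling", slopes, p, ok)


def transmitted_untransmitted(pop: Population, parent_pop: Population):
    """Transmitted and untransmitted genotypes, resolved from the pedigree.

    The transmitted genotype is the offspring's own; the untransmitted one is
    the midparental remainder g_m + g_f - g.  Phase plus pedigree make this
    exact (never statistically inferred).
    """
    if np.any(pop.mother < 0):
        raise ValueError("offspring population with recorded parents required")
    g = pop.genotypes().astype(np.int16)
    gpar = parent_pop.genotypes().astype(np.int16)
    gu = gpar[pop.mother] + gpar[pop.father] - g
    return g, gu


def parent_offspring_gwas(phenotypes, g_T, g_U) -> GWASResult:
    """Joint regression of trait on transmitted and untransmitted genotypes.

    Returns the two coefficients alpha_hat_T, alpha_hat_U per locus and their
    difference as the direct-effect estimate.  Loci where the two regressors
    are collinear (e.g. no heterozygous parents) are masked.
    """
    y = np.asarray(phenotypes, dtype=float)
    t = np.asarray(g_T, dtype=float)
    u = np.asarray(g_U, dtype=float)
    tc = t - t.mean(axis=0)
    uc = u - u.mean(axis=0)
    yc = y - y.mean()
    n = y.size
    stt = (tc * tc).mean(axis=0)
    suu = (uc * uc).mean(axis=0)
    stu = (tc * uc).mean(axis=0)
    sty = tc.T @ yc / n
    suy = uc.T @ yc / n
    det = stt * suu - stu * stu
    scale = np.maximum(stt * suu, 1e-300)
    ok = det > 1e-12 * scale
    aT = np.zeros(t.shape[1])
    aU = np.zeros(t.shape[1])
    aT[ok] = (suu[ok] * sty[ok] - stu[ok] * suy[ok]) / det[ok]
    aU[ok] = (stt[ok] * suy[ok] - stu[ok] * sty[ok]) / det[ok]
    return GWASResult(
        "parent_offspring", aT - aU, t.mean(axis=0) / 2.0, ok,
        alpha_hat_T=aT, alpha_hat_U=aU,
    )


def build_pgs(genotypes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Linear polygenic score: weighted sum of genotype counts."""
    g = np.asarray(genotypes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if g.shape[1] != w.size:
        raise ValueError("weights must align with genotyped loci")
    return g @ w


def sibling_pgs_regression(delta_pgs: np.ndarray, delta_pheno: np.ndarray):
    """Slope and covariance of sibling phenotype differences on PGS differences."""
    dp = np.asarray(delta_pgs, dtype=float)
    dy = np.asarray(delta_pheno, dtype=float)
    v = dp.var()
    if v <= 0:
        raise ValueError("degenerate PGS difference variance")
    cov = np.mean((dp - dp.mean()) * (dy - dy.mean()))
    return cov / v, cov


def one_sib_per_family(pop: Population, rng: np.random.Generator) -> np.ndarray:
    """Indices choosing one sibling at random from each sibship."""
    a, b = sib_pairs(pop)
    pick = rng.integers(0, 2, a.size)
    return np.where(pick == 0, a, b)


def summary_metrics(result: GWASResult, alpha_true: np.ndarray,
                    beta_hat: Optional[np.ndarray] = None,
                    loci: Optional[np.ndarray] = None) -> dict:
    """The three per-locus averages used to summarise confounding.

    mean bias E[alpha_hat - alpha], heterozygosity-weighted mean square
    E[2 p (1-p) alpha_hat^2], and (given a second trait's estimates) the
    heterozygosity-weighted cross product E[2 p (1-p) alpha_hat beta_hat].
    Heterozygosity uses sample allele frequencies, 2 p_hat (1 - p_hat).
    Masked loci are excluded; their count is reported.
    """
    sel = np.arange(result.alpha_hat.size) if loci is None else np.asarray(loci)
    ok = result.mask[sel]
    a = result.alpha_hat[sel][ok]
    p = result.p_hat[sel][ok]
    at = np.asarray(alpha_true, dtype=float)[sel][ok]
    w = 2.0 * p * (1.0 - p)
    out = {
        "mean_bias": float(np.mean(a - at)) if a.size else np.nan,
        "het_weighted_msq": float(np.mean(w * a * a)) if a.size else np.nan,
        "n_masked": int((~result.mask[sel]).sum()),
    }
    if beta_hat is not None:
        b = np.asarray(beta_hat, dtype=float)[sel][ok]
        out["het_weighted_cross"] = float(np.mean(w * a * b)) if a.size else np.nan
    return out
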