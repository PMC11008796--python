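"""Forward-in-time simulation of a phased diploid, monogamous population.

The population model: discrete generations, exact 1:1 sex ratio, monogamous
pairs, exactly two offspring per pair (full siblings), with brood sex
composition fixed so that a quarter of pairs have two daughters, a quarter
two sons, and half one of each.  Phenotypes are additive over loci,

    Y = Y* + sum_l g_l a_l^d  +  sum_l (g_l^m + g_l^f) a_l^i  +  eps,

where g_l counts focal (trait-increasing) alleles and eps ~ N(0, V_E).
Mating is random, or assortative via an iterative perturbed-rank-matching
algorithm that drives the mate score correlation to a target value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genome_map import LinkageMap

__all__ = [
    "Population",
    "TraitArchitecture",
    "MatingPlan",
    "ConvergenceError",
    "init_founders",
    "init_two_populations",
    "meiosis",
    "gametes",
    "random_mating_plan",
    "assortative_mating_plan",
    "make_next_generation",
    "compute_phenotypes",
    "apply_sibling_indirect",
    "stabilizing_selection",
    "sib_pairs",
    "merge_populations",
    "rng_for_replicate",
]

FEMALE, MALE = 0, 1


class ConvergenceError(RuntimeError):
    """The assortative-mating search failed to reach the target correlation."""


@dataclass
class Population:
    """Phased diploid cohort.

    ``haps`` has shape (n, 2, n_loci) with entries 0/1 counting the focal
    allele; for non-founders haplotype 0 is maternally and haplotype 1
    paternally inherited.  ``mother`` / ``father`` index the previous
    generation (-1 for founders).  Offspring of mating-plan pair j occupy
    rows 2j and 2j+1, so consecutive rows are full siblings.
    """

    haps: np.ndarray
    sex: np.ndarray
    mother: np.ndarray
    father: np.ndarray

    @property
    def n(self) -> int:
        return self.haps.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haps.shape[2]

    def genotypes(self) -> np.ndarray:
        """Focal-allele counts, shape (n, n_loci)."""
        return self.haps.sum(axis=1, dtype=np.int8)

    def freqs(self) -> np.ndarray:
        return self.haps.mean(axis=(0, 1))

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)


@dataclass
class TraitArchitecture:
    """Per-locus direct and parental (indirect) effects plus noise variance.

    The focal allele at each causal locus is the allele whose direct effect
    is non-negative, so ``alpha_d >= 0`` wherever it is nonzero.
    """

    loci: np.ndarray
    alpha_d: np.ndarray
    alpha_i: Optional[np.ndarray] = None
    V_E: float = 0.0
    Y_star: float = 0.0

    def __post_init__(self):
        self.loci = np.asarray(self.loci, dtype=np.int64)
        self.alpha_d = np.asarray(self.alpha_d, dtype=float)
        if self.alpha_i is None:
            self.alpha_i = np.zeros_like(self.alpha_d)
        self.alpha_i = np.asarray(self.alpha_i, dtype=float)
        if not (self.loci.size == self.alpha_d.size == self.alpha_i.size):
            raise ValueError("loci / effect arrays must align")
        if np.any(self.alpha_d < 0):
            raise ValueError("focal-allele convention requires alpha_d >= 0")
        if self.V_E < 0:
            raise ValueError("V_E must be non-negative")

    @property
    def has_indirect(self) -> bool:
        return bool(np.any(self.alpha_i != 0))


@dataclass
class MatingPlan:
    """Monogamous pairing of all females with all males."""

    female_idx: np.ndarray
    male_idx: np.ndarray
    achieved_rho: float = np.nan
    iterations: int = 0

    @property
    def n_pairs(self) -> int:
        return self.female_idx.size


def rng_for_replicate(seed: int, replicate: int) -> np.random.Generator:
    """Independent generator per replicate, replicate index folded into the seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def init_founders(n: int, freqs, rng: np.random.Generator) -> Population:
    """Founders at Hardy-Weinberg and linkage equilibrium.

    Every haplotype allele is an independent Bernoulli(freq) draw; sexes are
    assigned half/half at random.  ``n`` must be divisible by 4 so that the
    brood sex-ratio scheme has whole numbers of pairs per quartile.
    """
    if n % 4:
        raise ValueError("population size must be divisible by 4")
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    haps = (rng.random((n, 2, freqs.size)) < freqs).astype(np.uint8)
    sex = np.repeat([FEMALE, MALE], n // 2).astype(np.uint8)
    rng.shuffle(sex)
    none = np.full(n, -1, dtype=np.int64)
    return Population(haps, sex, none, none.copy())


def init_two_populations(n_loci: int, maf: float, fst: float,
                         rng: np.random.Generator):
    """Drift-like diverged allele frequencies for two populations.

    Ancestral frequencies are uniform on [maf, 1-maf]; each population's
    frequency is the ancestral value plus an independent Gaussian perturbation
    with variance 2 p (1-p) F_ST, clamped to [0, 1].  Returns
    (ancestral, freqs_pop1, freqs_pop2).
    """
    if fst < 0:
        raise ValueError("F_ST must be non-negative")
    pa = rng.uniform(maf, 1.0 - maf, size=n_loci)
    sd = np.sqrt(2.0 * pa * (1.0 - pa) * fst)
    p1 = np.clip(pa + rng.normal(0.0, 1.0, n_loci) * sd, 0.0, 1.0)
    p2 = np.clip(pa + rng.normal(0.0, 1.0, n_loci) * sd, 0.0, 1.0)
    return pa, p1, p2


def gametes(parent_haps: np.ndarray, gmap: LinkageMap, sex: str,
            rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent, vectorised over parents.

    Crossovers are interference-free: the transmitted haplotype starts from a
    fair coin per chromosome and switches between the parent's two haplotypes
    after each interval with probability equal to that interval's
    (sex-specific) recombination fraction.
    """
    switch = gmap.interval_switch_probs(sex).astype(np.float32)
    k = parent_haps.shape[0]
    flips = rng.random((k, switch.size), dtype=np.float32) < switch
    hap_idx = np.logical_xor.accumulate(flips, axis=1)
    return np.where(hap_idx, parent_haps[:, 1, :], parent_haps[:, 0, :])


def meiosis(parent_haps: np.ndarray, gmap: LinkageMap, rng: np.random.Generator,
            sex: str = "female") -> np.ndarray:
    """Single-parent convenience wrapper around :func:`gametes`."""
    return gametes(parent_haps[None, :, :], gmap, sex, rng)[0]


def random_mating_plan(pop: Population, rng: np.random.Generator) -> MatingPlan:
    """Uniform random monogamous matching of females to males."""
    f = pop.females()
    m = pop.males()
    if f.size != m.size:
        raise ValueError("unequal sex counts")
    return MatingPlan(rng.permutation(f), rng.permutation(m), achieved_rho=np.nan)


def _rank_match_corr(f_idx, f_scores, m_idx, m_scores, f_keys, m_keys):
    of = np.argsort(-f_keys, kind="stable")
    om = np.argsort(-m_keys, kind="stable")
    r = np.corrcoef(f_scores[of], m_scores[om])[0, 1]
    return r, f_idx[of], m_idx[om]


def assortative_mating_plan(pop: Population, female_scores, male_scores,
                            rho: float, epsilon: Optional[float] = None,
                            rng: Optional[np.random.Generator] = None,
                            max_iter: int = 500) -> MatingPlan:
    """Monogamous pairing with a target mate score correlation.

    Implements the perturbed rank-matching search: females are ranked on
    their (trait-1) scores and males on their (trait-2) scores.  If the
    rank-matching correlation rho_0 already falls below rho + epsilon the
    ranking is accepted outright.  Otherwise scores are perturbed with
    i.i.d. Gaussian noise of standard deviation xi before ranking; each
    candidate xi is tried 5 times (fresh noise, same xi) and the realisation
    whose true-score correlation is closest to the target is kept.  xi is
    then doubled / bisected / halved according to whether the last two
    achieved correlations sit above / straddle / below the target, starting
    from xi_0 = 4 (max - min of the pooled scores) and xi_1 = 2 xi_0,
    until |rho_k - rho| < epsilon.

    ``female_scores`` / ``male_scores`` are aligned with ``pop.females()`` /
    ``pop.males()``.  Default epsilon is rho / 100.
    """
    if not (-1.0 < rho < 1.0):
        raise ValueError("rho must lie in (-1, 1)")
    if epsilon is None:
        epsilon = abs(rho) / 100.0 if rho != 0 else 1e-3
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    f_idx, m_idx = pop.females(), pop.males()
    fs = np.asarray(female_scores, dtype=float)
    ms = np.asarray(male_scores, dtype=float)
    if fs.size != f_idx.size or ms.size != m_idx.size:
        raise ValueError("scores must align with the females/males of the population")

    rho0, pf, pm = _rank_match_corr(f_idx, fs, m_idx, ms, fs, ms)
    if rho0 < rho + epsilon:
        return MatingPlan(pf, pm, achieved_rho=float(rho0), iterations=0)

    pooled = np.concatenate([fs, ms])
    xi_prev = 4.0 * (pooled.max() - pooled.min())
    xi = 2.0 * xi_prev
    rho_prev = rho0
    for it in range(1, max_iter + 1):
        best = None
        for _ in range(5):
            fk = fs + rng.normal(0.0, xi, fs.size)
            mk = ms + rng.normal(0.0, xi, ms.size)
            r, cf, cm = _rank_match_corr(f_idx, fs, m_idx, ms, fk, mk)
            if best is None or abs(r - rho) < abs(best[0] - rho):
                best = (r, cf, cm)
        rho_k, pf, pm = best
        if abs(rho_k - rho) < epsilon:
            return MatingPlan(pf, pm, achieved_rho=float(rho_k), iterations=it)
        if rho_prev > rho and rho_k > rho:
            xi_next = 2.0 * xi
        elif rho_prev < rho and rho_k < rho:
            xi_next = xi / 2.0
        else:
            xi_next = 0.5 * (xi_prev + xi)
        xi_prev, xi, rho_prev = xi, xi_next, rho_k
    raise ConvergenceError(
        f"assortative mating did not reach rho={rho} within {max_iter} iterations"
    )


def make_next_generation(pop: Population, plan: MatingPlan, gmap: LinkageMap,
                         rng: np.random.Generator) -> Population:
    """Two full siblings per pair; population size is conserved.

    Pairs are randomly permuted before brood sex assignment: the first
    quarter produce two daughters, the next quarter two sons, and the
    remaining half a daughter and a son.
    """
    P = plan.n_pairs
    if P % 4:
        raise ValueError("number of pairs must be divisible by 4")
    perm = rng.permutation(P)
    mothers = plan.female_idx[perm]
    fathers = plan.male_idx[perm]

    mother_rep = np.repeat(mothers, 2)
    father_rep = np.repeat(fathers, 2)
    mat = gametes(pop.haps[mother_rep], gmap, "female", rng)
    pat = gametes(pop.haps[father_rep], gmap, "male", rng)
    haps = np.stack([mat, pat], axis=1)

    q = P // 4
    brood = np.empty((P, 2), dtype=np.uint8)
    brood[:q] = [FEMALE, FEMALE]
    brood[q:2 * q] = [MALE, MALE]
    brood[2 * q:] = [FEMALE, MALE]
    sex = brood.reshape(-1)
    return Population(haps, sex, mother_rep.astype(np.int64), father_rep.astype(np.int64))


def sib_pairs(pop: Population):
    """Row indices of first and second sibs (offspring populations only)."""
    if np.any(pop.mother < 0):
        raise ValueError("founder population has no sibships")
    a = np.arange(0, pop.n, 2)
    return a, a + 1


def merge_populations(pop1: Population, pop2: Population) -> Population:
    """Pool two cohorts into one admixed population (parent indices dropped)."""
    if pop1.n_loci != pop2.n_loci:
        raise ValueError("locus sets differ")
    haps = np.concatenate([pop1.haps, pop2.haps])
    sex = np.concatenate([pop1.sex, pop2.sex])
    none = np.full(haps.shape[0], -1, dtype=np.int64)
    return Population(haps, sex, none, none.copy())


def take(pop: Population, idx: np.ndarray) -> Population:
    """Sub-population of the given individuals (parent indices preserved)."""
    return Population(pop.haps[idx], pop.sex[idx], pop.mother[idx], pop.father[idx])


def compute_phenotypes(pop: Population, arch: TraitArchitecture,
                       rng: Optional[np.random.Generator] = None,
                       parent_pop: Optional[Population] = None) -> np.ndarray:
    """Additive phenotype of the cohort (direct + parental indirect + noise)."""
    g = pop.haps[:, :, arch.loci].sum(axis=1)
    y = arch.Y_star + g @ arch.alpha_d
    if arch.has_indirect:
        if parent_pop is None or np.any(pop.mother < 0):
            raise ValueError("parental genotypes required when indirect effects are nonzero")
        gpar = parent_pop.haps[:, :, arch.loci].sum(axis=1)
        y = y + (gpar[pop.mother] + gpar[pop.father]) @ arch.alpha_i
    if arch.V_E > 0:
        if rng is None:
            raise ValueError("rng required when V_E > 0")
        y = y + rng.normal(0.0, np.sqrt(arch.V_E), pop.n)
    return y


def apply_sibling_indirect(base_a: np.ndarray, base_b: np.ndarray, beta: float):
    """Resolve the mutual sibling feedback Y_i = base_i + beta * Y_j.

    ``base_i`` is the phenotype without the sibling term (Y* + a g_i + eps_i).
    The simultaneous solution is Y_i = (base_i + beta * base_j) / (1 - beta^2),
    which requires |beta| < 1.
    """
    if abs(beta) >= 1:
        raise ValueError("sibling feedback requires |beta| < 1")
    denom = 1.0 - beta * beta
    ya = (base_a + beta * base_b) / denom
    yb = (base_b + beta * base_a) / denom
    return ya, yb


def stabilizing_selection(pop: Population, phenos: np.ndarray, optimum: float,
                          V_S: float, rng: np.random.Generator,
                          n_keep_per_sex: Optional[int] = None) -> np.ndarray:
    """Viability selection: Gaussian fitness around the optimum.

    Individuals survive with probability proportional to
    exp(-(Y - optimum)^2 / (2 V_S)).  Survivors are drawn without replacement
    (weighted, per sex) so they can enter the monogamous mating scheme;
    returns the indices of surviving individuals (females then males).
    """
    if V_S <= 0:
        raise ValueError("V_S must be positive")
    logw = -((phenos - optimum) ** 2) / (2.0 * V_S)
    out = []
    for idx in (pop.females(), pop.males()):
        k = idx.size // 2 if n_keep_per_sex is None else n_keep_per_sex
        # Gumbel top-k == weighted sampling without replacement
        keys = logw[idx] + rng.gumbel(size=idx.size)
        out.append(idx[np.argsort(-keys)[:k]])
    return np.concatenate(out)
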