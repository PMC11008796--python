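"""Closed-form expected effect-size estimates and biases.

These expressions predict, from LD matrices or scenario parameters, what the
population, sibling and parent-offspring (transmitted/untransmitted) designs
estimate in expectation.  They serve both as standalone calculators and as
oracles for the forward simulations.

Notation: D and D~ are cis-/trans-LD in the GWAS sample, D' and D~' the same
quantities in the sample's parents; c_ll' is the sex-averaged recombination
fraction; H_l the fraction of heterozygous parents at l; F Wright's
inbreeding coefficient; a^d and a^i the direct and (parental) indirect
effects per focal allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "expected_population_estimate",
    "expected_family_estimate",
    "expected_untransmitted_estimate",
    "am_equilibrium_inflation",
    "architecture_density_scaling",
    "stratification_ld",
    "admixture_ld_trajectory",
    "BulmerState",
    "solve_bulmer",
    "solve_bulmer_observed",
    "bulmer_attenuation",
    "masked_am_correlation",
    "sibling_indirect_bias",
]


def _as_vec(x, L):
    a = np.zeros(L) if x is None else np.asarray(x, dtype=float)
    if a.ndim == 0:
        a = np.full(L, float(a))
    if a.size != L:
        raise ValueError("effect/confound vector has wrong length")
    return a


def expected_population_estimate(D, D_tilde, D_prime, D_tilde_prime,
                                 alpha_d, alpha_i=None, p=None, F=None,
                                 env_cov=None) -> np.ndarray:
    """Expected population-GWAS estimate at every locus.

    a_hat(pop)_l = (2 / V_l) [ sum_k D_lk a^d_k + sum_k D~_lk a^d_k
                   + sum_k (D'_lk + D~'_lk + 2 D~_lk) a^i_k
                   + (1/2) Cov(g_l, eps) ],
    with V_l = 2 p (1-p) (1 + F) the genotypic variance at l.  Sample LD (D,
    D~) carries the direct genetic confounds; parental LD plus sample
    trans-LD carry the indirect ones; env_cov is the per-locus Cov(g, eps)
    primitive (default 0).
    """
    D = np.asarray(D, dtype=float)
    L = D.shape[0]
    Dt = np.asarray(D_tilde, dtype=float)
    ad = _as_vec(alpha_d, L)
    ai = _as_vec(alpha_i, L)
    env = _as_vec(env_cov, L)
    if p is None:
        # V_l from the sample LD diagonals: 2 p q per haploid plus 2 * trans diag
        V = 2.0 * np.diag(D) + 2.0 * np.diag(Dt)
    else:
        p = _as_vec(p, L)
        Fv = _as_vec(F, L)
        V = 2.0 * p * (1.0 - p) * (1.0 + Fv)
    if np.any(V <= 0):
        raise ValueError("zero genotypic variance at some locus")
    num = D @ ad + Dt @ ad
    if np.any(ai != 0):
        Dp = np.asarray(D_prime, dtype=float)
        Dtp = np.asarray(D_tilde_prime, dtype=float)
        num = num + (Dp + Dtp + 2.0 * Dt) @ ai
    num = num + 0.5 * env
    return 2.0 * num / V


def expected_family_estimate(D_prime, D_tilde_prime, alpha_d, H, c_matrix,
                             coupling_rep: Optional[tuple] = None):
    """Expected within-family direct-effect estimate (sibling or T-U design).

    a_hat(fam)_l = (2 / H_l) sum_k (1 - 2 c_lk) (D'_lk - D~'_lk) a^d_k.
    Only linked confounders (c < 1/2) contribute, through the excess of
    coupling over repulsion double heterozygotes among parents:
    D' - D~' = (H_coup - H_rep) / 2.  If ``coupling_rep=(H_coup, H_rep)`` is
    given, the equivalent coupling/repulsion form is evaluated and returned
    as a second array (it agrees with the first to machine precision).
    """
    Dp = np.asarray(D_prime, dtype=float)
    Dtp = np.asarray(D_tilde_prime, dtype=float)
    c = np.asarray(c_matrix, dtype=float)
    L = Dp.shape[0]
    ad = _as_vec(alpha_d, L)
    H = _as_vec(H, L)
    if np.any(H <= 0):
        raise ValueError("no heterozygous parents at some locus")
    est = (2.0 / H) * (((1.0 - 2.0 * c) * (Dp - Dtp)) @ ad)
    if coupling_rep is None:
        return est
    coup, rep = coupling_rep
    alt = (2.0 / H) * (((0.5 - c) * (np.asarray(coup) - np.asarray(rep))) @ ad)
    return est, alt


def expected_untransmitted_estimate(D_prime, D_tilde_prime, D_tilde_sample,
                                    alpha_d, alpha_i, H, c_matrix, F=0.0,
                                    env_cov_U=None, env_cov=None) -> np.ndarray:
    """Expected coefficient on the untransmitted genotype, a_hat(U).

    General-F form:
    a_hat(U)_l = 1 / (H_l (1+3F)) * (
        2 sum_k [ D'((1+3F) c - 2F) + D~'(-(1+3F) c + 1 + F) + (1-F) D~ ] a^d
        + 2 (1-F) sum_k [ D' + D~' + 2 D~ ] a^i
        + (1+F) Cov(gU, eps) - 2 F Cov(g, eps) ).
    At F = 0 this reduces to the transparent form in which the local term is
    the indirect effect itself and the direct genetic confound is
    sum_k (D' c + D~'(1-c) + D~) a^d.
    """
    Dp = np.asarray(D_prime, dtype=float)
    Dtp = np.asarray(D_tilde_prime, dtype=float)
    Dt = np.asarray(D_tilde_sample, dtype=float)
    c = np.asarray(c_matrix, dtype=float)
    L = Dp.shape[0]
    ad = _as_vec(alpha_d, L)
    ai = _as_vec(alpha_i, L)
    H = _as_vec(H, L)
    Fv = _as_vec(F, L)
    envU = _as_vec(env_cov_U, L)
    env = _as_vec(env_cov, L)
    denom = H * (1.0 + 3.0 * Fv)
    if np.any(denom <= 0):
        raise ValueError("H (1 + 3F) must be positive")
    Fc = Fv[:, None]
    direct = (Dp * ((1.0 + 3.0 * Fc) * c - 2.0 * Fc)
              + Dtp * (-(1.0 + 3.0 * Fc) * c + 1.0 + Fc)
              + (1.0 - Fc) * Dt) @ ad
    indirect = (1.0 - Fv) * ((Dp + Dtp + 2.0 * Dt) @ ai)
    num = 2.0 * direct + 2.0 * indirect + (1.0 + Fv) * envU - 2.0 * Fv * env
    return num / denom


def am_equilibrium_inflation(h2: float, rho: float, mode: str = "same_trait") -> float:
    """Equilibrium effect of assortative mating on population-GWAS estimates.

    * ``same_trait``: estimates at causal loci are inflated by 1 / (1 - h^2 rho).
    * ``cross_asym``: under sex-asymmetric cross-trait AM, the spurious
      estimate at loci causal only for the *other* trait is h^2 rho / 2 times
      the causal-locus effect (equal heritabilities and architectures).
    * ``cross_sym``: with sex-symmetric cross-trait AM the level is h^2 rho.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    x = h2 * rho
    if mode == "same_trait":
        if x >= 1.0:
            raise ValueError("h2 * rho must be < 1")
        return 1.0 / (1.0 - x)
    if mode == "cross_asym":
        return x / 2.0
    if mode == "cross_sym":
        return x
    raise ValueError(f"unknown mode {mode!r}")


def architecture_density_scaling(n1: int, n2: int) -> float:
    """Relative magnitude of spurious estimates at trait-1 loci, |L2| / |L1|.

    Under cross-trait AM between a sparse trait 1 (|L1| loci) and a dense
    trait 2 (|L2| loci) with equal genic variances, the AM signal loads
    |L2|/|L1| times more heavily per trait-1 locus.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("locus counts must be positive")
    return n2 / n1


def stratification_ld(p1, p2):
    """Cis- and trans-LD in an equal-weight mixture of two populations.

    D(S)_lk = (1/4) (p1_l - p2_l)(p1_k - p2_k), and the trans-LD is
    identical: structure alone puts cis and trans in lockstep, which is why
    within-family designs are immune to it.
    """
    dp = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    D = 0.25 * np.outer(dp, dp)
    return D, D.copy()


def admixture_ld_trajectory(p1, p2, A: float, c_matrix, t: int):
    """Cis-LD t generations after single-pulse admixture; trans-LD after t>=1.

    D_0 = A(1-A)(p1_l - p2_l)(p1_k - p2_k), decaying as (1 - c_lk)^t under
    random mating, while the trans-LD is zero in every generation after
    admixture.  Returns (D_t, D_tilde_t).
    """
    if not (0.0 <= A <= 1.0):
        raise ValueError("A must lie in [0, 1]")
    if t < 0:
        raise ValueError("t must be non-negative")
    dp = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    D0 = A * (1.0 - A) * np.outer(dp, dp)
    c = np.asarray(c_matrix, dtype=float)
    Dt = D0 * (1.0 - c) ** t
    trans = D0 if t == 0 else np.zeros_like(D0)
    return Dt, trans


# ---------------------------------------------------------------------------
# Stabilizing selection (Bulmer model)
# ---------------------------------------------------------------------------


@dataclass
class BulmerState:
    """Equilibrium of the Bulmer model under Gaussian stabilizing selection.

    ``d_star`` (< 0) is the equilibrium disequilibrium contribution to the
    additive variance measured before selection acts in a generation;
    selection within the generation deepens it to d_star (1 + 2 c_bar_h).
    All variances are pre-selection equilibrium values.
    """

    V_g: float
    V_E: float
    V_S_over_V_P: float
    c_bar_h: float
    d_star: float
    n_loci: Optional[int] = None

    @property
    def V_A(self) -> float:
        return self.V_g + self.d_star

    @property
    def V_P(self) -> float:
        return self.V_A + self.V_E

    @property
    def h2(self) -> float:
        return self.V_A / self.V_P

    @property
    def delta(self) -> float:
        """Per-generation disequilibrium generated by selection (negative)."""
        return 2.0 * self.c_bar_h * self.d_star


def _delta_sel(V_A: float, V_P: float, vs_ratio: float) -> float:
    """Within-generation change in additive variance under Gaussian selection.

    Selection of width V_S = vs_ratio * V_P changes the additive variance by
    -V_A^2 / (V_S + V_P); the change is pure disequilibrium (allele
    frequencies are second-order).
    """
    return -(V_A * V_A) / (vs_ratio * V_P + V_P)


def solve_bulmer(V_g: float, V_E: float, V_S_over_V_P: float, c_bar_h: float,
                 n_loci: Optional[int] = None, tol: float = 1e-10,
                 max_iter: int = 10_000) -> BulmerState:
    """Equilibrium d* from genic parameters, by damped fixed-point iteration.

    At equilibrium the per-pair cis-LD balance gives
    d* = delta / (2 c_bar_h) with delta = -V_A^2 / (V_S + V_P) evaluated at
    the equilibrium (pre-selection) variances V_A = V_g + d*,
    V_P = V_A + V_E, V_S = (V_S/V_P) V_P.  Iterates from d = 0 with 0.5
    damping; raises if the fixed point does not converge.
    """
    if min(V_g, V_E) < 0 or V_S_over_V_P <= 0 or not (0 < c_bar_h <= 0.5):
        raise ValueError("variances must be non-negative, V_S/V_P > 0, c_bar_h in (0, 0.5]")
    d = 0.0
    for _ in range(max_iter):
        V_A = V_g + d
        V_P = V_A + V_E
        if V_A <= 0 or V_P <= 0:
            raise ArithmeticError("Bulmer iteration left the admissible region")
        d_new = _delta_sel(V_A, V_P, V_S_over_V_P) / (2.0 * c_bar_h)
        if abs(d_new - d) <= tol * max(1.0, abs(d_new)):
            return BulmerState(V_g, V_E, V_S_over_V_P, c_bar_h, d_new, n_loci)
        d = 0.5 * (d + d_new)
    raise ArithmeticError("Bulmer fixed point did not converge")


def solve_bulmer_observed(h2: float, V_S_over_V_P: float, c_bar_h: float,
                          V_P: float = 1.0, n_loci: Optional[int] = None) -> BulmerState:
    """Equilibrium state anchored on *observed* pre-selection h2 and V_P.

    When the heritability and phenotypic variance are the measured,
    equilibrium (pre-selection) values, d* follows in closed form:
    delta = -V_A^2 / (V_S + V_P) with V_A = h2 V_P, and
    d* = delta / (2 c_bar_h); the genic variance is V_g = V_A - d*.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    V_A = h2 * V_P
    V_E = V_P - V_A
    d_star = _delta_sel(V_A, V_P, V_S_over_V_P) / (2.0 * c_bar_h)
    return BulmerState(V_A - d_star, V_E, V_S_over_V_P, c_bar_h, d_star, n_loci)


def bulmer_attenuation(V_g=None, V_E=None, V_S_over_V_P=None, c_bar_h=None,
                       state: Optional[BulmerState] = None) -> dict:
    """Proportionate attenuation of effect-size estimates per design.

    (a - a_hat)/a equals -d*/V_g in a pre-selection population GWAS,
    -d*(1 + 2 c_bar_h)/V_g post-selection, and -d*(1 - 2 c_bar_h)/V_g in a
    within-family GWAS (either timing).  Also returns the family/pre ratio
    (1 - 2 c_bar_h) and family/post ratio (1 - 2 c_bar_h)/(1 + 2 c_bar_h).
    """
    if state is None:
        state = solve_bulmer(V_g, V_E, V_S_over_V_P, c_bar_h)
    d, ch, Vg = state.d_star, state.c_bar_h, state.V_g
    return {
        "d_star": d,
        "pre_pop": -d / Vg,
        "post_pop": -d * (1.0 + 2.0 * ch) / Vg,
        "family": -d * (1.0 - 2.0 * ch) / Vg,
        "family_over_pre": 1.0 - 2.0 * ch,
        "family_over_post": (1.0 - 2.0 * ch) / (1.0 + 2.0 * ch),
    }


def masked_am_correlation(rho_true: float, state: BulmerState,
                          timing: str = "pre") -> float:
    """Apparent mate correlation from cross-chromosome PGS correlations.

    Stabilizing selection builds negative signed LD between unlinked causal
    loci that partially cancels the positive LD assortative mating creates,
    so AM-strength estimates that attribute all cross-chromosome signed LD to
    assortative mating are biased downward.  On the mate-correlation scale
    the deficit is

        delta_rho = T * (V_P / (V_P + V_S)) / h^4,

    where V_P/(V_P+V_S) is the within-generation proportional variance
    reduction by selection, h^4 converts between the phenotypic
    mate-correlation scale and the PGS-covariance scale, and T = 1 if
    selection has not yet acted in the measured generation or T = 2 if it
    has (selection within the generation doubles the unlinked-pair
    disequilibrium).  Without selection the apparent and true correlations
    coincide.
    """
    if not (0.0 < rho_true < 1.0):
        raise ValueError("rho_true must lie in (0, 1)")
    if timing not in ("pre", "post"):
        raise ValueError("timing must be 'pre' or 'post'")
    k = 1.0 / (1.0 + state.V_S_over_V_P)
    T = 1.0 if timing == "pre" else 2.0
    return rho_true - T * k / state.h2 ** 2


def sibling_indirect_bias(alpha: float, beta: float, r_g_sibs: float = 0.5):
    """Expected estimates under a mutual sibling effect of strength beta.

    The sibling design estimates alpha / (1 + beta) (defined for beta > -1);
    the population design, sampling one sibling per family, estimates
    (alpha + alpha beta r_g_sibs) / (1 - beta^2), defined only for |beta| < 1
    because the phenotypic feedback otherwise diverges.  Returns
    (sib_estimate, pop_estimate); pop_estimate is NaN at |beta| >= 1.
    """
    if beta <= -1:
        raise ValueError("sibling estimate undefined for beta <= -1")
    sib = alpha / (1.0 + beta)
    pop = np.nan if abs(beta) >= 1 else alpha * (1.0 + beta * r_g_sibs) / (1.0 - beta * beta)
    return sib, pop
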