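"""Config-driven drivers for the desk-scale confounding experiments.

Each driver runs a replicated forward simulation of one confounding scenario
(cross-trait assortative mating, same-trait assortative mating, unequal
architectures, population structure and admixture, sibling indirect effects)
or evaluates the stabilizing-selection theory on a grid, and returns a tidy
table (generation, design, metric, mean, MC standard error, replicates).
Every driver is bit-reproducible given (config, seed): one seeded generator
per replicate, with the replicate index folded into the seed.

Default sizes are desk-scale study conditions: N = 4,000 individuals and
around 200 causal loci with a few hundred replicates, in place of the
N = 40,000 / 1,000-locus / 10,000-replicate scale used for the published
figures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import theory
from .genome_map import LinkageMap, apportion_loci, synthetic_autosome_table, uniform_map
from .gwas import (
    one_sib_per_family,
    parent_offspring_gwas,
    population_gwas,
    sibling_gwas,
    transmitted_untransmitted,
)
from .pop_sim import (
    Population,
    assortative_mating_plan,
    init_founders,
    init_two_populations,
    make_next_generation,
    merge_populations,
    random_mating_plan,
    rng_for_replicate,
    sib_pairs,
)

__all__ = [
    "CrossTraitAMConfig",
    "SameTraitAMConfig",
    "ArchitectureConfig",
    "AdmixtureConfig",
    "StabilizingConfig",
    "SiblingIndirectConfig",
    "run_fig_crosstrait_am",
    "run_fig_sametrait_am",
    "run_fig_architecture",
    "run_fig_admixture",
    "run_fig_stabilizing",
    "run_sibling_indirect",
    "load_config",
    "write_experiment",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


def _make_map(kind: str, n_loci: int, total_morgans: float) -> LinkageMap:
    if kind == "uniform":
        return uniform_map(n_loci, total_morgans)
    if kind == "human":
        return apportion_loci(synthetic_autosome_table(), n_loci)
    raise ValueError(f"unknown map kind {kind!r}")


@dataclass
class CrossTraitAMConfig:
    """Sex-asymmetric cross-trait assortative mating, then random mating."""

    n: int = 4000
    n_loci_1: int = 100
    n_loci_2: int = 100
    rho: float = 0.2
    am_generations: int = 19
    total_generations: int = 39
    map_kind: str = "uniform"
    total_morgans: float = 1.0
    n_replicates: int = 200
    seed: int = 0
    designs: tuple = ("population", "sibling", "parent_offspring")


@dataclass
class SameTraitAMConfig:
    """Random-mating burn-in, same-trait AM, then random mating again."""

    n: int = 4000
    n_loci: int = 200
    rho: float = 0.2
    burn_in: int = 30
    am_generations: int = 20
    post_generations: int = 20
    maf: float = 0.1
    effect_sd: float = 1.0
    map_kind: str = "uniform"
    total_morgans: float = 1.0
    n_replicates: int = 100
    seed: int = 0


@dataclass
class ArchitectureConfig:
    """Cross-trait AM between a sparse trait 1 and a dense trait 2."""

    n: int = 4000
    n_loci_1: int = 20
    n_loci_2: int = 200
    rho: float = 0.2
    burn_in: int = 10
    am_generations: int = 20
    maf: float = 0.1
    effect_sd_2: float = 1.0
    map_kind: str = "human"
    total_morgans: float = 1.0
    n_replicates: int = 50
    seed: int = 0

    @property
    def effect_sd_1(self) -> float:
        # equal genic variances across the two traits
        return self.effect_sd_2 * np.sqrt(self.n_loci_2 / self.n_loci_1)


@dataclass
class AdmixtureConfig:
    """Two drift-diverged populations, isolated then admixed 50:50."""

    n: int = 4000  # total size; each isolated population is n/2
    n_loci: int = 200
    fst: float = 0.1
    maf: float = 0.2
    pre_generations: int = 5
    post_generations: int = 10
    effect_sd: float = 1.0
    map_kind: str = "human"
    total_morgans: float = 1.0
    n_replicates: int = 100
    seed: int = 0


@dataclass
class StabilizingConfig:
    """Analytic attenuation surfaces over (h^2, V_S/V_P)."""

    h2_grid: tuple = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    vs_grid: tuple = (20, 30, 50, 80, 120, 170)
    c_bar_h: float = 0.464
    n_loci: int = 1000
    rho_mates: float = 0.25
    seed: int = 0


@dataclass
class SiblingIndirectConfig:
    """Mutual sibling effect of strength beta at an unlinked causal locus."""

    n: int = 4000
    betas: tuple = (-0.5, 0.2, 0.5, 1.0)
    alpha: float = 1.0
    V_E: float = 1.0
    p: float = 0.5
    n_replicates: int = 300
    seed: int = 0


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _masked_mean(res, loci) -> float:
    ok = res.mask[loci]
    return float(res.alpha_hat[loci][ok].mean()) if ok.any() else np.nan


def _tidy(rows) -> pd.DataFrame:
    """Aggregate per-replicate records into mean / MC standard error."""
    df = pd.DataFrame(rows)
    g = df.groupby(["generation", "design", "metric"], as_index=False)["value"]
    out = g.agg(mean="mean", sd="std", n_replicates="count")
    out["se"] = out["sd"] / np.sqrt(out["n_replicates"])
    return out.drop(columns="sd")


def _evolve(pop: Population, gmap: LinkageMap, rng, plan_fn) -> Population:
    plan = plan_fn(pop, rng)
    return make_next_generation(pop, plan, gmap, rng)


def _three_design_records(off: Population, parents: Population, y, rng,
                          designs=("population", "sibling", "parent_offspring")):
    """Per-locus estimates for the three designs on one offspring cohort."""
    out = {}
    g = off.genotypes().astype(float)
    pick = one_sib_per_family(off, rng)
    if "population" in designs:
        out["population"] = population_gwas(g[pick], y[pick])
    if "sibling" in designs:
        a, b = sib_pairs(off)
        out["sibling"] = sibling_gwas(g[a], g[b], y[a], y[b])
    if "parent_offspring" in designs:
        gT, gU = transmitted_untransmitted(off, parents)
        out["parent_offspring"] = parent_offspring_gwas(y[pick], gT[pick], gU[pick])
    return out


def _het_weighted_msq(res, loci=None) -> float:
    sel = np.arange(res.alpha_hat.size) if loci is None else loci
    ok = res.mask[sel]
    a = res.alpha_hat[sel][ok]
    p = res.p_hat[sel][ok]
    return float(np.mean(2 * p * (1 - p) * a * a)) if a.size else np.nan


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def run_fig_crosstrait_am(cfg: CrossTraitAMConfig) -> pd.DataFrame:
    """Spurious cross-trait estimates at trait-1 loci, per generation.

    Traits 1 and 2 have distinct, interleaved causal sets with all effects 1
    and heritability 1.  Mothers' trait-1 scores are matched to fathers'
    trait-2 scores at correlation rho for the first ``am_generations``
    parental generations, then mating is random.  The recorded metric is the
    mean trait-2 effect-size estimate at trait-1 loci (true value 0).
    """
    L = cfg.n_loci_1 + cfg.n_loci_2
    if cfg.n_loci_1 != cfg.n_loci_2:
        raise ValueError("interleaving requires equal architecture sizes")
    gmap = _make_map(cfg.map_kind, L, cfg.total_morgans)
    loci1 = np.arange(0, L, 2)
    loci2 = np.arange(1, L, 2)
    a1 = np.zeros(L)
    a1[loci1] = 1.0
    a2 = np.zeros(L)
    a2[loci2] = 1.0

    rows = []
    for rep in range(cfg.n_replicates):
        rng = rng_for_replicate(cfg.seed, rep)
        pop = init_founders(cfg.n, np.full(L, 0.5), rng)
        for t in range(cfg.total_generations):
            g = pop.genotypes().astype(float)
            if t < cfg.am_generations:
                y1 = g @ a1
                y2 = g @ a2
                plan = assortative_mating_plan(
                    pop, y1[pop.females()], y2[pop.males()], cfg.rho, rng=rng)
            else:
                plan = random_mating_plan(pop, rng)
            off = make_next_generation(pop, plan, gmap, rng)
            y2_off = off.genotypes().astype(float) @ a2
            res = _three_design_records(off, pop, y2_off, rng, designs=cfg.designs)
            for design, r in res.items():
                rows.append({"generation": t + 1, "design": design,
                             "metric": "mean_alpha_hat_trait1_loci",
                             "value": _masked_mean(r, loci1), "replicate": rep})
            pop = off
    return _tidy(rows)


def run_fig_sametrait_am(cfg: SameTraitAMConfig) -> pd.DataFrame:
    """Heterozygosity-weighted mean squared estimate under same-trait AM.

    Effects are half-normal (the focal allele is the trait-increasing one)
    with the given spread, founder frequencies uniform on [maf, 1-maf], and
    heritability 1.  Burn-in under random mating lets drift-generated local
    LD reach its plateau before AM switches on.
    """
    L = cfg.n_loci
    gmap = _make_map(cfg.map_kind, L, cfg.total_morgans)
    total = cfg.burn_in + cfg.am_generations + cfg.post_generations
    rows = []
    for rep in range(cfg.n_replicates):
        rng = rng_for_replicate(cfg.seed, rep)
        alpha = np.abs(rng.normal(0.0, cfg.effect_sd, L))
        freqs = rng.uniform(cfg.maf, 1.0 - cfg.maf, L)
        pop = init_founders(cfg.n, freqs, rng)
        for t in range(total):
            g = pop.genotypes().astype(float)
            y = g @ alpha
            in_am = cfg.burn_in <= t < cfg.burn_in + cfg.am_generations
            if in_am:
                plan = assortative_mating_plan(
                    pop, y[pop.females()], y[pop.males()], cfg.rho, rng=rng)
            else:
                plan = random_mating_plan(pop, rng)
            off = make_next_generation(pop, plan, gmap, rng)
            y_off = off.genotypes().astype(float) @ alpha
            res = _three_design_records(off, pop, y_off, rng,
                                        designs=("population", "sibling"))
            gen = t + 1 - cfg.burn_in  # generation 1 = first AM offspring
            for design, r in res.items():
                rows.append({"generation": gen, "design": design,
                             "metric": "het_weighted_msq",
                             "value": _het_weighted_msq(r), "replicate": rep})
            p_off = off.genotypes().mean(axis=0) / 2.0
            rows.append({"generation": gen, "design": "true",
                         "metric": "het_weighted_msq",
                         "value": float(np.mean(2 * p_off * (1 - p_off) * alpha ** 2)),
                         "replicate": rep})
            pop = off
    return _tidy(rows)


def run_fig_architecture(cfg: ArchitectureConfig):
    """|estimate| distributions at trait-1 vs trait-2 loci, trait-2 GWAS.

    Trait 1 is sparse (few loci, large effects), trait 2 dense, with genic
    variances equalised; cross-trait AM loads the mating signal per-locus
    more heavily onto the sparse trait's loci.  Returns (pooled per-locus
    table, summary table with mean and 95th percentile of |estimate|).
    """
    L = cfg.n_loci_1 + cfg.n_loci_2
    gmap = _make_map(cfg.map_kind, L, cfg.total_morgans)
    # trait-1 loci evenly spaced among the trait-2 loci
    step = L // cfg.n_loci_1
    loci1 = np.arange(0, L, step)[: cfg.n_loci_1]
    loci2 = np.setdiff1d(np.arange(L), loci1)

    pooled = []
    for rep in range(cfg.n_replicates):
        rng = rng_for_replicate(cfg.seed, rep)
        a1 = np.zeros(L)
        a2 = np.zeros(L)
        a1[loci1] = np.abs(rng.normal(0.0, cfg.effect_sd_1, cfg.n_loci_1))
        a2[loci2] = np.abs(rng.normal(0.0, cfg.effect_sd_2, cfg.n_loci_2))
        freqs = rng.uniform(cfg.maf, 1.0 - cfg.maf, L)
        pop = init_founders(cfg.n, freqs, rng)
        for t in range(cfg.burn_in + cfg.am_generations):
            g = pop.genotypes().astype(float)
            if t >= cfg.burn_in:
                y1 = g @ a1
                y2 = g @ a2
                plan = assortative_mating_plan(
                    pop, y1[pop.females()], y2[pop.males()], cfg.rho, rng=rng)
            else:
                plan = random_mating_plan(pop, rng)
            # GWAS at the end of burn-in (random mating) and at the end of AM
            if t + 1 in (cfg.burn_in, cfg.burn_in + cfg.am_generations):
                off = make_next_generation(pop, plan, gmap, rng)
                y2_off = off.genotypes().astype(float) @ a2
                pick = one_sib_per_family(off, rng)
                res = population_gwas(off.genotypes().astype(float)[pick], y2_off[pick])
                phase = "random_mating" if t + 1 == cfg.burn_in else "assortative_mating"
                for cls, loci in (("trait1", loci1), ("trait2", loci2)):
                    ok = res.mask[loci]
                    for v in np.abs(res.alpha_hat[loci][ok]):
                        pooled.append({"phase": phase, "locus_class": cls,
                                       "abs_alpha_hat": v, "replicate": rep})
                pop = off
            else:
                pop = make_next_generation(pop, plan, gmap, rng)
    pooled = pd.DataFrame(pooled)
    summary = (pooled.groupby(["phase", "locus_class"])["abs_alpha_hat"]
               .agg(mean="mean", q95=lambda s: s.quantile(0.95), n="count")
               .reset_index())
    return pooled, summary


def run_fig_admixture(cfg: AdmixtureConfig) -> pd.DataFrame:
    """Het-weighted mean squared estimate around an admixture event.

    Two populations with drift-like F_ST divergence evolve in isolation
    (generations < 0, GWAS on the pooled sample), then merge 50:50 at
    generation 0 and mate randomly.  Records population and sibling metrics
    plus the true reference E[2p(1-p) a^2].
    """
    L = cfg.n_loci
    half = cfg.n / 2
    if half % 4:
        raise ValueError("n/2 must be divisible by 4")
    gmap = _make_map(cfg.map_kind, L, cfg.total_morgans)
    rows = []
    for rep in range(cfg.n_replicates):
        rng = rng_for_replicate(cfg.seed, rep)
        alpha = np.abs(rng.normal(0.0, cfg.effect_sd, L))
        _, p1, p2 = init_two_populations(L, cfg.maf, cfg.fst, rng)
        popA = init_founders(int(half), p1, rng)
        popB = init_founders(int(half), p2, rng)

        def record(off, parents_for_po, gen):
            y = off.genotypes().astype(float) @ alpha
            res = _three_design_records(off, parents_for_po, y, rng,
                                        designs=("population", "sibling"))
            for design, r in res.items():
                rows.append({"generation": gen, "design": design,
                             "metric": "het_weighted_msq",
                             "value": _het_weighted_msq(r), "replicate": rep})
            p = off.genotypes().mean(axis=0) / 2.0
            rows.append({"generation": gen, "design": "true",
                         "metric": "het_weighted_msq",
                         "value": float(np.mean(2 * p * (1 - p) * alpha ** 2)),
                         "replicate": rep})

        # isolated phase: GWAS on the pooled (stratified) sample
        for t in range(cfg.pre_generations):
            offA = _evolve(popA, gmap, rng, random_mating_plan)
            offB = _evolve(popB, gmap, rng, random_mating_plan)
            pooled = merge_populations(offA, offB)
            # sibling pairs survive pooling because offspring rows stay adjacent
            pooled.mother = np.concatenate([offA.mother, offB.mother + popA.n])
            pooled.father = np.concatenate([offA.father, offB.father + popA.n])
            record(pooled, None, t - cfg.pre_generations)
            popA, popB = offA, offB

        pop = merge_populations(popA, popB)
        for t in range(cfg.post_generations):
            off = _evolve(pop, gmap, rng, random_mating_plan)
            record(off, pop, t + 1)
            pop = off
    return _tidy(rows)


def run_fig_stabilizing(cfg: StabilizingConfig) -> pd.DataFrame:
    """Analytic attenuation surfaces and masked mate correlations."""
    rows = []
    for h2 in cfg.h2_grid:
        for vs in cfg.vs_grid:
            st = theory.solve_bulmer_observed(h2, vs, cfg.c_bar_h, n_loci=cfg.n_loci)
            att = theory.bulmer_attenuation(state=st)
            rows.append({
                "h2": h2, "V_S_over_V_P": vs,
                "pre_pop_pct": 100 * att["pre_pop"],
                "post_pop_pct": 100 * att["post_pop"],
                "family_pct": 100 * att["family"],
                "masked_rho_pre": theory.masked_am_correlation(cfg.rho_mates, st, "pre"),
                "masked_rho_post": theory.masked_am_correlation(cfg.rho_mates, st, "post"),
            })
    return pd.DataFrame(rows)


def run_sibling_indirect(cfg: SiblingIndirectConfig) -> pd.DataFrame:
    """Sibling and population estimator means across the beta grid.

    A single unlinked causal locus with effect alpha; the mutual sibling
    feedback is solved exactly for |beta| < 1.  At beta = 1 individual
    phenotypes are undefined (the feedback diverges) but sibling differences
    remain well-defined, so only the sibling design is evaluated there.
    """
    gmap = uniform_map(2, 0.0)  # two trivially linked dummy positions
    freqs = np.array([cfg.p, cfg.p])
    rows = []
    for rep in range(cfg.n_replicates):
        rng = rng_for_replicate(cfg.seed, rep)
        pop = init_founders(cfg.n, freqs, rng)
        off = _evolve(pop, gmap, rng, random_mating_plan)
        g = off.genotypes().astype(float)[:, :1]
        a_idx, b_idx = sib_pairs(off)
        eps = rng.normal(0.0, np.sqrt(cfg.V_E), cfg.n)
        base = cfg.alpha * g[:, 0] + eps
        for beta in cfg.betas:
            if abs(beta) < 1:
                denom = 1.0 - beta * beta
                ya = (base[a_idx] + beta * base[b_idx]) / denom
                yb = (base[b_idx] + beta * base[a_idx]) / denom
                res_sib = sibling_gwas(g[a_idx], g[b_idx], ya, yb)
                pick = rng.integers(0, 2, a_idx.size)
                gp = np.where(pick == 0, g[a_idx, 0], g[b_idx, 0])
                yp = np.where(pick == 0, ya, yb)
                res_pop = population_gwas(gp[:, None], yp)
                rows.append({"generation": 0, "design": "population",
                             "metric": f"alpha_hat@beta={beta}",
                             "value": float(res_pop.alpha_hat[0]), "replicate": rep})
            else:
                # beta = 1: only differences are defined
                dg = g[a_idx, 0] - g[b_idx, 0]
                dy = (cfg.alpha * dg + eps[a_idx] - eps[b_idx]) / (1.0 + beta)
                res_sib = sibling_gwas(g[a_idx], g[b_idx], dy, np.zeros_like(dy))
            rows.append({"generation": 0, "design": "sibling",
                         "metric": f"alpha_hat@beta={beta}",
                         "value": float(res_sib.alpha_hat[0]), "replicate": rep})
    return _tidy(rows)


# ---------------------------------------------------------------------------
# config I/O and experiment outputs
# ---------------------------------------------------------------------------

_CONFIGS = {
    "crosstrait_am": CrossTraitAMConfig,
    "sametrait_am": SameTraitAMConfig,
    "architecture": ArchitectureConfig,
    "admixture": AdmixtureConfig,
    "stabilizing": StabilizingConfig,
    "sibling_indirect": SiblingIndirectConfig,
}

_RUNNERS = {
    "crosstrait_am": run_fig_crosstrait_am,
    "sametrait_am": run_fig_sametrait_am,
    "admixture": run_fig_admixture,
    "stabilizing": run_fig_stabilizing,
    "sibling_indirect": run_sibling_indirect,
}


def load_config(path):
    """Load a scenario config from YAML ({scenario: name, params...})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    name = raw.pop("scenario")
    cls = _CONFIGS[name]
    raw = {k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()}
    return name, cls(**raw)


def run_named(name: str, cfg) -> pd.DataFrame:
    return _RUNNERS[name](cfg)


def write_experiment(df: pd.DataFrame, out_prefix: str, cfg, seed=None) -> None:
    """Tidy TSV plus a JSON run manifest (config hash, seed, version)."""
    from . import __version__

    df.to_csv(f"{out_prefix}.tsv", sep="\t", index=False)
    cfg_dict = dataclasses.asdict(cfg)
    blob = json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg_dict.get("seed", seed),
        "package_version": __version__,
    }
    with open(f"{out_prefix}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
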