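"""Cross-trait assortative mating: spurious estimates at non-causal loci.

Sex-asymmetric AM (mothers' trait 1 x fathers' trait 2, rho = 0.2) between
two traits with distinct interleaved causal sets for 19 generations, then
random mating.  Tracks the mean trait-2 effect-size estimate at trait-1 loci
(whose true effect on trait 2 is zero) for the population, sibling and
parent-offspring designs, against the first-order equilibrium level
h^2 rho / 2 = 0.1.  Writes results/02_crosstrait_am.tsv.
"""

import argparse
import pathlib

from gwasconf.experiments import CrossTraitAMConfig, run_fig_crosstrait_am, write_experiment


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replicates", type=int, default=100)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cfg = CrossTraitAMConfig(n_replicates=args.replicates, seed=args.seed)
    df = run_fig_crosstrait_am(cfg)
    write_experiment(df, str(out / "02_crosstrait_am"), cfg)

    pop = df[df.design == "population"].set_index("generation")
    sib = df[df.design == "sibling"].set_index("generation")
    g_end = cfg.am_generations
    print(f"population design: mean spurious estimate {pop.loc[g_end,'mean']:.4f} "
          f"(+-{pop.loc[g_end,'se']:.4f}) at generation {g_end}; "
          "first-order equilibrium level 0.1")
    print(f"  one generation after AM stops: {pop.loc[g_end+1,'mean']:.4f} "
          "(trans-LD gone, bias roughly halves)")
    print(f"sibling design: mean estimate {sib.loc[g_end,'mean']:.4f} during AM "
          f"(downward-biased), {sib.loc[g_end+2,'mean']:.4f} two generations after "
          "cessation (sign flips as only cis-LD remains)")
    print(f"wrote {out / '02_crosstrait_am.tsv'}")


if __name__ == "__main__":
    main()
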