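"""Power calibration of the synthetic trait generator's default effects.

For each default trait this script estimates, over replicate simulated
studies, the rejection rate of the per-dataset ecotype and ecotype x
region tests that drive the parallelism classifier, plus the resulting
category-level accuracy.  The generator's default effect magnitudes were
chosen so that every class-defining test has high power (>= ~0.9) at the
default study design while null tests stay at the nominal alpha; re-run
this script after changing the design or the trait configuration.

Usage: python scripts/calibrate_traits.py [--n-seeds 20] [--seed 1000]
"""

import argparse

import numpy as np

from parallodrome import parallelism as pl
from parallodrome import pheno as ph
from parallodrome import synthdata as sd

TRUTH_TO_CALL = {
    "parallel": "parallel_genetic",
    "plastic": "plastic",
    "nonparallel_genetic": "nonparallel_genetic",
    "null": "none",
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-seeds", type=int, default=20)
    ap.add_argument("--seed", type=int, default=1000)
    args = ap.parse_args()

    truth = sd.trait_truth()
    rates = {}
    scores = []
    for s in range(args.n_seeds):
        F = ph.preprocess_traits(
            sd.simulate_phenotypes(dataset="field", seed=args.seed + 2 * s))
        Gd = ph.preprocess_traits(
            sd.simulate_phenotypes(dataset="garden", seed=args.seed + 2 * s + 1))
        ff, gf = ph.fit_all_traits(F), ph.fit_all_traits(Gd)
        table, _ = pl.classify_all(ff, gf)
        ok = 0
        for t, c in zip(table.trait, table.call):
            good = TRUTH_TO_CALL[truth[t]] == c or (
                truth[t] == "plastic" and c == "nonparallel_plastic")
            ok += good
            r = rates.setdefault(t, dict(fe=0, fi=0, ge=0, gi=0, miss=0))
            r["miss"] += not good
            r["fe"] += ff[t].p_ecotype <= 0.05
            r["fi"] += ff[t].p_interaction <= 0.05
            r["ge"] += gf[t].p_ecotype <= 0.05
            r["gi"] += gf[t].p_interaction <= 0.05
        scores.append(ok)
    n = args.n_seeds
    print(f"{'trait':5s} {'class':20s} {'fld_eco':>7s} {'fld_int':>7s} "
          f"{'grd_eco':>7s} {'grd_int':>7s} {'miss':>5s}")
    for t, r in rates.items():
        print(f"{t:5s} {truth[t]:20s} {r['fe']/n:7.2f} {r['fi']/n:7.2f} "
              f"{r['ge']/n:7.2f} {r['gi']/n:7.2f} {r['miss']/n:5.2f}")
    print(f"\ncorrect calls per study: {scores}  "
          f"median {np.median(scores):.1f} / 16")


if __name__ == "__main__":
    main()
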