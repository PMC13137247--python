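#!/usr/bin/env python
"""HREX-wt-MTD on the coarse-grained chain over the 8-replica ladder.

Runs the combined engine the way the production workflow does: the
geometric solute-tempering ladder (lambda 1 -> 0.426934) flattens the
torsion barriers in the hot replicas, each replica deposits its own
well-tempered bias on d1 with heights scaled as w/lambda, and
configurations swap between ladder neighbors.  Statistics come from the
unscaled (lambda = 1) replica only.

Writes results/hrex_exchanges.dat and results/hrex_d1_fes.dat.
"""
import argparse

import numpy as np

from petfes.cg_polymer import ChainGeometry, TorsionPotential
from petfes.colvar import ColvarTable, write_colvar, write_fes
from petfes.constants import T_SAMPLING
from petfes.enhanced_sampling import (CGChainSystem, HrexSchedule, MetadSpec,
                                      lambda_ladder, run_hrex_wtmtd)
from petfes.fes_analysis import (block_error, discard_transient,
                                 frame_weights, make_fes)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=3)
parser.add_argument("--steps", type=int, default=30_000)
args = parser.parse_args()

geometry = ChainGeometry()
potential = TorsionPotential(gt_gap=-4.71)   # amorphous calibration
system = CGChainSystem(geometry, potential)
ladder = lambda_ladder(8, 0.426934)
spec = MetadSpec(cv_names=("d1",), w0=0.5, sigma=0.05, gamma=15.0, pace=100)
sched = HrexSchedule(n_steps=args.steps, exchange_interval=500,
                     record_stride=10)

result = run_hrex_wtmtd(system, ladder, spec, wall_specs=(), schedule=sched,
                        seed=args.seed, T=T_SAMPLING)

rates = result.acceptance_rates()
print("ladder:", " ".join(f"{x:.4f}" for x in ladder))
for i, r in enumerate(rates):
    print(f"pair ({ladder.lambdas[i]:.3f}, {ladder.lambdas[i + 1]:.3f}): "
          f"exchange acceptance {100 * r:.0f}%")
rows = [[i, ladder.lambdas[i], ladder.lambdas[i + 1],
         result.exchange_attempts[i], result.exchange_accepts[i], rates[i]]
        for i in range(len(rates))]
write_colvar(ColvarTable(("pair", "lambda_i", "lambda_j", "attempts",
                          "accepts", "rate"), rows),
             "results/hrex_exchanges.dat")

cold = result.cold
bias = result.biases[0]
w = frame_weights(cold, bias, T_SAMPLING)
cold2, w2 = discard_transient(cold, w, 0.2)
edges = np.arange(1.0, 4.3, 0.05)
fes = make_fes(cold2, w2, ("d1",), edges, T_SAMPLING)
fes.errors = block_error(cold2, w2, "d1", fes.edges[0], T_SAMPLING)
write_fes(fes, "results/hrex_d1_fes.dat")
occ = fes.occupied
print(f"cold-replica d1 FES over [{fes.centers(0)[occ].min():.2f}, "
      f"{fes.centers(0)[occ].max():.2f}] nm, "
      f"{bias.n_kernels} kernels on the cold bias")
print("wrote results/hrex_exchanges.dat, results/hrex_d1_fes.dat")
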