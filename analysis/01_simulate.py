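"""Generate the synthetic study datasets.

Produces, under results/synthetic/: the CEST profile table for the default
12-residue scenario at the four saturation fields, the R1rho decay table,
the ITC injection tables for the temperature series (duplicates), and the
ground-truth records used by the later recovery steps.
"""

import json
import sys
from pathlib import Path

import numpy as np

from foldbind import io as fio
from foldbind import synthetic as syn

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/synthetic")
OUT.mkdir(parents=True, exist_ok=True)

scen = syn.make_default_scenario(seed=SEED, sigma=0.004)
dataset, truth = syn.generate_cest_dataset(scen)
fio.write_profile_table(dataset, OUT / "cest_profiles.tsv")
(OUT / "cest_truth.json").write_text(json.dumps(truth, indent=2,
                                                default=float))
shifts = {rid: m.shift_f for rid, m in dataset.residues.items()}
(OUT / "residue_shifts.json").write_text(json.dumps(shifts, indent=2))
print(f"CEST: {len(dataset.profiles)} profiles "
      f"({len(dataset.residues)} residues x {len(scen.experiments)} fields), "
      f"sigma = {scen.sigma}")

rng = np.random.default_rng(SEED)
rates = {rid: float(r) for rid, r in
         zip(sorted(shifts), rng.uniform(3.0, 12.0, len(shifts)))}
curves = syn.generate_decays(rates, sigma=1.0, seed=SEED)
fio.write_decay_table(curves, OUT / "decays.tsv")
(OUT / "decay_truth.json").write_text(json.dumps(rates, indent=2))
print(f"R1rho: {len(curves)} decay curves at the 11-delay schedule")

series, itc_truth = syn.generate_titrations(seed=SEED, duplicates=2,
                                            sigma_q=0.5)
fio.write_injection_table(series, OUT / "injections.tsv")
(OUT / "itc_truth.json").write_text(json.dumps(itc_truth, indent=2,
                                               default=float))
print(f"ITC: {len(series)} titrations "
      f"(duplicates at {sorted({s.temperature for s in series})} K)")
print(f"tables written to {OUT}/")
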