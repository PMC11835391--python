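"""Steered work accumulation and Jarzynski reconstruction.

Runs the near-equilibrium reference protocol (k = 300, v = 0.05, 200
replicates) on the 5 kT double well, estimates the free-energy profile
by exponential averaging and by the second-order cumulant, and prints
the barrier summary against the analytic surface.

Outputs under results/:
    work_profiles_forward.tsv     per-replicate work vs restraint center
    fep_jarzynski.tsv             exponential-average profile
    fep_cumulant.tsv              cumulant profile
    barrier_summary.tsv           ΔG, Δ_fG‡, Δ_bG‡ vs analytic truth
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ptse import (
    PotentialSpec,
    SteeringProtocol,
    cumulant_estimate,
    jarzynski_estimate,
    run_msmd,
)
from ptse.fep import barrier_summary
from ptse.potentials import analytic_rc_profile
from ptse.tables import write_fep, write_work_profiles

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int) -> None:
    OUT.mkdir(exist_ok=True)
    spec = PotentialSpec(family="double_well_1d", barrier_height=5.0,
                         well_positions=(-1.0, 1.0), temperature=1.0)
    proto = SteeringProtocol(lambda_start=-1.2, lambda_end=1.2,
                             force_constant=300.0, velocity=0.05,
                             n_replicates=200, temperature=1.0)
    seeds = [seed * 100_003 + i for i in range(200)]
    profiles = run_msmd(spec, proto, seeds=seeds, equilibration_steps=4000,
                        dt=2.5e-4)
    fep = jarzynski_estimate(profiles, 1.0, seed=seed)
    cum = cumulant_estimate(profiles, 1.0)
    write_work_profiles(OUT / "work_profiles_forward.tsv", profiles)
    write_fep(OUT / "fep_jarzynski.tsv", fep)
    write_fep(OUT / "fep_cumulant.tsv", cum)

    bs = barrier_summary(fep, min_prominence=0.5)
    ana = analytic_rc_profile(spec, fep.rc_grid)
    pd.DataFrame([{
        "delta_G": bs.delta_G, "delta_fG": bs.delta_fG, "delta_bG": bs.delta_bG,
        "ts_position": bs.ts_position,
        "analytic_barrier": 5.0,
        "max_profile_error": float(np.abs(fep.G - ana).max()),
    }]).to_csv(OUT / "barrier_summary.tsv", sep="\t", index=False)
    print(f"Jarzynski barrier {bs.delta_fG:.2f} kT (analytic 5.00); "
          f"max profile error {np.abs(fep.G - ana).max():.2f} kT; "
          f"cumulant barrier {cum.G.max():.2f} kT")
    print(f"Tables written to {OUT}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
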