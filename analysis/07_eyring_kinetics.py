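"""Initial-rate extraction and Eyring activation-parameter analysis.

Generates synthetic product time courses and temperature-dependent
rate constants around the reference activation parameters
(ΔH‡ = 15.3 kcal/mol, ΔS‡ = −5.7 cal/mol/K over 293–333 K), then
recovers both through the initial-rate and Eyring-fit machinery.

Outputs under results/:
    rate_table.tsv      synthetic temperature-dependent rate constants
    eyring_fit.tsv      recovered ΔH‡/ΔS‡ with SEs and diagnostics
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ptse import RateMeasurement, eyring_fit, eyring_rate, initial_rate
from ptse.tables import write_rate_table

OUT = Path(__file__).resolve().parents[1] / "results"

DH_TRUE, DS_TRUE = 15.3, -5.7  # kcal/mol, cal/mol/K


def main(seed: int) -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    # initial-rate extraction from a product time course
    t = np.linspace(0.0, 10.0, 10)  # min
    k_true, enzyme = 4.0, 0.05
    course = enzyme * k_true * t + rng.normal(0, 0.02, len(t))
    k_obs, se, diag = initial_rate(t, course, enzyme)
    print(f"Initial rate: k_obs = {k_obs:.2f} ± {se:.2f} min⁻¹ "
          f"(true 4.00, window {diag['window_points']}/{len(t)} points)")

    # temperature series with 3% multiplicative noise
    T = np.linspace(293.0, 333.0, 9)
    k = eyring_rate(DH_TRUE, DS_TRUE, T) * np.exp(rng.normal(0, 0.03, len(T)))
    ms = [RateMeasurement(t_, kk, se=0.03 * kk, condition="Ca2+")
          for t_, kk in zip(T, k)]
    write_rate_table(OUT / "rate_table.tsv", ms)
    fit = eyring_fit(ms)
    pd.DataFrame([{
        "delta_H_kcal_mol": fit.delta_H, "delta_H_se": fit.delta_H_se,
        "delta_S_cal_mol_K": fit.delta_S, "delta_S_se": fit.delta_S_se,
        "delta_G_298_kcal_mol": fit.delta_G(298.15),
        "r_squared": fit.diagnostics["r_squared"],
        "true_delta_H": DH_TRUE, "true_delta_S": DS_TRUE,
    }]).to_csv(OUT / "eyring_fit.tsv", sep="\t", index=False)
    print(f"Eyring fit over {T.min():.0f}–{T.max():.0f} K: "
          f"ΔH‡ = {fit.delta_H:.1f} ± {fit.delta_H_se:.1f} kcal/mol, "
          f"ΔS‡ = {fit.delta_S:.1f} ± {fit.delta_S_se:.1f} cal/mol/K "
          f"(truth {DH_TRUE}, {DS_TRUE}); ΔG‡(298 K) = {fit.delta_G(298.15):.1f} kcal/mol")
    print(f"Tables written to {OUT}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
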