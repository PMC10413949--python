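"""Simulate digestion-phase chemical exchange and scenario metrics.

For three congeners spanning the hydrophobicity range and both enzyme
treatments, simulates the 72 h digestion phase twice: with the
strip-removal sampling schedule (laboratory emulation) and with the
plastic retained (environmentally realistic scenario).  Reports the
solid-basis LDPE concentration fold increase and the percent of total
gut chemical newly sequestered by the plastic, and writes the tidy
trajectories.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gutflux.exchange import bioavailability_reduction, fold_increase, initialize_state, simulate
from gutflux.synthetic import ScenarioSpec, make_congeners, make_kinetics_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    spec = ScenarioSpec(seed=3)
    picks = ("C01", "C05", "C10")  # low / mid / high hydrophobicity
    grid = np.unique(np.concatenate([np.linspace(0.0, 72.0, 73),
                                     np.asarray(spec.schedule)]))
    scenario_rows, traj_frames = [], []
    for enzyme in ("high", "low"):
        ds = make_kinetics_dataset(spec, enzyme)
        sys = ds["system"]
        for cg in picks:
            kp = ds["truth"][cg]
            a = ds["anchors"][cg]
            s0 = initialize_state(sys, kp, c_pom_star_day28=a["c_pom_star_day28"],
                                  c_ldpe_star0=a["c_ldpe_star0"])
            log_kow = ds["ldpe"].query("congener == @cg").log_kow.iloc[0]
            for removed, label in ((True, "strip-sampling"), (False, "plastic-retained")):
                traj = simulate(sys, kp, s0, grid, apply_removals=removed)
                scenario_rows.append({
                    "enzyme": enzyme, "congener": cg, "log_kow": log_kow,
                    "scenario": label,
                    "fold_increase_c_ldpe": fold_increase(traj),
                    "bioavailability_reduction_pct": bioavailability_reduction(traj),
                    "mass_balance_error": traj.mass_balance_error(),
                })
                f = traj.frame()
                f.insert(0, "scenario", label)
                f.insert(0, "congener", cg)
                f.insert(0, "enzyme", enzyme)
                traj_frames.append(f[f.t_h.isin(spec.schedule)])

    scen = pd.DataFrame(scenario_rows)
    scen.to_csv(OUT / "exchange_scenarios.csv", index=False)
    pd.concat(traj_frames, ignore_index=True).to_csv(
        OUT / "exchange_trajectories.csv", index=False)

    for _, r in scen.iterrows():
        print(f"{r.enzyme:4s} enzyme, {r.congener} (logKow {r.log_kow:.2f}), "
              f"{r.scenario:15s}: C*_LDPE x{r.fold_increase_c_ldpe:6.2f}, "
              f"plastic newly holds {r.bioavailability_reduction_pct:5.2f}% of gut load "
              f"(mass balance {r.mass_balance_error:.1e})")
    print(f"wrote {OUT / 'exchange_scenarios.csv'} and exchange_trajectories.csv")


if __name__ == "__main__":
    main()
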