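#!/usr/bin/env python
"""Compute plant- and animal-side network resilience (beta_eff) for every
simulated site network and summarise how beta_eff relates to richness and
connectance.

Requires 01_simulate_studies.py to have been run first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from econetres import beta_eff, network_summary, project, read_incidence

OUT = Path("results/synthetic")


def main() -> None:
    for name in ("pollination", "seed_dispersal"):
        net_dir = OUT / name / "networks"
        if not net_dir.exists():
            raise SystemExit(f"{net_dir} missing: run analysis/01_simulate_studies.py first")
        rows = []
        for f in sorted(net_dir.glob("*.csv")):
            net = read_incidence(f)
            s = network_summary(net)
            rows.append({
                "site_id": f.stem,
                "richness": s["richness"],
                "connectance": s["connectance"],
                "beta_eff_plant": beta_eff(project(net, "plant")).beta_eff,
                "beta_eff_animal": beta_eff(project(net, "animal")).beta_eff,
            })
        df = pd.DataFrame(rows).set_index("site_id")
        df.to_csv(OUT / name / "resilience.csv")
        r_plant = np.corrcoef(np.log(df["richness"]), np.log(df["beta_eff_plant"]))[0, 1]
        r_animal = np.corrcoef(np.log(df["richness"]), np.log(df["beta_eff_animal"]))[0, 1]
        print(f"{name}: {len(df)} networks; log beta_eff vs log richness "
              f"r={r_plant:.2f} (plant), r={r_animal:.2f} (animal) "
              f"-> {OUT / name / 'resilience.csv'}")


if __name__ == "__main__":
    main()
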