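#!/usr/bin/env python
"""Simulate all six GR-network topologies at reference rates.

Writes hourly fold-change trajectories and a 24 h fold-change summary
under results/, and prints the qualitative contrasts the catalogue is
built around: autoregulation-driven GR amplification in the sensitive-
cell models, its attenuation (and the Erg dip) under Erg/GR crosstalk,
and the activation-pool-only GR rise in the resistant-cell models.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from grkin.models import MODEL_NAMES, build_model
from grkin.simulate import fold_change_at, simulate
from grkin.synthetic import example_rates

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    times = np.arange(0.0, 24.01, 1.0)
    frames = []
    summary = []
    for mid, name in MODEL_NAMES.items():
        spec = build_model(mid)
        sim = simulate(spec, example_rates(mid), times=times)
        df = sim.to_frame()
        df.insert(0, "model_id", mid)
        frames.append(df)
        for (gene, level) in sorted(sim.fold):
            summary.append({
                "model_id": mid, "model": name, "observable": f"{gene}.{level}",
                "fold_24h": round(fold_change_at(sim, (gene, level), 24.0), 3)})
    pd.concat(frames, ignore_index=True).to_csv(OUT / "trajectories.csv", index=False)
    tab = pd.DataFrame(summary)
    tab.to_csv(OUT / "fold_changes_24h.csv", index=False)

    t24 = {(r["model_id"], r["observable"]): r["fold_24h"] for r in summary}
    print("24 h fold changes at the reference rate set:\n")
    print(tab.to_string(index=False))
    print(f"\nGR protein at 24 h with autoregulation alone (model 3): "
          f"{t24[(3, 'GR.protein')]}-fold; with Erg crosstalk added (model 4): "
          f"{t24[(4, 'GR.protein')]}-fold.")
    print(f"Crosstalk repression pushes Erg mRNA below baseline "
          f"(model 4, 24 h: {t24[(4, 'Erg.mrna')]}-fold).")
    print(f"Without autoregulation the resistant-cell models raise GR protein "
          f"only through the active pool (model 5: {t24[(5, 'GR.protein')]}-fold) "
          f"while GR mRNA stays at {t24[(5, 'GR.mrna')]}-fold.")


if __name__ == "__main__":
    main()
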