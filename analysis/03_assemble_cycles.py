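#!/usr/bin/env python
"""Assemble thermodynamic cycles and classify mutations.

Two passes:
1. the bundled published KIT per-state ddG table (the headline result:
   D816V both destabilizes the inactive state and overstabilizes the active
   one, total activation ddG 26.3 +/- 1.4 kJ/mol);
2. the synthetic legs estimated in 02_estimate_free_energies.py, closing
   the loop from work samples to classification.

Writes results/kit_cycle_report.json, results/kit_scatter.tsv and
results/synthetic_cycles.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from kitddg.cycles import LegResult, assemble_cycle, classify_mutation
from kitddg.estimators import FreeEnergyEstimate
from kitddg.kitdata import kit_cycles

LEGS = Path("results/leg_estimates.tsv")
RESULTS = Path("results")


def main() -> None:
    # --- published KIT values -------------------------------------------
    report = {}
    print("published KIT table:")
    for name, cyc in kit_cycles().items():
        cls = classify_mutation(cyc)
        act = (
            f"{cyc.ddg_activation.value:+.1f} +/- {cyc.ddg_activation.se:.1f}"
            if cyc.ddg_activation
            else "   n/a"
        )
        print(f"  {name}: ddG_inactive {cyc.ddg_inactive.value:+.1f}, "
              f"ddG_activation {act} -> {cls.label}")
        report[name] = {
            "ddg_inactive": cyc.ddg_inactive.value,
            "ddg_active": cyc.ddg_active.value if cyc.ddg_active else None,
            "ddg_activation": (
                cyc.ddg_activation.value if cyc.ddg_activation else None
            ),
            "label": cls.label,
            "notes": list(cyc.notes),
        }
    (RESULTS / "kit_cycle_report.json").write_text(
        json.dumps(report, indent=2) + "\n"
    )
    pd.DataFrame(
        [
            {
                "mutation": m,
                "ddg_inactive": r["ddg_inactive"],
                "ddg_active": r["ddg_active"] if r["ddg_active"] is not None else 0.0,
                "label": r["label"],
            }
            for m, r in report.items()
        ]
    ).to_csv(RESULTS / "kit_scatter.tsv", sep="\t", index=False)

    # --- synthetic legs from 02 -----------------------------------------
    if not LEGS.exists():
        print("\n(no synthetic leg estimates; run 02_estimate_free_energies.py)")
        return
    legs = pd.read_csv(LEGS, sep="\t")
    rows = []
    print("\nsynthetic cycles:")
    for mutation in sorted({t.split("_")[0] for t in legs["transformation_id"]}):
        sub = legs[legs["transformation_id"].str.startswith(f"{mutation}_")]
        cyc = assemble_cycle(
            mutation,
            [
                LegResult(
                    mutation=mutation,
                    leg=row.transformation_id.removeprefix(f"{mutation}_"),
                    estimate=FreeEnergyEstimate(
                        dg=row.dg_bar, uncertainty=row.se_bar, method="BAR"
                    ),
                )
                for row in sub.itertuples(index=False)
            ],
        )
        cls = classify_mutation(cyc)
        print(f"  {mutation}: ddG_activation "
              f"{cyc.ddg_activation.value:+.2f} +/- {cyc.ddg_activation.se:.2f}"
              f" -> {cls.label}")
        rows.append(
            {
                "mutation": mutation,
                "ddg_inactive": round(cyc.ddg_inactive.value, 3),
                "ddg_active": round(cyc.ddg_active.value, 3),
                "ddg_activation": round(cyc.ddg_activation.value, 3),
                "se_activation": round(cyc.ddg_activation.se, 3),
                "label": cls.label,
            }
        )
    pd.DataFrame(rows).to_csv(RESULTS / "synthetic_cycles.tsv", sep="\t",
                              index=False)
    print(f"-> {RESULTS / 'synthetic_cycles.tsv'}")


if __name__ == "__main__":
    main()
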