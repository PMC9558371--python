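#!/usr/bin/env python
"""Generate Crooks-consistent synthetic work tables for every cycle leg.

Stands in for the driven alchemical transitions: for each mutation x leg we
pick a ground-truth dG and a dissipation, then draw 450 forward and 450
reverse work values from the Gaussian pair that satisfies the Crooks
fluctuation theorem at 310 K.  Writes results/work_tables/<leg>.tsv plus a
ground-truth manifest for the downstream recovery check.
"""

import json
from pathlib import Path

from kitddg.workgen import WorkGenSpec, generate_cft_work_samples, write_work_tsv

OUT = Path("results/work_tables")

# (transformation_id, dg_true kJ/mol, dissipation kJ/mol); dg values chosen
# so the assembled cycles land in distinct regions of the 2-D ddG plane
LEGS = [
    ("mutA_unfolded", 2.0, 1.5),
    ("mutA_folded_inactive", 20.0, 3.0),   # inactive strongly destabilized
    ("mutA_folded_active", -4.0, 3.0),     # active stabilized -> activating
    ("mutB_unfolded", -1.0, 1.5),
    ("mutB_folded_inactive", 0.5, 3.0),    # near-neutral inactive
    ("mutB_folded_active", 11.0, 3.0),     # active destabilized -> deactivating
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for i, (tid, dg_true, dissipation) in enumerate(LEGS):
        ws = generate_cft_work_samples(
            WorkGenSpec(
                dg_true=dg_true,
                dissipation=dissipation,
                seed=100 + i,
                transformation_id=tid,
            )
        )
        path = OUT / f"{tid}.tsv"
        write_work_tsv(path, ws)
        manifest[tid] = {"dg_true": dg_true, "dissipation": dissipation}
        print(f"{tid}: {ws.n_forward}+{ws.n_reverse} transitions -> {path}")
    (OUT / "ground_truth.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print(f"ground truth manifest -> {OUT / 'ground_truth.json'}")


if __name__ == "__main__":
    main()
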