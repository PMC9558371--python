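"""Bundled per-state ddG table for the five studied KIT mutations.

The packaged TSV holds the published per-state relative stabilities of the
three oncogenic (V559A, V560D, D816V) and two piebald (G812V, V620A) KIT
mutants.  Caveats carried in the ``source`` column and surfaced by the
loader:

* D816V's inactive-state ddG is reconstructed as minus the WT-referenced
  activation baseline (19.8 +/- 0.5 kJ/mol) rather than printed standalone.
* G812V's inactive-state ddG appears twice with differing standard errors
  (0.5 and 0.4); both rows are kept and the discrepancy is flagged, with the
  first-printed value used as primary.
* V559A and V560D per-state values are shown only graphically in the source;
  the numbers here are synthetic stand-ins with the published sign and a
  plausible magnitude, flagged ``synthetic_figure_standin``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cycles import MutationCycle, ValueSE

__all__ = ["load_kit_table", "kit_cycles", "KIT_MUTATIONS"]

KIT_MUTATIONS = ("V559A", "V560D", "D816V", "G812V", "V620A")

_DATA_FILE = "kit_printed_ddg.tsv"


def load_kit_table() -> pd.DataFrame:
    """The bundled ddG table as a DataFrame.

    Columns: mutation, state (inactive|active), ddg_kJ_per_mol,
    se_kJ_per_mol, source.
    """
    ref = resources.files("kitddg.data").joinpath(_DATA_FILE)
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def kit_cycles(table: pd.DataFrame | None = None) -> dict[str, MutationCycle]:
    """Assemble the bundled table into MutationCycles keyed by mutation.

    Duplicate (mutation, state) rows — the flagged G812V inactive-state
    discrepancy — use the first row as primary; the alternates and any
    non-'printed' provenance are recorded in ``MutationCycle.notes``.
    """
    df = load_kit_table() if table is None else table
    cycles: dict[str, MutationCycle] = {}
    for mutation, grp in df.groupby("mutation", sort=False):
        values: dict[str, ValueSE] = {}
        notes: list[str] = []
        for state, rows in grp.groupby("state", sort=False):
            first = rows.iloc[0]
            values[state] = ValueSE(
                float(first["ddg_kJ_per_mol"]), float(first["se_kJ_per_mol"])
            )
            if first["source"] != "printed":
                notes.append(f"{state}: source={first['source']}")
            for _, alt in rows.iloc[1:].iterrows():
                notes.append(
                    f"{state}: alternate printing "
                    f"{alt['ddg_kJ_per_mol']} +/- {alt['se_kJ_per_mol']} "
                    f"({alt['source']}); primary uses SE "
                    f"{first['se_kJ_per_mol']}"
                )
        if "inactive" not in values:
            raise ValueError(f"{mutation}: bundled table lacks an inactive row")
        cycles[mutation] = MutationCycle(
            mutation=mutation,
            ddg_inactive=values["inactive"],
            ddg_active=values.get("active"),
            notes=tuple(notes),
        )
    return cycles
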