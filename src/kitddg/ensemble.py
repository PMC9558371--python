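"""Coordinate-ensemble container with multi-model PDB I/O.

An :class:`Ensemble` is an ordered stack of frames over a fixed atom table,
the in-memory form of a trajectory snapshot set.  Coordinates are stored in
nanometres; PDB files (angstroms) are converted on read/write.  Residue
numbers are author numbers taken verbatim from the source structure, so KIT
residues are addressable as D810, R791, K623 etc. without renumbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

ATOM_COLUMNS = ["chain", "resnum", "resname", "name"]

_NM_PER_ANGSTROM = 0.1


@dataclass
class Ensemble:
    """Frames (n_frames, n_atoms, 3) in nm over a shared atom table.

    ``atoms`` is a DataFrame with columns ``chain`` (str), ``resnum``
    (int, author numbering), ``resname`` (str), ``name`` (PDB atom name).
    """

    coords: np.ndarray
    atoms: pd.DataFrame

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None, :, :]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns {missing}")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError(
                f"atom table has {len(self.atoms)} rows but frames have "
                f"{self.coords.shape[1]} atoms"
            )
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, resnum: int, name: str, chain: str | None = None) -> int:
        """Index of the unique atom (resnum, name[, chain]); KeyError if absent."""
        mask = (self.atoms["resnum"] == resnum) & (self.atoms["name"] == name)
        if chain is not None:
            mask &= self.atoms["chain"] == chain
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise KeyError(f"no atom {name} in residue {resnum}")
        if idx.size > 1:
            raise KeyError(
                f"atom {name} in residue {resnum} is ambiguous; pass chain"
            )
        return int(idx[0])

    def select(self, predicate: "Selection") -> np.ndarray:
        """Resolve a selection into sorted atom indices.

        A selection may be a boolean mask, an integer index array, or a
        callable mapping the atom table to a boolean mask.
        """
        if callable(predicate):
            mask = np.asarray(predicate(self.atoms))
        else:
            mask = np.asarray(predicate)
        if mask.dtype == bool:
            if mask.size != self.n_atoms:
                raise ValueError("boolean selection has wrong length")
            idx = np.flatnonzero(mask)
        else:
            idx = np.unique(mask.astype(int))
            if idx.size and (idx[0] < 0 or idx[-1] >= self.n_atoms):
                raise IndexError("selection index out of range")
        if idx.size == 0:
            raise ValueError("selection matches no atoms")
        return idx

    def subset(self, predicate: "Selection") -> "Ensemble":
        idx = self.select(predicate)
        return Ensemble(self.coords[:, idx, :].copy(), self.atoms.iloc[idx])

    # ---------------------------------------------------------------- PDB I/O

    def write_pdb(self, path: str | Path) -> None:
        """Write as a multi-model PDB (MODEL/ENDMDL per frame)."""
        from Bio.PDB import PDBIO

        io = PDBIO()
        io.set_structure(self._to_biopdb())
        io.save(str(path))

    def _to_biopdb(self):
        from Bio.PDB.StructureBuilder import StructureBuilder

        builder = StructureBuilder()
        builder.init_structure("ens")
        for f in range(self.n_frames):
            builder.init_model(f)
            seen_chain = None
            seen_res = None
            serial = 1
            for i, row in enumerate(self.atoms.itertuples(index=False)):
                if row.chain != seen_chain:
                    builder.init_chain(row.chain)
                    builder.init_seg("    ")
                    seen_chain, seen_res = row.chain, None
                if row.resnum != seen_res:
                    builder.init_residue(row.resname, " ", int(row.resnum), " ")
                    seen_res = row.resnum
                builder.init_atom(
                    row.name,
                    self.coords[f, i] / _NM_PER_ANGSTROM,
                    0.0,
                    1.0,
                    " ",
                    _pdb_fullname(row.name),
                    serial,
                    element=row.name[0],
                )
                serial += 1
        return builder.get_structure()

    @classmethod
    def from_pdb(cls, path: str | Path) -> "Ensemble":
        """Read a single- or multi-model PDB file."""
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("ens", str(path))
        models = list(structure)
        if not models:
            raise ValueError(f"no models in {path}")

        rows = []
        ref_atoms = []
        for chain in models[0]:
            for residue in chain:
                for atom in residue:
                    rows.append(
                        (
                            chain.id,
                            int(residue.id[1]),
                            residue.resname.strip(),
                            atom.get_name(),
                        )
                    )
                    ref_atoms.append((chain.id, residue.id, atom.get_name()))
        atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)

        coords = np.empty((len(models), len(rows), 3), dtype=float)
        for f, model in enumerate(models):
            for i, (chain_id, res_id, atom_name) in enumerate(ref_atoms):
                try:
                    coords[f, i] = model[chain_id][res_id][atom_name].coord
                except KeyError as exc:
                    raise ValueError(
                        f"model {f} is missing atom {atom_name} of residue "
                        f"{res_id[1]} (all frames must share the atom table)"
                    ) from exc
        return cls(coords * _NM_PER_ANGSTROM, atoms)


Selection = Callable[[pd.DataFrame], "np.ndarray"] | np.ndarray | Sequence[int]


def _pdb_fullname(name: str) -> str:
    # PDB columns 13-16: pad 1-3 character names with a leading blank
    return name if len(name) >= 4 else f" {name:<3s}"


def backbone_mask(
    atoms: pd.DataFrame, residue_ranges: Sequence[tuple[int, int]] | None = None
) -> np.ndarray:
    """Boolean mask for backbone atoms N, CA, C, O, optionally restricted to
    inclusive author-numbered residue ranges."""
    mask = atoms["name"].isin(["N", "CA", "C", "O"]).to_numpy()
    if residue_ranges is not None:
        in_range = np.zeros(len(atoms), dtype=bool)
        resnum = atoms["resnum"].to_numpy()
        for lo, hi in residue_ranges:
            in_range |= (resnum >= lo) & (resnum <= hi)
        mask &= in_range
    return mask
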