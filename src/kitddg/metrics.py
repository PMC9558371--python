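"""Structural activation-state metrics for kinase coordinate ensembles.

Implements the descriptor set used to monitor KIT activation on trajectory
snapshots: backbone dihedrals of the DFG motif (D810, F811) and the HDR
arginine (R791), the catalytic salt-bridge distances K623-E640 and
K623-D810, and principal component analysis of backbone fluctuations —
globally over the kinase-domain residue ranges 571-688 and 763-930, or
restricted to the catalytic/regulatory spine residues — with projection of
further ensembles or deposited structures onto a reference model.

Conventions
-----------
* Dihedrals follow the standard right-handed (IUPAC) sign convention and are
  reported in degrees on (-180, 180].
* Psi is measured to the carbonyl oxygen (atoms N-CA-C-O) by default; the
  conventional definition via the next residue's amide nitrogen is available
  through ``convention="amide"``.
* PCA superposes every frame onto the mean structure of the selection by
  least squares (uniform weights, no masses) before building the 3Nx3N
  covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .ensemble import Ensemble, Selection, backbone_mask

__all__ = [
    "MetricSeries",
    "PCAModel",
    "dihedral_angle",
    "residue_phi",
    "residue_psi",
    "dfg_descriptor",
    "hdr_descriptor",
    "salt_bridge_distance",
    "fit_pca",
    "spine_pca",
    "project",
    "subsample_evenly",
    "GLOBAL_PCA_RESIDUE_RANGES",
    "CATALYTIC_SPINE_RESIDUES",
    "REGULATORY_SPINE_RESIDUES",
]

#: Kinase-domain backbone ranges (author numbering) for the global PCA.
GLOBAL_PCA_RESIDUE_RANGES: tuple[tuple[int, int], ...] = ((571, 688), (763, 930))
#: Catalytic-spine residues; the regulatory spine follows.  (The duplicated
#: catalytic-spine leucine in some listings is L799.)
CATALYTIC_SPINE_RESIDUES: tuple[int, ...] = (621, 603, 678, 798, 799, 800)
REGULATORY_SPINE_RESIDUES: tuple[int, ...] = (656, 644, 811, 790)


@dataclass(frozen=True)
class MetricSeries:
    """A named per-frame scalar series with units ('degrees' or 'nm')."""

    name: str
    values: np.ndarray
    units: str

    def __post_init__(self):
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self)), self.name: self.values}
        )


# --------------------------------------------------------------------------
# dihedrals
# --------------------------------------------------------------------------


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion p1-p2-p3-p4 in degrees on (-180, 180].

    Right-handed convention: looking down the p2->p3 axis, the angle is
    positive when the far bond (p3->p4) is rotated clockwise from the near
    bond (p2->p1).  A cis (eclipsed) arrangement gives 0, trans gives 180.

    Raises ValueError when consecutive points coincide or the three bond
    vectors around an axis are collinear (undefined plane).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) == 0:
            raise ValueError("consecutive dihedral points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise ValueError("collinear triple: dihedral plane undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    ang = np.degrees(np.arctan2(y, x))
    return float(180.0 if np.isclose(ang, -180.0) else ang)


def _dihedral_series(
    ens: Ensemble, quad: Sequence[int], name: str
) -> MetricSeries:
    vals = np.array(
        [
            dihedral_angle(*(ens.coords[f, i] for i in quad))
            for f in range(ens.n_frames)
        ]
    )
    return MetricSeries(name=name, values=vals, units="degrees")


PsiConvention = Literal["carbonyl", "amide"]


def residue_phi(
    ens: Ensemble, resnum: int, chain: str | None = None
) -> MetricSeries:
    """Backbone phi of residue ``resnum``: C(resnum-1)-N-CA-C, per frame.

    Needs residue ``resnum - 1``; requesting phi of a chain's first residue
    raises KeyError.
    """
    quad = [
        ens.atom_index(resnum - 1, "C", chain),
        ens.atom_index(resnum, "N", chain),
        ens.atom_index(resnum, "CA", chain),
        ens.atom_index(resnum, "C", chain),
    ]
    return _dihedral_series(ens, quad, f"phi_{resnum}")


def residue_psi(
    ens: Ensemble,
    resnum: int,
    chain: str | None = None,
    convention: PsiConvention = "carbonyl",
) -> MetricSeries:
    """Backbone psi of residue ``resnum``, per frame.

    The default 'carbonyl' convention measures N-CA-C-O (the torsion to the
    residue's own carbonyl oxygen); 'amide' measures the textbook
    N-CA-C-N(resnum+1).  The two differ by ~180 degrees.
    """
    if convention == "carbonyl":
        last = ens.atom_index(resnum, "O", chain)
    elif convention == "amide":
        last = ens.atom_index(resnum + 1, "N", chain)
    else:
        raise ValueError(f"unknown psi convention {convention!r}")
    quad = [
        ens.atom_index(resnum, "N", chain),
        ens.atom_index(resnum, "CA", chain),
        ens.atom_index(resnum, "C", chain),
        last,
    ]
    return _dihedral_series(ens, quad, f"psi_{resnum}")


def dfg_descriptor(
    ens: Ensemble,
    asp_resnum: int = 810,
    phe_resnum: int = 811,
    convention: PsiConvention = "carbonyl",
) -> dict[str, MetricSeries]:
    """Phi/psi of the DFG aspartate and phenylalanine (D810/F811 in KIT).

    Returns the four raw angle series keyed ``phi_810`` etc.; no in/out
    binary call is made (the classification boundary is left to the user).
    """
    return {
        f"phi_{asp_resnum}": residue_phi(ens, asp_resnum),
        f"psi_{asp_resnum}": residue_psi(ens, asp_resnum, convention=convention),
        f"phi_{phe_resnum}": residue_phi(ens, phe_resnum),
        f"psi_{phe_resnum}": residue_psi(ens, phe_resnum, convention=convention),
    }


def hdr_descriptor(ens: Ensemble, arg_resnum: int = 791) -> MetricSeries:
    """HDR-motif orientation: phi of the HDR arginine (R791 in KIT)."""
    return residue_phi(ens, arg_resnum)


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------

_AMINE_NITROGENS = ("NZ",)
_CARBOXYLATE_OXYGENS = ("OE1", "OE2", "OD1", "OD2")


def salt_bridge_distance(
    ens: Ensemble,
    lys_resnum: int,
    acidic_resnum: int,
    chain: str | None = None,
) -> MetricSeries:
    """Minimum lysine amine-N to carboxylate-O distance per frame, in nm.

    The per-frame value is the minimum over all NZ x {OE1,OE2} (Glu) or
    NZ x {OD1,OD2} (Asp) pairs, so it is invariant to the chemically
    arbitrary OE1/OE2 (OD1/OD2) labeling.
    """
    atoms = ens.atoms
    def _side_chain(resnum, names):
        mask = (atoms["resnum"] == resnum) & atoms["name"].isin(names)
        if chain is not None:
            mask &= atoms["chain"] == chain
        return np.flatnonzero(mask.to_numpy())

    n_idx = _side_chain(lys_resnum, _AMINE_NITROGENS)
    o_idx = _side_chain(acidic_resnum, _CARBOXYLATE_OXYGENS)
    if n_idx.size == 0:
        raise KeyError(f"residue {lys_resnum} has no amine nitrogen (NZ)")
    if o_idx.size == 0:
        raise KeyError(
            f"residue {acidic_resnum} has no carboxylate oxygens "
            f"{_CARBOXYLATE_OXYGENS}"
        )
    diff = (
        ens.coords[:, n_idx, None, :] - ens.coords[:, None, o_idx, :]
    )  # (F, nN, nO, 3)
    dist = np.sqrt((diff**2).sum(axis=-1)).min(axis=(1, 2))
    return MetricSeries(
        name=f"dist_{lys_resnum}_{acidic_resnum}", values=dist, units="nm"
    )


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PCAModel:
    """PCA of superposed coordinate fluctuations over an atom selection.

    ``mean`` (n_sel, 3) is the converged superposition reference; ``modes``
    (n_modes, 3*n_sel) are orthonormal rows sorted by non-increasing
    ``variances`` (nm^2).  ``atom_indices`` records the selection within the
    fitted ensemble's atom table; ``atoms`` the corresponding rows.
    """

    mean: np.ndarray
    modes: np.ndarray
    variances: np.ndarray
    atom_indices: np.ndarray
    atoms: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def explained_fraction(self) -> np.ndarray:
        total = self.variances.sum()
        if total == 0:
            raise ZeroDivisionError("model has zero total variance")
        return self.variances / total

    def to_dict(self) -> dict:
        return {
            "mean_nm": self.mean.tolist(),
            "modes": self.modes.tolist(),
            "variances_nm2": self.variances.tolist(),
            "atoms": self.atoms.to_dict(orient="list"),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        atoms = pd.DataFrame(d["atoms"])
        return cls(
            mean=np.asarray(d["mean_nm"], dtype=float),
            modes=np.asarray(d["modes"], dtype=float),
            variances=np.asarray(d["variances_nm2"], dtype=float),
            atom_indices=np.arange(len(atoms)),
            atoms=atoms,
            meta=dict(d.get("meta", {})),
        )


def _kabsch_superpose(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares superpose each frame of (F, N, 3) onto ref (N, 3)."""
    ref_c = ref - ref.mean(axis=0)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        x = coords[f]
        x_c = x - x.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, x_c)
        out[f] = rot.apply(x_c) + ref.mean(axis=0)
    return out


class ZeroCovarianceError(ValueError):
    """All frames identical over the selection: covariance is zero."""


def fit_pca(
    ens: Ensemble,
    selection: Selection | None = None,
    superpose: bool = True,
    max_iter: int = 10,
) -> PCAModel:
    """PCA of the 3Nx3N covariance of (superposed) selection coordinates.

    Each frame is least-squares superposed onto the running mean structure
    of the selection (iterated to convergence, uniform weights); the
    covariance of the flattened coordinates is then eigendecomposed.  Modes
    are orthonormal and variances sorted non-increasing.

    ``selection=None`` uses all atoms.  At least two frames are required;
    an ensemble whose frames are all identical raises
    :class:`ZeroCovarianceError`.
    """
    if ens.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    idx = (
        np.arange(ens.n_atoms) if selection is None else ens.select(selection)
    )
    sub = ens.coords[:, idx, :]
    if superpose:
        ref = sub[0]
        for _ in range(max_iter):
            aligned = _kabsch_superpose(sub, ref)
            new_ref = aligned.mean(axis=0)
            if np.max(np.abs(new_ref - ref)) < 1e-12:
                ref = new_ref
                break
            ref = new_ref
        sub = _kabsch_superpose(sub, ref)
    mean = sub.mean(axis=0)
    flat = sub.reshape(ens.n_frames, -1) - mean.ravel()
    cov = flat.T @ flat / (ens.n_frames - 1)
    if not np.any(cov):
        raise ZeroCovarianceError(
            "all frames identical over the selection; covariance is zero"
        )
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows are modes
    return PCAModel(
        mean=mean,
        modes=evecs,
        variances=evals,
        atom_indices=idx,
        atoms=ens.atoms.iloc[idx].reset_index(drop=True),
        meta={
            "superposed": bool(superpose),
            "mass_weighted": False,
            "n_frames": ens.n_frames,
        },
    )


def spine_pca(
    ens: Ensemble,
    catalytic: Sequence[int] = CATALYTIC_SPINE_RESIDUES,
    regulatory: Sequence[int] = REGULATORY_SPINE_RESIDUES,
    superpose: bool = True,
) -> PCAModel:
    """PCA restricted to the catalytic- and regulatory-spine residues.

    Raises KeyError naming any spine residue absent from the atom table.
    """
    wanted = list(catalytic) + list(regulatory)
    present = set(ens.atoms["resnum"].tolist())
    missing = [r for r in wanted if r not in present]
    if missing:
        raise KeyError(f"spine residues missing from ensemble: {missing}")
    mask = ens.atoms["resnum"].isin(wanted).to_numpy()
    model = fit_pca(ens, mask, superpose=superpose)
    model.meta["spine_residues"] = wanted
    return model


def project(model: PCAModel, ens: Ensemble | np.ndarray) -> np.ndarray:
    """Project frames onto the model's modes: (n_frames, n_modes).

    Accepts an Ensemble (the model's atom selection is re-resolved against
    its atom table by residue number + atom name) or a raw coordinate array
    of shape (n_frames, n_sel, 3) already matching the model selection.
    Frames are superposed onto the model mean before subtracting it.
    """
    if isinstance(ens, Ensemble):
        try:
            idx = np.array(
                [
                    ens.atom_index(int(r.resnum), r.name, None)
                    for r in model.atoms.itertuples(index=False)
                ]
            )
        except KeyError as exc:
            raise KeyError(f"ensemble does not match model selection: {exc}")
        sub = ens.coords[:, idx, :]
    else:
        sub = np.asarray(ens, dtype=float)
        if sub.ndim == 2:
            sub = sub[None, :, :]
        if sub.shape[1:] != model.mean.shape:
            raise ValueError(
                f"coordinate block {sub.shape[1:]} does not match model "
                f"selection {model.mean.shape}"
            )
    if model.meta.get("superposed", True):
        sub = _kabsch_superpose(sub, model.mean)
    flat = sub.reshape(sub.shape[0], -1) - model.mean.ravel()
    return flat @ model.modes.T


def subsample_evenly(ens: Ensemble, n: int = 750) -> Ensemble:
    """Evenly spaced frame subset of size ``n``, always keeping both ends.

    Indices are ``round(k*(F-1)/(n-1))`` for k = 0..n-1 (just frame 0 when
    n = 1).  Requires 1 <= n <= n_frames.
    """
    f = ens.n_frames
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > f:
        raise ValueError(f"cannot take {n} snapshots from {f} frames")
    if n == 1:
        idx = np.array([0])
    else:
        idx = np.rint(np.arange(n) * (f - 1) / (n - 1)).astype(int)
    return Ensemble(ens.coords[idx].copy(), ens.atoms)
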