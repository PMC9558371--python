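"""Synthetic-data generators: Crooks-consistent work samples and toy ensembles.

The generators stand in for the expensive upstream stages of the pipeline
(equilibrium MD and driven alchemical transitions) with analytically
controlled output:

* :func:`generate_cft_work_samples` draws forward/reverse work from the
  unique Gaussian pair that satisfies the Crooks fluctuation theorem exactly
  at a chosen dG and mean dissipated work, via the fluctuation-dissipation
  width ``sigma^2 = 2 W_diss / beta``.
* :func:`generate_peptide_frames` builds idealized-geometry backbone chains
  with prescribed phi/psi dihedrals by internal-coordinate (NeRF)
  construction, for round-trip testing of the dihedral metrics.
* :func:`generate_gaussian_ensemble` samples frames around a mean structure
  along prescribed orthogonal modes with prescribed variances, for PCA
  recovery tests.
* :func:`generate_salt_bridge_ensemble` places lysine amine / acidic
  carboxylate side-chain sites at prescribed minimum distances.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import beta_from_temperature
from .ensemble import ATOM_COLUMNS, Ensemble
from .estimators import WorkSet

__all__ = [
    "WorkGenSpec",
    "DihedralSpec",
    "EnsembleGenSpec",
    "generate_cft_work_samples",
    "generate_peptide_frames",
    "generate_gaussian_ensemble",
    "generate_salt_bridge_ensemble",
    "rigid_body_modes",
    "write_work_tsv",
    "read_work_tsv",
]

#: Transitions per direction used in the source study's alchemical protocol.
DEFAULT_N_TRANSITIONS = 450
DEFAULT_TEMPERATURE_K = 310.0


@dataclass(frozen=True)
class WorkGenSpec:
    """Parameters of one synthetic forward/reverse work experiment.

    ``dg_true`` is the target free-energy difference (kJ/mol); ``dissipation``
    the mean dissipated work per transition (kJ/mol, >= 0).  Forward work is
    N(dg_true + dissipation, 2*dissipation/beta) and reverse work
    N(-dg_true + dissipation, same variance), the Gaussian pair that obeys
    the Crooks relation exactly.
    """

    dg_true: float
    dissipation: float
    n_forward: int = DEFAULT_N_TRANSITIONS
    n_reverse: int = DEFAULT_N_TRANSITIONS
    temperature: float = DEFAULT_TEMPERATURE_K
    seed: int = 0
    transformation_id: str = "synthetic"

    def __post_init__(self):
        if self.dissipation < 0:
            raise ValueError("dissipation must be >= 0")
        if self.n_forward < 1 or self.n_reverse < 1:
            raise ValueError("need at least one transition per direction")
        beta_from_temperature(self.temperature)


def generate_cft_work_samples(spec: WorkGenSpec) -> WorkSet:
    """Draw a WorkSet satisfying the Crooks fluctuation theorem at spec values.

    At zero dissipation the distributions collapse to point masses at
    ``+dg_true`` (forward) and ``-dg_true`` (reverse).  The generating
    ``dg_true`` is recorded in ``WorkSet.meta`` for test oracles only.
    """
    beta = beta_from_temperature(spec.temperature)
    sigma = np.sqrt(2.0 * spec.dissipation / beta)
    rng = np.random.default_rng(spec.seed)
    forward = spec.dg_true + spec.dissipation + sigma * rng.standard_normal(
        spec.n_forward
    )
    reverse = -spec.dg_true + spec.dissipation + sigma * rng.standard_normal(
        spec.n_reverse
    )
    return WorkSet(
        forward_work=forward,
        reverse_work=reverse,
        temperature=spec.temperature,
        transformation_id=spec.transformation_id,
        meta={"dg_true": spec.dg_true, "dissipation": spec.dissipation},
    )


# --------------------------------------------------------------------------
# peptide backbone construction (NeRF internal coordinates)
# --------------------------------------------------------------------------

# idealized backbone geometry, lengths in nm and angles in degrees
_BOND_N_CA = 0.1458
_BOND_CA_C = 0.1525
_BOND_C_N = 0.1329
_BOND_C_O = 0.1231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8
_OMEGA_TRANS = 180.0


@dataclass(frozen=True)
class DihedralSpec:
    """Per-frame dihedral targets for a synthetic backbone chain.

    ``phi`` and ``psi`` map author residue numbers to either a scalar target
    (replicated over frames) or a length-``n_frames`` sequence, in degrees on
    (-180, 180].  Psi here is the carbonyl-oxygen torsion N-CA-C-O, matching
    the measurement convention in :mod:`kitddg.metrics`.  Unlisted residues
    fall back to an extended-chain default.  Gaussian noise of ``noise_sd``
    degrees is added independently per frame and dihedral.
    """

    n_residues: int
    n_frames: int = 1
    phi: Mapping[int, float | Sequence[float]] = field(default_factory=dict)
    psi: Mapping[int, float | Sequence[float]] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    first_resnum: int = 1
    chain_id: str = "A"
    resname: str = "ALA"

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("chain needs >= 2 residues")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for table, label in ((self.phi, "phi"), (self.psi, "psi")):
            for resnum, target in table.items():
                vals = np.atleast_1d(np.asarray(target, dtype=float))
                if np.any(vals <= -180.0) or np.any(vals > 180.0):
                    raise ValueError(
                        f"{label}[{resnum}] outside (-180, 180]: {target}"
                    )
                if vals.size not in (1, self.n_frames):
                    raise ValueError(
                        f"{label}[{resnum}] must be scalar or length n_frames"
                    )

    def _targets(self, table, default: float) -> np.ndarray:
        """(n_frames, n_residues) array of targets."""
        out = np.full((self.n_frames, self.n_residues), default, dtype=float)
        for resnum, target in table.items():
            i = resnum - self.first_resnum
            if not 0 <= i < self.n_residues:
                raise ValueError(f"residue {resnum} outside the chain")
            out[:, i] = np.asarray(target, dtype=float)
        return out


_DEFAULT_PHI = -120.0
_DEFAULT_PSI = -40.0  # carbonyl-O torsion of an extended chain (psi_N ~ 140)


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Next atom position from three predecessors and internal coordinates."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def generate_peptide_frames(spec: DihedralSpec) -> Ensemble:
    """Build backbone frames whose measured dihedrals match the spec targets.

    Atoms N, CA, C, O per residue with idealized bond lengths/angles and
    trans peptide bonds; measuring phi (C-N-CA-C) or psi (N-CA-C-O) on the
    output reproduces each target within ``noise_sd`` plus numerical
    round-off.
    """
    rng = np.random.default_rng(spec.seed)
    phi_t = spec._targets(spec.phi, _DEFAULT_PHI)
    psi_t = spec._targets(spec.psi, _DEFAULT_PSI)
    if spec.noise_sd > 0:
        phi_t = phi_t + rng.normal(0.0, spec.noise_sd, phi_t.shape)
        psi_t = psi_t + rng.normal(0.0, spec.noise_sd, psi_t.shape)

    n_res = spec.n_residues
    coords = np.empty((spec.n_frames, 4 * n_res, 3))
    for f in range(spec.n_frames):
        xyz = np.empty((4 * n_res, 3))
        # residue 0 seed triad in the xy-plane
        n0 = np.array([0.0, 0.0, 0.0])
        ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
        ang = np.deg2rad(180.0 - _ANGLE_N_CA_C)
        c0 = ca0 + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
        xyz[0], xyz[1], xyz[2] = n0, ca0, c0
        xyz[3] = _place_atom(n0, ca0, c0, _BOND_C_O, _ANGLE_CA_C_O, psi_t[f, 0])
        prev_n, prev_ca, prev_c = n0, ca0, c0
        for i in range(1, n_res):
            n_i = _place_atom(
                prev_n, prev_ca, prev_c, _BOND_C_N, _ANGLE_CA_C_N,
                psi_t[f, i - 1] + 180.0,
            )
            ca_i = _place_atom(
                prev_ca, prev_c, n_i, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA_TRANS
            )
            c_i = _place_atom(
                prev_c, n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi_t[f, i]
            )
            o_i = _place_atom(n_i, ca_i, c_i, _BOND_C_O, _ANGLE_CA_C_O, psi_t[f, i])
            base = 4 * i
            xyz[base], xyz[base + 1], xyz[base + 2], xyz[base + 3] = (
                n_i, ca_i, c_i, o_i,
            )
            prev_n, prev_ca, prev_c = n_i, ca_i, c_i
        coords[f] = xyz

    rows = []
    for i in range(n_res):
        resnum = spec.first_resnum + i
        for name in ("N", "CA", "C", "O"):
            rows.append((spec.chain_id, resnum, spec.resname, name))
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return Ensemble(coords, atoms)


# --------------------------------------------------------------------------
# Gaussian mode ensembles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleGenSpec:
    """A low-rank Gaussian ensemble: mean structure plus orthogonal modes.

    ``mean`` has shape (n_atoms, 3) in nm; ``modes`` (n_modes, n_atoms*3),
    pairwise orthogonal within ``orth_tol`` (they are normalized internally);
    ``variances`` in nm^2.  Frame k = mean + sum_m z_km * mode_m with
    z_km ~ N(0, variance_m).
    """

    mean: np.ndarray
    modes: np.ndarray
    variances: Sequence[float]
    n_frames: int
    seed: int = 0
    atoms: pd.DataFrame | None = None
    orth_tol: float = 1e-8

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        modes = np.asarray(self.modes, dtype=float)
        variances = np.asarray(self.variances, dtype=float)
        if mean.ndim != 2 or mean.shape[1] != 3:
            raise ValueError("mean must have shape (n_atoms, 3)")
        if modes.ndim != 2 or modes.shape[1] != mean.size:
            raise ValueError("modes must have shape (n_modes, n_atoms*3)")
        if np.any(variances < 0):
            raise ValueError("variances must be >= 0")
        if variances.size != modes.shape[0]:
            raise ValueError("one variance per mode required")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        norms = np.linalg.norm(modes, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length mode vector")
        unit = modes / norms[:, None]
        gram = unit @ unit.T
        off = gram - np.diag(np.diag(gram))
        if np.max(np.abs(off)) > self.orth_tol:
            raise ValueError("mode vectors are not pairwise orthogonal")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "modes", unit)
        object.__setattr__(self, "variances", variances)


def generate_gaussian_ensemble(spec: EnsembleGenSpec) -> Ensemble:
    """Sample frames mean + sum_m z_m * mode_m, z_m ~ N(0, variance_m)."""
    rng = np.random.default_rng(spec.seed)
    n_atoms = spec.mean.shape[0]
    z = rng.standard_normal((spec.n_frames, len(spec.variances))) * np.sqrt(
        np.asarray(spec.variances)
    )
    disp = z @ spec.modes  # (n_frames, n_atoms*3)
    coords = spec.mean[None, :, :] + disp.reshape(spec.n_frames, n_atoms, 3)
    if spec.atoms is not None:
        atoms = spec.atoms
    else:
        atoms = pd.DataFrame(
            [("A", i + 1, "GLY", "CA") for i in range(n_atoms)],
            columns=ATOM_COLUMNS,
        )
    return Ensemble(coords, atoms)


def rigid_body_modes(mean: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, n_atoms*3) of rigid translations and rotations
    linearized at ``mean``.

    Useful for planting PCA modes that survive least-squares superposition
    unchanged: project candidate modes against this basis first.
    """
    mean = np.asarray(mean, dtype=float)
    n = mean.shape[0]
    centred = mean - mean.mean(axis=0)
    basis = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        basis.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(e, centred).ravel())
    basis = np.array(basis)
    # orthonormalize (rotations about different axes are not orthogonal in general)
    q, _ = np.linalg.qr(basis.T)
    return q.T[: basis.shape[0]]


def generate_salt_bridge_ensemble(
    distances_nm: Sequence[float],
    lys_resnum: int = 623,
    acidic_resnum: int = 640,
    acidic_resname: str = "GLU",
    decoy_offset_nm: float = 0.2,
    chain_id: str = "A",
) -> Ensemble:
    """Fixture ensemble realizing a prescribed K(NZ)-acid(O) minimum distance.

    Per frame, the lysine NZ sits at the origin, the nearer carboxylate
    oxygen at the prescribed distance along +x, and the second oxygen
    ``decoy_offset_nm`` farther out, so the min-over-pairs distance equals
    the prescribed series exactly.  Only the side-chain sites the salt-bridge
    metric reads (NZ and OE1/OE2 or OD1/OD2) are placed.
    """
    distances = np.asarray(distances_nm, dtype=float)
    if distances.ndim != 1 or distances.size == 0:
        raise ValueError("distances_nm must be a non-empty 1-D sequence")
    if np.any(distances < 0):
        raise ValueError("distances must be >= 0")
    o_names = ("OE1", "OE2") if acidic_resname == "GLU" else ("OD1", "OD2")
    rows = [
        (chain_id, lys_resnum, "LYS", "NZ"),
        (chain_id, acidic_resnum, acidic_resname, o_names[0]),
        (chain_id, acidic_resnum, acidic_resname, o_names[1]),
    ]
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    coords = np.zeros((distances.size, 3, 3))
    coords[:, 1, 0] = distances
    coords[:, 2, 0] = distances + decoy_offset_nm
    return Ensemble(coords, atoms)


# --------------------------------------------------------------------------
# work-table TSV dialect
# --------------------------------------------------------------------------

WORK_TSV_COLUMNS = ["transformation_id", "direction", "work_kJ_per_mol"]


def write_work_tsv(
    path: str | Path,
    worksets: WorkSet | Sequence[WorkSet],
    header_comments: Sequence[str] = (),
) -> None:
    """Write WorkSets as TSV: one row per transition.

    Columns: transformation_id, direction (forward|reverse), work_kJ_per_mol.
    Temperature is recorded as a ``# temperature_K=`` comment line.
    """
    if isinstance(worksets, WorkSet):
        worksets = [worksets]
    temps = {ws.temperature for ws in worksets}
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        for t in sorted(temps):
            fh.write(f"# temperature_K={t!r}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(WORK_TSV_COLUMNS)
        for ws in worksets:
            for w in ws.forward_work:
                writer.writerow([ws.transformation_id, "forward", repr(float(w))])
            for w in ws.reverse_work:
                writer.writerow([ws.transformation_id, "reverse", repr(float(w))])


def read_work_tsv(
    path: str | Path, temperature: float | None = None
) -> list[WorkSet]:
    """Parse the work TSV dialect back into WorkSets (one per transformation).

    The temperature comes from the ``# temperature_K=`` comment unless
    overridden.  Malformed rows are reported with their line number.  Rows
    sharing a transformation_id are pooled; ids whose rows appear in
    non-contiguous blocks are pooled too (a caller-visible warning is left to
    the CLI, which logs them).
    """
    groups: dict[str, dict[str, list[float]]] = {}
    order: list[str] = []
    file_temp = None
    with open(path) as fh:
        lines = list(fh)
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "temperature_K=" in line:
                file_temp = float(line.split("temperature_K=")[1])
            continue
        parts = line.split("\t")
        if not header_seen:
            if parts != WORK_TSV_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected header {WORK_TSV_COLUMNS}, "
                    f"got {parts}"
                )
            header_seen = True
            continue
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        tid, direction, work_s = parts
        if direction not in ("forward", "reverse"):
            raise ValueError(
                f"{path}:{lineno}: direction must be forward|reverse, got "
                f"{direction!r}"
            )
        try:
            work = float(work_s)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: work value {work_s!r} is not a number"
            ) from None
        if tid not in groups:
            groups[tid] = {"forward": [], "reverse": []}
            order.append(tid)
        groups[tid][direction].append(work)
    if not header_seen:
        raise ValueError(f"{path}: empty work table (no header)")
    if not groups:
        raise ValueError(f"{path}: work table contains no transitions")
    temp = temperature if temperature is not None else file_temp
    if temp is None:
        raise ValueError(
            f"{path}: no temperature_K comment in file and none supplied"
        )
    out = []
    for tid in order:
        g = groups[tid]
        if not g["forward"] or not g["reverse"]:
            raise ValueError(
                f"{path}: transformation {tid!r} lacks one direction"
            )
        out.append(
            WorkSet(
                forward_work=np.array(g["forward"]),
                reverse_work=np.array(g["reverse"]),
                temperature=temp,
                transformation_id=tid,
            )
        )
    return out
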