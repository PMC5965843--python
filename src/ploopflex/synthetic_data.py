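"""Synthetic inputs for the whole analysis surface.

Builds toy polypeptides with prescribed backbone dihedrals (internal-
coordinate / NeRF chain extension on an ideal-geometry table), applies known
rigid motions and peptide-bond flips to them, assembles multi-model
ensembles, and simulates fluorogenic phosphatase assay progress curves from
Michaelis-Menten kinetics.  Every generator is deterministic under a fixed
seed, so these objects serve as exact oracles for the geometry and kinetics
layers: the generating motion, flip site, or rate parameters are known by
construction.

The simulated assay reproduces the layout of a DiFMUP plate assay: product
fluorescence read at 2-minute intervals for 10 minutes at six substrate
concentrations (50, 100, 250, 500, 1000, 1500 uM), with multiplicative
Gaussian noise on each reading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .geometry_core import RigidTransform
from .kinetics import ProgressCurve, michaelis_menten_velocity
from .structure_io import AMINO3_TO_1, Atom, Chain, Model, Residue, Structure

__all__ = [
    "PeptideSpec",
    "AssaySpec",
    "build_peptide",
    "perturb_rigid",
    "make_flip_pair",
    "make_ensemble",
    "make_ploop_fixture",
    "simulate_progress_curves",
    "ideal_geometry",
]

_ONE_TO_THREE = {v: k for k, v in AMINO3_TO_1.items() if len(k) == 3}
# prefer canonical residues over modified ones for the reverse map
for _canon in ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
               "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
               "TYR", "VAL"):
    _ONE_TO_THREE[AMINO3_TO_1[_canon]] = _canon


def ideal_geometry() -> dict:
    """Versioned ideal bond length/angle table used by the peptide builder."""
    with resources.files("ploopflex.data").joinpath("ideal_geometry.json").open() as fh:
        return json.load(fh)


@dataclass
class PeptideSpec:
    """Sequence plus per-residue (phi, psi, omega) in degrees.

    ``phi[0]`` is unused (no preceding carbonyl); ``psi[-1]`` is used only to
    place the final carbonyl oxygen. ``omega[i]`` is the torsion of the
    peptide bond preceding residue i and defaults to 180 (trans).
    """

    sequence: str
    phi: Sequence[float]
    psi: Sequence[float]
    omega: Sequence[float] | None = None
    geometry_version: str = "1.0"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n < 2:
            raise ValueError("peptide needs at least 2 residues")
        for aa in self.sequence:
            if aa not in _ONE_TO_THREE:
                raise ValueError(f"invalid residue letter {aa!r}")
        if len(self.phi) != n or len(self.psi) != n:
            raise ValueError("phi/psi lists must match sequence length")
        if self.omega is None:
            self.omega = [180.0] * n
        elif len(self.omega) != n:
            raise ValueError("omega list must match sequence length")

    @classmethod
    def uniform(cls, sequence: str, phi: float = -57.0, psi: float = -47.0
                ) -> "PeptideSpec":
        n = len(sequence)
        return cls(sequence, [phi] * n, [psi] * n)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position D bonded to C with given internal coordinates."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        -bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(spec: PeptideSpec, chain_id: str = "A",
                  structure_id: str = "SYNTH") -> Structure:
    """Build backbone (N, CA, C, O) plus CB (non-Gly) from internal coordinates.

    The construction is exact: interior dihedrals recovered from the built
    coordinates equal the specification to floating-point precision.
    """
    geo = ideal_geometry()
    bl, ba, tor = geo["bond_lengths"], geo["bond_angles"], geo["torsions"]
    n_res = len(spec.sequence)

    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))

    # first residue: N at origin, CA on +x, C in the xy-plane
    N[0] = np.array([0.0, 0.0, 0.0])
    CA[0] = np.array([bl["N-CA"], 0.0, 0.0])
    th = np.deg2rad(180.0 - ba["N-CA-C"])
    C[0] = CA[0] + bl["CA-C"] * np.array([np.cos(th), np.sin(th), 0.0])

    for i in range(1, n_res):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1],
                           bl["C-N"], ba["CA-C-N"], spec.psi[i - 1])
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i],
                            bl["N-CA"], ba["C-N-CA"], spec.omega[i])
        C[i] = _place_atom(C[i - 1], N[i], CA[i],
                           bl["CA-C"], ba["N-CA-C"], spec.phi[i])

    chain = Chain(chain_id)
    serial = 1
    for i, aa in enumerate(spec.sequence):
        res = Residue(chain_id, i + 1, "", _ONE_TO_THREE[aa])
        # carbonyl O anti to the following amide nitrogen: torsion(N,CA,C,O) = psi - 180
        o_torsion = spec.psi[i] - 180.0
        O = _place_atom(N[i], CA[i], C[i], bl["C-O"], ba["CA-C-O"], o_torsion)
        for name, el, xyz in (("N", "N", N[i]), ("CA", "C", CA[i]),
                              ("C", "C", C[i]), ("O", "O", O)):
            res.atoms.append(Atom(serial, name, el, xyz))
            serial += 1
        if aa != "G":
            CB = _place_atom(C[i], N[i], CA[i], bl["CA-CB"], ba["N-CA-CB"],
                             tor["C-N-CA-CB_improper"])
            res.atoms.append(Atom(serial, "CB", "C", CB))
            serial += 1
        chain.residues.append(res)

    model = Model(chains=[chain])
    s = Structure(structure_id, [model])
    s.provenance["generator"] = {"kind": "build_peptide",
                                 "geometry_version": spec.geometry_version}
    return s


def perturb_rigid(s: Structure, axis, angle_deg: float,
                  translation=(0.0, 0.0, 0.0)) -> Structure:
    """Apply a known rigid motion to every atom; the motion is recorded in
    ``provenance`` so superposition can be checked against it exactly."""
    t = RigidTransform.from_axis_angle(axis, angle_deg, translation)
    out = s.transformed(t.rotation, t.translation)
    out.provenance["rigid_motion"] = {
        "axis": list(np.asarray(axis, float)),
        "angle_deg": float(angle_deg),
        "translation": list(np.asarray(translation, float)),
    }
    return out


def make_flip_pair(spec: PeptideSpec, flip_at: int,
                   angle_deg: float = 180.0) -> tuple[Structure, Structure]:
    """Peptide pair differing by a flip of the ``flip_at``/``flip_at``+1
    peptide bond.

    ``flip_at`` is a 1-based residue number and must be interior. The second
    structure has the peptide unit C(i), O(i), N(i+1) rotated ``angle_deg``
    (default ~180, a true flip) about the CA(i)-CA(i+1) axis; bonds to both
    flanking CA atoms are preserved, so the chain stays closed.
    """
    n = len(spec.sequence)
    if not (1 < flip_at < n):
        raise ValueError("flip site must be an interior residue")
    a = build_peptide(spec)
    b = build_peptide(spec)
    chain = b.first_chain
    res_i = chain.residues[flip_at - 1]
    res_j = chain.residues[flip_at]
    ca_i = res_i.atom("CA").coords
    ca_j = res_j.atom("CA").coords
    rot = RigidTransform.from_axis_angle(ca_j - ca_i, angle_deg)
    for atom in (res_i.atom("C"), res_i.atom("O"), res_j.atom("N")):
        atom.coords = rot.apply(atom.coords - ca_i) + ca_i
    b.provenance["flip"] = {"residue": flip_at, "angle_deg": float(angle_deg)}
    return a, b


def make_ensemble(spec: PeptideSpec, phi_samples: Sequence[float],
                  psi_samples: Sequence[float], residue: int) -> Structure:
    """Multi-model ensemble varying (phi, psi) of one residue across models."""
    if len(phi_samples) != len(psi_samples) or len(phi_samples) == 0:
        raise ValueError("need equal-length, non-empty phi/psi sample lists")
    models = []
    for ph, ps in zip(phi_samples, psi_samples):
        phi = list(spec.phi)
        psi = list(spec.psi)
        phi[residue - 1] = float(ph)
        psi[residue - 1] = float(ps)
        member = build_peptide(PeptideSpec(spec.sequence, phi, psi, spec.omega))
        models.append(member.first_model)
    s = Structure("ENSEMBLE", models)
    s.provenance["generator"] = {"kind": "make_ensemble", "n_models": len(models)}
    return s


def make_ploop_fixture(state: str = "active", motif_start: int = 1
                       ) -> Structure:
    """Eight-residue phosphate-binding-loop stand-in with controlled amide
    orientations.

    Builds the HCMGGLGR signature motif as a toy loop, then drops a
    single-atom pseudo-ligand on the side the central backbone amides point
    to (``state="active"``) or the opposite side (``state="inactive"``), so
    the loop-state classifier has a known ground truth.
    """
    if state not in ("active", "inactive"):
        raise ValueError("state must be 'active' or 'inactive'")
    spec = PeptideSpec.uniform("HCMGGLGR", phi=-70.0, psi=-30.0)
    s = build_peptide(spec)
    chain = s.first_chain
    # give the catalytic cysteine its thiol so the S-gamma pocket fallback works
    cys = chain.residues[1]
    cb, ca = cys.atom("CB"), cys.atom("CA")
    sg_dir = cb.coords - ca.coords
    sg_dir = sg_dir / np.linalg.norm(sg_dir)
    cys.atoms.append(Atom(998, "SG", "S", cb.coords + 1.81 * sg_dir))
    central = chain.residues[2:6]  # motif positions 3-6
    dirs, anchors = [], []
    for res in central:
        idx = chain.residues.index(res)
        prev = chain.residues[idx - 1]
        n = res.atom("N").coords
        h_dir = _amide_direction(n, res.atom("CA").coords, prev.atom("C").coords)
        dirs.append(h_dir)
        anchors.append(n)
    mean_dir = np.mean(dirs, axis=0)
    mean_dir /= np.linalg.norm(mean_dir)
    center = np.mean(anchors, axis=0)
    offset = 3.0 if state == "active" else -3.0
    lig = Residue("A", 900, "", "LIG")
    lig.atoms.append(Atom(999, "P1", "P", center + offset * mean_dir))
    s.first_model.hetero.append(lig)
    s.provenance["ploop_fixture"] = {"state": state}
    return s


def _amide_direction(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    """Planar-amide pseudo-hydrogen direction at a backbone nitrogen."""
    u = (ca - n) / np.linalg.norm(ca - n)
    v = (c_prev - n) / np.linalg.norm(c_prev - n)
    h = -(u + v)
    return h / np.linalg.norm(h)


# ---------------------------------------------------------------------------
# kinetics simulation

PAPER_CONCENTRATIONS_UM = (50.0, 100.0, 250.0, 500.0, 1000.0, 1500.0)


@dataclass
class AssaySpec:
    """Parameters for a simulated fluorogenic phosphatase plate assay.

    Defaults mirror the study conditions the package is designed around:
    10 nM enzyme, six substrate concentrations from 50 to 1500 uM, readings
    every 2 minutes for 10 minutes, and 2% multiplicative read noise (a
    typical plate-reader coefficient of variation).
    """

    kcat: float  # s^-1
    km_mM: float
    enzyme_nM: float = 10.0
    substrate_uM: Sequence[float] = PAPER_CONCENTRATIONS_UM
    times_min: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    noise_sd: float = 0.02
    noise_model: str = "multiplicative"  # or "additive" (sd in signal units)
    seed: int = 0
    pH: float = 5.0
    temperature_C: float = 60.0

    def __post_init__(self) -> None:
        if self.kcat <= 0 or self.km_mM <= 0 or self.enzyme_nM <= 0:
            raise ValueError("kcat, KM and enzyme concentration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.noise_model not in ("multiplicative", "additive"):
            raise ValueError("noise model must be multiplicative or additive")


def simulate_progress_curves(spec: AssaySpec) -> list[ProgressCurve]:
    """Simulate product-accumulation curves in the initial-rate regime.

    product(t) = v(S0) * t with v from the Michaelis-Menten rate law at the
    nominal substrate concentration (substrate depletion neglected over the
    short window), then multiplicative Gaussian noise per reading. A fixed
    seed yields identical curves; per-concentration streams are derived from
    the master seed so each curve is reproducible in isolation.
    """
    curves = []
    times = np.asarray(spec.times_min, float)
    vmax_uM_min = spec.kcat * spec.enzyme_nM * 60.0 / 1000.0
    for k, s0 in enumerate(spec.substrate_uM):
        rng = np.random.default_rng(int(spec.seed) * 1000 + k)
        v = michaelis_menten_velocity(s0 / 1000.0, vmax_uM_min, spec.km_mM)
        signal = v * times
        if spec.noise_sd > 0:
            eps = rng.standard_normal(len(times))
            if spec.noise_model == "multiplicative":
                signal = signal * (1.0 + spec.noise_sd * eps)
            else:
                signal = signal + spec.noise_sd * eps
        curves.append(ProgressCurve(
            times_min=times.copy(), signal=np.asarray(signal, float),
            substrate_uM=float(s0), enzyme_nM=spec.enzyme_nM,
            pH=spec.pH, temperature_C=spec.temperature_C,
        ))
    return curves
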