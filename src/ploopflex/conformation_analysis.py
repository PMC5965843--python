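"""Backbone conformation analysis.

Per-residue phi/psi/omega tables, glycine-aware Ramachandran classification,
peptide-bond flip detection between conformers, phosphate-binding-loop
(P-loop) amide-orientation scoring with active/inactive classification, and
normalized dihedral histograms over coordinate ensembles.

The deposited X-ray models carry no hydrogens, so backbone amide directions
use a pseudo-hydrogen from planar-amide geometry: the N-H unit vector is
taken opposite to the sum of the N->CA and N->C(prev) unit vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .geometry_core import dihedral, kabsch_superpose
from .structure_io import Chain, Residue, Structure

__all__ = [
    "DihedralRecord",
    "RamaClass",
    "PeptideFlipReport",
    "AmideOrientation",
    "PLoopState",
    "EnsembleDihedralHistogram",
    "backbone_dihedrals",
    "classify_rama",
    "detect_peptide_flip",
    "ploop_state",
    "ensemble_dihedral_histogram",
    "amide_pseudo_h",
    "CHAIN_BREAK_CA_DISTANCE",
    "FLIP_THRESHOLD_DEG",
    "AMIDE_COSINE_MARGIN",
]

CHAIN_BREAK_CA_DISTANCE = 4.5  # A; consecutive CA further apart => chain break
FLIP_THRESHOLD_DEG = 90.0      # carbonyl rotation above this counts as a flip
AMIDE_COSINE_MARGIN = 0.2      # mean-cosine margin for active/inactive calls


@dataclass
class DihedralRecord:
    residue: tuple[str, int, str]
    res_name: str
    phi: float | None
    psi: float | None
    omega: float | None


@dataclass
class RamaClass:
    label: str          # favored-general | allowed-general | glycine-only | outlier
    region_id: str | None


@dataclass
class PeptideFlipReport:
    residue_pair: tuple[int, int]
    carbonyl_rotation_deg: float
    flipped: bool
    threshold_deg: float = FLIP_THRESHOLD_DEG


@dataclass
class AmideOrientation:
    residue: tuple[str, int, str]
    cosine: float
    pocket_tag: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.cosine <= 1.0 + 1e-9:
            raise ValueError("cosine out of [-1, 1]")


@dataclass
class PLoopState:
    state: str  # active | inactive | indeterminate
    orientations: list[AmideOrientation]
    mean_cosine: float
    pocket_tag: str
    warning: str | None = None


@dataclass
class EnsembleDihedralHistogram:
    residue: tuple[str, int, str]
    angle_type: str
    frequencies: np.ndarray  # 36 bins of 10 degrees over (-180, 180]
    ensemble_size: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        if self.frequencies.shape != (36,):
            raise ValueError("histogram must have exactly 36 bins")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("histogram frequencies must sum to 1")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(-180.0, 180.0, 37)


# ---------------------------------------------------------------------------
# dihedral tables


def _is_connected(prev: Residue, res: Residue) -> bool:
    ca_p, ca = prev.atom("CA"), res.atom("CA")
    if ca_p is None or ca is None:
        return False
    return float(np.linalg.norm(ca.coords - ca_p.coords)) <= CHAIN_BREAK_CA_DISTANCE


def backbone_dihedrals(chain: Chain) -> list[DihedralRecord]:
    """phi/psi/omega per residue; angles absent at termini and chain breaks."""
    residues = [r for r in chain.residues]
    if not any(r.backbone_complete for r in residues):
        raise ValueError(f"chain {chain.chain_id}: no backbone-complete residues")
    records = []
    for i, r in enumerate(residues):
        phi = psi = omega = None
        prev = residues[i - 1] if i > 0 else None
        nxt = residues[i + 1] if i + 1 < len(residues) else None
        if prev is not None and not _is_connected(prev, r):
            prev = None
        if nxt is not None and not _is_connected(r, nxt):
            nxt = None
        if r.backbone_complete:
            if prev is not None and prev.atom("C") is not None:
                phi = dihedral(prev.atom("C").coords, r.atom("N").coords,
                               r.atom("CA").coords, r.atom("C").coords)
                if prev.atom("CA") is not None:
                    omega = dihedral(prev.atom("CA").coords, prev.atom("C").coords,
                                     r.atom("N").coords, r.atom("CA").coords)
            if nxt is not None and nxt.atom("N") is not None:
                psi = dihedral(r.atom("N").coords, r.atom("CA").coords,
                               r.atom("C").coords, nxt.atom("N").coords)
        records.append(DihedralRecord(r.key, r.res_name, phi, psi, omega))
    return records


# ---------------------------------------------------------------------------
# Ramachandran classification


def _load_rama_regions() -> dict:
    with resources.files("ploopflex.data").joinpath("rama_polygons.json").open() as fh:
        return json.load(fh)


_RAMA = None


def _rama() -> dict:
    global _RAMA
    if _RAMA is None:
        _RAMA = _load_rama_regions()
    return _RAMA


def _point_in_polygon(x: float, y: float, vertices: list) -> bool:
    """Ray casting with points on the boundary counted as inside."""
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # boundary check: point on segment
        dx, dy = x2 - x1, y2 - y1
        cross = dx * (y - y1) - dy * (x - x1)
        if abs(cross) < 1e-9:
            if min(x1, x2) - 1e-9 <= x <= max(x1, x2) + 1e-9 and \
               min(y1, y2) - 1e-9 <= y <= max(y1, y2) + 1e-9:
                return True
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * dx / dy
            if x < x_int:
                inside = not inside
    return inside


def _in_any(phi: float, psi: float, polygons: list) -> str | None:
    for poly in polygons:
        if _point_in_polygon(phi, psi, poly["vertices"]):
            return poly["id"]
    return None


def classify_rama(rec: DihedralRecord, res_type: str | None = None) -> RamaClass:
    """Deterministic region label from (phi, psi, residue type).

    Labels: ``favored-general`` and ``allowed-general`` for the shared
    regions; ``glycine-only`` when a glycine sits in its extended (phi > 0
    mirror) regions; ``outlier`` otherwise. A non-glycine residue in a
    glycine-only region is an outlier, which is exactly the criterion used
    to argue that a given loop conformation requires glycine.
    """
    if rec.phi is None or rec.psi is None:
        raise ValueError("cannot classify: phi or psi absent")
    res_type = (res_type or rec.res_name or "").upper()
    regions = _rama()
    hit = _in_any(rec.phi, rec.psi, regions["general_favored"])
    if hit:
        return RamaClass("favored-general", hit)
    hit = _in_any(rec.phi, rec.psi, regions["general_allowed"])
    if hit:
        return RamaClass("allowed-general", hit)
    if res_type in ("GLY", "G"):
        hit = _in_any(rec.phi, rec.psi, regions["glycine"])
        if hit:
            return RamaClass("glycine-only", hit)
    return RamaClass("outlier", None)


# ---------------------------------------------------------------------------
# peptide flips


def detect_peptide_flip(a: Structure, b: Structure, residue: int,
                        chain_a: str | None = None, chain_b: str | None = None,
                        threshold_deg: float = FLIP_THRESHOLD_DEG) -> PeptideFlipReport:
    """Compare the carbonyl orientation of ``residue`` between two conformers.

    The CA atoms of residues i-1..i+2 (those present; at least 3 required)
    are superposed between the two structures, and the rotation of the
    residue-i C=O unit vector is measured in that local frame.  Angles above
    the threshold (default 90 degrees; a genuine flip is ~180) are reported
    as flips.  Symmetric in the argument order.
    """
    ch_a = a.first_model.chain(chain_a) if chain_a else a.first_chain
    ch_b = b.first_model.chain(chain_b) if chain_b else b.first_chain
    res_a, res_a1 = _residue_pair(ch_a, residue)
    res_b, res_b1 = _residue_pair(ch_b, residue)
    for r in (res_a, res_a1, res_b, res_b1):
        if r.atom("C") is None or r.atom("O") is None or r.atom("CA") is None:
            raise ValueError(f"residue {r.seq_num}: missing backbone carbonyl atoms")

    frame_a, frame_b = [], []
    for off in (-1, 0, 1, 2):
        ra = ch_a.residue(residue + off)
        rb = ch_b.residue(residue + off)
        if ra is not None and rb is not None and \
                ra.atom("CA") is not None and rb.atom("CA") is not None:
            frame_a.append(ra.atom("CA").coords)
            frame_b.append(rb.atom("CA").coords)
    if len(frame_a) < 3:
        raise ValueError("fewer than 3 flanking CA atoms to define the local frame")
    sup = kabsch_superpose(np.array(frame_a), np.array(frame_b))

    co_a = res_a.atom("O").coords - res_a.atom("C").coords
    co_b_global = res_b.atom("O").coords - res_b.atom("C").coords
    co_b = sup.transform.rotation @ co_b_global
    cosang = float(co_a @ co_b / (np.linalg.norm(co_a) * np.linalg.norm(co_b)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return PeptideFlipReport((residue, residue + 1), angle,
                             angle > threshold_deg, threshold_deg)


def _residue_pair(chain: Chain, seq_num: int) -> tuple[Residue, Residue]:
    r = chain.residue(seq_num)
    r1 = chain.residue(seq_num + 1)
    if r is None or r1 is None:
        raise ValueError(f"residues {seq_num}/{seq_num + 1} not both present")
    return r, r1


# ---------------------------------------------------------------------------
# P-loop amide orientation


def amide_pseudo_h(res: Residue, prev: Residue) -> np.ndarray:
    """Unit N->H direction from planar-amide geometry (no hydrogens needed)."""
    n = res.atom("N").coords
    ca = res.atom("CA").coords
    c_prev = prev.atom("C").coords
    u = (ca - n) / np.linalg.norm(ca - n)
    v = (c_prev - n) / np.linalg.norm(c_prev - n)
    h = -(u + v)
    nh = np.linalg.norm(h)
    if nh < 1e-9:
        raise ValueError("degenerate amide geometry")
    return h / nh


def _pocket_center(s: Structure, chain: Chain, motif_start: int,
                   pocket: str) -> tuple[np.ndarray | None, str]:
    cys = chain.residue(motif_start + 1)  # catalytic cysteine, motif position 2
    sg = cys.atom("SG") if cys is not None else None
    if pocket in ("ligand-centroid", "auto"):
        ref = sg.coords if sg is not None else None
        if ref is None:
            ca = chain.residue(motif_start + 3)
            ref = ca.atom("CA").coords if ca is not None and ca.atom("CA") else None
        candidates = []
        for het in s.first_model.hetero:
            coords = np.array([a.coords for a in het.atoms])
            centroid = coords.mean(axis=0)
            if ref is None or np.linalg.norm(centroid - ref) <= 8.0:
                candidates.append((np.linalg.norm(centroid - ref) if ref is not None
                                   else 0.0, centroid))
        if candidates:
            candidates.sort(key=lambda t: t[0])
            return candidates[0][1], "ligand-centroid"
        if pocket == "ligand-centroid":
            return None, "ligand-centroid"
    if sg is not None:
        return sg.coords, "catalytic-S-gamma"
    return None, "unresolved"


def ploop_state(s: Structure, motif_start: int, pocket: str = "auto",
                chain: str | None = None,
                margin: float = AMIDE_COSINE_MARGIN) -> PLoopState:
    """Classify a P-loop as active or inactive from its amide orientations.

    The four central motif residues (positions 3-6, e.g. Gly95-Gly98 of the
    HCxxGxxR motif starting at 92) each contribute the cosine between their
    backbone N->H direction and the direction from N to the pocket center
    (bound-ligand centroid when present, else the catalytic cysteine Sg).
    ``active`` requires the mean cosine above +margin with at least 3 of the
    4 residues individually above it; ``inactive`` is the mirror condition;
    anything else is ``indeterminate``.
    """
    ch = s.first_model.chain(chain) if chain else s.first_chain
    motif = [ch.residue(motif_start + k) for k in range(8)]
    if any(r is None for r in motif):
        raise ValueError(f"P-loop motif residues {motif_start}-{motif_start + 7} "
                         "not all present")
    center, tag = _pocket_center(s, ch, motif_start, pocket)
    if center is None:
        return PLoopState("indeterminate", [], float("nan"), tag,
                          warning="pocket center unresolvable (no ligand in pocket)")

    orientations = []
    for k in (2, 3, 4, 5):  # central four residues of the 8-residue motif
        res = motif[k]
        prev = ch.residue(res.seq_num - 1)
        if prev is None or res.atom("N") is None or res.atom("CA") is None \
                or prev.atom("C") is None:
            raise ValueError(f"residue {res.seq_num}: incomplete amide geometry")
        h = amide_pseudo_h(res, prev)
        to_pocket = center - res.atom("N").coords
        to_pocket = to_pocket / np.linalg.norm(to_pocket)
        orientations.append(AmideOrientation(res.key, float(h @ to_pocket), tag))

    cosines = np.array([o.cosine for o in orientations])
    mean = float(cosines.mean())
    above = int((cosines > margin).sum())
    below = int((cosines < -margin).sum())
    if mean > margin and above >= 3:
        state = "active"
    elif mean < -margin and below >= 3:
        state = "inactive"
    else:
        state = "indeterminate"
    return PLoopState(state, orientations, mean, tag)


# ---------------------------------------------------------------------------
# ensemble histograms


def ensemble_dihedral_histogram(s: Structure, residue: int, angle_type: str,
                                chain: str | None = None
                                ) -> EnsembleDihedralHistogram:
    """Normalized 36-bin (10-degree) histogram of one dihedral over all models.

    Bins cover (-180, 180] and are right-inclusive; frequencies sum to 1.
    """
    if angle_type not in ("phi", "psi"):
        raise ValueError("angle_type must be 'phi' or 'psi'")
    if not s.models:
        raise ValueError("empty ensemble")
    values = []
    key = None
    for m in s.models:
        ch = m.chain(chain) if chain else (m.chains[0] if m.chains else None)
        if ch is None:
            raise ValueError("model without polymer chain in ensemble")
        recs = backbone_dihedrals(ch)
        rec = next((r for r in recs if r.residue[1] == residue), None)
        if rec is None:
            raise ValueError(f"residue {residue} absent from an ensemble member")
        val = getattr(rec, angle_type)
        if val is None:
            raise ValueError(f"{angle_type} undefined for residue {residue} "
                             "in an ensemble member")
        values.append(val)
        key = rec.residue
    vals = np.asarray(values, float)
    # map to (-180, 180], then right-inclusive 10-degree bins
    vals = np.where(vals <= -180.0, vals + 360.0, vals)
    idx = np.ceil((vals + 180.0) / 10.0).astype(int) - 1
    idx = np.clip(idx, 0, 35)
    counts = np.bincount(idx, minlength=36).astype(float)
    return EnsembleDihedralHistogram(key, angle_type, counts / counts.sum(),
                                     len(values))
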