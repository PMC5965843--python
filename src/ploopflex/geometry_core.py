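"""Rigid-body superposition, RMSD, and torsion angles.

These are the primitives behind every conformational comparison in the
package: closed-form least-squares (Kabsch) superposition, RMSD evaluated in
a fixed frame, signed dihedral angles, and sequence-guided structural
alignment with iterative outlier trimming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import Residue, Structure

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "ResidueCorrespondence",
    "kabsch_superpose",
    "rmsd_in_frame",
    "dihedral",
    "align_structures",
]


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation R orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation matrix determinant is not +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)
                        ) -> "RigidTransform":
        axis = np.asarray(axis, float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("rotation axis must be non-zero")
        axis = axis / n
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        return cls(R, np.asarray(translation, float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Composition: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    pairs: list[tuple[object, object]] = field(default_factory=list)


@dataclass
class ResidueCorrespondence:
    """Ordered, non-crossing residue pairing between two structures."""

    pairs: list[tuple[tuple, tuple]]
    score: float
    ca_distances: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)


def kabsch_superpose(coords_a, coords_b, pairs=None) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of paired point sets.

    Returns the transform that, applied to ``coords_b``, minimizes the RMSD
    to ``coords_a`` (closed-form SVD solution with the proper-rotation sign
    correction). Collinear/degenerate sets still solve but raise a rank
    warning.
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be equal-length N x 3 arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs at least 3 points, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        warnings.warn("degenerate (rank-deficient) point set in superposition",
                      RuntimeWarning, stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(B) - A) ** 2, axis=1))))
    result_pairs = list(pairs) if pairs is not None else [(i, i) for i in range(n)]
    return SuperpositionResult(transform, rmsd, n, result_pairs)


def rmsd_in_frame(coords_a, coords_b, transform: RigidTransform) -> float:
    """RMSD of ``transform(coords_b)`` from ``coords_a`` with no re-fitting."""
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape:
        raise ValueError("paired coordinate lists have mismatched lengths")
    return float(np.sqrt(np.mean(np.sum((transform.apply(B) - A) ** 2, axis=1))))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, IUPAC convention, range (-180, 180].

    Computed with the standard atan2 construction; invariant under any common
    rigid motion of the four points.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-9:
            raise ValueError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


# ---------------------------------------------------------------------------
# structure-level alignment


def _ca_coords(residues: list[Residue]) -> np.ndarray:
    return np.array([r.atom("CA").coords for r in residues])


def _sequence_pairs(res_a: list[Residue], res_b: list[Residue]
                    ) -> tuple[list[tuple[int, int]], float]:
    """Global pairwise sequence alignment (BLOSUM62, affine gaps -10/-0.5)."""
    from .structure_io import AMINO3_TO_1

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    seq_a = "".join(AMINO3_TO_1.get(r.res_name, "A") for r in res_a)
    seq_b = "".join(AMINO3_TO_1.get(r.res_name, "A") for r in res_b)
    seq_a = seq_a.replace("U", "C").replace("O", "K")
    seq_b = seq_b.replace("U", "C").replace("O", "K")
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        pairs.extend((a_start + k, b_start + k) for k in range(a_end - a_start))
    return pairs, float(aln.score)


def align_structures(a: Structure, b: Structure, mode: str = "sequence-guided",
                     chain_a: str | None = None, chain_b: str | None = None,
                     max_cycles: int = 10,
                     ) -> tuple[ResidueCorrespondence, SuperpositionResult]:
    """Pair residues between two structures and superpose on their CA atoms.

    ``sequence-guided`` establishes candidate pairs by global sequence
    alignment, then iteratively trims pairs deviating more than
    max(2 x RMSD, 2.0 A) and re-superposes until the pair set is stable
    (at most ``max_cycles`` cycles); the surviving pairs are the
    "structurally aligned" residues.  ``identical-numbering`` pairs residues
    by author number, for same-protein comparisons, with no trimming.
    """
    ca = a.first_model.chain(chain_a) if chain_a else a.first_chain
    cb = b.first_model.chain(chain_b) if chain_b else b.first_chain
    if ca is None or cb is None:
        raise ValueError("requested chain not present")
    res_a = [r for r in ca.residues if r.atom("CA") is not None]
    res_b = [r for r in cb.residues if r.atom("CA") is not None]
    if not res_a or not res_b:
        raise ValueError("no alignable residues (missing CA atoms)")

    score = 0.0
    if mode == "identical-numbering":
        by_num = {(r.seq_num, r.icode): r for r in res_b}
        pairs = [(ra, by_num[(ra.seq_num, ra.icode)]) for ra in res_a
                 if (ra.seq_num, ra.icode) in by_num]
    elif mode == "sequence-guided":
        idx_pairs, score = _sequence_pairs(res_a, res_b)
        pairs = [(res_a[i], res_b[j]) for i, j in idx_pairs
                 if i < len(res_a) and j < len(res_b)]
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    if len(pairs) < 3:
        raise ValueError("alignment failure: fewer than 3 residue pairs")

    current = pairs
    sup = kabsch_superpose(_ca_coords([p[0] for p in current]),
                           _ca_coords([p[1] for p in current]))
    if mode == "sequence-guided":
        for _ in range(max_cycles):
            A = _ca_coords([p[0] for p in current])
            B = _ca_coords([p[1] for p in current])
            dev = np.linalg.norm(sup.transform.apply(B) - A, axis=1)
            cut = max(2.0 * sup.rmsd, 2.0)
            keep = dev <= cut
            if keep.all() or keep.sum() < 3:
                break
            current = [p for p, k in zip(current, keep) if k]
            sup = kabsch_superpose(_ca_coords([p[0] for p in current]),
                                   _ca_coords([p[1] for p in current]))

    A = _ca_coords([p[0] for p in current])
    B = _ca_coords([p[1] for p in current])
    dists = np.linalg.norm(sup.transform.apply(B) - A, axis=1)
    corr = ResidueCorrespondence(
        pairs=[(ra.key, rb.key) for ra, rb in current],
        score=score,
        ca_distances=dists,
    )
    sup.pairs = corr.pairs
    return corr, sup
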