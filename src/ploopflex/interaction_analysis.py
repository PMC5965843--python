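"""Hydrogen-bond networks and side-chain packing contacts.

Hydrogen bonds are detected geometrically on heavy atoms (the crystal
structures carry no hydrogens): donor-acceptor distance within a cutoff and
a minimum angle at the donor, measured from the donor's bonded antecedent
atoms. Network differencing matches bonds between two conformers by residue
number and atom name, which is how "bond X present in one form but not the
other" statements are made precise.

Packing is quantified as carbon-carbon contact counts: unordered pairs of a
side-chain carbon of the query residue with any carbon of any other residue
of the same polymer chain within a cutoff (default 4.5 A). Sequence
neighbours are not excluded and each pair is counted once; alternate
counting conventions (excluding bonded neighbours, counting distinct
partner atoms or residues) are reported alongside so a published count can
be located among them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Chain, Residue, Selection, Structure, select_atoms

__all__ = [
    "HBond",
    "HBondCriteria",
    "NetworkDiff",
    "ContactCount",
    "find_hbonds",
    "compare_hbond_networks",
    "count_cc_contacts",
    "contact_profile",
]

# Heavy-atom donor/acceptor tables (standard amino-acid chemistry).
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
# bonded heavy-atom antecedents used for the donor-angle criterion
_ANTECEDENTS = {
    "N": ("CA",), "NE": ("CD", "CZ"), "NH1": ("CZ",), "NH2": ("CZ",),
    "NZ": ("CE",), "ND2": ("CG",), "NE2": ("CD", "CE1", "CD2"),
    "ND1": ("CG", "CE1"), "NE1": ("CD1", "CE2"),
    "OG": ("CB",), "OG1": ("CB",), "OH": ("CZ",),
}

# carbons belonging to hydrophilic side-chain functional groups
HYDROPHILIC_GROUP_CARBONS = {
    "HIS": {"CG", "CD2", "CE1"},   # imidazole
    "ARG": {"CZ"},                 # guanidinium
    "ASP": {"CG"},                 # carboxylate
    "GLU": {"CD"},
    "ASN": {"CG"},                 # amide
    "GLN": {"CD"},
}


@dataclass
class HBondCriteria:
    max_distance: float = 3.5      # donor-acceptor heavy-atom distance, A
    min_donor_angle: float = 90.0  # antecedent-donor-acceptor angle, degrees


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, int, str, str]     # chain, seq, res_name, atom name
    acceptor: tuple[str, int, str, str]
    distance: float
    donor_angle: float

    @property
    def label(self) -> tuple:
        """Identity used for cross-structure matching: residue number + atom name."""
        return (self.donor[1], self.donor[3], self.acceptor[1], self.acceptor[3])


@dataclass
class NetworkDiff:
    only_in_a: list[HBond]
    only_in_b: list[HBond]
    shared: list[tuple[HBond, HBond]]
    warning: str | None = None


@dataclass
class ContactCount:
    residue: tuple[str, int, str]
    res_name: str
    count: int
    cutoff: float
    partners: list[tuple[int, str]] = field(default_factory=list)
    alternates: dict = field(default_factory=dict)


def _donor_atoms(res: Residue) -> list:
    out = []
    if res.atom("N") is not None and res.res_name != "PRO":
        out.append(res.atom("N"))
    for name in SIDECHAIN_DONORS.get(res.res_name, ()):
        a = res.atom(name)
        if a is not None:
            out.append(a)
    return out


def _acceptor_atoms(res: Residue) -> list:
    out = []
    if res.atom("O") is not None:
        out.append(res.atom("O"))
    oxt = res.atom("OXT")
    if oxt is not None:
        out.append(oxt)
    for name in SIDECHAIN_ACCEPTORS.get(res.res_name, ()):
        a = res.atom(name)
        if a is not None:
            out.append(a)
    return out


def _donor_angle(res: Residue, donor, acceptor_coords: np.ndarray) -> float:
    """Minimum antecedent-donor-acceptor angle over bonded antecedents."""
    angles = []
    for ant_name in _ANTECEDENTS.get(donor.name, ()):
        ant = res.atom(ant_name)
        if ant is None:
            continue
        u = ant.coords - donor.coords
        v = acceptor_coords - donor.coords
        cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        angles.append(float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
    return min(angles) if angles else 180.0


def _region_residues(s: Structure, sel: Selection | None) -> list[Residue]:
    m = s.models[0]
    residues = [r for c in m.chains for r in c.residues]
    if sel is None:
        return residues
    chains = set(sel.chains) if sel.chains is not None else None
    out = []
    for r in residues:
        if chains is not None and r.chain_id not in chains:
            continue
        if not sel._residue_ok(r.seq_num):
            continue
        out.append(r)
    return out


def find_hbonds(s: Structure, region_a: Selection | None = None,
                region_b: Selection | None = None,
                criteria: HBondCriteria | None = None) -> list[HBond]:
    """Geometric hydrogen bonds between (or within) selected regions.

    With both regions given, one partner must come from each region (either
    may donate). With ``region_b`` omitted, all bonds within ``region_a``
    (or the whole polymer) are returned. Donor and acceptor must belong to
    different residues.
    """
    criteria = criteria or HBondCriteria()
    res_a = _region_residues(s, region_a)
    res_b = _region_residues(s, region_b) if region_b is not None else res_a
    if not res_a or not res_b:
        raise ValueError("a queried region selects no residues")
    bonds: set[HBond] = set()

    def scan(donor_side: list[Residue], acceptor_side: list[Residue]) -> None:
        for rd in donor_side:
            for donor in _donor_atoms(rd):
                for ra in acceptor_side:
                    if ra.key == rd.key:
                        continue
                    for acc in _acceptor_atoms(ra):
                        d = float(np.linalg.norm(acc.coords - donor.coords))
                        if d > criteria.max_distance:
                            continue
                        ang = _donor_angle(rd, donor, acc.coords)
                        if ang < criteria.min_donor_angle:
                            continue
                        bonds.add(HBond(
                            (rd.chain_id, rd.seq_num, rd.res_name, donor.name),
                            (ra.chain_id, ra.seq_num, ra.res_name, acc.name),
                            round(d, 3), round(ang, 1)))

    scan(res_a, res_b)
    if region_b is not None:
        scan(res_b, res_a)
    return sorted(bonds, key=lambda b: (b.donor, b.acceptor))


def compare_hbond_networks(a: Structure, b: Structure,
                           region_a: Selection | None = None,
                           region_b: Selection | None = None,
                           criteria: HBondCriteria | None = None) -> NetworkDiff:
    """Difference the hydrogen-bond networks of two conformers.

    Bonds are matched by (donor residue number, donor atom, acceptor residue
    number, acceptor atom), i.e. by identity of the interacting groups, so a
    bond that migrates to a different partner shows up as one loss plus one
    gain.
    """
    warning = None
    try:
        bonds_a = find_hbonds(a, region_a, region_b, criteria)
    except ValueError as exc:
        bonds_a, warning = [], f"region missing in {a.id}: {exc}"
    try:
        bonds_b = find_hbonds(b, region_a, region_b, criteria)
    except ValueError as exc:
        bonds_b, warning = [], f"region missing in {b.id}: {exc}"
    map_a = {h.label: h for h in bonds_a}
    map_b = {h.label: h for h in bonds_b}
    only_a = [h for k, h in map_a.items() if k not in map_b]
    only_b = [h for k, h in map_b.items() if k not in map_a]
    shared = [(map_a[k], map_b[k]) for k in map_a if k in map_b]
    return NetworkDiff(only_a, only_b, shared, warning)


# ---------------------------------------------------------------------------
# packing contacts


def _chain_carbon_atoms(chain: Chain):
    """(residue, atom) for every carbon in a polymer chain."""
    for r in chain.residues:
        for a in r.atoms:
            if a.element.upper() == "C":
                yield r, a


def count_cc_contacts(s: Structure, residue: int, cutoff: float = 4.5,
                      chain: str | None = None) -> ContactCount:
    """Carbon-carbon packing contacts mediated by one residue's side chain.

    Counts unordered atom pairs (side-chain carbon of the residue, carbon of
    any other residue of the same polymer chain) within ``cutoff``.
    Intra-residue pairs, hetero groups and waters are excluded; sequence-
    adjacent residues are not. ``alternates`` reports the same quantity
    under nearby conventions: excluding +/-1 sequence neighbours, distinct
    partner carbon atoms, and distinct partner residues.
    """
    ch = s.first_model.chain(chain) if chain else s.first_chain
    query = ch.residue(residue)
    if query is None:
        raise KeyError(f"residue {residue} not found in chain {ch.chain_id}")
    sc_carbons = [a for a in query.side_chain_atoms() if a.element.upper() == "C"]
    if not sc_carbons:
        return ContactCount(query.key, query.res_name, 0, cutoff,
                            alternates={"no_neighbors": 0, "partner_atoms": 0,
                                        "partner_residues": 0})

    others = [(r, a) for r, a in _chain_carbon_atoms(ch) if r.key != query.key]
    if not others:
        return ContactCount(query.key, query.res_name, 0, cutoff,
                            alternates={"no_neighbors": 0, "partner_atoms": 0,
                                        "partner_residues": 0})
    tree = cKDTree(np.array([a.coords for _, a in others]))
    pair_count = 0
    pairs_no_neighbors = 0
    partner_atoms: set[int] = set()
    partner_residues: set[tuple] = set()
    partners: list[tuple[int, str]] = []
    for sc in sc_carbons:
        for j in tree.query_ball_point(sc.coords, cutoff):
            r_other, a_other = others[j]
            pair_count += 1
            partner_atoms.add(j)
            partner_residues.add(r_other.key)
            partners.append((r_other.seq_num, a_other.name))
            if abs(r_other.seq_num - query.seq_num) > 1:
                pairs_no_neighbors += 1
    return ContactCount(
        query.key, query.res_name, pair_count, cutoff,
        partners=sorted(set(partners)),
        alternates={
            "no_neighbors": pairs_no_neighbors,
            "partner_atoms": len(partner_atoms),
            "partner_residues": len(partner_residues),
        },
    )


def contact_profile(s: Structure, cutoff: float = 4.5, chain: str | None = None,
                    exclude_hydrophilic_groups: bool = False) -> pd.DataFrame:
    """Per-residue side-chain carbon contact counts for a whole chain.

    ``exclude_hydrophilic_groups`` drops carbons belonging to hydrophilic
    functional groups (His imidazole, Arg guanidinium, Asp/Glu carboxylate,
    Asn/Gln amide) from each residue's side-chain carbon set, separating
    hydrophobic packing from polar-group burial.
    """
    ch = s.first_model.chain(chain) if chain else s.first_chain
    rows = []
    for r in ch.residues:
        cc = count_cc_contacts(s, r.seq_num, cutoff, chain=ch.chain_id)
        count = cc.count
        if exclude_hydrophilic_groups and r.res_name in HYDROPHILIC_GROUP_CARBONS:
            excluded = HYDROPHILIC_GROUP_CARBONS[r.res_name]
            sc = [a for a in r.side_chain_atoms()
                  if a.element.upper() == "C" and a.name not in excluded]
            count = _count_for_atoms(s, ch, r, sc, cutoff)
        rows.append({"chain": r.chain_id, "seq_num": r.seq_num,
                     "res_name": r.res_name, "contacts": count,
                     "partner_atoms": cc.alternates["partner_atoms"],
                     "partner_residues": cc.alternates["partner_residues"]})
    return pd.DataFrame(rows)


def _count_for_atoms(s: Structure, ch: Chain, query: Residue, atoms, cutoff: float
                     ) -> int:
    others = [(r, a) for r, a in _chain_carbon_atoms(ch) if r.key != query.key]
    if not others or not atoms:
        return 0
    tree = cKDTree(np.array([a.coords for _, a in others]))
    return sum(len(tree.query_ball_point(a.coords, cutoff)) for a in atoms)
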