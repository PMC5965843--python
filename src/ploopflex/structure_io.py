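"""Coordinate I/O and atom selection.

Reads PDB/mmCIF files (via gemmi) into a small uniform hierarchy
(Structure -> Model -> Chain -> Residue -> Atom) that the geometry and
interaction layers operate on.  Only heavy atoms of a single conformer are
kept by default: alternate locations are resolved to the highest-occupancy
conformer and waters are discarded unless requested, because every
downstream geometric quantity (RMSD, dihedrals, hydrogen bonds, packing
contacts) is defined on single-conformer heavy-atom coordinates.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Model",
    "Structure",
    "Selection",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "select_atoms",
    "extract_sequence",
    "fetch_structure",
]

# Standard residues treated as polymer (amino acids plus common modified ones
# that substitute for them in deposited models).
AMINO3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues mapped to their parent amino acid
    "MSE": "M", "SEC": "U", "PYL": "O", "CSO": "C", "PTR": "Y",
    "SEP": "S", "TPO": "T", "HYP": "P", "MLY": "K",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

_ELEMENTS = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "AR", "K", "CA", "SC", "TI", "V", "CR", "MN", "FE",
    "CO", "NI", "CU", "ZN", "GA", "GE", "AS", "SE", "BR", "KR", "RB", "SR",
    "Y", "ZR", "MO", "RU", "PD", "AG", "CD", "I", "XE", "CS", "BA", "W",
    "PT", "AU", "HG", "PB", "U",
}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed or is malformed."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if self.element and self.element.upper() not in _ELEMENTS:
            raise ValueError(f"atom {self.name}: unknown element {self.element!r}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def backbone_complete(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C", "O"))

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    def is_polymer(self) -> bool:
        return self.res_name in AMINO3_TO_1

    def side_chain_atoms(self) -> list[Atom]:
        backbone = {"N", "CA", "C", "O", "OXT"}
        return [a for a in self.atoms if a.name not in backbone]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seq_num: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq_num == seq_num and r.icode == icode:
                return r
        return None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Model:
    chains: list[Chain] = field(default_factory=list)
    hetero: list[Residue] = field(default_factory=list)
    waters: list[Residue] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None


@dataclass
class Structure:
    id: str
    models: list[Model] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("structure must contain at least one model")

    @property
    def first_model(self) -> Model:
        return self.models[0]

    @property
    def first_chain(self) -> Chain:
        if not self.first_model.chains:
            raise ValueError(f"structure {self.id}: no polymer chain")
        return self.first_model.chains[0]

    @property
    def hetero(self) -> list[Residue]:
        return self.first_model.hetero

    def all_atoms(self, model_index: int = 0) -> list[Atom]:
        out: list[Atom] = []
        m = self.models[model_index]
        for c in m.chains:
            for r in c.residues:
                out.extend(r.atoms)
        for r in m.hetero:
            out.extend(r.atoms)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a deep copy with all coordinates mapped x -> R x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        new_models = []
        for m in self.models:
            nm = Model()
            for group_in, group_out in (
                (m.chains, None),
                (m.hetero, nm.hetero),
                (m.waters, nm.waters),
            ):
                if group_out is None:
                    for c in m.chains:
                        nc = Chain(c.chain_id)
                        for r in c.residues:
                            nc.residues.append(_transform_residue(r, rotation, translation))
                        nm.chains.append(nc)
                else:
                    for r in group_in:
                        group_out.append(_transform_residue(r, rotation, translation))
            new_models.append(nm)
        return Structure(self.id, new_models, dict(self.provenance))


def _transform_residue(r: Residue, rot: np.ndarray, trans: np.ndarray) -> Residue:
    nr = Residue(r.chain_id, r.seq_num, r.icode, r.res_name)
    for a in r.atoms:
        nr.atoms.append(
            Atom(a.serial, a.name, a.element, rot @ a.coords + trans,
                 a.occupancy, a.b_factor, a.altloc)
        )
    return nr


@dataclass
class Selection:
    """Declarative atom selection applied in stable (chain, residue, atom) order.

    ``residues`` may be an inclusive ``(lo, hi)`` range in author numbering or
    an explicit set of residue numbers; ``None`` means no constraint.
    """

    chains: Sequence[str] | None = None
    residues: tuple[int, int] | Iterable[int] | None = None
    atom_names: Sequence[str] | None = None
    elements: Sequence[str] | None = None
    hetero: bool = False
    model_index: int = 0

    def _residue_ok(self, seq_num: int) -> bool:
        if self.residues is None:
            return True
        if isinstance(self.residues, tuple) and len(self.residues) == 2 and all(
            isinstance(x, int) for x in self.residues
        ):
            lo, hi = self.residues
            return lo <= seq_num <= hi
        return seq_num in set(self.residues)


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> first altloc ID."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        out.append(best)
    return out


def read_structure(path: str | Path, fmt: str = "auto", keep_waters: bool = False) -> Structure:
    """Read a PDB or mmCIF file into the uniform hierarchy.

    Parameters
    ----------
    path : file path
    fmt : one of ``{"pdb", "mmcif", "auto"}``
    keep_waters : retain water residues on ``Model.waters`` (default off)
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt.lower()
    if fmt == "auto":
        gfmt = gemmi.CoorFormat.Detect
    elif fmt == "pdb":
        gfmt = gemmi.CoorFormat.Pdb
    elif fmt == "mmcif":
        gfmt = gemmi.CoorFormat.Mmcif
    else:
        raise ValueError(f"unknown format {fmt!r}; expected pdb, mmcif, or auto")
    try:
        gst = gemmi.read_structure(str(path), format=gfmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    gst.setup_entities()

    models: list[Model] = []
    for gmodel in gst:
        model = Model()
        for gchain in gmodel:
            chain = Chain(gchain.name)
            for gres in gchain:
                res = Residue(gchain.name, gres.seqid.num, gres.seqid.icode.strip(),
                              gres.name)
                for ga in gres:
                    el = ga.element.name.upper() if ga.element else ""
                    if el == "H" or el == "D":
                        continue  # heavy atoms only
                    res.atoms.append(
                        Atom(ga.serial, ga.name, el or "C",
                             np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                             ga.occ, ga.b_iso, ga.altloc.strip() or "")
                    )
                if not res.atoms:
                    continue
                res.atoms = _resolve_altlocs(res.atoms)
                if res.res_name in WATER_NAMES:
                    if keep_waters:
                        model.waters.append(res)
                elif res.is_polymer():
                    if not chain.residues or chain.residues[-1].key != res.key:
                        chain.residues.append(res)
                else:
                    model.hetero.append(res)
            if chain.residues:
                model.chains.append(chain)
        models.append(model)
    if not models or not any(m.chains or m.hetero for m in models):
        raise StructureParseError(f"{path}: no atoms found")
    return Structure(path.stem.upper(), models)


def write_structure(s: Structure, path: str | Path, fmt: str = "pdb") -> None:
    """Write a Structure to a PDB file (coordinates at 3-decimal precision)."""
    if fmt.lower() != "pdb":
        raise ValueError("only PDB output is supported")
    if not any(c.residues for m in s.models for c in m.chains) and not any(
        m.hetero for m in s.models
    ):
        raise ValueError("refusing to write a structure with no atoms")
    gst = gemmi.Structure()
    gst.name = s.id
    for i, m in enumerate(s.models, start=1):
        gmodel = gemmi.Model(i)
        for c in m.chains:
            gchain = gemmi.Chain(c.chain_id)
            for r in c.residues:
                gchain.add_residue(_to_gemmi_residue(r, het=False))
            gmodel.add_chain(gchain)
        if m.hetero or m.waters:
            # hetero residues go on their recorded chain ids
            het_chains: dict[str, gemmi.Chain] = {}
            for r in list(m.hetero) + list(m.waters):
                cid = r.chain_id or "Z"
                if cid not in het_chains:
                    het_chains[cid] = gemmi.Chain(cid)
                het_chains[cid].add_residue(_to_gemmi_residue(r, het=True))
            for gchain in het_chains.values():
                gmodel.add_chain(gchain)
        gst.add_model(gmodel)
    gst.setup_entities()
    doc_path = str(Path(path))
    gst.write_pdb(doc_path)


def _to_gemmi_residue(r: Residue, het: bool) -> gemmi.Residue:
    gres = gemmi.Residue()
    gres.name = r.res_name
    gres.seqid = gemmi.SeqId(r.seq_num, r.icode or " ")
    gres.het_flag = "H" if het else "A"
    for a in r.atoms:
        ga = gemmi.Atom()
        ga.name = a.name
        ga.element = gemmi.Element(a.element.capitalize())
        ga.pos = gemmi.Position(*np.round(a.coords, 3))
        ga.occ = a.occupancy
        ga.b_iso = a.b_factor
        ga.serial = a.serial
        gres.add_atom(ga)
    return gres


def select_atoms(s: Structure, sel: Selection) -> list[Atom]:
    """Apply a Selection; returns atoms in stable (chain, residue, atom) order."""
    m = s.models[sel.model_index]
    chains = set(sel.chains) if sel.chains is not None else None
    names = set(sel.atom_names) if sel.atom_names is not None else None
    elements = {e.upper() for e in sel.elements} if sel.elements is not None else None
    out: list[Atom] = []
    if sel.hetero:
        residue_iter = [(r.chain_id, r) for r in m.hetero]
    else:
        residue_iter = [(c.chain_id, r) for c in m.chains for r in c.residues]
    for cid, r in residue_iter:
        if chains is not None and cid not in chains:
            continue
        if not sel._residue_ok(r.seq_num):
            continue
        for a in r.atoms:
            if names is not None and a.name not in names:
                continue
            if elements is not None and a.element.upper() not in elements:
                continue
            out.append(a)
    return out


def extract_sequence(chain: Chain) -> str:
    """One-letter sequence of a polymer chain; unknown residues map to 'X'."""
    polymer = [r for r in chain.residues if r.res_name not in WATER_NAMES]
    if not polymer:
        raise ValueError(f"chain {chain.chain_id}: no polymer residues")
    return "".join(AMINO3_TO_1.get(r.res_name, "X") for r in polymer)


RCSB_URL = "https://files.rcsb.org/download/{code}.pdb"


def fetch_structure(accession: str, cache_dir: str | Path = "scratch/pdb",
                    timeout: float = 15.0) -> Structure:
    """Download a deposited entry from the PDB and parse it.

    A network convenience only: raises ``ConnectionError`` when the archive
    is unreachable. Files are cached under ``cache_dir``.
    """
    code = accession.strip().upper()
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    target = cache_dir / f"{code}.pdb"
    if not target.exists():
        url = RCSB_URL.format(code=code)
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                data = resp.read()
        except OSError as exc:
            raise ConnectionError(
                f"could not retrieve {code} from the PDB archive: {exc}"
            ) from exc
        target.write_bytes(data)
    return read_structure(target, fmt="pdb")
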