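"""Structure parsing and per-atom physicochemical annotation.

Atoms are the source of every chemical surface feature: partial charge,
Kyte-Doolittle hydropathy of the parent residue, and a coarse
hydrogen-bond donor/acceptor class derived from heavy-atom identity.
PDB parsing itself is delegated to gemmi; this module only filters the
records and attaches the lookup-table annotations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = ["AtomSet", "parse_structure", "KYTE_DOOLITTLE", "VDW_RADII"]

# Kyte-Doolittle hydropathy, per residue (unitless).
KYTE_DOOLITTLE: dict[str, float] = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}

# van der Waals radii by element symbol, Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70

# Simplified fixed partial charges (elementary charge units).  Only the
# strongly polar/ionizable heavy atoms carry charge; the surface charge
# channel is standardized per protein downstream, so only the sign
# structure and relative magnitudes matter.
_SIDECHAIN_CHARGES: dict[tuple[str, str], float] = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NE"): 0.2, ("ARG", "NH1"): 0.4, ("ARG", "NH2"): 0.4,
    ("HIS", "ND1"): 0.1, ("HIS", "NE2"): 0.1,
}
_BACKBONE_CHARGES = {"O": -0.4, "N": 0.3, "OXT": -0.5}

# Heavy-atom H-bond classes: +1 donor, -1 acceptor, 0 neither/ambivalent.
# Hydroxyl oxygens (SER OG, THR OG1, TYR OH) are both donor and acceptor
# and are scored 0.
_DONORS = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("TRP", "NE1"),
}
_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("MET", "SD"),
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class AtomSet:
    """Columnar container of atoms with per-atom annotations.

    All arrays share the first dimension.  Coordinates are Angstrom;
    partial charges are elementary charge units; hydropathy is the
    Kyte-Doolittle value of the parent residue.
    """

    atom_id: np.ndarray          # (k,) int
    atom_name: np.ndarray        # (k,) str
    element: np.ndarray          # (k,) str
    coords: np.ndarray           # (k, 3) float, Angstrom
    residue_name: np.ndarray     # (k,) str, 3-letter code
    residue_seq: np.ndarray      # (k,) int
    insertion_code: np.ndarray   # (k,) str
    chain_id: np.ndarray         # (k,) str
    radius: np.ndarray           # (k,) float, Angstrom
    partial_charge: np.ndarray   # (k,) float
    hydropathy: np.ndarray       # (k,) float
    hbond_class: np.ndarray      # (k,) int in {-1, 0, +1}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if np.any(self.radius <= 0):
            raise ValueError("atom radii must be positive")

    def __len__(self) -> int:
        return len(self.atom_id)

    def subset(self, mask: np.ndarray) -> "AtomSet":
        """Return a new AtomSet restricted to ``mask`` (bool or index array)."""
        return AtomSet(
            **{
                f: (getattr(self, f)[mask] if f != "meta" else dict(self.meta))
                for f in self.__dataclass_fields__
            }
        )

    def select_residues(self, selection) -> "AtomSet":
        """Subset by an iterable of (chain_id, residue_seq) pairs."""
        wanted = set(selection)
        mask = np.array(
            [(c, int(s)) in wanted for c, s in zip(self.chain_id, self.residue_seq)],
            dtype=bool,
        )
        return self.subset(mask)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomSet":
        """Apply x -> R x + t to every coordinate; identities untouched."""
        out = self.subset(np.ones(len(self), dtype=bool))
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def to_pdb(self) -> str:
        """Serialize as PDB text (single model, single altloc)."""
        st = gemmi.Structure()
        st.name = self.meta.get("name", "atomset")
        model = gemmi.Model("1")
        chains: dict[str, gemmi.Chain] = {}
        prev_res_key = None
        res = None
        for i in range(len(self)):
            cid = str(self.chain_id[i])
            if cid not in chains:
                chains[cid] = gemmi.Chain(cid)
            key = (cid, int(self.residue_seq[i]), str(self.insertion_code[i]))
            if key != prev_res_key:
                res = gemmi.Residue()
                res.name = str(self.residue_name[i])
                res.seqid = gemmi.SeqId(int(self.residue_seq[i]),
                                        str(self.insertion_code[i]) or " ")
                chains[cid].add_residue(res)
                prev_res_key = key
            at = gemmi.Atom()
            at.name = str(self.atom_name[i])
            at.element = gemmi.Element(str(self.element[i]))
            at.pos = gemmi.Position(*self.coords[i])
            at.occ = 1.0
            res.add_atom(at)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
        st.setup_entities()
        return st.make_pdb_string()


def _annotate(res_name: str, atom_name: str, element: str):
    radius = VDW_RADII.get(element.upper(), _DEFAULT_RADIUS)
    charge = _SIDECHAIN_CHARGES.get((res_name, atom_name))
    if charge is None:
        charge = _BACKBONE_CHARGES.get(atom_name, 0.0)
    hydro = KYTE_DOOLITTLE.get(res_name, 0.0)
    if (res_name, atom_name) in _DONORS or (atom_name == "N" and res_name != "PRO"):
        hb = 1
    elif (res_name, atom_name) in _ACCEPTORS or atom_name in ("O", "OXT"):
        hb = -1
    else:
        hb = 0
    return radius, charge, hydro, hb


def _validate_coordinate_columns(pdb_text: str) -> None:
    # gemmi tolerates some malformed records; reject them explicitly so the
    # error names the offending line.
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise ValueError(
                    f"malformed {what} coordinate field on line {lineno}: {line!r}"
                ) from None


def parse_structure(
    pdb_text: str,
    chains: list[str] | None = None,
    include_hetero: bool = False,
    include_waters: bool = False,
) -> AtomSet:
    """Parse PDB text into an annotated :class:`AtomSet`.

    Only the first model is read.  Waters and hetero records (ions,
    ligands) are excluded by default; hydrogens are kept when present.
    ``chains`` optionally restricts to the named chain ids.

    Raises ``ValueError`` on malformed coordinate fields (naming the
    line) and when the filtered selection contains no atoms.
    """
    _validate_coordinate_columns(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError("no atoms: structure contains no models")
    model = st[0]

    cols: dict[str, list] = {k: [] for k in (
        "atom_id", "atom_name", "element", "coords", "residue_name",
        "residue_seq", "insertion_code", "chain_id", "radius",
        "partial_charge", "hydropathy", "hbond_class")}
    idx = 0
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            if res.name in _WATER_NAMES:
                if not include_waters:
                    continue
            elif res.het_flag == "H" and not include_hetero:
                continue
            for atom in res:
                cols["atom_id"].append(idx)
                cols["atom_name"].append(atom.name)
                cols["element"].append(atom.element.name)
                cols["coords"].append([atom.pos.x, atom.pos.y, atom.pos.z])
                cols["residue_name"].append(res.name)
                cols["residue_seq"].append(res.seqid.num)
                cols["insertion_code"].append(
                    res.seqid.icode.strip() if res.seqid.icode else "")
                cols["chain_id"].append(chain.name)
                r, q, h, hb = _annotate(res.name, atom.name, atom.element.name)
                cols["radius"].append(r)
                cols["partial_charge"].append(q)
                cols["hydropathy"].append(h)
                cols["hbond_class"].append(hb)
                idx += 1
    if idx == 0:
        raise ValueError("no atoms after filtering (check chain selection)")

    return AtomSet(
        atom_id=np.asarray(cols["atom_id"], dtype=int),
        atom_name=np.asarray(cols["atom_name"], dtype=object),
        element=np.asarray(cols["element"], dtype=object),
        coords=np.asarray(cols["coords"], dtype=float),
        residue_name=np.asarray(cols["residue_name"], dtype=object),
        residue_seq=np.asarray(cols["residue_seq"], dtype=int),
        insertion_code=np.asarray(cols["insertion_code"], dtype=object),
        chain_id=np.asarray(cols["chain_id"], dtype=object),
        radius=np.asarray(cols["radius"], dtype=float),
        partial_charge=np.asarray(cols["partial_charge"], dtype=float),
        hydropathy=np.asarray(cols["hydropathy"], dtype=float),
        hbond_class=np.asarray(cols["hbond_class"], dtype=int),
        meta={"n_chains": len({c for c in cols["chain_id"]})},
    )
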