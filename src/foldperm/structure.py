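"""Structure-derived observables for permutation analysis.

Implements the geometric quantities used to compare wild-type and
circularly permuted structures:

* Kabsch-Sander electrostatic hydrogen-bond energies and a DSSP-style
  alpha-helix assignment (4-turns -> minimal helices);
* Shrake-Rupley accessible surface area (per residue);
* heavy-atom contact maps and relative contact order (RCO);
* reindexing of contact maps under circular permutation;
* optimal-superposition RMSD via the Kabsch algorithm.

PDB files are read and written through Biopython; residues are indexed
by their 1-based position in the chain after dropping hetero/solvent
records.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

# Kabsch-Sander electrostatic prefactor: q1*q2*332 kcal A / mol e^2
_KS_PREFACTOR = 0.084 * 332.0  # 27.888
#: H-bond assignment threshold, kcal/mol
HBOND_ENERGY_CUTOFF = -0.5

#: van der Waals radii for ASA, Angstrom (element symbol -> radius)
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

_BACKBONE = ("N", "CA", "C", "O")


@dataclass
class Residue:
    """One residue: 1-based chain position, name, atom coordinates."""

    index: int
    name: str
    atoms: dict[str, np.ndarray]
    elements: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}
        for name in self.atoms:
            self.elements.setdefault(name, _guess_element(name))

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in _BACKBONE)

    def heavy_coords(self) -> np.ndarray:
        xyz = [c for n, c in self.atoms.items() if self.elements[n] != "H"]
        return np.array(xyz) if xyz else np.empty((0, 3))


def _guess_element(atom_name: str) -> str:
    # two-letter elements are rare in protein chains; the first alphabetic
    # character of the atom name identifies the element ("1HB" -> H)
    for ch in atom_name.strip():
        if ch.isalpha():
            return ch.upper()
    return "C"


@dataclass
class ProteinStructure:
    """Ordered residues of one chain of one model."""

    residues: list[Residue]
    chain_id: str = "A"
    model_number: int = 1

    def __post_init__(self):
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    def backbone_coords(self, atom: str = "CA") -> np.ndarray:
        return np.array([r.atoms[atom] for r in self.residues if atom in r.atoms])


@dataclass
class ContactMap:
    """Residue-residue heavy-atom contacts with sequence separations."""

    chain_length: int
    contacts: list[tuple[int, int, int]]  # (i, j, n_atom_pairs), i < j
    cutoff: float
    atom_scope: str = "heavy"
    min_seq_sep: int = 1

    def __post_init__(self):
        seen = set()
        for i, j, n in self.contacts:
            if not (1 <= i < j <= self.chain_length):
                raise ValueError(f"contact ({i},{j}) outside 1..L, i<j")
            if (i, j) in seen:
                raise ValueError(f"duplicate contact ({i},{j})")
            seen.add((i, j))

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass(frozen=True)
class PermutationSpec:
    """Circular permutation: wild-type residue ``new_start`` becomes
    position 1; ``linker_length`` residues are inserted (conceptually,
    index-only) at the junction of the joined native termini."""

    new_start: int
    linker_length: int = 0

    def __post_init__(self):
        if self.new_start < 1:
            raise ValueError("new_start must be >= 1")
        if self.linker_length < 0:
            raise ValueError("linker_length must be >= 0")


# ---------------------------------------------------------------- PDB I/O

def read_structure(pdb_source, model: int = 1, chain: str | None = None
                   ) -> ProteinStructure:
    """Read one model / one chain of a PDB file into a ProteinStructure.

    ``model`` is the 1-based position of the model in the file (NMR
    ensembles store many).  Hetero and solvent records are dropped;
    insertion codes are rejected rather than silently renumbered.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    handle = pdb_source
    if isinstance(pdb_source, (str, Path)):
        handle = str(pdb_source)
    elif isinstance(pdb_source, str):
        handle = io.StringIO(pdb_source)
    structure = parser.get_structure("pdb", handle)
    models = list(structure)
    if model < 1 or model > len(models):
        raise ValueError(
            f"model {model} requested but file contains {len(models)} model(s)")
    mdl = models[model - 1]
    chains = list(mdl)
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise ValueError(f"chain {chain!r} not found")
    ch = chains[0]

    residues = []
    pos = 0
    for res in ch:
        hetflag, _resseq, icode = res.id
        if hetflag.strip():
            continue  # hetero / solvent
        if icode.strip():
            raise ValueError(
                f"insertion code {icode!r} at residue {res.id} unsupported")
        pos += 1
        atoms = {a.get_name(): a.get_coord().astype(float) for a in res}
        elements = {a.get_name(): (a.element or "C").upper() for a in res}
        residues.append(Residue(pos, res.get_resname(), atoms, elements))
    return ProteinStructure(residues, chain_id=ch.id, model_number=model)


def write_structure(struct: ProteinStructure, path) -> None:
    """Write a ProteinStructure as a single-model PDB file."""
    from Bio.PDB import PDBIO
    from Bio.PDB.Atom import Atom
    from Bio.PDB.Chain import Chain
    from Bio.PDB.Model import Model
    from Bio.PDB.Residue import Residue as BPResidue
    from Bio.PDB.Structure import Structure as BPStructure

    s = BPStructure("synthetic")
    m = Model(0)
    c = Chain(struct.chain_id)
    serial = 1
    for res in struct.residues:
        r = BPResidue((" ", res.index, " "), res.name, "")
        for name, coord in res.atoms.items():
            a = Atom(name, np.asarray(coord, float), 0.0, 1.0, " ",
                     name.ljust(4), serial, element=res.elements[name])
            serial += 1
            r.add(a)
        c.add(r)
    m.add(c)
    s.add(m)
    out = PDBIO()
    out.set_structure(s)
    out.save(str(path))


# ------------------------------------------------------- hydrogen bonding

def place_amide_hydrogen(prev_res: Residue, res: Residue) -> np.ndarray | None:
    """Geometric backbone amide H (DSSP convention): 1.0 A from N along
    the C(i-1)->O(i-1) direction reversed, i.e. opposite the previous
    carbonyl.  Returns None when the needed atoms are missing."""
    if "N" not in res.atoms or not {"C", "O"} <= prev_res.atoms.keys():
        return None
    co = prev_res.atoms["C"] - prev_res.atoms["O"]
    norm = np.linalg.norm(co)
    if norm == 0:
        return None
    return res.atoms["N"] + co / norm


def hbond_energy(donor: Residue, acceptor: Residue,
                 h_coord: np.ndarray | None = None) -> float | None:
    """Kabsch-Sander electrostatic H-bond energy, kcal/mol.

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) between the
    acceptor carbonyl (C, O) and the donor amide (N, H).  Returns None
    (unassignable) when atoms are missing or the donor is a proline.
    """
    if donor.name.strip().upper() == "PRO":
        return None
    if "N" not in donor.atoms or not {"C", "O"} <= acceptor.atoms.keys():
        return None
    h = h_coord if h_coord is not None else donor.atoms.get("H")
    if h is None:
        return None
    n = donor.atoms["N"]
    c, o = acceptor.atoms["C"], acceptor.atoms["O"]
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        return None
    return float(_KS_PREFACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn))


def hbond_energy_from_distances(r_on: float, r_ch: float, r_oh: float,
                                r_cn: float) -> float:
    """Kabsch-Sander energy directly from the four distances (A)."""
    return float(_KS_PREFACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn))


def assign_helices(struct: ProteinStructure,
                   use_file_hydrogens: bool = False
                   ) -> tuple[list[str], int]:
    """DSSP-style alpha-helix assignment from i -> i+4 hydrogen bonds.

    A 4-turn exists at position i when the carbonyl of residue i accepts
    a hydrogen bond (Kabsch-Sander E < -0.5 kcal/mol) from the amide of
    residue i+4.  Two consecutive 4-turns, at i and i+1, make residues
    i+1..i+4 alpha-helical; overlapping turn pairs extend the helix.

    Returns per-residue labels ('H' helical, '-' coil, '?' unassignable
    backbone) and the helical residue count.
    """
    res = struct.residues
    n = len(res)
    labels = ["-"] * n
    for k, r in enumerate(res):
        if not r.has_backbone():
            labels[k] = "?"
    if n < 5:
        warnings.warn("chain shorter than 5 residues; no helix possible")
        return labels, 0

    # amide H per residue (index 0 has no preceding carbonyl)
    h_coords: list[np.ndarray | None] = [None] * n
    for k in range(1, n):
        if use_file_hydrogens and "H" in res[k].atoms:
            h_coords[k] = res[k].atoms["H"]
        else:
            h_coords[k] = place_amide_hydrogen(res[k - 1], res[k])

    turn = [False] * n  # turn[k]: CO(k) -> NH(k+4), 0-based
    for k in range(n - 4):
        e = hbond_energy(res[k + 4], res[k], h_coord=h_coords[k + 4])
        turn[k] = e is not None and e < HBOND_ENERGY_CUTOFF

    for k in range(n - 5):
        if turn[k] and turn[k + 1]:
            for j in range(k + 1, k + 5):
                if labels[j] != "?":
                    labels[j] = "H"
    return labels, labels.count("H")


# ------------------------------------------------------------------- ASA

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic golden-spiral lattice)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * k
    rho = np.sqrt(1.0 - z**2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def accessible_surface_area(
    struct: ProteinStructure,
    residue_selection=None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> dict[int, float]:
    """Shrake-Rupley per-residue accessible surface area, A^2.

    Every atom of the structure occludes; ``residue_selection`` (residue
    indices, residue names, or a predicate on Residue) restricts only
    which residues are reported.  Deterministic for a fixed point count.
    """
    atoms, owner, radii = [], [], []
    for res in struct.residues:
        for name, coord in res.atoms.items():
            elem = res.elements[name]
            if elem not in VDW_RADII:
                warnings.warn(
                    f"unknown element {elem!r} for atom {name}; using "
                    f"default radius {DEFAULT_VDW_RADIUS} A")
            atoms.append(coord)
            owner.append(res.index)
            radii.append(VDW_RADII.get(elem, DEFAULT_VDW_RADIUS))
    xyz = np.asarray(atoms)
    radii = np.asarray(radii) + probe_radius
    owner = np.asarray(owner)

    if residue_selection is None:
        wanted = set(r.index for r in struct.residues)
    elif callable(residue_selection):
        wanted = {r.index for r in struct.residues if residue_selection(r)}
    else:
        sel = set(residue_selection)
        wanted = {r.index for r in struct.residues
                  if r.index in sel or r.name in sel}

    sphere = _fibonacci_sphere(n_sphere_points)
    tree = cKDTree(xyz)
    asa = {idx: 0.0 for idx in wanted}
    rmax = radii.max()
    for a in range(len(xyz)):
        if owner[a] not in wanted:
            continue
        pts = xyz[a] + radii[a] * sphere
        neighbours = [b for b in tree.query_ball_point(xyz[a], radii[a] + rmax)
                      if b != a]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for b in neighbours:
            accessible &= np.linalg.norm(pts - xyz[b], axis=1) >= radii[b]
            if not accessible.any():
                break
        frac = accessible.mean()
        asa[owner[a]] += frac * 4.0 * np.pi * radii[a] ** 2
    return asa


# --------------------------------------------------- contacts & topology

def contact_map(struct: ProteinStructure, cutoff: float = 6.0,
                min_seq_sep: int = 1) -> ContactMap:
    """Heavy-atom contact map: residues i, j (|i-j| >= min_seq_sep) are in
    contact when any heavy-atom pair lies within ``cutoff`` A; the number
    of such atom pairs is recorded for atom-pair-weighted contact order."""
    coords, owner = [], []
    for res in struct.residues:
        xyz = res.heavy_coords()
        coords.append(xyz)
        owner.extend([res.index] * len(xyz))
    allxyz = np.vstack([c for c in coords if len(c)]) if coords else np.empty((0, 3))
    owner = np.asarray(owner)
    tree = cKDTree(allxyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    counts: dict[tuple[int, int], int] = {}
    for a, b in pairs:
        i, j = int(owner[a]), int(owner[b])
        if i == j:
            continue
        if i > j:
            i, j = j, i
        if j - i < min_seq_sep:
            continue
        counts[(i, j)] = counts.get((i, j), 0) + 1
    contacts = [(i, j, n) for (i, j), n in sorted(counts.items())]
    return ContactMap(chain_length=len(struct), contacts=contacts,
                      cutoff=cutoff, min_seq_sep=min_seq_sep)


def relative_contact_order(cmap: ContactMap,
                           weighting: str = "atom_pairs") -> float:
    """Relative contact order: mean sequence separation of contacts over
    chain length, RCO = (1/(L N)) * sum(dS).

    ``atom_pairs`` counts every contacting heavy-atom pair (the
    convention of the contact-order literature); ``residue_pairs``
    counts each residue pair once.
    """
    if not cmap.contacts:
        raise ValueError("empty contact map; RCO undefined")
    if weighting == "atom_pairs":
        n = sum(c[2] for c in cmap.contacts)
        total = sum(c[2] * (c[1] - c[0]) for c in cmap.contacts)
    elif weighting == "residue_pairs":
        n = len(cmap.contacts)
        total = sum(c[1] - c[0] for c in cmap.contacts)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return total / (cmap.chain_length * n)


def circular_permute(cmap: ContactMap, spec: PermutationSpec) -> ContactMap:
    """Relabel a contact map under circular permutation.

    Residue i moves to ((i - new_start) mod L) + 1; residues preceding
    the new start (which wrap past the joined native termini) are
    additionally shifted by ``linker_length``, and the chain grows by the
    linker.  The contact set is preserved as residue pairs; only
    sequence separations change.
    """
    L = cmap.chain_length
    if spec.new_start > L:
        raise ValueError(f"new_start {spec.new_start} exceeds chain length {L}")

    def relabel(i: int) -> int:
        j = ((i - spec.new_start) % L) + 1
        if i < spec.new_start:
            j += spec.linker_length
        return j

    contacts = []
    for i, j, n in cmap.contacts:
        a, b = relabel(i), relabel(j)
        if a > b:
            a, b = b, a
        contacts.append((a, b, n))
    return ContactMap(chain_length=L + spec.linker_length,
                      contacts=sorted(contacts), cutoff=cmap.cutoff,
                      atom_scope=cmap.atom_scope, min_seq_sep=cmap.min_seq_sep)


# ------------------------------------------------------------------ RMSD

def kabsch_rmsd(coords_a, coords_b, selection=None) -> float:
    """Optimal-superposition RMSD (A) via the Kabsch algorithm.

    Proper rotation enforced (reflection corrected through the sign of
    the smallest singular value); invariant to rigid motion of either
    coordinate set.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if selection is not None:
        sel = np.asarray(selection)
        a, b = a[sel], b[sel]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    if len(a) < 3:
        raise ValueError("need >= 3 points for superposition")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    # rotated-A vs B squared distance via singular values
    e0 = (a0**2).sum() + (b0**2).sum()
    msd = (e0 - 2.0 * (s[0] + s[1] + d * s[2])) / len(a)
    return float(np.sqrt(max(msd, 0.0)))
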