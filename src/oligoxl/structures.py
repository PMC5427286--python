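"""Atomic structures, assembly hierarchy and screw-transform geometry.

A small-heat-shock-protein dodecamer is organised as 12 subunits -> 6
domain-swapped dimers -> 2 "trimer-of-dimer" discs stacked along a 3-fold
axis.  The two discs are related by a screw transform: a twist ``theta``
about the 3-fold axis combined with a translation ``d`` along it.  This
module reads/writes coordinates (via gemmi), builds ideal double-disc
assemblies from a single dimer, and measures the screw parameters back
from any two-disc assembly.

Conventions
-----------
* The 3-fold axis is ``z`` after inertia alignment; disc 0 is the disc
  with the lower centroid projection.
* The twist is reported in ``[0, 60)`` degrees: the 3-fold symmetry of a
  disc makes the twist degenerate modulo 120 degrees, and the
  eclipsed/staggered ambiguity folds that once more, so 0 means eclipsed
  discs (as in the template crystal structure) and 30 means maximally
  staggered.
* Residue numbers are 1-based mature-protein numbering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "AssemblyMap",
    "ScrewTransform",
    "StructureError",
    "read_structure",
    "write_structure",
    "infer_assembly_map",
    "build_assembly",
    "measure_screw",
    "superpose",
]


class StructureError(ValueError):
    """Raised for unparseable files, empty models or unsupported assemblies."""


@dataclass
class Atom:
    element: str
    name: str
    resnum: int
    chain: str
    xyz: np.ndarray  # shape (3,), Angstrom

    def copy(self) -> "Atom":
        return Atom(self.element, self.name, self.resnum, self.chain,
                    self.xyz.copy())


@dataclass
class Structure:
    """A set of atoms grouped into chains.

    Every atom belongs to exactly one chain; the Calpha of a given
    (chain, residue) is unique or absent.
    """

    atoms: list[Atom] = field(default_factory=list)
    chain_sequences: dict[str, str] = field(default_factory=dict)

    # -- basic queries ---------------------------------------------------
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def chain_atoms(self, chain: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain]

    def coords(self, chain: str | None = None) -> np.ndarray:
        sel = self.atoms if chain is None else self.chain_atoms(chain)
        if not sel:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in sel])

    def ca_atoms(self, chain: str | None = None) -> list[Atom]:
        return [a for a in self.atoms
                if a.name == "CA" and (chain is None or a.chain == chain)]

    def ca_coords(self, chain: str | None = None) -> np.ndarray:
        sel = self.ca_atoms(chain)
        if not sel:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in sel])

    def ca(self, chain: str, resnum: int) -> np.ndarray | None:
        """Calpha position of (chain, residue), or None if unmodeled."""
        for a in self.atoms:
            if a.chain == chain and a.resnum == resnum and a.name == "CA":
                return a.xyz
        return None

    # -- transforms ------------------------------------------------------
    def transformed(self, R: np.ndarray, t: np.ndarray,
                    chain_rename: dict[str, str] | None = None) -> "Structure":
        """Return a copy with coordinates ``R @ x + t`` (optionally renaming
        chains)."""
        out = Structure(chain_sequences=dict(self.chain_sequences))
        for a in self.atoms:
            chain = a.chain if chain_rename is None else chain_rename.get(a.chain, a.chain)
            out.atoms.append(Atom(a.element, a.name, a.resnum, chain,
                                  R @ a.xyz + np.asarray(t, float)))
        if chain_rename:
            out.chain_sequences = {chain_rename.get(c, c): s
                                   for c, s in self.chain_sequences.items()}
        return out

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms],
                         dict(self.chain_sequences))

    def merged(self, other: "Structure") -> "Structure":
        out = self.copy()
        out.atoms.extend(a.copy() for a in other.atoms)
        out.chain_sequences.update(other.chain_sequences)
        return out


@dataclass(frozen=True)
class AssemblyMap:
    """chain -> (subunit index, dimer index, disc index) hierarchy.

    12 subunits form 6 dimers form 2 discs of 3 dimers each (or a single
    disc of 6 chains for hexamers).
    """

    subunit: dict[str, int]
    dimer: dict[str, int]
    disc: dict[str, int]

    def relation(self, chain_a: str, chain_b: str) -> str:
        if chain_a == chain_b:
            return "same_subunit"
        if self.dimer[chain_a] == self.dimer[chain_b]:
            return "same_dimer"
        if self.disc[chain_a] == self.disc[chain_b]:
            return "same_disc"
        return "other_disc"

    def chains(self) -> list[str]:
        return sorted(self.subunit, key=self.subunit.get)

    def disc_chains(self, disc: int) -> list[str]:
        return [c for c in self.chains() if self.disc[c] == disc]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["chain\tsubunit\tdimer\tdisc"]
        for c in self.chains():
            lines.append(f"{c}\t{self.subunit[c]}\t{self.dimer[c]}\t{self.disc[c]}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AssemblyMap":
        sub: dict[str, int] = {}
        dim: dict[str, int] = {}
        dsc: dict[str, int] = {}
        for line in Path(path).read_text().splitlines()[1:]:
            c, s, d, k = line.split("\t")
            sub[c], dim[c], dsc[c] = int(s), int(d), int(k)
        return cls(sub, dim, dsc)


@dataclass(frozen=True)
class ScrewTransform:
    """Rigid screw motion: twist about an axis plus translation along it."""

    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    axis_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    theta_deg: float = 0.0
    d: float = 0.0  # Angstrom

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.axis_direction)
        if not math.isclose(n, 1.0, abs_tol=1e-9):
            object.__setattr__(self, "axis_direction",
                               tuple(np.asarray(self.axis_direction) / n))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def read_structure(path: str | Path, fmt: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Chain ids and residue numbers are preserved verbatim.  Duplicate
    (chain, residue, atom name) records trigger a warning; the last
    record wins.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureError(f"unknown format: {fmt}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0 or all(len(model) == 0 for model in st):
        raise StructureError(f"empty structure in {path}")

    out = Structure()
    seen: dict[tuple[str, int, str], int] = {}
    model = st[0]
    for chain in model:
        seq_parts: dict[int, str] = {}
        for res in chain:
            one = _THREE_TO_ONE.get(res.name, "X")
            seq_parts[res.seqid.num] = one
            for at in res:
                key = (chain.name, res.seqid.num, at.name)
                atom = Atom(at.element.name, at.name, res.seqid.num,
                            chain.name,
                            np.array([at.pos.x, at.pos.y, at.pos.z]))
                if key in seen:
                    warnings.warn(
                        f"duplicate atom {key}; last record wins", stacklevel=2)
                    out.atoms[seen[key]] = atom
                else:
                    seen[key] = len(out.atoms)
                    out.atoms.append(atom)
        out.chain_sequences[chain.name] = "".join(
            seq_parts[k] for k in sorted(seq_parts))
    if not out.atoms:
        raise StructureError(f"empty structure in {path}")
    return out


def write_structure(structure: Structure, path: str | Path,
                    fmt: str | None = None) -> None:
    """Write a structure as PDB (default) or mmCIF."""
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = gemmi.Structure()
    st.name = path.stem
    model = gemmi.Model("1")
    for chain_name in structure.chains():
        chain = gemmi.Chain(chain_name)
        seq = structure.chain_sequences.get(chain_name, "")
        # gemmi copies residues on add_residue, so each residue is
        # assembled (with its atoms) before insertion
        by_res: dict[int, list[Atom]] = {}
        for a in structure.chain_atoms(chain_name):
            by_res.setdefault(a.resnum, []).append(a)
        for resnum in by_res:
            res = gemmi.Residue()
            res.seqid = gemmi.SeqId(resnum, " ")
            one = seq[resnum - 1] if 0 < resnum <= len(seq) else "G"
            res.name = _ONE_TO_THREE.get(one, "GLY")
            for a in by_res[resnum]:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.xyz)
                at.occ = 1.0
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _rot_z(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_FLIP_X = np.diag([1.0, -1.0, -1.0])  # 180 deg about the x axis


def superpose(mobile: Structure | np.ndarray, target: Structure | np.ndarray,
              atom_name: str = "CA") -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(R, t, rmsd)`` with ``det(R) = +1`` such that
    ``R @ mobile + t`` best fits ``target``.  Improper rotations are
    never returned, so a mirrored copy keeps a positive RMSD.
    """
    P = mobile.ca_coords() if isinstance(mobile, Structure) else np.asarray(mobile, float)
    Q = target.ca_coords() if isinstance(target, Structure) else np.asarray(target, float)
    if isinstance(mobile, Structure) and atom_name != "CA":
        P = np.array([a.xyz for a in mobile.atoms if a.name == atom_name])
    if isinstance(target, Structure) and atom_name != "CA":
        Q = np.array([a.xyz for a in target.atoms if a.name == atom_name])
    if P.shape != Q.shape:
        raise StructureError(
            f"selection mismatch: {P.shape[0]} vs {Q.shape[0]} atoms")
    if P.shape[0] < 3:
        raise StructureError("need at least 3 atoms to superpose")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# assembly construction
# ---------------------------------------------------------------------------

_DODECAMER_CHAINS = list("ABCDEFGHIJKL")


def build_assembly(dimer: Structure,
                   screw: ScrewTransform) -> tuple[Structure, AssemblyMap]:
    """Replicate a 2-chain dimer into a double-disc dodecamer.

    Disc 0 is the dimer replicated by the C3 rotations (0, 120, 240
    degrees) about ``z``; disc 1 is disc 0 rotated 180 degrees about the
    in-plane ``x`` axis (2-fold flip), then twisted by ``theta`` about
    ``z`` and translated ``d`` along it.  Disc 0 is recentred so its
    Calpha centroid sits at ``z = 0``, which makes the build/measure
    round trip exact.
    """
    chains = dimer.chains()
    if len(chains) != 2:
        raise StructureError(f"dimer must have 2 chains, got {len(chains)}")
    # recentre so the disc-0 Calpha centroid lies in the z=0 plane and the
    # x/y centroid is on the axis
    ca = dimer.ca_coords()
    disc0_ca = np.concatenate([ca @ _rot_z(a).T for a in (0.0, 120.0, 240.0)])
    shift = np.array([0.0, 0.0, -disc0_ca[:, 2].mean()])
    base = dimer.transformed(np.eye(3), shift)

    new_names = iter(_DODECAMER_CHAINS)
    parts: list[Structure] = []
    sub: dict[str, int] = {}
    dim: dict[str, int] = {}
    dsc: dict[str, int] = {}
    idx = 0
    for disc in (0, 1):
        for k, ang in enumerate((0.0, 120.0, 240.0)):
            if disc == 0:
                R, t = _rot_z(ang), np.zeros(3)
            else:
                R = _rot_z(screw.theta_deg + ang) @ _FLIP_X
                t = np.array([0.0, 0.0, screw.d])
            rename = {chains[0]: next(new_names), chains[1]: next(new_names)}
            part = base.transformed(R, t, chain_rename=rename)
            parts.append(part)
            for c in rename.values():
                sub[c] = idx
                dim[c] = disc * 3 + k
                dsc[c] = disc
                idx += 1
    assembly = parts[0]
    for p in parts[1:]:
        assembly = assembly.merged(p)
    amap = AssemblyMap(sub, dim, dsc)

    # clash check: any inter-chain Calpha pair closer than 1 A
    allca = assembly.ca_coords()
    owner = np.concatenate([[i] * len(p.ca_atoms()) for i, p in enumerate(parts)])
    if len(allca) > 1:
        from scipy.spatial import cKDTree
        tree = cKDTree(allca)
        for i, j in tree.query_pairs(1.0):
            if owner[i] != owner[j]:
                warnings.warn("clashing dimer placement (< 1 A between "
                              "inter-chain Calpha atoms)", stacklevel=2)
                break
    return assembly, amap


def _principal_axis(ca: np.ndarray) -> np.ndarray:
    """Eigenvector of the gyration tensor with the most isolated eigenvalue
    (the cylinder axis of a double-disc particle)."""
    centred = ca - ca.mean(axis=0)
    cov = centred.T @ centred / len(ca)
    vals, vecs = np.linalg.eigh(cov)
    gaps = [abs(vals[0] - vals[1]) + abs(vals[0] - vals[2]),
            abs(vals[1] - vals[0]) + abs(vals[1] - vals[2]),
            abs(vals[2] - vals[0]) + abs(vals[2] - vals[1])]
    return vecs[:, int(np.argmax(gaps))]


def infer_assembly_map(structure: Structure,
                       axis_hint: np.ndarray | None = None) -> AssemblyMap:
    """Partition a 6- or 12-chain assembly into discs and dimers.

    Discs are split by the chain-centroid projection along the 3-fold
    axis (principal inertia axis unless ``axis_hint`` is given); dimers
    are paired by the maximal count of inter-chain Calpha pairs within
    8 A (the domain-swap interface dominates all other contacts).
    """
    chains = structure.chains()
    if len(chains) not in (6, 12):
        raise StructureError(
            f"unsupported assembly: {len(chains)} chains (need 6 or 12)")
    ca_by_chain = {c: structure.ca_coords(c) for c in chains}
    allca = structure.ca_coords()
    axis = (np.asarray(axis_hint, float) if axis_hint is not None
            else _principal_axis(allca))
    axis = axis / np.linalg.norm(axis)

    if len(chains) == 12:
        proj = {c: float(ca_by_chain[c].mean(axis=0) @ axis) for c in chains}
        order = sorted(chains, key=proj.get)
        lower, upper = set(order[:6]), set(order[6:])
        # disc 0 = lower centroid along the axis
        disc = {c: (0 if c in lower else 1) for c in chains}
        disc_sets = [sorted(lower, key=chains.index), sorted(upper, key=chains.index)]
    else:
        disc = {c: 0 for c in chains}
        disc_sets = [chains]

    dimer: dict[str, int] = {}
    dimer_idx = 0
    for members in disc_sets:
        counts = {}
        for a, b in permutations(members, 2):
            if (b, a) in counts:
                continue
            from scipy.spatial import cKDTree
            hits = cKDTree(ca_by_chain[a]).query_ball_tree(
                cKDTree(ca_by_chain[b]), 8.0)
            counts[(a, b)] = sum(len(h) for h in hits)
        best_total, best_match = -1, None
        for match in _perfect_matchings(list(members)):
            total = sum(counts.get(p, counts.get((p[1], p[0]), 0)) for p in match)
            if total > best_total:
                best_total, best_match = total, match
        for pair in best_match:
            for c in pair:
                dimer[c] = dimer_idx
            dimer_idx += 1
    subunit = {c: i for i, c in enumerate(chains)}
    return AssemblyMap(subunit, dimer, disc)


def _perfect_matchings(items: list[str]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for i, other in enumerate(rest):
        pair = (first, other)
        remaining = rest[:i] + rest[i + 1:]
        for sub in _perfect_matchings(remaining):
            yield [pair] + sub


# ---------------------------------------------------------------------------
# screw measurement
# ---------------------------------------------------------------------------

def measure_screw(assembly: Structure, amap: AssemblyMap,
                  axis_hint: np.ndarray | None = None) -> ScrewTransform:
    """Measure disc twist and separation of a two-disc assembly.

    ``d`` is the distance between the two disc Calpha centroids
    projected on the 3-fold axis.  ``theta`` is the in-plane rotation
    about the axis that minimises the Calpha RMSD between disc 1 and the
    2-fold-flipped disc 0, folded into ``[0, 60)`` degrees.
    """
    discs = {amap.disc[c] for c in amap.chains()}
    if discs != {0, 1}:
        raise StructureError("screw measurement needs a two-disc assembly")

    allca = assembly.ca_coords()
    axis = (np.asarray(axis_hint, float) if axis_hint is not None
            else _principal_axis(allca))
    axis = axis / np.linalg.norm(axis)
    # rotate the frame so the axis is z
    zhat = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, zhat)
    if np.linalg.norm(v) < 1e-12:
        R_frame = np.eye(3) if axis @ zhat > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        angle = math.acos(np.clip(axis @ zhat, -1, 1))
        k = v / np.linalg.norm(v)
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R_frame = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K

    chains0 = amap.disc_chains(0)
    chains1 = amap.disc_chains(1)
    ca0 = {c: assembly.ca_coords(c) @ R_frame.T for c in chains0}
    ca1 = {c: assembly.ca_coords(c) @ R_frame.T for c in chains1}
    cen0 = np.concatenate(list(ca0.values())).mean(axis=0)
    cen1 = np.concatenate(list(ca1.values())).mean(axis=0)
    if cen0[2] > cen1[2]:  # disc 0 is the lower disc by convention
        chains0, chains1, ca0, ca1, cen0, cen1 = (
            chains1, chains0, ca1, ca0, cen1, cen0)
    d = float(cen1[2] - cen0[2])

    # centre x/y on the axis (overall centroid), flip disc 0 about x
    centre = np.concatenate(list(ca0.values()) + list(ca1.values())).mean(axis=0)
    centre[2] = 0.0
    flipped = {c: (ca0[c] - centre) @ _FLIP_X.T for c in chains0}
    moved1 = {c: ca1[c] - centre for c in chains1}
    # align z centroids so only the in-plane rotation remains
    z_off = (np.concatenate(list(moved1.values()))[:, 2].mean()
             - np.concatenate(list(flipped.values()))[:, 2].mean())
    flipped = {c: v + np.array([0.0, 0.0, z_off]) for c, v in flipped.items()}

    # dimer-level correspondences: the 2-fold flip reverses the cyclic
    # order of the three dimers, so try 3 shifts x 2 directions x 2
    # within-dimer chain orders
    dimers0 = _disc_dimers(amap, chains0)
    dimers1 = _disc_dimers(amap, chains1)
    best = (math.inf, 0.0)
    for shift in range(3):
        for direction in (1, -1):
            for swap in (False, True):
                P_parts, Q_parts = [], []
                for i, d0 in enumerate(dimers0):
                    d1 = dimers1[(shift + direction * i) % 3]
                    pair1 = (d1[1], d1[0]) if swap else d1
                    for c0, c1 in zip(d0, pair1):
                        if len(flipped[c0]) == len(moved1[c1]):
                            P_parts.append(flipped[c0])
                            Q_parts.append(moved1[c1])
                if not P_parts:
                    continue
                P = np.concatenate(P_parts)
                Q = np.concatenate(Q_parts)
                num = float(np.sum(P[:, 0] * Q[:, 1] - P[:, 1] * Q[:, 0]))
                den = float(np.sum(P[:, 0] * Q[:, 0] + P[:, 1] * Q[:, 1]))
                phi = math.degrees(math.atan2(num, den))
                diff = P @ _rot_z(phi).T - Q
                rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
                if rmsd < best[0]:
                    best = (rmsd, phi)
    phi = best[1] % 120.0
    theta = min(phi, 120.0 - phi)
    return ScrewTransform(theta_deg=theta, d=d)


def _disc_dimers(amap: AssemblyMap, chains: list[str]) -> list[tuple[str, str]]:
    by_dimer: dict[int, list[str]] = {}
    for c in chains:
        by_dimer.setdefault(amap.dimer[c], []).append(c)
    return [tuple(sorted(v, key=amap.subunit.get))
            for _, v in sorted(by_dimer.items())]
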