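"""Solvent-accessible surface areas and DNA-histone interface geometry.

SASA uses Shrake-Rupley sphere sampling with a deterministic Fibonacci
point lattice, so every area is bit-reproducible across runs.  Buried
interface area between two atom groups A and B is derived from three SASA
evaluations (A alone, B alone, A+B together) and reported under both common
conventions: ``buried_sum = sasa_A + sasa_B - sasa_AB`` (total area lost on
both faces) and ``buried_avg = buried_sum / 2`` (one-face average).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import GroupingError, NucdeformError
from .model import (
    AtomRecord,
    DNA_ROLE_SET,
    HISTONE_ROLE_SET,
    NucleosomeModel,
    Residue,
)

# Element-keyed united-atom van der Waals radii (Å); configurable because
# different tools ship slightly different tables.
VDW_RADII = {
    "default": {
        "C": 1.70,
        "N": 1.55,
        "O": 1.52,
        "P": 1.80,
        "S": 1.80,
        "H": 1.20,
        "SE": 1.90,
        "FE": 1.47,
        "ZN": 1.39,
        "MG": 1.73,
        "MN": 1.61,
        "NA": 2.27,
        "K": 2.75,
        "CL": 1.75,
    }
}


class RadiusError(NucdeformError):
    """An atom's element has no radius in the chosen set."""


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere sampling (Fibonacci lattice)."""
    i = np.arange(n_points, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(elements: Sequence[str], radii_set: str) -> np.ndarray:
    table = VDW_RADII[radii_set]
    out = np.empty(len(elements))
    for k, el in enumerate(elements):
        r = table.get(el.upper())
        if r is None:
            raise RadiusError(f"no van der Waals radius for element {el!r} in set {radii_set!r}")
        out[k] = r
    return out


def sasa(
    atoms: Iterable[AtomRecord] | tuple[np.ndarray, Sequence[str]],
    probe: float = 1.4,
    n_points: int = 960,
    radii_set: str = "default",
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake-Rupley.

    ``atoms`` is either an iterable of :class:`AtomRecord` or a tuple of
    (N x 3 coordinates, element symbols).  Each atom's area is the exposed
    fraction of its Fibonacci test points times the sphere area at radius
    ``r + probe``.
    """
    if isinstance(atoms, tuple):
        coords, elements = atoms
        coords = np.asarray(coords, dtype=float)
    else:
        records = list(atoms)
        coords = np.array([a.xyz for a in records], dtype=float).reshape(-1, 3)
        elements = [a.element for a in records]
    n = len(coords)
    if n == 0:
        raise ValueError("sasa needs at least one atom")
    radii = _radii_for(elements, radii_set) + probe
    sphere = fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()
    neighbor_lists = tree.query_ball_tree(tree, r=max_reach)

    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 > radii[j] ** 2
            if not exposed.any():
                break
        areas[i] = exposed.sum() / n_points * 4.0 * np.pi * radii[i] ** 2
    return areas


@dataclass
class BuriedAreaResult:
    sasa_A: float
    sasa_B: float
    sasa_AB: float
    probe: float
    n_points: int
    radii_set: str

    @property
    def buried_sum(self) -> float:
        return self.sasa_A + self.sasa_B - self.sasa_AB

    @property
    def buried_avg(self) -> float:
        return self.buried_sum / 2.0

    def value(self, convention: str = "sum") -> float:
        if convention == "sum":
            return self.buried_sum
        if convention == "avg":
            return self.buried_avg
        raise ValueError(f"unknown convention {convention!r} (sum|avg)")

    def to_dict(self) -> dict:
        return {
            "sasa_A": self.sasa_A,
            "sasa_B": self.sasa_B,
            "sasa_AB": self.sasa_AB,
            "buried_sum": self.buried_sum,
            "buried_avg": self.buried_avg,
            "probe": self.probe,
            "n_points": self.n_points,
            "radii_set": self.radii_set,
        }


def _group_atoms(
    nmodel: NucleosomeModel, roles: Iterable[str]
) -> tuple[np.ndarray, list[str], list[tuple[Residue, AtomRecord]]]:
    coords, elements, refs = [], [], []
    roleset = set(roles)
    for chain in nmodel.structure.chains:
        if nmodel.roles.get(chain.chain_id) not in roleset:
            continue
        for res in chain.residues:
            for a in res.atoms:
                if a.element in {"H", "D"}:
                    continue
                coords.append(a.xyz)
                elements.append(a.element)
                refs.append((res, a))
    return np.asarray(coords, dtype=float).reshape(-1, 3), elements, refs


def buried_area(
    nmodel: NucleosomeModel,
    group_A: Iterable[str] | None = None,
    group_B: Iterable[str] | None = None,
    probe: float = 1.4,
    n_points: int = 960,
    radii_set: str = "default",
) -> BuriedAreaResult:
    """Buried surface area between two role groups (defaults: DNA vs histones).

    Ligand chains and solvent are excluded unless named in a group.  Three
    SASA evaluations with identical parameters; both conventions reported.
    """
    group_A = set(DNA_ROLE_SET if group_A is None else group_A)
    group_B = set(HISTONE_ROLE_SET if group_B is None else group_B)
    overlap = group_A & group_B
    if overlap:
        raise GroupingError(f"groups overlap on roles {sorted(overlap)}")
    ca, ea, _ = _group_atoms(nmodel, group_A)
    cb, eb, _ = _group_atoms(nmodel, group_B)
    if len(ca) == 0 or len(cb) == 0:
        raise GroupingError("both groups must contain atoms")
    a = float(sasa((ca, ea), probe, n_points, radii_set).sum())
    b = float(sasa((cb, eb), probe, n_points, radii_set).sum())
    ab = float(
        sasa((np.vstack([ca, cb]), list(ea) + list(eb)), probe, n_points, radii_set).sum()
    )
    return BuriedAreaResult(a, b, ab, probe, n_points, radii_set)


def min_group_distance(
    nmodel: NucleosomeModel,
    group_A: Iterable[str],
    group_B: Iterable[str],
) -> tuple[float, tuple]:
    """Minimum heavy-atom distance between two role groups and the atom pair.

    Returns ``(distance_A, ((residue_A, atom_A), (residue_B, atom_B)))``.
    """
    ca, _, ra = _group_atoms(nmodel, group_A)
    cb, _, rb = _group_atoms(nmodel, group_B)
    if len(ca) == 0 or len(cb) == 0:
        raise GroupingError("both groups must contain atoms")
    tree = cKDTree(cb)
    dists, idx = tree.query(ca)
    i = int(np.argmin(dists))
    j = int(idx[i])
    return float(dists[i]), (ra[i], rb[j])


def list_contacts(
    nmodel: NucleosomeModel,
    group_A: Iterable[str],
    group_B: Iterable[str],
    cutoff: float = 4.0,
) -> list[tuple]:
    """All heavy-atom pairs between the groups within ``cutoff`` Å, by distance.

    Each entry is ``((residue_A, atom_A), (residue_B, atom_B), distance)``.
    """
    ca, _, ra = _group_atoms(nmodel, group_A)
    cb, _, rb = _group_atoms(nmodel, group_B)
    if len(ca) == 0 or len(cb) == 0:
        raise GroupingError("both groups must contain atoms")
    tree_a = cKDTree(ca)
    tree_b = cKDTree(cb)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)
    out = []
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(ca[i] - cb[j]))
            out.append((ra[i], rb[j], d))
    out.sort(key=lambda e: e[2])
    return out


def contacts_tsv(contacts: list[tuple]) -> str:
    lines = ["chainA\tresA\tatomA\tchainB\tresB\tatomB\tdist_A"]
    for (res_a, atom_a), (res_b, atom_b), d in [(c[0], c[1], c[2]) for c in contacts]:
        ra, rb = res_a.ref, res_b.ref
        lines.append(
            f"{ra.chain_id}\t{ra.res_name}{ra.auth_seq}\t{atom_a.name}\t"
            f"{rb.chain_id}\t{rb.res_name}{rb.auth_seq}\t{atom_b.name}\t{d:.3f}"
        )
    return "\n".join(lines) + "\n"
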