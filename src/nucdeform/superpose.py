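"""Rigid (Kabsch) and similarity (Umeyama) superposition anchored on histones.

Model pairs are aligned on the Cα atoms of histone H3 (both copies pooled by
default), mirroring the standard practice of comparing nucleosome structures
after matching their histone cores rather than the deformable DNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    CorrespondenceError,
    InsufficientPointsError,
    PruningCollapseError,
    RoleError,
)
from .model import NucleosomeModel, Residue, ResidueRef

PROTEIN_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
NUCLEIC_ONE_LETTER = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U", "DI": "I",
    "A": "A", "C": "C", "G": "G", "U": "U",
}


@dataclass
class RigidTransform:
    """Proper rotation + translation; maps x to R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-8:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) <= 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SimilarityTransform:
    """Rigid transform with an isotropic scale; maps x to s * R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        RigidTransform(self.rotation, self.translation)  # validates R
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(coords, dtype=float) @ self.rotation.T) + self.translation


@dataclass
class CorrespondenceMap:
    """Ordered residue pairings between two models for one chain role."""

    pairs: list[tuple[ResidueRef, ResidueRef, tuple[str, ...]]]
    anchor_role: str
    mode: str

    def __len__(self) -> int:
        return len(self.pairs)

    def coordinates(
        self, ref: NucleosomeModel, test: NucleosomeModel
    ) -> tuple[np.ndarray, np.ndarray, list[tuple[ResidueRef, ResidueRef, str]]]:
        """Paired coordinate arrays (and atom labels) over all shared atoms."""
        P, Q, labels = [], [], []
        ref_res = _residue_index(ref)
        test_res = _residue_index(test)
        for rref, tref, names in self.pairs:
            r, t = ref_res[rref.key()], test_res[tref.key()]
            for name in names:
                ra, ta = r.atom(name), t.atom(name)
                if ra is None or ta is None:
                    continue
                P.append(ra.xyz)
                Q.append(ta.xyz)
                labels.append((rref, tref, name))
        return np.asarray(P, dtype=float), np.asarray(Q, dtype=float), labels


def _residue_index(model: NucleosomeModel) -> dict[tuple[str, int, str], Residue]:
    return {r.ref.key(): r for r in model.structure.iter_residues()}


def _one_letter(res: Residue) -> str:
    name = res.ref.res_name
    return PROTEIN_ONE_LETTER.get(name) or NUCLEIC_ONE_LETTER.get(name) or "X"


def _shared_atoms(a: Residue, b: Residue, atom_filter: set[str] | None) -> tuple[str, ...]:
    names = a.atom_names() & b.atom_names()
    if atom_filter is not None:
        names &= set(atom_filter)
    return tuple(sorted(names))


def build_correspondence(
    ref: NucleosomeModel,
    test: NucleosomeModel,
    role: str,
    mode: str = "auth_number",
    atom_filter: set[str] | None = frozenset({"CA"}),
) -> CorrespondenceMap:
    """Pair residues of one chain role between two models.

    Modes: ``auth_number`` (match author numbering), ``sequence_align``
    (global alignment, match +1 / mismatch -1 / gap -2, robust to
    renumbering), ``frame_position`` (match dyad-frame positions; DNA).
    ``atom_filter`` restricts the shared atom names (default Cα; pass ``None``
    for all shared atoms).
    """
    try:
        rchain = ref.chain_for_role(role)
        tchain = test.chain_for_role(role)
    except RoleError as exc:
        raise RoleError(f"correspondence for {role!r}: {exc}") from exc

    pairs: list[tuple[ResidueRef, ResidueRef, tuple[str, ...]]] = []
    if mode == "auth_number":
        tmap = {(r.ref.auth_seq, r.ref.icode): r for r in tchain.residues}
        for r in rchain.residues:
            t = tmap.get((r.ref.auth_seq, r.ref.icode))
            if t is not None:
                pairs.append((r.ref, t.ref, _shared_atoms(r, t, atom_filter)))
    elif mode == "sequence_align":
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        sr = "".join(_one_letter(r) for r in rchain.residues)
        st = "".join(_one_letter(r) for r in tchain.residues)
        aln = aligner.align(sr, st)[0]
        for (r0, r1), (t0, t1) in zip(*aln.aligned):
            for i, j in zip(range(r0, r1), range(t0, t1)):
                r, t = rchain.residues[i], tchain.residues[j]
                pairs.append((r.ref, t.ref, _shared_atoms(r, t, atom_filter)))
    elif mode == "frame_position":
        rpos = {ref.frame.get(r.ref.key()): r for r in rchain.residues}
        rpos.pop(None, None)
        for t in tchain.residues:
            p = test.frame.get(t.ref.key())
            r = rpos.get(p) if p is not None else None
            if r is not None:
                pairs.append((r.ref, t.ref, _shared_atoms(r, t, atom_filter)))
    else:
        raise ValueError(f"unknown correspondence mode {mode!r}")

    pairs = [p for p in pairs if p[2]]
    if not pairs:
        raise CorrespondenceError(f"no matchable residues for role {role!r} in mode {mode!r}")
    return CorrespondenceMap(pairs=pairs, anchor_role=role, mode=mode)


def kabsch(
    P: np.ndarray,
    Q: np.ndarray,
    weights: Sequence[float] | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal proper-rotation superposition of P onto Q; returns (T, rmsd).

    Minimizes the (weighted) RMSD of ``R @ P + t`` against ``Q``; a reflection
    in the SVD solution is corrected by flipping the sign of the smallest
    singular direction, preserving molecular chirality.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching N x 3 arrays")
    n = P.shape[0]
    if n < 3:
        raise InsufficientPointsError(f"need >= 3 point pairs, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative, same length as P, not all zero")
        w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    P0 = P - cp
    Q0 = Q - cq
    H = (P0 * w[:, None]).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if S[-1] < 1e-10 * max(S[0], 1e-30):
        warnings.warn("degenerate (near-collinear) point set; superposition may be ill-conditioned")
    t = cq - R @ cp
    resid = P0 @ R.T - Q0
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", resid, resid))))
    return RigidTransform(R, t), rmsd


def umeyama(
    P: np.ndarray, Q: np.ndarray, weights: Sequence[float] | None = None
) -> tuple[SimilarityTransform, float]:
    """Jointly optimal similarity (scale + rigid) superposition of P onto Q.

    The scale estimate is how voxel-size miscalibration between maps shows
    up when superposing models refined against them; a scale of 1 recovers
    the Kabsch solution exactly.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching N x 3 arrays")
    n = P.shape[0]
    if n < 3:
        raise InsufficientPointsError(f"need >= 3 point pairs, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    P0 = P - cp
    Q0 = Q - cq
    var_p = float(np.sum(w * np.einsum("ij,ij->i", P0, P0)))
    H = (P0 * w[:, None]).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    ones = np.array([1.0, 1.0, d])
    R = Vt.T @ np.diag(ones) @ U.T
    scale = float((S * ones).sum() / var_p)
    t = cq - scale * (R @ cp)
    resid = scale * (P0 @ R.T) - Q0
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", resid, resid))))
    return SimilarityTransform(R, t, scale), rmsd


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    diagnostics: dict = field(default_factory=dict)


def _anchor_roles(ref: NucleosomeModel, test: NucleosomeModel, anchor: str) -> list[str]:
    """Anchor role plus its primed twin when both models carry it (pooled)."""
    roles = [anchor]
    primed = anchor + "'"
    if primed in ref.roles.values() and primed in test.roles.values():
        roles.append(primed)
    return roles


def superpose_models(
    ref: NucleosomeModel,
    test: NucleosomeModel,
    anchor: str = "H3",
    atom_filter: set[str] | None = frozenset({"CA"}),
    mode: str = "auth_number",
    prune: str = "none",
    prune_cutoff: float = 2.0,
    max_iter: int = 10,
    pool_copies: bool = True,
) -> SuperpositionResult:
    """Histone-anchored rigid superposition of ``test`` onto ``ref``.

    Both copies of the anchor histone are pooled by default (symmetric and
    deterministic); set ``pool_copies=False`` to restrict to the unprimed
    copy.  ``prune="iterative"`` repeats the fit dropping atom pairs whose
    residual exceeds ``prune_cutoff`` Å until stable (sensitivity analysis;
    off for headline numbers).
    """
    roles = _anchor_roles(ref, test, anchor) if pool_copies else [anchor]
    P_parts, Q_parts, labels = [], [], []
    for role in roles:
        cmap = build_correspondence(ref, test, role, mode=mode, atom_filter=atom_filter)
        P, Q, lab = cmap.coordinates(ref, test)
        if len(P):
            P_parts.append(P)
            Q_parts.append(Q)
            labels.extend(lab)
    if not P_parts:
        raise CorrespondenceError(f"no anchor atoms for roles {roles}")
    # test -> ref: solve for the transform taking test coordinates onto ref
    P = np.vstack(Q_parts)  # test
    Q = np.vstack(P_parts)  # ref
    n_total = len(P)

    keep = np.ones(n_total, dtype=bool)
    transform, rmsd = kabsch(P, Q)
    n_dropped = 0
    if prune == "iterative":
        for _ in range(max_iter):
            resid = np.linalg.norm(transform.apply(P) - Q, axis=1)
            new_keep = keep & (resid <= prune_cutoff)
            if new_keep.sum() < 3:
                raise PruningCollapseError(
                    f"pruning at cutoff {prune_cutoff} Å left {int(new_keep.sum())} pairs"
                )
            if np.array_equal(new_keep, keep):
                break
            keep = new_keep
            transform, rmsd = kabsch(P[keep], Q[keep])
        n_dropped = int(n_total - keep.sum())
    elif prune != "none":
        raise ValueError(f"unknown prune mode {prune!r}")

    diagnostics = {
        "anchor_roles": roles,
        "mode": mode,
        "pairs_used": int(keep.sum()),
        "pairs_dropped": n_dropped,
        "anchor_rmsd": rmsd,
        "prune": prune,
    }
    return SuperpositionResult(transform=transform, diagnostics=diagnostics)


def apply_transform(model: NucleosomeModel, transform: RigidTransform) -> NucleosomeModel:
    """Return a copy of ``model`` with every atom moved by ``transform``."""
    out = model.copy()
    for _res, atom in out.structure.iter_atoms():
        atom.xyz = transform.apply(atom.xyz[None, :])[0]
    return out
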