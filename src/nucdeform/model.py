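"""Atomic structure containers, I/O, nucleosome chain roles and the dyad frame.

The coordinate frame used throughout the package is per-strand 5'->3'
numbering with the dyad nucleotide at position 0; the base-pair partner of
position ``i`` on one strand is position ``-i`` on the other.  Author residue
numbers are never assumed to equal frame positions — the frame is always
built explicitly.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np

from .errors import AnchorError, FormatError, RoleError, StructureParseError

# Backbone atom names used for all DNA RMSD work (heavy atoms of the
# sugar-phosphate backbone; present in abasic sites too).
BACKBONE_ATOMS = frozenset(
    {"C1'", "C2'", "C3'", "C4'", "C5'", "O3'", "O4'", "O5'", "P", "OP1", "OP2"}
)

HISTONE_ROLES = ("H3", "H4", "H2A", "H2B", "H3'", "H4'", "H2A'", "H2B'")
STRAND_ROLES = ("strand_top", "strand_bottom")
DNA_ROLE_SET = frozenset(STRAND_ROLES)
HISTONE_ROLE_SET = frozenset(HISTONE_ROLES)
UNIQUE_ROLES = HISTONE_ROLE_SET | DNA_ROLE_SET

# Residue-name vocabularies.  Damaged/abasic codes are configurable because
# depositions vary; unknown nucleic residues are kept and flagged, not dropped.
STANDARD_NUCLEIC = frozenset({"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "U"})
DEOXYINOSINE_CODES = frozenset({"DI", "HYP", "OIP"})
AP_SITE_CODES = frozenset({"AP", "ABA", "3DR", "ORP"})
NUCLEIC_NAMES = STANDARD_NUCLEIC | DEOXYINOSINE_CODES | AP_SITE_CODES

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

# Histone fold chain-length classes for auto role assignment (Xenopus-like
# full-length histones; deposited models may be trimmed, hence ranges).
HISTONE_LENGTH_RANGES = {
    "H3": (132, 150),
    "H2A": (124, 131),
    "H2B": (112, 123),
    "H4": (90, 111),
}
# Ranges are disjoint; heavily trimmed depositions fall outside them and
# should supply an explicit role map instead of auto mode.


@dataclass
class AtomRecord:
    """One atom: PDB-style name (primes normalized to ``'``), element, xyz in Å."""

    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name!r}: xyz must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be nonempty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} not in [0,1]")


@dataclass(frozen=True)
class ResidueRef:
    chain_id: str
    auth_seq: int
    icode: str = ""
    res_name: str = ""

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.auth_seq, self.icode)


@dataclass
class Residue:
    ref: ResidueRef
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}

    @property
    def is_nucleic(self) -> bool:
        return self.ref.res_name in NUCLEIC_NAMES or "C1'" in self.atom_names()


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_nucleic(self) -> bool:
        if not self.residues:
            return False
        n = sum(1 for r in self.residues if r.is_nucleic)
        return n > len(self.residues) / 2


@dataclass
class StructureModel:
    """Ordered chains of ordered residues; the in-memory form of a PDB/mmCIF file."""

    chains: list[Chain] = field(default_factory=list)
    source_format: str = ""
    metadata: dict = field(default_factory=dict)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def iter_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def iter_atoms(self) -> Iterator[tuple[Residue, AtomRecord]]:
        for r in self.iter_residues():
            for a in r.atoms:
                yield r, a

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def copy(self) -> "StructureModel":
        return copy.deepcopy(self)


def _normalize_atom_name(name: str) -> str:
    # mmCIF and some PDB dialects use * or the Unicode prime for the sugar primes
    return name.strip().replace("*", "'").replace("′", "'")


def read_structure(
    path: str | Path,
    format: str = "auto",
    keep_waters: bool = False,
    keep_hydrogens: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Altloc duplicates are resolved to the highest-occupancy conformer (ties:
    first encountered).  Waters and hydrogens are excluded by default; every
    analysis in this package is heavy-atom based.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"file not found: {path}")
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"
    if fmt not in {"pdb", "mmcif"}:
        raise FormatError(f"unknown format {format!r} (expected pdb|mmcif|auto)")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models in file")
    gmodel = st[0]

    model = StructureModel(source_format=fmt, metadata={"path": str(path), "name": st.name})
    for gchain in gmodel:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            res_name = gres.name.strip()
            if not keep_waters and res_name in WATER_NAMES:
                continue
            ref = ResidueRef(
                chain_id=gchain.name,
                auth_seq=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                res_name=res_name,
            )
            # altloc resolution: group by atom name, keep highest occupancy
            by_name: dict[str, AtomRecord] = {}
            order: list[str] = []
            for ga in gres:
                el = ga.element.name
                if not keep_hydrogens and el in {"H", "D"}:
                    continue
                rec = AtomRecord(
                    name=_normalize_atom_name(ga.name),
                    element=el,
                    xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    bfactor=ga.b_iso,
                    altloc=ga.altloc if ga.altloc != "\x00" else "",
                )
                prev = by_name.get(rec.name)
                if prev is None:
                    by_name[rec.name] = rec
                    order.append(rec.name)
                elif rec.occupancy > prev.occupancy:
                    by_name[rec.name] = rec
            residue = Residue(ref=ref, atoms=[by_name[n] for n in order])
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            model.chains.append(chain)
    if not model.chains:
        raise StructureParseError(f"{path}: no atoms read")
    return model


def write_structure(
    model: StructureModel,
    path: str | Path,
    bfactor_channel: Mapping[ResidueRef, float] | None = None,
) -> Path:
    """Write ``model`` as PDB text.

    When ``bfactor_channel`` is given, every atom of a keyed residue carries
    that residue's scalar in the B-factor column, clamped to [0, 999.99]
    (PDB column width).  Useful for temperature-map exports.
    """
    if not model.chains:
        raise ValueError("cannot write an empty model")
    channel: dict[tuple[str, int, str], float] = {}
    if bfactor_channel is not None:
        for ref, value in bfactor_channel.items():
            channel[ref.key()] = float(value)

    st = gemmi.Structure()
    st.name = model.metadata.get("name", "nucdeform")
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.ref.res_name or "UNK"
            gres.seqid = gemmi.SeqId(res.ref.auth_seq, res.ref.icode or " ")
            b_override = channel.get(res.ref.key())
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = a.occupancy
                b = a.bfactor if b_override is None else b_override
                ga.b_iso = float(min(max(b, 0.0), 999.99))
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    path = Path(path)
    try:
        path.write_text(st.make_pdb_string())
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path


@dataclass
class NucleosomeModel:
    """A structure with nucleosome chain roles and the dyad-centred frame.

    ``roles`` maps chain_id to one of H3/H4/H2A/H2B (primed for the second
    copy), strand_top, strand_bottom, or ligand.  ``frame`` maps a residue key
    to its dyad-relative position (built by :func:`build_coordinate_frame`).
    """

    structure: StructureModel
    roles: dict[str, str] = field(default_factory=dict)
    frame: dict[tuple[str, int, str], int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def chains_for_role(self, role: str) -> list[Chain]:
        ids = [cid for cid, r in self.roles.items() if r == role]
        return [self.structure.chain(cid) for cid in ids]

    def chain_for_role(self, role: str) -> Chain:
        chains = self.chains_for_role(role)
        if not chains:
            raise RoleError(f"role {role!r} not assigned in this model")
        if len(chains) > 1:
            raise RoleError(f"role {role!r} assigned to multiple chains")
        return chains[0]

    def position_of(self, ref: ResidueRef) -> int | None:
        return self.frame.get(ref.key())

    def strand_residues(self, role: str) -> dict[int, Residue]:
        """Frame position -> residue for one DNA strand role."""
        chain = self.chain_for_role(role)
        out: dict[int, Residue] = {}
        for res in chain.residues:
            pos = self.frame.get(res.ref.key())
            if pos is not None:
                out[pos] = res
        return out

    def copy(self) -> "NucleosomeModel":
        return NucleosomeModel(
            structure=self.structure.copy(),
            roles=dict(self.roles),
            frame=dict(self.frame),
            flags=list(self.flags),
        )


def assign_nucleosome_roles(
    model: StructureModel,
    role_config: Mapping[str, str] | str = "auto",
) -> NucleosomeModel:
    """Attach nucleosome roles to the chains of ``model``.

    Explicit mode: ``role_config`` maps chain_id -> role; unique roles
    (strands, histones) may appear at most once.  Auto mode classifies DNA
    strands by nucleic residue content and histone classes by chain length;
    protein chains outside all histone length classes become ``ligand``
    (e.g. a bound glycosylase).  Auto mode is meant for idealized or
    well-behaved models — deposited structures should use an explicit map.
    """
    if isinstance(role_config, str):
        if role_config != "auto":
            raise RoleError(f"role_config must be a mapping or 'auto', got {role_config!r}")
        return _auto_assign(model)

    seen: dict[str, str] = {}
    for cid, role in role_config.items():
        model.chain(cid)  # raises KeyError for unknown chain
        if role in UNIQUE_ROLES and role in seen.values():
            other = next(c for c, r in seen.items() if r == role)
            raise RoleError(f"role {role!r} mapped to both chain {other!r} and {cid!r}")
        seen[cid] = role
    flags = []
    n_strands = sum(1 for r in seen.values() if r in DNA_ROLE_SET)
    if n_strands != 2:
        raise RoleError(f"need exactly one strand_top and one strand_bottom, got {n_strands}")
    n_hist = sum(1 for r in seen.values() if r in HISTONE_ROLE_SET)
    if n_hist < 8:
        flags.append(f"sub-stoichiometric histone core: {n_hist}/8 roles assigned")
    return NucleosomeModel(structure=model, roles=seen, flags=flags)


def _auto_assign(model: StructureModel) -> NucleosomeModel:
    nucleic = [c for c in model.chains if c.is_nucleic]
    protein = [c for c in model.chains if not c.is_nucleic]
    if len(nucleic) < 2 or len(protein) < 8:
        raise RoleError(
            f"auto mode needs >=2 nucleic and >=8 protein chains, "
            f"found {len(nucleic)} nucleic / {len(protein)} protein"
        )
    if len(nucleic) > 2:
        ids = [c.chain_id for c in nucleic]
        raise RoleError(f"auto mode ambiguity: {len(nucleic)} nucleic chains {ids}; supply a role map")
    roles: dict[str, str] = {}
    # Strand polarity cannot be inferred from composition alone; chain order is
    # used and should be confirmed via an explicit map for deposited models.
    roles[nucleic[0].chain_id] = "strand_top"
    roles[nucleic[1].chain_id] = "strand_bottom"

    buckets: dict[str, list[Chain]] = {k: [] for k in HISTONE_LENGTH_RANGES}
    for c in protein:
        n = len(c)
        hits = [k for k, (lo, hi) in HISTONE_LENGTH_RANGES.items() if lo <= n <= hi]
        if len(hits) > 1:
            raise RoleError(
                f"auto mode ambiguity: chain {c.chain_id!r} length {n} matches {hits}"
            )
        if hits:
            buckets[hits[0]].append(c)
        else:
            roles[c.chain_id] = "ligand"
    flags = []
    for base, chains in buckets.items():
        if len(chains) > 2:
            ids = [c.chain_id for c in chains]
            raise RoleError(f"auto mode ambiguity: {len(chains)} candidate {base} chains {ids}")
        for i, c in enumerate(chains):
            roles[c.chain_id] = base if i == 0 else base + "'"
    n_hist = sum(1 for r in roles.values() if r in HISTONE_ROLE_SET)
    if n_hist < 8:
        flags.append(f"sub-stoichiometric histone core: {n_hist}/8 roles assigned")
    return NucleosomeModel(structure=model, roles=roles, flags=flags)


def build_coordinate_frame(
    nmodel: NucleosomeModel,
    dyad_spec: Mapping[str, int] | str,
) -> NucleosomeModel:
    """Assign dyad-relative positions to every DNA nucleotide (in place).

    ``dyad_spec`` maps a strand role (or chain id) to the author residue
    number of its position-0 nucleotide, or is the string ``"center"`` to put
    the dyad at the middle residue of each strand (odd-length idealized
    duplexes).  Positions increase 5'->3' along the stored residue order.
    """
    for role in STRAND_ROLES:
        chain = nmodel.chain_for_role(role)
        if dyad_spec == "center":
            k = (len(chain.residues) - 1) // 2
        elif isinstance(dyad_spec, str):
            raise AnchorError(f"unknown dyad spec {dyad_spec!r}")
        else:
            auth = dyad_spec.get(role, dyad_spec.get(chain.chain_id))
            if auth is None:
                raise AnchorError(f"dyad spec has no entry for {role} (chain {chain.chain_id})")
            k = next(
                (i for i, r in enumerate(chain.residues) if r.ref.auth_seq == int(auth)),
                None,
            )
            if k is None:
                raise AnchorError(
                    f"dyad residue {auth} not found on {role} (chain {chain.chain_id})"
                )
        for i, res in enumerate(chain.residues):
            nmodel.frame[res.ref.key()] = i - k
    return nmodel


@dataclass
class CoverageReport:
    """Modeled position spans and gaps per DNA strand."""

    spans: dict[str, list[tuple[int, int]]]
    gaps: dict[str, list[tuple[int, int, int]]]  # (start, end, length)
    terminal_truncations: dict[str, list[tuple[int, int, int]]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "spans": self.spans,
                "gaps": self.gaps,
                "terminal_truncations": self.terminal_truncations,
            },
            sort_keys=True,
        )

    def to_tsv(self) -> str:
        lines = ["chain\tspan_start\tspan_end"]
        for role in sorted(self.spans):
            for a, b in self.spans[role]:
                lines.append(f"{role}\t{a}\t{b}")
        return "\n".join(lines) + "\n"


def _runs(positions: Iterable[int]) -> list[tuple[int, int]]:
    pos = sorted(set(positions))
    if not pos:
        return []
    runs = [[pos[0], pos[0]]]
    for p in pos[1:]:
        if p == runs[-1][1] + 1:
            runs[-1][1] = p
        else:
            runs.append([p, p])
    return [(a, b) for a, b in runs]


def coverage_report(
    nmodel: NucleosomeModel,
    expected: Mapping[str, tuple[int, int]] | None = None,
) -> CoverageReport:
    """Report maximal runs of consecutive modeled positions per strand.

    With ``expected`` (role -> (min_pos, max_pos)), missing runs are reported
    as gaps and any gap abutting a strand end is flagged a terminal truncation.
    Without it, only internal gaps between modeled spans are reported.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    gaps: dict[str, list[tuple[int, int, int]]] = {}
    trunc: dict[str, list[tuple[int, int, int]]] = {}
    for role in STRAND_ROLES:
        positions = sorted(nmodel.strand_residues(role))
        runs = _runs(positions)
        spans[role] = runs
        g: list[tuple[int, int, int]] = []
        t: list[tuple[int, int, int]] = []
        for (a0, b0), (a1, _b1) in zip(runs, runs[1:]):
            g.append((b0 + 1, a1 - 1, a1 - 1 - b0))
        if expected is not None and role in expected and runs:
            lo, hi = expected[role]
            if runs[0][0] > lo:
                t.append((lo, runs[0][0] - 1, runs[0][0] - lo))
            if runs[-1][1] < hi:
                t.append((runs[-1][1] + 1, hi, hi - runs[-1][1]))
        gaps[role] = g
        trunc[role] = t
    return CoverageReport(spans=spans, gaps=gaps, terminal_truncations=trunc)
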