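"""Idealized nucleosome models with injectable ground-truth perturbations.

The generator wraps an ideal duplex of pseudo-nucleotides around a
superhelical path (defaults approximate canonical nucleosome geometry:
147 bp, 1.65 turns, 41.8 Å superhelix radius) and builds a pseudo-atom
histone core, so every analysis stage can be exercised offline against
known ground truth.  Nucleotides are chemically idealized — the analyses
consume only atom names, coordinates and frame indices — and three
deformation modes seen in glycosylase-engaged nucleosomes can be injected:
a local outward bump, a 1-bp (or k-bp) register translocation toward a
strand end, and terminal unwrapping; plus isotropic coordinate noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .model import (
    AtomRecord,
    Chain,
    NucleosomeModel,
    Residue,
    ResidueRef,
    StructureModel,
    write_structure,
)

# Backbone pseudo-atom offsets in the per-nucleotide frame, Å:
# x = radially out of the DNA helix axis (toward the phosphate), y = along
# the strand's 5'->3' direction, z completes the right-handed triad.
_BACKBONE_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "P": (0.0, 0.0, 0.0),
    "OP1": (0.85, 0.9, 1.0),
    "OP2": (0.85, -0.9, -1.0),
    "O5'": (-1.0, 1.1, 0.3),
    "C5'": (-2.1, 1.6, 0.6),
    "C4'": (-3.1, 0.9, 0.1),
    "O4'": (-3.6, -0.2, 0.8),
    "C3'": (-3.2, -0.6, -1.2),
    "O3'": (-2.8, -1.9, -1.5),
    "C2'": (-4.5, -1.2, -0.4),
    "C1'": (-4.7, -0.7, 1.0),
}
_PHOSPHATE_GROUP = ("P", "OP1", "OP2")

#: Azimuthal half-offset between the two backbones around the duplex axis;
#: 2 x 82 deg puts the strands 164 deg apart across the minor groove,
#: giving a B-DNA-like narrow/wide groove asymmetry with minor-groove
#: widths of ~4.4-7.1 A on the ideal particle.
_STRAND_PHASE_DEG = 82.0

_HISTONE_CHAIN_PLAN = [
    ("A", "H3", 135),
    ("B", "H4", 102),
    ("C", "H2A", 128),
    ("D", "H2B", 122),
    ("E", "H3'", 135),
    ("F", "H4'", 102),
    ("G", "H2A'", 128),
    ("H", "H2B'", 122),
]


@dataclass
class NcpGeometryParams:
    """Geometry of the idealized particle (defaults: canonical-like NCP)."""

    n_bp: int = 147
    superhelix_radius: float = 41.8
    superhelix_pitch: float = 23.9
    total_turns: float = 1.65
    bp_twist_deg: float = 34.5
    backbone_radius: float = 9.0
    core_radius: float = 32.0
    core_spacing: float = 3.5

    def validate(self) -> None:
        lengths = (
            self.superhelix_radius,
            self.superhelix_pitch,
            self.backbone_radius,
            self.core_radius,
            self.core_spacing,
            self.total_turns,
        )
        if any(v <= 0 for v in lengths):
            raise ParameterError("all geometry lengths must be positive")
        if self.n_bp < 11:
            raise ParameterError("n_bp must be >= 11")
        if self.n_bp % 2 == 0:
            raise ParameterError("n_bp must be odd (a dyad nucleotide is required)")

    @property
    def half_span(self) -> int:
        return (self.n_bp - 1) // 2

    def theta(self, p: float) -> float:
        """Superhelical angle at (possibly fractional) base-pair index p."""
        return p * self.total_turns * 2.0 * np.pi / (self.n_bp - 1)

    def path_point(self, p: float) -> np.ndarray:
        th = self.theta(p)
        return np.array(
            [
                self.superhelix_radius * np.cos(th),
                self.superhelix_radius * np.sin(th),
                self.superhelix_pitch * th / (2.0 * np.pi),
            ]
        )

    def path_frame(self, p: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(tangent, radial-out, binormal) unit triad at path index p."""
        th = self.theta(p)
        t = np.array(
            [
                -self.superhelix_radius * np.sin(th),
                self.superhelix_radius * np.cos(th),
                self.superhelix_pitch / (2.0 * np.pi),
            ]
        )
        t /= np.linalg.norm(t)
        u = np.array([np.cos(th), np.sin(th), 0.0])
        v = np.cross(t, u)
        return t, u, v

    def rise_per_bp(self) -> float:
        """Arc length of the superhelical path per base-pair step."""
        dth = self.total_turns * 2.0 * np.pi / (self.n_bp - 1)
        return float(
            np.hypot(self.superhelix_radius * dth, self.superhelix_pitch * dth / (2 * np.pi))
        )


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def nucleotide_coords(
    params: NcpGeometryParams,
    p: float,
    strand: str,
    names: tuple[str, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Parametric backbone atom coordinates for the nucleotide at path index p.

    ``strand`` is ``strand_top`` or ``strand_bottom``; indices outside the
    wrapped range extrapolate along the same superhelical path (used when a
    register translocation slides nucleotides past a strand end).
    """
    t, u, v = params.path_frame(p)
    twist = np.deg2rad(params.bp_twist_deg)
    phase = np.deg2rad(_STRAND_PHASE_DEG)
    psi = twist * p + (phase if strand == "strand_top" else -phase)
    e1 = np.cos(psi) * u + np.sin(psi) * v
    e2 = t if strand == "strand_bottom" else -t  # 5'->3' direction of the strand
    e3 = np.cross(e1, e2)
    base = params.path_point(p) + params.backbone_radius * e1
    names = tuple(_BACKBONE_TEMPLATE) if names is None else names
    out = {}
    for name in names:
        x, y, z = _BACKBONE_TEMPLATE[name]
        out[name] = base + x * e1 + y * e2 + z * e3
    return out


def generate_ideal_ncp(
    params: NcpGeometryParams | None = None,
    di_position: int | None = None,
) -> NucleosomeModel:
    """Build the idealized particle: two antiparallel strands plus pseudo-core.

    The frame is attached directly (positions -half..+half, dyad 0, partner
    i <-> -i); chain "I" is the top strand, "J" the bottom (damaged) strand,
    and chains A..H carry the eight histone roles.  ``di_position`` renames
    one bottom-strand nucleotide to DI to mark a lesion site.  Fully
    deterministic.
    """
    params = params or NcpGeometryParams()
    params.validate()
    half = params.half_span

    structure = StructureModel(source_format="generated", metadata={"params": asdict(params)})
    roles: dict[str, str] = {}
    frame: dict[tuple[str, int, str], int] = {}

    # Strands: bottom 5'->3' traverses path index -half..+half (frame = p);
    # top 5'->3' traverses +half..-half (frame = -p), so partner(i) = -i.
    for chain_id, role, res_name in (("I", "strand_top", "DT"), ("J", "strand_bottom", "DA")):
        chain = Chain(chain_id=chain_id)
        path_order = range(half, -half - 1, -1) if role == "strand_top" else range(-half, half + 1)
        for auth, p in enumerate(path_order, start=1):
            pos = -p if role == "strand_top" else p
            name = res_name
            if role == "strand_bottom" and di_position is not None and pos == di_position:
                name = "DI"
            coords = nucleotide_coords(params, p, role)
            atoms = []
            for atom_name, xyz in coords.items():
                if auth == 1 and atom_name in _PHOSPHATE_GROUP:
                    continue  # 5'-terminal nucleotide has no phosphate
                atoms.append(AtomRecord(atom_name, _element_of(atom_name), xyz))
            ref = ResidueRef(chain_id=chain_id, auth_seq=auth, res_name=name)
            chain.residues.append(Residue(ref=ref, atoms=atoms))
            frame[ref.key()] = pos
        structure.chains.append(chain)
        roles[chain_id] = role

    # Pseudo-histone core: lattice ball partitioned into eight chains whose
    # residue counts fall in the auto-classification length classes.
    pts = _core_lattice(params)
    needed = sum(n for _, _, n in _HISTONE_CHAIN_PLAN)
    if len(pts) < needed:
        raise ParameterError(
            f"core lattice has {len(pts)} points but {needed} pseudo-residues are needed"
        )
    k = 0
    for chain_id, role, n_res in _HISTONE_CHAIN_PLAN:
        chain = Chain(chain_id=chain_id)
        for auth in range(1, n_res + 1):
            ref = ResidueRef(chain_id=chain_id, auth_seq=auth, res_name="ALA")
            chain.residues.append(
                Residue(ref=ref, atoms=[AtomRecord("CA", "C", pts[k].copy())])
            )
            k += 1
        structure.chains.append(chain)
        roles[chain_id] = role

    return NucleosomeModel(structure=structure, roles=roles, frame=frame)


def _core_lattice(params: NcpGeometryParams) -> np.ndarray:
    s = params.core_spacing
    m = int(np.floor(params.core_radius / s))
    axis = np.arange(-m, m + 1) * s
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= params.core_radius]
    order = np.lexsort((pts[:, 0], pts[:, 1], pts[:, 2]))
    return pts[order]


@dataclass
class PerturbationSpec:
    """Ground-truth deformation to inject into an ideal model.

    kinds: ``bump`` (Gaussian-profiled rigid outward displacement, amplitude
    Å at ``center``), ``register`` (slide nucleotides from ``start`` to the
    ``end`` terminus onto the path positions of their ``offset``-removed
    neighbors, author numbering preserved), ``unwrap`` (rotate the terminal
    segment off the core by ``amplitude`` degrees about the radial axis at
    ``start``, or delete it when ``delete`` is set, emulating unmodeled
    density), ``noise`` (i.i.d. Gaussian displacement, ``sigma`` Å, seeded).
    """

    kind: str
    strand: str = "strand_bottom"
    center: int | None = None
    start: int | None = None
    end: str = "5p"
    amplitude: float = 0.0
    offset: int = 0
    halfwidth: float = 2.0
    sigma: float = 0.0
    delete: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _strand_scope(spec_strand: str) -> list[str]:
    if spec_strand == "both":
        return ["strand_top", "strand_bottom"]
    if spec_strand in {"strand_top", "strand_bottom"}:
        return [spec_strand]
    raise ParameterError(f"unknown strand scope {spec_strand!r}")


def perturb(
    model: NucleosomeModel,
    spec: PerturbationSpec,
    params: NcpGeometryParams | None = None,
) -> NucleosomeModel:
    """Return a perturbed copy of ``model``.

    ``register`` and ``unwrap`` are defined relative to the ideal path and
    expect a model generated with the same ``params`` (defaults used when
    omitted); perturbations compose by repeated calls, with path-defined
    kinds applied first.
    """
    params = params or NcpGeometryParams()
    out = model.copy()
    out.structure.metadata.setdefault("perturbations", []).append(spec.to_dict())

    if spec.kind == "bump":
        if spec.center is None:
            raise ParameterError("bump needs a center position")
        _check_in_range(out, "strand_bottom" if spec.strand == "both" else spec.strand,
                        spec.center)
        for role in _strand_scope(spec.strand):
            # for a both-strand bump the center names the damaged (bottom)
            # position; the top strand is bumped at the partner positions
            center = spec.center
            if spec.strand == "both" and role == "strand_top":
                center = -spec.center
            for pos, res in out.strand_residues(role).items():
                d = spec.amplitude * np.exp(
                    -((pos - center) ** 2) / (2.0 * spec.halfwidth**2)
                )
                if d == 0.0:
                    continue
                centroid = np.mean([a.xyz for a in res.atoms], axis=0)
                radial = np.array([centroid[0], centroid[1], 0.0])
                norm = np.linalg.norm(radial)
                if norm == 0:
                    continue
                shift = d * radial / norm
                for a in res.atoms:
                    a.xyz = a.xyz + shift

    elif spec.kind == "register":
        # start/end are in path coordinates (= bottom-strand frame positions);
        # the whole segment slides by `offset` path steps along the ideal path.
        if spec.start is None or spec.offset == 0:
            raise ParameterError("register needs a start position and a nonzero offset")
        half = params.half_span
        path_range = (-half, spec.start) if spec.end == "5p" else (spec.start, half)
        moved = 0
        doomed: set = set()
        for role in _strand_scope(spec.strand):
            for pos, res in out.strand_residues(role).items():
                path_p = pos if role == "strand_bottom" else -pos
                if not path_range[0] <= path_p <= path_range[1]:
                    continue
                target = path_p + spec.offset
                if not -half <= target <= half:
                    # slid past the wrapped region: disordered, hence unmodeled
                    doomed.add(res.ref.key())
                    continue
                coords = nucleotide_coords(
                    params, target, role, names=tuple(a.name for a in res.atoms)
                )
                for a in res.atoms:
                    a.xyz = coords[a.name]
                moved += 1
        if doomed:
            for chain in out.structure.chains:
                chain.residues = [r for r in chain.residues if r.ref.key() not in doomed]
            for key in doomed:
                out.frame.pop(key, None)
        if moved == 0:
            raise ParameterError(f"register range {path_range} covers no nucleotides")

    elif spec.kind == "unwrap":
        if spec.start is None:
            raise ParameterError("unwrap needs a start position")
        half = params.half_span
        if spec.end == "5p":
            path_range = (-half, spec.start)
        else:
            path_range = (spec.start, half)
        affected = []
        for role in ("strand_top", "strand_bottom"):
            residues = out.strand_residues(role)
            for pos, res in residues.items():
                path_p = pos if role == "strand_bottom" else -pos
                if path_range[0] <= path_p <= path_range[1]:
                    affected.append((role, pos, res))
        if not affected:
            raise ParameterError(f"unwrap range {path_range} covers no nucleotides")
        if spec.delete:
            doomed = {res.ref.key() for _, _, res in affected}
            for chain in out.structure.chains:
                chain.residues = [r for r in chain.residues if r.ref.key() not in doomed]
            for key in doomed:
                out.frame.pop(key, None)
        else:
            boundary = spec.start if spec.end == "5p" else spec.start
            pivot = params.path_point(boundary)
            _, axis, _ = params.path_frame(boundary)  # radial axis: hinge
            R = _rodrigues(axis, np.deg2rad(spec.amplitude))
            for _, _, res in affected:
                for a in res.atoms:
                    a.xyz = pivot + R @ (a.xyz - pivot)

    elif spec.kind == "noise":
        if spec.sigma < 0:
            raise ParameterError("noise sigma must be nonnegative")
        rng = np.random.default_rng(spec.seed)
        for role in _strand_scope(spec.strand if spec.strand else "both"):
            for _pos, res in sorted(out.strand_residues(role).items()):
                for a in res.atoms:
                    a.xyz = a.xyz + rng.normal(0.0, spec.sigma, size=3)

    else:
        raise ParameterError(f"unknown perturbation kind {spec.kind!r}")
    return out


def _check_in_range(model: NucleosomeModel, strand: str, position: int) -> None:
    for role in _strand_scope(strand):
        residues = model.strand_residues(role)
        if position not in residues:
            raise ParameterError(f"position {position} not modeled on {role}")


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the canonical fixture suite as PDB files plus a JSON manifest.

    Ten fixtures: the unperturbed particle, four bump amplitudes (1/3/5/8 Å
    at -30), register slides of +-1 bp from -53 to the 5' exit, a deleted
    terminal segment from -61 (emulating unmodeled density), and two noise
    levels (0.1 / 0.5 Å).  Regenerating with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = NcpGeometryParams()
    ideal = generate_ideal_ncp(params, di_position=-30)

    specs: dict[str, PerturbationSpec | None] = {"canonical": None}
    for a in (1, 3, 5, 8):
        specs[f"bump_a{a}"] = PerturbationSpec(
            kind="bump", strand="strand_bottom", center=-30, amplitude=float(a), halfwidth=2.0
        )
    specs["register_p1"] = PerturbationSpec(
        kind="register", strand="strand_bottom", start=-53, offset=1
    )
    specs["register_m1"] = PerturbationSpec(
        kind="register", strand="strand_bottom", start=-53, offset=-1
    )
    specs["unwrap_del61"] = PerturbationSpec(
        kind="unwrap", strand="both", start=-61, delete=True
    )
    specs["noise_s01"] = PerturbationSpec(kind="noise", strand="both", sigma=0.1, seed=seed)
    specs["noise_s05"] = PerturbationSpec(kind="noise", strand="both", sigma=0.5, seed=seed + 1)

    manifest: dict = {"seed": seed, "params": asdict(params), "fixtures": {}}
    for name, spec in specs.items():
        model = ideal if spec is None else perturb(ideal, spec, params)
        path = out_dir / f"{name}.pdb"
        write_structure(model.structure, path)
        manifest["fixtures"][name] = {
            "file": path.name,
            "spec": None if spec is None else spec.to_dict(),
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
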