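"""End-to-end comparison workflow: read, superpose, profile, interface, register.

``run_compare`` executes the full analysis a structural comparison of two
nucleosome models requires — histone-anchored superposition (with an
optional similarity-scale check for voxel-size miscalibration), backbone
RMSD profiles and site windows, buried DNA-histone surface area for both
models, register-shift tracking, and coverage reporting — and writes a
reproducible report bundle (TSV/JSON/PDB plus a run log).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from .distortion import (
    export_temperature_model,
    per_nucleotide_rmsd,
    profile_extrema,
    site_windows,
)
from .errors import NucdeformError, StageError
from .interface import buried_area
from .model import (
    NucleosomeModel,
    assign_nucleosome_roles,
    build_coordinate_frame,
    coverage_report,
    read_structure,
)
from .register import segment_register, spatial_register_track
from .superpose import apply_transform, build_correspondence, superpose_models, umeyama


@dataclass
class ComparisonConfig:
    """All knobs of a pairwise comparison; defaults echo the package defaults."""

    ref_path: str = ""
    test_path: str = ""
    ref_roles: Mapping[str, str] | str = "auto"
    test_roles: Mapping[str, str] | str = "auto"
    ref_dyad: Mapping[str, int] | str = "center"
    test_dyad: Mapping[str, int] | str = "center"
    damage_sites: list[int] = field(default_factory=list)
    damaged_strand: str = "strand_bottom"
    anchor: str = "H3"
    pool_copies: bool = True
    prune: str = "none"
    prune_cutoff: float = 2.0
    max_iter: int = 10
    window_halfwidth: int = 5
    window_mode: str = "pooled"
    sasa_probe: float = 1.4
    sasa_points: int = 960
    radii_set: str = "default"
    ba_convention: str = "sum"
    register_halfwidth: int = 3
    register_anchor: str = "C1'"
    scale_check: bool = True
    out_dir: str = "compare_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ref_roles"] = dict(self.ref_roles) if not isinstance(self.ref_roles, str) else self.ref_roles
        d["test_roles"] = dict(self.test_roles) if not isinstance(self.test_roles, str) else self.test_roles
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "ComparisonConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _load_model(
    path: str, roles: Mapping[str, str] | str, dyad: Mapping[str, int] | str, stage: str
) -> NucleosomeModel:
    try:
        structure = read_structure(path)
    except NucdeformError as exc:
        raise StageError("read_structure", str(exc)) from exc
    try:
        nmodel = assign_nucleosome_roles(structure, roles)
    except NucdeformError as exc:
        raise StageError(f"assign_roles:{stage}", str(exc)) from exc
    try:
        build_coordinate_frame(nmodel, dyad)
    except NucdeformError as exc:
        raise StageError(f"build_frame:{stage}", str(exc)) from exc
    return nmodel


def run_compare(config: ComparisonConfig) -> dict:
    """Run the full comparison; returns the summary dict (also written to disk).

    Outputs in ``config.out_dir``: profile.tsv, summary.json, temperature.pdb,
    register.tsv, coverage_{ref,test}.json, run.log.  Stage failures raise
    :class:`StageError` naming the stage; partial outputs are preserved.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    log_lines: list[str] = []
    t0 = time.time()

    def log(stage: str, **info) -> None:
        entry = {"stage": stage, "t_s": round(time.time() - t0, 3), **info}
        log_lines.append(json.dumps(entry, sort_keys=True))

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    summary: dict = {
        "tool": "nucdeform",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
    }

    try:
        ref = _load_model(config.ref_path, config.ref_roles, config.ref_dyad, "ref")
        test = _load_model(config.test_path, config.test_roles, config.test_dyad, "test")
        log("load", ref=config.ref_path, test=config.test_path)

        if config.scale_check:
            try:
                cmap = build_correspondence(ref, test, config.anchor)
                P, Q, _ = cmap.coordinates(ref, test)
                sim, sim_rmsd = umeyama(Q, P)  # test -> ref
                summary["scale_check"] = {"scale": sim.scale, "rmsd": sim_rmsd}
                log("scale_check", scale=sim.scale)
            except NucdeformError as exc:
                raise StageError("scale_check", str(exc)) from exc

        try:
            sup = superpose_models(
                ref,
                test,
                anchor=config.anchor,
                prune=config.prune,
                prune_cutoff=config.prune_cutoff,
                max_iter=config.max_iter,
                pool_copies=config.pool_copies,
            )
            test_sup = apply_transform(test, sup.transform)
            summary["superposition"] = sup.diagnostics
            log("superpose", **sup.diagnostics)
        except NucdeformError as exc:
            raise StageError("superpose", str(exc)) from exc

        try:
            profile = per_nucleotide_rmsd(ref, test_sup)
            profile.to_tsv(out_dir / "profile.tsv")
            summary["extrema"] = {}
            for role in ("strand_top", "strand_bottom"):
                if profile.strand(role):
                    ex = profile_extrema(profile, role)
                    summary["extrema"][role] = {
                        "argmax": ex.argmax,
                        "max_rmsd": ex.max_rmsd,
                        "secondary_peaks": ex.secondary_peaks,
                    }
            export_temperature_model(profile, test_sup, out_dir / "temperature.pdb")
            log("profile", entries=len(profile.entries))
        except NucdeformError as exc:
            raise StageError("profile", str(exc)) from exc

        try:
            summary["site_windows"] = {}
            for site in config.damage_sites:
                summary["site_windows"][str(site)] = site_windows(
                    ref,
                    test_sup,
                    center=site,
                    halfwidth=config.window_halfwidth,
                    damaged_strand=config.damaged_strand,
                    mode=config.window_mode,
                )
            log("windows", sites=config.damage_sites)
        except NucdeformError as exc:
            raise StageError("windows", str(exc)) from exc

        try:
            ba_ref = buried_area(
                ref, probe=config.sasa_probe, n_points=config.sasa_points,
                radii_set=config.radii_set,
            )
            ba_test = buried_area(
                test, probe=config.sasa_probe, n_points=config.sasa_points,
                radii_set=config.radii_set,
            )
            conv = config.ba_convention
            summary["buried_area"] = {
                "ref": ba_ref.to_dict(),
                "test": ba_test.to_dict(),
                "convention": conv,
                "difference": ba_test.value(conv) - ba_ref.value(conv),
            }
            log("buried_area", ref=ba_ref.value(conv), test=ba_test.value(conv))
        except NucdeformError as exc:
            raise StageError("buried_area", str(exc)) from exc

        try:
            track = spatial_register_track(
                ref,
                test_sup,
                strand=config.damaged_strand,
                search_halfwidth=config.register_halfwidth,
                anchor_atom=config.register_anchor,
            )
            track.to_tsv(out_dir / "register.tsv")
            seg = segment_register(track, damage_sites=set(config.damage_sites))
            summary["register"] = {
                "warnings": track.warnings,
                "shifts": [asdict(s) for s in seg["shifts"]],
                "noise": [asdict(s) for s in seg["noise"]],
            }
            log("register", shifts=len(seg["shifts"]))
        except NucdeformError as exc:
            raise StageError("register", str(exc)) from exc

        try:
            for name, model in (("ref", ref), ("test", test)):
                cov = coverage_report(model)
                (out_dir / f"coverage_{name}.json").write_text(cov.to_json())
            log("coverage")
        except NucdeformError as exc:
            raise StageError("coverage", str(exc)) from exc

        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        log("done")
        return summary
    finally:
        log_path.write_text("\n".join(log_lines) + "\n")
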