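"""Detection of local translational register shifts of nucleosomal DNA.

After a histone-anchored superposition, a register shift shows up as test
nucleotides sitting on the spatial positions that *different* sequence
indices occupy in the reference: nucleotide i matching reference position
i+1 is a +1 shift.  The track is built per nucleotide by nearest-anchor
matching within a small search window, then segmented into maximal runs of
constant offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import RoleError, ScoreUndefinedError, TrackError
from .model import NucleosomeModel


@dataclass
class Segment:
    strand: str
    offset: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegisterTrack:
    """Per-position integer spatial register offsets with match distances."""

    strand: str
    offsets: dict[int, int] = field(default_factory=dict)
    match_dist: dict[int, float] = field(default_factory=dict)
    search_halfwidth: int = 3
    anchor_atom: str = "C1'"
    warnings: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["strand\tposition\toffset\tmatch_dist_A"]
        for pos in sorted(self.offsets):
            lines.append(
                f"{self.strand}\t{pos}\t{self.offsets[pos]}\t{self.match_dist[pos]:.4f}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _anchor_xyz(res, anchor_atom: str) -> np.ndarray | None:
    """Anchor coordinate: named atom, else backbone centroid fallback."""
    a = res.atom(anchor_atom)
    if a is not None:
        return a.xyz
    if res.atoms:
        return np.mean([at.xyz for at in res.atoms], axis=0)
    return None


def spatial_register_track(
    ref: NucleosomeModel,
    test: NucleosomeModel,
    strand: str,
    search_halfwidth: int = 3,
    anchor_atom: str = "C1'",
    min_zero_fraction: float = 0.6,
) -> RegisterTrack:
    """Per-nucleotide spatial register offsets of ``test`` against ``ref``.

    For each test nucleotide at position i, the offset is
    ``argmin_{j in [i-h, i+h]} |test_anchor(i) - ref_anchor(j)| - i``, with
    ties broken toward zero offset, then toward the negative offset.  When
    fewer than ``min_zero_fraction`` of tracked positions have zero offset
    the global register itself may differ and a warning is recorded.
    """
    try:
        test_res = test.strand_residues(strand)
        ref_res = ref.strand_residues(strand)
    except RoleError as exc:
        raise RoleError(f"register track: {exc}") from exc

    track = RegisterTrack(
        strand=strand, search_halfwidth=search_halfwidth, anchor_atom=anchor_atom
    )
    for i in sorted(test_res):
        txyz = _anchor_xyz(test_res[i], anchor_atom)
        if txyz is None:
            continue
        best: tuple[float, int] | None = None
        for j in range(i - search_halfwidth, i + search_halfwidth + 1):
            r = ref_res.get(j)
            rxyz = _anchor_xyz(r, anchor_atom) if r is not None else None
            if rxyz is None:
                continue
            d = float(np.linalg.norm(txyz - rxyz))
            delta = j - i
            if best is None:
                best = (d, delta)
            else:
                bd, bdelta = best
                # tie-break: smaller distance; then |delta| toward 0; then negative
                if d < bd - 1e-9 or (
                    abs(d - bd) <= 1e-9
                    and (abs(delta), delta) < (abs(bdelta), bdelta)
                ):
                    best = (d, delta)
        if best is None:
            continue  # no ref anchor within the search window
        track.offsets[i] = best[1]
        track.match_dist[i] = best[0]
    if not track.offsets:
        raise TrackError(f"empty register track for strand {strand!r}")
    zero_frac = sum(1 for v in track.offsets.values() if v == 0) / len(track.offsets)
    if zero_frac < min_zero_fraction:
        msg = (
            f"only {zero_frac:.0%} of positions at zero offset; the global "
            "register may differ and the comparison may be misaligned"
        )
        track.warnings.append(msg)
        warnings.warn(msg)
    return track


def segment_register(
    track: RegisterTrack,
    min_run: int = 3,
    damage_sites: set[int] | None = None,
) -> dict:
    """Maximal constant-offset runs of a track; report nonzero runs as shifts.

    Runs shorter than ``min_run`` are flagged as noise unless they contain a
    declared damage site.  Returns a dict with ``segments`` (all runs),
    ``shifts`` (reported nonzero runs) and ``noise`` (suppressed excursions).
    """
    if not track.offsets:
        raise TrackError("cannot segment an empty track")
    damage_sites = damage_sites or set()
    positions = sorted(track.offsets)
    segments: list[Segment] = []
    start = prev = positions[0]
    cur = track.offsets[start]
    for pos in positions[1:]:
        if track.offsets[pos] == cur and pos == prev + 1:
            prev = pos
            continue
        segments.append(Segment(track.strand, cur, start, prev))
        start = prev = pos
        cur = track.offsets[pos]
    segments.append(Segment(track.strand, cur, start, prev))

    shifts, noise = [], []
    for seg in segments:
        if seg.offset == 0:
            continue
        covers_damage = any(seg.start <= s <= seg.end for s in damage_sites)
        if seg.length >= min_run or covers_damage:
            shifts.append(seg)
        else:
            noise.append(seg)
    return {"segments": segments, "shifts": shifts, "noise": noise}


def flipped_nucleotide_score(
    nmodel: NucleosomeModel,
    position: int,
    strand: str = "strand_bottom",
    anchor_atom: str = "C1'",
) -> float:
    """Extrusion score for one nucleotide (values >> 1 indicate flipping out).

    The raw quantity is the distance of the nucleotide's C1' from the
    midpoint of the C1' atoms of its cross-strand neighborhood partners
    (partners of positions i-1 and i+1, i.e. -(i-1) and -(i+1) on the other
    strand), normalized by the median of that quantity over all interior
    positions of the strand.
    """
    other = "strand_top" if strand == "strand_bottom" else "strand_bottom"
    mine = nmodel.strand_residues(strand)
    theirs = nmodel.strand_residues(other)

    def raw(i: int) -> float | None:
        res = mine.get(i)
        left = theirs.get(-(i - 1))
        right = theirs.get(-(i + 1))
        if res is None or left is None or right is None:
            return None
        c = _anchor_xyz(res, anchor_atom)
        cl = _anchor_xyz(left, anchor_atom)
        cr = _anchor_xyz(right, anchor_atom)
        if c is None or cl is None or cr is None:
            return None
        return float(np.linalg.norm(c - 0.5 * (cl + cr)))

    value = raw(position)
    if value is None:
        raise ScoreUndefinedError(
            f"insufficient cross-strand neighbors for {strand} position {position}"
        )
    pool = [r for i in sorted(mine) if (r := raw(i)) is not None]
    med = float(np.median(pool))
    if med <= 0:
        raise ScoreUndefinedError("degenerate geometry: zero median baseline")
    return value / med
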