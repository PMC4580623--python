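"""Backrub backbone moves.

A three-residue backrub rotates the segment between Ca(i-1) and Ca(i+1)
about the axis through those two atoms by an angle theta, then counter-
rotates the two flanking peptide-bond planes about their own Ca-Ca axes so
that the displacement of the C-O and N-H groups from their pre-move
positions is minimized.  The pivot Ca atoms are exact fixed points and all
covalent bond lengths are preserved: the move changes only dihedral degrees
of freedom.

Rotated atom set for pivot residue i: C, O of residue i-1; every atom of
residue i; N (and H, when present) of residue i+1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .structure import Pose


@dataclass
class BackrubParams:
    """Width of the Gaussian from which backrub angles are drawn.

    The default of 4.57 degrees is the standard deviation of backbone
    rotations observed in alternate-conformation crystal structures.
    """

    sigma_theta: float = 4.57

    def __post_init__(self):
        if self.sigma_theta <= 0:
            raise ValueError("sigma_theta must be positive")


@dataclass
class BackrubMove:
    pivot: tuple[str, int]
    theta: float
    corrections: bool = True

    def __post_init__(self):
        if abs(self.theta) >= 90.0:
            raise ValueError("|theta| >= 90 degrees is pathological for a backrub move")


def sample_backrub_angle(params: BackrubParams, rng: np.random.Generator) -> float:
    """Draw theta ~ N(0, sigma_theta^2), in degrees."""
    return float(rng.normal(0.0, params.sigma_theta))


def _segment_atoms(pose: Pose, pivot):
    """(prev, res, next) residues and the list of AtomRecords in the rotated segment."""
    res = pose.residue(tuple(pivot))
    prev_r, next_r = pose.neighbors(res.key)
    if prev_r is None or next_r is None:
        raise ValueError(f"pivot {pivot} lacks a flanking residue; cannot backrub")
    core = []
    for nm in ("C", "O"):
        if nm in prev_r.backbone:
            core.append(prev_r.backbone[nm])
    core.extend(res.atoms)
    for nm in ("N", "H"):
        if nm in next_r.backbone:
            core.append(next_r.backbone[nm])
    return prev_r, res, next_r, core


def apply_backrub(pose: Pose, move: BackrubMove) -> Pose:
    """Apply a backrub move in place; returns the same pose.

    With ``move.corrections`` the two flanking peptide-bond planes are
    counter-rotated by the closed-form angle that minimizes the summed
    squared displacement of the C-O and N-H group atoms from their pre-move
    positions.
    """
    prev_r, res, next_r, segment = _segment_atoms(pose, move.pivot)
    if move.theta == 0.0:
        return pose  # exact identity, bit-for-bit
    ca_prev = prev_r.backbone["CA"].coords.copy()
    ca_next = next_r.backbone["CA"].coords.copy()
    axis = ca_next - ca_prev

    pep1 = [prev_r.backbone[nm] for nm in ("C", "O") if nm in prev_r.backbone]
    pep1 += [res.backbone[nm] for nm in ("N", "H") if nm in res.backbone]
    pep2 = [res.backbone[nm] for nm in ("C", "O") if nm in res.backbone]
    pep2 += [next_r.backbone[nm] for nm in ("N", "H") if nm in next_r.backbone]
    pre1 = np.array([a.coords for a in pep1])
    pre2 = np.array([a.coords for a in pep2])

    pts = np.array([a.coords for a in segment])
    new = geometry.rotation_about_axis(pts, ca_prev, axis, move.theta)
    for a, xyz in zip(segment, new):
        a.coords = xyz

    if move.corrections:
        ca_i = res.backbone["CA"].coords
        for group, pre, origin, ax_end in (
            (pep1, pre1, ca_prev, ca_i),
            (pep2, pre2, ca_i, ca_next),
        ):
            cur = np.array([a.coords for a in group])
            alpha = geometry.optimal_rotation_angle(cur, pre, origin, ax_end - origin)
            fixed = geometry.rotation_about_axis(cur, origin, ax_end - origin, alpha)
            for a, xyz in zip(group, fixed):
                a.coords = xyz
    return pose


def measure_altloc_backrub_angles(
    pose: Pose, d_center: float = 0.2, d_flank: float = 0.2
) -> list[float]:
    """Backrub angles implied by alternate coordinates.

    For every three-residue window where the central Ca moves by more than
    `d_center` Angstrom between altlocs A and B while both flanking Ca atoms
    move by less than `d_flank`, returns the rotation angle about the
    Ca(i-1) -> Ca(i+1) axis that best maps the A-state central Ca onto the
    B-state one (projected-angle computation, degrees).
    """
    angles = []
    for idx in range(1, len(pose.residues) - 1):
        res = pose.residues[idx]
        prev_r, next_r = pose.neighbors(res.key)
        if prev_r is None or next_r is None:
            continue
        ca_a = res.backbone["CA"].coords
        ca_b = _alt_coords(res, "CA")
        if ca_b is None:
            continue
        if np.linalg.norm(ca_a - ca_b) <= d_center:
            continue
        flank_ok = True
        for fr in (prev_r, next_r):
            alt = _alt_coords(fr, "CA")
            if alt is not None and np.linalg.norm(fr.backbone["CA"].coords - alt) >= d_flank:
                flank_ok = False
        if not flank_ok:
            continue
        origin = prev_r.backbone["CA"].coords
        axis = next_r.backbone["CA"].coords - origin
        theta = geometry.optimal_rotation_angle(
            ca_a[None, :], ca_b[None, :], origin, axis
        )
        angles.append(theta)
    return angles


def _alt_coords(res, name: str):
    for a in res.alt_atoms:
        if a.name == name:
            return a.coords
    return None


def write_angle_list(angles, path) -> None:
    """One-column TSV of measured backrub angles, for distribution fitting."""
    with open(path, "w") as fh:
        fh.write("theta_deg\n")
        for t in angles:
            fh.write(f"{t:.4f}\n")
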