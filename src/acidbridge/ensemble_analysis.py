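"""Trajectory-style flexibility metrics: backbone RMSD series and per-residue RMSF."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .homology import superpose
from .structio import Ensemble, Structure

__all__ = ["RmsdSeries", "RmsfProfile", "backbone_rmsd_series", "per_residue_rmsf"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class RmsdSeries:
    """Backbone RMSD of each frame against a reference structure."""

    frame_indices: np.ndarray
    rmsd: np.ndarray       # A
    mean_rmsd: float       # A


@dataclass
class RmsfProfile:
    """Per-residue fluctuation about the ensemble mean position."""

    residue_ids: list[tuple[str, int, str]]   # (chain, resnum, icode)
    rmsf: np.ndarray                          # A


def _backbone_coords(structure: Structure, atom_names=BACKBONE_ATOMS) -> np.ndarray:
    rows, missing = [], []
    for res in structure.residues:
        if not res.is_protein:
            continue
        for name in atom_names:
            a = res.atom(name)
            if a is None:
                missing.append(f"{res.label}:{name}")
            else:
                rows.append(a.coords)
    if missing:
        raise ValueError(f"missing backbone atoms: {', '.join(missing[:10])}")
    return np.vstack(rows)


def backbone_rmsd_series(
    ensemble: Ensemble,
    reference: Structure,
    superpose_each: bool = True,
) -> RmsdSeries:
    """RMSD of every frame's backbone (N, CA, C, O) against ``reference``.

    With ``superpose_each`` (the default) every frame is first rigid-body
    fitted onto the reference, so the series measures internal deformation;
    without it the raw coordinate deviation is reported.
    """
    ref = _backbone_coords(reference)
    values = np.empty(ensemble.n_frames)
    for i, frame in enumerate(ensemble.frames):
        coords = _backbone_coords(frame)
        if coords.shape != ref.shape:
            raise ValueError(f"frame {i} backbone does not match the reference topology")
        if superpose_each:
            values[i] = superpose(coords, ref).rmsd
        else:
            values[i] = float(np.sqrt(((coords - ref) ** 2).sum(axis=1).mean()))
    return RmsdSeries(
        frame_indices=np.arange(ensemble.n_frames),
        rmsd=values,
        mean_rmsd=float(values.mean()),
    )


def per_residue_rmsf(ensemble: Ensemble, align_to_mean: bool = True) -> RmsfProfile:
    """Per-residue C-alpha fluctuation about the ensemble mean structure.

    RMSF_i = sqrt(mean over frames of |r_i(f) - <r_i>|^2), computed on
    C-alpha positions.  With ``align_to_mean`` every frame is first
    superposed onto the ensemble mean (iterated once from the raw mean),
    making the profile invariant to a global rigid transform of all frames.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    ids = [
        r.key for r in ensemble.frames[0].residues
        if r.is_protein and r.atom("CA") is not None
    ]
    coords = np.stack([
        np.vstack([
            r.atom("CA").coords
            for r in frame.residues
            if r.is_protein and r.atom("CA") is not None
        ])
        for frame in ensemble.frames
    ])  # (n_frames, n_res, 3)
    if align_to_mean and coords.shape[1] >= 3:
        mean = coords.mean(axis=0)
        for _ in range(2):  # mean and fit are coupled; two rounds suffice here
            aligned = np.empty_like(coords)
            for f in range(coords.shape[0]):
                sup = superpose(coords[f], mean)
                aligned[f] = sup.apply(coords[f])
            coords = aligned
            mean = coords.mean(axis=0)
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    return RmsfProfile(residue_ids=ids, rmsf=rmsf)
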