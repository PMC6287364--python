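"""Synthetic structures, ensembles and kinetics tables with known ground truth.

Every downstream stage of the design pipeline — salt-bridge detection,
titration, ensemble flexibility metrics, decay and Michaelis–Menten fits —
is testable against these generators without any external structure or
laboratory data.  All generators are pure functions of (spec, seed):
identical seeds give identical outputs.

The toy structures are ideal poly-alanine helices on which oppositely
charged residue pairs are planted with an exact minimum charged-atom N–O
distance; only the charged-atom geometry matters to the bridge criterion,
so no rotamer sampling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .structio import Atom, Ensemble, Residue, Structure

__all__ = [
    "ToyStructureSpec",
    "DecaySpec",
    "MMSpec",
    "CHARGED_GROUPS",
    "make_toy_structure",
    "jitter_ensemble",
    "simulate_decay",
    "simulate_mm",
]

#: charged side-chain group per residue type: (atom names, element,
#: canonical distance of the group centroid from the C-alpha, Angstrom)
CHARGED_GROUPS: dict[str, tuple[tuple[str, ...], str, float]] = {
    "ARG": (("NH1", "NH2"), "N", 4.1),
    "LYS": (("NZ",), "N", 4.7),
    "HIS": (("ND1", "NE2"), "N", 3.6),
    "ASP": (("OD1", "OD2"), "O", 2.9),
    "GLU": (("OE1", "OE2"), "O", 3.9),
}

_BASIC = ("ARG", "LYS", "HIS")
_ACIDIC = ("ASP", "GLU")

# ideal alpha-helix parameters
_HELIX_RISE = 1.5          # A per residue along the axis
_HELIX_TWIST = 100.0       # degrees per residue
_HELIX_RADIUS = 2.3        # A, C-alpha distance from the axis
_GROUP_HALF_SPACING = 0.55  # A, half-separation of two-atom charged groups
_PAIR_STRIDE = 8           # residues between successive planted pairs


@dataclass
class ToyStructureSpec:
    """Blueprint for a toy helix with planted salt-bridge partners.

    ``planted_pairs`` lists (basic residue type, acidic residue type,
    target minimum N–O distance in Angstrom); the generator guarantees the
    realised minimum charged-atom distance matches the target to well
    within 0.05 A.  Target distances below 2.0 A are sterically infeasible
    and rejected.
    """

    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    n_residues: int | None = None
    chain: str = "A"
    helix_rise: float = _HELIX_RISE
    helix_twist: float = _HELIX_TWIST
    helix_radius: float = _HELIX_RADIUS
    seed: int = 0

    def __post_init__(self) -> None:
        for basic, acidic, dist in self.planted_pairs:
            if basic not in _BASIC:
                raise ValueError(f"basic residue type must be one of {_BASIC}, got {basic}")
            if acidic not in _ACIDIC:
                raise ValueError(f"acidic residue type must be one of {_ACIDIC}, got {acidic}")
            if dist <= 2.0:
                raise ValueError(f"target distance {dist} A is infeasible (must exceed 2.0 A)")

    @property
    def resolved_n_residues(self) -> int:
        need = _PAIR_STRIDE * len(self.planted_pairs) + 2
        if self.n_residues is None:
            return need
        if self.n_residues < need:
            raise ValueError(
                f"{len(self.planted_pairs)} pairs need >= {need} residues, got {self.n_residues}"
            )
        return self.n_residues


@dataclass
class DecaySpec:
    """First-order activity decay: A(t) = A0 * exp(-(ln2/half_life) * t) * (1+eps)."""

    half_life: float                      # minutes
    timepoints: Sequence[float]           # minutes, increasing
    initial_activity: float = 100.0       # arbitrary units
    noise_sd: float = 0.0                 # relative (multiplicative) noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")
        t = np.asarray(self.timepoints, dtype=float)
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("timepoints must be non-negative and strictly increasing")


@dataclass
class MMSpec:
    """Michaelis–Menten initial rates: v = kcat*E*S/(KM+S) * (1+eps)."""

    km: float                             # uM
    kcat: float                           # 1/s
    enzyme_conc: float                    # uM
    substrate_levels: Sequence[float]     # uM
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.km, self.kcat, self.enzyme_conc) <= 0:
            raise ValueError("km, kcat and enzyme_conc must all be positive")


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

def _helix_frame(i: int, spec: ToyStructureSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """C-alpha position, outward radial unit vector and axis unit vector."""
    ang = np.radians(spec.helix_twist * i)
    radial = np.array([np.cos(ang), np.sin(ang), 0.0])
    ca = spec.helix_radius * radial + np.array([0.0, 0.0, spec.helix_rise * i])
    return ca, radial, np.array([0.0, 0.0, 1.0])


def _group_atoms(names: tuple[str, ...], centroid: np.ndarray, spread_dir: np.ndarray) -> list[np.ndarray]:
    if len(names) == 1:
        return [centroid]
    u = spread_dir / np.linalg.norm(spread_dir)
    return [centroid - _GROUP_HALF_SPACING * u, centroid + _GROUP_HALF_SPACING * u]


def _min_cross_distance(pts_a: Sequence[np.ndarray], pts_b: Sequence[np.ndarray]) -> float:
    return min(float(np.linalg.norm(a - b)) for a in pts_a for b in pts_b)


def make_toy_structure(spec: ToyStructureSpec) -> Structure:
    """Build a poly-alanine helix carrying the planted charged pairs.

    Each planted pair occupies two consecutive residues; the basic partner's
    charged group points radially outward, and the acidic partner's group is
    positioned along the inter-group line (by bisection) so the minimum N–O
    distance equals the target exactly.
    """
    n = spec.resolved_n_residues
    residues: list[Residue] = []
    serial = 0

    def add_atom(res_atoms, name, element, coords, resname, resnum):
        nonlocal serial
        serial += 1
        res_atoms.append(Atom(
            serial=serial, name=name, element=element, residue_name=resname,
            chain=spec.chain, residue_number=resnum, coords=np.asarray(coords, float),
        ))

    # residue index (0-based) -> (residue type, charged atom coords list)
    planted: dict[int, tuple[str, list[np.ndarray]]] = {}
    for k, (basic, acidic, target) in enumerate(spec.planted_pairs):
        i_basic = _PAIR_STRIDE * k + 1
        i_acid = i_basic + 1
        ca_b, radial_b, axis = _helix_frame(i_basic, spec)
        b_names, _, b_dist = CHARGED_GROUPS[basic]
        b_centroid = ca_b + b_dist * radial_b
        b_pts = _group_atoms(b_names, b_centroid, axis)

        a_names, _, _ = CHARGED_GROUPS[acidic]
        ca_a, _, _ = _helix_frame(i_acid, spec)
        # direction from the basic group out toward the acid residue
        w = ca_a + 3.0 * radial_b - b_centroid
        w = w / np.linalg.norm(w)
        spread = np.cross(w, axis)
        if np.linalg.norm(spread) < 1e-6:
            spread = np.cross(w, np.array([1.0, 0.0, 0.0]))

        def realised(t: float) -> float:
            return _min_cross_distance(b_pts, _group_atoms(a_names, b_centroid + t * w, spread))

        lo, hi = 0.0, target + 4.0
        for _ in range(80):  # bisection: realised(t) is increasing for t >= 0
            mid = 0.5 * (lo + hi)
            if realised(mid) < target:
                lo = mid
            else:
                hi = mid
        t_star = 0.5 * (lo + hi)
        a_pts = _group_atoms(a_names, b_centroid + t_star * w, spread)
        planted[i_basic] = (basic, b_pts)
        planted[i_acid] = (acidic, a_pts)

    for i in range(n):
        resnum = i + 1
        ca, radial, axis = _helix_frame(i, spec)
        resname = planted[i][0] if i in planted else "ALA"
        atoms: list[Atom] = []
        # minimal backbone: N, CA, C, O plus CB along the outward radial
        add_atom(atoms, "N", "N", ca - 0.7 * radial - np.array([0, 0, 0.8]), resname, resnum)
        add_atom(atoms, "CA", "C", ca, resname, resnum)
        add_atom(atoms, "C", "C", ca + 0.6 * radial + np.array([0, 0, 0.9]), resname, resnum)
        add_atom(atoms, "O", "O", ca + 1.2 * radial + np.array([0, 0, 1.5]), resname, resnum)
        add_atom(atoms, "CB", "C", ca + 1.53 * radial, resname, resnum)
        if i in planted:
            names, element, _ = CHARGED_GROUPS[resname]
            for name, pt in zip(names, planted[i][1]):
                add_atom(atoms, name, element, pt, resname, resnum)
        residues.append(Residue(
            chain=spec.chain, residue_number=resnum, residue_name=resname, atoms=atoms,
        ))
    return Structure(id=f"toy-{spec.seed}", residues=residues).sort()


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def jitter_ensemble(
    structure: Structure,
    sigma: float | Sequence[float],
    n_frames: int,
    seed: int = 0,
    include_reference: bool = False,
    frame_interval: float | None = None,
) -> Ensemble:
    """Gaussian-jittered frames around a reference structure.

    Each atom of frame *i* is displaced by an i.i.d. isotropic Gaussian with
    the standard deviation of its residue (``sigma`` may be a scalar or a
    per-residue vector).  With ``include_reference`` the first frame is the
    unperturbed reference.  The expected per-atom RMSF of a frame set is
    ``sigma * sqrt(3)`` (isotropic displacement in three dimensions).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n_res = len(structure.residues)
    sig = np.asarray(sigma, dtype=float)
    if sig.ndim == 0:
        sig = np.full(n_res, float(sig))
    if sig.shape != (n_res,):
        raise ValueError(f"sigma must be scalar or length {n_res}, got shape {sig.shape}")
    if np.any(sig < 0):
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    frames: list[Structure] = []
    for f in range(n_frames):
        frame = structure.copy()
        frame.id = f"{structure.id}|frame{f}"
        if not (include_reference and f == 0):
            for ridx, res in enumerate(frame.residues):
                for a in res.atoms:
                    a.coords = a.coords + rng.normal(0.0, 1.0, size=3) * sig[ridx]
        frames.append(frame)
    return Ensemble(frames=frames, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# kinetics tables
# ---------------------------------------------------------------------------

def simulate_decay(spec: DecaySpec) -> pd.DataFrame:
    """Residual-activity time series with first-order inactivation.

    Returns a DataFrame with columns ``time_min`` and ``activity``.
    Noise is multiplicative Gaussian (spectrophotometric error scales with
    the signal).
    """
    t = np.asarray(spec.timepoints, dtype=float)
    kd = np.log(2.0) / spec.half_life
    clean = spec.initial_activity * np.exp(-kd * t)
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise_sd, size=t.shape) if spec.noise_sd > 0 else 0.0
    return pd.DataFrame({"time_min": t, "activity": clean * (1.0 + eps)})


def simulate_mm(spec: MMSpec) -> pd.DataFrame:
    """Michaelis–Menten initial-rate table.

    Returns a DataFrame with columns ``substrate_uM`` and ``rate_uM_per_s``;
    v = kcat * E * S / (KM + S), with multiplicative Gaussian noise.
    """
    s = np.asarray(spec.substrate_levels, dtype=float)
    if np.any(s <= 0):
        raise ValueError("substrate levels must be positive")
    clean = spec.kcat * spec.enzyme_conc * s / (spec.km + s)
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise_sd, size=s.shape) if spec.noise_sd > 0 else 0.0
    return pd.DataFrame({"substrate_uM": s, "rate_uM_per_s": clean * (1.0 + eps)})
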