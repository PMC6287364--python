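"""Salt-bridge detection and persistence across conformational ensembles.

A salt bridge is called when a positively charged side-chain nitrogen
(Lys NZ, Arg NH1/NH2, or both ring nitrogens ND1/NE2 of a doubly
protonated histidine) lies within 4.0 A of a carboxylate oxygen
(Glu OE1/OE2, Asp OD1/OD2).  Distances are heavy-atom distances, the
cutoff is closed (<= 4.0 A), and a residue pair counts once no matter how
many of its atom pairs qualify (a bidentate Arg–Glu contact is one
bridge).  Histidine participates only when its fractional charge at the
survey pH is at least one half, which is what makes the survey pH-aware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protonation import MODEL_PKAS, TitrationModel
from .structio import Ensemble, Residue, Structure

__all__ = [
    "POSITIVE_ATOMS",
    "NEGATIVE_ATOMS",
    "BridgeCriterion",
    "SaltBridge",
    "detect_salt_bridges",
    "bridge_occupancy",
]

#: positively charged donor atoms per residue type
POSITIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}

#: negatively charged acceptor atoms per residue type
NEGATIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
}


@dataclass
class BridgeCriterion:
    """Geometric + protonation rule for calling a salt bridge."""

    cutoff: float = 4.0
    ph: float = 2.5
    his_requires_protonation: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class SaltBridge:
    """A residue-pair ionic contact, with ensemble occupancy when applicable."""

    positive: tuple[str, int, str]   # (chain, resnum, resname)
    negative: tuple[str, int, str]
    min_distance: float
    atom_pair: tuple[str, str]
    occupancy: float = 1.0
    distance_mean: float | None = None
    distance_min: float | None = None
    distance_max: float | None = None

    @property
    def pair_key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.positive[0], self.positive[1]), (self.negative[0], self.negative[1]))

    @property
    def label(self) -> str:
        p, n = self.positive, self.negative
        return f"{p[2]}{p[1]}({p[0]})–{n[2]}{n[1]}({n[0]})"


def _his_charge(residue: Residue, model: TitrationModel | None, ph: float) -> float:
    """Fractional charge of a histidine at ``ph``.

    Uses the residue's effective pKa when a titration model covers it, and
    the model histidine pKa otherwise.
    """
    pka = MODEL_PKAS["HIS"]
    if model is not None:
        for s in model.sites:
            if (
                s.site_kind == "HIS"
                and s.chain == residue.chain
                and s.residue_number == residue.residue_number
            ):
                pka = s.effective_pka if s.effective_pka is not None else s.model_pka
                break
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def _charged_partners(
    structure: Structure,
    criterion: BridgeCriterion,
    titration: TitrationModel | None,
) -> tuple[list[tuple[Residue, np.ndarray, list[str]]], list[tuple[Residue, np.ndarray, list[str]]]]:
    pos, neg = [], []
    for res in structure.residues:
        if not res.is_protein:
            continue
        if res.residue_name in POSITIVE_ATOMS:
            if (
                res.residue_name == "HIS"
                and criterion.his_requires_protonation
                and _his_charge(res, titration, criterion.ph) < 0.5
            ):
                continue
            names = [n for n in POSITIVE_ATOMS[res.residue_name] if res.atom(n)]
            if names:
                pos.append((res, res.atom_coords(names), names))
        elif res.residue_name in NEGATIVE_ATOMS:
            names = [n for n in NEGATIVE_ATOMS[res.residue_name] if res.atom(n)]
            if names:
                neg.append((res, res.atom_coords(names), names))
    return pos, neg


def _pair_min_distance(
    coords_p: np.ndarray, names_p: list[str], coords_n: np.ndarray, names_n: list[str]
) -> tuple[float, tuple[str, str]]:
    d = np.linalg.norm(coords_p[:, None, :] - coords_n[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return float(d[i, j]), (names_p[i], names_n[j])


def detect_salt_bridges(
    structure: Structure,
    criterion: BridgeCriterion | None = None,
    titration: TitrationModel | None = None,
) -> list[SaltBridge]:
    """All residue pairs satisfying the charged-atom distance criterion.

    Returns one :class:`SaltBridge` per qualifying (positive residue,
    negative residue) pair, annotated with the minimum qualifying atom-atom
    distance.  Pass a solved :class:`TitrationModel` to gate histidines on
    their *effective* pKa; without one the model histidine pKa (6.3) is
    used at ``criterion.ph``.
    """
    criterion = criterion or BridgeCriterion()
    pos, neg = _charged_partners(structure, criterion, titration)
    out: list[SaltBridge] = []
    for res_p, coords_p, names_p in pos:
        for res_n, coords_n, names_n in neg:
            dist, pair = _pair_min_distance(coords_p, names_p, coords_n, names_n)
            if dist <= criterion.cutoff:
                out.append(SaltBridge(
                    positive=(res_p.chain, res_p.residue_number, res_p.residue_name),
                    negative=(res_n.chain, res_n.residue_number, res_n.residue_name),
                    min_distance=dist,
                    atom_pair=pair,
                    occupancy=1.0,
                ))
    out.sort(key=lambda b: b.pair_key)
    return out


def bridge_occupancy(
    ensemble: Ensemble,
    criterion: BridgeCriterion | None = None,
    titration: TitrationModel | None = None,
    occupancy_threshold: float = 0.5,
) -> list[SaltBridge]:
    """Bridges persisting across ensemble frames.

    A pair's occupancy is the fraction of frames in which it satisfies the
    criterion; pairs at or above ``occupancy_threshold`` are returned with
    summary statistics of their per-frame minimum distance (over all
    frames, whether or not the frame qualified).  Set the threshold to 0
    for a union-over-frames survey.
    """
    criterion = criterion or BridgeCriterion()
    if not ensemble.frames:
        raise ValueError("empty ensemble")
    n_frames = ensemble.n_frames

    hits: dict[tuple, dict] = {}
    for frame in ensemble.frames:
        pos, neg = _charged_partners(frame, criterion, titration)
        for res_p, coords_p, names_p in pos:
            for res_n, coords_n, names_n in neg:
                dist, pair = _pair_min_distance(coords_p, names_p, coords_n, names_n)
                key = (res_p.key, res_n.key)
                rec = hits.setdefault(key, {
                    "positive": (res_p.chain, res_p.residue_number, res_p.residue_name),
                    "negative": (res_n.chain, res_n.residue_number, res_n.residue_name),
                    "distances": [], "n_hit": 0, "best": (np.inf, pair),
                })
                rec["distances"].append(dist)
                if dist <= criterion.cutoff:
                    rec["n_hit"] += 1
                    if dist < rec["best"][0]:
                        rec["best"] = (dist, pair)

    out: list[SaltBridge] = []
    for rec in hits.values():
        occ = rec["n_hit"] / n_frames
        if rec["n_hit"] > 0 and occ >= occupancy_threshold:
            d = np.array(rec["distances"])
            out.append(SaltBridge(
                positive=rec["positive"],
                negative=rec["negative"],
                min_distance=float(rec["best"][0]),
                atom_pair=rec["best"][1],
                occupancy=occ,
                distance_mean=float(d.mean()),
                distance_min=float(d.min()),
                distance_max=float(d.max()),
            ))
    out.sort(key=lambda b: b.pair_key)
    return out
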