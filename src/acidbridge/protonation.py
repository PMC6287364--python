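"""pH-dependent protonation states and the pH-dependent stability term.

A protein's net charge Q(pH) — its proton-binding isotherm — links to the
pH dependence of its unfolding free energy through the Wyman relation:
integrating the folded-minus-unfolded charge difference over pH gives the
change in unfolding free energy between two pH values.  This module
assigns per-site effective pKas with an openly documented mean-field
scheme (Henderson–Hasselbalch sites shifted by a burial/Born term and by
screened Coulomb site–site interactions) and performs that integration.

The scheme is a transparent stand-in for heavyweight continuum
electrostatics: it has the same interface and the same pH-integration
structure, and all its constants live in :class:`TitrationConfig`.
Absolute free-energy magnitudes from it are therefore indicative, not
quantitative; downstream classification uses them only through a coarse
threshold rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .structio import Structure, _NeighborCounter

__all__ = [
    "MODEL_PKAS",
    "TitratableSite",
    "TitrationConfig",
    "TitrationModel",
    "ChargeCurve",
    "find_titratable_sites",
    "effective_pkas",
    "unfolded_model",
    "protonation_state",
    "net_charge_curve",
    "ph_stability_delta",
    "one_site_stability_delta",
]

logger = logging.getLogger(__name__)

#: model (solution) pKa of each titratable site kind
MODEL_PKAS = {
    "ASP": 4.0, "GLU": 4.4, "HIS": 6.3, "LYS": 10.4,
    "ARG": 12.0, "TYR": 9.6, "CYS": 8.3, "NTERM": 7.5, "CTERM": 3.8,
}

_ACID_KINDS = frozenset({"ASP", "GLU", "TYR", "CYS", "CTERM"})

#: charged atoms per site kind (heavy atoms carrying the titratable charge)
_SITE_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2"),
    "TYR": ("OH",),
    "CYS": ("SG",),
}

_DISULFIDE_CUTOFF = 2.3  # A, SG-SG distance below which CYS is bonded, not titratable

COULOMB_KCAL = 332.0     # kcal*A/mol/e^2
R_KCAL = 1.987204259e-3  # kcal/mol/K


@dataclass
class TitratableSite:
    """One ionisable group with its model and environment-shifted pKa."""

    chain: str
    residue_number: int
    residue_name: str
    site_kind: str
    model_pka: float
    charged_atoms: tuple[str, ...]
    centroid: np.ndarray
    is_acid: bool
    effective_pka: float | None = None

    @property
    def label(self) -> str:
        return f"{self.chain}:{self.residue_name}{self.residue_number}:{self.site_kind}"


@dataclass
class TitrationConfig:
    """Constants of the mean-field titration scheme.

    ``epsilon_eff`` is the effective dielectric screening the site–site
    Coulomb term; ``born_scale`` (pKa units) is the maximum desolvation
    shift a fully buried site receives (up for acids, down for bases);
    burial is the 9-A heavy-atom neighbor count scaled linearly between
    ``n_low`` and ``n_high``.
    """

    temperature: float = 298.15   # K
    epsilon_eff: float = 20.0
    born_scale: float = 1.5       # pKa units at full burial
    n_low: int = 15
    n_high: int = 40
    burial_radius: float = 9.0    # A
    target_ph: float = 2.5        # pH at which interaction charges are evaluated
    tol: float = 0.01             # max pKa change for convergence
    max_iter: int = 50
    model_pkas: dict = field(default_factory=lambda: dict(MODEL_PKAS))

    def __post_init__(self) -> None:
        if self.epsilon_eff <= 1:
            raise ValueError("epsilon_eff must exceed 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    @classmethod
    def from_yaml(cls, path) -> "TitrationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "temperature": self.temperature, "epsilon_eff": self.epsilon_eff,
            "born_scale": self.born_scale, "n_low": self.n_low,
            "n_high": self.n_high, "burial_radius": self.burial_radius,
            "target_ph": self.target_ph, "tol": self.tol,
            "max_iter": self.max_iter, "model_pkas": self.model_pkas,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class TitrationModel:
    """Sites plus the configuration they were (or will be) solved under."""

    sites: list[TitratableSite]
    config: TitrationConfig = field(default_factory=TitrationConfig)
    converged: bool = True
    n_iterations: int = 0

    def site_pkas(self) -> np.ndarray:
        return np.array([
            s.effective_pka if s.effective_pka is not None else s.model_pka
            for s in self.sites
        ])


@dataclass
class ChargeCurve:
    """Net protein charge on a pH grid (the proton-binding isotherm)."""

    ph_grid: np.ndarray
    q: np.ndarray


def _site_charge(pka: float, ph: float, is_acid: bool) -> float:
    theta = 1.0 / (1.0 + 10.0 ** (ph - pka))
    return -(1.0 - theta) if is_acid else theta


# ---------------------------------------------------------------------------
# site discovery
# ---------------------------------------------------------------------------

def _disulfide_cys(structure: Structure) -> set[tuple[str, int, str]]:
    sg = [
        (r.key, r.atom("SG").coords)
        for r in structure.residues
        if r.is_protein and r.residue_name == "CYS" and r.atom("SG") is not None
    ]
    bonded: set[tuple[str, int, str]] = set()
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            if np.linalg.norm(sg[i][1] - sg[j][1]) < _DISULFIDE_CUTOFF:
                bonded.add(sg[i][0])
                bonded.add(sg[j][0])
    return bonded


def find_titratable_sites(
    structure: Structure, config: TitrationConfig | None = None
) -> list[TitratableSite]:
    """All ionisable groups: side chains of D/E/H/K/R/Y/free-C plus chain termini.

    Disulfide-bonded cysteines (SG–SG below 2.3 A) are excluded.  A residue
    whose charged atoms are all missing is skipped with a warning; partial
    groups (e.g. a GLU with only OE1 modelled) are kept.
    """
    config = config or TitrationConfig()
    pkas = config.model_pkas
    bonded_cys = _disulfide_cys(structure)
    sites: list[TitratableSite] = []

    def make_site(res, kind: str, atom_names: Sequence[str]) -> TitratableSite | None:
        coords = res.atom_coords(atom_names)
        if coords.shape[0] == 0:
            logger.warning("site %s at %s has no charged atoms; skipped", kind, res.label)
            return None
        if coords.shape[0] < len(atom_names):
            logger.warning("site %s at %s is missing charged atoms", kind, res.label)
        return TitratableSite(
            chain=res.chain, residue_number=res.residue_number,
            residue_name=res.residue_name, site_kind=kind,
            model_pka=pkas[kind],
            charged_atoms=tuple(n for n in atom_names if res.atom(n) is not None),
            centroid=coords.mean(axis=0),
            is_acid=kind in _ACID_KINDS,
        )

    for chain in structure.chains():
        chain_res = structure.protein_residues(chain)
        if not chain_res:
            continue
        for res in chain_res:
            kind = res.residue_name
            if kind not in _SITE_ATOMS:
                continue
            if kind == "CYS" and res.key in bonded_cys:
                continue
            site = make_site(res, kind, _SITE_ATOMS[kind])
            if site is not None:
                sites.append(site)
        nterm = make_site(chain_res[0], "NTERM", ("N",))
        if nterm is not None:
            sites.append(nterm)
        cterm_names = ("OXT", "O") if chain_res[-1].atom("OXT") else ("O",)
        cterm = make_site(chain_res[-1], "CTERM", cterm_names)
        if cterm is not None:
            sites.append(cterm)
    return sites


# ---------------------------------------------------------------------------
# effective pKas (mean-field self-consistent scheme)
# ---------------------------------------------------------------------------

def effective_pkas(
    structure: Structure,
    config: TitrationConfig | None = None,
    sites: list[TitratableSite] | None = None,
) -> TitrationModel:
    """Solve for environment-shifted pKas by mean-field self-consistency.

    Each site's effective pKa is its model pKa plus

    * a burial (Born/desolvation) shift: ``+born_scale*b`` for acids and
      ``-born_scale*b`` for bases, where the burial fraction ``b`` scales
      the 9-A heavy-atom neighbor count linearly between ``n_low`` and
      ``n_high`` (clamped to [0, 1]); and
    * a screened Coulomb shift from the other sites' fractional charges at
      the target pH, ``-sum_j q_j * 332/(eps_eff * r_ij) / (ln10 * R * T)``.

    The coupled system is iterated (synchronous updates) until the largest
    pKa change drops below ``tol``; a non-converged model is returned
    flagged rather than raised.
    """
    config = config or TitrationConfig()
    if sites is None:
        sites = find_titratable_sites(structure, config)
    sites = [replace(s) for s in sites]
    n = len(sites)
    model = np.array([s.model_pka for s in sites])
    if n == 0:
        return TitrationModel(sites=[], config=config)

    counter = _NeighborCounter(structure)
    burial = np.empty(n)
    for i, s in enumerate(sites):
        cnt = counter(s.centroid, config.burial_radius)
        burial[i] = np.clip((cnt - config.n_low) / (config.n_high - config.n_low), 0.0, 1.0)
    acid = np.array([s.is_acid for s in sites])
    born = np.where(acid, config.born_scale * burial, -config.born_scale * burial)

    centroids = np.vstack([s.centroid for s in sites])
    diff = centroids[:, None, :] - centroids[None, :, :]
    rij = np.linalg.norm(diff, axis=2)
    with np.errstate(divide="ignore"):
        inv_r = np.where(rij > 0, 1.0 / np.maximum(rij, 1e-9), 0.0)
    np.fill_diagonal(inv_r, 0.0)

    ln10_rt = math.log(10.0) * R_KCAL * config.temperature
    coupling = COULOMB_KCAL / config.epsilon_eff * inv_r / ln10_rt  # pKa units per unit charge

    pka = model + born
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        theta = 1.0 / (1.0 + 10.0 ** (config.target_ph - pka))
        q = np.where(acid, -(1.0 - theta), theta)
        new_pka = model + born - coupling @ q
        delta = float(np.max(np.abs(new_pka - pka)))
        pka = new_pka
        if delta < config.tol:
            converged = True
            break
    if not converged:
        logger.warning("effective_pkas did not converge in %d iterations", config.max_iter)
    for s, p in zip(sites, pka):
        s.effective_pka = float(p)
    return TitrationModel(sites=sites, config=config, converged=converged, n_iterations=it)


def unfolded_model(model: TitrationModel) -> TitrationModel:
    """Null unfolded-state reference: model pKas with no environmental shifts."""
    sites = [replace(s, effective_pka=s.model_pka) for s in model.sites]
    return TitrationModel(sites=sites, config=model.config)


# ---------------------------------------------------------------------------
# state, isotherm, Wyman integration
# ---------------------------------------------------------------------------

def protonation_state(model: TitrationModel, ph: float) -> list[dict]:
    """Per-site protonation fraction and fractional charge at ``ph``.

    theta = 1/(1+10^(pH-pKa)); acids carry -(1-theta), bases +theta.  A
    histidine with both ring nitrogens protonated (theta near 1 at acidic
    pH) carries +1 and is the only His form that can donate a salt bridge.
    """
    out = []
    for s in model.sites:
        pka = s.effective_pka if s.effective_pka is not None else s.model_pka
        theta = 1.0 / (1.0 + 10.0 ** (ph - pka))
        out.append({
            "site": s, "label": s.label, "theta": theta,
            "charge": -(1.0 - theta) if s.is_acid else theta,
        })
    return out


def net_charge_curve(model: TitrationModel, ph_grid: Sequence[float]) -> ChargeCurve:
    """Proton-binding isotherm Q(pH) = sum of per-site fractional charges."""
    grid = np.asarray(ph_grid, dtype=float)
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("ph_grid must be strictly increasing")
    pkas = model.site_pkas()
    acid = np.array([s.is_acid for s in model.sites])
    if pkas.size == 0:
        return ChargeCurve(ph_grid=grid, q=np.zeros_like(grid))
    theta = 1.0 / (1.0 + 10.0 ** (grid[:, None] - pkas[None, :]))
    q = np.where(acid[None, :], -(1.0 - theta), theta).sum(axis=1)
    return ChargeCurve(ph_grid=grid, q=q)


def ph_stability_delta(
    folded_model: TitrationModel,
    unfolded: TitrationModel | None = None,
    ph_from: float = 7.0,
    ph_to: float = 2.5,
    step: float = 0.01,
) -> float:
    """Change of unfolding free energy between two pH values (kcal/mol).

    Wyman linkage:  dG_unfold(ph_to) - dG_unfold(ph_from)
    = -R*T*ln10 * integral over pH of [Q_unfolded - Q_folded].

    The integral is evaluated by the composite trapezoid rule with a step
    no larger than ``step`` pH units (the isotherm difference is smooth, a
    sum of logistic terms).  Swapping the limits flips the sign exactly.
    A positive result means unfolding is harder at ``ph_to`` than at
    ``ph_from`` — the protein gains stability moving to ``ph_to``.
    """
    if unfolded is None:
        unfolded = unfolded_model(folded_model)
    if len(unfolded.sites) != len(folded_model.sites):
        raise ValueError("folded and unfolded models must share the same site list")
    if step <= 0 or step > 0.01:
        raise ValueError("step must be in (0, 0.01]")
    if ph_from == ph_to:
        return 0.0
    sign = 1.0
    lo, hi = ph_from, ph_to
    if lo > hi:
        lo, hi = hi, lo
        sign = -1.0
    n_steps = max(2, int(math.ceil((hi - lo) / step)) + 1)
    grid = np.linspace(lo, hi, n_steps)
    qf = net_charge_curve(folded_model, grid).q
    qu = net_charge_curve(unfolded, grid).q
    rt_ln10 = R_KCAL * folded_model.config.temperature * math.log(10.0)
    integral = float(np.trapezoid(qu - qf, grid))
    return sign * (-rt_ln10 * integral)


def one_site_stability_delta(
    pka_folded: float, pka_unfolded: float, ph_from: float, ph_to: float,
    is_acid: bool = True, temperature: float = 298.15,
) -> float:
    """Closed-form one-site Wyman integral (analytic reference).

    For a single site the charge difference integrates to
    log10[(1+10^(pH-pKa))] differences, identically for acids and bases
    since the forms differ by a pH-independent constant.
    """
    def anti(pka: float, ph: float) -> float:
        # integral of theta(pH) dpH = pH - log10(1 + 10^(pH - pKa)) + C
        return ph - math.log10(1.0 + 10.0 ** (ph - pka))

    # Q_u - Q_f = theta_u - theta_f for both acids and bases
    integral = (
        (anti(pka_unfolded, ph_to) - anti(pka_unfolded, ph_from))
        - (anti(pka_folded, ph_to) - anti(pka_folded, ph_from))
    )
    rt_ln10 = R_KCAL * temperature * math.log(10.0)
    return -rt_ln10 * integral
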