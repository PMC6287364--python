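"""Candidate mutant construction, pH-dependent ddG scoring and the design pipeline.

The end-to-end procedure grafts salt bridges from an acid-stable donor
scaffold onto an acceptor enzyme: survey the donor's bridges at the target
pH, map them through a sequence alignment, and at every incompatible
position build the mutation(s) that recreate the donor's charge pair.
Each candidate is scored with a pH-dependent stability change

    ddG_mut = [dG_unfold^wt - dG_unfold^mut] (target pH vs reference pH)
              - bridge_bonus * (n_new_bridges - n_lost_bridges)
              + clash_penalty * n_clashes

(negative = stabilizing) and classified with a +-0.5 kcal/mol rule.  The
titration term comes from the mean-field scheme in
:mod:`acidbridge.protonation`; its magnitudes are indicative rather than
quantitative, which is why the downstream decision is the coarse
three-way classification, not the raw number.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bridges import BridgeCriterion, SaltBridge, bridge_occupancy, detect_salt_bridges
from .homology import (
    AlignmentResult,
    BridgePositionCall,
    Superposition,
    align_sequences,
    map_bridge_positions,
    superpose_structures,
)
from .protonation import TitrationConfig, effective_pkas, ph_stability_delta
from .structio import AA3_TO_1, Atom, Ensemble, Residue, Structure
from .synth import CHARGED_GROUPS, _GROUP_HALF_SPACING

__all__ = [
    "Mutation",
    "MutantBuild",
    "DesignCandidate",
    "DesignReport",
    "CLASH_DISTANCE",
    "build_mutant",
    "mutation_clashes",
    "ddg_mutation",
    "classify_effect",
    "run_design_pipeline",
]

logger = logging.getLogger(__name__)

CLASH_DISTANCE = 2.5   # A: a new heavy atom closer than this to another residue clashes
_BACKBONE = ("N", "CA", "C", "O", "OXT", "CB")

_STANDARD_20 = frozenset(AA3_TO_1)


@dataclass
class Mutation:
    """A single point substitution, e.g. A55R."""

    chain: str
    residue_number: int
    wt: str    # 3-letter code expected at the position
    new: str   # 3-letter replacement

    def __post_init__(self) -> None:
        if self.new not in _STANDARD_20:
            raise ValueError(f"unknown replacement residue {self.new!r}")

    @property
    def notation(self) -> str:
        return f"{AA3_TO_1.get(self.wt, 'X')}{self.residue_number}{AA3_TO_1[self.new]}"


@dataclass
class MutantBuild:
    """A mutated structure plus steric bookkeeping from the build."""

    structure: Structure
    mutations: list[Mutation]
    clashes: list[tuple[str, int]] = field(default_factory=list)

    @property
    def has_clash(self) -> bool:
        return bool(self.clashes)


@dataclass
class DesignCandidate:
    """A grafted salt-bridge candidate with its score and verdict."""

    mutations: list[Mutation]
    donor_bridge: SaltBridge
    ddg_mut: float
    effect: str
    n_new_bridges: int = 0
    n_lost_bridges: int = 0
    n_clashes: int = 0

    @property
    def name(self) -> str:
        return "/".join(m.notation for m in self.mutations)


@dataclass
class DesignReport:
    """Full pipeline output: survey, mapping and ranked candidates."""

    donor_bridges: list[SaltBridge]
    calls: list[BridgePositionCall]
    candidates: list[DesignCandidate]
    alignment: AlignmentResult | None = None
    superposition: Superposition | None = None
    stage_log: list[str] = field(default_factory=list)

    @property
    def n_conserved(self) -> int:
        return sum(c.call == "conserved" for c in self.calls)

    @property
    def n_incompatible(self) -> int:
        return sum(c.call == "incompatible" for c in self.calls)

    @property
    def n_unmappable(self) -> int:
        return sum(c.call == "unmappable" for c in self.calls)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "candidate": c.name,
                "mutations": ";".join(m.notation for m in c.mutations),
                "donor_bridge": c.donor_bridge.label,
                "n_new_bridges": c.n_new_bridges,
                "n_lost_bridges": c.n_lost_bridges,
                "n_clashes": c.n_clashes,
                "ddg_mut": c.ddg_mut,
                "effect": c.effect,
            }
            for c in sorted(self.candidates, key=lambda c: c.ddg_mut)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mutant construction
# ---------------------------------------------------------------------------

def _sidechain_direction(res: Residue) -> np.ndarray:
    ca = res.atom("CA")
    if ca is None:
        raise ValueError(f"residue {res.label} has no CA atom")
    cb = res.atom("CB")
    if cb is not None:
        d = cb.coords - ca.coords
    else:
        # pseudo-CB direction from the backbone for glycine-like residues
        n, c = res.atom("N"), res.atom("C")
        if n is None or c is None:
            raise ValueError(f"residue {res.label} lacks atoms to place a side chain")
        d = (ca.coords - n.coords) + (ca.coords - c.coords)
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise ValueError(f"degenerate side-chain direction at {res.label}")
    return d / norm


def build_mutant(structure: Structure, mutations: list[Mutation]) -> MutantBuild:
    """Apply point mutations by minimal side-chain grafting.

    The residue is renamed, side-chain atoms beyond CB are dropped, and —
    for charged replacements — the new charged group is placed along the
    C-alpha -> C-beta direction at its canonical distance.  The backbone is
    untouched.  Any new heavy atom closer than 2.5 A to an atom of another
    residue raises the build's clash flag for that position.
    """
    mut_structure = structure.copy()
    clashes: list[tuple[str, int]] = []
    serial = max((a.serial for a in mut_structure.atoms()), default=0)

    for mut in mutations:
        try:
            res = mut_structure.get_residue(mut.chain, mut.residue_number)
        except KeyError as exc:
            raise ValueError(f"no residue at {mut.chain}:{mut.residue_number}") from exc
        if res.residue_name != mut.wt:
            raise ValueError(
                f"wild-type mismatch at {mut.chain}:{mut.residue_number}: "
                f"structure has {res.residue_name}, mutation expects {mut.wt}"
            )
        direction = _sidechain_direction(res)
        res.residue_name = mut.new
        res.atoms = [a for a in res.atoms if a.name in _BACKBONE]
        for a in res.atoms:
            a.residue_name = mut.new

        new_atoms: list[np.ndarray] = []
        if mut.new in CHARGED_GROUPS:
            names, element, dist = CHARGED_GROUPS[mut.new]
            ca = res.atom("CA")
            centroid = ca.coords + dist * direction
            spread = np.cross(direction, [0.0, 0.0, 1.0])
            if np.linalg.norm(spread) < 1e-6:
                spread = np.cross(direction, [1.0, 0.0, 0.0])
            spread = spread / np.linalg.norm(spread)
            positions = (
                [centroid]
                if len(names) == 1
                else [centroid - _GROUP_HALF_SPACING * spread,
                      centroid + _GROUP_HALF_SPACING * spread]
            )
            for name, pos in zip(names, positions):
                serial += 1
                res.atoms.append(Atom(
                    serial=serial, name=name, element=element,
                    residue_name=mut.new, chain=res.chain,
                    residue_number=res.residue_number,
                    insertion_code=res.insertion_code, coords=pos,
                ))
                new_atoms.append(pos)

        if new_atoms:
            others = np.vstack([
                a.coords
                for r in mut_structure.residues
                if r.key != res.key
                for a in r.atoms
                if not a.is_hydrogen
            ]) if len(mut_structure.residues) > 1 else np.empty((0, 3))
            for pos in new_atoms:
                if others.size and np.min(np.linalg.norm(others - pos, axis=1)) < CLASH_DISTANCE:
                    clashes.append((res.chain, res.residue_number))
                    break
    return MutantBuild(structure=mut_structure, mutations=list(mutations), clashes=clashes)


def mutation_clashes(structure: Structure, positions: list[tuple[str, int]]) -> int:
    """Number of listed residues with a heavy atom within 2.5 A of another residue."""
    n = 0
    for chain, resnum in positions:
        res = structure.get_residue(chain, resnum)
        others = np.vstack([
            a.coords
            for r in structure.residues
            if r.key != res.key
            for a in r.atoms
            if not a.is_hydrogen
        ]) if len(structure.residues) > 1 else np.empty((0, 3))
        if not others.size:
            continue
        side = [a.coords for a in res.atoms if a.name not in _BACKBONE and not a.is_hydrogen]
        for pos in side:
            if np.min(np.linalg.norm(others - pos, axis=1)) < CLASH_DISTANCE:
                n += 1
                break
    return n


# ---------------------------------------------------------------------------
# scoring and classification
# ---------------------------------------------------------------------------

def _differing_positions(wt: Structure, mut: Structure) -> list[tuple[str, int]]:
    wt_res = {r.key: r for r in wt.residues}
    mut_res = {r.key: r for r in mut.residues}
    if set(wt_res) != set(mut_res):
        raise ValueError("structures have different residue sets")
    diff = []
    for key, r in wt_res.items():
        if r.residue_name != mut_res[key].residue_name:
            diff.append((key[0], key[1]))
    return diff


def ddg_mutation(
    wt: Structure,
    mutant: Structure,
    target_ph: float = 2.5,
    reference_ph: float = 7.0,
    config: TitrationConfig | None = None,
    criterion: BridgeCriterion | None = None,
    bridge_bonus: float = 1.0,
    clash_penalty: float = 5.0,
) -> tuple[float, dict]:
    """pH-dependent stability change of a mutation (kcal/mol; negative = stabilizing).

    Combines (i) the difference of the wild-type and mutant Wyman pH
    integrals between the reference and target pH, (ii) a bonus per net
    salt bridge gained at the target pH, and (iii) a penalty per clashing
    mutated residue.  Returns the value plus a breakdown dict.
    """
    config = config or TitrationConfig(target_ph=target_ph)
    criterion = criterion or BridgeCriterion(ph=target_ph)
    diff_positions = _differing_positions(wt, mutant)

    if not diff_positions:
        return 0.0, {
            "titration": 0.0, "n_new_bridges": 0, "n_lost_bridges": 0, "n_clashes": 0,
        }

    model_wt = effective_pkas(wt, config)
    model_mut = effective_pkas(mutant, config)
    dg_wt = ph_stability_delta(model_wt, None, ph_from=reference_ph, ph_to=target_ph)
    dg_mut = ph_stability_delta(model_mut, None, ph_from=reference_ph, ph_to=target_ph)
    titration_term = dg_wt - dg_mut

    bridges_wt = {b.pair_key for b in detect_salt_bridges(wt, criterion, model_wt)}
    bridges_mut = {b.pair_key for b in detect_salt_bridges(mutant, criterion, model_mut)}
    n_new = len(bridges_mut - bridges_wt)
    n_lost = len(bridges_wt - bridges_mut)

    n_clash = mutation_clashes(mutant, diff_positions)

    value = titration_term - bridge_bonus * (n_new - n_lost) + clash_penalty * n_clash
    return value, {
        "titration": titration_term,
        "n_new_bridges": n_new,
        "n_lost_bridges": n_lost,
        "n_clashes": n_clash,
    }


def classify_effect(ddg_mut: float) -> str:
    """Three-way call with the +-0.5 kcal/mol rule.

    ddG below -0.5 is stabilizing, above +0.5 destabilizing, and the closed
    band [-0.5, 0.5] neutral.
    """
    if not math.isfinite(ddg_mut):
        raise ValueError("ddG must be finite")
    if ddg_mut < -0.5:
        return "stabilizing"
    if ddg_mut > 0.5:
        return "destabilizing"
    return "neutral"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_design_pipeline(
    donor: Structure,
    acceptor: Structure,
    target_ph: float = 2.5,
    reference_ph: float = 7.0,
    config: TitrationConfig | None = None,
    criterion: BridgeCriterion | None = None,
    donor_ensemble: Ensemble | None = None,
    occupancy_threshold: float = 0.5,
    bridge_bonus: float = 1.0,
    clash_penalty: float = 5.0,
) -> DesignReport:
    """Full homologous salt-bridge grafting pipeline.

    Stages: donor titration -> donor bridge survey (single structure, or
    ensemble occupancy when ``donor_ensemble`` is given) -> global sequence
    alignment and C-alpha superposition -> projection of donor bridges onto
    the acceptor -> one candidate per incompatible position pair (grafting
    the donor's residue types; single or double mutation as required) ->
    ddG scoring and classification.  Candidates failing to build (e.g.
    wild-type bookkeeping errors) are logged and skipped rather than
    aborting the report.
    """
    config = config or TitrationConfig(target_ph=target_ph)
    criterion = criterion or BridgeCriterion(ph=target_ph)
    log: list[str] = []

    donor_titration = effective_pkas(donor, config)
    log.append(f"donor titration: {len(donor_titration.sites)} sites")

    if donor_ensemble is not None:
        donor_bridges = bridge_occupancy(
            donor_ensemble, criterion, donor_titration, occupancy_threshold
        )
        log.append(f"donor survey (ensemble, occ>={occupancy_threshold}): "
                   f"{len(donor_bridges)} bridges")
    else:
        donor_bridges = detect_salt_bridges(donor, criterion, donor_titration)
        log.append(f"donor survey: {len(donor_bridges)} bridges")

    donor_chain = donor.chains()[0]
    acceptor_chain = acceptor.chains()[0]
    alignment = align_sequences(
        donor.sequence(donor_chain), acceptor.sequence(acceptor_chain)
    )
    log.append(f"alignment: identity {alignment.identity:.2f}%, "
               f"similarity {alignment.similarity:.2f}%")
    try:
        sup = superpose_structures(donor, acceptor, alignment, donor_chain, acceptor_chain)
        log.append(f"superposition: rmsd {sup.rmsd:.3f} A over {sup.n_pairs} CA pairs")
    except ValueError as exc:
        sup = None
        log.append(f"superposition failed: {exc}")

    calls = map_bridge_positions(
        donor_bridges, alignment, acceptor, donor, donor_chain, acceptor_chain
    )
    log.append(
        f"mapping: {sum(c.call == 'conserved' for c in calls)} conserved, "
        f"{sum(c.call == 'incompatible' for c in calls)} incompatible, "
        f"{sum(c.call == 'unmappable' for c in calls)} unmappable"
    )

    candidates: list[DesignCandidate] = []
    for call in calls:
        if call.call != "incompatible" or not call.mutation_targets:
            continue
        mutations = [
            Mutation(chain=chain, residue_number=resnum, wt=current, new=required)
            for chain, resnum, current, required in call.mutation_targets
        ]
        try:
            build = build_mutant(acceptor, mutations)
            value, parts = ddg_mutation(
                acceptor, build.structure,
                target_ph=target_ph, reference_ph=reference_ph,
                config=config, criterion=criterion,
                bridge_bonus=bridge_bonus, clash_penalty=clash_penalty,
            )
            candidates.append(DesignCandidate(
                mutations=mutations,
                donor_bridge=call.donor_bridge,
                ddg_mut=value,
                effect=classify_effect(value),
                n_new_bridges=parts["n_new_bridges"],
                n_lost_bridges=parts["n_lost_bridges"],
                n_clashes=parts["n_clashes"],
            ))
        except ValueError as exc:
            msg = f"candidate at {call.donor_bridge.label} failed: {exc}"
            logger.warning(msg)
            log.append(msg)
    candidates.sort(key=lambda c: c.ddg_mut)
    log.append(f"{len(candidates)} candidates scored")
    return DesignReport(
        donor_bridges=donor_bridges,
        calls=calls,
        candidates=candidates,
        alignment=alignment,
        superposition=sup,
        stage_log=log,
    )
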