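"""Sequence alignment, rigid superposition and homologous bridge mapping.

The grafting logic rests on three steps: globally align the donor and
acceptor sequences (Needleman–Wunsch with affine gaps, BLOSUM62),
rigid-body superpose the scaffolds (Kabsch least squares over aligned
C-alpha pairs), and project every donor salt bridge through the alignment
onto the acceptor.  A donor bridge whose two mapped acceptor positions
already hold an oppositely charged pair is *conserved*; one where either
side lacks a compatible charge is *incompatible* and its non-matching
side(s) become mutation targets; bridges hitting gap columns are
*unmappable*.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .bridges import NEGATIVE_ATOMS, POSITIVE_ATOMS, SaltBridge
from .structio import AA3_TO_1, Structure

__all__ = [
    "AlignmentResult",
    "Superposition",
    "BridgePositionCall",
    "align_sequences",
    "superpose",
    "superpose_structures",
    "map_bridge_positions",
    "read_fasta",
]

_POSITIVE_TYPES = frozenset(POSITIVE_ATOMS)
_NEGATIVE_TYPES = frozenset(NEGATIVE_ATOMS)
_VALID_LETTERS = frozenset(AA3_TO_1.values())


@dataclass
class AlignmentResult:
    """A global pairwise alignment with identity/similarity bookkeeping.

    Identity and similarity use the full alignment length (gap columns
    included) as denominator — the EMBOSS-needle convention — and are
    therefore convention-sensitive numbers.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float        # percent over all columns
    similarity: float      # percent of columns with positive substitution score
    position_map: list[tuple[int, int]]   # 0-based (index in a, index in b)

    def a_to_b(self) -> dict[int, int]:
        return dict(self.position_map)


@dataclass
class Superposition:
    """Least-squares rigid-body fit: x_b ~ R @ x_a + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class BridgePositionCall:
    """A donor bridge projected onto the acceptor, with its verdict."""

    donor_bridge: SaltBridge
    call: str                               # "conserved" | "incompatible" | "unmappable"
    acceptor_positive: tuple[str, int, str] | None = None
    acceptor_negative: tuple[str, int, str] | None = None
    reason: str = ""
    mutation_targets: list[tuple[str, int, str, str]] | None = None
    # each target: (chain, resnum, current resname, required donor resname)


def align_sequences(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment with affine gap penalties.

    ``gap_open``/``gap_extend`` are positive penalties; a gap of length L
    costs ``gap_open + (L-1)*gap_extend``.
    """
    for seq in (seq_a, seq_b):
        if not seq:
            raise ValueError("sequences must be non-empty")
        bad = set(seq.upper()) - _VALID_LETTERS
        if bad:
            raise ValueError(f"invalid residue letters: {sorted(bad)}")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()

    aligner = Align.PairwiseAligner()
    sub = substitution_matrices.load(matrix)
    aligner.substitution_matrix = sub
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])

    n_cols = len(aligned_a)
    n_ident = n_sim = 0
    position_map: list[tuple[int, int]] = []
    ia = ib = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            position_map.append((ia, ib))
            if ca == cb:
                n_ident += 1
            if sub[ca, cb] > 0:
                n_sim += 1
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        identity=100.0 * n_ident / n_cols,
        similarity=100.0 * n_sim / n_cols,
        position_map=position_map,
    )


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Kabsch least-squares rotation/translation mapping ``coords_a`` onto ``coords_b``.

    Requires at least three non-collinear point pairs; reflections are
    corrected so the rotation is always proper (det +1).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both have shape (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("at least 3 point pairs are required")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if np.linalg.matrix_rank(ac, tol=1e-8) < 2:
        raise ValueError("points are collinear; superposition is under-determined")
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = b.mean(axis=0) - rot @ a.mean(axis=0)
    resid = ac @ rot.T - bc
    rmsd = float(np.sqrt((resid ** 2).sum() / n))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=n)


def superpose_structures(
    structure_a: Structure,
    structure_b: Structure,
    alignment: AlignmentResult | None = None,
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> Superposition:
    """Superpose two structures over C-alpha atoms of aligned residue pairs.

    Without an explicit alignment the sequences are aligned first; pairing
    uses alignment columns where both residues are present and both have a
    C-alpha atom.
    """
    chain_a = chain_a or structure_a.chains()[0]
    chain_b = chain_b or structure_b.chains()[0]
    if alignment is None:
        alignment = align_sequences(structure_a.sequence(chain_a), structure_b.sequence(chain_b))
    res_a = structure_a.protein_residues(chain_a)
    res_b = structure_b.protein_residues(chain_b)
    pa, pb = [], []
    for ia, ib in alignment.position_map:
        ca_a = res_a[ia].atom("CA")
        ca_b = res_b[ib].atom("CA")
        if ca_a is not None and ca_b is not None:
            pa.append(ca_a.coords)
            pb.append(ca_b.coords)
    return superpose(np.vstack(pa), np.vstack(pb))


def _acceptor_residue_at(acceptor_residues, idx: int):
    return acceptor_residues[idx] if 0 <= idx < len(acceptor_residues) else None


def map_bridge_positions(
    donor_bridges: Sequence[SaltBridge],
    alignment: AlignmentResult,
    acceptor: Structure,
    donor: Structure,
    donor_chain: str | None = None,
    acceptor_chain: str | None = None,
) -> list[BridgePositionCall]:
    """Project donor salt bridges onto acceptor positions through the alignment.

    For each donor bridge the acceptor residues at the two mapped alignment
    positions are inspected: one positive-type (ARG/LYS/HIS) plus one
    negative-type (ASP/GLU) residue is a *conserved* bridge; anything else
    is *incompatible* with the deviating side(s) recorded as mutation
    targets (to the donor's residue types); a gap on either side makes the
    bridge *unmappable*.  The three calls partition the donor bridge list.
    """
    donor_chain = donor_chain or donor.chains()[0]
    acceptor_chain = acceptor_chain or acceptor.chains()[0]
    donor_res = donor.protein_residues(donor_chain)
    acceptor_res = acceptor.protein_residues(acceptor_chain)
    donor_index = {
        (r.chain, r.residue_number): i for i, r in enumerate(donor_res)
    }
    a2b = alignment.a_to_b()

    calls: list[BridgePositionCall] = []
    for bridge in donor_bridges:
        keys = (
            (bridge.positive[0], bridge.positive[1]),
            (bridge.negative[0], bridge.negative[1]),
        )
        mapped = []
        for key in keys:
            di = donor_index.get(key)
            mapped.append(a2b.get(di) if di is not None else None)
        if mapped[0] is None or mapped[1] is None:
            calls.append(BridgePositionCall(
                donor_bridge=bridge, call="unmappable",
                reason="bridge position maps to a gap or lies outside the alignment",
            ))
            continue
        acc_pos = acceptor_res[mapped[0]]
        acc_neg = acceptor_res[mapped[1]]
        pos_ok = acc_pos.residue_name in _POSITIVE_TYPES
        neg_ok = acc_neg.residue_name in _NEGATIVE_TYPES
        targets = []
        reasons = []
        if not pos_ok:
            targets.append((
                acc_pos.chain, acc_pos.residue_number,
                acc_pos.residue_name, bridge.positive[2],
            ))
            reasons.append(f"{acc_pos.label} lacks a positive charge")
        if not neg_ok:
            targets.append((
                acc_neg.chain, acc_neg.residue_number,
                acc_neg.residue_name, bridge.negative[2],
            ))
            reasons.append(f"{acc_neg.label} lacks a negative charge")
        calls.append(BridgePositionCall(
            donor_bridge=bridge,
            call="conserved" if pos_ok and neg_ok else "incompatible",
            acceptor_positive=(acc_pos.chain, acc_pos.residue_number, acc_pos.residue_name),
            acceptor_negative=(acc_neg.chain, acc_neg.residue_number, acc_neg.residue_name),
            reason="; ".join(reasons),
            mutation_targets=targets or None,
        ))
    return calls


def read_fasta(path) -> dict[str, str]:
    """Sequences from a FASTA file, keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(Path(path)), "fasta")}
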