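"""Fixed-backbone sequence design by max-product belief propagation.

The total log-odds score of a sequence on a fixed backbone decomposes into
per-residue terms (the single-residue burial/SS score) and per-pair terms
(the pair score over qualifying contacts).  Exponentiated, this is a
pairwise Markov random field over the 20-letter alphabet whose partition
function does not depend on the sequence, so the maximum a posteriori (MAP)
sequence is exactly the sequence of maximum total score.  Max-product belief
propagation finds it exactly on trees and usually well on loopy contact
graphs; a brute-force enumerator serves as the exact oracle on small
instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import (
    AA_INDEX,
    ScoringModel,
    SingleResidueModel,
    extract_pair_geometry,
    pair_score_tables,
    single_residue_score,
)
from .structure import AMINO_ACIDS, ProteinStructure, ResidueAnnotation, annotate

__all__ = [
    "MRFModel",
    "BPResult",
    "build_mrf",
    "max_product_bp",
    "brute_force_map",
    "core_mask",
    "sequence_identity",
]


@dataclass
class MRFModel:
    """Node and edge log-potential tables over a finite alphabet."""

    n_nodes: int
    node_log_potentials: np.ndarray  # (n_nodes, A)
    edges: list[tuple[int, int, np.ndarray]]  # i < j, (A, A) matrices
    alphabet: str = AMINO_ACIDS

    def __post_init__(self):
        self.node_log_potentials = np.asarray(self.node_log_potentials, dtype=float)
        if self.node_log_potentials.shape[0] != self.n_nodes:
            raise ValueError("one potential vector per node required")
        seen = set()
        for i, j, mat in self.edges:
            if not (0 <= i < j < self.n_nodes):
                raise ValueError("edges must satisfy 0 <= i < j < n_nodes")
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i}, {j})")
            seen.add((i, j))
            if not np.all(np.isfinite(mat)):
                raise ValueError("edge potentials must be finite")
        if not np.all(np.isfinite(self.node_log_potentials)):
            raise ValueError("node potentials must be finite")

    @property
    def alphabet_size(self) -> int:
        return self.node_log_potentials.shape[1]

    def log_potential(self, assignment) -> float:
        """Total log-potential of one assignment (indices or letters)."""
        if isinstance(assignment, str):
            assignment = [self.alphabet.index(c) for c in assignment]
        assignment = np.asarray(assignment, dtype=int)
        total = float(self.node_log_potentials[np.arange(self.n_nodes), assignment].sum())
        for i, j, mat in self.edges:
            total += float(mat[assignment[i], assignment[j]])
        return total


@dataclass
class BPResult:
    map_sequence: str
    converged: bool
    n_iterations: int
    max_message_delta: float
    max_marginals: np.ndarray  # (n_nodes, A), normalised to max 0 per node


def build_mrf(
    s: ProteinStructure,
    pair_m: ScoringModel,
    single_m: SingleResidueModel | None = None,
    annotations: list[ResidueAnnotation] | None = None,
) -> MRFModel:
    """MRF whose log-potential of any sequence equals its total score.

    Node i's potential vector holds the single-residue score of each type at
    position i (zero without a single-residue model); an edge exists for
    every qualifying pair, carrying the 20 x 20 pair-score matrix.  Edges
    whose matrix is identically zero (no fitted type-pair densities reach
    them) are pruned as inert.
    """
    n = len(s)
    node = np.zeros((n, 20))
    if single_m is not None:
        if annotations is None:
            annotations = annotate(s)
        for k, ann in enumerate(annotations):
            for aa, a in AA_INDEX.items():
                node[k, a] = single_residue_score(single_m, aa, ann.acc_class, ann.ss_class)
    geometry = extract_pair_geometry(s, pair_m.r_max, pair_m.min_seq_sep)
    tables = pair_score_tables(pair_m, geometry)
    edges = []
    for pg, mat in zip(geometry, tables):
        if np.any(mat):
            edges.append((pg.i, pg.j, mat))
    return MRFModel(n_nodes=n, node_log_potentials=node, edges=edges)


def max_product_bp(
    m: MRFModel,
    max_iters: int = 200,
    damping: float = 0.2,
    tol: float = 1e-8,
    seed: int = 0,
    fallback_dampings: tuple[float, ...] = (0.5, 0.4, 0.7),
) -> BPResult:
    """Synchronous damped max-product message passing in log space.

    Messages are normalised to max-entry 0 each round; the decode takes the
    per-node max-marginal argmax with ties broken toward the lowest alphabet
    index, then is refined by greedy coordinate ascent.  Non-convergence
    within ``max_iters`` is reported, not raised: the schedule is re-run at
    the fallback damping values and the best-scoring decode returned.
    """
    result = _bp_single(m, max_iters, damping, tol)
    if not result.converged and fallback_dampings:
        best = result
        best_score = m.log_potential(result.map_sequence)
        for d in fallback_dampings:
            alt = _bp_single(m, 2 * max_iters, d, tol)
            alt_score = m.log_potential(alt.map_sequence)
            if alt_score > best_score:
                best, best_score = alt, alt_score
        # BP-guided decimation (a few damping settings) for small models;
        # on large design graphs the ladder + coordinate ascent stands.
        if m.n_nodes * m.alphabet_size <= 1000:
            for dec_damping in (0.0, damping, 0.5):
                dec = _decimation_decode(m, max_iters, dec_damping, tol)
                dec_score = m.log_potential(dec)
                if dec_score > best_score:
                    best_score = dec_score
                    best = BPResult(
                        map_sequence=dec,
                        converged=result.converged,
                        n_iterations=result.n_iterations,
                        max_message_delta=result.max_message_delta,
                        max_marginals=best.max_marginals,
                    )
        # Report the primary schedule's convergence status either way.
        return BPResult(
            map_sequence=best.map_sequence,
            converged=result.converged,
            n_iterations=result.n_iterations,
            max_message_delta=result.max_message_delta,
            max_marginals=best.max_marginals,
        )
    return result


def _decimation_decode(m: MRFModel, max_iters: int, damping: float, tol: float) -> str:
    """BP-guided decimation: repeatedly fix the most decided node.

    After each (damped) message-passing run, the unfixed nodes whose
    max-marginals have the largest margin between best and second-best
    letter (the top ~10%, at least one) are clamped to their argmax by a
    large node-potential bias, and BP re-runs on the conditioned model.
    Deterministic; a standard decoding for loopy models where plain
    max-product oscillates.  The result gets a final coordinate-ascent pass.
    """
    A = m.alphabet_size
    node = m.node_log_potentials.copy()
    fixed = np.full(m.n_nodes, -1)
    CLAMP = 1e6
    while (fixed < 0).any():
        sub = MRFModel(
            n_nodes=m.n_nodes,
            node_log_potentials=node,
            edges=m.edges,
            alphabet=m.alphabet,
        )
        run = _bp_single(sub, max_iters, damping, tol)
        beliefs = run.max_marginals
        margins = np.sort(beliefs, axis=1)[:, -1] - np.sort(beliefs, axis=1)[:, -2]
        margins[fixed >= 0] = -np.inf
        n_unfixed = int((fixed < 0).sum())
        n_fix = max(1, n_unfixed // 10)
        for pick in np.argsort(-margins)[:n_fix]:
            letter = int(beliefs[pick].argmax())
            fixed[pick] = letter
            node = node.copy()
            node[pick] -= CLAMP
            node[pick, letter] += CLAMP
    fixed = _icm_refine(m, fixed)
    return "".join(m.alphabet[a] for a in fixed)


def _bp_single(m: MRFModel, max_iters: int, damping: float, tol: float) -> BPResult:
    A = m.alphabet_size
    # Directed messages m[(i -> j)] as vectors over x_j.
    neighbors: dict[int, list[tuple[int, np.ndarray]]] = {k: [] for k in range(m.n_nodes)}
    for i, j, mat in m.edges:
        neighbors[i].append((j, mat))  # message i->j uses mat[x_i, x_j]
        neighbors[j].append((i, mat.T))
    messages = {
        (i, j): np.zeros(A) for i in range(m.n_nodes) for j, _ in neighbors[i]
    }
    delta = float("inf")
    iteration = 0
    converged = False
    for iteration in range(1, max_iters + 1):
        new_messages = {}
        delta = 0.0
        for (i, j), old in messages.items():
            incoming = m.node_log_potentials[i].copy()
            for k, _ in neighbors[i]:
                if k != j:
                    incoming += messages[(k, i)]
            mat = next(mt for (k, mt) in neighbors[i] if k == j)
            msg = (incoming[:, None] + mat).max(axis=0)
            msg -= msg.max()
            msg = (1.0 - damping) * msg + damping * old
            delta = max(delta, float(np.abs(msg - old).max()))
            new_messages[(i, j)] = msg
        messages = new_messages
        if delta < tol:
            converged = True
            break
    beliefs = m.node_log_potentials.copy()
    for (i, j), msg in messages.items():
        beliefs[j] += msg
    beliefs -= beliefs.max(axis=1, keepdims=True)
    decode = beliefs.argmax(axis=1)  # argmax returns the lowest index on ties
    decode = _icm_refine(m, decode)
    return BPResult(
        map_sequence="".join(m.alphabet[a] for a in decode),
        converged=converged,
        n_iterations=iteration,
        max_message_delta=delta,
        max_marginals=beliefs,
    )


def _icm_refine(m: MRFModel, decode: np.ndarray, max_sweeps: int = 50) -> np.ndarray:
    """Greedy coordinate ascent from a decode (iterated conditional modes).

    Max-marginal argmax decoding on loopy graphs can land one coordinate off
    the best joint assignment; ICM sweeps never decrease the log-potential
    and stop at a coordinate-wise local optimum, deterministically (lowest
    index wins ties).
    """
    neighbors: dict[int, list[tuple[int, np.ndarray]]] = {k: [] for k in range(m.n_nodes)}
    for i, j, mat in m.edges:
        neighbors[i].append((j, mat))
        neighbors[j].append((i, mat.T))
    decode = decode.copy()
    for _ in range(max_sweeps):
        changed = False
        for i in range(m.n_nodes):
            local = m.node_log_potentials[i].copy()
            for j, mat in neighbors[i]:
                local += mat[:, decode[j]]
            best = int(local.argmax())
            if best != decode[i] and local[best] > local[decode[i]]:
                decode[i] = best
                changed = True
        if not changed:
            break
    return decode


def brute_force_map(m: MRFModel, alphabet_size: int | None = None) -> str:
    """Exhaustive MAP by enumerating every assignment (small models only).

    Returns the lexicographically smallest maximiser on ties.  The total
    state space is capped at 10^7 assignments.
    """
    A = m.alphabet_size if alphabet_size is None else alphabet_size
    if A**m.n_nodes > 10**7:
        raise ValueError("state space too large for brute force")
    shape = (A,) * m.n_nodes
    total = np.zeros(shape)
    for k in range(m.n_nodes):
        idx = [None] * m.n_nodes
        idx[k] = slice(None)
        total += m.node_log_potentials[k, :A][tuple(idx)]
    for i, j, mat in m.edges:  # i < j by construction
        reshaped_shape = [1] * m.n_nodes
        reshaped_shape[i] = A
        reshaped_shape[j] = A
        total += mat[:A, :A].reshape(reshaped_shape)
    # np.argmax on the flattened C-ordered array returns the first (and thus
    # lexicographically smallest) maximiser.
    flat_best = int(total.argmax())
    assignment = np.unravel_index(flat_best, shape)
    return "".join(m.alphabet[a] for a in assignment)


def core_mask(s: ProteinStructure, min_neighbors: int = 20, radius: float = 10.0) -> list[bool]:
    """True for residues with more than 20 other C-beta atoms within 10 A."""
    cb = s.cb_coordinates()
    d = np.linalg.norm(cb[:, None, :] - cb[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return [(int((row <= radius).sum()) > min_neighbors) for row in d]


def sequence_identity(a: str, b: str, mask: list[bool] | None = None) -> float:
    """Percent identical positions, optionally restricted to a mask."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if mask is not None:
        if len(mask) != len(a):
            raise ValueError("mask length must match the sequences")
        pairs = [(x, y) for x, y, keep in zip(a, b, mask) if keep]
    else:
        pairs = list(zip(a, b))
    if not pairs:
        raise ValueError("no positions to compare")
    matches = sum(1 for x, y in pairs if x == y)
    return 100.0 * matches / len(pairs)
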