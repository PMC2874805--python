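"""Gapless threading benchmark machinery.

A threading solution assigns a candidate sequence (a shuffled native, a
window of a foreign donor sequence, or the native itself) to a fixed
template backbone and scores the assignment.  The benchmark statistics are
the rank of the native solution among all candidates (strict-greater
counting, so ties are resolved optimistically) and the fractional rank --
rank divided by the number of candidates -- which is comparable across
templates with very different candidate counts.

Scoring thousands of candidates reuses per-pair 20 x 20 score tables
precomputed once per template, so each candidate costs one table-lookup sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .scoring import (
    AA_INDEX,
    DepthModel,
    PairGeometry,
    ScoringModel,
    SingleResidueModel,
    depth_score,
    extract_pair_geometry,
    pair_score_tables,
    single_residue_score,
)
from .structure import ProteinStructure, ResidueAnnotation, annotate

logger = logging.getLogger(__name__)

__all__ = [
    "ThreadingCandidate",
    "RankResult",
    "TemplateScorer",
    "shuffle_decoys",
    "gapless_offsets",
    "rank_native",
    "homolog_average",
    "grouped_kfold",
    "roc_auc",
]


@dataclass
class ThreadingCandidate:
    sequence: str
    source: str  # native | shuffle | cross | homolog-average
    offset: int = 0
    score: float = float("nan")


@dataclass(frozen=True)
class RankResult:
    native_rank: int
    n_candidates: int

    @property
    def fractional_rank(self) -> float:
        return self.native_rank / self.n_candidates


class TemplateScorer:
    """Fixed-backbone scorer for many candidate sequences of one template.

    Precomputes the qualifying-pair geometry, the per-pair type-pair score
    tables and (optionally) per-position single-residue and depth score
    vectors.  Candidate sequences then score as pure table lookups; the
    template's burial/SS annotations are kept fixed while the donor supplies
    the types, per the fixed-backbone premise.
    """

    def __init__(
        self,
        template: ProteinStructure,
        pair_m: ScoringModel,
        single_m: SingleResidueModel | None = None,
        depth_m: DepthModel | None = None,
        depth_z: list[float] | None = None,
        annotations: list[ResidueAnnotation] | None = None,
        geometry: list[PairGeometry] | None = None,
    ):
        self.template = template
        if geometry is None:
            geometry = extract_pair_geometry(template, pair_m.r_max, pair_m.min_seq_sep)
        self.geometry = geometry
        self.tables = pair_score_tables(pair_m, geometry)
        self.pair_i = np.array([pg.i for pg in geometry], dtype=int)
        self.pair_j = np.array([pg.j for pg in geometry], dtype=int)
        n = len(template)
        self.position_scores = np.zeros((n, 20))
        if single_m is not None:
            if annotations is None:
                annotations = annotate(template)
            for k, ann in enumerate(annotations):
                for aa, a in AA_INDEX.items():
                    self.position_scores[k, a] += single_residue_score(
                        single_m, aa, ann.acc_class, ann.ss_class
                    )
        if depth_m is not None:
            if depth_z is None:
                raise ValueError("depth_z required with a depth model")
            for k, z in enumerate(depth_z):
                for aa, a in AA_INDEX.items():
                    self.position_scores[k, a] += depth_score(depth_m, aa, z)

    def encode(self, sequences: list[str]) -> np.ndarray:
        n = len(self.template)
        enc = np.empty((len(sequences), n), dtype=np.int8)
        for row, seq in enumerate(sequences):
            if len(seq) != n:
                raise ValueError("candidate length does not match template")
            enc[row] = [AA_INDEX[aa] for aa in seq]
        return enc

    def score_encoded(self, enc: np.ndarray) -> np.ndarray:
        scores = np.zeros(len(enc))
        if len(self.pair_i):
            ti = enc[:, self.pair_i]  # (n_cand, P)
            tj = enc[:, self.pair_j]
            p_idx = np.arange(len(self.pair_i))
            scores += self.tables[p_idx[None, :], ti, tj].sum(axis=1)
        positions = np.arange(enc.shape[1])
        scores += self.position_scores[positions[None, :], enc.astype(int)].sum(axis=1)
        return scores

    def score(self, sequences: list[str]) -> np.ndarray:
        """Total scores of candidate sequences on this template."""
        return self.score_encoded(self.encode(sequences))


def shuffle_decoys(seq: str, n: int, seed: int) -> list[str]:
    """n uniform random permutations of ``seq``, none equal to the native.

    Decoys may collide with each other (sampling with replacement over
    permutation space); only the exact native string is rejected, and the
    number of mutual collisions is logged.
    """
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    if len(seq) < 2:
        raise ValueError("sequence too short to shuffle")
    rng = np.random.default_rng(seed)
    letters = np.array(list(seq))
    decoys: list[str] = []
    while len(decoys) < n:
        cand = "".join(rng.permutation(letters))
        if cand != seq:
            decoys.append(cand)
    n_collisions = n - len(set(decoys))
    if n_collisions:
        logger.info("shuffle_decoys: %d duplicate decoys among %d", n_collisions, n)
    return decoys


def gapless_offsets(template_len: int, donor_len: int) -> list[int]:
    """All start offsets of a gapless alignment of the template onto a donor."""
    if donor_len < template_len:
        raise ValueError("donor sequence shorter than the template structure")
    return list(range(donor_len - template_len + 1))


def rank_native(scored: list[tuple[str, float]], native_id: str) -> RankResult:
    """Optimistic rank of the native candidate: 1 + #(strictly better)."""
    native_scores = [s for cid, s in scored if cid == native_id]
    if len(native_scores) != 1:
        raise ValueError("native candidate must appear exactly once")
    native = native_scores[0]
    better = sum(1 for _, s in scored if s > native)
    return RankResult(native_rank=1 + better, n_candidates=len(scored))


def homolog_average(
    scorer: TemplateScorer,
    native_window: str,
    homolog_windows: list[str],
) -> float:
    """Mean template score over the native window and its homolog windows.

    Each homolog solution replaces the threaded segment with the aligned
    (gapless, equal-length) segment of a homologous sequence; averaging the
    scores pools evidence across structurally equivalent sequences.
    """
    windows = [native_window] + list(homolog_windows)
    n = len(scorer.template)
    if any(len(w) != n for w in windows):
        raise ValueError("all windows must match the template length")
    return float(scorer.score(windows).mean())


def grouped_kfold(protein_ids: list[str], k: int = 10, seed: int = 0) -> list[list[str]]:
    """Partition protein ids into k folds balanced to within one protein.

    All data for a protein lands in exactly one fold, so cross-validated
    models are never evaluated on structures they trained on.
    """
    if len(protein_ids) < k:
        raise ValueError("fewer proteins than folds")
    if len(set(protein_ids)) != len(protein_ids):
        raise ValueError("protein ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(protein_ids))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(protein_ids[idx])
    return folds


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney identity, half credit on ties)."""
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("need both positive and negative examples")
    y = [1 if lab == "pos" else 0 for lab in labels]
    return float(roc_auc_score(y, list(scores)))
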