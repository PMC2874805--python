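"""Evaluation protocols: cross-validated per-type-pair AUC and rank tables.

The discriminative quality of each residue-type pair's score is measured by
the area under the ROC curve separating native observations (geometry typed
by the native sequence) from non-native ones (the same geometric
observations re-typed by a shuffled sequence), pooled over grouped
cross-validation folds so no model is scored on the structures it trained
on.  Rank tables summarise threading experiments by counts at rank or
fractional-rank thresholds plus the median fractional rank, and the
correlation between a type pair's AUC and the amount of its training data
is measured by Spearman's rho.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .scoring import (
    ScoringModel,
    canonical_omega,
    canonical_pair,
    extract_pair_geometry,
    fit_scoring_model,
    pair_score,
    PairObservation,
)
from .structure import ProteinStructure
from .threading import RankResult, grouped_kfold, roc_auc, shuffle_decoys

__all__ = ["EvalReport", "per_pair_auc_cv", "rank_table", "spearman_auc_vs_n"]


@dataclass
class EvalReport:
    """Per-type-pair AUC table: one row per pair with training count and AUC."""

    auc_table: pd.DataFrame  # columns: pair, n_train, auc (NaN where undefined)
    dim: int
    n_folds: int

    def defined(self) -> pd.DataFrame:
        return self.auc_table.dropna(subset=["auc"])


def _observations_with_sequence(s, geometry, seq):
    obs = []
    for pg in geometry:
        t1, t2, omega = canonical_omega(pg, seq[pg.i], seq[pg.j])
        obs.append(PairObservation(t1=t1, t2=t2, omega=omega, protein_id=s.id, i=pg.i, j=pg.j))
    return obs


def per_pair_auc_cv(
    structures: list[ProteinStructure],
    dim: int,
    k: int = 10,
    seed: int = 0,
    max_components: int = 100,
    min_count: int | None = None,
) -> EvalReport:
    """Cross-validated AUC of every type pair's score.

    For each fold, a model is trained on the other folds; positives are the
    native-typed observations of the held-out structures and negatives the
    same geometric observations typed by one shuffled sequence per
    structure.  Scores are pooled over folds before computing each type
    pair's AUC; pairs lacking either class are reported as NaN.
    """
    ids = [s.id for s in structures]
    by_id = {s.id: s for s in structures}
    folds = grouped_kfold(ids, k=k, seed=seed)
    rows: dict[tuple[str, str], dict[str, list[float]]] = {}
    n_train_total: dict[tuple[str, str], int] = {}
    for fold_idx, fold in enumerate(folds):
        train_structs = [by_id[i] for i in ids if i not in fold]
        test_structs = [by_id[i] for i in fold]
        from .scoring import train as train_model

        model = train_model(
            train_structs, dim=dim, seed=seed + fold_idx,
            max_components=max_components, min_count=min_count,
        )
        for s in test_structs:
            geometry = extract_pair_geometry(s, model.r_max, model.min_seq_sep)
            native_seq = s.sequence
            sid_hash = zlib.crc32(s.id.encode()) % 10007
            decoy_seq = shuffle_decoys(
                native_seq, 1, seed=(seed * 100003 + fold_idx * 1009 + sid_hash) % (2**31 - 1)
            )[0]
            for label, seq in (("pos", native_seq), ("neg", decoy_seq)):
                for obs in _observations_with_sequence(s, geometry, seq):
                    key = canonical_pair(obs.t1, obs.t2)
                    entry = rows.setdefault(key, {"pos": [], "neg": []})
                    entry[label].append(pair_score(model, obs.t1, obs.t2, obs.omega))
        # Training-count bookkeeping (pooled over folds).
        for s in train_structs:
            for obs in _observations_with_sequence(
                s, extract_pair_geometry(s, model.r_max, model.min_seq_sep), s.sequence
            ):
                key = canonical_pair(obs.t1, obs.t2)
                n_train_total[key] = n_train_total.get(key, 0) + 1
    records = []
    for key in sorted(set(rows) | set(n_train_total)):
        entry = rows.get(key, {"pos": [], "neg": []})
        if entry["pos"] and entry["neg"]:
            auc = roc_auc(
                entry["pos"] + entry["neg"],
                ["pos"] * len(entry["pos"]) + ["neg"] * len(entry["neg"]),
            )
        else:
            auc = np.nan
        records.append(
            {
                "pair": "".join(key),
                "n_train": n_train_total.get(key, 0) / max(1, len(folds)),
                "auc": auc,
            }
        )
    return EvalReport(auc_table=pd.DataFrame(records), dim=dim, n_folds=k)


def rank_table(
    results: list[RankResult],
    rank_thresholds: list[int] = (1, 50, 100),
    fractional_thresholds: list[float] = (0.001, 0.01, 0.1),
) -> dict:
    """Counts (and percentages) of templates at or under rank thresholds,
    plus the median fractional rank."""
    if not results:
        raise ValueError("no rank results to summarise")
    n = len(results)
    ranks = np.array([r.native_rank for r in results])
    fracs = np.array([r.fractional_rank for r in results])
    out = {
        "n": n,
        "median_fractional_rank": float(np.median(fracs)),
        "rank_counts": {},
        "fractional_counts": {},
    }
    for t in rank_thresholds:
        c = int((ranks <= t).sum())
        out["rank_counts"][t] = (c, 100.0 * c / n)
    for t in fractional_thresholds:
        c = int((fracs <= t).sum())
        out["fractional_counts"][t] = (c, 100.0 * c / n)
    return out


def spearman_auc_vs_n(report: EvalReport) -> tuple[float, float]:
    """Spearman rank correlation between per-pair AUC and training count."""
    table = report.defined()
    if len(table) < 5:
        raise ValueError("need at least 5 type pairs with a defined AUC")
    rho, p = spearmanr(table["n_train"], table["auc"])
    return float(rho), float(p)
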