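"""Log-odds scoring functions over backbone geometry.

The pair score of residues i and j is the log ratio between the probability
of their six relative coordinates under the native distribution for that
residue-type pair and under a single type-independent background
distribution (the distribution of all residue pairs regardless of type,
equivalent to shuffled sequences on native backbones).  Only pairs at least
``min_seq_sep`` = 6 residues apart in sequence and with C-beta separation at
most ``r_max`` = 10 Angstrom enter the score: closer pairs are dictated by
local secondary structure, farther ones barely interact.

A 1D model scores the C-beta distance alone (KDE fits), a 3D model the
relative position (r, theta, phi), and a 6D model position plus orientation
(GMM fits).  The total score of a sequence on a backbone is the sum of pair
scores plus optional single-residue (burial x secondary structure) and
membrane-depth log-odds terms, in the spirit of a Naive Bayes classifier;
classification against a prior odds ratio R_prior thresholds the total at
-log(R_prior).

Type pairs are unordered (210 of them) but the 3D/6D coordinates depend on
which residue anchors frame 1.  The canonical orientation anchors the
alphabetically earlier type (the lower residue index for equal types); the
same canonicalisation is applied in training and in evaluation, which makes
pair_score(t1, t2, .) exactly symmetric.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .density import (
    DENSITY_FLOOR,
    PERIODIC_DIMS,
    Density1D,
    GMMDensity,
    InsufficientDataError,
    augment_periodic,
    density_from_dict,
    density_to_dict,
    fit_gmm,
    fit_kde_1d,
)
from .geometry import (
    RelativeCoordinates,
    invert_relative_coordinates,
    relative_coordinates,
    residue_frame,
)
from .structure import AMINO_ACIDS, ProteinStructure, ResidueAnnotation, annotate

__all__ = [
    "PairGeometry",
    "PairObservation",
    "ScoringModel",
    "SingleResidueModel",
    "DepthModel",
    "extract_pair_geometry",
    "extract_pairs",
    "train",
    "fit_scoring_model",
    "pair_score",
    "pair_score_tables",
    "single_residue_score",
    "train_single_residue",
    "train_depth",
    "depth_score",
    "total_score",
    "map_classify",
    "save_model",
    "load_model",
]

AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
ACC_INDEX = {"buried": 0, "surface": 1}
SS_INDEX = {"H": 0, "E": 1, "C": 2}

R_MAX_DEFAULT = 10.0
MIN_SEQ_SEP_DEFAULT = 6


@dataclass(frozen=True)
class PairGeometry:
    """Geometry of one qualifying residue pair, in both frame orders.

    ``forward`` anchors residue i (i < j), ``reverse`` anchors residue j.
    Which one a score uses depends on the residue types being scored.
    """

    i: int
    j: int
    forward: RelativeCoordinates
    reverse: RelativeCoordinates


@dataclass(frozen=True)
class PairObservation:
    """One training observation: a canonically oriented typed pair."""

    t1: str
    t2: str
    omega: RelativeCoordinates
    protein_id: str
    i: int
    j: int


def canonical_pair(t1: str, t2: str) -> tuple[str, str]:
    """Unordered type pair in canonical (alphabetical) order."""
    return (t1, t2) if t1 <= t2 else (t2, t1)


def extract_pair_geometry(
    s: ProteinStructure,
    r_max: float = R_MAX_DEFAULT,
    min_seq_sep: int = MIN_SEQ_SEP_DEFAULT,
    include_interchain: bool = False,
) -> list[PairGeometry]:
    """All qualifying pairs of a structure with both frame orientations."""
    frames = [residue_frame(res) for res in s.residues]
    cb = s.cb_coordinates()
    out: list[PairGeometry] = []
    n = len(s)
    for i in range(n):
        ri = s.residues[i]
        for j in range(i + 1, n):
            rj = s.residues[j]
            if ri.chain_id == rj.chain_id:
                if rj.residue_index - ri.residue_index < min_seq_sep:
                    continue
            elif not include_interchain:
                continue
            if np.linalg.norm(cb[j] - cb[i]) > r_max:
                continue
            out.append(
                PairGeometry(
                    i=i,
                    j=j,
                    forward=relative_coordinates(frames[i], frames[j]),
                    reverse=relative_coordinates(frames[j], frames[i]),
                )
            )
    return out


def canonical_omega(pg: PairGeometry, ti: str, tj: str) -> tuple[str, str, RelativeCoordinates]:
    """Canonically oriented (t1, t2, omega) for pair geometry plus types."""
    if tj < ti:
        return tj, ti, pg.reverse
    return ti, tj, pg.forward


def extract_pairs(
    s: ProteinStructure,
    sequence: str | None = None,
    r_max: float = R_MAX_DEFAULT,
    min_seq_sep: int = MIN_SEQ_SEP_DEFAULT,
    include_interchain: bool = False,
) -> list[PairObservation]:
    """Typed, canonically oriented observations of all qualifying pairs."""
    seq = s.sequence if sequence is None else sequence
    if len(seq) != len(s):
        raise ValueError("sequence length does not match structure")
    obs = []
    for pg in extract_pair_geometry(s, r_max, min_seq_sep, include_interchain):
        t1, t2, omega = canonical_omega(pg, seq[pg.i], seq[pg.j])
        obs.append(
            PairObservation(t1=t1, t2=t2, omega=omega, protein_id=s.id, i=pg.i, j=pg.j)
        )
    return obs


@dataclass
class ScoringModel:
    """Per-type-pair native densities plus the shared background density."""

    dim: int
    native_densities: dict[tuple[str, str], Density1D | GMMDensity]
    background_density: Density1D | GMMDensity
    r_max: float = R_MAX_DEFAULT
    min_seq_sep: int = MIN_SEQ_SEP_DEFAULT
    density_floor: float = DENSITY_FLOOR

    def __post_init__(self):
        if self.dim not in (1, 3, 6):
            raise ValueError("dim must be 1, 3 or 6")


def _project(omegas: list[RelativeCoordinates], dim: int) -> np.ndarray:
    return np.array([o.as_vector(dim) for o in omegas])


def fit_scoring_model(
    observations: list[PairObservation],
    dim: int,
    seed: int = 0,
    max_components: int = 100,
    min_count: int | None = None,
    background_omegas: list[RelativeCoordinates] | None = None,
    r_max: float = R_MAX_DEFAULT,
    min_seq_sep: int = MIN_SEQ_SEP_DEFAULT,
    max_background_samples: int = 20000,
) -> ScoringModel:
    """Fit native per-type-pair densities and the pooled background.

    A native density is fit only for type pairs with at least
    ``min_count`` = max(50, 10 dim) observations; sparser pairs are marked
    absent and contribute a score of exactly 0.  The background pools the
    relative coordinates of every observation (and, for 3D/6D, both frame
    orientations when supplied) regardless of type; beyond
    ``max_background_samples`` it is fit to a seeded subsample, since a
    smooth pooled density gains nothing from more points.
    """
    if not observations:
        raise InsufficientDataError("no pair observations to fit")
    if min_count is None:
        min_count = max(50, 10 * dim)
    periodic = PERIODIC_DIMS[dim]

    def _fit(X: np.ndarray, fit_seed: int):
        if dim == 1:
            return fit_kde_1d(X.ravel(), grid_max=r_max + 2.0)
        Xa = augment_periodic(X, periodic) if periodic else X
        return fit_gmm(Xa, max_components=max_components, seed=fit_seed)

    bg_omegas = background_omegas if background_omegas is not None else [
        o.omega for o in observations
    ]
    bg_X = _project(bg_omegas, dim)
    if len(bg_X) > max_background_samples:
        keep = np.random.default_rng(seed).choice(
            len(bg_X), size=max_background_samples, replace=False
        )
        bg_X = bg_X[np.sort(keep)]
    background = _fit(bg_X, seed)

    by_pair: dict[tuple[str, str], list[RelativeCoordinates]] = {}
    for obs in observations:
        by_pair.setdefault(canonical_pair(obs.t1, obs.t2), []).append(obs.omega)
    native: dict[tuple[str, str], Density1D | GMMDensity] = {}
    for idx, key in enumerate(sorted(by_pair)):
        omegas = by_pair[key]
        if len(omegas) < min_count:
            continue  # absent: scores 0 for this type pair
        # Offset the seed per pair so fits are independent yet reproducible.
        pair_seed = (seed + 9973 * (1 + idx)) % (2**31 - 1)
        try:
            native[key] = _fit(_project(omegas, dim), pair_seed)
        except InsufficientDataError:
            continue
    return ScoringModel(
        dim=dim,
        native_densities=native,
        background_density=background,
        r_max=r_max,
        min_seq_sep=min_seq_sep,
    )


def train(
    structures: list[ProteinStructure],
    dim: int,
    seed: int = 0,
    max_components: int = 100,
    min_count: int | None = None,
    r_max: float = R_MAX_DEFAULT,
    min_seq_sep: int = MIN_SEQ_SEP_DEFAULT,
) -> ScoringModel:
    """Train a scoring model from native structures (native sequences).

    The background is fit to both frame orientations of every qualifying
    pair: with types stripped, neither residue is a preferred anchor.
    """
    if not structures:
        raise InsufficientDataError("no structures to train on")
    observations: list[PairObservation] = []
    background_omegas: list[RelativeCoordinates] = []
    for s in structures:
        geom = extract_pair_geometry(s, r_max, min_seq_sep)
        seq = s.sequence
        for pg in geom:
            t1, t2, omega = canonical_omega(pg, seq[pg.i], seq[pg.j])
            observations.append(
                PairObservation(t1=t1, t2=t2, omega=omega, protein_id=s.id, i=pg.i, j=pg.j)
            )
            background_omegas.append(pg.forward)
            background_omegas.append(pg.reverse)
    if not observations:
        raise InsufficientDataError("structures contain no qualifying pairs")
    return fit_scoring_model(
        observations,
        dim=dim,
        seed=seed,
        max_components=max_components,
        min_count=min_count,
        background_omegas=background_omegas,
        r_max=r_max,
        min_seq_sep=min_seq_sep,
    )


def _floored_logpdf(d, X: np.ndarray, floor: float) -> np.ndarray:
    if isinstance(d, Density1D):
        lp = d.logpdf(X.ravel())
    else:
        lp = d.logpdf(X)
    return np.maximum(lp, math.log(floor))


def pair_score(
    m: ScoringModel,
    t1: str,
    t2: str,
    omega: RelativeCoordinates,
) -> float:
    """Log-odds pair score, 0 for type pairs without a fitted density.

    ``omega`` is oriented with ``t1`` anchoring frame 1; when the types are
    not in canonical (alphabetical) order the orientation is inverted first,
    which makes the score exactly symmetric:
    score(t1, t2, omega(1->2)) == score(t2, t1, omega(2->1)).
    """
    if omega.r > m.r_max:
        raise ValueError(f"pair at r = {omega.r:.2f} exceeds r_max = {m.r_max}")
    key = canonical_pair(t1, t2)
    d = m.native_densities.get(key)
    if d is None:
        return 0.0
    if t2 < t1:
        omega = invert_relative_coordinates(omega)
    X = omega.as_vector(m.dim)[None, :]
    ln = _floored_logpdf(d, X, m.density_floor)
    lb = _floored_logpdf(m.background_density, X, m.density_floor)
    return float(ln[0] - lb[0])


def pair_score_tables(
    m: ScoringModel,
    geometry: list[PairGeometry],
) -> np.ndarray:
    """Per-pair 20 x 20 score tables for a fixed backbone.

    ``tables[p, a, b]`` is the score of pair ``p`` when residue i has type
    ``AMINO_ACIDS[a]`` and residue j type ``AMINO_ACIDS[b]``.  Evaluating
    every fitted density once over all pairs makes threading thousands of
    candidate sequences a pure table-lookup sum.
    """
    P = len(geometry)
    tables = np.zeros((P, 20, 20))
    if P == 0:
        return tables
    fwd = _project([pg.forward for pg in geometry], m.dim)
    rev = _project([pg.reverse for pg in geometry], m.dim)
    log_floor = math.log(m.density_floor)
    bg_f = _floored_logpdf(m.background_density, fwd, m.density_floor)
    bg_r = _floored_logpdf(m.background_density, rev, m.density_floor)
    for (a, b), d in m.native_densities.items():
        ia, ib = AA_INDEX[a], AA_INDEX[b]
        nat_f = _floored_logpdf(d, fwd, m.density_floor)
        tables[:, ia, ib] = nat_f - bg_f
        if a != b:
            nat_r = _floored_logpdf(d, rev, m.density_floor)
            tables[:, ib, ia] = nat_r - bg_r
    return tables


@dataclass
class SingleResidueModel:
    """Per-type log-odds of (burial class, secondary structure class).

    ``log_odds[t, acc, ss]`` = log P(acc, ss | type t, native) -
    log P(acc, ss | non-native), where the non-native distribution is the
    type-independent property distribution a shuffled sequence induces.
    """

    log_odds: np.ndarray  # (20, 2, 3)

    def __post_init__(self):
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.shape != (20, 2, 3):
            raise ValueError("log_odds must have shape (20, 2, 3)")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log_odds entries must be finite")

    @classmethod
    def from_counts(
        cls,
        native_counts: np.ndarray,
        background_counts: np.ndarray,
        pseudocount: float = 0.0,
    ) -> "SingleResidueModel":
        """Build from (acc, ss) count tables.

        ``native_counts`` may be (2, 3) -- a type-agnostic table applied to
        all 20 types -- or (20, 2, 3); ``background_counts`` is (2, 3).
        """
        native_counts = np.asarray(native_counts, dtype=float) + pseudocount
        background_counts = np.asarray(background_counts, dtype=float) + pseudocount
        if native_counts.shape == (2, 3):
            native_counts = np.broadcast_to(native_counts, (20, 2, 3)).copy()
        if native_counts.shape != (20, 2, 3) or background_counts.shape != (2, 3):
            raise ValueError("count tables must be (20|none, 2, 3) and (2, 3)")
        p_native = native_counts / native_counts.sum(axis=(1, 2), keepdims=True)
        p_bg = background_counts / background_counts.sum()
        return cls(log_odds=np.log(p_native) - np.log(p_bg)[None, :, :])


def train_single_residue(
    structures: list[ProteinStructure],
    annotations: list[list[ResidueAnnotation]] | None = None,
    pseudocount: float = 1.0,
) -> SingleResidueModel:
    """Estimate the single-residue log-odds table from native structures.

    The native table counts (type, burial, SS) occurrences; the non-native
    table is the pooled (burial, SS) distribution regardless of type, which
    is exactly what shuffling sequences on the same backbones converges to.
    Laplace smoothing keeps sparse cells finite.
    """
    if annotations is None:
        annotations = [annotate(s) for s in structures]
    native = np.zeros((20, 2, 3))
    for s, anns in zip(structures, annotations):
        for res, ann in zip(s.residues, anns):
            native[AA_INDEX[res.aa_type], ACC_INDEX[ann.acc_class], SS_INDEX[ann.ss_class]] += 1
    background = native.sum(axis=0)
    return SingleResidueModel.from_counts(native, background, pseudocount=pseudocount)


def single_residue_score(m: SingleResidueModel, aa: str, acc: str, ss: str) -> float:
    return float(m.log_odds[AA_INDEX[aa], ACC_INDEX[acc], SS_INDEX[ss]])


@dataclass
class DepthModel:
    """Membrane depth propensities: per-type and background densities of |z|."""

    per_aa_density: dict[str, Density1D]
    background_density: Density1D


def train_depth(
    samples: list[tuple[str, float]],
    bandwidth: float | None = None,
) -> DepthModel:
    """Fit per-type and background KDEs of membrane depth magnitude |z|.

    Both densities are symmetric in z by construction: they are fit to and
    stored over |z| only.
    """
    by_aa: dict[str, list[float]] = {}
    all_z: list[float] = []
    for aa, z in samples:
        if aa not in AA_INDEX:
            raise ValueError(f"unknown amino acid {aa!r}")
        by_aa.setdefault(aa, []).append(abs(z))
        all_z.append(abs(z))
    if len(all_z) < 2:
        raise InsufficientDataError("need at least 2 depth samples")
    grid_max = max(all_z) + 5.0
    background = fit_kde_1d(all_z, bandwidth=bandwidth, grid_max=grid_max)
    per_aa = {
        aa: fit_kde_1d(zs, bandwidth=bandwidth, grid_max=grid_max)
        for aa, zs in by_aa.items()
        if len(zs) >= 2
    }
    return DepthModel(per_aa_density=per_aa, background_density=background)


def depth_score(m: DepthModel, aa: str, z: float) -> float:
    """log P(|z| | aa) - log P(|z|); even in z by construction."""
    if aa not in AA_INDEX:
        raise ValueError(f"unknown amino acid {aa!r}")
    d = m.per_aa_density.get(aa)
    if d is None:
        return 0.0
    az = abs(z)
    return float(d.logpdf(az)[0] - m.background_density.logpdf(az)[0])


def total_score(
    s: ProteinStructure,
    seq: str,
    pair_m: ScoringModel,
    single_m: SingleResidueModel | None = None,
    depth_m: DepthModel | None = None,
    depth_z: list[float] | None = None,
    annotations: list[ResidueAnnotation] | None = None,
    geometry: list[PairGeometry] | None = None,
) -> float:
    """Total log-odds score of a sequence threaded onto a fixed backbone.

    Sum of pair scores over qualifying pairs, plus single-residue and depth
    terms when their models are supplied.  ``geometry`` and ``annotations``
    may be precomputed once per template and reused across sequences.
    """
    if len(seq) != len(s):
        raise ValueError("sequence length does not match structure")
    if geometry is None:
        geometry = extract_pair_geometry(s, pair_m.r_max, pair_m.min_seq_sep)
    total = 0.0
    for pg in geometry:
        t1, t2, omega = canonical_omega(pg, seq[pg.i], seq[pg.j])
        total += pair_score(pair_m, t1, t2, omega)
    if single_m is not None:
        if annotations is None:
            annotations = annotate(s)
        for k, aa in enumerate(seq):
            total += single_residue_score(single_m, aa, annotations[k].acc_class, annotations[k].ss_class)
    if depth_m is not None:
        if depth_z is None:
            raise ValueError("depth_z required when a depth model is supplied")
        for aa, z in zip(seq, depth_z):
            total += depth_score(depth_m, aa, z)
    return total


def map_classify(total: float, r_prior: float = 1.0) -> str:
    """MAP decision: 'native' iff total > -log(R_prior); ties go non-native."""
    if r_prior <= 0:
        raise ValueError("r_prior must be positive")
    return "native" if total > -math.log(r_prior) else "non_native"


# ---------------------------------------------------------------------------
# Serialization

MODEL_SCHEMA = "bbscore-model-1"


def model_to_dict(m: ScoringModel) -> dict:
    return {
        "schema": MODEL_SCHEMA,
        "dim": m.dim,
        "r_max": m.r_max,
        "min_seq_sep": m.min_seq_sep,
        "density_floor": m.density_floor,
        "background": density_to_dict(m.background_density),
        "native": {f"{a}{b}": density_to_dict(d) for (a, b), d in m.native_densities.items()},
    }


def model_from_dict(payload: dict) -> ScoringModel:
    if payload.get("schema") != MODEL_SCHEMA:
        raise ValueError(f"unknown model schema {payload.get('schema')!r}")
    return ScoringModel(
        dim=payload["dim"],
        native_densities={
            (key[0], key[1]): density_from_dict(d) for key, d in payload["native"].items()
        },
        background_density=density_from_dict(payload["background"]),
        r_max=payload["r_max"],
        min_seq_sep=payload["min_seq_sep"],
        density_floor=payload["density_floor"],
    )


def save_model(m: ScoringModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(m)))


def load_model(path: str | Path) -> ScoringModel:
    return model_from_dict(json.loads(Path(path).read_text()))
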