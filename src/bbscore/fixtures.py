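"""Synthetic structures and planted training distributions.

Everything the package needs for testing and desk-scale experiments is
generated here, with no downloads: ideal helices and hairpins built by
internal-coordinate chaining with ideal covalent geometry, compact globules
built from a persistent self-avoiding C-alpha walk with per-residue N/C
atoms synthesised to give well-conditioned local frames, helix bundles
assembled from rigidly placed ideal helices, and transmembrane helix pairs
with per-residue membrane depths.

Planted sequence preferences are specified directly in the six-coordinate
space the scorer uses: each residue-type pair may carry Gaussian affinity
bumps over a subset of {r, theta, phi, alpha, beta, gamma}.  Native
sequences are assigned by Gibbs sampling from the induced pairwise field on
the actual backbone geometry, so type/geometry co-occurrence follows the
planted densities while shuffled sequences destroy it by construction.
The defaults give some preferences that are visible to a distance-only (1D)
score, some only to a positional (3D) score, and some only to the full
orientational (6D) score, mirroring the information ordering the potentials
are meant to resolve.

These generators emulate frame geometry and pair statistics, not protein
chemistry: globule and bundle backbones are not everywhere covalently
continuous, and no side chains exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import place_virtual_cbeta
from .scoring import PairGeometry, extract_pair_geometry
from .structure import BackboneResidue, ProteinStructure

__all__ = [
    "PlantedBump",
    "PlantedSpec",
    "default_planted_spec",
    "make_ideal_helix",
    "make_toy_protein",
    "sample_training_set",
    "make_membrane_helix_pair",
    "combine_helices",
    "sample_depth_data",
]

# Ideal backbone covalent parameters (lengths in Angstrom, angles in degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA_TRANS = 180.0


def _place_atom(a, b, c, length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given three predecessors, bond length, angle and dihedral
    (standard internal-coordinate / NeRF construction)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    theta = math.radians(angle_deg)
    chi = -math.radians(dihedral_deg)  # sign matches the IUPAC dihedral reader
    d_local = np.array(
        [-length * math.cos(theta), length * math.sin(theta) * math.cos(chi),
         length * math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _chain_from_torsions(
    torsions: list[tuple[float, float]],
    chain_id: str = "A",
    start_index: int = 0,
    aa: str = "A",
) -> list[BackboneResidue]:
    """Backbone residues from a (phi, psi) list with ideal covalent geometry."""
    n = len(torsions)
    coords: list[dict[str, np.ndarray]] = []
    N0 = np.zeros(3)
    CA0 = np.array([BOND_N_CA, 0.0, 0.0])
    theta = math.radians(ANGLE_N_CA_C)
    C0 = CA0 + BOND_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])
    coords.append({"N": N0, "CA": CA0, "C": C0})
    for k in range(1, n):
        prev = coords[-1]
        psi_prev = torsions[k - 1][1]
        N = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA = _place_atom(prev["CA"], prev["C"], N, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        C = _place_atom(prev["C"], N, CA, BOND_CA_C, ANGLE_N_CA_C, torsions[k][0])
        coords.append({"N": N, "CA": CA, "C": C})
    residues = []
    for k, atom in enumerate(coords):
        cb = place_virtual_cbeta(atom["N"], atom["CA"], atom["C"])
        residues.append(
            BackboneResidue(
                chain_id=chain_id,
                residue_index=start_index + k,
                aa_type=aa,
                N=atom["N"],
                CA=atom["CA"],
                C=atom["C"],
                CB=cb,
            )
        )
    return residues


def make_ideal_helix(
    n: int, phi_deg: float = -57.0, psi_deg: float = -47.0, structure_id: str = "helix"
) -> ProteinStructure:
    """Ideal alpha-helix (or any uniform-torsion chain) of n residues."""
    if n < 2:
        raise ValueError("need at least 2 residues")
    torsions = [(phi_deg, psi_deg)] * n
    return ProteinStructure(residues=_chain_from_torsions(torsions), id=structure_id)


def _reindexed(residues: list[BackboneResidue], chain_id: str = "A") -> list[BackboneResidue]:
    out = []
    for k, r in enumerate(residues):
        out.append(
            BackboneResidue(
                chain_id=chain_id, residue_index=k, aa_type=r.aa_type,
                N=r.N, CA=r.CA, C=r.C, CB=r.CB, cb_is_virtual=r.cb_is_virtual,
            )
        )
    return out


def _rigidly_placed(residues, rotation: np.ndarray, translation: np.ndarray):
    out = []
    for r in residues:
        out.append(
            BackboneResidue(
                chain_id=r.chain_id, residue_index=r.residue_index, aa_type=r.aa_type,
                N=rotation @ r.N + translation,
                CA=rotation @ r.CA + translation,
                C=rotation @ r.C + translation,
                CB=rotation @ r.CB + translation,
                cb_is_virtual=r.cb_is_virtual,
            )
        )
    return out


def _helix_axis_frame(residues) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, rotation) aligning the helix principal axis with +z."""
    ca = np.vstack([r.CA for r in residues])
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    # Rotation sending axis -> z via Rodrigues.
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(axis @ z)
    if s < 1e-9:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return centroid, rot


def _standing_helix(n: int) -> list[BackboneResidue]:
    """Ideal helix rigidly moved so its axis is +z and centroid the origin."""
    residues = make_ideal_helix(n).residues
    centroid, rot = _helix_axis_frame(residues)
    return _rigidly_placed(residues, rot, -rot @ centroid)


def _synthesize_backbone_from_ca(
    ca: np.ndarray, chain_id: str = "A"
) -> list[BackboneResidue]:
    """Per-residue N/C/CB atoms around a C-alpha trace.

    N points toward the previous C-alpha and C toward the next, both tilted
    out of the local chain plane so the N-CA-C angle stays well away from
    collinear and every frame is non-degenerate.
    """
    n = len(ca)
    residues = []
    for k in range(n):
        if k > 0:
            dp = ca[k - 1] - ca[k]
        else:
            dp = None
        if k + 1 < n:
            dn = ca[k + 1] - ca[k]
        else:
            dn = None
        if dp is None:
            # Terminal: synthesise a backward direction at ~120 deg from dn.
            dn_u = dn / np.linalg.norm(dn)
            perp = np.cross(dn_u, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(dn_u, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            dp = -0.5 * dn_u + 0.866 * perp
        if dn is None:
            dp_u = dp / np.linalg.norm(dp)
            perp = np.cross(dp_u, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(dp_u, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            dn = -0.5 * dp_u + 0.866 * perp
        dp = dp / np.linalg.norm(dp)
        dn = dn / np.linalg.norm(dn)
        e2 = np.cross(dp, dn)
        if np.linalg.norm(e2) < 1e-3:
            e2 = np.cross(dp, [0.0, 0.0, 1.0])
            if np.linalg.norm(e2) < 1e-3:
                e2 = np.cross(dp, [0.0, 1.0, 0.0])
        e2 /= np.linalg.norm(e2)
        u_n = dp + 0.45 * e2
        u_n /= np.linalg.norm(u_n)
        u_c = dn + 0.45 * e2
        u_c /= np.linalg.norm(u_c)
        N = ca[k] + 1.46 * u_n
        C = ca[k] + 1.52 * u_c
        cb = place_virtual_cbeta(N, ca[k], C)
        residues.append(
            BackboneResidue(
                chain_id=chain_id, residue_index=k, aa_type="A",
                N=N, CA=ca[k], C=C, CB=cb,
            )
        )
    return residues


def _compact_ca_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    """Persistent self-avoiding walk of step 3.8 A confined to a sphere.

    The confinement radius targets roughly native packing density
    (~135 A^3 per residue), which yields contact-rich, globule-like traces.
    """
    radius = (n * 135.0 * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    step = 3.8
    min_sep = 3.6
    for _attempt in range(50):
        ca = [np.zeros(3)]
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        ok = True
        for _k in range(1, n):
            placed = False
            for _try in range(200):
                pull = -ca[-1] / max(np.linalg.norm(ca[-1]), 1e-9)
                proposal = 1.2 * direction + 0.7 * rng.standard_normal(3)
                proposal += 0.6 * pull * max(0.0, np.linalg.norm(ca[-1]) / radius)
                proposal /= np.linalg.norm(proposal)
                candidate = ca[-1] + step * proposal
                if np.linalg.norm(candidate) > radius:
                    continue
                if len(ca) > 1:
                    dists = np.linalg.norm(np.vstack(ca[:-1]) - candidate, axis=1)
                    if dists.min() < min_sep:
                        continue
                ca.append(candidate)
                direction = proposal
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.vstack(ca)
    raise RuntimeError(f"could not place a compact {n}-residue walk")


def make_toy_protein(
    n_residues: int,
    topology: str = "globule",
    seed: int = 0,
    structure_id: str | None = None,
) -> ProteinStructure:
    """Synthetic test structure with at least one qualifying residue pair.

    Topologies: ``hairpin`` (two extended strands joined by a tight turn),
    ``helix-bundle`` (ideal helices rigidly packed on a grid, antiparallel),
    ``globule`` (compact self-avoiding C-alpha walk with synthesised N/C).
    Deterministic per (topology, n_residues, seed).
    """
    if n_residues < 12:
        raise ValueError("toy proteins need at least 12 residues")
    sid = structure_id or f"{topology}-{n_residues}-{seed}"
    rng = np.random.default_rng(seed)
    if topology == "hairpin":
        arm = (n_residues - 2) // 2
        # Two extended strands joined by a type-I'-like two-residue turn.
        torsions = (
            [(-135.0, 135.0)] * arm
            + [(57.0, 47.0), (78.0, 6.0)]
            + [(-135.0, 135.0)] * (n_residues - arm - 2)
        )
        residues = _chain_from_torsions(torsions)
        return ProteinStructure(residues=residues, id=sid)
    if topology == "helix-bundle":
        n_helices = max(2, min(4, n_residues // 14))
        per = n_residues // n_helices
        spacing = 8.6
        grid = [(0, 0), (1, 0), (0, 1), (1, 1)]
        residues: list[BackboneResidue] = []
        for h in range(n_helices):
            length = per if h < n_helices - 1 else n_residues - per * (n_helices - 1)
            helix = _standing_helix(length)
            flip = np.diag([1.0, -1.0, -1.0]) if h % 2 else np.eye(3)
            gx, gy = grid[h]
            jitter = rng.uniform(-0.4, 0.4, size=3)
            shift = np.array([gx * spacing, gy * spacing, 0.0]) + jitter
            residues.extend(_rigidly_placed(helix, flip, shift))
        return ProteinStructure(residues=_reindexed(residues), id=sid)
    if topology == "globule":
        ca = _compact_ca_walk(n_residues, rng)
        return ProteinStructure(residues=_synthesize_backbone_from_ca(ca), id=sid)
    raise ValueError(f"unknown topology {topology!r}")


# ---------------------------------------------------------------------------
# Planted sequence preferences


@dataclass(frozen=True)
class PlantedBump:
    """A Gaussian affinity bump over a subset of the six coordinates.

    ``dims`` indexes into (r, theta, phi, alpha, beta, gamma); periodic
    coordinates (phi, alpha, gamma) use wrapped differences.
    """

    dims: tuple[int, ...]
    mu: tuple[float, ...]
    sigma: tuple[float, ...]
    amplitude: float


_PERIODIC = {2, 3, 5}


@dataclass
class PlantedSpec:
    """Planted per-type-pair affinities over the relative-coordinate space."""

    alphabet: str
    composition: np.ndarray
    bumps: dict[tuple[str, str], list[PlantedBump]]

    def __post_init__(self):
        self.composition = np.asarray(self.composition, dtype=float)
        self.composition = self.composition / self.composition.sum()
        for key in self.bumps:
            if key != tuple(sorted(key)):
                raise ValueError(f"bump key {key} must be canonically ordered")

    def log_affinity(self, a: str, b: str, omega6: np.ndarray) -> float:
        key = (a, b) if a <= b else (b, a)
        total = 0.0
        for bump in self.bumps.get(key, ()):  # absent pair: neutral
            z2 = 0.0
            for d, mu, sigma in zip(bump.dims, bump.mu, bump.sigma):
                diff = omega6[d] - mu
                if d in _PERIODIC:
                    diff = (diff + math.pi) % (2.0 * math.pi) - math.pi
                z2 += (diff / sigma) ** 2
            total += bump.amplitude * math.exp(-0.5 * z2)
        return total


def default_planted_spec() -> PlantedSpec:
    """The standard planted preferences used across the fixture suite.

    The Cys-Cys bump sits at r = 3.8 A (the disulfide-like distance) and is
    visible to all three scores; the Glu-Lys bump lives in theta only (3D+),
    the Leu-Leu bump in phi only (3D+), and the Leu-Trp and Trp-Trp bumps in
    Euler angles only (6D only).
    """
    alphabet = "ACEKLW"
    # Each type participates in exactly two bumps, and every bump region
    # occupies a comparably small fraction (a few percent) of the observed
    # coordinate distribution, so no subset of the alphabet is globally
    # favoured.  Angular preferences are joint 2-coordinate windows: theta/phi
    # bumps are visible to the 3D score but not the 1D one, Euler-angle bumps
    # only to the 6D score.
    bumps = {
        ("C", "C"): [PlantedBump(dims=(0,), mu=(3.8,), sigma=(0.35,), amplitude=3.0)],
        ("A", "C"): [PlantedBump(dims=(0,), mu=(5.0,), sigma=(0.30,), amplitude=2.5)],
        ("A", "K"): [PlantedBump(dims=(1, 2), mu=(0.6, -1.5), sigma=(0.35, 0.50), amplitude=5.0)],
        ("E", "K"): [PlantedBump(dims=(1, 2), mu=(2.4, 1.2), sigma=(0.35, 0.50), amplitude=5.0)],
        ("E", "W"): [PlantedBump(dims=(3, 4), mu=(-1.0, 2.2), sigma=(0.50, 0.35), amplitude=5.0)],
        ("L", "W"): [PlantedBump(dims=(4, 5), mu=(0.9, 0.8), sigma=(0.35, 0.50), amplitude=5.0)],
        ("L", "L"): [PlantedBump(dims=(3, 5), mu=(1.5, -1.5), sigma=(0.50, 0.50), amplitude=5.0)],
    }
    return PlantedSpec(alphabet=alphabet, composition=np.ones(len(alphabet)), bumps=bumps)


def strong_cc_planted_spec() -> PlantedSpec:
    """Variant with a dominant Cys-Cys distance preference.

    Used for experiments that need a single unmistakable distance-visible
    signal (disulfide-like Cys-Cys pairing at 3.8 A): the Cys-Cys bump is
    strengthened and cysteine made more common.
    """
    spec = default_planted_spec()
    spec.bumps[("C", "C")] = [
        PlantedBump(dims=(0,), mu=(3.8,), sigma=(0.35,), amplitude=10.0)
    ]
    spec.bumps[("A", "C")] = [
        PlantedBump(dims=(0,), mu=(5.0,), sigma=(0.30,), amplitude=5.0)
    ]
    comp = spec.composition.copy()
    comp[spec.alphabet.index("C")] *= 0.7
    spec.composition = comp / comp.sum()
    return spec


def null_planted_spec() -> PlantedSpec:
    """No preferences at all: sequences are independent of geometry."""
    return PlantedSpec(alphabet="ACEKLW", composition=np.ones(6), bumps={})


def _affinity_tables(
    spec: PlantedSpec, geometry: list[PairGeometry]
) -> list[np.ndarray]:
    """Per-pair (A, A) affinity tables with canonical orientation applied."""
    A = len(spec.alphabet)
    tables = []
    for pg in geometry:
        fwd = pg.forward.as_vector(6)
        rev = pg.reverse.as_vector(6)
        table = np.zeros((A, A))
        for ia, a in enumerate(spec.alphabet):
            for ib, b in enumerate(spec.alphabet):
                omega = fwd if a <= b else rev
                table[ia, ib] = spec.log_affinity(a, b, omega)
        tables.append(table)
    return tables


def _gibbs_sequence(
    spec: PlantedSpec,
    geometry: list[PairGeometry],
    n_residues: int,
    rng: np.random.Generator,
    n_sweeps: int = 6,
) -> str:
    A = len(spec.alphabet)
    tables = _affinity_tables(spec, geometry)
    partners: dict[int, list[tuple[int, np.ndarray]]] = {k: [] for k in range(n_residues)}
    for pg, table in zip(geometry, tables):
        # Center over the candidate-type axis so bumps express relative
        # preferences instead of a net drift toward bump-carrying types.
        fwd = table - table.mean(axis=0, keepdims=True)
        rev = table.T - table.T.mean(axis=0, keepdims=True)
        partners[pg.i].append((pg.j, fwd))
        partners[pg.j].append((pg.i, rev))
    log_comp = np.log(spec.composition)
    types = rng.choice(A, size=n_residues, p=spec.composition)
    for _sweep in range(n_sweeps):
        for i in range(n_residues):
            logits = log_comp.copy()
            for j, table in partners[i]:
                logits += table[:, types[j]]
            p = np.exp(logits - logits.max())
            p /= p.sum()
            types[i] = rng.choice(A, p=p)
    return "".join(spec.alphabet[t] for t in types)


def sample_training_set(
    spec: PlantedSpec,
    n_structures: int = 20,
    n_residues: int = 60,
    seed: int = 0,
    topology: str = "globule",
) -> tuple[list[ProteinStructure], list[str]]:
    """Structures with native sequences Gibbs-sampled from the planted field.

    Each structure's qualifying-pair geometry is generated first; the
    sequence is then drawn so that type pairs co-occur with the relative
    coordinates their planted densities favour.  The returned structures
    carry their native sequences (``structure.sequence``) and the sequences
    are also returned separately.
    """
    rng = np.random.default_rng(seed)
    structures: list[ProteinStructure] = []
    sequences: list[str] = []
    for k in range(n_structures):
        s = make_toy_protein(
            n_residues, topology=topology, seed=int(rng.integers(2**31 - 1)),
            structure_id=f"train-{k:03d}",
        )
        geometry = extract_pair_geometry(s)
        seq = _gibbs_sequence(spec, geometry, len(s), rng)
        for res, aa in zip(s.residues, seq):
            res.aa_type = aa
        structures.append(s)
        sequences.append(seq)
    return structures, sequences


def random_relative_coordinates(rng: np.random.Generator, r: float) -> "RelativeCoordinates":
    """Relative coordinates at distance r with isotropic random orientation."""
    from .geometry import RelativeCoordinates

    return RelativeCoordinates(
        r=float(r),
        theta=float(np.arccos(rng.uniform(-1.0, 1.0))),
        phi=float(rng.uniform(-math.pi, math.pi)),
        alpha=float(rng.uniform(-math.pi, math.pi)),
        beta=float(np.arccos(rng.uniform(-1.0, 1.0))),
        gamma=float(rng.uniform(-math.pi, math.pi)),
    )


def sample_planted_distance_observations(
    n_per_pair: int = 10000,
    seed: int = 0,
    cc_mean: float = 3.8,
    cc_sigma: float = 0.3,
    r_max: float = 10.0,
):
    """Typed pair observations with a tight planted Cys-Cys distance mode.

    Cys-Cys distances are drawn from a Gaussian at the disulfide-like
    separation (3.8 A), truncated to (2.5, r_max]; several other type pairs
    share a broad background with density proportional to r^2 (the volume
    element) on [3.0, r_max].  Orientations are isotropic throughout, so
    only the distance coordinate is informative.
    """
    from .scoring import PairObservation

    rng = np.random.default_rng(seed)
    obs = []

    def _background_r():
        while True:
            r = r_max * rng.random() ** (1.0 / 3.0)
            if r >= 3.0:
                return r

    for idx in range(n_per_pair):
        while True:
            r = rng.normal(cc_mean, cc_sigma)
            if 2.5 < r <= r_max:
                break
        obs.append(
            PairObservation(
                t1="C", t2="C", omega=random_relative_coordinates(rng, r),
                protein_id="planted", i=0, j=6 + idx,
            )
        )
    for t1, t2 in (("A", "A"), ("A", "E"), ("E", "E"), ("A", "K"), ("E", "K"), ("K", "K")):
        for idx in range(n_per_pair):
            obs.append(
                PairObservation(
                    t1=t1, t2=t2, omega=random_relative_coordinates(rng, _background_r()),
                    protein_id="planted", i=0, j=6 + idx,
                )
            )
    return obs


def make_homolog_windows(
    s: ProteinStructure,
    spec: PlantedSpec,
    n_homologs: int = 5,
    resample_fraction: float = 0.25,
    seed: int = 0,
) -> list[str]:
    """Structure-compatible homologs of a structure's native sequence.

    Each homolog resamples a random fraction of positions from the planted
    field conditioned on the rest of the sequence, mimicking evolutionary
    substitutions that preserve structural fit.  Homologs of an unrelated
    (decoy) sequence, by contrast, are plain random substitutions -- only
    the true native's relatives carry structure-aware signal.
    """
    rng = np.random.default_rng(seed)
    geometry = extract_pair_geometry(s)
    A = len(spec.alphabet)
    aa_index = {aa: k for k, aa in enumerate(spec.alphabet)}
    tables = _affinity_tables(spec, geometry)
    partners: dict[int, list[tuple[int, np.ndarray]]] = {k: [] for k in range(len(s))}
    for pg, table in zip(geometry, tables):
        fwd = table - table.mean(axis=0, keepdims=True)
        rev = table.T - table.T.mean(axis=0, keepdims=True)
        partners[pg.i].append((pg.j, fwd))
        partners[pg.j].append((pg.i, rev))
    log_comp = np.log(spec.composition)
    out = []
    for _ in range(n_homologs):
        types = np.array([aa_index[aa] for aa in s.sequence])
        chosen = rng.random(len(s)) < resample_fraction
        for i in np.flatnonzero(chosen):
            logits = log_comp.copy()
            for j, table in partners[i]:
                logits += table[:, types[j]]
            p = np.exp(logits - logits.max())
            p /= p.sum()
            types[i] = rng.choice(A, p=p)
        out.append("".join(spec.alphabet[t] for t in types))
    return out


def random_substitution_windows(
    seq: str,
    alphabet: str,
    n_windows: int,
    rate: float,
    rng: np.random.Generator,
) -> list[str]:
    """Copies of a sequence with independent per-position substitutions."""
    out = []
    for _ in range(n_windows):
        window = list(seq)
        for pos in range(len(window)):
            if rng.random() < rate:
                window[pos] = alphabet[int(rng.integers(len(alphabet)))]
        out.append("".join(window))
    return out


# ---------------------------------------------------------------------------
# Membrane fixtures


def make_membrane_helix_pair(
    seed: int = 0,
    contact_rich: bool = True,
    helix_length: int = 20,
    n_homologs: int = 5,
    substitution_rate: float = 0.2,
) -> tuple[ProteinStructure, ProteinStructure, list[float], list[str]]:
    """Antiparallel transmembrane helix pair with depths and homolog windows.

    Returns the two helices (chains A and B), per-residue membrane depths
    (z of each C-alpha, helix axis normal to the membrane so depths span
    about [-15, 15] A), and homolog windows: copies of the combined native
    sequence with independent per-position substitutions at the given rate.
    With ``contact_rich`` the axis spacing is tight enough for at least 15
    inter-helix residue contacts (< 4 A atomic separation).
    """
    rng = np.random.default_rng(seed)
    spacing = 7.2 if contact_rich else 13.0
    h1_res = _standing_helix(helix_length)
    h2_res = _standing_helix(helix_length)
    h1_res = _rigidly_placed(h1_res, np.eye(3), np.zeros(3))
    h2_res = _rigidly_placed(h2_res, np.diag([1.0, -1.0, -1.0]), np.array([spacing, 0.0, 0.0]))
    membrane_aas = "AFGILVWC"
    for res_list, chain in ((h1_res, "A"), (h2_res, "B")):
        for r in res_list:
            r.chain_id = chain
            r.aa_type = membrane_aas[int(rng.integers(len(membrane_aas)))]
    h1 = ProteinStructure(residues=h1_res, id=f"tm-{seed}-A")
    h2 = ProteinStructure(residues=h2_res, id=f"tm-{seed}-B")
    depths = [float(r.CA[2]) for r in h1_res] + [float(r.CA[2]) for r in h2_res]
    native = h1.sequence + h2.sequence
    homologs = []
    for _ in range(n_homologs):
        window = list(native)
        for pos in range(len(window)):
            if rng.random() < substitution_rate:
                window[pos] = membrane_aas[int(rng.integers(len(membrane_aas)))]
        homologs.append("".join(window))
    return h1, h2, depths, homologs


def combine_helices(h1: ProteinStructure, h2: ProteinStructure) -> ProteinStructure:
    """Fuse two helices into one single-chain template for threading.

    Indices stay contiguous, so inter-helix pairs pass the sequence
    separation filter automatically once the gap exceeds it.
    """
    residues = _reindexed(h1.residues + h2.residues)
    return ProteinStructure(residues=residues, id=f"{h1.id}+{h2.id}")


def sample_depth_data(
    n: int = 2000, seed: int = 0
) -> list[tuple[str, float]]:
    """Planted membrane-depth samples (aa, z) with type-specific propensities.

    Hydrophobics concentrate at the membrane centre (|z| small), charged and
    polar types near the headgroup region (|z| around 15 A), alanine/glycine
    spread uniformly.  Depths are signed and symmetric about z = 0.
    """
    rng = np.random.default_rng(seed)
    center_aas = "LIVF"
    edge_aas = "KREDQ"
    flat_aas = "AG"
    samples: list[tuple[str, float]] = []
    for _ in range(n):
        group = rng.random()
        if group < 0.45:
            aa = center_aas[int(rng.integers(len(center_aas)))]
            z = rng.normal(0.0, 5.0)
        elif group < 0.8:
            aa = edge_aas[int(rng.integers(len(edge_aas)))]
            z = rng.choice([-1.0, 1.0]) * rng.normal(15.0, 3.0)
        else:
            aa = flat_aas[int(rng.integers(len(flat_aas)))]
            z = rng.uniform(-20.0, 20.0)
        samples.append((aa, float(np.clip(z, -20.0, 20.0))))
    return samples
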