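"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the pipeline's inputs:

* chromophore trajectories — an idealized 11-cis-retinal + lysine scaffold
  whose named torsions are set frame by frame to draws from wrapped-normal
  distributions (by rotating the relevant methyl carbon about the torsion's
  central bond), with isotropic Gaussian jitter and optional global rigid
  motion on top;
* opsin coding sequences — an intact reference CDS with chosen residues
  planted at bovine-numbered tuning sites and ORF lesions (deletions,
  insertions, premature stops) applied at known codon positions;
* developmental count tables — negative-binomial gene x sample counts
  with stage-specific means, unequal library depths, and an optionally
  planted fold change.

Every generator returns its output together with a machine-readable
ground-truth record. Trajectory realism is deliberately minimal: only the
statistics the descriptors measure are controlled, no force field is
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .descriptors import ANGLE_SPECS, LYS_RET_ATOM_ORDER, Trajectory, dihedral
from .expression import CountMatrix
from .sequences import OpsinSequence, bovine_reference, map_to_bovine_numbering

__all__ = [
    "TrajectoryRecipe",
    "SequenceRecipe",
    "Lesion",
    "make_trajectory",
    "expected_rmsf_curve",
    "solve_jitter_for_auc",
    "rh2_replay_recipe",
    "make_sequence",
    "reference_opsin",
    "make_counts",
]

# ---------------------------------------------------------------------------
# idealized LYS+RET scaffold
#
# Internal-coordinate (z-matrix) definition: each atom is placed from its
# parent A, angle reference B and torsion reference C with bond |D-A|,
# angle D-A-B and dihedral D-A-B-C. Bond lengths/angles are generic
# organic values; the named torsions carry neutral base values that the
# per-frame sampler overrides.

_ZMATRIX: list[tuple[str, str | None, str | None, str | None,
                     float, float, float]] = [
    # atom, parent, angle ref, torsion ref, bond(A), angle(deg), torsion(deg)
    ("N",   None,  None,  None,  0.0,  0.0,   0.0),
    ("CA",  "N",   None,  None,  1.46, 0.0,   0.0),
    ("C",   "CA",  "N",   None,  1.52, 110.0, 0.0),
    ("O",   "C",   "CA",  "N",   1.23, 120.0, 30.0),
    ("CB",  "CA",  "N",   "C",   1.53, 110.0, 120.0),
    ("CG",  "CB",  "CA",  "N",   1.53, 112.0, 175.0),
    ("CD",  "CG",  "CB",  "CA",  1.53, 112.0, -170.0),
    ("CE",  "CD",  "CG",  "CB",  1.53, 112.0, 170.0),
    ("NZ",  "CE",  "CD",  "CG",  1.47, 111.0, -175.0),
    ("C15", "NZ",  "CE",  "CD",  1.28, 121.0, 178.0),
    ("C14", "C15", "NZ",  "CE",  1.45, 122.0, -178.0),
    ("C13", "C14", "C15", "NZ",  1.35, 123.0, 177.0),
    ("C20", "C13", "C14", "C15", 1.50, 117.0, 2.0),     # torsion3 base
    ("C12", "C13", "C14", "C15", 1.46, 119.0, -178.0),
    ("C11", "C12", "C13", "C14", 1.34, 122.0, 176.0),
    ("C10", "C11", "C12", "C13", 1.45, 121.0, -6.0),    # 11-cis kink
    ("C9",  "C10", "C11", "C12", 1.36, 123.0, 178.0),
    ("C19", "C9",  "C10", "C11", 1.50, 116.0, 4.0),
    ("C8",  "C9",  "C10", "C11", 1.46, 119.0, -177.0),
    ("C7",  "C8",  "C9",  "C10", 1.34, 124.0, 176.0),
    ("C6",  "C7",  "C8",  "C9",  1.47, 123.0, -150.0),
    ("C5",  "C6",  "C7",  "C8",  1.35, 122.0, 178.0),
    ("C18", "C5",  "C6",  "C7",  1.50, 118.0, 3.0),     # torsion15 base
    ("C4",  "C5",  "C6",  "C7",  1.51, 120.0, -178.0),
    ("C3",  "C4",  "C5",  "C6",  1.52, 112.0, 45.0),
    ("C2",  "C3",  "C4",  "C5",  1.52, 111.0, -48.0),
    ("C1",  "C2",  "C3",  "C4",  1.54, 111.0, 50.0),
    ("C16", "C1",  "C2",  "C3",  1.54, 109.0, 65.0),
    ("C17", "C1",  "C2",  "C3",  1.54, 109.0, -175.0),
]

#: For each rotatable named torsion: the movable leaf atom and the two
#: atoms of the central bond it rotates about.
_ROTATABLE: dict[str, tuple[str, str, str]] = {
    "torsion15": ("C18", "C6", "C5"),
    "torsion3": ("C20", "C14", "C13"),
    "torsion12": ("C19", "C9", "C8"),
}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom D from refs A (parent), B, C."""
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    ab = a - b
    bc_hat = ab / np.linalg.norm(ab)
    cb = b - c
    n = np.cross(cb, bc_hat)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc_hat)
    d_local = bond * np.array([-np.cos(theta),
                               np.sin(theta) * np.cos(phi),
                               np.sin(theta) * np.sin(phi)])
    return a + d_local[0] * bc_hat + d_local[1] * m + d_local[2] * n


def base_scaffold() -> Trajectory:
    """The idealized LYS+RET structure as a single-frame trajectory."""
    pos: dict[str, np.ndarray] = {}
    for name, parent, ang_ref, tor_ref, bond, angle, torsion in _ZMATRIX:
        if parent is None:
            pos[name] = np.zeros(3)
        elif ang_ref is None:
            pos[name] = pos[parent] + np.array([bond, 0.0, 0.0])
        elif tor_ref is None:
            theta = np.radians(angle)
            pos[name] = pos[parent] + bond * np.array(
                [-np.cos(theta), np.sin(theta), 0.0])
        else:
            pos[name] = _place(pos[parent], pos[ang_ref], pos[tor_ref],
                               bond, angle, torsion)
    coords = np.array([pos[a] for a in LYS_RET_ATOM_ORDER])[None]
    return Trajectory(atoms=LYS_RET_ATOM_ORDER, coords=coords)


def _wrap_deg(x):
    w = (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0
    w = np.where(np.isclose(w, -180.0), 180.0, w)
    return w if w.ndim else float(w)


# ---------------------------------------------------------------------------
# trajectory generator


@dataclass
class TrajectoryRecipe:
    """Controls for the synthetic chromophore trajectory.

    ``dihedral_targets`` maps a named torsion (torsion15/torsion3/
    torsion12) to a (location, spread) pair in degrees; per-frame values
    are drawn from the wrapped normal with those parameters. Only torsions
    whose leaf atom can rotate about the central bond are accepted.
    ``jitter_sigma`` is the per-axis Gaussian noise in Angstrom added to
    every atom; ``global_motion`` optionally composes a random rigid
    transform per frame (which superposition must undo).
    """

    n_frames: int = 5000
    dihedral_targets: dict[str, tuple[float, float]] = field(
        default_factory=dict)
    jitter_sigma: float = 0.0
    global_motion: str = "none"  # "none" | "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.global_motion not in ("none", "random"):
            raise ValueError("global_motion must be 'none' or 'random'")
        for name, (_, spread) in self.dihedral_targets.items():
            if name not in ANGLE_SPECS:
                raise ValueError(f"unknown angle spec {name!r}")
            if name not in _ROTATABLE:
                raise ValueError(
                    f"{name!r} is not realizable by bond rotation on the "
                    f"scaffold (rotatable: {sorted(_ROTATABLE)})")
            if spread < 0:
                raise ValueError(f"{name}: spread must be >= 0")


def _axis_geometry(base: np.ndarray, idx: dict[str, int], name: str):
    """Rotation axis and leaf geometry for a rotatable torsion."""
    leaf, b, c = _ROTATABLE[name]
    p_b, p_c = base[idx[b]], base[idx[c]]
    u = p_c - p_b
    u /= np.linalg.norm(u)
    leaf_pos = base[idx[leaf]]
    proj = p_b + np.dot(leaf_pos - p_b, u) * u
    radial = leaf_pos - proj
    return idx[leaf], p_b, u, proj, radial


def _rotation_sign(base: np.ndarray, idx: dict[str, int], name: str) -> float:
    """Sign s such that rotating the leaf by s*delta about the central bond
    axis increases the measured dihedral by delta."""
    spec = ANGLE_SPECS[name]
    leaf_i, _, u, proj, _ = _axis_geometry(base, idx, name)
    pts = [base[idx[a]] for a in spec]
    before = dihedral(*pts)
    probe = Rotation.from_rotvec(np.radians(10.0) * u)
    moved = base.copy()
    moved[leaf_i] = probe.apply(moved[leaf_i] - proj) + proj
    after = dihedral(*[moved[idx[a]] for a in spec])
    return 1.0 if abs(_wrap_deg(after - before - 10.0)) < 1e-6 else -1.0


def make_trajectory(recipe: TrajectoryRecipe
                    ) -> tuple[Trajectory, dict]:
    """Generate a trajectory and its ground-truth sidecar.

    Deterministic for a fixed seed. The sidecar records the expected value
    of every descriptor the trajectory was built to realize: target
    torsion medians, the base-scaffold values of untargeted angles, and
    the linearized expectation of the post-superposition RMSF curve and
    its area (see :func:`expected_rmsf_curve`).
    """
    rng = np.random.default_rng(recipe.seed)
    base = base_scaffold().coords[0]
    idx = {a: i for i, a in enumerate(LYS_RET_ATOM_ORDER)}
    n = recipe.n_frames

    coords = np.broadcast_to(base, (n, *base.shape)).copy()
    target_draws: dict[str, np.ndarray] = {}
    for name, (loc, spread) in recipe.dihedral_targets.items():
        leaf_i, _, u, proj, _ = _axis_geometry(base, idx, name)
        sign = _rotation_sign(base, idx, name)
        spec = ANGLE_SPECS[name]
        current = dihedral(*[base[idx[a]] for a in spec])
        draws = _wrap_deg(rng.normal(loc, spread, size=n))
        target_draws[name] = draws
        deltas = _wrap_deg(draws - current)
        rotvecs = np.radians(sign * deltas)[:, None] * u[None, :]
        rots = Rotation.from_rotvec(rotvecs)
        coords[:, leaf_i, :] = rots.apply(base[leaf_i] - proj) + proj

    if recipe.jitter_sigma > 0:
        coords = coords + rng.normal(0.0, recipe.jitter_sigma,
                                     size=coords.shape)

    if recipe.global_motion == "random":
        quats = rng.normal(size=(n, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        rots = Rotation.from_quat(quats)
        shifts = rng.normal(0.0, 5.0, size=(n, 3))
        for f in range(n):
            coords[f] = rots[f].apply(coords[f]) + shifts[f]

    traj = Trajectory(atoms=LYS_RET_ATOM_ORDER, coords=coords)

    per_atom, auc = expected_rmsf_curve(recipe)
    expected: dict[str, float] = {"rmsf_auc": auc}
    base_traj_vals = {
        name: dihedral(*[base[idx[a]] for a in spec]) if len(spec) == 4
        else None
        for name, spec in ANGLE_SPECS.items()
    }
    for name in ("torsion15", "torsion3", "torsion12"):
        if name in recipe.dihedral_targets:
            expected[f"{name}_median"] = _wrap_deg(
                recipe.dihedral_targets[name][0])
        else:
            expected[f"{name}_median"] = base_traj_vals[name]
    ground_truth = {
        "kind": "trajectory",
        "seed": recipe.seed,
        "n_frames": n,
        "jitter_sigma": recipe.jitter_sigma,
        "dihedral_targets": {k: list(v) for k, v in
                             recipe.dihedral_targets.items()},
        "expected": expected,
        "expected_rmsf_per_atom": per_atom.tolist(),
    }
    return traj, ground_truth


def expected_rmsf_curve(recipe: TrajectoryRecipe
                        ) -> tuple[np.ndarray, float]:
    """Linearized expectation of the post-superposition RMSF curve.

    Each atom carries isotropic jitter variance sigma^2 per axis; a leaf
    atom whose torsion is sampled additionally fluctuates tangentially on
    its rotation circle with variance rho^2 * (1 - exp(-s^2)) for angular
    spread s (the exact circular variance of a wrapped normal). The
    least-squares rigid fit removes the projection of the displacement
    field onto the 6-dimensional rigid-motion subspace; in the
    small-displacement limit that projection is orthogonal, so the removed
    variance is computed exactly from the per-atom covariances and the
    rigid-mode basis of the base scaffold.
    """
    base = base_scaffold().coords[0]
    idx = {a: i for i, a in enumerate(LYS_RET_ATOM_ORDER)}
    m = base.shape[0]
    sigma2 = recipe.jitter_sigma ** 2

    covs = np.array([np.eye(3) * sigma2 for _ in range(m)])
    for name, (_, spread) in recipe.dihedral_targets.items():
        leaf_i, _, u, _, radial = _axis_geometry(base, idx, name)
        rho = np.linalg.norm(radial)
        s2 = np.radians(spread) ** 2
        circ_var = rho ** 2 * (1.0 - np.exp(-s2))
        tangent = np.cross(u, radial / rho)
        covs[leaf_i] += circ_var * np.outer(tangent, tangent)

    # rigid-motion basis (3 translations + 3 rotations about the centroid)
    centered = base - base.mean(axis=0)
    modes = np.zeros((6, m, 3))
    for k in range(3):
        modes[k, :, k] = 1.0
    for k, axis in enumerate(np.eye(3)):
        modes[3 + k] = np.cross(axis, centered)
    flat = modes.reshape(6, -1)
    q, _ = np.linalg.qr(flat.T)  # (3m, 6) orthonormal basis
    e = q.T.reshape(6, m, 3)

    # residual_i = tr(C_i) - 2 E[u_i . (Pu)_i] + E|(Pu)_i|^2 for the
    # orthogonal projection P onto the rigid modes
    g = np.einsum("kia,iab,lib->kl", e, covs, e)  # 6x6 mode covariance
    cross = np.einsum("kia,iab,kib->i", e, covs, e)
    proj = np.einsum("kia,lia,kl->i", e, e, g)
    total = np.array([np.trace(c) for c in covs])
    residual = np.clip(total - 2.0 * cross + proj, 0.0, None)
    per_atom = np.sqrt(residual)
    return per_atom, float(np.trapezoid(per_atom))


def solve_jitter_for_auc(target_auc: float,
                         dihedral_targets: dict[str, tuple[float, float]],
                         ) -> float:
    """Jitter sigma that makes the expected RMSF curve area hit a target,
    given the torsional spreads already in the recipe."""

    def f(sigma):
        r = TrajectoryRecipe(n_frames=2, dihedral_targets=dihedral_targets,
                             jitter_sigma=sigma)
        return expected_rmsf_curve(r)[1] - target_auc

    floor = f(0.0)
    if floor > 0:
        raise ValueError(
            f"target rmsf_auc {target_auc} below the torsional floor "
            f"{floor + target_auc:.3f}; reduce spreads")
    return float(brentq(f, 0.0, 5.0, xtol=1e-10))


def rh2_replay_recipe(torsion15: float, rmsf_auc_target: float,
                      spread: float = 8.0, n_frames: int = 5000,
                      seed: int = 0) -> TrajectoryRecipe:
    """A recipe whose trajectory realizes given Torsion15 median and
    RMSF-curve area, for end-to-end replay through the RH2 model.

    The 8 degree default spread is a typical room-temperature width for a
    methyl-bearing ring torsion in a protein interior.
    """
    targets = {"torsion15": (torsion15, spread)}
    sigma = solve_jitter_for_auc(rmsf_auc_target, targets)
    return TrajectoryRecipe(n_frames=n_frames, dihedral_targets=targets,
                            jitter_sigma=sigma, seed=seed)


# ---------------------------------------------------------------------------
# sequence generator

_CODONS = {
    "A": ("GCT", "GCC", "GCA"), "C": ("TGT", "TGC"), "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"), "F": ("TTT", "TTC"), "G": ("GGT", "GGC", "GGA"),
    "H": ("CAT", "CAC"), "I": ("ATT", "ATC"), "K": ("AAA", "AAG"),
    "L": ("CTG", "CTT", "CTC"), "M": ("ATG",), "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA"), "Q": ("CAA", "CAG"), "R": ("CGT", "CGC"),
    "S": ("TCT", "TCC", "AGC"), "T": ("ACT", "ACC", "ACA"),
    "V": ("GTT", "GTC", "GTG"), "W": ("TGG",), "Y": ("TAT", "TAC"),
}

#: Class-typical residues planted into synthetic reference opsins.
CLASS_DEFAULT_SITES: dict[str, dict[int, str]] = {
    "lws": {164: "S", 181: "H", 261: "Y", 269: "T", 292: "A"},
    "sws1": {86: "F"},
    "rh2": {122: "E"},
    "sws2": {},
    "rh1": {},
    "unknown": {},
}


@dataclass(frozen=True)
class Lesion:
    kind: str  # "deletion" | "insertion" | "stop"
    position: int  # 1-based reference codon position
    length: int = 0  # nt, for deletion/insertion

    def nt_span(self) -> tuple[int, int]:
        """1-based nt interval occupied on the reference."""
        start = (self.position - 1) * 3 + 1
        if self.kind == "deletion":
            return start, start + self.length - 1
        return start, start + 2  # insertion point / replaced stop codon


@dataclass
class SequenceRecipe:
    opsin_class: str = "rh1"
    site_residues: dict[int, str] = field(default_factory=dict)
    lesions: list[Lesion] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        spans = sorted(l.nt_span() for l in self.lesions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("lesions overlap")


def _back_translate(protein: str) -> str:
    """Deterministic back-translation cycling synonymous codons so the CDS
    has no long repeats (which keeps alignment gap placement unambiguous)."""
    return "".join(_CODONS[aa][i % len(_CODONS[aa])]
                   for i, aa in enumerate(protein))


def reference_opsin(opsin_class: str = "rh1") -> OpsinSequence:
    """An intact synthetic opsin CDS for a class: the bovine rod opsin
    protein back-translated, with the class-typical tuning residues
    planted, plus a terminal stop codon."""
    protein = list(bovine_reference().protein)
    for site, res in CLASS_DEFAULT_SITES.get(opsin_class, {}).items():
        protein[site - 1] = res
    cds = _back_translate("".join(protein)) + "TAA"
    return OpsinSequence(id=f"synthetic_{opsin_class}_ref",
                         species="synthetic",
                         opsin_class=opsin_class, cds=cds)


def make_sequence(recipe: SequenceRecipe,
                  reference: OpsinSequence | None = None
                  ) -> tuple[OpsinSequence, dict]:
    """Plant tuning-site residues and lesions on an intact reference CDS.

    Site edits are codon replacements at the bovine-numbered positions
    (mapped through the reference's numbering alignment); lesions are then
    applied right-to-left so earlier coordinates stay valid. Returns the
    sequence plus a ground-truth sidecar with every planted feature.
    """
    if reference is None:
        reference = reference_opsin(recipe.opsin_class)
    if reference.cds is None:
        raise ValueError("reference must carry a CDS")

    numbering = map_to_bovine_numbering(reference)
    b2q = numbering.bovine_to_query()
    planted: dict[int, str] = {}
    cds = list(reference.cds)
    lesion_spans = [l.nt_span() for l in recipe.lesions]
    for site, res in sorted(recipe.site_residues.items()):
        if res not in _CODONS:
            raise ValueError(f"cannot encode residue {res!r}")
        if site not in b2q:
            raise ValueError(f"site {site} not alignable on the reference")
        codon_pos = b2q[site]  # reference residue index == codon index
        start, end = (codon_pos - 1) * 3 + 1, (codon_pos - 1) * 3 + 3
        if any(s <= end and e >= start for s, e in lesion_spans):
            raise ValueError(
                f"site {site} (codon {codon_pos}) overlaps a lesion")
        cds[start - 1:end] = _CODONS[res][0]
        planted[site] = res

    # the edited (pre-lesion) CDS is the coordinate frame lesions live in
    edited_ref = "".join(cds)
    from .orf import left_align_deletion, left_align_insertion

    lesion_truth = []
    for lesion in sorted(recipe.lesions, key=lambda l: -l.position):
        start, _ = lesion.nt_span()
        canonical_codon = lesion.position
        if lesion.kind == "deletion":
            canon_nt = left_align_deletion(edited_ref, start, lesion.length)
            canonical_codon = (canon_nt - 1) // 3 + 1
            del cds[start - 1:start - 1 + lesion.length]
        elif lesion.kind == "insertion":
            rng = np.random.default_rng(recipe.seed + lesion.position)
            insert = "".join(rng.choice(list("ACGT"), size=lesion.length))
            canon_after = left_align_insertion(edited_ref, start - 1, insert)
            canonical_codon = max(canon_after // 3 + 1, 1)
            cds[start - 1:start - 1] = list(insert)
        elif lesion.kind == "stop":
            cds[start - 1:start + 2] = "TAA"
        else:
            raise ValueError(f"unknown lesion kind {lesion.kind!r}")
        lesion_truth.append({
            "kind": lesion.kind,
            "reference_codon_position": lesion.position,
            "canonical_codon_position": canonical_codon,
            "length_nt": lesion.length,
        })
    lesion_truth.reverse()

    seq = OpsinSequence(
        id=f"synthetic_{recipe.opsin_class}_q{recipe.seed}",
        species="synthetic", opsin_class=recipe.opsin_class,
        cds="".join(cds))
    ground_truth = {
        "kind": "sequence",
        "reference_id": reference.id,
        "opsin_class": recipe.opsin_class,
        "planted_sites": {str(k): v for k, v in planted.items()},
        "lesions": lesion_truth,
    }
    return seq, ground_truth


# ---------------------------------------------------------------------------
# count-table generator


def make_counts(n_genes: int = 11,
                stages: tuple[str, ...] = ("225dd", "320dd", "410dd", "800dd"),
                n_replicates: int = 4,
                depth_range: tuple[float, float] = (1e5, 2e5),
                planted_fold: tuple[int, float] | None = None,
                dispersion: float = 20.0,
                seed: int = 0) -> tuple[CountMatrix, dict]:
    """Negative-binomial developmental count table with known truth.

    Gene base abundances are log-normal; each gene follows a smooth
    stage trajectory, and ``planted_fold=(gene_index, fold)`` forces one
    gene to rise by exactly ``fold`` from the first to the last stage.
    Library depths are drawn per replicate from ``depth_range`` so the
    depth normalization has real work to do. ``dispersion`` is the
    negative-binomial size parameter (larger = closer to Poisson),
    a moderate bulk-RNA-seq level by default.
    """
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1}" for i in range(n_genes)]

    base = rng.lognormal(mean=4.0, sigma=1.2, size=n_genes)
    slopes = rng.normal(0.0, 0.8, size=n_genes)  # log2 per stage step
    steps = np.arange(len(stages))
    log2_traj = np.outer(slopes, steps)
    stage_means = base[:, None] * 2.0 ** log2_traj  # gene x stage, pre-depth
    rel = stage_means / stage_means.sum(axis=0, keepdims=True)
    if planted_fold is not None:
        # depth normalization recovers RELATIVE abundance ratios, so the
        # planted fold is imposed on the gene's per-stage share directly
        g_idx, fold = planted_fold
        share0 = min(float(rel[g_idx, 0]), 1.0 / (2.0 * fold))
        share = share0 * fold ** (steps / (len(stages) - 1))
        for si in range(len(stages)):
            others = np.delete(np.arange(n_genes), g_idx)
            rel[others, si] *= (1.0 - share[si]) / rel[others, si].sum()
            rel[g_idx, si] = share[si]

    cols = {}
    replicate_map: dict[str, list[str]] = {s: [] for s in stages}
    for si, stage in enumerate(stages):
        for r in range(n_replicates):
            depth = rng.uniform(*depth_range)
            mean = rel[:, si] * depth
            p = dispersion / (dispersion + mean)
            counts = rng.negative_binomial(dispersion, p)
            label = f"{stage}_r{r + 1}"
            cols[label] = counts
            replicate_map[stage].append(label)

    matrix = CountMatrix(counts=pd.DataFrame(cols, index=genes))
    ground_truth = {
        "kind": "counts",
        "seed": seed,
        "stages": list(stages),
        "replicate_map": replicate_map,
        "relative_stage_means": pd.DataFrame(
            rel, index=genes, columns=list(stages)).to_dict(),
        "planted_fold": (None if planted_fold is None
                         else {"gene": genes[planted_fold[0]],
                               "fold": planted_fold[1]}),
    }
    return matrix, ground_truth
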