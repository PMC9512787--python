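"""Superposition and comparative model analysis.

Implements least-squares (Kabsch) rigid superposition, ensemble alignment on a
core selection, per-residue flexibility profiling, hinge/axis-angle rotation
measurement between two conformations, and composite-model splicing.

All superpositions default to Cα atoms; at coiled-coil resolutions the Cα
trace carries the whole signal.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import Selection, Structure, normalize_chain_map, resolve_selection

__all__ = [
    "RigidTransform",
    "FlexibilityProfile",
    "HingeMeasurement",
    "SpliceRecipe",
    "kabsch",
    "transform_structure",
    "align_ensemble",
    "flexibility_profile",
    "extreme_pair",
    "rotation_between",
    "splice_composite",
    "rotation_matrix",
    "angle_axis_of",
]


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


@dataclasses.dataclass
class FlexibilityProfile:
    """Per-residue deviation (Å) over the residues shared by all ensemble members."""

    values: dict[tuple[str, int, str], float]  # residue key -> deviation
    mode: str  # "extreme_pair" | "ensemble_rmsd"
    reference: int
    dropped: list[tuple[str, int, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        if any(v < 0 for v in self.values.values()):
            raise ValueError("deviations must be non-negative")

    def array(self) -> np.ndarray:
        """Values ordered by residue key."""
        return np.array([self.values[k] for k in sorted(self.values)], dtype=float)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.array(), q))


@dataclasses.dataclass
class HingeMeasurement:
    """Axis-angle rotation relating a mobile domain between two conformations."""

    angle_deg: float
    axis: np.ndarray  # unit vector, right-handed, angle in [0, 180]
    ref_selection: Selection | None
    mobile_selection: Selection | None
    residual_rmsd: float

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-6):
            raise ValueError("axis must be a unit vector")
        if not (0.0 <= self.angle_deg <= 180.0 + 1e-9):
            raise ValueError("angle must lie in [0, 180] degrees")
        object.__setattr__(self, "axis", axis)


@dataclasses.dataclass
class SpliceRecipe:
    """Which residue ranges to take from which source model, plus deletions."""

    splices: list[tuple[str, Selection]]
    deletions: list[Selection] = dataclasses.field(default_factory=list)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Point correspondence is positional.  Returns the transform minimising the
    RMSD and that minimum RMSD.  Degenerate (rank-deficient) configurations are
    handled through the SVD determinant correction, so reflections are never
    returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(mobile)) and np.all(np.isfinite(reference))):
        raise ValueError("non-finite coordinates")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    transform = RigidTransform(R, t)
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return transform, rmsd


def transform_structure(s: Structure, transform: RigidTransform) -> Structure:
    """Apply a rigid transform to every model of a structure."""
    out = s
    for mi in range(len(s.models)):
        out = out.with_coords(transform.apply(out.coords(mi)), model=mi)
    return out


def _core_ca(
    s: Structure,
    core: Selection,
    cmap: Mapping[str, str | Sequence[str]],
) -> tuple[list[tuple[str, int, str]], np.ndarray]:
    sel = dataclasses.replace(core, atom_filter="CA_only")
    idx, _missing = resolve_selection(s, sel, cmap)
    keys = [s.atoms()[i].residue_key for i in idx]
    return keys, s.coords()[idx]


def align_ensemble(
    ensemble: Sequence[Structure],
    core: Selection,
    chain_map: Mapping[str, str | Sequence[str]],
    reference_index: int = 0,
) -> tuple[list[Structure], list[float]]:
    """Superpose every ensemble member onto the reference over core Cα atoms.

    The reference model is left untouched.  All members must resolve the core
    selection to the same residue set; otherwise the offending models are
    reported.
    """
    if len(ensemble) < 1:
        raise ValueError("empty ensemble")
    ref_keys, ref_xyz = _core_ca(ensemble[reference_index], core, chain_map)
    offenders = []
    resolved = []
    for i, s in enumerate(ensemble):
        keys, xyz = _core_ca(s, core, chain_map)
        if keys != ref_keys:
            offenders.append(i)
        resolved.append(xyz)
    if offenders:
        raise ValueError(
            f"inconsistent core residue content across ensemble members: {offenders}"
        )
    aligned: list[Structure] = []
    rmsds: list[float] = []
    for i, s in enumerate(ensemble):
        if i == reference_index:
            aligned.append(s)
            rmsds.append(0.0)
            continue
        transform, rmsd = kabsch(resolved[i], ref_xyz)
        aligned.append(transform_structure(s, transform))
        rmsds.append(rmsd)
    return aligned, rmsds


def _shared_ca(
    ensemble: Sequence[Structure],
) -> tuple[list[tuple[str, int, str]], np.ndarray, list[tuple[str, int, str]]]:
    """Residues bearing a Cα in every member; returns keys, (M, N, 3) coords, dropped."""
    indices = [s.ca_index() for s in ensemble]
    shared = set(indices[0])
    union = set(indices[0])
    for ix in indices[1:]:
        shared &= set(ix)
        union |= set(ix)
    keys = sorted(shared)
    dropped = sorted(union - shared)
    if not keys:
        raise ValueError("no residues shared by all ensemble members")
    coords = np.stack(
        [s.coords()[[ix[k] for k in keys]] for s, ix in zip(ensemble, indices)]
    )
    return keys, coords, dropped


def extreme_pair(aligned: Sequence[Structure]) -> tuple[int, int]:
    """The two most distinct conformations: the pair maximising global Cα RMSD.

    Exhaustive over all pairs; ties break to the lexicographically first (i, j).
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 models")
    _, coords, _ = _shared_ca(aligned)
    best = (0, 1)
    best_rmsd = -1.0
    for i in range(len(aligned)):
        for j in range(i + 1, len(aligned)):
            rmsd = float(np.sqrt(np.mean(np.sum((coords[i] - coords[j]) ** 2, axis=1))))
            if rmsd > best_rmsd + 1e-12:
                best_rmsd = rmsd
                best = (i, j)
    return best


def flexibility_profile(
    aligned: Sequence[Structure],
    mode: str = "ensemble_rmsd",
    reference_index: int = 0,
) -> FlexibilityProfile:
    """Per-residue Cα deviation across an aligned ensemble.

    ``extreme_pair``: deviation between the two most distinct conformations,
    matching the convention of colouring the reference against the model with
    maximum deviation.  ``ensemble_rmsd``: root-mean-square deviation from the
    per-residue ensemble mean.  Residues missing from any member are dropped
    and reported.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 models")
    if mode not in ("extreme_pair", "ensemble_rmsd"):
        raise ValueError(f"unknown mode {mode!r}")
    keys, coords, dropped = _shared_ca(aligned)
    if mode == "extreme_pair":
        i, j = extreme_pair(aligned)
        dev = np.linalg.norm(coords[i] - coords[j], axis=1)
    else:
        mean = coords.mean(axis=0)
        dev = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    values = {k: float(v) for k, v in zip(keys, dev)}
    return FlexibilityProfile(values, mode=mode, reference=reference_index, dropped=dropped)


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (normalised) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    k = axis / n
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def angle_axis_of(R: np.ndarray, tol: float = 1e-6) -> tuple[float, np.ndarray]:
    """Angle (degrees, in [0, 180]) and right-handed unit axis of a rotation.

    Quaternion-based extraction, which stays well-conditioned at the 0° and
    180° boundaries where the arccos-of-trace formula loses precision.
    """
    R = np.asarray(R, dtype=float)
    c = (float(np.trace(R)) - 1.0) / 2.0
    if c > 1.0 + tol or c < -1.0 - tol:
        raise ValueError(f"invalid rotation trace {np.trace(R)}")
    rotvec = Rotation.from_matrix(R).as_rotvec()
    angle_rad = float(np.linalg.norm(rotvec))
    if angle_rad < 1e-12:  # axis undefined at 0°: +z by convention
        return 0.0, np.array([0.0, 0.0, 1.0])
    return float(np.degrees(angle_rad)), rotvec / angle_rad


def rotation_between(
    a: Structure,
    b: Structure,
    ref_sel: Selection | None,
    mobile_sel: Selection,
    chain_map: Mapping[str, str | Sequence[str]],
    center_mode: str = "none",
) -> HingeMeasurement:
    """Rotation of a mobile domain between two conformations.

    The structures are first superposed on ``ref_sel`` (Cα); the rotation is
    then the Kabsch rotation over ``mobile_sel``.  With an empty/None
    ``ref_sel`` and ``center_mode='centroid'`` the mobile domains are instead
    compared about their centroids (translation discarded), the convention
    used when relating domains centred on one another.
    """
    if center_mode not in ("none", "centroid"):
        raise ValueError(f"unknown center_mode {center_mode!r}")
    keys_a, xyz_a = _core_ca(a, mobile_sel, chain_map)
    keys_b, xyz_b = _core_ca(b, mobile_sel, chain_map)
    if keys_a != keys_b:
        raise ValueError("mobile selection resolves to different residue sets")
    if ref_sel is not None and ref_sel.terms:
        rka, ra = _core_ca(a, ref_sel, chain_map)
        rkb, rb = _core_ca(b, ref_sel, chain_map)
        if rka != rkb:
            raise ValueError("reference selection resolves to different residue sets")
        t_ref, _ = kabsch(rb, ra)
        xyz_b = t_ref.apply(xyz_b)
    elif center_mode != "centroid":
        raise ValueError("ref_sel is required unless center_mode='centroid'")
    transform, rmsd = kabsch(xyz_b, xyz_a)
    angle, axis = angle_axis_of(transform.rotation)
    return HingeMeasurement(
        angle_deg=angle,
        axis=axis,
        ref_selection=ref_sel,
        mobile_selection=mobile_sel,
        residual_rmsd=rmsd,
    )


def splice_composite(
    recipe: SpliceRecipe,
    models: Mapping[str, Structure],
    chain_map: Mapping[str, str | Sequence[str]],
    placements: Mapping[str, RigidTransform] | None = None,
) -> Structure:
    """Merge complementary residue ranges from several models into one.

    Each splice contributes the residues of its selection from its source
    model, rigidly transformed by that model's placement (identity when
    absent).  Spliced residue sets must be pairwise disjoint.  Deletions are
    applied afterwards; deleting a residue that was never spliced only warns.
    """
    placements = dict(placements or {})
    cmap = normalize_chain_map(chain_map)
    taken: dict[tuple[str, int, str], str] = {}
    out_atoms: list = []
    for model_id, sel in recipe.splices:
        if model_id not in models:
            raise KeyError(f"source model {model_id!r} not provided")
        src = models[model_id]
        placement = placements.get(model_id, RigidTransform.identity())
        placed = transform_structure(src, placement)
        sel_all = dataclasses.replace(sel, atom_filter="all_atoms")
        idx, _missing = resolve_selection(placed, sel_all, cmap)
        atoms = placed.atoms()
        clashes = sorted(
            {atoms[i].residue_key for i in idx if atoms[i].residue_key in taken}
        )
        if clashes:
            raise ValueError(f"overlapping splices at residues: {clashes}")
        for i in idx:
            taken[atoms[i].residue_key] = model_id
            out_atoms.append(atoms[i])
    delete_keys: set[tuple[str, int]] = set()
    for sel in recipe.deletions:
        for sub, start, end in sel.terms:
            for chain_id in cmap[sub]:
                for res_seq in range(start, end + 1):
                    delete_keys.add((chain_id, res_seq))
    present = {(a.chain_id, a.res_seq) for a in out_atoms}
    for key in sorted(delete_keys - present):
        warnings.warn(f"deletion of non-spliced residue {key}", stacklevel=2)
    out_atoms = [a for a in out_atoms if (a.chain_id, a.res_seq) not in delete_keys]
    if not out_atoms:
        raise ValueError("composite model is empty after deletions")
    out_atoms.sort(key=lambda a: a.atom_key)
    return Structure([out_atoms], name="composite")
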