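"""Seeded generators for helix-bundle structures, conformational ensembles,
crosslink tables, and simulated maps.

The generators emulate the statistical structure the analysis assumes about a
coiled-coil HAUS-like complex: multi-chain α-helical bundles, a two-state
hinge of known angle (the clamp motion), ensembles with a rigid core and
flexible periphery, and a BS3-style residue-pair crosslink table with planted
satisfied/violated links, sub-threshold decoys, and duplicate rows.  Every
generator records its ground truth so pipeline recovery of the planted
parameters can be asserted exactly.

All randomness flows through :func:`numpy.random.default_rng` (PCG64), so a
fixed seed reproduces outputs bit-for-bit across platforms.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import HingeMeasurement, rotation_matrix
from .structio import AtomRecord, Structure
from .xlink import CrosslinkRecord, CrosslinkSet

__all__ = [
    "BundleSpec",
    "HingeSpec",
    "FlexSpec",
    "CrosslinkSpec",
    "default_chain_map",
    "make_bundle",
    "make_hinge_ensemble",
    "make_flex_ensemble",
    "make_crosslinks",
    "sinusoid_profile",
    "step_profile",
]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclasses.dataclass
class BundleSpec:
    """An idealised α-helical bundle: ``n_chains`` straight helices on a circle.

    ``rise`` (Å/residue) and ``twist`` (deg/residue) are the canonical α-helix
    values; ``spacing`` is the distance between adjacent helix axes.
    """

    n_chains: int = 8
    residues_per_chain: int = 150
    rise: float = 1.5
    twist: float = 100.0
    spacing: float = 12.0
    helix_radius: float = 2.3

    def __post_init__(self):
        if self.n_chains < 1 or self.residues_per_chain < 1:
            raise ValueError("bundle dimensions must be positive")
        if self.rise <= 0 or self.spacing <= 0 or self.helix_radius <= 0:
            raise ValueError("bundle geometry parameters must be positive")


@dataclasses.dataclass
class HingeSpec:
    """Two-state hinge: residues past ``split_residue`` rotate by ``angle_deg``
    about ``axis`` through the split-residue Cα of the first chain."""

    split_residue: int = 75
    angle_deg: float = 23.0
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if np.linalg.norm(self.axis) == 0:
            raise ValueError("hinge axis must be non-zero")


@dataclasses.dataclass
class FlexSpec:
    """Ensemble of ``n_models`` copies with per-residue Gaussian displacements.

    ``amplitude`` (length ``residues_per_chain``) is the RMS displacement
    magnitude per residue in Å: displacement = amplitude/√3 × N(0, I₃), so the
    expected 3D displacement norm² equals amplitude².
    """

    n_models: int = 25
    amplitude: Sequence[float] | None = None

    def __post_init__(self):
        if self.n_models < 2:
            raise ValueError("need at least 2 models")
        if self.amplitude is not None and np.any(np.asarray(self.amplitude) < 0):
            raise ValueError("amplitudes must be non-negative")


@dataclasses.dataclass
class CrosslinkSpec:
    """Planted crosslink table emulating a deduplicated-then-filtered export.

    Defaults plant the study conditions: 190 unique above-threshold pairs
    (173 satisfied at 30 Å, 17 violated; intramolecular fraction 88/190),
    plus sub-threshold decoy pairs and duplicate rows at strictly lower score.
    """

    n_satisfied: int = 173
    n_violated: int = 17
    d_max: float = 30.0
    intra_fraction: float = 88.0 / 190.0
    n_decoys: int = 40
    n_duplicates: int = 20
    score_min: float = 250.0
    score_mu: float = 3.0  # lognormal params for the above-threshold offset
    score_sigma: float = 0.8

    def __post_init__(self):
        if self.n_satisfied < 0 or self.n_violated < 0:
            raise ValueError("link counts must be non-negative")
        if not 0.0 <= self.intra_fraction <= 1.0:
            raise ValueError("intra_fraction must be in [0, 1]")


def default_chain_map(n_chains: int) -> dict[str, str]:
    """Subunit-style names S1..Sn mapped onto the generated chain ids."""
    return {f"S{i + 1}": _CHAIN_IDS[i] for i in range(n_chains)}


def make_bundle(spec: BundleSpec | None = None) -> Structure:
    """Deterministic ideal Cα-trace helix bundle.

    Chains (ids A, B, ...) are straight α-helices along z arranged on a circle
    whose radius puts adjacent helix axes ``spacing`` apart.
    """
    spec = spec or BundleSpec()
    if spec.n_chains > len(_CHAIN_IDS):
        raise ValueError(f"at most {len(_CHAIN_IDS)} chains supported")
    if spec.n_chains == 1:
        centers = [np.zeros(2)]
    else:
        ring_r = spec.spacing / (2.0 * np.sin(np.pi / spec.n_chains))
        centers = [
            ring_r
            * np.array(
                [np.cos(2 * np.pi * c / spec.n_chains), np.sin(2 * np.pi * c / spec.n_chains)]
            )
            for c in range(spec.n_chains)
        ]
    atoms: list[AtomRecord] = []
    for c in range(spec.n_chains):
        cx, cy = centers[c]
        phase = np.deg2rad(spec.twist) * np.arange(spec.residues_per_chain)
        # stagger chains so inter-chain contacts are not perfectly in register
        phase = phase + 2 * np.pi * c / spec.n_chains
        for i in range(spec.residues_per_chain):
            x = cx + spec.helix_radius * np.cos(phase[i])
            y = cy + spec.helix_radius * np.sin(phase[i])
            z = i * spec.rise
            atoms.append(
                AtomRecord(
                    chain_id=_CHAIN_IDS[c],
                    res_seq=i + 1,
                    icode="",
                    res_name="ALA",
                    atom_name="CA",
                    element="C",
                    pos=(float(x), float(y), float(z)),
                )
            )
    return Structure([atoms], name="bundle")


def make_hinge_ensemble(
    bundle: BundleSpec | None = None,
    hinge: HingeSpec | None = None,
) -> tuple[list[Structure], HingeMeasurement]:
    """Two-state ensemble with a known hinge rotation.

    Model 2 equals model 1 with all residues past the split rotated as one
    rigid body by the stated angle about the stated axis through the
    split-residue Cα of the first chain.  The returned measurement is the
    applied (model 1 -> model 2) rotation; measuring model 2 against model 1
    recovers it exactly.
    """
    bundle = bundle or BundleSpec()
    hinge = hinge or HingeSpec()
    if not 1 < hinge.split_residue < bundle.residues_per_chain:
        raise ValueError("split residue must be interior to a chain")
    base = make_bundle(bundle)
    axis = np.asarray(hinge.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    R = rotation_matrix(axis, hinge.angle_deg)
    pivot = np.array(
        next(
            a.pos
            for a in base.atoms()
            if a.chain_id == _CHAIN_IDS[0] and a.res_seq == hinge.split_residue
        )
    )
    coords = base.coords()
    moved = coords.copy()
    mobile = np.array([a.res_seq > hinge.split_residue for a in base.atoms()])
    moved[mobile] = (coords[mobile] - pivot) @ R.T + pivot
    truth = HingeMeasurement(
        angle_deg=float(hinge.angle_deg) % 360.0
        if hinge.angle_deg <= 180
        else 360.0 - hinge.angle_deg,
        axis=axis if hinge.angle_deg > 0 else np.array([0.0, 0.0, 1.0]),
        ref_selection=None,
        mobile_selection=None,
        residual_rmsd=0.0,
    )
    return [base, base.with_coords(moved)], truth


def sinusoid_profile(n_residues: int, max_amp: float = 3.0, periods: float = 2.0) -> np.ndarray:
    """Smooth planted amplitude profile in [0, max_amp]."""
    x = np.linspace(0, 2 * np.pi * periods, n_residues)
    return 0.5 * max_amp * (1.0 - np.cos(x))


def step_profile(
    n_residues: int, core_amp: float = 0.0, term_amp: float = 3.0, n_term: int = 20
) -> np.ndarray:
    """Rigid core with flexible termini of ``n_term`` residues each."""
    amp = np.full(n_residues, core_amp, dtype=float)
    amp[:n_term] = term_amp
    amp[-n_term:] = term_amp
    return amp


def make_flex_ensemble(
    bundle: BundleSpec | None = None,
    flex: FlexSpec | None = None,
    seed: int = 0,
) -> tuple[list[Structure], np.ndarray]:
    """Ensemble of bundles with planted per-residue flexibility.

    Each model adds zero-mean Gaussian Cα displacements whose RMS magnitude
    per residue follows the amplitude profile (default: sinusoid).  Returns
    the ensemble and the planted profile.
    """
    bundle = bundle or BundleSpec()
    flex = flex or FlexSpec()
    amp = (
        np.asarray(flex.amplitude, dtype=float)
        if flex.amplitude is not None
        else sinusoid_profile(bundle.residues_per_chain)
    )
    if amp.shape != (bundle.residues_per_chain,):
        raise ValueError("amplitude profile length must equal residues_per_chain")
    rng = np.random.default_rng(seed)
    base = make_bundle(bundle)
    per_atom_amp = np.array([amp[a.res_seq - 1] for a in base.atoms()])
    coords = base.coords()
    ensemble = []
    for _ in range(flex.n_models):
        noise = rng.standard_normal(coords.shape) * (per_atom_amp[:, None] / np.sqrt(3.0))
        ensemble.append(base.with_coords(coords + noise))
    return ensemble, amp


def _plan_counts(spec: CrosslinkSpec) -> dict[str, int]:
    total = spec.n_satisfied + spec.n_violated
    n_intra = int(round(spec.intra_fraction * total))
    n_intra_sat = min(int(round(spec.intra_fraction * spec.n_satisfied)), n_intra)
    n_intra_vio = n_intra - n_intra_sat
    if n_intra_vio > spec.n_violated:
        n_intra_vio = spec.n_violated
        n_intra_sat = n_intra - n_intra_vio
    return {
        "intra_satisfied": n_intra_sat,
        "intra_violated": n_intra_vio,
        "inter_satisfied": spec.n_satisfied - n_intra_sat,
        "inter_violated": spec.n_violated - n_intra_vio,
    }


def make_crosslinks(
    s: Structure,
    spec: CrosslinkSpec | None = None,
    seed: int = 0,
) -> tuple[CrosslinkSet, pd.DataFrame]:
    """Sample a crosslink table with planted satisfaction labels.

    Satisfied pairs have Cα–Cα distance ≤ ``d_max`` and violated pairs > it,
    split intra/inter-molecularly per ``intra_fraction``.  Planted records
    score strictly above ``score_min`` (a shifted lognormal); decoys score
    strictly below it; duplicates repeat planted pairs at a strictly lower
    score.  Residue chemistry is relabelled K on one end and K/S/T/Y on the
    other in the table only (coordinates are untouched).

    Returns the record set (shuffled) and a ground-truth table with one row
    per emitted record (pair, distance, label, planted flag).
    """
    spec = spec or CrosslinkSpec()
    rng = np.random.default_rng(seed)
    ca = s.ca_index()
    keys = sorted(ca)
    coords = s.coords()[[ca[k] for k in keys]]
    chains = np.array([k[0] for k in keys])
    res = np.array([k[1] for k in keys])
    n = len(keys)
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    same = chains[iu] == chains[ju]
    near = d <= spec.d_max
    pools = {
        "intra_satisfied": np.flatnonzero(same & near),
        "intra_violated": np.flatnonzero(same & ~near),
        "inter_satisfied": np.flatnonzero(~same & near),
        "inter_violated": np.flatnonzero(~same & ~near),
    }
    plan = _plan_counts(spec)
    for cat, want in plan.items():
        if want > len(pools[cat]):
            raise ValueError(
                f"infeasible crosslink counts: {cat} wants {want}, "
                f"achievable maximum is {len(pools[cat])}"
            )
    chain_to_sub = {c: f"S{i + 1}" for i, c in enumerate(sorted(set(chains)))}

    chosen: list[tuple[int, str, bool]] = []  # (pair index, label, planted)
    used = set()
    for cat in ("intra_satisfied", "intra_violated", "inter_satisfied", "inter_violated"):
        pick = rng.choice(pools[cat], size=plan[cat], replace=False)
        label = "satisfied" if cat.endswith("satisfied") else "violated"
        for p in pick:
            chosen.append((int(p), label, True))
            used.add(int(p))
    # sub-threshold decoys: any unused pair
    free = np.array(sorted(set(range(len(iu))) - used))
    if spec.n_decoys > len(free):
        raise ValueError("infeasible decoy count")
    for p in rng.choice(free, size=spec.n_decoys, replace=False):
        chosen.append((int(p), "decoy", False))

    def record_for(pair_idx: int, score: float, planted: bool, label: str):
        i, j = int(iu[pair_idx]), int(ju[pair_idx])
        aa2 = str(rng.choice(list("KSTY")))
        rec = CrosslinkRecord(
            protein1=chain_to_sub[chains[i]],
            res1=int(res[i]),
            protein2=chain_to_sub[chains[j]],
            res2=int(res[j]),
            aggregate_score=float(score),
            aa1="K",
            aa2=aa2,
            n_spectra=int(rng.integers(1, 8)),
            replicate=f"R{int(rng.integers(1, 4))}",
        )
        truth = {
            "protein1": rec.protein1,
            "res1": rec.res1,
            "protein2": rec.protein2,
            "res2": rec.res2,
            "distance": float(d[pair_idx]),
            "label": label,
            "planted": planted,
            "score": float(score),
        }
        return rec, truth

    records: list[CrosslinkRecord] = []
    truth_rows: list[dict] = []
    planted_records: list[int] = []
    for pair_idx, label, planted in chosen:
        if planted:
            score = spec.score_min + float(rng.lognormal(spec.score_mu, spec.score_sigma))
        else:
            score = float(rng.uniform(25.0, spec.score_min - 1e-6))
        rec, truth = record_for(pair_idx, score, planted, label)
        records.append(rec)
        truth_rows.append(truth)
        if planted:
            planted_records.append(len(records) - 1)
    if spec.n_duplicates > len(planted_records):
        raise ValueError("more duplicates requested than planted records")
    dup_of = rng.choice(planted_records, size=spec.n_duplicates, replace=False)
    for k in dup_of:
        orig = records[int(k)]
        dup = dataclasses.replace(
            orig,
            aggregate_score=float(orig.aggregate_score * rng.uniform(0.3, 0.9)),
            replicate=f"R{int(rng.integers(1, 4))}",
        )
        records.append(dup)
        truth_rows.append(
            {
                "protein1": dup.protein1,
                "res1": dup.res1,
                "protein2": dup.protein2,
                "res2": dup.res2,
                "distance": np.nan,
                "label": "duplicate",
                "planted": False,
                "score": dup.aggregate_score,
            }
        )
    perm = rng.permutation(len(records))
    records = [records[i] for i in perm]
    truth = pd.DataFrame([truth_rows[i] for i in perm]).reset_index(drop=True)
    return CrosslinkSet(records), truth
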