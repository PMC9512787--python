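"""Config-driven orchestration of the full analysis.

A run configuration (YAML or an equivalent dict) names the input models,
crosslink table, chain map, selections, and stage parameters; each stage can
be omitted.  Stages run in a fixed order — ensemble alignment and flexibility,
crosslink dedup/filter/map/validate, violation–flexibility association,
density fitting and coverage, composite splicing, hinge measurement — and the
numeric results are collected into a single report that is byte-stable for
fixed inputs and seeds (no timestamps enter the report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .density import SIGMA_FACTOR, coverage, read_map, rigid_fit, simulate_map
from .geometry import (
    FlexibilityProfile,
    SpliceRecipe,
    align_ensemble,
    extreme_pair,
    flexibility_profile,
    rotation_between,
    splice_composite,
)
from .structio import Selection, read_structure, write_structure
from .xlink import (
    MappedCrosslink,
    ValidationParams,
    dedup_and_filter,
    flexibility_association,
    map_crosslinks,
    read_crosslinks,
    validate_crosslinks,
)

__all__ = [
    "load_reference_config",
    "reference_selection",
    "selection_from_dict",
    "RunConfig",
    "run_analysis",
    "summarize_pairs",
]


def load_reference_config() -> dict:
    """The shipped selection constants and validation defaults."""
    text = resources.files("augmintools").joinpath("data/reference_selections.yaml").read_text()
    return yaml.safe_load(text)


def selection_from_dict(d: Mapping[str, Sequence[Sequence[int]]], atom_filter: str = "CA_only") -> Selection:
    """Build a Selection from ``{subunit: [[start, end], ...]}``."""
    terms = []
    for sub, ranges in d.items():
        for start, end in ranges:
            terms.append((sub, int(start), int(end)))
    return Selection(tuple(terms), atom_filter=atom_filter)


def reference_selection(name: str, atom_filter: str = "CA_only") -> Selection:
    """A named selection from the shipped constants (e.g. ``n_clamp``)."""
    cfg = load_reference_config()
    if name not in cfg["selections"]:
        raise KeyError(f"no reference selection named {name!r}")
    return selection_from_dict(cfg["selections"][name], atom_filter=atom_filter)


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration; see :func:`run_analysis` for stage keys."""

    chain_map: dict
    stages: dict
    seed: int = 0
    outdir: str = "augmin_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        if "chain_map" not in raw:
            raise ValueError("config must declare a chain_map")
        known = {"ensemble", "crosslinks", "density", "composite", "hinge"}
        stages = {k: raw[k] for k in known if k in raw}
        return cls(
            chain_map=dict(raw["chain_map"]),
            stages=stages,
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "augmin_run")),
        )

    def digest(self) -> str:
        payload = json.dumps(
            {"chain_map": self.chain_map, "stages": self.stages, "seed": self.seed},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def summarize_pairs(mapped: Sequence[MappedCrosslink]) -> pd.DataFrame:
    """Symmetric per-subunit-pair crosslink count table over all records.

    Each link counts once for its unordered subunit pair (intra links sit on
    the diagonal), so the sum over unordered pairs equals the total record
    count.
    """
    subunits = sorted(
        {m.record.protein1 for m in mapped} | {m.record.protein2 for m in mapped}
    )
    table = pd.DataFrame(0, index=subunits, columns=subunits, dtype=int)
    for m in mapped:
        p1, p2 = sorted([m.record.protein1, m.record.protein2])
        table.loc[p1, p2] += 1
        if p1 != p2:
            table.loc[p2, p1] += 1
    return table


def _validation_params(d: Mapping | None) -> ValidationParams:
    d = d or {}
    ref = load_reference_config()["validation"]
    return ValidationParams(
        d_max=float(d.get("d_max", ref["d_max"])),
        score_min=float(d.get("score_min", ref["score_min"])),
        score_norm_factor=float(d.get("score_norm_factor", ref["score_norm_factor"])),
    )


def _round_summary(report: dict) -> dict:
    """Reporting conventions: percentages to integers, angles to 0.1 degree,
    distances/RMSDs to 0.01 Å.  Full precision stays in the main report."""
    out = {}
    if "crosslinks" in report:
        xs = report["crosslinks"]
        out["crosslinks"] = {
            "n_after_dedup_filter": xs["n_after_dedup_filter"],
            "n_intra": xs["n_intra"],
            "n_inter": xs["n_inter"],
            "percent_satisfied": None
            if xs["percent_satisfied"] is None
            else int(round(xs["percent_satisfied"])),
        }
    if "hinge" in report:
        out["hinge_angle_deg"] = round(report["hinge"]["angle_deg"], 1)
    if "ensemble" in report:
        out["ensemble_per_model_rmsd"] = [
            round(v, 2) for v in report["ensemble"]["per_model_rmsd"]
        ]
    if "density" in report:
        d = {}
        if "fit_cc" in report["density"]:
            d["fit_cc"] = round(report["density"]["fit_cc"], 3)
        if "coverage_fraction" in report["density"]:
            d["coverage_fraction"] = round(report["density"]["coverage_fraction"], 3)
        out["density"] = d
    return out


def run_analysis(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and write the report bundle.

    Stage configuration keys (all optional):

    ``ensemble``
        ``paths`` (list of model files), ``core`` (selection dict),
        ``reference_index``, ``modes`` (flexibility modes).
    ``crosslinks``
        ``table`` (residue-pair TSV/CSV), ``model`` (structure to validate
        against), ``params`` (d_max / score_min / score_norm_factor),
        ``association`` (q, n_perm; runs when the ensemble stage produced a
        profile).
    ``density``
        ``model``, optional ``map`` (simulated from the model when absent),
        ``resolution``, optional ``fit`` (search parameters), optional
        ``contour`` for coverage.
    ``composite``
        ``models`` (id -> path), ``splices`` (list of {model, select}),
        ``deletions`` (list of selection dicts), ``output``.
    ``hinge``
        ``model_a``, ``model_b``, ``ref`` / ``mobile`` selection dicts or
        reference-selection names, ``center_mode``.

    Any stage failure aborts the run naming the stage; the partial report is
    still written.
    """
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "config_sha256": cfg.digest(),
            "seed": cfg.seed,
        }
    }
    profile: FlexibilityProfile | None = None
    try:
        if "ensemble" in cfg.stages:
            report["ensemble"] = _stage_ensemble(cfg, outdir)
            profile = report["ensemble"].pop("_profile")
        if "crosslinks" in cfg.stages:
            report["crosslinks"] = _stage_crosslinks(cfg, outdir, profile)
        if "density" in cfg.stages:
            report["density"] = _stage_density(cfg)
        if "composite" in cfg.stages:
            report["composite"] = _stage_composite(cfg, outdir)
        if "hinge" in cfg.stages:
            report["hinge"] = _stage_hinge(cfg)
    except Exception as exc:
        failed = {"failed_stage": _current_stage(report), "error": str(exc)}
        report["aborted"] = failed
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise RuntimeError(f"stage {failed['failed_stage']!r} failed: {exc}") from exc
    report["summary"] = _round_summary(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _current_stage(report: dict) -> str:
    done = [k for k in ("ensemble", "crosslinks", "density", "composite", "hinge") if k in report]
    order = ["ensemble", "crosslinks", "density", "composite", "hinge"]
    for name in order:
        if name not in done:
            return name
    return "unknown"


def _stage_ensemble(cfg: RunConfig, outdir: Path) -> dict:
    sc = cfg.stages["ensemble"]
    ensemble = [read_structure(p) for p in sc["paths"]]
    core = selection_from_dict(sc["core"])
    ref_idx = int(sc.get("reference_index", 0))
    aligned, rmsds = align_ensemble(ensemble, core, cfg.chain_map, reference_index=ref_idx)
    modes = sc.get("modes", ["ensemble_rmsd"])
    profiles = {}
    primary: FlexibilityProfile | None = None
    for mode in modes:
        prof = flexibility_profile(aligned, mode=mode, reference_index=ref_idx)
        profiles[mode] = {
            f"{c}:{r}{ic}": round(v, 4) for (c, r, ic), v in sorted(prof.values.items())
        }
        if primary is None:
            primary = prof
    pd.DataFrame(
        [
            {"mode": mode, "residue": key, "deviation": val}
            for mode, d in profiles.items()
            for key, val in d.items()
        ]
    ).to_csv(outdir / "flexibility_profile.tsv", sep="\t", index=False)
    i, j = extreme_pair(aligned)
    return {
        "n_models": len(aligned),
        "per_model_rmsd": [float(r) for r in rmsds],
        "extreme_pair": [i, j],
        "profiles": profiles,
        "_profile": primary,
    }


def _stage_crosslinks(cfg: RunConfig, outdir: Path, profile: FlexibilityProfile | None) -> dict:
    sc = cfg.stages["crosslinks"]
    params = _validation_params(sc.get("params"))
    xs = read_crosslinks(sc["table"], columns=sc.get("columns"))
    filtered = dedup_and_filter(xs, params)
    model = read_structure(sc["model"])
    mapped = map_crosslinks(filtered, model, cfg.chain_map, d_max=params.d_max)
    rep = validate_crosslinks(mapped, params)
    rep.export.to_csv(outdir / "crosslinks_validated.tsv", sep="\t", index=False)
    rep.pair_matrix.to_csv(outdir / "crosslink_pair_matrix.tsv", sep="\t")
    pairs = summarize_pairs(mapped)
    pairs.to_csv(outdir / "crosslink_pair_counts.tsv", sep="\t")
    out = {
        "n_input_rows": len(xs),
        "n_after_dedup_filter": len(filtered),
        "n_intra": sum(1 for r in filtered if r.is_intra),
        "n_inter": sum(1 for r in filtered if not r.is_intra),
        **rep.to_dict(),
        "pair_counts": {
            f"{a}-{b}": int(pairs.loc[a, b])
            for a in pairs.index
            for b in pairs.columns
            if a <= b and pairs.loc[a, b]
        },
    }
    assoc_cfg = sc.get("association")
    if assoc_cfg is not None and profile is not None:
        stat = flexibility_association(
            mapped,
            profile,
            q=float(assoc_cfg.get("q", 0.8)),
            n_perm=int(assoc_cfg.get("n_perm", 999)),
            seed=cfg.seed,
        )
        out["association"] = {
            "observed_fraction": stat.observed_fraction,
            "p_value": stat.p_value,
            "n_violated": stat.n_violated,
            "defined": stat.defined,
            "note": stat.note,
        }
    return out


def _stage_density(cfg: RunConfig) -> dict:
    sc = cfg.stages["density"]
    model = read_structure(sc["model"])
    resolution = float(sc.get("resolution", load_reference_config()["density"]["resolution"]))
    sigma_factor = float(sc.get("sigma_factor", SIGMA_FACTOR))
    if "map" in sc and sc["map"]:
        target = read_map(sc["map"], voxel_size_override=sc.get("voxel_size_override"))
    else:
        target = simulate_map(model, resolution, sigma_factor=sigma_factor)
    out: dict = {"resolution": resolution}
    if sc.get("fit", None) is not None:
        fit_cfg = sc["fit"] or {}
        result = rigid_fit(
            model,
            target,
            resolution,
            search=fit_cfg.get("search"),
            sigma_factor=sigma_factor,
        )
        out["fit_cc"] = result.cc
        out["fit_n_evaluations"] = result.n_evaluations
    if "contour" in sc:
        frac, _flags = coverage(model, target, float(sc["contour"]))
        out["coverage_fraction"] = frac
    return out


def _stage_composite(cfg: RunConfig, outdir: Path) -> dict:
    sc = cfg.stages["composite"]
    models = {mid: read_structure(path) for mid, path in sc["models"].items()}
    splices = [
        (item["model"], selection_from_dict(item["select"], atom_filter="all_atoms"))
        for item in sc["splices"]
    ]
    deletions = [selection_from_dict(d) for d in sc.get("deletions", [])]
    recipe = SpliceRecipe(splices=splices, deletions=deletions)
    composite = splice_composite(recipe, models, cfg.chain_map)
    out_path = outdir / sc.get("output", "composite.pdb")
    write_structure(composite, out_path)
    return {
        "n_atoms": composite.n_atoms(),
        "n_residues": len(composite.residue_keys()),
        "output": out_path.name,
    }


def _stage_hinge(cfg: RunConfig) -> dict:
    sc = cfg.stages["hinge"]
    a = read_structure(sc["model_a"])
    b = read_structure(sc["model_b"])

    def _sel(value) -> Selection | None:
        if value is None:
            return None
        if isinstance(value, str):
            return reference_selection(value)
        return selection_from_dict(value)

    measurement = rotation_between(
        a,
        b,
        _sel(sc.get("ref")),
        _sel(sc["mobile"]),
        cfg.chain_map,
        center_mode=sc.get("center_mode", "none"),
    )
    return {
        "angle_deg": measurement.angle_deg,
        "axis": [float(x) for x in measurement.axis],
        "residual_rmsd": measurement.residual_rmsd,
    }
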