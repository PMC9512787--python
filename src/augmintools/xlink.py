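"""Crosslinking-MS residue-pair tables: filtering, mapping, validation.

The pipeline starts from an exported residue-pair table (one row per
identified crosslink site, possibly with duplicate entries from replicate
searches).  Records are deduplicated by keeping the best-scoring copy of each
unordered residue pair, filtered at a strict aggregate-score threshold, mapped
onto a structure as Cα–Cα distances, and validated against the
crosslinker-compatible distance threshold (30 Å for BS3).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import FlexibilityProfile
from .structio import Structure, normalize_chain_map

__all__ = [
    "CrosslinkRecord",
    "CrosslinkSet",
    "MappedCrosslink",
    "ValidationParams",
    "SatisfactionReport",
    "AssociationStat",
    "read_crosslinks",
    "write_crosslinks",
    "dedup_and_filter",
    "map_crosslinks",
    "validate_crosslinks",
    "flexibility_association",
]

DEFAULT_COLUMNS = {
    "protein1": "protein1",
    "res1": "res1",
    "protein2": "protein2",
    "res2": "res2",
    "score": "score",
}


@dataclasses.dataclass(frozen=True)
class CrosslinkRecord:
    """One residue-pair crosslink with its aggregate confidence score.

    The aggregate score is the sum of spectrum-level scores (-ln of the search
    expectation value) over all spectra supporting the pair.  BS3 chemistry
    constrains one end to lysine and the other to K/S/T/Y.
    """

    protein1: str
    res1: int
    protein2: str
    res2: int
    aggregate_score: float
    aa1: str = "K"
    aa2: str = "K"
    n_spectra: int = 1
    replicate: str = ""

    def __post_init__(self):
        if self.res1 < 1 or self.res2 < 1:
            raise ValueError("residue numbers must be >= 1")
        if self.aggregate_score < 0:
            raise ValueError("aggregate score must be non-negative")

    @property
    def pair_key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Unordered residue-pair identity."""
        ends = sorted([(self.protein1, self.res1), (self.protein2, self.res2)])
        return (ends[0], ends[1])

    @property
    def is_intra(self) -> bool:
        return self.protein1 == self.protein2


class CrosslinkSet:
    """An ordered collection of crosslink records (duplicates permitted)."""

    def __init__(self, records: Sequence[CrosslinkRecord]):
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein1": r.protein1,
                    "res1": r.res1,
                    "aa1": r.aa1,
                    "protein2": r.protein2,
                    "res2": r.res2,
                    "aa2": r.aa2,
                    "score": r.aggregate_score,
                    "n_spectra": r.n_spectra,
                    "replicate": r.replicate,
                }
                for r in self.records
            ]
        )


@dataclasses.dataclass
class MappedCrosslink:
    """A record resolved to model coordinates with its Cα–Cα distance."""

    record: CrosslinkRecord
    coord1: tuple[float, float, float] | None
    coord2: tuple[float, float, float] | None
    chain1: str | None
    chain2: str | None
    distance: float | None  # Å, None when unmapped
    status: str  # "satisfied" | "violated" | "unmapped"
    link_type: str  # "intra" | "inter"


@dataclasses.dataclass
class ValidationParams:
    """Validation constants: 30 Å Cα–Cα threshold, strict score > 250,
    exported scores divided by 10."""

    d_max: float = 30.0
    score_min: float = 250.0
    score_norm_factor: float = 10.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if self.score_min < 0:
            raise ValueError("score_min must be non-negative")


@dataclasses.dataclass
class SatisfactionReport:
    """Counts and per-subunit-pair matrix from distance-threshold validation."""

    n_total: int
    n_mapped: int
    n_satisfied: int
    n_violated: int
    n_unmapped: int
    percent_satisfied: float | None  # None when nothing mapped
    pair_matrix: pd.DataFrame  # unordered subunit pairs, mapped links only
    export: pd.DataFrame  # per-link table with normalised scores
    d_max: float

    @property
    def percent_satisfied_int(self) -> int | None:
        return None if self.percent_satisfied is None else int(round(self.percent_satisfied))

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_mapped": self.n_mapped,
            "n_satisfied": self.n_satisfied,
            "n_violated": self.n_violated,
            "n_unmapped": self.n_unmapped,
            "percent_satisfied": self.percent_satisfied,
            "percent_satisfied_rounded": self.percent_satisfied_int,
            "d_max": self.d_max,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclasses.dataclass
class AssociationStat:
    """Violated-link vs flexible-residue association with a permutation null."""

    observed_fraction: float | None
    p_value: float | None
    n_violated: int
    n_flexible_residues: int
    quantile: float
    n_perm: int
    defined: bool
    note: str = (
        "statistic and permutation null are a formalisation of a qualitative "
        "observation; see docs/methods.md"
    )


def read_crosslinks(
    path: str | Path,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> CrosslinkSet:
    """Read a delimited residue-pair table.

    ``columns`` maps canonical names (protein1, res1, protein2, res2, score,
    and optionally aa1, aa2, n_spectra, replicate) to the file's header names.
    The delimiter is inferred from the extension when not given (.csv -> comma,
    otherwise tab).  Duplicate rows are permitted at this stage.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = dict(DEFAULT_COLUMNS)
    cols.update({k: v for k, v in (columns or {}).items()})
    for canonical, name in cols.items():
        if name not in df.columns:
            raise ValueError(f"missing mandatory column {name!r} (for {canonical})")
    records: list[CrosslinkRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            res1 = int(row[cols["res1"]])
            res2 = int(row[cols["res2"]])
            score = float(row[cols["score"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i}: non-numeric residue or score ({exc})") from exc
        records.append(
            CrosslinkRecord(
                protein1=str(row[cols["protein1"]]),
                res1=res1,
                protein2=str(row[cols["protein2"]]),
                res2=res2,
                aggregate_score=score,
                aa1=str(row.get("aa1", "K") or "K"),
                aa2=str(row.get("aa2", "K") or "K"),
                n_spectra=int(row.get("n_spectra", 1) or 1),
                replicate=str(row.get("replicate", "") or ""),
            )
        )
    return CrosslinkSet(records)


def write_crosslinks(xs: CrosslinkSet, path: str | Path, sep: str = "\t") -> None:
    xs.to_dataframe().to_csv(path, sep=sep, index=False)


def dedup_and_filter(xs: CrosslinkSet, params: ValidationParams | None = None) -> CrosslinkSet:
    """Keep the best-scoring copy of each unordered residue pair, then apply
    the strict aggregate-score filter (score > score_min).

    Ties keep the first occurrence in input order.  Output is sorted by
    descending score (stable, so equal scores stay in input order).
    """
    params = params or ValidationParams()
    best: dict[tuple, CrosslinkRecord] = {}
    order: dict[tuple, int] = {}
    for i, rec in enumerate(xs):
        key = rec.pair_key
        if key not in best or rec.aggregate_score > best[key].aggregate_score:
            if key not in best:
                order[key] = i
            best[key] = rec
    kept = [
        best[key]
        for key in sorted(order, key=order.get)
        if best[key].aggregate_score > params.score_min
    ]
    kept.sort(key=lambda r: -r.aggregate_score)
    return CrosslinkSet(kept)


def map_crosslinks(
    xs: CrosslinkSet,
    s: Structure,
    chain_map: Mapping[str, str | Sequence[str]],
    d_max: float = 30.0,
    model: int = 0,
) -> list[MappedCrosslink]:
    """Resolve each record to Cα coordinates and a Euclidean distance.

    When a subunit maps to several chains, the chain combination giving the
    minimum distance is used.  Links with either endpoint absent from the
    model are flagged unmapped.
    """
    cmap = normalize_chain_map(chain_map)
    ca = s.ca_index(model)
    coords = s.coords(model)
    by_chain_res: dict[tuple[str, int], int] = {}
    for (chain, res, _icode), idx in ca.items():
        by_chain_res.setdefault((chain, res), idx)
    out: list[MappedCrosslink] = []
    for rec in xs:
        for protein in (rec.protein1, rec.protein2):
            if protein not in cmap:
                raise KeyError(f"unknown protein {protein!r} in crosslink table")
        ends1 = [
            (c, by_chain_res[(c, rec.res1)])
            for c in cmap[rec.protein1]
            if (c, rec.res1) in by_chain_res
        ]
        ends2 = [
            (c, by_chain_res[(c, rec.res2)])
            for c in cmap[rec.protein2]
            if (c, rec.res2) in by_chain_res
        ]
        link_type = "intra" if rec.is_intra else "inter"
        if not ends1 or not ends2:
            out.append(
                MappedCrosslink(rec, None, None, None, None, None, "unmapped", link_type)
            )
            continue
        best = None
        for c1, i1 in ends1:
            for c2, i2 in ends2:
                if c1 == c2 and rec.res1 == rec.res2:
                    continue  # an end cannot crosslink to itself
                d = float(np.linalg.norm(coords[i1] - coords[i2]))
                if best is None or d < best[0]:
                    best = (d, c1, i1, c2, i2)
        if best is None:
            out.append(
                MappedCrosslink(rec, None, None, None, None, None, "unmapped", link_type)
            )
            continue
        d, c1, i1, c2, i2 = best
        status = "satisfied" if d <= d_max else "violated"
        out.append(
            MappedCrosslink(
                rec,
                tuple(coords[i1]),
                tuple(coords[i2]),
                c1,
                c2,
                d,
                status,
                link_type,
            )
        )
    return out


def validate_crosslinks(
    mapped: Sequence[MappedCrosslink],
    params: ValidationParams | None = None,
) -> SatisfactionReport:
    """Distance-threshold validation of mapped crosslinks.

    A link is satisfied when its Cα–Cα distance is within ``d_max``
    (inclusive).  Unmapped links are counted separately and excluded from the
    satisfaction percentage.  The per-pair matrix counts mapped links between
    unordered subunit pairs; the export table carries scores divided by the
    normalisation factor.
    """
    params = params or ValidationParams()
    n_total = len(mapped)
    n_sat = n_vio = n_unmapped = 0
    subunits = sorted(
        {m.record.protein1 for m in mapped} | {m.record.protein2 for m in mapped}
    )
    matrix = pd.DataFrame(0, index=subunits, columns=subunits, dtype=int)
    rows = []
    for m in mapped:
        if m.distance is None:
            status = "unmapped"
            n_unmapped += 1
        elif m.distance <= params.d_max:
            status = "satisfied"
            n_sat += 1
        else:
            status = "violated"
            n_vio += 1
        m.status = status
        if status != "unmapped":
            p1, p2 = sorted([m.record.protein1, m.record.protein2])
            matrix.loc[p1, p2] += 1
            if p1 != p2:
                matrix.loc[p2, p1] += 1
        rows.append(
            {
                "protein1": m.record.protein1,
                "res1": m.record.res1,
                "protein2": m.record.protein2,
                "res2": m.record.res2,
                "score": m.record.aggregate_score,
                "score_normalized": m.record.aggregate_score / params.score_norm_factor,
                "distance": m.distance,
                "status": status,
                "type": m.link_type,
            }
        )
    n_mapped = n_sat + n_vio
    percent = 100.0 * n_sat / n_mapped if n_mapped else None
    return SatisfactionReport(
        n_total=n_total,
        n_mapped=n_mapped,
        n_satisfied=n_sat,
        n_violated=n_vio,
        n_unmapped=n_unmapped,
        percent_satisfied=percent,
        pair_matrix=matrix,
        export=pd.DataFrame(rows),
        d_max=params.d_max,
    )


def flexibility_association(
    mapped: Sequence[MappedCrosslink],
    profile: FlexibilityProfile,
    q: float = 0.8,
    n_perm: int = 999,
    seed: int = 0,
) -> AssociationStat:
    """Do violated crosslinks preferentially touch flexible residues?

    A residue is flexible when its profile value exceeds the ``q``-quantile of
    the profile.  The observed statistic is the fraction of violated links
    with at least one flexible endpoint; the null permutes the
    satisfied/violated labels over mapped links with counts fixed, and
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    threshold = profile.quantile(q)
    flexible = {key for key, v in profile.values.items() if v > threshold}
    flexible_cr = {(chain, res) for chain, res, _ic in flexible}

    usable = [m for m in mapped if m.status in ("satisfied", "violated")]
    touches = np.array(
        [
            ((m.chain1, m.record.res1) in flexible_cr)
            or ((m.chain2, m.record.res2) in flexible_cr)
            for m in usable
        ],
        dtype=bool,
    )
    is_violated = np.array([m.status == "violated" for m in usable], dtype=bool)
    n_violated = int(is_violated.sum())
    if n_violated == 0 or len(usable) == 0:
        return AssociationStat(None, None, n_violated, len(flexible), q, n_perm, False)
    observed = float(touches[is_violated].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(usable))[:n_violated]
        if float(touches[perm].mean()) >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return AssociationStat(observed, p, n_violated, len(flexible), q, n_perm, True)
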