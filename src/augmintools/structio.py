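"""Atomic structure I/O, residue-range selections, and sequence identity.

Structures are stored as flat lists of atom records with author residue
numbering (the numbering printed in structure-deposition records and used
throughout for selections).  Parsing and serialisation of PDB/mmCIF files is
delegated to :mod:`gemmi`; this module only defines the in-memory contract the
rest of the package relies on.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "AtomRecord",
    "Structure",
    "Selection",
    "normalize_chain_map",
    "read_structure",
    "write_structure",
    "resolve_selection",
    "pairwise_identity",
    "read_fasta",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom with author numbering; coordinates in Å."""

    chain_id: str
    res_seq: int
    icode: str  # "" when absent
    res_name: str
    atom_name: str
    element: str
    pos: tuple[float, float, float]

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def atom_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.res_seq, self.icode, self.atom_name)


class Structure:
    """A hierarchical atomic model: models -> atom records.

    Atom identity ``(chain_id, res_seq, icode, atom_name)`` is unique within a
    model.  Coordinates must be finite.
    """

    def __init__(self, models: Sequence[Sequence[AtomRecord]], name: str = ""):
        if not models or not any(len(m) for m in models):
            raise ValueError("structure must contain at least one atom")
        self.name = name
        self.models: list[list[AtomRecord]] = [list(m) for m in models]
        for i, model in enumerate(self.models):
            seen = set()
            for a in model:
                if a.atom_key in seen:
                    raise ValueError(f"duplicate atom {a.atom_key} in model {i}")
                seen.add(a.atom_key)
                if not np.all(np.isfinite(a.pos)):
                    raise ValueError(f"non-finite coordinates for atom {a.atom_key}")

    def __len__(self) -> int:
        return len(self.models)

    def n_atoms(self, model: int = 0) -> int:
        return len(self.models[model])

    def atoms(self, model: int = 0) -> list[AtomRecord]:
        return self.models[model]

    def coords(self, model: int = 0) -> np.ndarray:
        """(N, 3) coordinate array in model order."""
        return np.array([a.pos for a in self.models[model]], dtype=float)

    def chain_ids(self, model: int = 0) -> list[str]:
        out: list[str] = []
        for a in self.models[model]:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residue_keys(self, model: int = 0) -> list[tuple[str, int, str]]:
        out: list[tuple[str, int, str]] = []
        seen = set()
        for a in self.models[model]:
            if a.residue_key not in seen:
                seen.add(a.residue_key)
                out.append(a.residue_key)
        return out

    def atom_index(self, model: int = 0) -> dict[tuple[str, int, str, str], int]:
        return {a.atom_key: i for i, a in enumerate(self.models[model])}

    def ca_index(self, model: int = 0) -> dict[tuple[str, int, str], int]:
        """Residue key -> index of its Cα atom."""
        out: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.models[model]):
            if a.atom_name == "CA" and a.residue_key not in out:
                out[a.residue_key] = i
        return out

    def with_coords(self, coords: np.ndarray, model: int = 0) -> "Structure":
        """Copy of this structure with the given model's coordinates replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.models[model]), 3):
            raise ValueError("coordinate array shape mismatch")
        models = [list(m) for m in self.models]
        models[model] = [
            dataclasses.replace(a, pos=tuple(float(x) for x in c))
            for a, c in zip(models[model], coords)
        ]
        return Structure(models, name=self.name)


@dataclasses.dataclass(frozen=True)
class Selection:
    """Residue ranges per subunit, e.g. N-clamp = HAUS2 1-117 + HAUS6 1-267 ...

    ``terms`` are ``(subunit, start_res, end_res)`` with inclusive bounds in
    author numbering.  ``atom_filter`` restricts to Cα atoms or keeps all.
    """

    terms: tuple[tuple[str, int, int], ...]
    atom_filter: str = "CA_only"  # or "all_atoms"

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple((str(s), int(a), int(b)) for s, a, b in self.terms))
        for sub, start, end in self.terms:
            if start > end:
                raise ValueError(f"selection term {sub} {start}-{end}: start > end")
        if self.atom_filter not in ("CA_only", "all_atoms"):
            raise ValueError(f"unknown atom_filter {self.atom_filter!r}")

    @property
    def subunits(self) -> list[str]:
        return sorted({s for s, _, _ in self.terms})

    def n_residues(self) -> int:
        return sum(end - start + 1 for _, start, end in self.terms)


def normalize_chain_map(chain_map: Mapping[str, str | Sequence[str]]) -> dict[str, list[str]]:
    """Subunit name -> list of chain ids; scalar values become one-element lists."""
    out: dict[str, list[str]] = {}
    for sub, chains in chain_map.items():
        if isinstance(chains, str):
            out[str(sub)] = [chains]
        else:
            out[str(sub)] = [str(c) for c in chains]
        if not out[str(sub)]:
            raise ValueError(f"subunit {sub!r} maps to no chains")
    return out


def _icode(gemmi_icode: str) -> str:
    return "" if gemmi_icode in ("\x00", " ", "") else gemmi_icode


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Author numbering and insertion codes are preserved.  Alternate locations
    are collapsed to the highest-occupancy conformer (first encountered on a
    tie).  One model per MODEL block.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format
    if fmt is None:
        fmt = "mmCIF" if path.suffix.lower() in (".cif", ".mmcif") else "PDB"
    try:
        if fmt == "mmCIF":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "PDB":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    models: list[list[AtomRecord]] = []
    for model in st:
        records: list[AtomRecord] = []
        for chain in model:
            for res in chain:
                best: dict[str, gemmi.Atom] = {}
                for atom in res:
                    prev = best.get(atom.name)
                    if prev is None or atom.occ > prev.occ:
                        best[atom.name] = atom
                for atom in res:  # preserve file order of retained conformers
                    if best.get(atom.name) is not atom:
                        continue
                    records.append(
                        AtomRecord(
                            chain_id=chain.name,
                            res_seq=res.seqid.num,
                            icode=_icode(res.seqid.icode),
                            res_name=res.name,
                            atom_name=atom.name,
                            element=atom.element.name,
                            pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                        )
                    )
        if records:
            models.append(records)
    if not models:
        raise ValueError(f"{path}: empty structure")
    return Structure(models, name=path.stem)


def write_structure(s: Structure, path: str | Path, format: str = "PDB") -> None:
    """Write a structure as PDB (the only supported output format)."""
    if format != "PDB":
        raise ValueError("only PDB output is supported")
    for model in s.models:
        for a in model:
            if not (-999 <= a.res_seq <= 9999):
                raise ValueError(
                    f"residue number {a.res_seq} does not fit the PDB field width"
                )
            if len(a.chain_id) > 1:
                raise ValueError(f"chain id {a.chain_id!r} too long for PDB output")
    st = gemmi.Structure()
    st.name = s.name or "model"
    for mi, model in enumerate(s.models, start=1):
        gm = gemmi.Model(mi)
        by_chain: dict[str, list[AtomRecord]] = {}
        for a in model:
            by_chain.setdefault(a.chain_id, []).append(a)
        for chain_id, atoms in by_chain.items():
            gc = gemmi.Chain(chain_id)
            groups: list[list[AtomRecord]] = []
            current_key = None
            for a in atoms:
                if a.residue_key != current_key:
                    groups.append([])
                    current_key = a.residue_key
                groups[-1].append(a)
            for group in groups:
                res = gemmi.Residue()
                res.name = group[0].res_name
                res.seqid = gemmi.SeqId(group[0].res_seq, group[0].icode or " ")
                for a in group:
                    ga = gemmi.Atom()
                    ga.name = a.atom_name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.pos)
                    ga.occ = 1.0
                    res.add_atom(ga)
                gc.add_residue(res)  # add_residue copies, so fill first
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def resolve_selection(
    s: Structure,
    sel: Selection,
    chain_map: Mapping[str, str | Sequence[str]],
    model: int = 0,
) -> tuple[list[int], list[tuple[str, int]]]:
    """Resolve a selection to atom indices plus a missing-residue report.

    Returns ``(indices, missing)`` where ``indices`` are positions into
    ``s.atoms(model)`` sorted by ``(chain, res_seq, icode, atom_name)`` and
    ``missing`` lists requested ``(chain_id, res_seq)`` pairs with no matching
    atom.  Residues absent from the model are reported, never silently dropped.
    """
    cmap = normalize_chain_map(chain_map)
    for sub in sel.subunits:
        if sub not in cmap:
            raise KeyError(f"subunit {sub!r} not in chain map")
    # any insertion code counts as the residue being present
    by_residue: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(s.models[model]):
        by_residue.setdefault((a.chain_id, a.res_seq), []).append(i)
    indices: list[int] = []
    missing: list[tuple[str, int]] = []
    for sub, start, end in sel.terms:
        for chain_id in cmap[sub]:
            for res_seq in range(start, end + 1):
                hits = list(by_residue.get((chain_id, res_seq), ()))
                if sel.atom_filter == "CA_only":
                    hits = [i for i in hits if s.models[model][i].atom_name == "CA"]
                if hits:
                    indices.extend(hits)
                else:
                    missing.append((chain_id, res_seq))
    indices = sorted(set(indices), key=lambda i: s.models[model][i].atom_key)
    if not indices and not missing:
        raise ValueError("selection resolved to nothing (empty terms?)")
    if not indices:
        raise ValueError(f"selection resolved to no atoms; missing residues: {missing}")
    return indices, missing


# --- sequence identity ------------------------------------------------------

def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    return seq


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[float, tuple[str, str]]:
    """Global pairwise identity between two amino-acid sequences.

    Alignment uses the named substitution matrix with affine gap penalties;
    terminal gaps are free and their columns are excluded from the identity
    denominator.  Identity is the fraction of identical aligned positions over
    the remaining aligned columns, scaled to 0-100.

    Returns ``(percent_identity, (gapped_a, gapped_b))``.
    """
    seq_a = _check_sequence(seq_a)
    seq_b = _check_sequence(seq_b)
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aligner.mode = "global"
    aligner.end_gap_score = 0.0
    aln = aligner.align(seq_a, seq_b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    # trim terminal-gap columns: leading/trailing runs where either row is gapped
    start = 0
    while start < len(ga) and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    end = len(ga)
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    # identical sequences with no internal gaps: full length
    cols = end - start
    if cols == 0:
        return 0.0, (ga, gb)
    ident = sum(1 for i in range(start, end) if ga[i] == gb[i] and ga[i] != "-")
    return 100.0 * ident / cols, (ga, gb)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{record id: sequence}`` dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out
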