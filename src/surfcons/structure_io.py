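"""Read, filter and write protein structures in PDB format.

The in-memory model is deliberately small: an ordered list of heavy atoms
with author residue numbering preserved verbatim.  Reading applies the
standard filters used for solvent-accessibility work on crystal structures:
hydrogens out, waters out, heteroatoms out by default (optionally keeping
modified residues such as MSE mapped to their standard parent), and at most
one alternate-location conformer per atom (highest occupancy, first in file
order on ties).  Residues that were declared missing (REMARK 465) or that
fall in numbering gaps are detectably absent rather than silently dropped.

Parsing and serialisation are delegated to :mod:`gemmi`; this module owns
only the filtering policy and the lightweight containers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np

from .errors import EmptyInputError, FormatError, LookupFailure

__all__ = [
    "ResidueId",
    "Atom",
    "Structure",
    "RadiiSet",
    "read_structure",
    "read_structure_text",
    "select_subunit",
    "assign_radii",
    "write_pdb",
]

#: residue names treated as water
WATER_NAMES = frozenset({"HOH", "DOD", "WAT", "H2O"})

#: modified residues mapped to their standard parent when keep_modified=True
MODIFIED_PARENT: Mapping[str, str] = {
    "MSE": "MET",  # selenomethionine
    "CSE": "CYS",  # selenocysteine (PDB: SEC)
    "SEC": "CYS",
    "MLY": "LYS",
    "PTR": "TYR",
    "SEP": "SER",
    "TPO": "THR",
}


@dataclass(frozen=True, order=True)
class ResidueId:
    """Author residue identity: (chain, number, insertion code)."""

    chain: str
    number: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:33" or "B:100A"
        return f"{self.chain}:{self.number}{self.icode}"


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a filtered structure."""

    name: str
    element: str
    coords: tuple[float, float, float]
    residue_name: str
    residue: ResidueId
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise FormatError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise FormatError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}"
            )


@dataclass
class Structure:
    """An ordered collection of filtered heavy atoms plus absence bookkeeping.

    ``reported_missing`` holds residues listed in REMARK 465 (unmodelled in
    the crystal); :meth:`unresolved_in_range` additionally detects numbering
    gaps so disordered segments are visible even without the remark.
    """

    atoms: list[Atom]
    id: str = ""
    reported_missing: frozenset[ResidueId] = field(default_factory=frozenset)

    # -- basic views ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue.chain, None)
        return list(seen)

    @property
    def resolved_residues(self) -> frozenset[ResidueId]:
        return frozenset(a.residue for a in self.atoms)

    def residues(self) -> Iterator[tuple[ResidueId, str, list[int]]]:
        """Iterate residues in atom order as (id, name, atom indices)."""
        order: dict[ResidueId, tuple[str, list[int]]] = {}
        for i, a in enumerate(self.atoms):
            order.setdefault(a.residue, (a.residue_name, []))[1].append(i)
        for rid, (name, idx) in order.items():
            yield rid, name, idx

    def residue_name(self, rid: ResidueId) -> str:
        for a in self.atoms:
            if a.residue == rid:
                return a.residue_name
        raise LookupFailure(f"residue {rid} not resolved in structure {self.id!r}")

    def unresolved_in_range(self, chain: str) -> frozenset[ResidueId]:
        """Residue numbers inside the chain's resolved span with no atoms.

        Detects internal disordered segments (e.g. an unmodelled loop) from
        numbering gaps alone; union with :attr:`reported_missing` for the
        full absence picture.
        """
        numbers = sorted(
            {a.residue.number for a in self.atoms if a.residue.chain == chain}
        )
        if not numbers:
            return frozenset()
        present = set(numbers)
        return frozenset(
            ResidueId(chain, n)
            for n in range(numbers[0], numbers[-1] + 1)
            if n not in present
        )

    def is_resolved(self, rid: ResidueId) -> bool:
        return rid in self.resolved_residues


# ---------------------------------------------------------------------------
# reading


def _validate_coordinate_lines(text: str) -> None:
    """Fail early, with a line number, on malformed ATOM/HETATM records."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6] not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise FormatError(f"line {lineno}: coordinate record too short")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise FormatError(
                f"line {lineno}: unparsable coordinates in {line[:6].strip()} record"
            ) from exc


def _parse_remark_465(text: str) -> frozenset[ResidueId]:
    """Extract residues declared missing via REMARK 465."""
    missing: set[ResidueId] = set()
    for line in text.splitlines():
        if not line.startswith("REMARK 465"):
            continue
        fields = line[10:].split()
        # data lines look like: [model] RES  C  SSSEQ[I]
        if len(fields) < 3:
            continue
        resname, chain, seq = fields[-3], fields[-2], fields[-1]
        if len(resname) > 3 or len(chain) != 1:
            continue
        icode = ""
        if seq and seq[-1].isalpha():
            seq, icode = seq[:-1], seq[-1]
        try:
            number = int(seq)
        except ValueError:
            continue
        missing.add(ResidueId(chain, number, icode))
    return frozenset(missing)


def read_structure_text(
    text: str,
    structure_id: str = "",
    *,
    keep_hetero: bool = False,
    keep_modified: bool = False,
) -> Structure:
    """Parse PDB text into a filtered :class:`Structure`.

    Filters applied, in order: hydrogens/deuteriums out; waters out; HETATM
    out unless ``keep_hetero`` (all) or ``keep_modified`` (only residues in
    :data:`MODIFIED_PARENT`, renamed to the parent); for alternate locations
    the highest-occupancy conformer wins, first in file order on ties.
    Only the first MODEL is read.
    """
    _validate_coordinate_lines(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"gemmi could not parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise EmptyInputError("no model in PDB input")
    model = st[0]

    raw: list[Atom] = []
    for chain in model:
        for res in chain:
            resname = res.name.strip().upper()
            if resname in WATER_NAMES:
                continue
            is_het = res.het_flag == "H"
            if is_het and not keep_hetero:
                if not (keep_modified and resname in MODIFIED_PARENT):
                    continue
                resname = MODIFIED_PARENT[res.name.strip().upper()]
            rid = ResidueId(chain.name, res.seqid.num, (res.seqid.icode or " ").strip())
            for at in res:
                elem = at.element.name.upper()
                if elem in ("H", "D"):
                    continue
                raw.append(
                    Atom(
                        name=at.name,
                        element=elem,
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                        residue_name=resname,
                        residue=rid,
                        altloc=(at.altloc or "").strip(),
                        occupancy=float(np.clip(at.occ, 0.0, 1.0)),
                        is_hetero=is_het,
                    )
                )
    if not raw:
        raise EmptyInputError(f"no atoms survive filtering in {structure_id!r}")

    atoms = _resolve_altlocs(raw)
    return Structure(
        atoms=atoms, id=structure_id, reported_missing=_parse_remark_465(text)
    )


def _resolve_altlocs(atoms: Iterable[Atom]) -> list[Atom]:
    """Keep one conformer per (residue, atom name): max occupancy, file order
    breaking ties.  Clears the altloc tag on the survivors."""
    best: dict[tuple[ResidueId, str], tuple[float, int, Atom]] = {}
    for order, a in enumerate(atoms):
        key = (a.residue, a.name)
        cur = best.get(key)
        if cur is None or a.occupancy > cur[0]:
            best[key] = (a.occupancy, order, a)
    survivors = sorted(best.values(), key=lambda t: t[1])
    return [replace(a, altloc="") for _, _, a in survivors]


def read_structure(
    path: str | Path,
    dialect: str = "pdb",
    *,
    structure_id: str | None = None,
    keep_hetero: bool = False,
    keep_modified: bool = False,
) -> Structure:
    """Read a PDB file from disk; see :func:`read_structure_text`."""
    if dialect != "pdb":
        raise FormatError(f"unsupported dialect {dialect!r}; only 'pdb' in v1")
    path = Path(path)
    if structure_id is None:
        structure_id = path.stem
    return read_structure_text(
        path.read_text(),
        structure_id,
        keep_hetero=keep_hetero,
        keep_modified=keep_modified,
    )


# ---------------------------------------------------------------------------
# selection


def select_subunit(structure: Structure, chains: Iterable[str]) -> Structure:
    """Restrict a structure to the named chains (monomer-mode SASA input)."""
    wanted = set(chains)
    if not wanted:
        raise LookupFailure("no chains requested")
    available = set(structure.chains)
    unknown = wanted - available
    if unknown:
        raise LookupFailure(
            f"chain(s) {sorted(unknown)} not in structure {structure.id!r}; "
            f"available: {sorted(available)}"
        )
    return Structure(
        atoms=[a for a in structure.atoms if a.residue.chain in wanted],
        id=structure.id,
        reported_missing=frozenset(
            r for r in structure.reported_missing if r.chain in wanted
        ),
    )


# ---------------------------------------------------------------------------
# van der Waals radii


@dataclass(frozen=True)
class RadiiSet:
    """Element-keyed van der Waals radii with an optional declared fallback.

    Unknown elements raise unless ``fallback`` is set: silent defaulting
    would bias SASA for e.g. selenium-substituted structures.
    """

    name: str
    by_element: Mapping[str, float]
    fallback: float | None = None

    def __post_init__(self) -> None:
        for elem, r in self.by_element.items():
            if not 0.0 < r < 3.0:
                raise FormatError(f"radius {r} for {elem} outside (0, 3.0) Å")

    def radius_for(self, element: str) -> float:
        r = self.by_element.get(element.upper())
        if r is not None:
            return r
        if self.fallback is not None:
            return self.fallback
        raise LookupFailure(
            f"no radius for element {element!r} in set {self.name!r} "
            "and no fallback configured"
        )

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "RadiiSet":
        by_element: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            elem, radius = line.split("\t")[:2]
            by_element[elem.upper()] = float(radius)
        return cls(name=name or Path(path).stem, by_element=by_element)

    @classmethod
    def bundled(cls, name: str = "chothia1976") -> "RadiiSet":
        ref = importlib.resources.files("surfcons.data") / f"radii_{name}.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_file(path, name=name)


def assign_radii(structure: Structure, radii: RadiiSet) -> np.ndarray:
    """Per-atom radius array aligned with ``structure.atoms``."""
    out = np.empty(len(structure.atoms))
    for i, a in enumerate(structure.atoms):
        try:
            out[i] = radii.radius_for(a.element)
        except LookupFailure as exc:
            raise LookupFailure(f"atom {a.name} ({a.residue}): {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# writing


def write_pdb(structure: Structure, path: str | Path | None = None) -> str:
    """Serialise a filtered structure back to PDB text (debug aid).

    Round-trips through :func:`read_structure_text` with coordinates at the
    PDB fixed-column precision (3 decimals).
    """
    st = gemmi.Structure()
    st.name = structure.id or "XXXX"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[ResidueId, gemmi.Residue] = {}
    for a in structure.atoms:
        ch = chains.get(a.residue.chain)
        if ch is None:
            ch = gemmi.Chain(a.residue.chain)
            chains[a.residue.chain] = ch
            model.add_chain(ch)
            ch = model[-1]
            chains[a.residue.chain] = ch
        res = residues.get(a.residue)
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue.number, a.residue.icode or " ")
            res.het_flag = "H" if a.is_hetero else "A"
            ch.add_residue(res)
            res = ch[-1]
            residues[a.residue] = res
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coords)
        at.occ = a.occupancy
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if path is not None:
        Path(path).write_text(text)
    return text
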