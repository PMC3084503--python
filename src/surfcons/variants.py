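"""Join variant tables to structures and conservation profiles.

This is the annotation layer: each missense variant (or single-residue
deletion) is located on every structure mapped for its carrier protein,
its wild-type identity is verified against the structure (a mismatch is a
hard error — silent misnumbering is the classic failure mode of this kind
of join), its relative solvent accessibility and burial are recorded per
structure, and its conservation grade is pulled from the per-column
profile.  Variants in unresolved (disordered) regions or on proteins
without structures keep explicit sentinels and are excluded from group
statistics, never imputed.

The package also bundles transcriptions of published annotation tables for
the three variant groups (platelet alloantigens, disease-causing mutations
in the same receptors, and non-immunogenic SNPs) so the group comparison
can be reproduced from published per-structure accessibility values.
"""

from __future__ import annotations

import enum
import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aa import ONE_TO_THREE, STANDARD_RESIDUES
from .errors import FormatError, IdentityMismatchError, LookupFailure
from .sasa import SasaParams, classify_burial
from .structure_io import ResidueId, Structure

__all__ = [
    "Substitution",
    "VariantRecord",
    "parse_substitution",
    "read_variant_table",
    "load_bundled_variants",
    "NumberingMap",
    "load_bundled_numbering_map",
    "MappingStatus",
    "map_variant_to_structure",
    "VariantProfile",
    "profile_variants",
    "contact_distance",
    "published_group_values",
    "group_values_from_profiles",
]


# ---------------------------------------------------------------------------
# variant records


@dataclass(frozen=True)
class Substitution:
    """Wild-type / position / mutant triple; mutant None for a deletion."""

    wild_type: str  # 3-letter
    position: int
    mutant: str | None  # 3-letter, or None for a single-residue deletion

    @property
    def is_deletion(self) -> bool:
        return self.mutant is None

    def __str__(self) -> str:
        wt = self.wild_type.capitalize()
        if self.is_deletion:
            return f"{wt}{self.position}del"
        return f"{wt}{self.position}{self.mutant.capitalize()}"


_SUB_RE = re.compile(
    r"^(?P<wt>[A-Za-z]{1,3})(?P<pos>\d+)(?P<mut>[A-Za-z]{1,3}|del)$"
)


def _to_three(token: str) -> str:
    token = token.upper()
    if len(token) == 1:
        if token not in ONE_TO_THREE:
            raise FormatError(f"unknown one-letter residue code {token!r}")
        return ONE_TO_THREE[token]
    if token not in STANDARD_RESIDUES:
        raise FormatError(f"unknown residue code {token!r}")
    return token


def parse_substitution(text: str) -> Substitution:
    """Parse compact substitution notation: 'Leu33Pro', 'L33P', 'Lys611del'."""
    m = _SUB_RE.match(text.strip())
    if not m:
        raise FormatError(f"malformed substitution token {text!r}")
    wt = _to_three(m.group("wt"))
    pos = int(m.group("pos"))
    if pos < 1:
        raise FormatError(f"position must be >= 1 in {text!r}")
    mut_token = m.group("mut")
    mut = None if mut_token.lower() == "del" else _to_three(mut_token)
    if mut is not None and mut == wt:
        raise FormatError(f"wild type equals mutant in {text!r}")
    return Substitution(wt, pos, mut)


@dataclass
class VariantRecord:
    """One variant with its group label and optional published annotations."""

    id: str
    gene: str
    substitution: Substitution
    group: str  # hpa | disease | neutral
    numbering_scheme: str = "mature"
    domain: str = ""
    annotations: dict = field(default_factory=dict)

    @property
    def position(self) -> int:
        return self.substitution.position

    def reported_sasa(self) -> dict[str, float | str]:
        """Published per-structure relative SASA, if transcribed.

        Returns {structure_id: percent} plus sentinel entries
        {structure_id: 'disordered'}; empty when no structure is known.
        """
        raw = self.annotations.get("sasa", "")
        out: dict[str, float | str] = {}
        if not raw:
            return out
        for token in str(raw).split(";"):
            token = token.strip()
            if not token:
                continue
            value, _sep, sid = token.partition(":")
            if not sid:
                raise FormatError(
                    f"variant {self.id}: malformed sasa token {token!r}"
                )
            if value.lower() == "disordered":
                out[sid] = "disordered"
            else:
                out[sid] = float(value)
        return out

    def mean_reported_sasa(self) -> float:
        vals = [v for v in self.reported_sasa().values() if isinstance(v, float)]
        return float(np.mean(vals)) if vals else float("nan")

    def reported_grade(self) -> int | None:
        g = self.annotations.get("conservation_grade", "")
        return int(g) if str(g).strip() else None


_REQUIRED_COLUMNS = ("id", "gene", "substitution", "group")


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV ('#' comments allowed) into validated records."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            sub = parse_substitution(row["substitution"])
        except FormatError as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
        extra = {
            c: row[c]
            for c in df.columns
            if c not in ("id", "gene", "substitution", "group",
                         "numbering_scheme", "domain")
        }
        records.append(
            VariantRecord(
                id=row["id"],
                gene=row["gene"],
                substitution=sub,
                group=row["group"],
                numbering_scheme=row.get("numbering_scheme", "mature") or "mature",
                domain=row.get("domain", "") or "",
                annotations=extra,
            )
        )
    if not records:
        raise FormatError(f"{path}: no variant rows")
    return records


_BUNDLED = {
    "hpa": "hpa_variants.tsv",
    "disease": "disease_variants.tsv",
    "neutral": "neutral_variants.tsv",
}


def load_bundled_variants(group: str | None = None) -> list[VariantRecord]:
    """Bundled transcribed variant tables; all three groups by default."""
    names = [_BUNDLED[group]] if group else list(_BUNDLED.values())
    records: list[VariantRecord] = []
    for name in names:
        ref = importlib.resources.files("surfcons.data") / name
        with importlib.resources.as_file(ref) as p:
            records.extend(read_variant_table(p))
    return records


# ---------------------------------------------------------------------------
# numbering


class NumberingMap:
    """Per-gene translation between mature-protein numbering, precursor
    numbering, structure author numbering and conservation-profile columns.

    Rows with structure_id '-' carry only the signal-peptide and MSA
    offsets for proteins without structures.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"gene", "structure_id", "chain", "position_offset",
                    "signal_peptide_offset", "msa_id", "msa_offset"}
        missing = required - set(table.columns)
        if missing:
            raise FormatError(f"numbering map missing columns {sorted(missing)}")
        self.table = table.copy()
        for col in ("position_offset", "signal_peptide_offset", "msa_offset"):
            self.table[col] = self.table[col].astype(int)

    @classmethod
    def from_file(cls, path: str | Path) -> "NumberingMap":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype=str,
                               keep_default_na=False))

    def structures_for(self, gene: str) -> list[tuple[str, str, int]]:
        """(structure_id, chain, position_offset) rows mapped for a gene."""
        rows = self.table[(self.table.gene == gene)
                          & (self.table.structure_id != "-")]
        return [(r.structure_id, r.chain, int(r.position_offset))
                for r in rows.itertuples()]

    def structure_entry(self, gene: str, structure_id: str):
        for sid, chain, off in self.structures_for(gene):
            if sid == structure_id:
                return chain, off
        return None

    def msa_for(self, gene: str) -> tuple[str, int] | None:
        rows = self.table[self.table.gene == gene]
        if rows.empty:
            return None
        r = rows.iloc[0]
        return (r.msa_id, int(r.msa_offset)) if r.msa_id else None

    def to_precursor(self, gene: str, mature_position: int) -> int:
        rows = self.table[self.table.gene == gene]
        if rows.empty:
            raise LookupFailure(f"gene {gene!r} not in numbering map")
        return mature_position + int(rows.iloc[0].signal_peptide_offset)

    def to_mature(self, gene: str, precursor_position: int) -> int:
        rows = self.table[self.table.gene == gene]
        if rows.empty:
            raise LookupFailure(f"gene {gene!r} not in numbering map")
        return precursor_position - int(rows.iloc[0].signal_peptide_offset)


def load_bundled_numbering_map() -> NumberingMap:
    ref = importlib.resources.files("surfcons.data") / "numbering_map.tsv"
    with importlib.resources.as_file(ref) as p:
        return NumberingMap.from_file(p)


# ---------------------------------------------------------------------------
# structure mapping


class MappingStatus(enum.Enum):
    MAPPED = "mapped"
    DISORDERED = "disordered"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class MappingResult:
    status: MappingStatus
    residue: ResidueId | None = None


def map_variant_to_structure(
    variant: VariantRecord,
    structure: Structure,
    numbering: NumberingMap,
) -> MappingResult:
    """Locate a variant on one structure.

    Returns MAPPED with the residue id when the position is resolved (after
    a mandatory wild-type identity check), DISORDERED when the position
    falls in an unresolved region of the mapped chain, and UNMAPPED when
    the gene has no mapping to this structure or the position lies outside
    the chain entirely.
    """
    entry = numbering.structure_entry(variant.gene, structure.id)
    if entry is None:
        return MappingResult(MappingStatus.UNMAPPED)
    chain, offset = entry
    mature_pos = variant.position
    if variant.numbering_scheme == "precursor":
        mature_pos = numbering.to_mature(variant.gene, variant.position)
    author_pos = mature_pos + offset
    rid = ResidueId(chain, author_pos)
    if structure.is_resolved(rid):
        found = structure.residue_name(rid)
        expected = variant.substitution.wild_type
        if found != expected:
            raise IdentityMismatchError(variant.id, expected, found, rid)
        return MappingResult(MappingStatus.MAPPED, rid)
    if rid in structure.reported_missing or rid in structure.unresolved_in_range(chain):
        return MappingResult(MappingStatus.DISORDERED)
    return MappingResult(MappingStatus.UNMAPPED)


def contact_distance(
    structure: Structure, residue: ResidueId, other_chains: Iterable[str]
) -> float:
    """Minimum heavy-atom distance (Å) from one residue to any residue of
    the named chains; distances below 4.0 Å are conventionally reported as
    contacts."""
    own = np.array([a.coords for a in structure.atoms if a.residue == residue])
    others = np.array(
        [a.coords for a in structure.atoms if a.residue.chain in set(other_chains)]
    )
    if own.size == 0:
        raise LookupFailure(f"residue {residue} not resolved")
    if others.size == 0:
        raise LookupFailure(f"no atoms in chains {sorted(set(other_chains))}")
    diff = own[:, None, :] - others[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


# ---------------------------------------------------------------------------
# profiles


@dataclass
class VariantProfile:
    """Per-variant structural and evolutionary annotation."""

    record: VariantRecord
    structure_sasa: dict[str, float | str]  # percent, 'disordered' or 'unmapped'
    conservation_grade: int | None
    conservation_label: str | None
    burial: dict[str, str]

    @property
    def mean_rel_sasa(self) -> float:
        vals = [v for v in self.structure_sasa.values() if isinstance(v, float)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def has_structural_value(self) -> bool:
        return any(isinstance(v, float) for v in self.structure_sasa.values())

    @property
    def overall_burial(self) -> str:
        if not self.has_structural_value:
            return "n/a"
        return classify_burial(self.mean_rel_sasa)


def profile_variants(
    variants: Sequence[VariantRecord],
    structures: Mapping[str, Structure],
    sasa_profiles: Mapping[str, pd.DataFrame],
    conservation: Mapping[str, object],
    numbering: NumberingMap,
    params: SasaParams = SasaParams(),
) -> tuple[list[VariantProfile], pd.DataFrame]:
    """Assemble one profile per variant (exactly one, no drops).

    ``sasa_profiles`` maps structure id -> per-residue table from
    :func:`surfcons.sasa.sasa_profile`; ``conservation`` maps MSA id ->
    fitted :class:`~surfcons.conservation.ConservationResult`.
    """
    profiles: list[VariantProfile] = []
    for var in variants:
        per_structure: dict[str, float | str] = {}
        burial: dict[str, str] = {}
        for sid, _chain, _off in numbering.structures_for(var.gene):
            if sid not in structures:
                continue
            result = map_variant_to_structure(var, structures[sid], numbering)
            if result.status is MappingStatus.MAPPED:
                prof = sasa_profiles[sid]
                rid = result.residue
                row = prof[(prof.chain == rid.chain)
                           & (prof.residue_seq == rid.number)
                           & (prof.icode == rid.icode)]
                rel = float(row.iloc[0].rel_sasa_pct)
                per_structure[sid] = rel
                burial[sid] = classify_burial(rel, params.burial_threshold)
            else:
                per_structure[sid] = result.status.value

        grade: int | None = None
        label: str | None = None
        msa_entry = numbering.msa_for(var.gene)
        if msa_entry is not None:
            msa_id, msa_offset = msa_entry
            result = conservation.get(msa_id)
            if result is not None:
                column = var.position + msa_offset
                g = result.grade_at(column)
                if g > 0:
                    grade = g
                    from .conservation import GRADE_LABELS

                    label = GRADE_LABELS[g]
        profiles.append(
            VariantProfile(
                record=var,
                structure_sasa=per_structure,
                conservation_grade=grade,
                conservation_label=label,
                burial=burial,
            )
        )
    return profiles, profiles_report(profiles)


def _format_sasa_cell(profile: VariantProfile) -> str:
    if not profile.structure_sasa:
        return "no structure"
    parts = []
    for sid, v in profile.structure_sasa.items():
        if isinstance(v, float):
            parts.append(f"{v:.1f}% ({sid})")
        elif v != MappingStatus.UNMAPPED.value:
            parts.append(f"{v} ({sid})")
    # structures that simply do not cover the position are omitted from the
    # printed cell; they stay in structure_sasa for provenance
    return "; ".join(parts) if parts else "unmapped"


def profiles_report(profiles: Sequence[VariantProfile]) -> pd.DataFrame:
    """Report table mirroring the published annotation-table layout."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "id": p.record.id,
                "gene": p.record.gene,
                "substitution": str(p.record.substitution),
                "group": p.record.group,
                "domain": p.record.domain,
                "sasa": _format_sasa_cell(p),
                "mean_rel_sasa_pct": p.mean_rel_sasa,
                "burial": p.overall_burial,
                "conservation_grade": p.conservation_grade,
                "conservation_label": p.conservation_label,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group-statistics inputs


def group_values_from_profiles(
    profiles: Sequence[VariantProfile],
) -> dict[str, dict[str, np.ndarray]]:
    """Per-group value vectors for the rank tests.

    'sasa': mean relative SASA per variant over its structure-resolved
    values (variants with none are excluded, never imputed);
    'conservation': the 1-9 grade (variants without a grade excluded).
    """
    sasa: dict[str, list[float]] = {}
    cons: dict[str, list[float]] = {}
    for p in profiles:
        g = p.record.group
        if p.has_structural_value:
            sasa.setdefault(g, []).append(p.mean_rel_sasa)
        if p.conservation_grade is not None:
            cons.setdefault(g, []).append(float(p.conservation_grade))
    return {
        "sasa": {k: np.array(v) for k, v in sasa.items()},
        "conservation": {k: np.array(v) for k, v in cons.items()},
    }


def published_group_values() -> dict[str, dict[str, np.ndarray]]:
    """Group value vectors from the bundled published-table transcriptions
    (per-variant mean over per-structure values; sentinels excluded)."""
    sasa: dict[str, list[float]] = {}
    cons: dict[str, list[float]] = {}
    for rec in load_bundled_variants():
        mean = rec.mean_reported_sasa()
        if np.isfinite(mean):
            sasa.setdefault(rec.group, []).append(mean)
        grade = rec.reported_grade()
        if grade is not None:
            cons.setdefault(rec.group, []).append(float(grade))
    return {
        "sasa": {k: np.array(v) for k, v in sasa.items()},
        "conservation": {k: np.array(v) for k, v in cons.items()},
    }
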