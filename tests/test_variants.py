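"""Variant parsing, numbering, structure mapping and profile assembly."""

import numpy as np
import pandas as pd
import pytest

from surfcons.errors import FormatError, IdentityMismatchError
from surfcons.sasa import sasa_profile
from surfcons.structure_io import ResidueId
from surfcons.synthetic import ToyFoldSpec, make_peptide, make_toy_fold
from surfcons.variants import (
    MappingStatus,
    NumberingMap,
    load_bundled_numbering_map,
    load_bundled_variants,
    map_variant_to_structure,
    parse_substitution,
    published_group_values,
    read_variant_table,
    VariantRecord,
)


class TestSubstitutionParsing:
    @pytest.mark.parametrize(
        "token,wt,pos,mut",
        [
            ("Leu33Pro", "LEU", 33, "PRO"),
            ("Thr140Ile", "THR", 140, "ILE"),
            ("L33P", "LEU", 33, "PRO"),
            ("Lys611del", "LYS", 611, None),
        ],
    )
    def test_valid_tokens(self, token, wt, pos, mut):
        sub = parse_substitution(token)
        assert (sub.wild_type, sub.position, sub.mutant) == (wt, pos, mut)
        assert sub.is_deletion == (mut is None)

    @pytest.mark.parametrize("bad", ["Leu33", "33Pro", "LeuXXPro", "Xyz33Pro",
                                     "Leu33Leu", "Leu0Pro"])
    def test_malformed_tokens_rejected(self, bad):
        with pytest.raises(FormatError):
            parse_substitution(bad)


class TestBundledTables:
    def test_group_counts(self):
        assert len(load_bundled_variants("hpa")) == 17
        assert len(load_bundled_variants("disease")) == 13
        assert len(load_bundled_variants("neutral")) == 8

    def test_deletion_record_present(self):
        hpa = {r.id: r for r in load_bundled_variants("hpa")}
        deletion = hpa["HPA-14"]
        assert deletion.substitution.is_deletion
        assert deletion.substitution.position == 611

    def test_structure_resolved_sasa_count(self):
        # of 17 alloantigens, 3 lack any structural value (one disordered
        # region, two proteins without structures)
        hpa = load_bundled_variants("hpa")
        with_value = [r for r in hpa if np.isfinite(r.mean_reported_sasa())]
        assert len(with_value) == 14

    def test_reported_sasa_parsing_multi_structure(self):
        hpa = {r.id: r for r in load_bundled_variants("hpa")}
        sasa = hpa["HPA-1"].reported_sasa()
        assert sasa == {"3FCS": 98.0, "3FCU": 100.0}
        assert hpa["HPA-3"].reported_sasa() == {"3FCS": "disordered"}
        assert hpa["HPA-12"].reported_sasa() == {}

    def test_mean_over_structures(self):
        hpa = {r.id: r for r in load_bundled_variants("hpa")}
        # four structure values: (62 + 43 + 76 + 43) / 4
        assert hpa["HPA-4"].mean_reported_sasa() == pytest.approx(56.0)

    def test_missing_required_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id\tgene\n1\tX\n")
        with pytest.raises(FormatError, match="substitution"):
            read_variant_table(p)

    def test_malformed_substitution_names_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "id\tgene\tsubstitution\tgroup\nV1\tX\tLeu33Pro\thpa\n"
            "V2\tX\tnonsense\thpa\n"
        )
        with pytest.raises(FormatError, match="row 3"):
            read_variant_table(p)


@pytest.fixture
def toy_setup():
    """5-residue peptide structure + numbering map for gene TOY."""
    st = make_peptide(["GLY", "ALA", "SER", "ALA", "ALA"], structure_id="toy1")
    numbering = NumberingMap(pd.DataFrame(
        [{"gene": "TOY", "structure_id": "toy1", "chain": "A",
          "position_offset": 0, "signal_peptide_offset": 3,
          "msa_id": "toymsa", "msa_offset": 0}]
    ))
    return st, numbering


def _variant(sub, gene="TOY", scheme="mature", vid="V1", group="hpa"):
    return VariantRecord(id=vid, gene=gene, substitution=parse_substitution(sub),
                         group=group, numbering_scheme=scheme)


class TestStructureMapping:
    def test_resolved_position_maps_with_identity_check(self, toy_setup):
        st, numbering = toy_setup
        res = map_variant_to_structure(_variant("Ala2Gly"), st, numbering)
        assert res.status is MappingStatus.MAPPED
        assert res.residue == ResidueId("A", 2)

    def test_wild_type_mismatch_is_hard_error(self, toy_setup):
        st, numbering = toy_setup
        with pytest.raises(IdentityMismatchError, match="ALA"):
            map_variant_to_structure(_variant("Leu2Pro"), st, numbering)

    def test_unmapped_gene_reports_no_structure(self, toy_setup):
        st, numbering = toy_setup
        res = map_variant_to_structure(
            _variant("Ala2Gly", gene="OTHER"), st, numbering
        )
        assert res.status is MappingStatus.UNMAPPED

    def test_disordered_region_detected_from_gap(self, toy_setup):
        _st, numbering = toy_setup
        # remove residue 3 -> internal numbering gap = disordered segment
        st = make_peptide(["GLY", "ALA", "SER", "ALA", "ALA"], structure_id="toy1")
        st.atoms = [a for a in st.atoms if a.residue.number != 3]
        res = map_variant_to_structure(_variant("Ser3Ala"), st, numbering)
        assert res.status is MappingStatus.DISORDERED

    def test_precursor_numbering_translates(self, toy_setup):
        st, numbering = toy_setup
        # precursor position 5 - signal offset 3 = mature position 2 (Ala)
        res = map_variant_to_structure(
            _variant("Ala5Gly", scheme="precursor"), st, numbering
        )
        assert res.status is MappingStatus.MAPPED
        assert res.residue == ResidueId("A", 2)

    def test_deletion_checks_deleted_residue(self, toy_setup):
        st, numbering = toy_setup
        res = map_variant_to_structure(_variant("Ser3del"), st, numbering)
        assert res.status is MappingStatus.MAPPED


class TestNumberingMap:
    def test_bundled_map_loads_and_inverts(self):
        nm = load_bundled_numbering_map()
        assert ("1JV2", "B", 0) in nm.structures_for("ITGB3")
        # mature <-> precursor round trip
        assert nm.to_mature("CD109", nm.to_precursor("CD109", 682)) == 682
        assert nm.to_precursor("CD109", 682) == 703

    def test_msa_mapping(self):
        nm = load_bundled_numbering_map()
        assert nm.msa_for("ITGB3") == ("beta-integrins", 0)


class TestProfiles:
    def test_every_variant_appears_exactly_once(self, benchmark_run):
        result, _cfg, _paths = benchmark_run
        report = result["report"]
        assert report.id.is_unique
        assert len(report) == len(result["profiles"]) == 38

    def test_identity_check_holds_for_all_mapped(self, benchmark_run):
        result, _cfg, _paths = benchmark_run
        # profile_variants raises on mismatch, so reaching here means all
        # mapped variants passed; assert every variant found its structure
        assert all(p.has_structural_value for p in result["profiles"])

    def test_mean_sasa_is_arithmetic_mean(self, benchmark_run):
        result, _cfg, _paths = benchmark_run
        for p in result["profiles"]:
            vals = [v for v in p.structure_sasa.values() if isinstance(v, float)]
            assert p.mean_rel_sasa == pytest.approx(np.mean(vals))

    def test_variant_without_structure_excluded_from_stats(self):
        groups = published_group_values()
        assert len(groups["sasa"]["hpa"]) == 14  # not 17
        assert len(groups["conservation"]["hpa"]) == 17


class TestPublishedSplit:
    def test_exposed_buried_split_of_published_values(self):
        """All structure-resolved alloantigen residues are exposed (>= 5%
        mean relative SASA) while every disease mutation printed below 5%
        classifies as buried."""
        from surfcons.sasa import classify_burial

        hpa = [r for r in load_bundled_variants("hpa")
               if np.isfinite(r.mean_reported_sasa())]
        assert len(hpa) == 14
        for r in hpa:
            for v in r.reported_sasa().values():
                if isinstance(v, float):
                    assert classify_burial(v) == "exposed", r.id

        disease = load_bundled_variants("disease")
        buried_printed = [
            r for r in disease
            if all(isinstance(v, float) and v < 5.0
                   for v in r.reported_sasa().values())
        ]
        assert len(buried_printed) >= 7
        for r in buried_printed:
            assert classify_burial(r.mean_reported_sasa()) == "buried"
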