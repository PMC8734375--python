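"""Hierarchy resolution, catalog construction, description parsing, exclusions."""

import pandas as pd
import pytest

from helpers import (
    brute_force_catalog,
    catalog_as_sets,
    make_single_api_graph,
    make_two_api_graph,
)
from rxmass.ingest import read_dmd, read_snomed_map
from rxmass.mapping import (
    BnfCatalog,
    apply_exclusions,
    build_bnf_catalog,
    parse_product_description,
    resolve_snomed,
)


class TestResolveSnomed:
    def test_amp_hit_takes_precedence(self):
        graph, _ = make_single_api_graph()
        res = resolve_snomed("30", graph)
        assert res.level == "AMP" and res.vmp_id == "20"

    def test_vmpp_hit_traverses_to_vmp(self):
        graph, _ = make_single_api_graph()
        res = resolve_snomed("40", graph)
        assert res.level == "VMPP" and res.vmp_id == "20"

    def test_ampp_hit_traverses_via_amp(self):
        graph, _ = make_single_api_graph()
        res = resolve_snomed("50", graph)
        assert res.level == "AMPP" and res.vmp_id == "20"

    def test_unknown_code_is_unresolved_value(self):
        graph, _ = make_single_api_graph()
        assert resolve_snomed("424242", graph) is None

    def test_levels_partition_all_codes(self, small_bundle):
        """Every mapped SNOMED code resolves at exactly one level; the level
        sets partition the code space."""
        graph, _ = read_dmd(small_bundle.dmd_dir)
        map_rows, _, _ = read_snomed_map(small_bundle.snomed_map)
        levels = {}
        for code in map_rows["snomed_code"]:
            res = resolve_snomed(code, graph)
            levels.setdefault(res.level if res else "unresolved", set()).add(code)
        sets = list(levels.values())
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                assert not (a & b)
        assert set().union(*sets) == set(map_rows["snomed_code"])


class TestBuildCatalog:
    def test_single_api_toy_catalog(self, units):
        """1 VMP / 3 AMPs / 2 VMPPs toy resolves to exactly one 500 mg capsule
        component, matching a hand traversal."""
        graph, map_rows = make_single_api_graph()
        catalog, unresolved = build_bnf_catalog(map_rows, graph, units)
        assert unresolved.empty
        assert len(catalog.components) == 1
        comp = catalog.components.iloc[0]
        assert (comp["api"], comp["strength_value"], comp["strength_unit"], comp["form"]) == (
            "Drug A", 500.0, "mg", "capsule",
        )
        assert not comp["ambiguous"]
        assert comp["provenance"] == "AMP"

    def test_two_api_combination_yields_two_components(self, units):
        graph, map_rows = make_two_api_graph()
        catalog, _ = build_bnf_catalog(map_rows, graph, units)
        comps = catalog.components
        assert len(comps) == 2
        assert sorted(comps["strength_value"]) == [125.0, 500.0]
        assert set(comps["api"]) == {"Amoxicillin", "Clavulanic acid"}
        assert set(comps["bnf_code"]) == {"0501013K0AAAAAA"}

    def test_empty_mapping_gives_empty_catalog(self, units):
        graph, _ = make_single_api_graph()
        catalog, unresolved = build_bnf_catalog(
            pd.DataFrame(columns=["bnf_code", "snomed_code", "description"]), graph, units
        )
        assert catalog.components.empty and unresolved.empty

    def test_disagreeing_strengths_flagged_ambiguous_not_averaged(self, units):
        graph, map_rows = make_single_api_graph()
        # second VMP, same ingredient at a different strength, mapped under
        # the same BNF code
        graph.vmps = pd.concat(
            [graph.vmps, pd.DataFrame([{"vmp_id": "22", "name": "Drug A 250mg capsules", "form_id": "900"}])],
            ignore_index=True,
        )
        graph.vpi = pd.concat(
            [graph.vpi, pd.DataFrame([{"vmp_id": "22", "ingredient_id": "10",
                                       "strength_value": 250.0, "strength_unit": "mg",
                                       "denominator_value": None, "denominator_unit": None}])],
            ignore_index=True,
        )
        map_rows = pd.concat(
            [map_rows, pd.DataFrame([{"bnf_code": "0500000A0AAAAAA", "snomed_code": "22", "description": "d"}])],
            ignore_index=True,
        )
        catalog, _ = build_bnf_catalog(map_rows, graph, units)
        assert catalog.components["ambiguous"].all()
        assert sorted(catalog.components["strength_value"]) == [250.0, 500.0]

    def test_row_order_independence(self, units, small_bundle):
        graph, _ = read_dmd(small_bundle.dmd_dir)
        map_rows, _, _ = read_snomed_map(small_bundle.snomed_map)
        a, _ = build_bnf_catalog(map_rows, graph, units)
        b, _ = build_bnf_catalog(map_rows.sample(frac=1, random_state=5), graph, units)
        pd.testing.assert_frame_equal(a.components, b.components)

    def test_exhaustive_path_oracle_equivalence_toy(self, units):
        for graph, map_rows in (make_single_api_graph(), make_two_api_graph()):
            catalog, _ = build_bnf_catalog(map_rows, graph, units)
            assert catalog_as_sets(catalog, units) == brute_force_catalog(map_rows, graph, units)

    def test_exhaustive_path_oracle_equivalence_fixture(self, tmp_path, units):
        """On a generated graph the catalog equals an exhaustive-path walk."""
        from rxmass.synth import DEFAULT_API_SPECS, FixtureConfig, generate_fixture

        cfg = FixtureConfig(seed=5, n_practices=2, n_months=1, rows_per_practice_month=4,
                            api_specs=DEFAULT_API_SPECS[:4], unmapped_fraction=0.0,
                            excluded_fraction=0.0)
        bundle = generate_fixture(cfg, tmp_path / "fx")
        graph, _ = read_dmd(bundle.dmd_dir)
        map_rows, _, _ = read_snomed_map(bundle.snomed_map)
        catalog, _ = build_bnf_catalog(map_rows, graph, units)
        assert catalog_as_sets(catalog, units) == brute_force_catalog(map_rows, graph, units)

    def test_csv_round_trip(self, units, tmp_path):
        graph, map_rows = make_two_api_graph()
        catalog, _ = build_bnf_catalog(map_rows, graph, units)
        path = tmp_path / "catalog.csv"
        catalog.to_csv(path)
        again = BnfCatalog.from_csv(path)
        def norm(df):
            df = df.copy()
            df["denominator_value"] = [
                -1.0 if pd.isna(v) else float(v) for v in df["denominator_value"]
            ]
            df["denominator_unit"] = [
                "-" if (v is None or pd.isna(v)) else str(v) for v in df["denominator_unit"]
            ]
            return df

        pd.testing.assert_frame_equal(norm(catalog.components), norm(again.components),
                                      check_dtype=False)


class TestParseDescription:
    @pytest.mark.parametrize(
        "text,stem,form_token,value,unit",
        [
            ("Phenergan_Tab 25 mg", "Phenergan", "Tab", 25.0, "mg"),
            ("Zopiclone_Tab 7.5 mg", "Zopiclone", "Tab", 7.5, "mg"),
            ("Diazepam_Tab 2 mg", "Diazepam", "Tab", 2.0, "mg"),
            ("Aripiprazole_Tab 10 mg", "Aripiprazole", "Tab", 10.0, "mg"),
            ("Clarithromycin_I/V Inf 500 mg Vl", "Clarithromycin", "I/V", 500.0, "mg"),
            ("Sod Chlor_Irrig Soln", "Sod Chlor", "Irrig", None, None),
        ],
    )
    def test_strength_and_form_extraction(self, text, stem, form_token, value, unit):
        parsed = parse_product_description(text)
        assert parsed.stem == stem
        assert parsed.form_token == form_token
        assert parsed.strength_value == value
        assert parsed.strength_unit == unit


class TestExclusions:
    def _catalog(self, rows):
        from rxmass.mapping import CATALOG_COLUMNS

        df = pd.DataFrame(rows)
        for col in CATALOG_COLUMNS:
            if col not in df.columns:
                df[col] = None
        df["ambiguous"] = False
        return BnfCatalog(df[CATALOG_COLUMNS])

    def test_bath_additive_form_excluded(self):
        cat = self._catalog([{"bnf_code": "A" * 15, "api": "X", "api_full": "X",
                              "strength_value": 1.0, "strength_unit": "mg", "form": "bath additive"}])
        kept, excluded = apply_exclusions(cat)
        assert kept.components.empty and len(excluded) == 1
        assert excluded.loc[0, "rule"] == "bath additive"

    def test_multivitamin_capsule_excluded_by_name(self):
        cat = self._catalog([{"bnf_code": "B" * 15, "api": "Multivit", "api_full": "Multivit",
                              "strength_value": 1.0, "strength_unit": "mg", "form": "capsule"}])
        kept, excluded = apply_exclusions(cat, descriptions={"B" * 15: "Multivitamin_Cap"})
        assert kept.components.empty
        assert excluded.loc[0, "rule"] == "multivitamin"

    def test_plain_tablet_kept(self):
        cat = self._catalog([{"bnf_code": "C" * 15, "api": "Diazepam", "api_full": "Diazepam",
                              "strength_value": 2.0, "strength_unit": "mg", "form": "tablet"}])
        kept, excluded = apply_exclusions(cat, descriptions={"C" * 15: "Diazepam_Tab 2 mg"})
        assert len(kept.components) == 1 and excluded.empty

    def test_partition_kept_plus_excluded_equals_catalog(self, small_pipeline):
        assert (
            len(small_pipeline["kept"].components) + len(small_pipeline["excluded"])
            == len(small_pipeline["catalog"].components)
        )
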