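import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from snpmeth import (
    SimulationParams,
    filter_rare_damaging,
    fisher_exact_2x2,
    gene_burden_test,
    generate_cohort,
    select_candidate_genes,
    variant_fisher_scan,
)

from oracles import fisher_two_sided_oracle, iter_all_tables


@pytest.fixture(scope="module")
def cohort():
    params = SimulationParams(
        seed=17, n_genes=40, n_probes=80, n_case=60, n_control=40,
        background_carrier_rate=0.05,
        enriched_genes=(("G0001", 10.0), ("G0002", 10.0)),
    )
    table, design, truth = generate_cohort(params)
    return table, design, truth


class TestFilter:
    def test_maf_boundary_is_strict(self, cohort):
        table, _, _ = cohort
        table = table.subset(np.arange(len(table)))
        table.df.loc[0, "maf"] = 0.05
        table.df.loc[1, "maf"] = 0.0499
        table.df.loc[[0, 1], "sift"] = "damaging"
        table.df.loc[[0, 1], "func_class"] = "nonsynonymous_SNV"
        kept, _ = filter_rare_damaging(table, maf_max=0.05)
        assert table.df.loc[0, "id"] not in set(kept.df["id"])
        assert table.df.loc[1, "id"] in set(kept.df["id"])

    def test_sift_tolerated_excluded(self, cohort):
        table, _, _ = cohort
        kept, _ = filter_rare_damaging(table, require_sift_damaging=True)
        assert (kept.df["sift"] == "damaging").all()
        kept_all, _ = filter_rare_damaging(table, require_sift_damaging=False)
        assert len(kept_all) >= len(kept)

    def test_filter_equals_rowwise_predicate(self, cohort):
        table, _, _ = cohort
        kept, summary = filter_rare_damaging(table)
        classes = {"nonsynonymous_SNV", "stopgain", "frameshift", "splicing"}
        expected = [
            row.id
            for row in table.df.itertuples(index=False)
            if row.maf < 0.05 and row.sift == "damaging" and row.func_class in classes
        ]
        assert kept.df["id"].tolist() == expected
        assert summary["n_variants"].sum() == len(expected)


class TestFisherExact:
    def test_hand_enumerated_table(self):
        # margins (4,4)/(4,4): 5 tables, two-sided mass 34/70
        _, p = fisher_exact_2x2(3, 1, 1, 3)
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_symmetric_table_p_one(self):
        odds, p = fisher_exact_2x2(5, 5, 5, 5)
        assert p == pytest.approx(1.0, abs=1e-12)
        assert odds == 1.0

    def test_all_zero_table(self):
        odds, p = fisher_exact_2x2(0, 0, 0, 0)
        assert p == 1.0 and np.isnan(odds)

    def test_infinite_odds_ratio(self):
        odds, _ = fisher_exact_2x2(3, 0, 1, 4)
        assert np.isposinf(odds)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 0, 0, 0)

    def test_matches_enumeration_oracle_small_n(self):
        # exhaustive check over every table with N <= 14 (full N <= 30 sweep
        # lives in the acceptance suite)
        for a, b, c, d in iter_all_tables(14):
            _, p = fisher_exact_2x2(a, b, c, d)
            assert abs(p - float(fisher_two_sided_oracle(a, b, c, d))) < 1e-10


class TestScan:
    def test_monomorphic_variant_flagged_p_one(self, cohort, two_group_design):
        table, design, _ = cohort
        table = table.subset(np.arange(len(table)))
        table.carriers.iloc[0, :] = False
        scan = variant_fisher_scan(table, design)
        row = scan[scan["id"] == table.df.loc[0, "id"]].iloc[0]
        assert row["p"] == 1.0 and bool(row["monomorphic"])

    def test_scan_equals_rowwise_fisher(self, cohort):
        table, design, _ = cohort
        scan = variant_fisher_scan(table, design)
        for row in scan.head(20).itertuples(index=False):
            _, p = fisher_exact_2x2(
                row.case_carriers,
                row.control_carriers,
                row.case_noncarriers,
                row.control_noncarriers,
            )
            assert row.p == pytest.approx(p, abs=1e-14)

    def test_null_scan_is_uniform_conservative(self):
        """Null variants: fraction with p<0.05 stays within Monte-Carlo
        error of the nominal level (exact tests are conservative)."""
        params = SimulationParams(
            seed=29, n_genes=500, variants_per_gene=(4, 4), n_probes=50,
            n_case=100, n_control=100, background_carrier_rate=0.1,
        )
        table, design, _ = generate_cohort(params)
        scan = variant_fisher_scan(table, design)
        frac = (scan["p"] < 0.05).mean()
        mc_se = np.sqrt(0.05 * 0.95 / len(scan))
        assert frac <= 0.05 + 3 * mc_se


class TestBurden:
    def test_single_variant_gene_equals_scan_p(self, cohort):
        table, design, _ = cohort
        counts = table.df.groupby("gene").size()
        singles = counts[counts == 1].index
        if len(singles) == 0:
            pytest.skip("no single-variant gene in fixture")
        scan = variant_fisher_scan(table, design).set_index("gene")
        burden = gene_burden_test(table, design).set_index("gene")
        for gene in singles:
            assert burden.loc[gene, "burden_p"] == pytest.approx(
                float(scan.loc[gene, "p"]), abs=1e-14
            )

    def test_multi_variant_carrier_counted_once(self, two_group_design):
        design = two_group_design(3, 3)
        df = pd.DataFrame(
            [
                ["v1", "chr1", 100, "A", "T", "G1", "nonsynonymous_SNV", "damaging", 0.01],
                ["v2", "chr1", 200, "A", "T", "G1", "nonsynonymous_SNV", "damaging", 0.01],
                ["v3", "chr1", 300, "A", "T", "G1", "nonsynonymous_SNV", "damaging", 0.01],
            ],
            columns=["id", "chrom", "pos", "ref", "alt", "gene", "func_class", "sift", "maf"],
        )
        carriers = pd.DataFrame(
            [[True, False, False, False, False, False]] * 3,
            index=df["id"],
            columns=design.samples,
        )
        from snpmeth.io import VariantTable

        burden = gene_burden_test(VariantTable(df, carriers), design)
        assert int(burden.loc[0, "case_carriers"]) == 1

    def test_burden_matches_setunion_oracle(self, cohort):
        table, design, _ = cohort
        burden = gene_burden_test(table, design).set_index("gene")
        for gene, ids in table.df.groupby("gene")["id"]:
            carrier = table.carriers.loc[ids].to_numpy().any(axis=0)
            case_mask = np.array([g == "case" for g in design.groups])
            a = int(carrier[case_mask].sum())
            b = int(carrier[~case_mask].sum())
            _, p = fisher_exact_2x2(a, b, int(case_mask.sum()) - a, int((~case_mask).sum()) - b)
            assert burden.loc[gene, "burden_p"] == pytest.approx(p, abs=1e-14)

    def test_adding_case_carrier_never_increases_burden_p(self, cohort):
        """For case-enriched genes, an extra case-only carrier can only push
        the two-sided exact p down (the two-sided test is monotone only in
        the direction of enrichment)."""
        table, design, _ = cohort
        burden0 = gene_burden_test(table, design).set_index("gene")
        enriched_dir = burden0[
            burden0["case_carriers"] / burden0["n_case"]
            >= burden0["control_carriers"] / burden0["n_control"]
        ]
        tested = 0
        for gene in enriched_dir.index[:5]:
            ids = table.df.loc[table.df.gene == gene, "id"]
            table2 = table.subset(np.arange(len(table)))
            free = [
                s for s in design.case_samples if not table2.carriers.loc[ids, s].any()
            ]
            if not free:
                continue
            table2.carriers.loc[ids[:1], free[0]] = True
            burden1 = gene_burden_test(table2, design).set_index("gene")
            assert burden1.loc[gene, "burden_p"] <= burden0.loc[gene, "burden_p"] + 1e-12
            tested += 1
        assert tested >= 3


class TestSelection:
    @pytest.fixture()
    def results(self):
        return pd.DataFrame(
            {
                "gene": ["A", "B", "C", "D"],
                "fisher_min_p": [0.04, 0.2, 0.004, 0.5],
                "burden_p": [0.2, 0.03, 0.004, 0.6],
            }
        )

    def test_union_flags(self, results):
        sel = select_candidate_genes(results, mode="union")
        assert set(sel["gene"]) == {"A", "B", "C"}
        a = sel[sel.gene == "A"].iloc[0]
        assert bool(a["fisher_hit"]) and not bool(a["burden_hit"])
        assert bool(sel[sel.gene == "C"]["top"].iloc[0])

    def test_intersection_excludes_single_route_hits(self, results):
        sel = select_candidate_genes(results, mode="intersection")
        assert set(sel["gene"]) == {"C"}

    def test_unknown_mode_rejected(self, results):
        with pytest.raises(ValueError):
            select_candidate_genes(results, mode="both")

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        ps=st.lists(
            st.tuples(
                st.floats(0.001, 1.0, allow_nan=False),
                st.floats(0.001, 1.0, allow_nan=False),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_inclusion_exclusion(self, ps):
        res = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(ps))],
                "fisher_min_p": [a for a, _ in ps],
                "burden_p": [b for _, b in ps],
            }
        )
        union = select_candidate_genes(res, mode="union")
        fisher = select_candidate_genes(res, mode="fisher_only")
        burden = select_candidate_genes(res, mode="burden_only")
        inter = select_candidate_genes(res, mode="intersection")
        assert len(union) == len(fisher) + len(burden) - len(inter)
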