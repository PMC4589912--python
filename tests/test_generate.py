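import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import sepsisbn as s
from sepsisbn.design import BAL, BLOOD, CLP, COMPARTMENTS, CONDITION_VARS, INJURY_INTERVAL
from sepsisbn.generate import BLOOD_NE_MEAN_0H, BLOOD_NE_MEAN_12H


class TestTruthPresets:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            s.default_truth("bogus")

    def test_paper_like_bal_collider(self, paper_like_truth):
        edges = set(paper_like_truth.compartments[BAL].edges())
        assert ("CLP", "NE") in edges
        assert ("LungInsult", "NE") in edges
        # the two condition parents are not adjacent in the truth
        assert ("CLP", "LungInsult") not in edges
        assert ("LungInsult", "CLP") not in edges
        # Y tail and albumin leak downstream of NE
        assert ("NE", "EO") in edges
        assert ("NE", "Albumin") in edges

    def test_paper_like_chemokines_insult_only(self, paper_like_truth):
        bal = paper_like_truth.compartments[BAL].nodes
        for chem in ("KC", "MIP2a", "LIX", "MCP1"):
            assert bal[chem].cond_parents == ("LungInsult",)

    def test_null_preset_has_no_edges(self):
        truth = s.default_truth("null")
        assert all(not t.edges() for t in truth.compartments.values())

    def test_blood_ne_calibrated_below_baseline_at_12h(self, paper_like_truth):
        ne = paper_like_truth.compartments[BLOOD].nodes["NE"]
        assert ne.conditional_mean((1, 2)) == BLOOD_NE_MEAN_12H
        assert ne.conditional_mean((1, 1)) == BLOOD_NE_MEAN_0H
        assert ne.conditional_mean((1, 2)) < ne.conditional_mean((1, 1))


class TestGenerateCohort:
    def test_shapes_and_columns(self, paper_like_cohort):
        for comp, table in paper_like_cohort.items():
            assert len(table.data) == 120  # 12 groups x 10
            for cond in CONDITION_VARS:
                assert cond in table.data.columns
        assert "Albumin" in paper_like_cohort[BAL].data.columns
        assert "Albumin" not in paper_like_cohort[BLOOD].data.columns

    def test_all_values_non_negative_and_finite(self, paper_like_cohort):
        for table in paper_like_cohort.values():
            values = table.data[table.mediators].to_numpy()
            assert np.isfinite(values).all()
            assert (values >= 0).all()

    def test_rows_match_design_groups(self, paper_like_cohort):
        valid = {g.condition.as_tuple() for g in s.enumerate_design()}
        for table in paper_like_cohort.values():
            conds = set(
                map(tuple, table.data[list(CONDITION_VARS)].to_numpy())
            )
            assert conds <= valid
            assert len(conds) == 12

    def test_seed_determinism_byte_for_byte(self, paper_like_truth):
        a = s.generate_cohort(paper_like_truth, None, 5, seed=42)
        b = s.generate_cohort(paper_like_truth, None, 5, seed=42)
        for comp in COMPARTMENTS:
            assert a[comp].data.to_csv() == b[comp].data.to_csv()

    def test_different_seeds_differ(self, paper_like_truth):
        a = s.generate_cohort(paper_like_truth, None, 5, seed=1)
        b = s.generate_cohort(paper_like_truth, None, 5, seed=2)
        assert not a[BAL].data.equals(b[BAL].data)

    def test_invalid_n_per_group(self, paper_like_truth):
        with pytest.raises(ValueError):
            s.generate_cohort(paper_like_truth, None, 0, seed=1)

    def test_cyclic_truth_rejected(self):
        from sepsisbn.generate import CompartmentTruth, NodeModel

        with pytest.raises(ValueError, match="cycle"):
            CompartmentTruth(
                "bal",
                {
                    "A": NodeModel(mean=1.0, sigma=0.5, med_parents={"B": 1.0}),
                    "B": NodeModel(mean=1.0, sigma=0.5, med_parents={"A": 1.0}),
                },
            )


class TestMomentRecovery:
    def test_condition_parent_means_recovered_at_large_n(self, paper_like_truth):
        """Empirical conditional means converge to the configured means."""
        tables = s.generate_cohort(paper_like_truth, None, 1000, seed=11)
        for comp in COMPARTMENTS:
            truth = paper_like_truth.compartments[comp]
            df = tables[comp].data
            for name, model in truth.nodes.items():
                if not model.cond_parents or model.med_parents:
                    continue
                for key, sub in df.groupby(list(model.cond_parents)):
                    key = key if isinstance(key, tuple) else (key,)
                    target = model.conditional_mean(tuple(int(k) for k in key))
                    vals = sub[name].to_numpy()
                    se = vals.std(ddof=1) / np.sqrt(len(vals))
                    assert abs(vals.mean() - target) < 3 * se, (comp, name, key)

    def test_blood_ne_12h_below_0h(self, paper_like_truth):
        tables = s.generate_cohort(paper_like_truth, None, 500, seed=3)
        df = tables[BLOOD].data
        clp = df[df[CLP] == 1]
        m0 = clp[clp[INJURY_INTERVAL] == 1]["NE"].mean()
        m12 = clp[clp[INJURY_INTERVAL] == 2]["NE"].mean()
        assert m12 < m0


class TestNullIndependence:
    def test_null_mediators_independent_of_conditions(self):
        """Chi-squared on discretized null data rejects at ~alpha = 0.001."""
        truth = s.default_truth("null")
        mediators = ["IL6", "TNFa", "NE", "KC", "EO"]
        tests = 0
        rejections = 0
        for seed in range(20):
            tables = s.generate_cohort(truth, None, 10, seed=seed)
            table, _ = s.discretize(tables[BAL].data)
            for med in mediators:
                for cond in CONDITION_VARS:
                    ct = pd.crosstab(table.data[cond], table.data[med])
                    if ct.shape[0] < 2 or ct.shape[1] < 2:
                        continue
                    _, p, _, _ = chi2_contingency(ct)
                    tests += 1
                    rejections += p < 0.001
        assert tests >= 250
        assert rejections / tests <= 0.05


class TestCohortIO:
    def test_write_and_read_roundtrip(self, paper_like_truth, tmp_path):
        tables = s.generate_cohort(paper_like_truth, None, 3, seed=5)
        written = s.write_cohort(tables, tmp_path, truth=paper_like_truth)
        assert (tmp_path / "cohort.json").exists()
        back = s.read_cohort({c: tmp_path / f"{c}.csv" for c in COMPARTMENTS})
        for comp in COMPARTMENTS:
            pd.testing.assert_frame_equal(
                back[comp].data, tables[comp].data, check_exact=False
            )

    def test_read_requires_condition_columns(self, tmp_path):
        pd.DataFrame({"IL6": [1.0, 2.0]}).to_csv(tmp_path / "bal.csv", index=False)
        with pytest.raises(ValueError, match="condition"):
            s.read_cohort({"bal": tmp_path / "bal.csv"})
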