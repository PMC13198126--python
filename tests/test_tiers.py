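"""Tier subtraction ledger and esterified-FA partition accounting."""

import numpy as np
import pandas as pd
import pytest

from lipidtiers.tiers import (
    LIPIDOME_SUM,
    TIER_DERIVED,
    TiersError,
    esterified_from_subtraction,
    partition_flows,
    partition_fractions,
    sink_by_class,
    tg_carbon_bins,
)


def _amounts(rows):
    return pd.DataFrame(rows, columns=["sample_id", "analyte", "amount_nmol_per_g"])


def _lipidome(rows):
    return pd.DataFrame(rows, columns=["sample_id", "species", "amount_nmol_per_g"])


class TestLedger:
    def test_subtraction_identity(self):
        ledger = esterified_from_subtraction(
            _amounts([("s1", "FA 18:1", 30.0)]),
            _amounts([("s1", "FA 18:1", 100.0)]),
        )
        row = ledger.iloc[0]
        assert row["esterified_amount"] == pytest.approx(70.0)
        assert not row["clamped"]

    def test_negative_subtraction_clamped_and_flagged(self):
        ledger = esterified_from_subtraction(
            _amounts([("s1", "FA 18:1", 35.0)]),
            _amounts([("s1", "FA 18:1", 30.0)]),
        )
        row = ledger.iloc[0]
        assert row["esterified_amount"] == 0.0
        assert row["clamped"]
        assert row["flag"] == "clamped"

    def test_one_tier_only_flagged_unmatched(self):
        ledger = esterified_from_subtraction(
            _amounts([("s1", "FA 18:1", 30.0), ("s1", "FA 17:1", 2.0)]),
            _amounts([("s1", "FA 18:1", 100.0)]),
        )
        un = ledger[ledger["analyte"] == "FA 17:1"].iloc[0]
        assert un["flag"] == "unmatched"
        assert np.isnan(un["esterified_amount"])

    def test_duplicate_rows_rejected(self):
        dup = _amounts([("s1", "FA 18:1", 1.0), ("s1", "FA 18:1", 2.0)])
        with pytest.raises(TiersError, match="duplicate"):
            esterified_from_subtraction(dup, _amounts([("s1", "FA 18:1", 3.0)]))


class TestPartition:
    def _ledger(self, est=20.0, fa="FA 18:1"):
        return pd.DataFrame(
            {
                "sample_id": ["s1"],
                "analyte": [fa],
                "free_amount": [5.0],
                "total_amount": [5.0 + est],
                "esterified_amount": [est],
                "clamped": [False],
                "flag": [""],
            }
        )

    def test_worked_example_quarter_fractions(self):
        """DG and PI at 5 nmol/g each carrying one 18:1, esterified pool 20
        nmol/g: each sink explains 5 x 1 / 20 = 0.25."""
        lip = _lipidome([
            ("s1", "DG 36:3(18:2_18:1)", 5.0),
            ("s1", "PI 36:3(18:2_18:1)", 5.0),
        ])
        pt = partition_fractions(lip, self._ledger(), "FA 18:1", denominator_mode=TIER_DERIVED)
        frac = pt.set_index("sink")["fraction"]
        assert frac["DG"] == pytest.approx(0.25)
        assert frac["PI"] == pytest.approx(0.25)
        assert pt["coverage"].iloc[0] == pytest.approx(0.5)

    def test_sphingolipids_never_move_fractions(self):
        lip = _lipidome([
            ("s1", "DG 36:3(18:2_18:1)", 5.0),
            ("s1", "PI 36:3(18:2_18:1)", 5.0),
        ])
        base = partition_fractions(lip, self._ledger(), "FA 18:1")
        with_sm = _lipidome([
            ("s1", "DG 36:3(18:2_18:1)", 5.0),
            ("s1", "PI 36:3(18:2_18:1)", 5.0),
            ("s1", "SM 33:1;O2", 1e6),
            ("s1", "Cer d18:1/17:0", 1e6),
        ])
        after = partition_fractions(with_sm, self._ledger(), "FA 18:1")
        pd.testing.assert_frame_equal(
            base.drop(columns="unresolved_amount"),
            after.drop(columns="unresolved_amount"),
        )

    def test_lipidome_sum_fractions_normalize_to_one(self):
        lip = _lipidome([
            ("s1", "DG 36:3(18:2_18:1)", 5.0),
            ("s1", "PI 36:3(18:2_18:1)", 5.0),
            ("s1", "TG 52:2(16:0_18:1_18:1)", 7.0),
        ])
        pt = partition_fractions(lip, self._ledger(), "FA 18:1", denominator_mode=LIPIDOME_SUM)
        assert pt["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_sink_gets_fraction_one(self):
        lip = _lipidome([("s1", "TG 54:3(18:1_18:1_18:1)", 4.0)])
        pt = partition_fractions(
            lip, self._ledger(), "FA 18:1",
            sinks=lambda s: "all", denominator_mode=LIPIDOME_SUM,
        )
        assert pt["fraction"].iloc[0] == pytest.approx(1.0)

    def test_multiplicity_weighting(self):
        # the TG carries two 18:1 chains: contribution 2 x 7 = 14
        lip = _lipidome([("s1", "TG 52:2(16:0_18:1_18:1)", 7.0)])
        pt = partition_fractions(lip, self._ledger(), "FA 18:1")
        assert pt["contribution"].iloc[0] == pytest.approx(14.0)
        assert pt["fraction"].iloc[0] == pytest.approx(14.0 / 20.0)

    def test_sum_composition_species_go_to_unresolved(self):
        lip = _lipidome([
            ("s1", "DG 36:3(18:2_18:1)", 5.0),
            ("s1", "TG 52:3", 9.0),
        ])
        pt = partition_fractions(lip, self._ledger(), "FA 18:1")
        assert set(pt["sink"]) == {"DG"}
        assert pt["unresolved_amount"].iloc[0] == pytest.approx(9.0)

    def test_undefined_denominator_flagged(self):
        lip = _lipidome([("s1", "DG 36:3(18:2_18:1)", 5.0)])
        pt = partition_fractions(lip, self._ledger(est=0.0), "FA 18:1")
        assert (pt["flag"] == "undefined_denominator").all()
        assert pt["fraction"].isna().all()

    def test_monotonicity_in_lipidome_sum_mode(self):
        lip1 = _lipidome([
            ("s1", "DG 36:3(18:2_18:1)", 5.0),
            ("s1", "PC 34:1(16:0_18:1)", 5.0),
        ])
        lip2 = _lipidome([
            ("s1", "DG 36:3(18:2_18:1)", 8.0),
            ("s1", "PC 34:1(16:0_18:1)", 5.0),
        ])
        f1 = partition_fractions(lip1, self._ledger(), "FA 18:1", denominator_mode=LIPIDOME_SUM
                                 ).set_index("sink")["fraction"]
        f2 = partition_fractions(lip2, self._ledger(), "FA 18:1", denominator_mode=LIPIDOME_SUM
                                 ).set_index("sink")["fraction"]
        assert f2["DG"] > f1["DG"]
        assert f2["PC"] < f1["PC"]


class TestTgBins:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("TG 48:2", "TG C<=50"),
            ("TG 50:1", "TG C<=50"),  # boundary inclusive on the lower bin
            ("TG 52:3", "TG C>50"),
        ],
    )
    def test_default_boundary(self, name, expected):
        from lipidtiers.nomenclature import parse_lipid_name

        assert tg_carbon_bins()(parse_lipid_name(name)) == expected

    def test_configurable_boundary_and_non_tg_passthrough(self):
        from lipidtiers.nomenclature import parse_lipid_name

        bins = tg_carbon_bins(45)
        assert bins(parse_lipid_name("TG 48:2")) == "TG C>45"
        assert bins(parse_lipid_name("PC 34:1")) == "PC"


class TestFlows:
    def _partition(self, fracs):
        rows = []
        for sample, (dg, pc) in fracs.items():
            rows += [
                {"sample_id": sample, "fa": "FA 18:1", "sink": "DG", "fraction": dg},
                {"sample_id": sample, "fa": "FA 18:1", "sink": "PC", "fraction": pc},
            ]
        return pd.DataFrame(rows)

    def test_identical_conditions_have_zero_deltas(self):
        p = self._partition({"a": (0.2, 0.8), "b": (0.3, 0.7)})
        flow = partition_flows({"ctl": p, "trt": p.copy()})
        assert (flow["delta"].abs() < 1e-12).all()

    def test_single_condition_equals_its_fractions(self):
        p = self._partition({"a": (0.2, 0.8)})
        flow = partition_flows({"only": p})
        assert flow.set_index("sink")["mean_fraction"]["DG"] == pytest.approx(0.2)
        assert "delta" not in flow.columns

    def test_injected_shift_detected_with_direction(self):
        ctl = self._partition({f"c{i}": (0.20, 0.80) for i in range(4)})
        trt = self._partition({f"t{i}": (0.30, 0.70) for i in range(4)})
        # jitter so the t test is defined
        rng = np.random.default_rng(0)
        for df in (ctl, trt):
            df["fraction"] += rng.normal(0, 1e-3, len(df))
        flow = partition_flows({"ctl": ctl, "trt": trt})
        dg = flow[(flow["sink"] == "DG") & (flow["condition"] == "trt")].iloc[0]
        assert dg["delta"] == pytest.approx(0.10, abs=0.01)
        assert dg["significant"]

    def test_mismatched_sinks_rejected(self):
        p1 = self._partition({"a": (0.2, 0.8)})
        p2 = p1.copy()
        p2.loc[p2["sink"] == "PC", "sink"] = "TG"
        with pytest.raises(TiersError, match="mismatched sink"):
            partition_flows({"x": p1, "y": p2})
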