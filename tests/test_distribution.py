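"""Partition-coefficient methods and clearance conversions.

The worked-value tests re-evaluate each published partition equation
independently (explicit arithmetic straight from the composition table)
and compare against the implementation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from struct2pk import distribution as dist
from struct2pk.distribution import (
    KP_METHODS,
    ParameterSet,
    classify_ionization,
    clint_to_cl,
    compute_kp,
    plasma_mimic_kp,
    scale_microsomal_clint,
    vdss_from_kp,
    wellstirred_cl_to_clint,
)
from struct2pk.physio import TISSUES, TissueComposition


class TestIonization:
    def test_acid_at_its_pka_is_half_ionized(self):
        state = classify_ionization(7.4, None)
        assert state.fraction_acid_ionized == pytest.approx(0.5)

    def test_strong_base_two_units_above_ph(self):
        state = classify_ionization(None, 9.4)
        assert state.fraction_base_ionized == pytest.approx(1 / (1 + 10**-2), rel=1e-9)
        assert state.ionization_class == "base"

    def test_no_pka_is_neutral_unionized(self):
        state = classify_ionization(None, None)
        assert state.ionization_class == "neutral"
        assert state.fraction_ionized == 0.0

    def test_classification_thresholds(self):
        assert classify_ionization(4.0, 9.0).ionization_class == "zwitterion"
        assert classify_ionization(4.0, 3.0).ionization_class == "acid"
        assert classify_ionization(11.0, 9.0).ionization_class == "base"
        assert classify_ionization(11.0, 3.0).ionization_class == "neutral"


class TestPlasmaMimic:
    @pytest.mark.parametrize("method", KP_METHODS)
    def test_plasma_like_tissue_partitions_at_unity(self, method, comp):
        params = ParameterSet(fu=0.25, logp=2.0, mw=300.0)
        assert plasma_mimic_kp(method, params, comp) == pytest.approx(1.0, abs=1e-9)


class TestPoulinTheilFamily:
    def test_berezhkovskiy_equals_poulin_theil_at_full_unbound(self, comp):
        params = ParameterSet(fu=1.0, logp=2.0, mw=300.0)
        pt = compute_kp("poulin_theil", params, comp).kp
        bz = compute_kp("berezhkovskiy", params, comp).kp
        assert np.allclose(pt, bz, rtol=1e-12)

    def test_berezhkovskiy_correction_direction_for_bound_drug(self, comp):
        """For a highly bound drug the corrected equation lowers lean-tissue Kp.

        Dividing the plasma aqueous term by fu inflates the denominator, so
        the correction systematically deflates Kp relative to the original
        whole-ratio fu_p/fu_t scaling whenever fu < 1.
        """
        for logp in (0.0, 1.0, 2.0, 3.0):
            params = ParameterSet(fu=0.05, logp=logp, mw=300.0)
            pt = compute_kp("poulin_theil", params, comp).kp
            bz = compute_kp("berezhkovskiy", params, comp).kp
            for tissue in ("muscle", "heart", "kidney", "brain"):
                assert bz[tissue] <= pt[tissue]

    def test_poulin_theil_muscle_worked_value(self, comp):
        """Independent re-evaluation of the published non-adipose equation."""
        params = ParameterSet(fu=0.1, logp=2.0, mw=300.0)
        row = comp.row("muscle")
        pl = comp.plasma
        p = 10.0**2.0
        fw_t = row["f_water_ec"] + row["f_water_ic"]
        fw_p = pl["f_water_ec"] + pl["f_water_ic"]
        num = p * (row["f_nl"] + 0.3 * row["f_np"]) + (fw_t + 0.7 * row["f_np"])
        den = p * (pl["f_nl"] + 0.3 * pl["f_np"]) + (fw_p + 0.7 * pl["f_np"])
        fu_t = 1.0 / (1.0 + 0.5 * (1.0 - 0.1) / 0.1)
        expected = num / den * 0.1 / fu_t
        got = compute_kp("poulin_theil", params, comp)["muscle"]
        assert got == pytest.approx(expected, rel=1e-6)

    def test_low_logp_limit_is_water_ratio(self, comp):
        """As logP -> -inf partitioning reduces to the aqueous-phase ratio."""
        params = ParameterSet(fu=1.0, logp=-12.0, mw=100.0)
        row = comp.row("muscle")
        pl = comp.plasma
        fw_t = row["f_water_ec"] + row["f_water_ic"] + 0.7 * row["f_np"]
        fw_p = pl["f_water_ec"] + pl["f_water_ic"] + 0.7 * pl["f_np"]
        got = compute_kp("poulin_theil", params, comp)["muscle"]
        assert got == pytest.approx(fw_t / fw_p, rel=1e-6)


class TestRodgersRowland:
    def test_pure_water_tissue_neutral_compound_kpu_unity(self):
        table = pd.DataFrame(
            {
                "f_water_ec": 1.0,
                "f_water_ic": 0.0,
                "f_nl": 0.0,
                "f_np": 0.0,
                "ap_mg_per_g": 0.0,
                "albumin_ratio": 0.0,
                "f_protein": 0.0,
            },
            index=pd.Index(list(TISSUES), name="tissue"),
        )
        table.loc["plasma"] = [1.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0]
        comp_water = TissueComposition(table=table)
        params = ParameterSet(fu=1.0, logp=-5.0, mw=100.0)
        kp = compute_kp("rodgers_rowland", params, comp_water)
        # fu = 1 so Kp == Kpu
        assert kp["muscle"] == pytest.approx(1.0, rel=1e-6)

    def test_acidic_phospholipid_binding_increases_base_kp(self, comp):
        params = ParameterSet(fu=0.2, logp=2.0, mw=350.0, pka_base=10.0)
        base = compute_kp("rodgers_rowland", params, comp)["muscle"]
        richer = comp.table.copy()
        richer.loc["muscle", "ap_mg_per_g"] *= 2.0
        kp_richer = compute_kp("rodgers_rowland", params, TissueComposition(table=richer))["muscle"]
        assert kp_richer > base

    def test_strong_base_worked_value(self, comp):
        """Independent evaluation of the moderate-to-strong base equations."""
        fu, logp, pka = 0.2, 2.0, 9.0
        params = ParameterSet(fu=fu, logp=logp, mw=350.0, pka_base=pka)
        p = 10.0**logp
        x_iw = 10.0 ** (pka - 7.0)
        y_p = 10.0 ** (pka - 7.4)
        x_bc = 10.0 ** (pka - 7.22)
        kpu_bc = (0.45 - 1.0 + 1.0) / (0.45 * fu)
        pterm_bc = p * 0.0017 + (0.3 * p + 0.7) * 0.0029
        ka_ap = (
            (kpu_bc - (1 + x_bc) / (1 + y_p) * 0.603 - pterm_bc / (1 + y_p))
            * (1 + y_p)
            / (0.5 * x_bc)
        )
        row = comp.row("liver")
        pterm = p * row["f_nl"] + (0.3 * p + 0.7) * row["f_np"]
        kpu = (
            row["f_water_ec"]
            + (1 + x_iw) / (1 + y_p) * row["f_water_ic"]
            + ka_ap * row["ap_mg_per_g"] * x_iw / (1 + y_p)
            + pterm / (1 + y_p)
        )
        expected = kpu * fu
        got = compute_kp("rodgers_rowland", params, comp)["liver"]
        assert got == pytest.approx(expected, rel=1e-6)

    def test_acid_worked_value(self, comp):
        """Independent evaluation of the acid/neutral-branch equations."""
        fu, logp, pka = 0.1, 1.5, 4.5
        params = ParameterSet(fu=fu, logp=logp, mw=250.0, pka_acid=pka)
        p = 10.0**logp
        x = 10.0 ** (7.0 - pka)
        y = 10.0 ** (7.4 - pka)
        pl = comp.plasma
        fw_p = pl["f_water_ec"] + pl["f_water_ic"]
        pterm_p = p * pl["f_nl"] + (0.3 * p + 0.7) * pl["f_np"]
        ka_pr = 1.0 / fu - fw_p - pterm_p / (1 + y)
        row = comp.row("kidney")
        pterm = p * row["f_nl"] + (0.3 * p + 0.7) * row["f_np"]
        kpu = (
            row["f_water_ec"]
            + (1 + x) / (1 + y) * row["f_water_ic"]
            + pterm / (1 + y)
            + ka_pr * row["albumin_ratio"]
        )
        expected = kpu * fu
        got = compute_kp("rodgers_rowland", params, comp)["kidney"]
        assert got == pytest.approx(expected, rel=1e-6)

    def test_base_flag_without_pka_falls_back_to_neutral(self):
        with pytest.warns(UserWarning, match="falling back to neutral"):
            params = ParameterSet(fu=0.2, logp=2.0, mw=300.0, ionization_class="base")
        assert params.ionization_class == "neutral"


class TestSchmittAndPkSim:
    def test_schmitt_adipose_kp_increases_with_logp(self, comp):
        values = [
            compute_kp("schmitt", ParameterSet(fu=0.2, logp=lp, mw=300.0), comp)["adipose"]
            for lp in (0.0, 1.0, 2.0, 3.0, 4.0)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_schmitt_worked_value(self, comp):
        """Independent evaluation of the implemented composition sum."""
        params = ParameterSet(fu=0.3, logp=2.5, mw=320.0, pka_base=9.0)
        fb = 1.0 / (1.0 + 10.0 ** (7.4 - 9.0))
        f_n, f_cat = (1.0 - fb), fb
        p = 10.0**2.5
        k_np = p * (f_n + 0.3 * f_cat)
        k_nl = p * (f_n + 0.001 * (1 - f_n))
        k_ap = p * (f_n + 20.0 * f_cat)
        k_prot = 0.163 + 0.0221 * k_np
        row = comp.row("heart")
        affinity = (
            row["f_water_ec"] + row["f_water_ic"]
            + k_nl * row["f_nl"]
            + k_np * row["f_np"]
            + k_ap * row["ap_mg_per_g"] / 1000.0
            + k_prot * row["f_protein"]
        )
        assert compute_kp("schmitt", params, comp)["heart"] == pytest.approx(
            0.3 * affinity, rel=1e-6
        )

    def test_pksim_monotone_in_logp_for_lipid_tissues(self, comp):
        lo = compute_kp("pksim_standard", ParameterSet(fu=0.2, logp=1.0, mw=300.0), comp)
        hi = compute_kp("pksim_standard", ParameterSet(fu=0.2, logp=3.0, mw=300.0), comp)
        for tissue in TISSUES:
            assert hi[tissue] >= lo[tissue]

    def test_pksim_worked_value(self, comp):
        params = ParameterSet(fu=0.2, logp=2.0, mw=300.0)
        p = 100.0
        pl = comp.plasma
        fw_p = pl["f_water_ec"] + pl["f_water_ic"]
        f_l_p = pl["f_nl"] + pl["f_np"] + pl["ap_mg_per_g"] / 1000.0
        k_prot = (1.0 / 0.2 - fw_p - p * f_l_p) / pl["f_protein"]
        row = comp.row("skin")
        fw_t = row["f_water_ec"] + row["f_water_ic"]
        f_l_t = row["f_nl"] + row["f_np"] + row["ap_mg_per_g"] / 1000.0
        expected = 0.2 * (fw_t + p * f_l_t + k_prot * row["f_protein"])
        assert compute_kp("pksim_standard", params, comp)["skin"] == pytest.approx(
            expected, rel=1e-6
        )


class TestKpGridProperties:
    def test_all_methods_positive_finite_on_random_grid(self, comp):
        rng = np.random.default_rng(1234)
        for _ in range(40):
            params = ParameterSet(
                fu=float(rng.uniform(0.01, 1.0)),
                logp=float(rng.uniform(-2.0, 6.0)),
                mw=float(rng.uniform(150.0, 600.0)),
                pka_acid=float(rng.uniform(2.0, 12.0)) if rng.random() < 0.5 else None,
                pka_base=float(rng.uniform(2.0, 12.0)) if rng.random() < 0.5 else None,
            )
            for method in KP_METHODS:
                kp = compute_kp(method, params, comp).kp  # KpVector validates > 0, finite
                assert np.all(np.isfinite(kp)) and np.all(kp > 0)

    def test_vdss_spread_across_methods_for_lipophilic_base(self, comp, phys, lipophilic_base):
        vd = [vdss_from_kp(compute_kp(m, lipophilic_base, comp), phys) for m in KP_METHODS]
        assert max(vd) - min(vd) > 0
        assert max(vd) / min(vd) > 1.1  # materially different, not round-off


def test_kp_table_long_format(comp):
    from struct2pk.distribution import kp_table

    params = {"a": ParameterSet(fu=0.3, logp=2.0, mw=300.0)}
    table = kp_table(params, methods=("poulin_theil", "schmitt"), comp=comp)
    assert set(table.columns) == {"compound_id", "method", "tissue", "kp"}
    assert len(table) == 2 * 11  # two methods x eleven tissues
    assert (table["kp"] > 0).all()


class TestWellStirred:
    def test_midpoint_identity(self):
        # CLh = Qh/2 at fu_b = 1 implies CLint = Qh
        assert wellstirred_cl_to_clint(27.6, 1.0, qh=55.2) == pytest.approx(55.2, rel=1e-12)

    def test_low_extraction_limit(self):
        cl = 1e-6
        assert wellstirred_cl_to_clint(cl, 0.5) == pytest.approx(cl / 0.5, rel=1e-6)

    def test_worked_value(self):
        got = wellstirred_cl_to_clint(40.0, 0.1, qh=55.2, bp=1.0)
        assert got == pytest.approx(55.2 * 40.0 / (0.1 * 15.2), rel=1e-12)

    def test_flow_limited_ceiling(self):
        assert clint_to_cl(1e12, 1.0, qh=55.2) == pytest.approx(55.2, rel=1e-9)

    def test_half_flow_at_matched_intrinsic(self):
        assert clint_to_cl(55.2, 1.0, qh=55.2) == pytest.approx(27.6, rel=1e-12)

    def test_exceeding_hepatic_flow_rejected(self):
        with pytest.raises(ValueError, match="exceeds hepatic blood flow"):
            wellstirred_cl_to_clint(60.0, 0.5, qh=55.2)

    @settings(max_examples=100, derandomize=True)
    @given(
        cl_frac=st.floats(1e-4, 0.999),
        fu=st.floats(0.01, 1.0),
        qh=st.floats(10.0, 100.0),
        bp=st.floats(0.5, 2.0),
    )
    def test_round_trip_identity(self, cl_frac, fu, qh, bp):
        cl = cl_frac * qh * bp
        clint = wellstirred_cl_to_clint(cl, fu, qh=qh, bp=bp)
        assert clint_to_cl(clint, fu, qh=qh, bp=bp) == pytest.approx(cl, rel=1e-9)


class TestMicrosomalScaling:
    def test_worked_value(self):
        out = scale_microsomal_clint(10.0, mppgl=45.0, liver_g_per_kg=40.0)
        assert out["whole_body"] == pytest.approx(18.0, rel=1e-12)
        assert out["specific"] == pytest.approx(0.45, rel=1e-12)

    def test_zero_and_linearity(self):
        assert scale_microsomal_clint(0.0)["whole_body"] == 0.0
        single = scale_microsomal_clint(7.0, mppgl=45.0)["whole_body"]
        doubled = scale_microsomal_clint(7.0, mppgl=90.0)["whole_body"]
        assert doubled == pytest.approx(2 * single, rel=1e-12)
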