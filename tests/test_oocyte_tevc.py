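"""Virtual TEVC: protocols, extractors, heteromers, fixture generation."""

import json

import numpy as np
import pytest

from trekleak.ionic_driving import (
    MUTANT_PROFILE,
    ND96,
    OOCYTE_INTERNAL,
    PermeabilityProfile,
    ThermalContext,
    fit_permeability_ratio,
    nernst_potential,
)
from trekleak.ionic_driving import ErevSeries
from trekleak.oocyte_tevc import (
    RAMP_PROTOCOL,
    STEP_PROTOCOL,
    ChannelPopulation,
    EmRootError,
    IVRelation,
    NoReversalError,
    OocyteModel,
    VoltageProtocol,
    apply_adrenergic,
    assemble_heteromers,
    generate_fixture_suite,
    measure_erev,
    run_protocol,
    solve_em,
)

ROOM = ThermalContext(294.15)


def single_population_model(alpha, noise_sd=0.0, seed=None, genotype="wt"):
    return OocyteModel(
        populations=(
            ChannelPopulation(
                "trek", PermeabilityProfile(1.0, alpha), 1.0, genotype=genotype
            ),
        ),
        noise_sd=noise_sd,
        seed=seed,
    )


class TestRunProtocol:
    def test_selective_channel_reverses_at_nernst(self):
        _, iv = run_protocol(single_population_model(0.0), RAMP_PROTOCOL)
        e_k = nernst_potential(ND96.k_mM, OOCYTE_INTERNAL.k_mM, ROOM)
        assert measure_erev(iv) == pytest.approx(e_k, abs=0.5)

    def test_mutant_reverses_at_ghk_prediction(self):
        _, iv = run_protocol(single_population_model(0.2), RAMP_PROTOCOL)
        assert measure_erev(iv) == pytest.approx(-41.7, abs=0.5)

    def test_seeded_determinism(self):
        t1, iv1 = run_protocol(single_population_model(0.2, 0.5, seed=4))
        t2, iv2 = run_protocol(single_population_model(0.2, 0.5, seed=4))
        np.testing.assert_array_equal(iv1.i_uA, iv2.i_uA)
        np.testing.assert_array_equal(t1.i_uA, t2.i_uA)

    def test_step_protocol_shapes(self):
        trace, iv = run_protocol(single_population_model(0.0), STEP_PROTOCOL)
        assert len(iv.v_mV) == 19  # −130 … +50 in 10-mV steps
        assert iv.v_mV[0] == -130.0 and iv.v_mV[-1] == 50.0

    def test_gating_relaxation_scales_toward_steady_state(self):
        model = single_population_model(0.0)
        trace_ss, _ = run_protocol(model, RAMP_PROTOCOL)
        trace_gate, _ = run_protocol(model, RAMP_PROTOCOL, gating_tau_s=0.1,
                                     gating_start=0.5)
        # early current reduced in magnitude, late current converged
        assert abs(trace_gate.i_uA[0]) < abs(trace_ss.i_uA[0])
        assert trace_gate.i_uA[-1] == pytest.approx(trace_ss.i_uA[-1], rel=1e-6)


class TestMeasureErev:
    def test_midpoint_interpolation(self):
        iv = IVRelation(v_mV=np.array([-60.0, -40.0]), i_uA=np.array([-1.0, 1.0]))
        assert measure_erev(iv) == pytest.approx(-50.0)

    def test_all_positive_rejected(self):
        iv = IVRelation(v_mV=np.array([-60.0, -40.0]), i_uA=np.array([1.0, 2.0]))
        with pytest.raises(NoReversalError):
            measure_erev(iv)

    def test_multiple_crossings_warns_and_returns_most_negative(self):
        iv = IVRelation(
            v_mV=np.array([-80.0, -60.0, -40.0, -20.0]),
            i_uA=np.array([-1.0, 1.0, -1.0, 1.0]),
        )
        with pytest.warns(UserWarning, match="zero crossings"):
            erev = measure_erev(iv)
        assert erev == pytest.approx(-70.0)


class TestSolveEm:
    def test_kir_only_rests_at_nernst_potassium(self):
        model = OocyteModel(kir_conductance=1.0)
        e_k = nernst_potential(ND96.k_mM, OOCYTE_INTERNAL.k_mM, ROOM)
        assert solve_em(model) == pytest.approx(e_k, abs=2.0)

    def test_leak_only_rests_at_leak_reversal(self):
        model = OocyteModel(leak_conductance=0.5, leak_reversal_mV=-20.0)
        assert solve_em(model) == pytest.approx(-20.0, abs=1e-3)

    def test_conductance_rescaling_invariance(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            alpha = rng.uniform(0, 0.5)
            g = rng.uniform(0.1, 5.0)
            kir = rng.uniform(0, 2.0)
            leak = rng.uniform(0.001, 0.2)
            base = OocyteModel(
                populations=(ChannelPopulation("p", PermeabilityProfile(1.0, alpha), g),),
                kir_conductance=kir,
                leak_conductance=leak,
            )
            c = rng.uniform(0.2, 10.0)
            scaled = OocyteModel(
                populations=(
                    ChannelPopulation("p", PermeabilityProfile(1.0, alpha), g * c),
                ),
                kir_conductance=kir * c,
                leak_conductance=leak * c,
            )
            assert solve_em(scaled) == pytest.approx(solve_em(base), abs=2e-3)

    def test_sodium_leak_depolarizes_but_not_below_ek(self):
        rng = np.random.default_rng(17)
        e_k = nernst_potential(ND96.k_mM, OOCYTE_INTERNAL.k_mM, ROOM)
        for _ in range(30):
            g_wt = rng.uniform(0.1, 2.0)
            kir = rng.uniform(0.0, 1.0)
            base = OocyteModel(
                populations=(ChannelPopulation("wt", PermeabilityProfile(1.0, 0.0), g_wt),),
                kir_conductance=kir,
            )
            with_mutant = OocyteModel(
                populations=base.populations
                + (ChannelPopulation("mut", PermeabilityProfile(1.0, rng.uniform(0.05, 0.5)),
                                     rng.uniform(0.1, 2.0), genotype="mutant"),),
                kir_conductance=kir,
            )
            em_base = solve_em(base)
            em_mut = solve_em(with_mutant)
            assert em_mut >= em_base - 1e-6
            assert em_mut >= e_k - 1e-6

    def test_kir_plus_mutant_depolarized_vs_kir_only(self):
        kir_only = OocyteModel(kir_conductance=1.0)
        kir_mut = OocyteModel(
            populations=(ChannelPopulation("mut", MUTANT_PROFILE, 1.0, genotype="mutant"),),
            kir_conductance=1.0,
        )
        assert solve_em(kir_mut) > solve_em(kir_only) + 5.0

    def test_no_root_diagnostic(self):
        # leak pulling to a reversal outside the scan window
        model = OocyteModel(leak_conductance=1.0, leak_reversal_mV=80.0)
        with pytest.raises(EmRootError, match="no zero-current root"):
            solve_em(model, v_min_mV=-150.0, v_max_mV=50.0)


class TestAssembleHeteromers:
    def test_pure_wildtype(self):
        classes = assemble_heteromers(1.0)
        assert len(classes) == 1
        label, weight, prof = classes[0]
        assert (label, weight, prof.alpha) == ("wt/wt", 1.0, 0.0)

    def test_heterozygous_binomial_weights(self):
        classes = assemble_heteromers(0.5)
        weights = {label: w for label, w, _ in classes}
        assert weights == pytest.approx(
            {"wt/wt": 0.25, "wt/mut": 0.5, "mut/mut": 0.25}
        )

    def test_pure_mutant(self):
        classes = assemble_heteromers(0.0)
        assert [c[0] for c in classes] == ["mut/mut"]
        assert classes[0][2].alpha == 0.2

    @pytest.mark.parametrize("f", [0.0, 0.2, 0.5, 0.8, 1.0])
    def test_weights_sum_to_one(self, f):
        assert sum(w for _, w, _ in assemble_heteromers(f)) == pytest.approx(1.0)

    def test_mutant_dominance_configurable(self):
        classes = assemble_heteromers(0.5, alpha_het=0.35)
        assert all(
            prof.alpha == 0.35 for label, _, prof in classes if "mut" in label
        )


class TestApplyAdrenergic:
    def test_wildtype_outward_suppressed(self):
        model = single_population_model(0.0, genotype="wt")
        stimulated = apply_adrenergic(model)
        i_before = model.total_current(40.0)
        i_after = stimulated.total_current(40.0)
        assert i_after <= 0.2 * i_before

    def test_mutant_inward_leak_enhanced(self):
        model = single_population_model(0.2, genotype="mutant")
        stimulated = apply_adrenergic(model)
        assert stimulated.total_current(-90.0) < model.total_current(-90.0) < 0

    def test_identity_rules_leave_model_unchanged(self):
        model = single_population_model(0.2, genotype="mutant")
        same = apply_adrenergic(model, {"mutant": (1.0, 1.0)})
        v = np.linspace(-120, 40, 50)
        np.testing.assert_allclose(same.total_current(v), model.total_current(v))

    def test_negative_scales_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            apply_adrenergic(single_population_model(0.0), {"wt": (-1.0, 1.0)})


class TestFixtureSuite:
    def test_reproducible_bytes(self, tmp_path):
        cfg = {"scenarios": ["fig3b", "fig5d", "fig6", "fig2e"]}
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = generate_fixture_suite(cfg, seed=42, out_dir=d1)
        m2 = generate_fixture_suite(cfg, seed=42, out_dir=d2)
        assert m1 == m2
        for name in m1["files"] + ["manifest.json"]:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_selectivity_fixture_refits_to_generating_alpha(self, tmp_path):
        manifest = generate_fixture_suite({"scenarios": ["fig3b"]}, seed=7, out_dir=tmp_path)
        series = ErevSeries.from_tsv(tmp_path / "fig3b_mutant.tsv")
        fit = fit_permeability_ratio(series)
        assert fit.alpha == pytest.approx(
            manifest["scenarios"]["fig3b"]["mutant"]["alpha"], abs=0.02
        )

    def test_manifest_lists_generating_parameters(self, tmp_path):
        generate_fixture_suite({"scenarios": ["fig6"]}, seed=3, out_dir=tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        wt = manifest["scenarios"]["fig6"]["wt"]
        for key in ("seed", "tau_fast_s", "tau_slow_s", "frac_persistent",
                    "p_half_mmH2O", "noise_sd", "sample_rate_Hz"):
            assert key in wt
        for name in manifest["files"]:
            assert (tmp_path / name).exists()

    def test_unknown_scenario_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown fixture scenario"):
            generate_fixture_suite({"scenarios": ["fig99"]}, seed=1, out_dir=tmp_path)


class TestModelValidation:
    def test_all_zero_conductance_rejected(self):
        with pytest.raises(ValueError, match="nonzero conductance"):
            OocyteModel(populations=())

    def test_bad_protocol_kind(self):
        with pytest.raises(ValueError, match="ramp"):
            VoltageProtocol(kind="sine")
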