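"""Unit and property tests for the circuit simulator layer."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pensense.circuit import (
    CircuitSpec,
    EnzymeSpec,
    RateParameters,
    TFSpec,
    TemplateSpec,
    active_tf_fraction,
    add_noise,
    build_network,
    enzyme_rate,
    integrate,
    simulate,
    switch_threshold,
    synthetic_switch_trace,
    template_occupancy,
)
from pensense.traces import batch_cq, extract_cq, FluorescenceTrace

TRPR = TFSpec(name="TrpR", dimer_concentration=210.0, operator_kd=0.02,
              ligand_name="L-trp", ligand_kd=20.0, mode="corepressor", ligand_hill=2.0)
LACI = TFSpec(name="LacI", dimer_concentration=110.0, operator_kd=0.04,
              ligand_name="IPTG", ligand_kd=23.0, mode="inducer",
              ligand_hill=1.0, induction_fold=1e4)


# ---------------------------------------------------------------------------
# spec validation
# ---------------------------------------------------------------------------

class TestSpecValidation:
    def test_sensing_template_requires_operator(self):
        with pytest.raises(ValueError, match="requires an operator"):
            TemplateSpec("psT", "psT", 5.0)
        with pytest.raises(ValueError, match="takes no operator"):
            TemplateSpec("aT", "aT", 50.0, operator="LacI")

    def test_killer_template_polarity_is_antisignal(self):
        t = TemplateSpec("pskT", "pskT", 5.0, operator="TrpR")
        assert t.output_polarity == "antisignal"
        with pytest.raises(ValueError, match="implies"):
            TemplateSpec("pskT", "pskT", 5.0, operator="TrpR", output_polarity="signal")

    def test_circuit_counts_roles(self):
        with pytest.raises(ValueError, match="exactly one aT"):
            CircuitSpec(templates=[TemplateSpec("rT", "rT", 10.0)])
        with pytest.raises(ValueError, match="exactly one rT"):
            CircuitSpec(templates=[TemplateSpec("aT", "aT", 50.0)])

    def test_undeclared_references_rejected(self):
        with pytest.raises(ValueError, match="undeclared TF"):
            CircuitSpec(templates=[
                TemplateSpec("aT", "aT", 50.0), TemplateSpec("rT", "rT", 10.0),
                TemplateSpec("psT", "psT", 5.0, operator="LacI"),
            ])
        with pytest.raises(ValueError, match="not declared"):
            CircuitSpec(templates=[
                TemplateSpec("aT", "aT", 50.0), TemplateSpec("rT", "rT", 10.0)],
                tfs=[LACI])

    def test_sink_must_outrun_amplification_at_trace_level(self):
        with pytest.raises(ValueError, match="deactivation flux"):
            RateParameters(k_deact=1e-9, km_deact=1.0)


# ---------------------------------------------------------------------------
# TF layer
# ---------------------------------------------------------------------------

class TestActiveTFFraction:
    def test_corepressor_inactive_without_ligand(self):
        assert active_tf_fraction(TRPR, 0.0) == 0.0

    def test_inducer_fully_competent_without_ligand(self):
        assert active_tf_fraction(LACI, 0.0) == 1.0

    def test_corepressor_half_saturation(self):
        tf = dataclasses.replace(TRPR, ligand_hill=1.0)
        assert active_tf_fraction(tf, 20.0) == pytest.approx(0.5)

    def test_inducer_residual_competence_at_saturation(self):
        assert active_tf_fraction(LACI, 1e9) == pytest.approx(1e-4, rel=1e-3)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            active_tf_fraction(TRPR, -1.0)


class TestTemplateOccupancy:
    def test_tight_binding_titration(self):
        # 4 nM TF on 5 nM template at 1 pM Kd binds essentially stoichiometrically
        assert template_occupancy(4.0, 5.0, 0.001) == pytest.approx(4.0, abs=0.01)

    def test_no_tf_no_binding(self):
        assert template_occupancy(0.0, 5.0, 1.0) == 0.0

    def test_equal_pools_at_kd(self):
        # frozen from the fixed-point iteration oracle below
        assert template_occupancy(10.0, 10.0, 10.0) == pytest.approx(3.8197, abs=1e-4)

    @given(
        tf=st.floats(0.0, 1e3), tmpl=st.floats(1e-3, 1e3),
        kd=st.floats(1e-4, 1e3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_fixed_point_iteration_and_bounds(self, tf, tmpl, kd):
        bound = template_occupancy(tf, tmpl, kd)
        assert 0.0 <= bound <= min(tf, tmpl) + 1e-9
        # bisection on the Langmuir self-consistency b = T*(tf-b)/(kd+tf-b),
        # whose left-minus-right side is strictly increasing in b
        lo, hi = 0.0, min(tf, tmpl)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            free_tf = tf - mid
            if mid - tmpl * free_tf / (kd + free_tf) > 0:
                hi = mid
            else:
                lo = mid
        assert bound == pytest.approx(0.5 * (lo + hi), rel=1e-6, abs=1e-9)

    def test_monotone_in_tf_and_kd(self):
        grid = np.linspace(0.0, 20.0, 30)
        occ = [template_occupancy(t, 5.0, 0.1) for t in grid]
        assert np.all(np.diff(occ) >= 0)
        kds = np.logspace(-3, 2, 20)
        occ_k = [template_occupancy(5.0, 5.0, k) for k in kds]
        assert np.all(np.diff(occ_k) <= 0)


# ---------------------------------------------------------------------------
# network construction and integration
# ---------------------------------------------------------------------------

class TestNetwork:
    def test_all_zero_concentrations_give_zero_rhs(self):
        spec = CircuitSpec(templates=[
            TemplateSpec("aT", "aT", 0.0), TemplateSpec("rT", "rT", 0.0)])
        net = build_network(spec)
        dy = net.rhs(0.0, net.initial_state())
        assert np.allclose(dy, 0.0)

    def test_fully_occluded_sensing_template_never_fires(self):
        # tight TF in huge excess: source flux negligible, switch stays off
        spec = CircuitSpec(
            templates=[
                TemplateSpec("aT", "aT", 50.0), TemplateSpec("pT", "pT", 7.0),
                TemplateSpec("rT", "rT", 10.0),
                TemplateSpec("psT", "psT", 5.0, operator="TrpR"),
            ],
            tfs=[dataclasses.replace(TRPR, operator_kd=1e-6)],
            ligand_inputs={"L-trp": 1e5},
        )
        res = batch_cq(simulate(spec, duration=600))[0]
        assert res.flat and res.inv_cq == 0.0

    def test_linear_subnetwork_matches_closed_form(self):
        # source + first-order decay only: s(t) = src/k (1 - exp(-k t))
        spec = CircuitSpec(templates=[
            TemplateSpec("aT", "aT", 0.0), TemplateSpec("rT", "rT", 0.0),
            TemplateSpec("sT", "sT", 1.0)])
        t, y, net = integrate(spec, 200.0, rtol=1e-10, atol=1e-12)
        r = spec.rates
        analytic = r.k_source / r.k_degr * (1.0 - np.exp(-r.k_degr * t[1:]))
        assert np.max(np.abs(y[0, 1:] - analytic) / analytic) < 1e-6

    def test_reporter_pool_is_conserved(self, bare_switch):
        spec = dataclasses.replace(bare_switch, initial_signal=5.0)
        t, y, net = integrate(spec, 300.0)
        total = y[net.species["rt_dark"]] + y[net.species["rt_lit"]]
        assert np.max(np.abs(total - net.rT)) < 1e-8

    def test_noise_free_reporter_is_non_decreasing(self, bare_switch):
        spec = dataclasses.replace(bare_switch, initial_signal=5.0)
        ts = simulate(spec, duration=400)
        assert np.min(np.diff(ts.traces[0])) >= -1e-9


class TestBistability:
    def test_no_source_no_signal_stays_flat(self, bare_switch):
        res = batch_cq(simulate(bare_switch, duration=400))[0]
        assert res.flat

    def test_outcome_is_monotone_in_initial_signal(self, bare_switch):
        fired = []
        for s0 in np.logspace(-5, 0, 9):
            spec = dataclasses.replace(bare_switch, initial_signal=float(s0))
            fired.append(int(not batch_cq(simulate(spec, duration=600))[0].flat))
        assert fired == sorted(fired), "firing must be monotone in initial signal"
        assert fired[0] == 0 and fired[-1] == 1

    def test_threshold_separates_flat_from_fired(self, bare_switch):
        thr = switch_threshold(bare_switch)
        lo = dataclasses.replace(bare_switch, initial_signal=0.1 * thr)
        hi = dataclasses.replace(bare_switch, initial_signal=10.0 * thr)
        assert batch_cq(simulate(lo, duration=600))[0].flat
        res_hi = batch_cq(simulate(hi, duration=600))[0]
        assert not res_hi.flat and res_hi.cq > 0

    def test_bistable_states_differ_by_half_amplitude(self, bare_switch):
        thr = switch_threshold(bare_switch)
        lo = simulate(dataclasses.replace(bare_switch, initial_signal=0.1 * thr), duration=600)
        hi = simulate(dataclasses.replace(bare_switch, initial_signal=10.0 * thr), duration=600)
        assert hi.traces[0, -1] - lo.traces[0, -1] > 0.5 * hi.full_scale

    def test_more_pseudotemplate_delays_switching(self):
        cqs = []
        for pT in (1.0, 4.0, 7.0, 10.0):
            spec = CircuitSpec(templates=[
                TemplateSpec("aT", "aT", 50.0), TemplateSpec("pT", "pT", pT),
                TemplateSpec("rT", "rT", 10.0), TemplateSpec("sT", "sT", 0.02)])
            res = batch_cq(simulate(spec, duration=600))[0]
            cqs.append(math.inf if res.flat else res.cq)
        assert cqs == sorted(cqs)


# ---------------------------------------------------------------------------
# enzyme layer
# ---------------------------------------------------------------------------

class TestEnzymeLayer:
    ENZ = EnzymeSpec(name="EcB", concentration=0.01, kcat=60.0,
                     km_indole=300.0, km_serine=1.0, product="L-trp")

    def test_zero_enzyme_zero_rate(self):
        e = dataclasses.replace(self.ENZ, concentration=0.0)
        assert enzyme_rate(e, 5000.0, 10.0) == 0.0

    def test_saturating_substrates_reach_kcat_limit(self):
        rate = enzyme_rate(self.ENZ, 1e9, 1e9)
        assert rate == pytest.approx(self.ENZ.kcat * self.ENZ.concentration, rel=1e-6)

    def test_faster_enzyme_earlier_switch(self, fig_config):
        spec = fig_config("fig4")
        cqs = []
        for kcat in (60.0, 20.0, 5.0):  # EcB > PfB T292S > PfB wt at 37C
            e = dataclasses.replace(spec.enzymes[0], kcat=kcat)
            res = batch_cq(simulate(dataclasses.replace(spec, enzymes=(e,)), duration=600))[0]
            assert not res.flat
            cqs.append(res.cq)
        assert cqs[0] < cqs[1] < cqs[2]

    def test_disruption_warning_above_threshold(self, fig_config):
        spec = fig_config("fig4")
        e = dataclasses.replace(spec.enzymes[0], concentration=12.0)
        ts = simulate(dataclasses.replace(spec, enzymes=(e,)), duration=30)
        assert any("non-specific disruption" in w for w in ts.warnings)

    def test_no_enzyme_behaves_as_ligand_free_circuit(self, fig_config):
        spec = fig_config("fig4")
        no_enzyme = dataclasses.replace(spec, enzymes=())
        no_substrate = spec.with_ligands(indole=0.0)
        a = simulate(no_enzyme, duration=300).traces
        b = simulate(no_substrate, duration=300).traces
        assert np.allclose(a, b, atol=1e-9)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

class TestNoise:
    def test_zero_sigma_is_identity(self, bare_switch):
        ts = simulate(dataclasses.replace(bare_switch, initial_signal=5.0), duration=200)
        assert np.array_equal(add_noise(ts, sigma_rel=0.0, seed=1).traces, ts.traces)

    def test_same_seed_same_output(self, bare_switch):
        ts = simulate(dataclasses.replace(bare_switch, initial_signal=5.0), duration=200)
        a = add_noise(ts, sigma_rel=0.05, seed=42)
        b = add_noise(ts, sigma_rel=0.05, seed=42)
        assert np.array_equal(a.traces, b.traces)
        assert not np.array_equal(a.traces, add_noise(ts, sigma_rel=0.05, seed=43).traces)

    def test_two_percent_noise_shifts_cq_at_most_3_minutes(self):
        time = np.arange(0.0, 401.0)
        clean = synthetic_switch_trace(150.0, duration=400.0)
        rng = np.random.default_rng(2024)
        for _ in range(60):
            noisy = clean * (1.0 + 0.02 * rng.standard_normal(clean.shape))
            res = extract_cq(FluorescenceTrace(time, noisy, "mc"))
            assert abs(res.cq - 150.0) <= 3.0
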