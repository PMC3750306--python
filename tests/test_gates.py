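import numpy as np
import pytest

import bclgate as bg
from bclgate.gates import CORNERS, FateLabel, GateType, SteadyStateError, _gate_type
from bclgate.model import I_BAX, I_BCLXL, I_CBS, I_CBX, I_CXB, I_SCAF

REST = bg.InputPoint(0.0, 0.0)


class TestBcl2SteadyState:
    def test_or_resting_composition(self, or_rest):
        """High-Bad resting cell: Bax fully sequestered, most Bad
        phosphorylated and scaffold-bound, a small free Bcl-xL buffer."""
        assert or_rest[I_CBX] == pytest.approx(2e4, rel=0.05)     # Bax:Bcl-xL
        assert or_rest[I_CXB] == pytest.approx(6.7e4, rel=0.05)   # Bcl-xL:Bad_u
        assert or_rest[I_CBS] == pytest.approx(1.33e5, rel=0.05)  # Bad_p:Scaffold
        assert or_rest[I_SCAF] == pytest.approx(6.7e4, rel=0.05)  # free scaffold
        # free Bcl-xL buffer from mass balance with 2/3 of Bad phosphorylated
        assert or_rest[I_BCLXL] == pytest.approx(1.33e4, rel=0.05)

    def test_and_resting_buffer_is_large(self, and_rest):
        """Low-Bad cell keeps a ~6e4-molecule free Bcl-xL buffer."""
        assert and_rest[I_BCLXL] == pytest.approx(6e4, rel=0.05)

    def test_akt_withdrawal_releases_all_bax(self, params, or_pools):
        """Full Akt dephosphorylation lets Bad capture the whole Bcl-xL pool
        and releases the entire ~2e4-molecule Bax complement."""
        ss = bg.bcl2_steady_state(bg.InputPoint(0.0, params.akt_tot), or_pools, params)
        assert ss[I_BAX] == pytest.approx(2e4, rel=0.05)

    def test_conservation_invariants(self, or_rest, or_pools):
        bclxl, bad, scaf = bg.conserved_pools(or_rest)
        assert bclxl == pytest.approx(or_pools.bclxl_tot, rel=1e-8)
        assert bad == pytest.approx(or_pools.bad_tot, rel=1e-8)
        assert scaf == pytest.approx(or_pools.scaffold_tot, rel=1e-8)

    def test_caspase_fields_on_low_branch(self, or_rest, params):
        low = bg.caspase_steady_states(float(or_rest[I_BAX]), params)[0]
        assert or_rest[9] == pytest.approx(low.procasp)
        assert or_rest[10] == pytest.approx(low.casp)

    def test_nonconvergence_reports_residual(self, params, or_pools):
        with pytest.raises(SteadyStateError) as err:
            bg.bcl2_steady_state(REST, or_pools, params, residual_tol=1e-30,
                                 max_hours=0.01)
        assert err.value.residual > 0

    @pytest.mark.parametrize("seed", range(8))
    def test_phosphorylated_fraction_closed_form(self, seed):
        """At steady state the phosphorylated-Bad fraction equals
        p1*Akt_p/(q1 + p1*Akt_p) regardless of the binding partners."""
        rng = np.random.default_rng(seed)
        params = bg.perturbed_parameters(seed=seed, log_sd=0.1)
        pools = bg.PoolConfiguration(
            bad_tot=float(rng.uniform(0.5e5, 2e5)),
            bclxl_tot=float(rng.uniform(0.5e5, 2e5)),
        )
        inputs = bg.InputPoint(
            float(rng.uniform(0, params.p53killer_max)),
            float(rng.uniform(0, params.akt_tot)),
        )
        ss = bg.bcl2_steady_state(inputs, pools, params, include_caspases=False)
        akt_p = inputs.akt_p(params)
        expected = params.p1 * akt_p / (params.q1 + params.p1 * akt_p)
        phospho = (ss[6] + ss[I_CBS]) / pools.bad_tot
        assert phospho == pytest.approx(expected, rel=1e-3)


class TestMacroParameters:
    def test_closed_form_values(self, params):
        m = bg.macro_parameters(params)
        assert m.m1 == pytest.approx(2e4, rel=1e-12)
        assert m.m2 == pytest.approx(6.8e4, rel=1e-12)
        assert m.m3 == pytest.approx(0.3, rel=1e-12)
        assert m.m4 == pytest.approx(30.0, rel=1e-12)
        assert m.m5 == pytest.approx(30.0, rel=1e-12)
        assert m.m6 == pytest.approx(2.0 / 3.0, rel=1e-12)
        assert m.m7 == pytest.approx(5.1e3, rel=0.01)

    def test_structural_inequalities(self, params):
        m = bg.macro_parameters(params)
        assert m.m1 < m.m2
        assert 0 < m.m6 < 1
        assert m.m3 * 100 == m.m4  # Bad binds Bcl-xL far more tightly than Bax


class TestAlgebraicCorners:
    @pytest.mark.parametrize(
        "preset, corner, fate",
        [
            ("OR", (0, 0), FateLabel.SURVIVAL),
            ("OR", (1, 0), FateLabel.APOPTOSIS),
            ("OR", (0, 1), FateLabel.APOPTOSIS),
            ("OR", (1, 1), FateLabel.APOPTOSIS),
            ("AND", (0, 0), FateLabel.SURVIVAL),
            ("AND", (1, 0), FateLabel.SURVIVAL),
            ("AND", (0, 1), FateLabel.SURVIVAL),
            ("AND", (1, 1), FateLabel.APOPTOSIS),
            ("AND_STAR", (1, 0), FateLabel.SURVIVAL),
            ("AND_STAR", (0, 1), FateLabel.SURVIVAL),
            ("AND_STAR", (1, 1), FateLabel.APOPTOSIS),
        ],
    )
    def test_published_truth_tables(self, params, preset, corner, fate):
        macro = bg.macro_parameters(params)
        pools = bg.POOL_PRESETS[preset]
        assert bg.algebraic_corner_prediction(corner, pools, macro) is fate


class TestGateClassification:
    def test_gate_type_mapping(self):
        S, A = FateLabel.SURVIVAL, FateLabel.APOPTOSIS

        def table(*fates):
            return dict(zip(CORNERS, fates))

        assert _gate_type(table(S, S, S, S)) is GateType.ALWAYS_SURVIVE
        assert _gate_type(table(S, S, S, A)) is GateType.AND
        assert _gate_type(table(S, A, A, A)) is GateType.OR
        assert _gate_type(table(S, A, S, A)) is GateType.P53_ONLY
        assert _gate_type(table(S, S, A, A)) is GateType.AKT_INTERMEDIATE
        assert _gate_type(table(A, A, A, A)) is GateType.CONSTITUTIVE
        with pytest.raises(ValueError, match="non-monotone"):
            _gate_type(table(S, A, A, S))

    @pytest.mark.parametrize(
        "preset, expected",
        [("OR", GateType.OR), ("AND", GateType.AND), ("AND_STAR", GateType.AND)],
    )
    def test_presets_give_published_gates(self, params, preset, expected):
        pools = bg.POOL_PRESETS[preset]
        ode = bg.classify_gate(pools, params, method="ode")
        alg = bg.classify_gate(pools, params, method="algebraic")
        assert ode.gate_type is expected
        assert alg.gate_type is expected
        assert ode.truth_table == alg.truth_table

    def test_ode_and_algebraic_agree_outside_margin_band(self, params):
        """The finite-affinity ODE fate may deviate from the stoichiometric
        inequality only when the inequality is within 10% of equality."""
        macro = bg.macro_parameters(params)
        for bad_tot in np.linspace(0.2e5, 2e5, 7):
            pools = bg.PoolConfiguration(bad_tot=float(bad_tot), bclxl_tot=1e5)
            bax_bif = macro.m7
            for corner in CORNERS:
                bax_tot = macro.m2 if corner[0] else macro.m1
                bad_u = pools.bad_tot if corner[1] else (1 - macro.m6) * pools.bad_tot
                rhs = pools.bclxl_tot + macro.m7
                margin = abs(bax_tot + bad_u - rhs)
                if margin <= 0.1 * rhs:
                    continue
                alg = bg.algebraic_corner_prediction(corner, pools, macro)
                ode = bg.classify_fate(
                    bg.InputPoint.from_corner(corner, params), pools, params,
                    bax_bif=bax_bif,
                )
                assert alg is ode, (bad_tot, corner)


@pytest.fixture(scope="module")
def or_scan(params, or_pools):
    return bg.input_plane_scan(or_pools, params, grid=15)


class TestInputPlaneScan:
    def test_monotone_in_both_inputs(self, or_scan):
        assert np.all(np.diff(or_scan.bax, axis=0) >= -1e-6)
        assert np.all(np.diff(or_scan.bax, axis=1) >= -1e-6)

    def test_corner_fates(self, or_scan, params, and_pools, bax_bif):
        assert or_scan.bax[0, 0] < bax_bif       # resting cell survives
        assert or_scan.bax[-1, -1] > bax_bif     # dual-max input kills
        assert or_scan.bax[-1, 0] > bax_bif      # p53 alone kills the OR cell
        and_scan = bg.input_plane_scan(and_pools, params, grid=5)
        assert and_scan.bax[-1, 0] < bax_bif     # ... but not the AND cell
        assert and_scan.bax[-1, -1] > bax_bif

    def test_isoline_touches_both_axes_for_or_gate(self, or_scan, bax_bif):
        iso = bg.apoptotic_isoline(or_scan, bax_bif)
        assert len(iso) > 0
        p53_at_zero_akt = iso[np.isclose(iso[:, 1], 0.0)]
        akt_at_zero_p53 = iso[np.isclose(iso[:, 0], 0.0)]
        assert len(p53_at_zero_akt) > 0
        assert len(akt_at_zero_p53) > 0

    def test_isoline_avoids_axes_for_and_gate(self, params, and_pools, bax_bif):
        scan = bg.input_plane_scan(and_pools, params, grid=15)
        iso = bg.apoptotic_isoline(scan, bax_bif)
        assert len(iso) > 0
        assert not np.any(np.isclose(iso[:, 0], 0.0))
        assert not np.any(np.isclose(iso[:, 1], 0.0))

    def test_empty_isoline_when_level_unreached(self, or_scan):
        iso = bg.apoptotic_isoline(or_scan, 1e9)
        assert iso.shape == (0, 2)

    def test_long_format_export(self, or_scan):
        df = or_scan.to_frame()
        assert list(df.columns) == ["p53_killer", "akt_u", "bax_ss"]
        assert len(df) == 15 * 15

    def test_rejects_degenerate_grid(self, params, or_pools):
        with pytest.raises(ValueError):
            bg.input_plane_scan(or_pools, params, grid=1)


class TestGateBoundary:
    def test_bad_tot_transitions_coarse(self, params, or_pools):
        """Coarse scan brackets the published AND (~0.9e5) and OR (~1.1e5)
        transition levels in total Bad."""
        scan = bg.gate_boundary(params, or_pools, "bad_tot", 0.5e5, 1.5e5, 5e3)
        or_onset = scan.boundaries[GateType.OR]
        and_types = [v for v, g in zip(scan.values, scan.gate_types) if g is GateType.AND]
        assert 1.05e5 <= or_onset <= 1.2e5
        assert 0.8e5 <= max(and_types) <= 0.95e5
        # between AND and OR the Akt signal alone suffices
        assert GateType.AKT_INTERMEDIATE in scan.gate_types

    def test_algebraic_oracle_for_or_onset(self, params, or_pools):
        """Solving the p53-only corner inequality for Bad_tot gives
        3*(BclxL_tot + m7 - m2); the scanned onset matches within a step."""
        m = bg.macro_parameters(params)
        predicted = 3 * (or_pools.bclxl_tot + m.m7 - m.m2)
        scan = bg.gate_boundary(params, or_pools, "bad_tot", 0.9e5, 1.3e5, 2e3)
        assert scan.corner_flips[(1, 0)] == pytest.approx(predicted, abs=4e3)

    def test_rejects_bad_arguments(self, params, or_pools):
        with pytest.raises(ValueError):
            bg.gate_boundary(params, or_pools, "bax_tot", 0, 1e5, 500)
        with pytest.raises(ValueError):
            bg.gate_boundary(params, or_pools, "bad_tot", 0, 1e5, -1)
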