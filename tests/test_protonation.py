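"""Titratable sites, mean-field pKa shifts and Wyman pH integration."""

import numpy as np
import pytest
from scipy.integrate import quad

from acidbridge.protonation import (
    MODEL_PKAS,
    ChargeCurve,
    TitratableSite,
    TitrationConfig,
    TitrationModel,
    effective_pkas,
    find_titratable_sites,
    net_charge_curve,
    one_site_stability_delta,
    ph_stability_delta,
    protonation_state,
    unfolded_model,
)
from acidbridge.synth import ToyStructureSpec, make_toy_structure
from tests.conftest import build_structure


def make_site(kind, centroid, pka=None, resnum=1):
    return TitratableSite(
        chain="A", residue_number=resnum, residue_name=kind if kind in MODEL_PKAS else "ALA",
        site_kind=kind, model_pka=pka if pka is not None else MODEL_PKAS[kind],
        charged_atoms=("X",), centroid=np.asarray(centroid, dtype=float),
        is_acid=kind in ("ASP", "GLU", "TYR", "CYS", "CTERM"),
    )


class TestFindSites:
    def test_toy_arg_glu_gives_four_sites(self, arg_glu_structure):
        sites = find_titratable_sites(arg_glu_structure)
        kinds = sorted(s.site_kind for s in sites)
        assert kinds == ["ARG", "CTERM", "GLU", "NTERM"]

    def test_partial_charged_group_kept_with_warning(self, caplog):
        st = make_toy_structure(ToyStructureSpec(planted_pairs=[("ARG", "GLU", 3.5)]))
        glu = st.get_residue("A", 3)
        glu.atoms = [a for a in glu.atoms if a.name != "OE2"]
        with caplog.at_level("WARNING"):
            sites = find_titratable_sites(st)
        glu_site = next(s for s in sites if s.site_kind == "GLU")
        assert glu_site.charged_atoms == ("OE1",)
        assert any("missing charged atoms" in r.message for r in caplog.records)

    def test_disulfide_bonded_cys_excluded(self):
        base = [("N", "N", (0, 0, -1)), ("CA", "C", (0, 0, 0)),
                ("C", "C", (1, 0, 0)), ("O", "O", (2, 0, 0))]
        st = build_structure([
            ("A", 1, "CYS", base + [("SG", "S", (0.0, 1.0, 0.0))]),
            ("A", 2, "CYS", [(n, e, (c[0] + 5, c[1], c[2])) for n, e, c in base]
             + [("SG", "S", (0.0, 1.0, 2.0))]),
        ])
        sites = find_titratable_sites(st)
        assert not any(s.site_kind == "CYS" for s in sites)

    def test_free_cys_titratable(self):
        base = [("N", "N", (0, 0, -1)), ("CA", "C", (0, 0, 0)),
                ("C", "C", (1, 0, 0)), ("O", "O", (2, 0, 0))]
        st = build_structure([
            ("A", 1, "CYS", base + [("SG", "S", (0.0, 1.0, 0.0))]),
        ])
        assert any(s.site_kind == "CYS" for s in find_titratable_sites(st))


class TestEffectivePkas:
    def test_isolated_site_keeps_model_pka(self):
        st = build_structure([("A", 1, "GLU", [
            ("CA", "C", (0, 0, 0)), ("OE1", "O", (3, 0, 0)), ("OE2", "O", (3, 1, 0)),
        ])])
        model = effective_pkas(st, sites=[make_site("GLU", (3.0, 0.5, 0.0))])
        assert model.sites[0].effective_pka == pytest.approx(4.4, abs=1e-9)
        assert model.converged

    def test_full_burial_adds_born_scale(self):
        # >=40 heavy atoms within 9 A of the site centroid -> burial 1
        grid = [
            ("A", i + 2, "ALA", [("CA", "C", (2.0 * x, 2.0 * y, 2.0 * z))])
            for i, (x, y, z) in enumerate(
                (x, y, z) for x in range(-2, 3) for y in range(-2, 3) for z in range(-2, 2)
            )
        ]
        st = build_structure(grid)
        model = effective_pkas(st, sites=[make_site("GLU", (0.0, 0.0, 0.0), resnum=999)])
        assert model.sites[0].effective_pka == pytest.approx(4.4 + 1.5, abs=1e-9)

    def test_nearby_protonated_arg_lowers_glu_pka(self):
        st = build_structure([("A", 1, "ALA", [("CA", "C", (100, 100, 100))])])
        sites = [make_site("GLU", (0, 0, 0), resnum=1), make_site("ARG", (4, 0, 0), resnum=2)]
        model = effective_pkas(st, sites=sites)
        glu = next(s for s in model.sites if s.site_kind == "GLU")
        arg = next(s for s in model.sites if s.site_kind == "ARG")
        assert glu.effective_pka < 4.4
        # single-step hand computation: shift = -q_arg * 332/(eps*r)/(ln10*R*T)
        config = model.config
        coupling = 332.0 / (config.epsilon_eff * 4.0) / (
            np.log(10) * 1.987204259e-3 * config.temperature)
        assert glu.effective_pka == pytest.approx(4.4 - coupling * arg_charge(arg, 2.5),
                                                  abs=0.05)
        assert arg.effective_pka > 12.0  # weakly negative GLU raises ARG pKa

    def test_result_independent_of_site_order(self, arg_glu_structure):
        sites = find_titratable_sites(arg_glu_structure)
        fwd = effective_pkas(arg_glu_structure, sites=sites)
        rev = effective_pkas(arg_glu_structure, sites=list(reversed(sites)))
        fwd_map = {s.label: s.effective_pka for s in fwd.sites}
        rev_map = {s.label: s.effective_pka for s in rev.sites}
        for label, pka in fwd_map.items():
            assert rev_map[label] == pytest.approx(pka, abs=0.02)

    def test_converges_on_toy_fixture(self, arg_glu_structure):
        model = effective_pkas(arg_glu_structure)
        assert model.converged and model.n_iterations < 50


def arg_charge(site, ph):
    return 1.0 / (1.0 + 10.0 ** (ph - site.effective_pka))


class TestProtonationState:
    def test_midpoint_half_protonated(self):
        model = TitrationModel(sites=[make_site("GLU", (0, 0, 0))])
        model.sites[0].effective_pka = 4.4
        state = protonation_state(model, ph=4.4)
        assert state[0]["theta"] == pytest.approx(0.5)
        assert state[0]["charge"] == pytest.approx(-0.5)

    def test_three_units_below_pka_nearly_protonated(self):
        model = TitrationModel(sites=[make_site("GLU", (0, 0, 0))])
        model.sites[0].effective_pka = 4.4
        state = protonation_state(model, ph=1.4)
        assert state[0]["theta"] == pytest.approx(0.999, abs=1e-3)

    def test_his_doubly_protonated_at_acidic_ph(self):
        model = TitrationModel(sites=[make_site("HIS", (0, 0, 0))])
        model.sites[0].effective_pka = 6.3
        state = protonation_state(model, ph=2.5)
        assert state[0]["charge"] == pytest.approx(1.0, abs=2e-4)

    def test_theta_strictly_inside_unit_interval(self):
        model = TitrationModel(sites=[make_site("LYS", (0, 0, 0))])
        for ph in (-2.0, 7.0, 16.0):
            theta = protonation_state(model, ph)[0]["theta"]
            assert 0.0 < theta < 1.0


class TestNetChargeCurve:
    def test_symmetric_acid_base_neutral_at_midpoint(self):
        model = TitrationModel(sites=[
            make_site("ASP", (0, 0, 0), pka=4.0),
            make_site("LYS", (5, 0, 0), pka=10.0),
        ])
        for s in model.sites:
            s.effective_pka = s.model_pka
        curve = net_charge_curve(model, [7.0])
        assert curve.q[0] == pytest.approx(0.0, abs=1e-12)

    def test_acid_only_limits(self):
        model = TitrationModel(sites=[
            make_site("GLU", (3 * i, 0, 0), resnum=i) for i in range(3)
        ])
        curve = net_charge_curve(model, [-2.0, 14.0])
        assert curve.q[0] == pytest.approx(0.0, abs=1e-5)
        assert curve.q[1] == pytest.approx(-3.0, abs=1e-3)

    def test_monotone_non_increasing_and_matches_per_site_sum(self):
        rng = np.random.default_rng(0)
        sites = []
        for i in range(6):
            kind = rng.choice(["ASP", "GLU", "LYS", "ARG", "HIS"])
            s = make_site(kind, rng.uniform(0, 20, 3), resnum=i)
            s.effective_pka = float(rng.uniform(2, 12))
            sites.append(s)
        model = TitrationModel(sites=sites)
        grid = np.linspace(0, 14, 57)
        curve = net_charge_curve(model, grid)
        assert np.all(np.diff(curve.q) <= 1e-12)
        # independent per-site sum
        expected = np.zeros_like(grid)
        for s in sites:
            theta = 1.0 / (1.0 + 10.0 ** (grid - s.effective_pka))
            expected += (theta - 1.0) if s.is_acid else theta
        np.testing.assert_allclose(curve.q, expected, atol=1e-12)

    def test_non_increasing_grid_rejected(self):
        model = TitrationModel(sites=[make_site("GLU", (0, 0, 0))])
        with pytest.raises(ValueError):
            net_charge_curve(model, [3.0, 2.0])


class TestPhStabilityDelta:
    def _one_site_models(self, pka_f, pka_u, is_acid=True):
        kind = "GLU" if is_acid else "LYS"
        folded = TitrationModel(sites=[make_site(kind, (0, 0, 0), pka=pka_u)])
        folded.sites[0].effective_pka = pka_f
        unf = unfolded_model(folded)
        return folded, unf

    def test_identical_models_give_zero(self, arg_glu_structure):
        model = effective_pkas(arg_glu_structure)
        same = unfolded_model(model)
        assert ph_stability_delta(same, same, 7.0, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_one_site_matches_closed_form(self):
        folded, unf = self._one_site_models(5.0, 4.0)
        val = ph_stability_delta(folded, unf, ph_from=7.0, ph_to=2.0)
        closed = one_site_stability_delta(5.0, 4.0, 7.0, 2.0)
        assert val == pytest.approx(closed, abs=1e-4)
        # independent high-resolution quadrature oracle
        rt_ln10 = 1.987204259e-3 * 298.15 * np.log(10)

        def integrand(ph):
            theta_u = 1.0 / (1.0 + 10.0 ** (ph - 4.0))
            theta_f = 1.0 / (1.0 + 10.0 ** (ph - 5.0))
            return theta_u - theta_f

        oracle, _ = quad(integrand, 7.0, 2.0, epsabs=1e-12)
        assert val == pytest.approx(-rt_ln10 * oracle, abs=1e-4)

    def test_base_site_matches_closed_form(self):
        folded, unf = self._one_site_models(9.5, 10.4, is_acid=False)
        val = ph_stability_delta(folded, unf, ph_from=7.0, ph_to=2.5)
        assert val == pytest.approx(
            one_site_stability_delta(9.5, 10.4, 7.0, 2.5), abs=1e-4)

    def test_swapping_limits_flips_sign(self):
        folded, unf = self._one_site_models(5.0, 4.0)
        fwd = ph_stability_delta(folded, unf, 7.0, 2.0)
        rev = ph_stability_delta(folded, unf, 2.0, 7.0)
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_additive_over_adjacent_intervals(self):
        folded, unf = self._one_site_models(5.5, 4.4)
        whole = ph_stability_delta(folded, unf, 7.0, 2.0)
        parts = (ph_stability_delta(folded, unf, 7.0, 4.0)
                 + ph_stability_delta(folded, unf, 4.0, 2.0))
        assert whole == pytest.approx(parts, abs=1e-6)

    def test_mismatched_site_lists_rejected(self):
        folded, _ = self._one_site_models(5.0, 4.0)
        other = TitrationModel(sites=[])
        with pytest.raises(ValueError):
            ph_stability_delta(folded, other, 7.0, 2.0)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        config = TitrationConfig(epsilon_eff=25.0, born_scale=2.0)
        path = tmp_path / "titration.yaml"
        config.to_yaml(path)
        back = TitrationConfig.from_yaml(path)
        assert back.epsilon_eff == 25.0 and back.born_scale == 2.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TitrationConfig(epsilon_eff=0.5)
        with pytest.raises(ValueError):
            TitrationConfig(tol=0.0)
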