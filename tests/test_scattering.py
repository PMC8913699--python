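"""Debye profiles, contrasts, Guinier fits, chi^2 scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contrast_screen.scattering import (ContrastSpec, ScatteringProfile,
                                        bead_neutron_contrast,
                                        bead_xray_contrast, chi2_score,
                                        debye_profile, forward_contribution,
                                        guinier_fit, icm_sans_profile,
                                        powerlaw_slope, read_profile,
                                        rg_direct, smear, write_profile)
from contrast_screen.structures_io import Transform, apply_transform
from contrast_screen.tables import (AA_FREQUENCIES, RESIDUES,
                                    solvent_neutron_sld)

from conftest import make_beads

Q = np.linspace(0.01, 0.25, 50)


def ones_contrast(n):
    return np.ones(n)


# ---------------------------------------------------------------------------
# contrasts

class TestContrasts:
    def test_xray_contrast_consistent_with_table(self):
        res = RESIDUES["GLY"]
        assert bead_xray_contrast("GLY") == pytest.approx(
            res.electrons - 0.334 * res.volume)
        # glycine residue (C2H3NO) carries 30 electrons
        assert res.electrons == 30

    def test_xray_zero_volume_equals_electron_count(self):
        assert bead_xray_contrast("GLY", solvent_density=0.0) == pytest.approx(
            RESIDUES["GLY"].electrons)

    def test_unknown_residue_raises(self):
        with pytest.raises(KeyError):
            bead_xray_contrast("XXX")

    def test_hydrogenated_in_water_positive(self):
        spec = ContrastSpec(d2o_fraction=0.0)
        for name in RESIDUES:
            assert bead_neutron_contrast(name, spec, 0.0) > 0

    def test_match_point_zero(self):
        # find the D2O fraction matching ALA and confirm zero crossing there
        spec_lo = ContrastSpec(d2o_fraction=0.0)
        spec_hi = ContrastSpec(d2o_fraction=1.0)
        lo = bead_neutron_contrast("ALA", spec_lo, 0.0)
        hi = bead_neutron_contrast("ALA", spec_hi, 0.0)
        assert lo > 0 > hi  # crosses zero somewhere in between
        f = lo / (lo - hi)
        mid = bead_neutron_contrast("ALA", ContrastSpec(d2o_fraction=f), 0.0)
        assert abs(mid) < 1e-6 * abs(lo)

    def test_75pct_deuteration_matches_pure_d2o(self):
        """75%-deuterated protein is nearly invisible in 100% D2O."""
        spec = ContrastSpec(d2o_fraction=1.0)
        w = np.array([AA_FREQUENCIES[n] for n in AA_FREQUENCIES])
        exc_h = np.array([bead_neutron_contrast(n, spec, 0.0)
                          for n in AA_FREQUENCIES])
        exc_d = np.array([bead_neutron_contrast(n, spec, 0.75)
                          for n in AA_FREQUENCIES])
        mean_d = abs(np.sum(w * exc_d) / w.sum())
        mean_abs_h = np.sum(w * np.abs(exc_h)) / w.sum()
        assert mean_d < 0.05 * mean_abs_h


# ---------------------------------------------------------------------------
# Debye profiles

class TestDebye:
    def test_single_bead_constant(self):
        m = make_beads([[0, 0, 0]])
        p = debye_profile(m, Q, form_factor="point", contrasts=[2.0])
        assert np.allclose(p.i, 4.0)

    def test_two_beads_closed_form(self):
        d = 10.0
        m = make_beads([[0, 0, 0], [0, 0, d]])
        p = debye_profile(m, Q, form_factor="point", contrasts=[1.0, 1.0])
        assert np.allclose(p.i, 2.0 * (1.0 + np.sin(Q * d) / (Q * d)),
                           atol=1e-12)

    def test_forward_limit_is_square_of_total_contrast(self):
        rng = np.random.default_rng(0)
        m = make_beads(rng.normal(size=(30, 3)) * 5)
        b = rng.uniform(0.5, 2.0, 30)
        q = np.array([1e-6])
        p = debye_profile(m, q, form_factor="point", contrasts=b)
        assert p.i[0] == pytest.approx(b.sum() ** 2, rel=1e-8)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        m = make_beads(rng.normal(size=(40, 3)) * 10)
        t = Transform.about_axis([0, 0, 1.0], 60.0)
        p0 = debye_profile(m, Q)
        p1 = debye_profile(apply_transform(m, t), Q)
        assert np.allclose(p1.i, p0.i, rtol=1e-10)

    def test_hist_matches_exact_for_point_beads(self):
        rng = np.random.default_rng(2)
        m = make_beads(rng.normal(size=(200, 3)) * 20)
        b = ones_contrast(200)
        q = np.linspace(0.005, 0.05, 20)
        pe = debye_profile(m, q, form_factor="point", method="exact",
                           contrasts=b)
        ph = debye_profile(m, q, form_factor="point", method="hist",
                           contrasts=b)
        assert np.allclose(ph.i, pe.i, rtol=2e-3)

    def test_empty_model_raises(self):
        m = make_beads(np.zeros((0, 3)))
        with pytest.raises(ValueError):
            debye_profile(m, Q)

    def test_nonpositive_q_raises(self):
        m = make_beads([[0, 0, 0]])
        with pytest.raises(ValueError):
            debye_profile(m, np.array([0.0, 0.1]))


class TestIcmSans:
    def test_zero_contrast_components_vanish_bitwise(self, toy, contrast_icm):
        """Forcing non-A contrast to zero equals the A-only profile."""
        truth, _, _ = toy
        full = truth.expand()
        q = np.linspace(0.006, 0.1, 30)
        from contrast_screen.scattering import _contrasts
        b = _contrasts(full, "neutron", contrast_icm)
        b_zeroed = np.where(full.component == "A", b, 0.0)
        p_zeroed = debye_profile(full, q, channel="neutron",
                                 spec=contrast_icm, contrasts=b_zeroed)
        a_only = full.subset(full.component == "A")
        p_a = debye_profile(a_only, q, channel="neutron", spec=contrast_icm)
        assert np.array_equal(p_zeroed.i, p_a.i)

    def test_icm_profile_close_to_a_only_in_fit_window(self, toy, contrast_icm):
        truth, _, _ = toy
        full = truth.expand()
        q = np.linspace(0.006, 0.12, 60)
        p_icm = icm_sans_profile(full, q, contrast_icm)
        a_only = full.subset(full.component == "A")
        p_a = debye_profile(a_only, q, channel="neutron", spec=contrast_icm)
        g = guinier_fit(ScatteringProfile(q, p_icm.i))
        win = q <= g.q_range[1]
        dev = np.abs((p_icm.i / p_icm.i[0])[win] / (p_a.i / p_a.i[0])[win] - 1)
        assert dev.max() < 0.05


# ---------------------------------------------------------------------------
# Guinier and direct Rg

class TestGuinier:
    def test_exact_guinier_curve_inverts(self):
        q = np.linspace(0.002, 0.05, 80)
        prof = ScatteringProfile(q, 7.0 * np.exp(-(q * 50.0) ** 2 / 3.0))
        g = guinier_fit(prof)
        assert g.rg == pytest.approx(50.0, abs=1e-6)
        assert g.i0 == pytest.approx(7.0, rel=1e-8)
        assert g.rg_err == pytest.approx(0.0, abs=1e-6)

    def test_window_respects_limit(self):
        q = np.linspace(0.002, 0.2, 300)
        prof = ScatteringProfile(q, np.exp(-(q * 40.0) ** 2 / 3.0))
        g = guinier_fit(prof, limit=1.3)
        assert g.q_range[1] * g.rg <= 1.3 + 1e-9

    def test_noiseless_toy_profile_matches_direct_rg(self, toy):
        truth, _, _ = toy
        full = truth.expand()
        q = np.linspace(0.004, 0.05, 60)
        p = debye_profile(full, q)
        g = guinier_fit(p)
        assert g.rg == pytest.approx(rg_direct(full, "contrast"), rel=0.03)

    def test_flat_profile_raises(self):
        q = np.linspace(0.01, 0.1, 30)
        with pytest.raises(ValueError):
            guinier_fit(ScatteringProfile(q, np.ones(30)))

    def test_rg_direct_closed_forms(self):
        # point mass
        assert rg_direct(make_beads([[1, 2, 3]])) == 0.0
        # thin ring of radius R has Rg = R
        th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        ring = make_beads(np.stack([10 * np.cos(th), 10 * np.sin(th),
                                    np.zeros_like(th)], axis=1))
        assert rg_direct(ring) == pytest.approx(10.0, rel=1e-6)


# ---------------------------------------------------------------------------
# chi^2 and smearing

class TestChi2:
    def exp_profile(self):
        q = np.linspace(0.01, 0.1, 40)
        i = np.exp(-(q * 30) ** 2 / 3)
        return ScatteringProfile(q, i, 0.02 * i)

    def test_self_score_zero_scale_one(self):
        e = self.exp_profile()
        s = chi2_score(ScatteringProfile(e.q, e.i), e)
        assert s.chi2 == pytest.approx(0.0, abs=1e-20)
        assert s.scale == pytest.approx(1.0)

    def test_scale_invariance(self):
        e = self.exp_profile()
        s = chi2_score(ScatteringProfile(e.q, 2.0 * e.i), e)
        assert s.chi2 == pytest.approx(0.0, abs=1e-20)
        assert s.scale == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=20)
    @given(st.floats(0.1, 50.0))
    def test_chi2_invariant_to_positive_scaling(self, c):
        e = self.exp_profile()
        calc = ScatteringProfile(e.q, e.i * (1 + 0.1 * np.sin(50 * e.q)))
        assert chi2_score(ScatteringProfile(e.q, c * calc.i), e).chi2 == \
            pytest.approx(chi2_score(calc, e).chi2, rel=1e-9)

    def test_noise_gives_reduced_chi2_near_one(self):
        rng = np.random.default_rng(42)
        q = np.linspace(0.01, 0.15, 200)
        i_true = np.exp(-(q * 40) ** 2 / 3)
        sigma = 0.03 * i_true
        obs = i_true + sigma * rng.standard_normal(200)
        s = chi2_score(ScatteringProfile(q, i_true),
                       ScatteringProfile(q, obs, sigma))
        assert 0.7 <= s.chi2 <= 1.4

    def test_missing_sigma_raises(self):
        e = self.exp_profile()
        with pytest.raises(ValueError):
            chi2_score(e, ScatteringProfile(e.q, e.i))


class TestSmear:
    def sphere_profile(self):
        q = np.linspace(0.005, 0.15, 200)
        qr = q * 50
        i = (3 * (np.sin(qr) - qr * np.cos(qr)) / qr ** 3) ** 2
        return ScatteringProfile(q, i)

    def test_zero_width_identity(self):
        p = self.sphere_profile()
        assert np.allclose(smear(p, 0.0).i, p.i)

    def test_constant_profile_unchanged(self):
        q = np.linspace(0.01, 0.1, 50)
        p = ScatteringProfile(q, np.full(50, 3.0))
        assert np.allclose(smear(p, 0.01).i, 3.0)

    def test_minimum_fills_monotonically(self):
        p = self.sphere_profile()
        k = np.argmin(p.i[(p.q > 0.05) & (p.q < 0.12)])
        window = (p.q > 0.05) & (p.q < 0.12)
        depths = [smear(p, dq).i[window].min() for dq in (0.0, 0.002, 0.005)]
        assert depths[0] < depths[1] < depths[2]


# ---------------------------------------------------------------------------
# misc

class TestForwardContribution:
    def test_single_component(self):
        (c,) = forward_contribution([("A", 1.0, 1e5)])
        assert c.contribution == pytest.approx(1.0)

    def test_equal_weights_mass_ratio(self):
        a, b = forward_contribution([("A", 0.5, 1e5), ("B", 0.5, 2e5)])
        assert a.contribution == pytest.approx(1 / 3)
        assert b.contribution == pytest.approx(2 / 3)

    @settings(derandomize=True, max_examples=20)
    @given(st.lists(st.tuples(st.floats(0.01, 1.0), st.floats(1e3, 1e7)),
                    min_size=1, max_size=6))
    def test_contributions_normalized(self, comps):
        out = forward_contribution([(f"c{i}", r, m)
                                    for i, (r, m) in enumerate(comps)])
        assert sum(c.contribution for c in out) == pytest.approx(1.0,
                                                                 abs=1e-12)


class TestPowerlaw:
    def test_exact_q_minus_two(self):
        q = np.geomspace(0.01, 0.1, 50)
        assert powerlaw_slope(ScatteringProfile(q, q ** -2.0),
                              (0.01, 0.1)) == pytest.approx(-2.0)

    def test_constant_zero_slope(self):
        q = np.geomspace(0.01, 0.1, 50)
        assert powerlaw_slope(ScatteringProfile(q, np.ones(50)),
                              (0.01, 0.1)) == pytest.approx(0.0, abs=1e-12)


class TestProfileIO:
    def test_roundtrip(self, tmp_path):
        q = np.linspace(0.01, 0.1, 20)
        p = ScatteringProfile(q, q ** -2, 0.05 * q ** -2, label="disk")
        path = tmp_path / "p.dat"
        write_profile(p, path)
        back = read_profile(path)
        assert np.allclose(back.q, p.q)
        assert np.allclose(back.i, p.i)
        assert np.allclose(back.sigma, p.sigma)

    def test_tolerates_headers_and_commas(self):
        text = ("# a SASBDB-like header\nQ I err\n"
                "0.01, 100.0, 1.0\n0.02, 90.0, 1.1\n0.03, 80.0, 1.2\n")
        p = read_profile(text)
        assert len(p) == 3
        assert p.sigma is not None

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            read_profile("# nothing here\n")
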