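"""Label propagation, positional enrichment, and pathway-fraction fitting."""

import numpy as np
import pytest

from sccmet.labelstate import LabelState
from sccmet.network import (
    NetworkError,
    PathwayParams,
    builtin_atom_map,
    load_atom_map,
)
from sccmet.tracer import TracerPathwayModel, mid_of, positional_enrichment, propagate
from sccmet.tracer_mc import sample_mid

NET = builtin_atom_map()


class TestLabelState:
    def test_mid_of_pure_states(self):
        atoms = ("C1", "C2", "C3", "C4")
        unl = LabelState.unlabelled("x", atoms)
        np.testing.assert_allclose(mid_of(unl), [1, 0, 0, 0, 0])
        full = LabelState.source("x", atoms, atoms, 1.0)
        np.testing.assert_allclose(mid_of(full), [0, 0, 0, 0, 1])

    def test_mid_of_single_atom_mixture(self):
        # uniform over the two one-hot patterns of a 2-atom molecule
        probs = np.zeros(4)
        probs[0b01] = 0.5
        probs[0b10] = 0.5
        s = LabelState("x", ("C1", "C2"), probs)
        np.testing.assert_allclose(mid_of(s), [0, 1, 0])

    def test_positional_enrichment_bounds_and_errors(self):
        s = LabelState.source("x", ("C1", "C2"), ("C2",), 0.4)
        assert positional_enrichment(s, "C2") == pytest.approx(0.4)
        assert positional_enrichment(s, "C1") == 0.0
        with pytest.raises(IndexError):
            positional_enrichment(s, "C9")
        with pytest.raises(IndexError):
            positional_enrichment(s, 5)

    def test_scramble_preserves_mid(self):
        probs = np.zeros(16)
        probs[0b0011] = 0.7
        probs[0b0000] = 0.3
        s = LabelState("x", ("C1", "C2", "C3", "C4"), probs)
        sc = s.scrambled_carbons()
        np.testing.assert_allclose(mid_of(sc), mid_of(s))
        # positional info symmetrised: C1 and C4 now share enrichment
        assert sc.positional("C1") == pytest.approx(sc.positional("C4"))


class TestNetworkValidation:
    def test_unmapped_atom_rejected(self):
        text = """
metabolites:
  a: {carbons: 2}
  b: {carbons: 2}
sources:
  U13C-glucose:
    a: {fraction: f_glc, labelled_atoms: [C1, C2]}
routes:
  - product: b
    weight: 1
    atoms: {C1: a.C1}
"""
        with pytest.raises(NetworkError, match="unmapped"):
            load_atom_map(text)

    def test_cycle_rejected(self):
        text = """
metabolites:
  a: {carbons: 1}
  b: {carbons: 1}
  c: {carbons: 1}
sources:
  U13C-glucose:
    a: {fraction: f_glc, labelled_atoms: [C1]}
routes:
  - {product: b, weight: 1, atoms: {C1: c.C1}}
  - {product: c, weight: 1, atoms: {C1: b.C1}}
"""
        with pytest.raises(NetworkError, match="cycle"):
            load_atom_map(text)

    def test_weights_must_sum_to_one(self):
        params = PathwayParams(f_pdh=0.3)
        NET.check_weights("U13C-glucose", params)  # complementary pairs: fine
        text = """
metabolites:
  a: {carbons: 1}
  b: {carbons: 1}
sources:
  U13C-glucose:
    a: {fraction: f_glc, labelled_atoms: [C1]}
routes:
  - {product: b, weight: 0.7, atoms: {C1: a.C1}}
"""
        amap = load_atom_map(text)
        with pytest.raises(NetworkError, match="sum to 1"):
            amap.check_weights("U13C-glucose", PathwayParams())


class TestPropagate:
    def test_glycolysis_sends_full_glucose_label_to_lactate(self):
        st = propagate(NET, "U13C-glucose", PathwayParams(f_glc=1.0, f_gln=0.0))
        np.testing.assert_allclose(mid_of(st["lactate"]), [0, 0, 0, 1])

    def test_oxidative_vs_reductive_citrate(self):
        # glutamate m+5 = 0.5 feeding an unlabelled acetyl pool
        base = PathwayParams(f_glc=0.0, f_gln=0.5, f_pc=0.0, f_pdh=0.0)
        ox = propagate(NET, "U13C-glutamine", base.replace(f_ox=1.0))
        assert mid_of(ox["glutamate"])[5] == pytest.approx(0.5)
        np.testing.assert_allclose(
            mid_of(ox["citrate"]), [0.5, 0, 0, 0, 0.5, 0, 0], atol=1e-12
        )
        red = propagate(NET, "U13C-glutamine", base.replace(f_red=1.0))
        np.testing.assert_allclose(
            mid_of(red["citrate"]), [0.5, 0, 0, 0, 0, 0.5, 0], atol=1e-12
        )

    def test_got_transamination_splits_aspartate_m4_m5(self):
        # skeleton m+4 fraction 0.4 (via f_pc dilution), amino-N pool fully
        # labelled, GOT share 0.5 -> m+5 = m+4 = 0.20
        p = PathwayParams(f_glc=0.0, f_gln=1.0, f_ox=1.0, f_pc=0.6,
                          f_pdh=0.0, t_got=0.5)
        st = propagate(NET, "U13C-U15N-glutamine", p)
        mid = mid_of(st["aspartate"])
        assert mid[5] == pytest.approx(0.20)
        assert mid[4] == pytest.approx(0.20)

    def test_dual_tracer_makes_15n_serine(self):
        p = PathwayParams(f_glc=0.0, f_gln=1.0, f_ser=0.5, t_psat=1.0)
        st = propagate(NET, "U13C-U15N-glutamine", p)
        assert st["serine"].positional("N1") == pytest.approx(0.5)
        # no carbon label reaches de-novo serine from glutamine (first turn)
        np.testing.assert_allclose(st["serine"].carbon_mid()[1:], 0, atol=1e-12)

    def test_glutamate_c4_traces_acetyl_unit_under_glucose(self):
        p = PathwayParams(f_glc=0.3, f_gln=0.0, f_pdh=1.0, f_pc=0.0, f_ox=1.0)
        st = propagate(NET, "U13C-glucose", p)
        assert st["glutamate"].positional("C4") == pytest.approx(0.3)
        assert st["glutamate"].positional("C2") == pytest.approx(0.0)
        # glutathione glutamyl dilutes by f_gsh
        p2 = p.replace(f_gsh=0.5)
        st2 = propagate(NET, "U13C-glucose", p2)
        assert st2["gsh_glutamyl"].positional("C4") == pytest.approx(0.15)

    def test_shmt_exchange_creates_m1_and_m2_serine(self):
        p = PathwayParams(f_glc=1.0, f_gln=0.0, f_ser=0.5, e_shmt=0.4)
        mid = mid_of(propagate(NET, "U13C-glucose", p)["serine"])
        assert mid[1] > 0 and mid[2] > 0

    def test_acl_cleavage_route_makes_m3_malate_iff_reductive(self):
        base = PathwayParams(f_glc=0.0, f_gln=1.0, f_pc=0.0, f_acl=0.3)
        with_red = propagate(NET, "U13C-glutamine", base.replace(f_ox=0.6))
        assert mid_of(with_red["malate"])[3] > 0
        assert mid_of(with_red["fumarate"])[3] > 0
        no_red = propagate(NET, "U13C-glutamine", base.replace(f_ox=1.0))
        assert mid_of(no_red["malate"])[3] == pytest.approx(0.0, abs=1e-12)

    def test_zero_source_fractions_leave_everything_unlabelled(self):
        p = PathwayParams(f_glc=0.0, f_gln=0.0)
        for tracer in ("U13C-glucose", "U13C-U15N-glutamine"):
            for state in propagate(NET, tracer, p).values():
                assert mid_of(state)[0] == pytest.approx(1.0)

    def test_propagate_linear_in_mixture_fraction(self):
        # citrate MID is affine in f_ox
        base = PathwayParams(f_glc=0.0, f_gln=0.8, f_pc=0.0)
        mids = {
            f: mid_of(propagate(NET, "U13C-glutamine",
                                base.replace(f_ox=f))["citrate"])
            for f in (0.0, 0.5, 1.0)
        }
        np.testing.assert_allclose(
            mids[0.5], 0.5 * (mids[0.0] + mids[1.0]), atol=1e-12
        )

    def test_states_are_proper_distributions(self):
        p = PathwayParams(f_glc=0.6, f_gln=0.7, f_acl=0.2, f_pc=0.2)
        for tracer in ("U13C-glucose", "U13C-glutamine", "U13C-U15N-glutamine"):
            for state in propagate(NET, tracer, p).values():
                assert state.probs.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(state.probs >= 0)


class TestMonteCarloAgreement:
    def test_enumeration_matches_molecule_sampler(self):
        rng = np.random.default_rng(42)
        p = PathwayParams(f_glc=0.7, f_gln=0.6, f_ox=0.7, f_acl=0.2,
                          f_pc=0.15, f_pdh=0.6, e_shmt=0.4, f_ser=0.5,
                          t_got=0.7, t_psat=0.8, f_gsh=0.5)
        n = 30_000
        for tracer, met in [("U13C-glucose", "citrate"),
                            ("U13C-U15N-glutamine", "aspartate"),
                            ("U13C-glucose", "serine")]:
            exact = mid_of(propagate(NET, tracer, p)[met])
            mc = sample_mid(met, n, tracer, p, rng)
            se = np.sqrt(exact * (1 - exact) / n)
            assert np.all(np.abs(mc - exact) <= 3.5 * se + 1e-12)


class TestFitFractions:
    def _observed(self, params, mets):
        st = propagate(NET, "U13C-glutamine", params)
        return {m: mid_of(st[m]) for m in mets}

    def test_noise_free_recovery_is_exact(self):
        true = PathwayParams(f_glc=0.0, f_gln=0.8, f_ox=0.7, f_pc=0.0)
        obs = self._observed(true, ["glutamate", "citrate", "malate",
                                    "aspartate"])
        res = TracerPathwayModel(
            obs, "U13C-glutamine", ["f_gln", "f_red"],
            fixed_params=PathwayParams(f_glc=0.0, f_pc=0.0),
        ).fit()
        assert res.params["f_red"] == pytest.approx(0.3, abs=1e-6)
        assert res.params["f_gln"] == pytest.approx(0.8, abs=1e-6)
        assert not res.non_identifiable

    def test_citrate_omission_flags_f_red_flat(self):
        true = PathwayParams(f_glc=0.0, f_gln=0.8, f_ox=0.7, f_pc=0.0)
        obs = self._observed(true, ["glutamate", "malate", "aspartate"])
        res = TracerPathwayModel(
            obs, "U13C-glutamine", ["f_gln", "f_red"],
            fixed_params=PathwayParams(f_glc=0.0, f_pc=0.0),
        ).fit()
        assert "f_red" in res.non_identifiable
        assert "f_gln" not in res.non_identifiable
        assert "non-identifiable" in res.summary()

    def test_underdetermined_system_rejected(self):
        obs = {"lactate": np.array([0.3, 0.0, 0.0, 0.7])}
        with pytest.raises(ValueError, match="informative"):
            TracerPathwayModel(
                obs, "U13C-glucose",
                ["f_glc", "f_pdh", "f_pc", "f_ser"],
            )
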