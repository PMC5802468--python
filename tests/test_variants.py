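import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pleiopace import build_neuron, build_san, integrate_cell
from pleiopace.synth import (
    CA_GENES,
    GeneratorConfig,
    GENE_TARGETS,
    NA_HCN_GENES,
    gene_class,
    generate_variant_table,
    provenance_comment,
)
from pleiopace.variants import (
    ADD,
    MULT,
    ParameterModification,
    VariantApplication,
    VariantEffect,
    VariantError,
    apply_variant,
    effects_to_frame,
    read_table,
    scale_modification,
    write_table,
)


class TestScaleModification:
    def test_additive_scales_linearly(self):
        mod = ParameterModification("na.act.v_off", ADD, 4.0)
        assert scale_modification(mod, 0.5).value == 2.0

    def test_multiplicative_scales_on_log(self):
        mod = ParameterModification("na.gbar", MULT, 2.0)
        assert scale_modification(mod, 0.5).value == pytest.approx(2 ** 0.5)

    def test_negative_scale_inverts_factor(self):
        mod = ParameterModification("na.gbar", MULT, 2.0)
        assert scale_modification(mod, -1.0).value == pytest.approx(0.5)

    def test_identity_and_neutral(self):
        for mod in (ParameterModification("hcn.act.v_off", ADD, -7.0),
                    ParameterModification("serca.p_up", MULT, 3.0)):
            assert scale_modification(mod, 1.0).value == mod.value
            assert scale_modification(mod, 0.0).neutral

    @given(st.floats(-1.0, 1.0), st.floats(-1.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_composition_on_log_scale(self, a, b):
        mod = ParameterModification("cat.gbar", MULT, 2.5)
        two_step = scale_modification(mod, a).value * scale_modification(mod, b).value
        one_step = scale_modification(mod, a + b).value
        assert two_step == pytest.approx(one_step, rel=1e-12)

    def test_invalid_factor_rejected(self):
        with pytest.raises(VariantError):
            ParameterModification("na.gbar", MULT, -1.0)

    def test_mode_path_compatibility_enforced(self):
        with pytest.raises(VariantError):
            ParameterModification("na.gbar", ADD, 2.0)
        with pytest.raises(VariantError):
            ParameterModification("na.act.v_off", MULT, 2.0)


class TestApplyVariant:
    def test_identity_effect_keeps_model_equal(self, san_mouse):
        eff = VariantEffect("id", "SCN1A", ())
        m = apply_variant(san_mouse, eff)
        assert np.array_equal(m.params, san_mouse.params)

    def test_zero_epsilon_is_bitwise_control(self, san_mouse):
        eff = VariantEffect("v", "HCN1", (
            ParameterModification("hcn.gbar", MULT, 2.0),
            ParameterModification("hcn.act.v_off", ADD, 5.0)))
        m = apply_variant(san_mouse, VariantApplication(eff, 0.0, 1.0))
        r1 = integrate_cell(san_mouse, None, 800.0)
        r2 = integrate_cell(m, None, 800.0)
        assert np.array_equal(r1.y, r2.y)

    def test_gbar_doubles_exactly(self, san_mouse):
        eff = VariantEffect("v", "HCN1",
                            (ParameterModification("hcn.gbar", MULT, 2.0),))
        m = apply_variant(san_mouse, VariantApplication(eff, 1.0, 1.0))
        assert m.param("hcn.gbar") == pytest.approx(
            2.0 * san_mouse.param("hcn.gbar"))
        # control untouched
        assert san_mouse.param("hcn.gbar") == build_san("mouse").param("hcn.gbar")

    def test_epsilon_bracketing_is_symmetric(self, san_mouse):
        eff = VariantEffect("v", "ATP2A2",
                            (ParameterModification("serca.p_up", MULT, 2.0),))
        base = san_mouse.param("serca.p_up")
        hi = apply_variant(san_mouse, VariantApplication(eff, 0.25, 1.0))
        lo = apply_variant(san_mouse, VariantApplication(eff, -0.25, 1.0))
        assert hi.param("serca.p_up") * lo.param("serca.p_up") == pytest.approx(
            base * base, rel=1e-12)

    def test_unresolvable_path_raises_with_path_name(self, neuron):
        eff = VariantEffect("v", "SCN1A",
                            (ParameterModification("kr.gbar", MULT, 2.0),))
        with pytest.raises(VariantError, match="kr.gbar"):
            apply_variant(neuron, eff)

    def test_cav13_alias_resolves_on_neuron(self, neuron):
        eff = VariantEffect("v", "CACNA1D",
                            (ParameterModification("cal13.gbar", MULT, 2.0),))
        m = apply_variant(neuron, eff)
        assert m.param("cal12.gbar") == pytest.approx(
            2.0 * neuron.param("cal12.gbar"))


class TestGenerator:
    def test_same_seed_identical_tables(self):
        cfg = GeneratorConfig(n_variants=20, seed=7)
        a = generate_variant_table(cfg)
        b = generate_variant_table(cfg)
        assert effects_to_frame(a).equals(effects_to_frame(b))

    def test_default_mixture_is_80_of_94_ca(self):
        effs = generate_variant_table(GeneratorConfig(n_variants=94, seed=1))
        classes = [gene_class(e.gene) for e in effs]
        assert len(effs) == 94
        assert classes.count("ca") == 80
        assert classes.count("na_hcn") == 14

    def test_values_within_declared_ranges(self):
        effs = generate_variant_table(GeneratorConfig(n_variants=200, seed=3))
        for eff in effs:
            for mod in eff.modifications:
                if mod.mode == ADD:
                    assert -10.0 <= mod.value <= 10.0
                else:
                    assert 1 / 3 <= mod.value <= 3.0

    def test_targets_match_gene_product(self):
        effs = generate_variant_table(GeneratorConfig(n_variants=150, seed=5))
        for eff in effs:
            allowed = {p for p, _ in GENE_TARGETS[eff.gene]}
            assert {m.path for m in eff.modifications} <= allowed

    def test_distributional_symmetry_at_large_n(self):
        effs = generate_variant_table(GeneratorConfig(n_variants=10_000, seed=9))
        offsets = [m.value for e in effs for m in e.modifications
                   if m.mode == ADD]
        logfac = [np.log(m.value) for e in effs for m in e.modifications
                  if m.mode == MULT]
        for sample, spread in ((offsets, 10 / np.sqrt(3)),
                               (logfac, np.log(3) / np.sqrt(3))):
            se = spread / np.sqrt(len(sample))
            assert abs(np.mean(sample)) < 3 * se

    def test_roundtrip_tsv_and_json(self, tmp_path):
        effs = generate_variant_table(GeneratorConfig(n_variants=30, seed=2))
        for ext in ("tsv", "json"):
            p = tmp_path / f"t.{ext}"
            write_table(effs, p, provenance_comment(GeneratorConfig(30, 2)))
            assert effects_to_frame(read_table(p)).equals(
                effects_to_frame(effs))

    def test_gene_classes_cover_declared_genes(self):
        for g in CA_GENES:
            assert gene_class(g) == "ca"
        for g in NA_HCN_GENES:
            assert gene_class(g) == "na_hcn"
        with pytest.raises(KeyError):
            gene_class("KCNQ1")
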