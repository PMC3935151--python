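"""Electron-equivalent balance table, percentages, and propagation."""

import numpy as np
import pytest

import dielmat as dm
from dielmat.balance import round_half_up


class TestDielAverage:
    def test_fixed_carbon_row(self):
        avg, sd = dm.diel_average(-121.4, 10.3, 77.5, 6.9)
        assert round_half_up(avg) == 99.5
        assert sd == pytest.approx(8.6)

    def test_glycogen_row(self):
        avg, sd = dm.diel_average(21.2, 25.2, -31.6, 30.4)
        assert avg == pytest.approx(26.4)
        assert sd == pytest.approx(27.8)

    @pytest.mark.parametrize("x", [-3.2, 0.0, 14.9])
    def test_identity_on_equal_noise_free_phases(self, x):
        assert dm.diel_average(x, 0.0, x, 0.0) == (abs(x), 0.0)

    def test_quadrature_option(self):
        _, sd = dm.diel_average(1.0, 3.0, 1.0, 4.0, sd_method="quadrature")
        assert sd == pytest.approx(2.5)  # sqrt(9+16)/2

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            dm.diel_average(1.0, -0.1, 1.0, 0.0)


class TestElectronEquivalents:
    @pytest.mark.parametrize("species, amount, expected", [
        ("acetate", 14.9, 119.2),
        ("h2", 0.83, 1.66),
        ("formate", 10.0, 10.0),
        ("propionate", 0.0, 0.0),
    ])
    def test_published_coefficient_products(self, species, amount, expected):
        assert dm.electron_equivalents(species, amount) == pytest.approx(
            expected)

    def test_linearity(self):
        a = dm.electron_equivalents("acetate", 3.0)
        assert dm.electron_equivalents("acetate", 6.0) == pytest.approx(2 * a)

    def test_unknown_species_lists_known(self):
        with pytest.raises(KeyError, match="acetate"):
            dm.electron_equivalents("butyrate", 1.0)

    def test_redox_preset_differs_for_formate(self):
        assert dm.electron_equivalents("formate", 1.0, dm.REDOX_COEFFS) == 2.0
        assert dm.electron_equivalents("propionate", 1.0,
                                       dm.REDOX_COEFFS) == 14.0


class TestBuildBalanceTable:
    def test_printed_inputs_reproduce_printed_columns(
            self, printed_balance_inputs, printed_table2):
        fixed, gly, net, total = printed_balance_inputs
        table = dm.build_balance_table(fixed, gly, net, total)
        assert round_half_up(table.row("fixed_c", "fixed_c").diel_avg) == 99.5
        assert round_half_up(table.row("fixed_c", "fixed_c").diel_avg_sd) == 8.6
        assert round_half_up(table.row("glycogen", "storage").diel_avg) == 26.4
        assert round_half_up(table.row("glycogen", "storage").diel_avg_sd) == 27.8
        # e− entries exactly consistent with 1-dp inputs
        assert table.row("acetate", "net").e_flux == pytest.approx(119.2)
        assert table.row("formate", "net").e_flux == pytest.approx(8.3)
        assert table.row("h2", "net").e_flux == pytest.approx(1.66)
        assert table.row("formate", "total").e_flux == pytest.approx(10.0)
        # entries printed from unrounded fluxes agree at input precision
        assert table.row("acetate", "total").e_flux == pytest.approx(
            printed_table2["e_column"]["total"]["acetate"], abs=0.5)

    def test_percentages_from_printed_e_column(self, printed_table2):
        # feed diel fluxes that reproduce the printed e− column exactly
        e = printed_table2["e_column"]
        fixed = (dm.AreaFlux("dic", "day", -e["fixed_c"] / 4.0),
                 dm.AreaFlux("dic", "night", e["fixed_c"] / 4.0))
        net = {sp: dm.AreaFlux(sp, "night", v / dm.PAPER_COEFFS[sp])
               for sp, v in e["net"].items()}
        total = {sp: dm.AreaFlux(sp, "night", v / dm.PAPER_COEFFS[sp])
                 for sp, v in e["total"].items()}
        table = dm.build_balance_table(fixed, None, net, total)
        assert round_half_up(table.pct_fermented) == 81.2
        assert round_half_up(table.pct_accessory) == 40.8

    def test_all_zero_products_give_zero_percentages(self):
        fixed = (dm.AreaFlux("dic", "day", -100.0),
                 dm.AreaFlux("dic", "night", 100.0))
        zero = {"acetate": dm.AreaFlux("acetate", "night", 0.0)}
        table = dm.build_balance_table(fixed, None, zero, zero)
        assert table.pct_fermented == 0.0
        assert table.pct_accessory == 0.0

    def test_missing_fixed_c_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            dm.build_balance_table(None, None, {}, {})

    def test_net_without_total_rejected(self):
        fixed = (dm.AreaFlux("dic", "day", -1.0),
                 dm.AreaFlux("dic", "night", 1.0))
        net = {"acetate": dm.AreaFlux("acetate", "night", 1.0)}
        with pytest.raises(ValueError, match="net but not total"):
            dm.build_balance_table(fixed, None, net, {})

    def test_scale_invariance_of_percentages(self, printed_balance_inputs):
        fixed, gly, net, total = printed_balance_inputs
        table = dm.build_balance_table(fixed, gly, net, total)
        scale = lambda f, k: dm.AreaFlux(f.species, f.phase,
                                         k * f.flux_mmol_m2,
                                         k * f.sd_mmol_m2, f.n_replicates,
                                         f.treatment)
        doubled = dm.build_balance_table(
            (scale(fixed[0], 2), scale(fixed[1], 2)),
            (scale(gly[0], 2), scale(gly[1], 2)),
            {k: scale(v, 2) for k, v in net.items()},
            {k: scale(v, 2) for k, v in total.items()})
        assert doubled.pct_fermented == pytest.approx(table.pct_fermented)
        assert doubled.pct_accessory == pytest.approx(table.pct_accessory)

    def test_accessory_not_exceeding_fermented(self, printed_balance_inputs):
        fixed, gly, net, total = printed_balance_inputs
        table = dm.build_balance_table(fixed, gly, net, total)
        assert table.pct_accessory <= table.pct_fermented

    def test_oracle_recomputation(self, printed_balance_inputs):
        # brute-force spreadsheet-style recomputation of every derived cell
        fixed, gly, net, total = printed_balance_inputs
        table = dm.build_balance_table(fixed, gly, net, total)
        coeffs = {"acetate": 8, "formate": 1, "propionate": 13, "h2": 2}
        tot_e = sum(abs(f.flux_mmol_m2) * coeffs[sp]
                    for sp, f in total.items())
        net_e = sum(abs(f.flux_mmol_m2) * coeffs[sp] for sp, f in net.items())
        fixed_e = (abs(fixed[0].flux_mmol_m2)
                   + abs(fixed[1].flux_mmol_m2)) / 2 * 4
        assert table.pct_fermented == pytest.approx(100 * tot_e / fixed_e)
        assert table.pct_accessory == pytest.approx(
            100 * (tot_e - net_e) / fixed_e)


class TestPercentErrors:
    def test_zero_denominator_raises(self):
        fixed = (dm.AreaFlux("dic", "day", 0.0),
                 dm.AreaFlux("dic", "night", 0.0))
        with pytest.raises(ValueError, match="denominator"):
            dm.build_balance_table(
                fixed, None,
                {"acetate": dm.AreaFlux("acetate", "night", 1.0)},
                {"acetate": dm.AreaFlux("acetate", "night", 2.0)})


class TestPropagateUncertainty:
    def test_mean_sd_reproduces_row_sd(self, printed_balance_inputs):
        fixed, gly, net, total = printed_balance_inputs
        table = dm.build_balance_table(fixed, gly, net, total)
        out = dm.propagate_uncertainty(table, "mean_sd")
        assert out.row("fixed_c", "fixed_c").e_flux_sd == pytest.approx(34.4)
        assert out.row("acetate", "net").e_flux_sd == pytest.approx(7.2)

    def test_zero_input_sds_propagate_to_zero(self):
        fixed = (dm.AreaFlux("dic", "day", -100.0),
                 dm.AreaFlux("dic", "night", 100.0))
        prods = {"acetate": dm.AreaFlux("acetate", "night", 10.0)}
        table = dm.build_balance_table(fixed, None, prods, prods)
        for method in ("mean_sd", "quadrature"):
            out = dm.propagate_uncertainty(table, method)
            assert all(r.e_flux_sd == 0.0 for r in out.rows)
            assert out.pct_fermented_sd == 0.0
        mc = dm.propagate_uncertainty(table, "monte_carlo", seed=0)
        assert all(r.e_flux_sd == 0.0 for r in mc.rows)

    def test_monte_carlo_matches_quadrature_on_linear_combination(
            self, printed_balance_inputs):
        # per-row e− SDs are linear in the fluxes, so MC and quadrature
        # must agree there (analytic variance of a scaled normal)
        fixed, gly, net, total = printed_balance_inputs
        table = dm.build_balance_table(fixed, gly, net, total)
        mc = dm.propagate_uncertainty(table, "monte_carlo",
                                      n_draws=100_000, seed=42)
        for sp, f in total.items():
            analytic = f.sd_mmol_m2 * dm.PAPER_COEFFS[sp]
            assert mc.row(sp, "total").e_flux_sd == pytest.approx(
                analytic, rel=0.05)

    def test_monte_carlo_deterministic_given_seed(self, printed_balance_inputs):
        fixed, gly, net, total = printed_balance_inputs
        table = dm.build_balance_table(fixed, gly, net, total)
        a = dm.propagate_uncertainty(table, "monte_carlo", seed=7)
        b = dm.propagate_uncertainty(table, "monte_carlo", seed=7)
        assert a.pct_fermented_sd == b.pct_fermented_sd

    def test_unknown_method_rejected(self, printed_balance_inputs):
        fixed, gly, net, total = printed_balance_inputs
        table = dm.build_balance_table(fixed, gly, net, total)
        with pytest.raises(ValueError, match="method"):
            dm.propagate_uncertainty(table, "bootstrap")


class TestStoichiometricRatio:
    def test_glucose_fermentation_gives_two_to_one(self):
        # glucose → 2 acetate + 2 CO₂ + 4 H₂
        ratio = dm.stoichiometric_electron_ratio(
            {"acetate": 2, "h2": 4}, dm.PAPER_COEFFS, "acetate", "h2")
        assert ratio == 2.0

    def test_identical_species_ratio_one(self):
        ratio = dm.stoichiometric_electron_ratio(
            {"acetate": 3}, dm.PAPER_COEFFS, "acetate", "acetate")
        assert ratio == 1.0

    def test_measured_net_ratio_scale(self):
        # net electron ratio of acetate to H₂ from the published fluxes
        assert 119.2 / 1.66 == pytest.approx(71.8, abs=0.05)
        ratio = dm.stoichiometric_electron_ratio(
            {"acetate": 14.9, "h2": 0.83}, dm.PAPER_COEFFS, "acetate", "h2")
        assert ratio == pytest.approx(119.2 / 1.66)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            dm.stoichiometric_electron_ratio(
                {"acetate": 1, "h2": 0}, dm.PAPER_COEFFS, "acetate", "h2")
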