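"""Release-threshold search, sweeps, correlation, and derivative scans."""

import numpy as np
import pytest

from drivebalance import (
    LifeCycle,
    ModelError,
    ReleaseSchedule,
    fold_efficiency,
    linkage_correlation,
    lof_derivative_scan,
    make_strategy,
    min_release_rate,
    parameter_sweep,
    run,
)
from drivebalance.genetics import CONSTRUCT_CLASS


def test_tiny_target_needs_tiny_release(pdne, lc6):
    res = min_release_rate(pdne, lc6, 1e-4, 36)
    assert res.attained
    assert res.rho < 2e-4


def test_bracket_validity(pdne, lc6):
    """The bisection result is attaining while rho minus twice the
    tolerance is not."""
    from drivebalance.experiments import RHO_TOL, _suppression_ok

    res = min_release_rate(pdne, lc6, 0.95, 36)
    ok_hi, _ = _suppression_ok(pdne, lc6, res.rho, 0.95, 36, "first_passage")
    ok_lo, _ = _suppression_ok(pdne, lc6, res.rho - 2 * RHO_TOL, 0.95, 36,
                               "first_passage")
    assert ok_hi and not ok_lo


def test_suppression_monotone_in_release_rate(pdne, lc6):
    mins = []
    for rho in (0.02, 0.05, 0.1, 0.2, 0.5):
        rel = ReleaseSchedule(genotype=pdne.release_genotype, rho=rho)
        mins.append(run(lc6, pdne.arch, pdne.params, rel, 25).females_rel.min())
    assert all(a >= b - 1e-12 for a, b in zip(mins, mins[1:]))


def test_threshold_monotone_in_target_and_rm(pdne):
    rhos = [
        min_release_rate(pdne, LifeCycle(Rm=rm), t, 36).rho
        for rm in (2, 6) for t in (0.67, 0.95)
    ]
    # non-decreasing in target at fixed Rm, and in Rm at fixed target
    assert rhos[0] <= rhos[1] and rhos[2] <= rhos[3]
    assert rhos[0] <= rhos[2] and rhos[1] <= rhos[3]


def test_unattainable_target_reported_not_raised(lc6):
    sit = make_strategy("sit")
    res = min_release_rate(sit, lc6, 0.99, 3, rho_max=0.5)
    assert not res.attained
    assert res.rho is None


def test_fold_efficiency_identity_and_validation(pdne, lc6):
    a = min_release_rate(pdne, lc6, 0.67, 10)
    assert fold_efficiency(a, a) == pytest.approx(1.0)
    b = min_release_rate(pdne, LifeCycle(Rm=2), 0.67, 10)
    with pytest.raises(ModelError):
        fold_efficiency(a, b)


def test_sweep_heterozygous_construct_cost_monotone(pdne, lc6):
    """Leaky construct expression increases selection against the
    construct, so required release rates rise."""
    table = parameter_sweep(pdne, "h_construct", [0.0, 0.05, 0.1, 0.2],
                            lc6, 0.95, 36)
    rhos = table["rho"].to_numpy()
    assert np.all(np.diff(rhos) >= -1e-9)
    assert table["attained"].all()


def test_sweep_residual_edit_fitness_attainable_at_half_for_low_rm(pdne):
    """At Rm=2, 95% suppression stays attainable with edits retaining
    half their fitness."""
    lc = LifeCycle(Rm=2)
    table = parameter_sweep(pdne, "s_edit", [1.0, 0.5], lc, 0.95, 36)
    assert table["attained"].all()


class TestLinkageCorrelation:
    def test_complete_coupling(self):
        haps = {("G", "Bc"): 0.3, ("W", "Wc"): 0.7}
        c = linkage_correlation(haps, lambda h: h[0] == "G",
                                lambda h: h[1] == "Bc")
        assert c == pytest.approx(1.0)

    def test_independent_assortment(self):
        pg, pb = 0.4, 0.4
        haps = {
            ("G", "Bc"): pg * pb, ("G", "Wc"): pg * (1 - pb),
            ("W", "Bc"): (1 - pg) * pb, ("W", "Wc"): (1 - pg) * (1 - pb),
        }
        c = linkage_correlation(haps, lambda h: h[0] == "G",
                                lambda h: h[1] == "Bc")
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_absent_element_signaled(self):
        with pytest.raises(ModelError):
            linkage_correlation({("W", "Wc"): 1.0},
                                lambda h: h[0] == "G",
                                lambda h: h[1] == "Bc")

    def test_recombination_decays_correlation(self, lc6):
        """A linked cleave-and-rescue booster starts tightly coupled to the
        construct and the correlation decays as recombination separates
        them."""
        spec = make_strategy("pdne1", booster="cnr", booster_copies=1)
        rel = ReleaseSchedule(genotype=spec.release_genotype, rho=1.0,
                              cadence="single")
        ts = run(lc6, spec.arch, spec.params, rel, 30)
        corr = [
            linkage_correlation(
                ts.haplotype_frequencies[t],
                lambda h: h[0] in CONSTRUCT_CLASS,
                lambda h: h[1] == "Bc",
            )
            for t in (1, 10, 20, 30)
        ]
        assert corr[0] > 0.9
        assert all(a > b for a, b in zip(corr, corr[1:]))
        assert corr[-1] < 0.5


class TestBooster:
    def test_homing_booster_is_transient(self, lc6):
        """The booster is inherited in a Mendelian fashion and is gradually
        lost, while the boosted construct plateaus at an elevated
        frequency."""
        spec = make_strategy("pdne1", booster="homing", booster_copies=1,
                             sex_limited_edit="female_only")
        rel = ReleaseSchedule(genotype=spec.release_genotype, rho=1.0,
                              cadence="single")
        ts = run(lc6, spec.arch, spec.params, rel, 60)
        hb = ts.table["freq_booster_Hb"].to_numpy()
        g = ts.table["freq_construct_G"].to_numpy()
        assert np.all(np.diff(hb[1:]) < 1e-12)  # monotone loss
        assert hb[-1] < 0.2 * hb[1]
        # boosting: the construct ends above its release frequency
        assert g[-1] > g[1]

    def test_boosted_release_requirement_drops(self, lc6):
        base = make_strategy("pdne1", sex_limited_edit="female_only")
        boosted = make_strategy("pdne1", booster="homing", booster_copies=2,
                                sex_limited_edit="female_only")
        r0 = min_release_rate(base, lc6, 0.95, 36)
        r2 = min_release_rate(boosted, lc6, 0.95, 36)
        assert r2.rho < r0.rho / 5


def test_lof_scan_zero_mutation_rate_has_no_derivatives(pdne, lc6):
    rel = ReleaseSchedule(genotype=pdne.release_genotype, rho=0.1)
    scan = lof_derivative_scan(pdne, lc6, rel, 10)
    assert scan["derivative_max"] == 0.0
    assert not scan["derivative_exceeds_release"]


def test_lof_reduces_suppression(lc6):
    """Loss-of-function mutations blunt editing, weakening suppression at
    equal release rates."""
    intact = make_strategy("pdne1")
    leaky = make_strategy("pdne1", mu_lof=0.01)
    out = {}
    for spec in (intact, leaky):
        rel = ReleaseSchedule(genotype=spec.release_genotype, rho=0.05)
        out[spec.params.mu_lof] = run(lc6, spec.arch, spec.params, rel,
                                      30).females_rel[-1]
    assert out[0.01] > out[0.0]
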