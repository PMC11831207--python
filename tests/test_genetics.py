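"""Gamete formation, viability, and offspring distributions."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from drivebalance import (
    Architecture,
    ConfigError,
    GeneticParams,
    Locus,
    gamete_distribution,
    genotype,
    make_strategy,
    offspring_distribution,
    viability,
    wildtype,
)
from drivebalance.genetics import ROLE_PDNE


def dist_close(actual, expected, tol=1e-12):
    assert set(actual) == set(expected), (actual, expected)
    for k, v in expected.items():
        assert actual[k] == pytest.approx(v, abs=tol)


@pytest.mark.parametrize(
    "params_kw, expected",
    [
        # certain editing in a functional heterozygote
        (dict(), {("G",): 0.5, ("E_dom",): 0.5}),
        # no editing
        (dict(u=0.0), {("G",): 0.5, ("W",): 0.5}),
        # partial editing splits W into W and E_dom
        (dict(u=0.4), {("G",): 0.5, ("W",): 0.3, ("E_dom",): 0.2}),
        # recessive-class edits
        (dict(frac_recessive=0.25),
         {("G",): 0.5, ("E_dom",): 0.375, ("E_rec",): 0.125}),
    ],
)
def test_heterozygote_gametes(pdne, params_kw, expected):
    het = genotype(("G",), ("W",), "m", pdne.arch)
    params = pdne.with_params(**params_kw).params
    dist_close(gamete_distribution(het, pdne.arch, params), expected)


@pytest.mark.parametrize("dead", ["G_dCas9", "G_dgRNA", "G_dBoth"])
def test_editing_requires_both_components(pdne, dead):
    """A construct missing Cas9 or its gRNA cannot edit."""
    het = genotype((dead,), ("W",), "m", pdne.arch)
    dist_close(
        gamete_distribution(het, pdne.arch, pdne.params),
        {(dead,): 0.5, ("W",): 0.5},
    )


def test_lof_mutation_split(pdne):
    """Each component loses function independently at mu_lof."""
    params = pdne.with_params(u=0.0, mu_lof=0.1).params
    hom = genotype(("G",), ("G",), "m", pdne.arch)
    dist_close(
        gamete_distribution(hom, pdne.arch, params),
        {("G",): 0.81, ("G_dCas9",): 0.09, ("G_dgRNA",): 0.09,
         ("G_dBoth",): 0.01},
    )


def _mendelian_two_locus_oracle(h1, h2, r):
    """Brute-force meiosis over two loci: parental 1-r, recombinant r."""
    out = {}
    for i, j in itertools.product((0, 1), repeat=2):
        hap = ((h1, h2)[i][0], (h1, h2)[j][1])
        p = 0.5 * ((1 - r) if i == j else r)
        out[hap] = out.get(hap, 0.0) + p
    return out


@pytest.mark.parametrize("r", [0.0, 0.05, 0.2, 0.5])
def test_segregation_matches_two_locus_oracle(r):
    """With all transmission distorters off, segregation is Mendelian."""
    arch = Architecture((
        Locus("construct", ROLE_PDNE),
        Locus("booster", "homing_booster"),
    ))
    params = GeneticParams(recomb_r=(r,))
    alleles_a = ("W", "G", "E_dom")
    alleles_b = ("Wc", "Hb")
    haps = list(itertools.product(alleles_a, alleles_b))
    for h1, h2 in itertools.combinations_with_replacement(haps, 2):
        parent = genotype(h1, h2, "f", arch)
        got = gamete_distribution(parent, arch, params)
        want = _mendelian_two_locus_oracle(*parent.haplotypes, r)
        want = {h: p for h, p in want.items() if p > 0}
        dist_close(got, want)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    u=st.floats(0, 1), frac=st.floats(0, 1), mu=st.floats(0, 1),
    hom=st.floats(0, 1), r=st.floats(0, 0.5),
    a1=st.sampled_from(["W", "G", "G_dCas9", "E_dom", "E_rec"]),
    a2=st.sampled_from(["W", "G", "G_dgRNA", "E_dom", "E_rec"]),
    b1=st.sampled_from(["Wc", "Hb"]), b2=st.sampled_from(["Wc", "Hb"]),
)
def test_gamete_distribution_normalized(u, frac, mu, hom, r, a1, a2, b1, b2):
    """Every gamete distribution sums to one for any parameter combination."""
    arch = Architecture((
        Locus("construct", ROLE_PDNE),
        Locus("booster", "homing_booster"),
    ))
    params = GeneticParams(u=u, frac_recessive=frac, mu_lof=mu,
                           homing_rate=hom, recomb_r=(r,))
    parent = genotype((a1, b1), (a2, b2), "f", arch)
    dist = gamete_distribution(parent, arch, params)
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(0.0 <= p <= 1.0 for p in dist.values())


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    r=st.floats(0, 0.5),
    a1=st.sampled_from(["W", "G", "E_dom"]),
    a2=st.sampled_from(["W", "G", "E_dom"]),
    b1=st.sampled_from(["Wc", "Hb"]), b2=st.sampled_from(["Wc", "Hb"]),
)
def test_segregation_conserves_allele_frequency(r, a1, a2, b1, b2):
    """Without editing/homing/shredding/mutation, gamete allele frequencies
    equal parental allele frequencies."""
    arch = Architecture((
        Locus("construct", ROLE_PDNE),
        Locus("booster", "homing_booster"),
    ))
    params = GeneticParams(recomb_r=(r,))
    parent = genotype((a1, b1), (a2, b2), "f", arch)
    dist = gamete_distribution(parent, arch, params)
    for locus in (0, 1):
        for allele in set(h[locus] for h in parent.haplotypes):
            parental = parent.count(locus, allele) / 2.0
            gametic = sum(p for h, p in dist.items() if h[locus] == allele)
            assert gametic == pytest.approx(parental, abs=1e-12)


def test_unknown_allele_is_configuration_error(pdne):
    with pytest.raises(ConfigError):
        genotype(("Z",), ("W",), "m", pdne.arch)


class TestViability:
    def test_construct_homozygote_lethal(self, pdne):
        gg = genotype(("G",), ("G",), "f", pdne.arch)
        v = viability(gg, pdne.arch, pdne.params)
        assert v.late_survival == 0.0
        assert v.early_survival == 1.0

    def test_dominant_edit_lethal_and_timing(self, pdne):
        params = pdne.with_params(timing="early").params
        we = genotype(("W",), ("E_dom",), "f", pdne.arch)
        v = viability(we, pdne.arch, params)
        assert v.early_survival == 0.0
        assert v.late_survival == 1.0

    def test_wild_type_unaffected(self, pdne):
        ww = wildtype(pdne.arch, "f")
        v = viability(ww, pdne.arch, pdne.params)
        assert (v.early_survival, v.late_survival, v.fertility) == (1, 1, 1)

    def test_heterozygous_construct_cost(self, pdne):
        params = pdne.with_params(h_construct=0.3, s_construct=0.5).params
        gw = genotype(("G",), ("W",), "f", pdne.arch)
        v = viability(gw, pdne.arch, params)
        assert v.late_survival == pytest.approx(0.85)

    def test_recessive_edit_costs_only_without_functional_copy(self, pdne):
        er_w = genotype(("E_rec",), ("W",), "f", pdne.arch)
        assert viability(er_w, pdne.arch, pdne.params).total == 1.0
        er_er = genotype(("E_rec",), ("E_rec",), "f", pdne.arch)
        assert viability(er_er, pdne.arch, pdne.params).late_survival == 0.0
        er_g = genotype(("E_rec",), ("G",), "f", pdne.arch)
        assert viability(er_g, pdne.arch, pdne.params).late_survival == 0.0

    def test_female_limited_edits_spare_males(self, pdne):
        params = pdne.with_params(sex_limited_edit="female_only").params
        for sex, expect in (("f", 0.0), ("m", 1.0)):
            we = genotype(("W",), ("E_dom",), sex, pdne.arch)
            assert viability(we, pdne.arch, params).late_survival == expect
        # the doublesex-like target keeps male function in edited alleles
        ge = genotype(("G",), ("E_dom",), "m", pdne.arch)
        assert viability(ge, pdne.arch, params).late_survival == 1.0

    def test_two_locus_dose_counting(self):
        p2 = make_strategy("pdne2")
        ok = genotype(("G", "Wb"), ("W", "Eb"), "f", p2.arch)
        assert viability(ok, p2.arch, p2.params).late_survival == 1.0
        dead = genotype(("W", "Wb"), ("W", "Eb"), "f", p2.arch)
        assert viability(dead, p2.arch, p2.params).late_survival == 0.0


class TestOffspring:
    def test_cross_to_wild_type(self, pdne):
        mother = wildtype(pdne.arch, "f")
        father = genotype(("G",), ("W",), "m", pdne.arch)
        od = offspring_distribution(mother, father, pdne.arch, pdne.params)
        by_pair = {}
        for g, p in od.items():
            key = g.haplotypes
            by_pair[key] = by_pair.get(key, 0.0) + p
        dist_close(by_pair, {
            (("G",), ("W",)): 0.5,
            (("E_dom",), ("W",)): 0.5,
        })
        # sexes split evenly within each genotype
        assert all(p == pytest.approx(0.25) for p in od.values())

    def test_wild_cross_identity(self, pdne):
        mother = wildtype(pdne.arch, "f")
        father = wildtype(pdne.arch, "m")
        od = offspring_distribution(mother, father, pdne.arch, pdne.params)
        assert sum(od.values()) == pytest.approx(1.0)
        assert {g.haplotypes for g in od} == {(("W",), ("W",))}

    def test_sterile_father_yields_empty_distribution(self):
        spec = make_strategy("ridl", timing="fertility")
        mother = wildtype(spec.arch, "f")
        od = offspring_distribution(mother, spec.release_genotype,
                                    spec.arch, spec.params)
        assert od == {}

    def test_offspring_distribution_normalized_with_editing(self, pdne):
        mother = genotype(("G",), ("W",), "f", pdne.arch)
        father = genotype(("G",), ("W",), "m", pdne.arch)
        od = offspring_distribution(mother, father, pdne.arch, pdne.params)
        assert sum(od.values()) == pytest.approx(1.0, abs=1e-12)
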