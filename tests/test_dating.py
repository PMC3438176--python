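"""rho statistic, clock conversions and the classic skyline."""

import math

import numpy as np
import pytest

from mitocr.dating import (ClockCalibration, RhoEstimate, classic_skyline,
                           default_clocks, rescale_age, rho_sigma, rho_to_age,
                           skyline_epoch_ratio, skyline_harmonic_mean)
from mitocr.network import build_mj, condense, ensure_node
from mitocr.simulate import Genealogy
from mitocr.variants import parse_motif

mk = parse_motif

# printed founder-age table: rho values and the per-mutation column
RHO_VALUES = {"D1g": 3.0, "B2l": 2.5, "C1b13": 1.55, "D4h3a5": 1.1}
SOARES_AGES = {"D1g": 27174, "B2l": 22645, "C1b13": 14040, "D4h3a5": 9964}
# published rate-based columns (0.302 is the base column)
ENDICOTT_AGES = {"D1g": 15175, "B2l": 14172, "C1b13": 11583, "D4h3a5": 10232}
RATE_COLUMNS = {
    0.45: {"D1g": 10184, "B2l": 9511, "C1b13": 7773, "D4h3a5": 6867},
    0.34: {"D1g": 13479, "B2l": 12588, "C1b13": 10288, "D4h3a5": 9088},
    0.24: {"D1g": 19096, "B2l": 17833, "C1b13": 14575, "D4h3a5": 12875},
}


def star_network(n):
    positions = [16223, 16298, 16311, 16319, 16355, 16356, 16357, 16362]
    motifs = [mk(str(positions[i]), f"s{i}") for i in range(n)]
    return ensure_node(build_mj(condense(motifs)), frozenset())


def test_rho_on_perfect_star():
    for n in (4, 6, 8):
        est = rho_sigma(star_network(n), frozenset())
        assert est.rho == pytest.approx(1.0)
        assert est.sigma == pytest.approx(1.0 / math.sqrt(n))


def test_sigma_scales_inverse_root_n():
    sigmas = [rho_sigma(star_network(n), frozenset()).sigma for n in (4, 8)]
    assert sigmas[0] / sigmas[1] == pytest.approx(math.sqrt(2))


def test_rho_is_mean_distance():
    motifs = [mk("073", "s1"), mk("073-146", "s2"), mk("073-146-263", "s3")]
    net = ensure_node(build_mj(condense(motifs)), frozenset())
    assert rho_sigma(net, frozenset()).rho == pytest.approx(2.0)


def test_rho_counts_individuals_not_haplotypes():
    motifs = [mk("073", "s1"), mk("073", "s2"), mk("073", "s3"),
              mk("073-146-263", "s4")]
    net = ensure_node(build_mj(condense(motifs)), frozenset())
    assert rho_sigma(net, frozenset()).rho == pytest.approx((3 * 1 + 3) / 4)
    assert rho_sigma(net, frozenset(), per_individual=False).rho == \
        pytest.approx(2.0)


def test_missing_root_raises():
    net = build_mj(condense([mk("073", "a"), mk("073-146", "b")]))
    with pytest.raises(ValueError):
        rho_sigma(net, frozenset(mk("263-489").variants))


def test_soares_column_from_rho():
    soares = default_clocks()["soares_cr"]
    for clade, rho in RHO_VALUES.items():
        age = rho_to_age(RhoEstimate(clade, rho, 0.0, 10), soares)
        assert age.age_years == SOARES_AGES[clade]


def test_rate_based_conversion_arithmetic():
    cal = ClockCalibration("x", "rate-based", 0.302, 1000)
    est = RhoEstimate("toy", 3.02, 0.0, 5)
    assert rho_to_age(est, cal).age_years == 10000
    assert rho_to_age(RhoEstimate("z", 0.0, 0.0, 5), cal).age_years == 0


def test_rate_based_needs_region_length():
    with pytest.raises(ValueError):
        rho_to_age(RhoEstimate("x", 1.0, 0.0, 5),
                   ClockCalibration("bad", "rate-based", 0.302, None))


def test_age_linear_in_rho():
    soares = default_clocks()["soares_cr"]
    base = rho_to_age(RhoEstimate("x", 1.0, 0.0, 5), soares).age_years
    for c in (0.5, 2.0, 3.7):
        scaled = rho_to_age(RhoEstimate("x", c, 0.0, 5), soares).age_years
        assert scaled == pytest.approx(c * base, abs=1)


def test_confidence_interval_converts_like_rho():
    soares = default_clocks()["soares_cr"]
    est = RhoEstimate("x", 2.0, 0.5, 10)
    age = rho_to_age(est, soares)
    assert age.ci[0] == pytest.approx((2.0 - 1.96 * 0.5) * soares.rate, abs=1)
    assert age.ci[1] == pytest.approx((2.0 + 1.96 * 0.5) * soares.rate, abs=1)


def test_rescale_identity_and_inverse():
    assert rescale_age(12345, 0.302, 0.302) == 12345
    a = rescale_age(15175, 0.302, 0.45)
    assert abs(rescale_age(a, 0.45, 0.302) - 15175) <= 1


def test_rescale_rejects_nonpositive_rates():
    with pytest.raises(ValueError):
        rescale_age(1000, 0.0, 0.3)


def test_published_table_closure_under_rescaling():
    """All twelve remaining rate-based cells follow from the 0.302 column
    by inverse-proportional rescaling, to +/-1 year."""
    for to_rate, column in RATE_COLUMNS.items():
        for clade, printed in column.items():
            got = rescale_age(ENDICOTT_AGES[clade], 0.302, to_rate)
            assert abs(got - printed) <= 1, (clade, to_rate, got, printed)


def test_skyline_closed_form_n2():
    gen = Genealogy([2, 2, -1], [0.0, 0.0, 1000 * 25.0], ["s1", "s2"])
    steps = classic_skyline(gen)
    assert len(steps) == 1
    assert steps[0].nef == pytest.approx(1000.0)
    assert steps[0].k == 2


def test_skyline_closed_form_n3():
    # I3 = 100 generations, I2 = 400 generations
    gen = Genealogy([3, 3, 4, 4, -1],
                    [0.0, 0.0, 0.0, 100 * 25.0, 500 * 25.0],
                    ["s1", "s2", "s3"])
    steps = classic_skyline(gen)
    assert [s.k for s in steps] == [2, 3]
    assert steps[1].nef == pytest.approx(3 * 100.0)
    assert steps[0].nef == pytest.approx(1 * 400.0)


def test_skyline_rejects_non_ultrametric_newick():
    with pytest.raises(Exception):
        classic_skyline("(a:100,(b:50,c:200):10);")


def test_skyline_harmonic_mean_equals_tmrca_moment_estimator():
    gen = Genealogy([3, 3, 4, 4, -1],
                    [0.0, 0.0, 0.0, 100 * 25.0, 500 * 25.0],
                    ["s1", "s2", "s3"])
    hm = skyline_harmonic_mean(classic_skyline(gen))
    n = 3
    assert hm == pytest.approx(500.0 / (2 * (1 - 1 / n)))


def test_epoch_ratio_flags_growth():
    # growth: long recent intervals (large recent Nef), coalescences bunched
    # in the small ancestral population (short ancient intervals)
    grow = Genealogy([4, 4, 5, 5, 6, 6, -1],
                     [0, 0, 0, 0, 300 * 25.0, 600 * 25.0, 700 * 25.0],
                     ["a", "b", "c", "d"])
    # constant size N=600: E[I_k] proportional to 1/(k(k-1)/2)
    const = Genealogy([4, 4, 5, 5, 6, 6, -1],
                      [0, 0, 0, 0, 100 * 25.0, 300 * 25.0, 900 * 25.0],
                      ["a", "b", "c", "d"])
    assert skyline_epoch_ratio(classic_skyline(const)) == pytest.approx(1.0)
    assert skyline_epoch_ratio(classic_skyline(grow)) > \
        skyline_epoch_ratio(classic_skyline(const))


def test_clock_registry_contents():
    clocks = default_clocks()
    assert {c.name for c in clocks.values()} == \
        {"howell", "kemp", "endicott", "santos", "soares_cr"}
    assert clocks["howell"].rate == 0.45
    assert clocks["santos"].rate == 0.24
    assert clocks["soares_cr"].mode == "per-mutation"
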