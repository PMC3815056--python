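"""Crossover calling, interval maps, classification, and coincidence."""

import numpy as np
import pandas as pd
import pytest

from sporemap import study
from sporemap.genotype_io import GenotypeMatrix, MarkerTable
from sporemap.meiosis_sim import (ChromosomeDef, CrossoverModel, SimConfig,
                                  simulate_population)
from sporemap.xo_map import (
    call_crossovers,
    classify_interval,
    coefficient_of_coincidence,
    count_multi_co_spores,
    interval_map,
    map_length,
)


def _mt(names_positions, chrom="c"):
    return MarkerTable(pd.DataFrame({
        "marker_name": [n for n, _ in names_positions],
        "chrom_id": chrom,
        "position_bp": [p for _, p in names_positions],
        "marker_type": "SSR",
    }))


def _gm(rows, markers):
    frame = pd.DataFrame(
        [[pd.NA if v == "NA" else v for v in row] for row in rows.values()],
        index=list(rows), columns=markers)
    return GenotypeMatrix(frame)


@pytest.fixture
def mt4():
    return _mt([("m1", 10_000), ("m2", 20_000), ("m3", 30_000),
                ("m4", 40_000)])


class TestCallCrossovers:
    def test_uniform_spore_has_no_events(self, mt4):
        gm = _gm({"s1": ["P1", "P1", "P1", "P1"]}, mt4.marker_names)
        ccs = call_crossovers(gm, mt4)
        assert ccs.events["s1"] == ()

    def test_single_switch_localised_between_flanks(self, mt4):
        gm = _gm({"s1": ["P1", "P1", "P2", "P2"]}, mt4.marker_names)
        ccs = call_crossovers(gm, mt4)
        (ev,) = ccs.events["s1"]
        assert (ev.left_marker, ev.right_marker) == ("m2", "m3")
        assert not ev.spans_gap

    def test_na_gap_event_spans_flanking_informative_markers(self, mt4):
        gm = _gm({"s1": ["P1", "NA", "P2", "P2"]}, mt4.marker_names)
        ccs = call_crossovers(gm, mt4)
        (ev,) = ccs.events["s1"]
        assert (ev.left_marker, ev.right_marker) == ("m1", "m3")
        assert ev.spans_gap
        # excluded from both underlying interval tallies
        im = interval_map(gm, mt4)
        assert im.intervals[0].n_informative == 0
        assert im.intervals[1].n_informative == 0

    def test_all_na_spore_flagged(self, mt4):
        gm = _gm({"s1": ["NA"] * 4, "s2": ["P1"] * 4}, mt4.marker_names)
        ccs = call_crossovers(gm, mt4)
        assert ccs.all_na_spores == ("s1",)

    def test_double_switch_counts_two_events(self, mt4):
        gm = _gm({"s1": ["P1", "P2", "P1", "P1"]}, mt4.marker_names)
        ccs = call_crossovers(gm, mt4)
        assert ccs.n_events("s1") == 2


class TestIntervalMap:
    def test_published_hotspot_arithmetic(self):
        """12 recombinants among 100 informative spores over 24.72 kb is
        12 cM at 2.06 kb/cM, a hotspot."""
        mt = _mt([("a", 0), ("b", 24_720)])
        rows = {f"s{i}": ["P1", "P2" if i < 12 else "P1"]
                for i in range(100)}
        im = interval_map(_gm(rows, mt.marker_names), mt)
        (iv,) = im.intervals
        assert iv.cM == pytest.approx(12.0)
        assert iv.kb_per_cM == pytest.approx(2.06)
        assert iv.klass == "hotspot"

    def test_zero_recombinants_is_linked(self):
        mt = _mt([("a", 0), ("b", 50_000)])
        rows = {f"s{i}": ["P1", "P1"] for i in range(40)}
        im = interval_map(_gm(rows, mt.marker_names), mt)
        assert im.intervals[0].klass == "linked"
        assert im.intervals[0].kb_per_cM is None

    def test_no_data_interval_excluded_from_total(self):
        mt = _mt([("a", 0), ("b", 10_000), ("c", 20_000)])
        rows = {"s1": ["P1", "NA", "P1"], "s2": ["P2", "NA", "P2"]}
        im = interval_map(_gm(rows, mt.marker_names), mt)
        assert im.intervals[0].klass == "no-data"
        assert map_length(im) == 0.0

    def test_map_length_sums_interval_cm(self, mt4):
        rows = {}
        for i in range(10):
            rows[f"s{i}"] = ["P1", "P2" if i < 1 else "P1", "P2" if i < 1
                             else "P1", "P2" if i < 3 else "P1"]
        im = interval_map(_gm(rows, mt4.marker_names), mt4)
        cms = [iv.cM for iv in im.intervals]
        assert map_length(im) == pytest.approx(sum(cms))

    def test_counts_match_events_when_fully_informative(self):
        """Without NA, interval recombinant counts equal per-interval event
        counts from the crossover caller exactly."""
        chrom = study.chromosome3()
        model = study.crossover_model("chr3", "nbs1-2")
        _, gm = simulate_population(
            [chrom], model, SimConfig(n_meioses=50, seed=9))
        mt = chrom.marker_table()
        im = interval_map(gm, mt)
        ccs = call_crossovers(gm, mt)
        per_interval = {iv.name: 0 for iv in im.intervals}
        for evs in ccs.events.values():
            for ev in evs:
                per_interval[f"{ev.left_marker}/{ev.right_marker}"] += 1
        for iv in im.intervals:
            assert iv.n_recombinant == per_interval[iv.name]


class TestClassification:
    @pytest.mark.parametrize("ratio,klass", [
        (2.06, "hotspot"), (10.10, "hotspot"), (14.99, "hotspot"),
        (15.0, "average"), (43.84, "average"), (73.99, "average"),
        (75.0, "average"), (75.01, "cold"), (94.29, "cold"),
        (303.84, "cold"), (None, "linked"),
    ])
    def test_boundaries(self, ratio, klass):
        assert classify_interval(ratio) == klass


class TestMultiCrossoverSpores:
    def test_no_multi(self, mt4):
        gm = _gm({"s1": ["P1", "P2", "P2", "P2"], "s2": ["P1"] * 4},
                 mt4.marker_names)
        assert count_multi_co_spores(call_crossovers(gm, mt4)) == 0

    def test_double_crossover_spore_counted(self, mt4):
        gm = _gm({"s1": ["P1", "P2", "P1", "P1"]}, mt4.marker_names)
        assert count_multi_co_spores(call_crossovers(gm, mt4)) == 1

    def test_poisson_thinning_expectation(self):
        """At nu = 1 a spore sees a Poisson(lambda/2) crossover process, so
        with k equal marker intervals covering the chromosome the number of
        detected events is Binomial(k, q) with q = (1 - e^(-2 mu/k))/2; the
        multi-crossover spore count matches that closed form."""
        L = 1_000_000
        k = 25
        marks = tuple((f"m{i}", 1 + i * (L - 1) // k) for i in range(k + 1))
        chrom = ChromosomeDef(chrom_id="c", length_bp=L,
                              centromere_bp=L // 2, markers=marks)
        model = CrossoverModel(mode="renewal", lam=2.0, nu=1.0)
        _, gm = simulate_population(
            [chrom], model, SimConfig(n_meioses=2500, seed=13))
        mt = chrom.marker_table()
        # one *random* spore per meiosis: independent across meioses and,
        # unlike a fixed position in the daughter-ordered tetrad, free of
        # conditioning on centromere-proximal crossover parity
        pick = np.random.default_rng(99).integers(0, 4, size=2500)
        keep = [f"t{i}_s{j}" for i, j in enumerate(pick)]
        gm1 = GenotypeMatrix(gm.frame.loc[keep])
        count = count_multi_co_spores(call_crossovers(gm1, mt))
        mu = 1.0  # lambda / 2
        q = (1 - np.exp(-2 * mu / k)) / 2
        p = 1 - (1 - q) ** k - k * q * (1 - q) ** (k - 1)
        n = len(keep)
        se = np.sqrt(p * (1 - p) * n)
        assert abs(count - p * n) <= 3 * se


class TestCoincidence:
    def test_observed_doubles_but_no_single_zero(self, mt4):
        gm = _gm({
            "s1": ["P1", "P2", "P2", "P2"],
            "s2": ["P1", "P1", "P2", "P2"],
            "s3": ["P1", "P1", "P1", "P1"],
        }, mt4.marker_names)
        coc, n_obs, n_exp = coefficient_of_coincidence(
            gm, mt4, ("m1/m2", "m2/m3"))
        assert coc == 0.0
        assert n_obs == 0
        assert n_exp > 0

    def test_zero_single_frequency_is_missing(self, mt4):
        gm = _gm({"s1": ["P1", "P1", "P2", "P2"],
                  "s2": ["P1", "P1", "P1", "P1"]}, mt4.marker_names)
        coc, _, _ = coefficient_of_coincidence(gm, mt4, ("m1/m2", "m2/m3"))
        assert coc is None

    def test_independent_intervals_give_unit_coincidence(self):
        chrom = study.chromosome3()
        model = CrossoverModel(mode="renewal", lam=2.0, nu=1.0)
        _, gm = simulate_population(
            [chrom], model, SimConfig(n_meioses=2500, seed=17))
        pick = np.random.default_rng(7).integers(0, 4, size=2500)
        keep = [f"t{i}_s{j}" for i, j in enumerate(pick)]
        gm1 = GenotypeMatrix(gm.frame.loc[keep])
        # wide, well-separated intervals for stable frequencies
        coc, n_obs, n_exp = coefficient_of_coincidence(
            gm1, chrom.marker_table(), ("c3D/c3E", "c3I/c3J"))
        assert coc is not None
        assert abs(n_obs - n_exp) <= 3 * np.sqrt(n_exp)
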