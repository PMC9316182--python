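import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfmap import linkage, synthetic_data
from rfmap.core import GenotypeCall, MarkerDef, Phenotype
from rfmap.linkage import (
    RecombinantTally,
    Side,
    build_map,
    inverse_kosambi,
    kosambi_cM,
    locate_interval,
    map_from_tallies,
    recombination_fraction,
    tally_recombinants,
)

from conftest import make_plant


def _tally(n_ho, n_he, n_total, position=1, name="m"):
    return RecombinantTally(MarkerDef(name, "Chr06", position), n_ho, n_he, n_total)


class TestTally:
    def test_all_a_calls_give_zero_recombinants(self):
        plants = [make_plant(f"p{i}", Phenotype.STERILE, "A", ["m"]) for i in range(45)]
        t = tally_recombinants(plants, MarkerDef("m", "Chr06", 1))
        assert (t.n_ho, t.n_he, t.n_total) == (0, 0, 45)

    def test_mixed_calls_counted_as_published_example(self):
        # 2 homozygous-restorer plus 1 heterozygous recombinant among 45
        symbols = ["B", "B", "H"] + ["A"] * 42
        plants = [
            make_plant(f"p{i}", Phenotype.STERILE, s, ["m"])
            for i, s in enumerate(symbols)
        ]
        t = tally_recombinants(plants, MarkerDef("m", "Chr06", 1))
        assert (t.n_ho, t.n_he, t.n_total) == (2, 1, 45)

    def test_missing_calls_excluded_from_total(self):
        plants = [
            make_plant("p1", Phenotype.STERILE, "-", ["m"]),
            make_plant("p2", Phenotype.STERILE, "H", ["m"]),
        ]
        t = tally_recombinants(plants, MarkerDef("m", "Chr06", 1))
        assert (t.n_ho, t.n_he, t.n_total) == (0, 1, 1)

    def test_fertile_plant_rejected(self):
        plants = [make_plant("p1", Phenotype.FERTILE, "A", ["m"])]
        with pytest.raises(ValueError, match="fertile"):
            tally_recombinants(plants, MarkerDef("m", "Chr06", 1))

    def test_counts_match_brute_force_scan(self):
        rng = np.random.default_rng(42)
        symbols = rng.choice(list("ABH-"), size=300, p=[0.7, 0.05, 0.15, 0.1])
        plants = [
            make_plant(f"p{i}", Phenotype.STERILE, s, ["m"])
            for i, s in enumerate(symbols)
        ]
        t = tally_recombinants(plants, MarkerDef("m", "Chr06", 1))
        # independent tally straight off the symbol list
        assert t.n_ho == sum(s == "B" for s in symbols)
        assert t.n_he == sum(s == "H" for s in symbols)
        assert t.n_total == sum(s != "-" for s in symbols)


class TestRecombinationFraction:
    @pytest.mark.parametrize(
        "n_ho, n_he, n_total, expected",
        [
            (0, 0, 336, 0.0),
            (3, 0, 45, 0.0667),
            (0, 43, 336, 0.06399),
        ],
    )
    def test_formula_values(self, n_ho, n_he, n_total, expected):
        c = recombination_fraction(_tally(n_ho, n_he, n_total))
        assert round(c, 5) == pytest.approx(expected, abs=5e-5)

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            recombination_fraction(_tally(0, 0, 0))

    def test_unlinked_marker_flagged_not_mapped(self):
        tallies = [_tally(0, 0, 40, position=1, name="a"),
                   _tally(25, 0, 40, position=2, name="b")]
        with pytest.warns(UserWarning, match="unlinked"):
            entries = map_from_tallies(tallies)
        unlinked = next(e for e in entries if e.marker.name == "b")
        assert unlinked.d_cm is None


class TestKosambi:
    @pytest.mark.parametrize(
        "n_ho, n_he, n_total, printed_cm",
        [
            (3, 0, 45, 6.71),
            (2, 1, 45, 5.58),
            (2, 0, 45, 4.46),
            (0, 2, 45, 2.22),
            (0, 1, 45, 1.11),
            (0, 43, 336, 6.43),
            (0, 35, 336, 5.23),
            (0, 24, 336, 3.58),
            (0, 6, 336, 0.89),
            (0, 2, 336, 0.30),
            (0, 1, 336, 0.15),
        ],
    )
    def test_published_distances(self, n_ho, n_he, n_total, printed_cm):
        """Natural-log Kosambi distances reproduce every printed value."""
        c = recombination_fraction(_tally(n_ho, n_he, n_total))
        assert round(kosambi_cM(c), 2) == printed_cm

    def test_zero_fraction_gives_zero_distance(self):
        assert kosambi_cM(0.0) == 0.0

    def test_out_of_range_rejected(self):
        for c in (-0.01, 0.5, 0.7):
            with pytest.raises(ValueError):
                kosambi_cM(c)

    @given(st.floats(0.001, 0.45))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_with_inverse(self, c):
        assert inverse_kosambi(kosambi_cM(c)) == pytest.approx(c, abs=1e-12)

    def test_strictly_increasing_and_convex(self):
        grid = np.linspace(0, 0.49, 200)
        d = np.array([kosambi_cM(c) for c in grid])
        assert np.all(np.diff(d) > 0)
        assert np.all(np.diff(d, 2) > 0)

    def test_small_distance_limit_is_identity(self):
        for c in (1e-4, 1e-5, 1e-6):
            assert kosambi_cM(c) / (100 * c) == pytest.approx(1.0, rel=1e-6)


class TestBuildMapFixture:
    def test_fine_map_reproduces_all_printed_distances(self, table3_fine):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            entries = map_from_tallies(table3_fine)
        printed = synthetic_data._read_tsv("table3_fine.tsv").set_index("marker")[
            "printed_d_cm"
        ]
        assert len(entries) == 28
        for entry in entries:
            assert round(entry.d_cm, 2) == printed[entry.marker.name]

    def test_cosegregating_block_identified(self, table3_fine):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            entries = map_from_tallies(table3_fine)
        coseg = {e.marker.name for e in entries if e.side is Side.COSEGREGATING}
        assert coseg == {"P06g8527", "P06gInDel-79", "P06gInDel-81"}

    def test_primary_map_interval(self, table3_primary):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            entries = map_from_tallies(table3_primary)
            interval = locate_interval(entries)
        assert interval.left_marker.name == "P06g8229"
        assert interval.right_marker.name == "P06g8560"

    def test_single_cosegregating_marker(self):
        entries = map_from_tallies([_tally(0, 0, 45)])
        assert entries[0].side is Side.COSEGREGATING
        assert entries[0].d_cm == 0.0


class TestLocateInterval:
    def test_fine_map_interval_and_span(self, table3_fine):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            interval = locate_interval(map_from_tallies(table3_fine))
        assert interval.left_marker.name == "P06gInDel-66"
        assert interval.right_marker.name == "P06gInDel-89"
        assert interval.span_bp == 533_810
        assert interval.span_kb == 533.81

    def test_all_zero_c_is_open_interval(self):
        tallies = [_tally(0, 0, 45, position=p, name=f"m{p}") for p in (1, 2, 3)]
        with pytest.raises(ValueError, match="open interval|no recombinant"):
            locate_interval(map_from_tallies(tallies))

    def test_block_touching_edge_is_open(self):
        tallies = [
            _tally(0, 0, 45, position=100, name="left_edge"),
            _tally(2, 0, 45, position=200, name="right"),
        ]
        with pytest.raises(ValueError, match="left"):
            locate_interval(map_from_tallies(tallies))

    def test_no_cosegregating_marker_rejected(self):
        tallies = [
            _tally(1, 0, 45, position=100, name="a"),
            _tally(2, 0, 45, position=200, name="b"),
        ]
        with pytest.raises(ValueError, match="co-segregating"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                locate_interval(map_from_tallies(tallies))


class TestAgainstSimulation:
    def test_marker_at_locus_never_recombines(self):
        model = synthetic_data.CrossoverModel(
            [(MarkerDef("at_locus", "Chr06", 5_000_000), 5.0)],
            locus_cm=5.0,
            locus_bp=5_000_000,
        )
        sterile = synthetic_data.simulate_sterile_plants(model, 150, seed=7)
        t = tally_recombinants(sterile, model.markers[0][0])
        assert (t.n_ho, t.n_he, t.n_total) == (0, 0, 150)

    def test_estimator_tracks_haldane_truth_at_5cm(self):
        """Mean c-hat over 200 replicates sits within 3 SE of the Haldane
        recombination fraction for a marker 5 cM from the locus."""
        r_true = (1 - np.exp(-0.1)) / 2
        model = synthetic_data.CrossoverModel(
            [(MarkerDef("m5", "Chr06", 1_000_000), 0.0)],
            locus_cm=5.0,
            locus_bp=6_000_000,
        )
        rng = np.random.default_rng(11)
        estimates = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(200):
                sterile = synthetic_data.simulate_sterile_plants(model, 100, rng)
                estimates.append(
                    recombination_fraction(
                        tally_recombinants(sterile, model.markers[0][0])
                    )
                )
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - r_true) < 3 * se
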