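import pytest

from conceptlink import (EraDefinition, build_link_map, era_link_maps,
                         topic_emergence, topic_year_distribution)
from conceptlink.temporal import DEFAULT_ERAS

from conftest import assignment, make_record


class TestTopicYearDistribution:
    def test_single_record_single_topic_is_100_percent(self):
        series = topic_year_distribution(
            [assignment("p1", "brain")], [make_record("p1", year=1999)],
            (1990, 2000))
        (s,) = series
        assert s.per_year_percent[1999] == 100.0
        assert s.emergence_year == 1999

    def test_three_to_one_split(self):
        assignments = [assignment(f"p{i}", "a") for i in range(3)]
        assignments.append(assignment("p3", "b"))
        records = [make_record(f"p{i}", year=1999) for i in range(4)]
        series = {s.topic: s for s in topic_year_distribution(
            assignments, records, (1999, 1999))}
        assert series["a"].per_year_percent[1999] == pytest.approx(75.0)
        assert series["b"].per_year_percent[1999] == pytest.approx(25.0)

    def test_within_year_percentages_sum_to_100(self):
        assignments = [assignment("p1", "a", "b"), assignment("p2", "b"),
                       assignment("p3", "c")]
        records = [make_record(p, year=2005) for p in ("p1", "p2", "p3")]
        series = topic_year_distribution(assignments, records, (2000, 2010))
        total = sum(s.per_year_percent[2005] for s in series)
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_year_without_records_has_no_entry(self):
        series = topic_year_distribution(
            [assignment("p1", "a")], [make_record("p1", year=1999)],
            (1990, 2000))
        assert 1998 not in series[0].per_year_percent

    def test_unknown_year_records_excluded(self):
        records = [make_record("p1", year=1999), make_record("p2", year=None)]
        series = topic_year_distribution(
            [assignment("p1", "a"), assignment("p2", "a")], records,
            (1990, 2000))
        assert series[0].per_year_percent == {1999: 100.0}

    def test_mention_mode_counts_match_events(self):
        a = assignment("p1", "x")  # one match event
        b = assignment("p2", "y", "y2")
        records = [make_record("p1", year=2000), make_record("p2", year=2000)]
        series = {s.topic: s for s in topic_year_distribution(
            [a, b], records, (2000, 2000), mode="mentions")}
        assert series["x"].per_year_percent[2000] == pytest.approx(100 / 3)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            topic_year_distribution([], [], (2000, 1990))


class TestTopicEmergence:
    def test_single_mention_year(self):
        series = topic_year_distribution(
            [assignment("p1", "a")], [make_record("p1", year=2015)],
            (1975, 2018))
        assert topic_emergence(series) == {"a": 2015}

    def test_empty_series(self):
        assert topic_emergence([]) == {}

    def test_first_nonzero_year_wins(self):
        assignments = [assignment("p1", "a"), assignment("p2", "a"),
                       assignment("p3", "b")]
        records = [make_record("p1", year=2001), make_record("p2", year=1997),
                   make_record("p3", year=2001)]
        series = topic_year_distribution(assignments, records, (1990, 2010))
        assert topic_emergence(series) == {"a": 1997, "b": 2001}


class TestEraLinkMaps:
    def eras(self):
        return [EraDefinition("early", 1975, 1990),
                EraDefinition("recent", 2012, 2018)]

    def test_era_boundaries_inclusive(self):
        assignments = {"A": [assignment("p1", "t")],
                       "B": [assignment("p2", "t")]}
        records = [make_record("p1", year=1990), make_record("p2", year=1990)]
        maps = era_link_maps(assignments, records, self.eras())
        assert len(maps["early"].themes) == 1
        assert maps["recent"].themes == []

    def test_gap_years_dropped(self):
        assignments = {"A": [assignment("p1", "t")],
                       "B": [assignment("p2", "t")]}
        records = [make_record("p1", year=1995), make_record("p2", year=1995)]
        maps = era_link_maps(assignments, records, self.eras())
        assert all(m.themes == [] for m in maps.values())

    def test_era_specific_three_way_link(self):
        # the three-way topic appears only in recent-era records
        assignments = {
            "A": [assignment("a1", "t"), assignment("a2", "old")],
            "B": [assignment("b1", "t"), assignment("b2", "old")],
            "C": [assignment("c1", "t")],
        }
        records = [make_record(p, year=2015) for p in ("a1", "b1", "c1")]
        records += [make_record(p, year=1980) for p in ("a2", "b2")]
        maps = era_link_maps(assignments, records, self.eras())
        recent_full = [t.topic for t in maps["recent"].full_intersection()]
        early_full = [t.topic for t in maps["early"].full_intersection()]
        assert recent_full == ["t"] and early_full == []
        assert [t.topic for t in maps["early"].themes] == ["old"]

    def test_overlapping_eras_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            era_link_maps({}, [], [EraDefinition("a", 1990, 2000),
                                   EraDefinition("b", 1995, 2005)])

    def test_restriction_consistency(self):
        # computing per era directly equals restricting then mapping
        assignments = {
            "A": [assignment("a1", "t"), assignment("a2", "t")],
            "B": [assignment("b1", "t")],
        }
        records = [make_record("a1", year=1980), make_record("a2", year=2015),
                   make_record("b1", year=1980)]
        maps = era_link_maps(assignments, records, self.eras())
        early_only = {
            "A": [a for a in assignments["A"] if a.pmid == "a1"],
            "B": assignments["B"],
        }
        direct = build_link_map(early_only)
        assert [(t.topic, t.link_group, t.publication_count)
                for t in maps["early"].themes] == \
               [(t.topic, t.link_group, t.publication_count)
                for t in direct.themes]


def test_default_eras_match_study_periods():
    spans = {(e.name, e.start_year, e.end_year) for e in DEFAULT_ERAS}
    assert spans == {("early", 1975, 1990), ("emerging", 1997, 2003),
                     ("recent", 2012, 2018)}


def test_invalid_era_rejected():
    with pytest.raises(ValueError):
        EraDefinition("bad", 2000, 1990)
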