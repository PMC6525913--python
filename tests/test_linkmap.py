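import random

import pytest

from conceptlink import (ThemeLink, build_link_map, classify_link_groups,
                         export_graph, import_graph, normalize_scores,
                         theme_counts)
from conceptlink.linkmap import read_theme_table, write_theme_table

from conftest import assignment


def brute_force_link_map(assignments_by_concept, min_count=1):
    """Independent enumeration over all (topic, concept, pmid) triples."""
    triples = {(t, concept, a.pmid)
               for concept, assignments in assignments_by_concept.items()
               for a in assignments for t in a.topics}
    topics = {t for t, _, _ in triples}
    result = {}
    for topic in topics:
        group = frozenset(
            c for c in assignments_by_concept
            if len({p for t, cc, p in triples if t == topic and cc == c})
            >= min_count)
        if not group:
            continue
        pubs = {p for t, c, p in triples if t == topic and c in group}
        result[topic] = (group, len(pubs))
    # normalize within group
    by_group = {}
    for topic, (group, n) in result.items():
        by_group.setdefault(group, []).append((topic, n))
    expected = {}
    for group, members in by_group.items():
        total = sum(n for _, n in members)
        for topic, n in members:
            expected[topic] = (group, n, n / total)
    return expected


class TestThemeCounts:
    def test_no_assignments(self):
        assert len(theme_counts({"A": [], "B": []})) == 0

    def test_distinct_pmids_counted(self, toy_assignments):
        counts = theme_counts(toy_assignments)
        assert counts[("y", "A")] == 1
        assert counts.get(("z", "A")) == 0


class TestClassifyLinkGroups:
    def test_toy_enumeration(self, toy_assignments):
        themes = classify_link_groups(theme_counts(toy_assignments), 1)
        groups = {t.topic: t.link_group for t in themes}
        assert groups == {"y": frozenset("ABC"), "x": frozenset("A"),
                          "z": frozenset("C")}

    def test_cross_concept_count_dedups_shared_pmids(self):
        shared = {
            "A": [assignment("p1", "y")],
            "B": [assignment("p1", "y"), assignment("p2", "y")],
        }
        themes = classify_link_groups(theme_counts(shared), 1)
        (theme,) = themes
        assert theme.publication_count == 2  # p1 counted once

    def test_raising_threshold_shrinks_groups(self, toy_assignments):
        at1 = {t.topic: t.link_group for t in
               classify_link_groups(theme_counts(toy_assignments), 1)}
        at2 = {t.topic: t.link_group for t in
               classify_link_groups(theme_counts(toy_assignments), 2)}
        for topic, group in at2.items():
            assert group <= at1[topic]


class TestNormalizeScores:
    def test_single_theme_scores_one(self):
        (theme,) = normalize_scores(
            [ThemeLink("x", frozenset("A"), 7)])
        assert theme.normalized_score == 1.0

    def test_two_counts_proportions(self):
        themes = normalize_scores([
            ThemeLink("cortical activation", frozenset("AB"), 113),
            ThemeLink("rehabilitation", frozenset("AB"), 86)])
        assert themes[0].normalized_score == pytest.approx(113 / 199)
        assert themes[1].normalized_score == pytest.approx(86 / 199)
        assert sum(t.normalized_score for t in themes) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            normalize_scores([])


class TestBuildLinkMap:
    def test_toy_three_groups(self, toy_assignments):
        cmap = build_link_map(toy_assignments)
        assert len(cmap.themes) == 3
        assert len(cmap.groups()) == 3
        assert [t.topic for t in cmap.full_intersection()] == ["y"]

    def test_identical_corpora_make_everything_pairwise(self):
        assignments = {
            "A": [assignment("p1", "x"), assignment("p2", "y")],
            "B": [assignment("p1", "x"), assignment("p2", "y")],
        }
        cmap = build_link_map(assignments)
        assert all(t.link_group == frozenset("AB") for t in cmap.themes)

    def test_partition_property(self, toy_assignments):
        cmap = build_link_map(toy_assignments)
        topics = {t for a in sum(toy_assignments.values(), []) for t in a.topics}
        assert sum(len(g) for g in cmap.groups().values()) == len(topics)

    def test_needs_two_concepts(self, toy_assignments):
        with pytest.raises(ValueError):
            build_link_map({"A": toy_assignments["A"]})

    def test_matches_brute_force_on_random_small_corpora(self):
        rng = random.Random(42)
        topics = ["t1", "t2", "t3", "t4"]
        for trial in range(25):
            assignments = {}
            for concept in ("A", "B", "C"):
                n = rng.randint(0, 7)  # <= 20 records total
                assignments[concept] = [
                    assignment(f"{concept}{i}" if rng.random() < 0.7 else f"s{i}",
                               *[t for t in topics if rng.random() < 0.4])
                    for i in range(n)]
            min_count = rng.choice([1, 1, 2])
            cmap = build_link_map(assignments, min_count)
            expected = brute_force_link_map(assignments, min_count)
            got = {t.topic: (t.link_group, t.publication_count,
                             t.normalized_score) for t in cmap.themes}
            assert set(got) == set(expected)
            for topic, (group, count, score) in expected.items():
                g_group, g_count, g_score = got[topic]
                assert g_group == group and g_count == count
                assert g_score == pytest.approx(score)

    def test_top_n_per_group_keeps_strongest(self, toy_assignments):
        extra = dict(toy_assignments)
        extra["A"] = extra["A"] + [assignment("a2", "x"), assignment("a3", "w")]
        cmap = build_link_map(extra, top_n_per_group=1)
        unique_a = [t for t in cmap.themes if t.link_group == frozenset("A")]
        assert [t.topic for t in unique_a] == ["x"]  # 2 docs beats 1


class TestGraphExport:
    def test_empty_map_has_only_concept_nodes(self):
        cmap = build_link_map({"A": [], "B": []})
        data = import_graph(export_graph(cmap, "json"), "json")
        assert data.concepts == ["A", "B"] and data.themes == []

    def test_edge_count_is_sum_of_group_sizes(self, toy_assignments):
        from conceptlink.linkmap import to_networkx

        cmap = build_link_map(toy_assignments)
        g = to_networkx(cmap)
        assert g.number_of_edges() == sum(
            len(t.link_group) for t in cmap.themes)

    def test_json_round_trip_byte_identical(self, toy_assignments):
        cmap = build_link_map(toy_assignments)
        once = export_graph(cmap, "json")
        again = export_graph(import_graph(once, "json"), "json")
        assert once == again

    def test_graphml_round_trip_preserves_themes(self, toy_assignments):
        cmap = build_link_map(toy_assignments)
        back = import_graph(export_graph(cmap, "graphml"), "graphml")
        assert {(t.topic, t.link_group, t.publication_count)
                for t in back.themes} == \
               {(t.topic, t.link_group, t.publication_count)
                for t in cmap.themes}

    def test_unsupported_format_lists_supported(self, toy_assignments):
        cmap = build_link_map(toy_assignments)
        with pytest.raises(ValueError, match="graphml.*json|json.*graphml"):
            export_graph(cmap, "dot")


def test_theme_table_round_trip(tmp_path, toy_assignments):
    cmap = build_link_map(toy_assignments)
    path = tmp_path / "themes.csv"
    write_theme_table(cmap, path)
    back = read_theme_table(path)
    assert {(t.topic, t.link_group, t.publication_count) for t in back} == \
           {(t.topic, t.link_group, t.publication_count) for t in cmap.themes}
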