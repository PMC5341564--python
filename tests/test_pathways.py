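"""GMT parsing, pathway score projection, top-fraction selection, overlaps."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.pathways import (
    Pathway,
    PathwayCollection,
    overlap_counts,
    percent_shared,
    read_gmt,
    score_pathways,
    select_top_fraction,
    write_gmt,
)
from netpharm.rwr import ScoreVector


def scores(**values):
    nodes = tuple(sorted(values))
    return ScoreVector(x=np.array([values[n] for n in nodes]), nodes=nodes,
                       iterations=0, residual=0.0, converged=True, r=0.3)


def collection(*sets):
    return PathwayCollection(tuple(
        Pathway(name, "d", tuple(genes)) for name, genes in sets
    ))


class TestGMT:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("P1\tdesc\tA\tB\n")
        coll = read_gmt(p)
        assert len(coll) == 1 and coll["P1"].genes == ("A", "B")

    def test_within_set_dedup(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("P1\td\tA\tA\tB\n")
        assert read_gmt(p)["P1"].genes == ("A", "B")

    def test_duplicate_pathway_name_rejected(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("P1\td\tA\nP1\td\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)

    def test_short_line_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("P1\td\tA\nP2\tonlydesc\n")
        with pytest.raises(ValueError, match=":2:"):
            read_gmt(p)

    def test_round_trip(self, tmp_path):
        coll = collection(("P1", "AB"), ("P2", "BCD"))
        p = tmp_path / "c.gmt"
        write_gmt(coll, p)
        back = read_gmt(p)
        assert back.names == coll.names
        assert all(back[n].genes == coll[n].genes for n in coll.names)


class TestScorePathways:
    def test_hand_mean(self):
        table = score_pathways(scores(A=0.4, B=0.2), collection(("P", "AB")))
        assert table.loc[0, "mean_score"] == pytest.approx(0.3)

    def test_unmapped_gene_zero_filled(self):
        table = score_pathways(scores(A=0.4), collection(("P", "AZ")))
        row = table.iloc[0]
        assert row["mean_score"] == pytest.approx(0.2)
        assert (row["n_genes"], row["n_mapped"]) == (2, 1)

    def test_fully_unmapped_pathway_scores_zero(self):
        table = score_pathways(scores(A=0.4), collection(("P", "YZ")))
        assert table.loc[0, "mean_score"] == 0.0

    def test_mapped_denominator_mode(self):
        table = score_pathways(scores(A=0.4), collection(("P", "AZ")),
                               denominator="mapped")
        assert table.loc[0, "mean_score"] == pytest.approx(0.4)

    def test_aggregation_consistency(self, planted_fixture):
        """sum(n_genes * mean) equals the total zero-filled score mass."""
        from netpharm.fixtures import generate_pathway_collection
        from netpharm.rwr import column_normalize, rwr
        from netpharm.seeds import disease_seed_vector

        net, disease = planted_fixture
        x = rwr(column_normalize(net), disease_seed_vector(disease, net))
        coll = generate_pathway_collection(list(net.nodes), n_pathways=40,
                                           module_genes=disease, rng_seed=1)
        table = score_pathways(x, coll)
        lhs = float((table["n_genes"] * table["mean_score"]).sum())
        score_of = x.as_dict()
        rhs = sum(score_of.get(g, 0.0) for p in coll for g in p.genes)
        assert lhs == pytest.approx(rhs)


class TestSelectTopFraction:
    def _table(self, n, score_fn=None):
        score_fn = score_fn or (lambda i: float(n - i))
        return pd.DataFrame({
            "pathway": [f"P{i:04d}" for i in range(n)],
            "n_genes": 10,
            "n_mapped": 10,
            "mean_score": [score_fn(i) for i in range(n)],
        })

    def test_floor_of_five_percent(self):
        assert len(select_top_fraction(self._table(4722), 0.05)) == 236

    def test_small_table_floor(self):
        assert len(select_top_fraction(self._table(20), 0.05)) == 1

    def test_tie_break_lexicographic(self):
        table = self._table(3, score_fn=lambda i: 1.0)
        assert select_top_fraction(table, 1 / 3) == {"P0000"}

    def test_zero_selection_is_error(self):
        with pytest.raises(ValueError, match="larger fraction"):
            select_top_fraction(self._table(10), 0.05)

    def test_selection_stable_under_row_shuffle(self):
        table = self._table(100, score_fn=lambda i: float(i % 7))  # many ties
        first = select_top_fraction(table, 0.10)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert select_top_fraction(shuffled, 0.10) == first
        # idempotence: the selected names re-select themselves from the top
        sub = table[table["pathway"].isin(first)]
        assert select_top_fraction(sub, 0.5) <= first


class TestOverlapCounts:
    def test_two_sets(self):
        s = overlap_counts({"X": {1, 2, 3}, "Y": {2, 3, 4}})
        assert s.intersections["AB"] == 2
        assert s.regions == {"A": 1, "B": 1, "AB": 2}
        assert s.union_size == 4

    def test_identical_sets(self):
        s = overlap_counts({"X": {1, 2}, "Y": {1, 2}})
        assert s.regions == {"AB": 2}

    def test_too_many_sets_rejected(self):
        with pytest.raises(ValueError):
            overlap_counts({str(i): {i} for i in range(5)})

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sets(st.integers(0, 30)), min_size=3, max_size=3).filter(
        lambda ss: any(ss)))
    def test_three_sets_match_brute_force(self, sets):
        named = {f"S{i}": s for i, s in enumerate(sets)}
        summary = overlap_counts(named)
        letters = "ABC"
        universe = set().union(*sets)
        # brute-force oracle: classify every element independently
        expected_regions = {}
        for el in universe:
            key = "".join(l for l, s in zip(letters, sets) if el in s)
            expected_regions[key] = expected_regions.get(key, 0) + 1
        assert summary.regions == expected_regions
        assert sum(summary.regions.values()) == len(universe)
        for combo in itertools.chain(
            itertools.combinations(letters, 2), [tuple(letters)]
        ):
            inter = set.intersection(*(sets["ABC".index(l)] for l in combo))
            assert summary.intersections["".join(combo)] == len(inter)


class TestPercentShared:
    @pytest.mark.parametrize(
        "num,den,decimals,expected",
        [
            (97, 236, 0, 41.0),     # shared disease/drug pathways of 236
            (81, 113, 1, 71.7),     # plasma-compound share of the drug-regulated set
            (119, 236, 1, 50.4),
            (80, 119, 1, 67.2),
            (70, 119, 1, 58.8),
            (46, 301, 1, 15.3),
            (11, 301, 1, 3.7),
            (97, 113, 0, 86.0),
            (11, 46, 0, 24.0),
            (0, 7, 0, 0.0),
        ],
    )
    def test_reported_ratios(self, num, den, decimals, expected):
        assert percent_shared(num, den, decimals) == expected

    def test_half_up_not_bankers(self):
        assert percent_shared(1, 16, 1) == 6.3  # 6.25 rounds up

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent_shared(1, 0)
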