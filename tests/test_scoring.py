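"""Document-frequency counting and the enrichment z-score pipeline."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from biofluidminer.entities import EntityClass, NormalizedMention
from biofluidminer.scoring import (
    DegenerateScoreSetError,
    MarkerDocFrequencies,
    ScoreRecord,
    apply_threshold,
    count_document_frequencies,
    expectation,
    normalized_difference,
    score_markers,
    threshold_sweep,
    write_score_table,
    zscores,
)
from biofluidminer.synthetic import (
    MarkerSpec,
    SyntheticCorpusConfig,
    end_to_end_expected_scores,
    generate_corpus,
)
from conftest import run_scoring_pipeline


def nm(symbol, pmid):
    return NormalizedMention(
        pmid=pmid, symbol=symbol, source_surface=symbol, entity_class=EntityClass.PROTEIN
    )


class TestCountDocumentFrequencies:
    def test_repeated_mentions_in_one_abstract_count_once(self):
        s1 = [nm("A", "p1")] * 5 + [nm("A", "p2")]
        rows = count_document_frequencies(s1, [])
        assert len(rows) == 1
        assert rows[0].df1 == 2
        assert rows[0].s1_pmids == frozenset({"p1", "p2"})

    def test_symbol_only_in_negative_set_is_excluded(self):
        rows = count_document_frequencies([nm("A", "p1")], [nm("B", "n1")])
        assert [r.symbol for r in rows] == ["A"]

    def test_empty_positive_mentions_warn_and_return_empty(self):
        with pytest.warns(UserWarning, match="Sp is empty"):
            assert count_document_frequencies([], [nm("B", "n1")]) == []

    def test_conservation_df1_plus_df2_is_dft(self):
        rows = count_document_frequencies(
            [nm("A", "p1"), nm("A", "p2")], [nm("A", "n1"), nm("A", "n2"), nm("A", "n3")]
        )
        assert rows[0].dft == rows[0].df1 + rows[0].df2 == 5

    def test_matches_naive_double_loop_on_random_corpus(self):
        # brute-force oracle: iterate (symbol, abstract) pairs directly
        import random

        rng = random.Random(123)
        symbols = ["A", "B", "C", "D"]
        s1_abstracts = {f"p{i}": rng.sample(symbols, rng.randint(0, 4)) for i in range(30)}
        s2_abstracts = {f"n{i}": rng.sample(symbols, rng.randint(0, 4)) for i in range(30)}
        s1_mentions = [
            nm(s, pmid)
            for pmid, syms in s1_abstracts.items()
            for s in syms
            for _ in range(rng.randint(1, 3))
        ]
        s2_mentions = [
            nm(s, pmid)
            for pmid, syms in s2_abstracts.items()
            for s in syms
            for _ in range(rng.randint(1, 3))
        ]
        rows = {r.symbol: r for r in count_document_frequencies(s1_mentions, s2_mentions)}
        for symbol in symbols:
            naive_df1 = sum(symbol in syms for syms in s1_abstracts.values())
            naive_df2 = sum(symbol in syms for syms in s2_abstracts.values())
            if naive_df1 == 0:
                assert symbol not in rows
            else:
                assert rows[symbol].df1 == naive_df1
                assert rows[symbol].df2 == naive_df2


class TestFormulas:
    @pytest.mark.parametrize(
        "dft,n1,n2,expected",
        [(10, 10, 90, 1.0), (7, 7, 0, 7.0), (4, 13, 13, 2.0)],
    )
    def test_expectation_examples(self, dft, n1, n2, expected):
        assert expectation(dft, n1, n2) == pytest.approx(expected)

    def test_expectation_requires_nonempty_union(self):
        with pytest.raises(ValueError):
            expectation(1, 0, 0)

    @pytest.mark.parametrize(
        "ev,ex,dft,expected",
        [(5, 1.0, 10, 0.4), (3, 3.0, 7, 0.0), (10, 0.001, 10, (10 - 0.001) / 10)],
    )
    def test_normalized_difference_examples(self, ev, ex, dft, expected):
        assert normalized_difference(ev, ex, dft) == pytest.approx(expected)

    def test_normalized_difference_requires_positive_dft(self):
        with pytest.raises(ValueError):
            normalized_difference(0, 0.0, 0)

    @given(
        df1=st.integers(min_value=1, max_value=500),
        df2=st.integers(min_value=0, max_value=5000),
        n1=st.integers(min_value=1, max_value=500),
        n2=st.integers(min_value=0, max_value=5000),
    )
    def test_f_bounded_in_unit_interval(self, df1, df2, n1, n2):
        df1 = min(df1, n1)
        df2 = min(df2, n2)
        dft = df1 + df2
        f = normalized_difference(df1, expectation(dft, n1, n2), dft)
        assert -1.0 <= f <= 1.0

    def test_f_strictly_increases_in_df1_at_fixed_dft(self):
        n1, n2, dft = 50, 500, 20
        values = [
            normalized_difference(df1, expectation(dft, n1, n2), dft)
            for df1 in range(0, dft + 1)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))


class TestZScores:
    def test_hand_computed_example(self):
        z, stats = zscores({"a": 0.4, "b": 0.0, "c": -0.4})
        assert z == pytest.approx({"a": 1.0, "b": 0.0, "c": -1.0})
        assert stats.mean_f == pytest.approx(0.0)
        assert stats.sd_f == pytest.approx(0.4)

    def test_output_ordered_by_z_then_symbol(self):
        z, _ = zscores({"b": 0.1, "a": 0.1, "c": 0.9, "d": -0.2})
        assert list(z) == ["c", "a", "b", "d"]

    @given(
        st.dictionaries(
            st.text(st.characters(categories=["Lu"]), min_size=1, max_size=4),
            st.floats(min_value=-1, max_value=1, allow_nan=False),
            min_size=2,
            max_size=20,
        )
    )
    def test_standardization_mean_zero_sd_one(self, f_by_symbol):
        values = list(f_by_symbol.values())
        if max(values) - min(values) < 1e-9:
            return  # degenerate sets are covered by the error-contract test
        z, _ = zscores(f_by_symbol)
        zs = list(z.values())
        n = len(zs)
        mean = sum(zs) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in zs) / (n - 1))
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(1.0, abs=1e-9)

    def test_translation_invariance(self):
        base = {"a": 0.4, "b": 0.1, "c": -0.3}
        shifted = {k: v + 0.25 for k, v in base.items()}
        z1, _ = zscores(base)
        z2, _ = zscores(shifted)
        for symbol in base:
            assert z1[symbol] == pytest.approx(z2[symbol])

    def test_degenerate_and_undersized_inputs_are_errors(self):
        with pytest.raises(DegenerateScoreSetError):
            zscores({"a": 0.5, "b": 0.5, "c": 0.5})
        with pytest.raises(ValueError, match="at least 2"):
            zscores({"a": 0.5})


class TestThreshold:
    def records(self, zs):
        return [
            ScoreRecord(
                symbol=f"S{i}", df1=1, df2=0, ex=0.5, ev=1, f=0.5, z=z
            )
            for i, z in enumerate(zs)
        ]

    def test_strict_inequality_at_cutoff(self):
        survivors = apply_threshold(self.records([1.5, 1.0, 0.2]), tau=1.0)
        assert [r.z for r in survivors] == [1.5]

    def test_very_low_tau_keeps_everything_in_order(self):
        recs = self.records([2.0, 0.5, -1.0])
        assert apply_threshold(recs, tau=-1e9) == recs

    def test_sweep_counts_non_increasing(self):
        recs = self.records([3.2, 2.1, 1.4, 1.0, 0.3, -0.5])
        taus = [1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
        table = threshold_sweep(recs, taus, known_symbols={"S0", "S3"})
        totals = table["n_known_significant"] + table["n_new_significant"]
        assert all(a >= b for a, b in zip(totals, totals[1:]))
        assert totals.iloc[0] == len(apply_threshold(recs, 1.0))

    def test_sweep_splits_known_and_new(self):
        recs = self.records([2.0])
        table = threshold_sweep(recs, [1.0, 3.0], known_symbols={"S0"})
        assert table.to_dict("records") == [
            {"tau": 1.0, "n_known_significant": 1, "n_new_significant": 0},
            {"tau": 3.0, "n_known_significant": 0, "n_new_significant": 0},
        ]


class TestPipelineAgainstOracle:
    def test_pipeline_equals_brute_force_on_small_corpus(self):
        config = SyntheticCorpusConfig(
            n1=20,
            n2=30,
            markers=(
                MarkerSpec("ENRICHED1", p1=0.9, p2=0.05, aliases=("enr-1",)),
                MarkerSpec("MIDDLE1", p1=0.4, p2=0.3),
                MarkerSpec("FLAT1", p1=0.3, p2=0.3),
                MarkerSpec("RARE1", p1=0.2, p2=0.6),
            ),
            seed=7,
        )
        corpus = generate_corpus(config)
        records, stats = run_scoring_pipeline(corpus, config)
        expected = end_to_end_expected_scores(corpus.manifest, config)
        assert {r.symbol for r in records} == set(expected)
        for r in records:
            for key in ("df1", "df2", "ex", "ev", "f", "z"):
                assert getattr(r, key) == pytest.approx(
                    expected[r.symbol][key], abs=1e-12
                )

    def test_fixed_count_design_scores_exactly(self):
        # p=1/0 design pins the counts: enriched df1=n1, backgrounds flat
        config = SyntheticCorpusConfig(
            n1=5,
            n2=5,
            markers=(
                MarkerSpec("ALWAYS1", p1=1.0, p2=0.0),
                MarkerSpec("BOTH1", p1=1.0, p2=1.0),
                MarkerSpec("HALF1", p1=1.0, p2=0.0, aliases=("hf-1",)),
            ),
            seed=3,
        )
        corpus = generate_corpus(config)
        assert corpus.manifest.df1 == {"ALWAYS1": 5, "BOTH1": 5, "HALF1": 5}
        assert corpus.manifest.df2 == {"BOTH1": 5}
        records, _ = run_scoring_pipeline(corpus, config)
        by_symbol = {r.symbol: r for r in records}
        # ALWAYS1/HALF1: dft=5, ex=2.5, f=0.5; BOTH1: dft=10, ex=5, f=0
        assert by_symbol["ALWAYS1"].f == pytest.approx(0.5)
        assert by_symbol["BOTH1"].f == pytest.approx(0.0)


def test_score_table_layout(tmp_path):
    records = [
        ScoreRecord(
            symbol="A",
            df1=3,
            df2=1,
            ex=1.0,
            ev=3,
            f=0.5,
            z=1.2,
            s1_pmids=frozenset({"2", "1"}),
        )
    ]
    out = tmp_path / "scores.tsv"
    with open(out, "w") as fh:
        write_score_table(records, fh)
    header, row = out.read_text().splitlines()
    assert header.split("\t") == [
        "symbol", "df1", "df2", "dft", "ex", "ev", "f", "z", "significant", "s1_pmids",
    ]
    assert row.split("\t") == ["A", "3", "1", "4", "1", "3", "0.5", "1.2", "1", "1;2"]
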