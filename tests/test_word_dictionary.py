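import itertools
import math

import numpy as np
import pytest

from pepwords import (
    AMINO_ACIDS,
    CompositionTable,
    Orf,
    Proteome,
    build_dictionary,
    cluster_redundant,
    expected_count,
    expected_frequency,
    read_dictionary,
    uniform_composition,
    write_dictionary,
)
from pepwords.word_dictionary import count_words, window_total

from conftest import brute_force_counts


class TestCounting:
    def test_homopolymer_hand_enumeration(self):
        d = build_dictionary(Proteome("g", (Orf("a", "AAAA"),)))
        assert {w: e.observed for w, e in d.entries.items()} == {"AA": 3, "AAA": 2}
        # AAAA itself occurs once and is dropped by the retention filter
        assert "AAAA" not in d.entries

    def test_all_unique_windows_give_empty_dictionary(self):
        d = build_dictionary(Proteome("g", (Orf("a", "ACDEF"),)))
        assert d.entries == {}
        assert d.window_totals[2] == 4

    def test_clustering_removes_duplicate_before_counting(self):
        p = cluster_redundant(
            Proteome("g", (Orf("a", "MKVMKVMKVMKV"), Orf("b", "MKVMKVMKVMKV")))
        )
        assert len(p) == 1
        d = build_dictionary(p)
        assert d.entries["MKV"].observed == 4  # one surviving copy only

    def test_windows_do_not_cross_orf_boundaries(self):
        d = build_dictionary(Proteome("g", (Orf("a", "MK"), Orf("b", "KM"))))
        # "KK" would only exist across the boundary
        assert d.observed("KK") == 0
        assert d.window_totals[2] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_brute_force_oracle(self, seed):
        from pepwords import free_living_composition, generate_proteome

        p = generate_proteome(
            free_living_composition(), n_orfs=6, length_dist=(60.0, 15.0),
            seed=seed, genome_id=f"g{seed}",
        )
        d = build_dictionary(p)
        for n in range(2, 13):
            oracle = brute_force_counts(p.sequences, n)
            assert d.window_totals[n] == sum(oracle.values())
            retained = {w: c for w, c in oracle.items() if c >= 2}
            got = {w: e.observed for w, e in d.entries.items() if len(w) == n}
            assert got == retained

    def test_counting_conservation_before_retention(self, random_proteome):
        for n in (2, 3, 5):
            counts = count_words(random_proteome.sequences, n)
            assert sum(counts.values()) == window_total(random_proteome, n)

    def test_invalid_range_rejected(self, random_proteome):
        with pytest.raises(ValueError):
            build_dictionary(random_proteome, nmin=5, nmax=3)
        with pytest.raises(ValueError):
            build_dictionary(random_proteome, nmin=1, nmax=12)

    def test_retention_filter_bounds(self, random_dictionary):
        for w, e in random_dictionary.entries.items():
            assert e.observed >= 2
            assert 2 <= len(w) <= 12


class TestExpectation:
    def test_dipeptide_alanine_worked_example(self):
        """Alanine at 5% -> homodipeptide AA expected at 0.25% of windows."""
        freq = {aa: 0.05 for aa in AMINO_ACIDS}
        comp = CompositionTable(freq, total_residues=10_000)
        d = build_dictionary(
            Proteome("g", (Orf("a", "MKVLAW" * 4),))
        )  # entries irrelevant; swap in the target composition
        d = type(d)(
            d.genome_id, d.entries, comp, d.window_totals,
            nmin=d.nmin, nmax=d.nmax, sequences=d.sequences,
        )
        assert expected_frequency("AA", d) == pytest.approx(0.0025)

    def test_uniform_composition_symmetry(self, uniform_proteome):
        d = build_dictionary(uniform_proteome)
        comp = uniform_composition(d.total_residues)
        d = type(d)(
            d.genome_id, d.entries, comp, d.window_totals,
            nmin=d.nmin, nmax=d.nmax, sequences=d.sequences,
        )
        values = [expected_frequency(a + b, d) for a, b in
                  itertools.product("ACDE", repeat=2)]
        assert values == pytest.approx([0.0025] * len(values))

    def test_trimer_matches_brute_force_formula(self, random_proteome):
        """Expected frequency of a 3-mer equals the hand-computed mean of its
        two 2-submer terms, with submer frequencies from exhaustive window
        enumeration."""
        d = build_dictionary(random_proteome)
        comp = d.composition
        two = brute_force_counts(random_proteome.sequences, 2)
        w2 = window_total(random_proteome, 2)
        for word in ["MKV", "LLA", "AAA"]:
            manual = 0.5 * (
                two.get(word[:2], 0) / w2 * comp[word[2]]
                + two.get(word[1:], 0) / w2 * comp[word[0]]
            )
            assert expected_frequency(word, d) == pytest.approx(manual)

    def test_expected_count_scale(self):
        freq = {aa: 0.05 for aa in AMINO_ACIDS}
        comp = CompositionTable(freq, total_residues=10_001)
        d = build_dictionary(Proteome("g", (Orf("a", "A" * 10_001),)))
        d = type(d)(
            d.genome_id, d.entries, comp, d.window_totals,
            nmin=d.nmin, nmax=d.nmax, sequences=d.sequences,
        )
        assert d.window_totals[2] == 10_000
        assert expected_count("AA", d) == pytest.approx(25.0)

    def test_zero_frequency_letter_gives_zero(self, random_proteome):
        d = build_dictionary(random_proteome)
        # construct a composition without tryptophan
        freq = dict(d.composition.freq)
        freq["A"] += freq["W"]
        freq["W"] = 0.0
        d = type(d)(
            d.genome_id, d.entries, CompositionTable(freq, d.total_residues),
            d.window_totals, nmin=d.nmin, nmax=d.nmax, sequences=d.sequences,
        )
        assert expected_frequency("WW", d) == 0.0
        assert expected_count("WAK", d) == 0.0

    def test_sum_of_expected_counts_is_window_total(self, random_proteome):
        """Normalization oracle: summed over all 400 dipeptides, expected
        counts reproduce the number of dipeptide windows exactly."""
        d = build_dictionary(random_proteome)
        total = sum(
            expected_count(a + b, d)
            for a, b in itertools.product(AMINO_ACIDS, repeat=2)
        )
        assert total == pytest.approx(d.window_totals[2], rel=1e-9)

    def test_residual_stored_consistently(self, random_dictionary):
        for e in random_dictionary.entries.values():
            assert e.residual == pytest.approx(
                abs(e.observed - e.expected) / math.sqrt(2)
            )

    def test_word_length_out_of_range_rejected(self, random_dictionary):
        with pytest.raises(ValueError):
            expected_frequency("A", random_dictionary)
        with pytest.raises(ValueError):
            expected_frequency("A" * 13, random_dictionary)


class TestSerialization:
    def test_round_trip(self, tmp_path, random_dictionary):
        path = write_dictionary(random_dictionary, tmp_path / "d.tsv")
        back = read_dictionary(path)
        assert back.genome_id == random_dictionary.genome_id
        assert back.window_totals == random_dictionary.window_totals
        assert set(back.entries) == set(random_dictionary.entries)
        for w, e in random_dictionary.entries.items():
            assert back.entries[w].observed == e.observed
            assert back.entries[w].expected == pytest.approx(e.expected, rel=1e-8)

    def test_deterministic_row_order(self, tmp_path, random_dictionary):
        p1 = write_dictionary(random_dictionary, tmp_path / "a.tsv")
        p2 = write_dictionary(random_dictionary, tmp_path / "b.tsv")
        assert p1.read_text() == p2.read_text()
        words = [
            line.split("\t")[0]
            for line in p1.read_text().splitlines()
            if line and not line.startswith(("#", "word"))
        ]
        assert words == sorted(words, key=lambda w: (len(w), w))
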