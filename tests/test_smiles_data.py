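"""Tokenizer, vocabulary, encoding, positional encoding and dataset I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claps.smiles_data import (EmbeddingTable, PAD_TOKEN, build_vocabulary,
                               decode, embed, encode, load_corpus,
                               murcko_scaffold, positional_encoding,
                               random_split, read_property_csv,
                               scaffold_split, tokenize)
from claps.synthetic import generate_synthetic_corpus, generate_synthetic_labels

CLINTOX_EXAMPLE = "C[NH+]1CCC[C@H]1c2cccnc2"


class TestTokenize:
    @pytest.mark.parametrize("s,expected", [
        ("CCO", ["C", "C", "O"]),
        ("C(Cl)Br", ["C", "(", "Cl", ")", "Br"]),
        ("ClCCl", ["Cl", "C", "Cl"]),
        ("C[NH+]1CC", ["C", "[NH+]", "1", "C", "C"]),
    ])
    def test_known_tokenizations(self, s, expected):
        assert tokenize(s) == expected

    def test_bracket_atoms_and_two_letter_elements_are_single_tokens(self):
        toks = tokenize(CLINTOX_EXAMPLE)
        assert "[NH+]" in toks and "[C@H]" in toks
        assert "".join(toks) == CLINTOX_EXAMPLE

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            tokenize("")

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_lossless_on_generated_molecules(self, seed):
        for s in generate_synthetic_corpus(3, seed=seed):
            assert "".join(tokenize(s)) == s


class TestVocabulary:
    def test_single_char_atoms(self):
        v = build_vocabulary(["CCO", "CCN"])
        assert len(v) == 5  # C, O, N + pad + mask
        assert {"C", "O", "N"} <= set(v.tokens)

    def test_two_letter_element_is_one_token(self):
        v = build_vocabulary(["ClCCl"])
        assert len(v) == 4  # Cl, C + specials
        assert "Cl" in v

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty corpus"):
            build_vocabulary([])

    def test_bijection_and_specials(self, corpus200):
        v = build_vocabulary(corpus200)
        assert sorted(v.ids.values()) == list(range(len(v)))
        assert v.pad_id != v.mask_id
        # first-appearance order: specials come last
        assert v.tokens[-2] == PAD_TOKEN

    def test_roundtrip_through_file(self, tmp_path, corpus200):
        v = build_vocabulary(corpus200)
        v.save(tmp_path / "vocab.json")
        v2 = type(v).load(tmp_path / "vocab.json")
        assert v2.tokens == v.tokens and v2.pad_id == v.pad_id


class TestEncode:
    def test_padding_and_true_length(self):
        v = build_vocabulary(["CCO"])
        mol = encode("CCO", v, C=6)
        assert mol.true_length == 3
        assert list(mol.token_ids[3:]) == [v.pad_id] * 3
        assert all(i != v.pad_id for i in mol.token_ids[:3])
        assert decode(mol, v) == "CCO"

    def test_overlength_is_an_error_not_truncation(self):
        v = build_vocabulary(["CCO"])
        with pytest.raises(ValueError, match="exceeds C"):
            encode("CCO", v, C=2)

    def test_unknown_token_rejected(self):
        v = build_vocabulary(["CCO"])
        with pytest.raises(KeyError, match="unknown token"):
            encode("CCS", v, C=8)

    def test_roundtrip_over_corpus(self, corpus200):
        v = build_vocabulary(corpus200)
        for s in corpus200[:50]:
            assert decode(encode(s, v, C=64), v) == s


class TestPositionalEncoding:
    def test_row_zero_alternates_zero_one(self):
        pe = positional_encoding(4, 6)
        assert np.allclose(pe[0], [0, 1, 0, 1, 0, 1])

    def test_matches_closed_form_at_random_entries(self, rng):
        C, d = 50, 16
        pe = positional_encoding(C, d)
        for _ in range(20):
            pos = int(rng.integers(C))
            i = int(rng.integers(d // 2))
            angle = pos / 10000 ** (2 * i / d)
            assert pe[pos, 2 * i] == pytest.approx(np.sin(angle), abs=1e-9)
            assert pe[pos, 2 * i + 1] == pytest.approx(np.cos(angle), abs=1e-9)

    def test_bounded_and_odd_dim_rejected(self):
        assert np.all(np.abs(positional_encoding(30, 8)) <= 1.0)
        with pytest.raises(ValueError):
            positional_encoding(10, 7)


class TestEmbed:
    def test_additive_structure(self, rng):
        v = build_vocabulary(["CCO", "CCN"])
        mol = encode("CCO", v, C=5)
        table = EmbeddingTable(len(v), 8, seed=2)
        pe = positional_encoding(5, 8)
        X = embed(mol, table, pe)
        assert X.shape == (5, 8)
        # X - P recovers the looked-up embedding row at every position
        for pos in range(5):
            np.testing.assert_allclose(X[pos] - pe[pos],
                                       table.matrix[mol.token_ids[pos]])
        zero = EmbeddingTable(len(v), 8, seed=2)
        zero.matrix[:] = 0.0
        np.testing.assert_allclose(embed(mol, zero, pe), pe)

    def test_shape_mismatch_rejected(self):
        v = build_vocabulary(["CCO"])
        mol = encode("CCO", v, C=5)
        with pytest.raises(ValueError):
            embed(mol, EmbeddingTable(len(v), 8, seed=0), positional_encoding(4, 8))

    def test_embedding_table_reproducible_under_seed(self):
        a = EmbeddingTable(7, 4, seed=9).matrix
        b = EmbeddingTable(7, 4, seed=9).matrix
        np.testing.assert_array_equal(a, b)


class TestPropertyCsv:
    def test_blank_cells_become_unobserved(self, tmp_path):
        p = tmp_path / "toy.csv"
        p.write_text("smiles,y\nCCO,1\nCCN,\nCCS,0\n")
        ds = read_property_csv(p, "smiles", ["y"], "classification")
        assert ds.observed.sum() == 2 and not ds.observed[1, 0]

    def test_missing_column_is_named_in_error(self, tmp_path):
        p = tmp_path / "toy.csv"
        p.write_text("smiles,y\nCCO,1\n")
        with pytest.raises(KeyError, match="z"):
            read_property_csv(p, "smiles", ["z"], "classification")

    def test_multilabel_example_row(self, tmp_path):
        p = tmp_path / "clintox.csv"
        p.write_text(f"smiles,a,b\n{CLINTOX_EXAMPLE},1,0\n"
                     "CCO,0,1\nCCC,1,1\n")
        ds = read_property_csv(p, "smiles", ["a", "b"], "classification")
        np.testing.assert_array_equal(ds.labels[0], [1.0, 0.0])

    def test_unparsable_smiles_dropped(self, tmp_path, caplog):
        p = tmp_path / "bad.csv"
        p.write_text("smiles,y\nCCO,1\nnot_a_smiles,0\nCCN,1\n")
        ds = read_property_csv(p, "smiles", ["y"], "classification")
        assert len(ds) == 2


class TestScaffolds:
    def test_acyclic_molecules_have_empty_scaffold(self):
        assert murcko_scaffold("CCO") == ""

    def test_side_chains_removed(self):
        assert murcko_scaffold("c1ccccc1CC") == murcko_scaffold("c1ccccc1C")

    def test_deterministic(self):
        assert murcko_scaffold("c1ccccc1") == murcko_scaffold("c1ccccc1")

    def test_unparsable_rejected(self):
        with pytest.raises(ValueError):
            murcko_scaffold("not_a_smiles")


class TestSplits:
    def _dataset(self, n, seed=0):
        smiles = generate_synthetic_corpus(n, seed=seed)
        return generate_synthetic_labels(smiles, "classification", seed=seed)

    def test_distinct_scaffolds_give_811(self):
        smiles = ["c1ccccc1C", "c1ccncc1C", "c1cccnc1C", "c1ccsc1C",
                  "c1ccoc1C", "C1CCCCC1C", "C1CCNCC1C", "C1CCOCC1C",
                  "C1CCCC1C", "Cc1cnccn1"]
        ds = generate_synthetic_labels(smiles, "classification", seed=0)
        sp = scaffold_split(ds)
        assert (len(sp.train), len(sp.valid), len(sp.test)) == (8, 1, 1)

    def test_scaffold_cohesion_and_partition(self):
        ds = self._dataset(300, seed=4)
        sp = scaffold_split(ds, seed=0)
        all_idx = sorted(sp.train + sp.valid + sp.test)
        assert all_idx == list(range(len(ds)))
        subset_of = {}
        for name, idx in (("t", sp.train), ("v", sp.valid), ("s", sp.test)):
            for i in idx:
                subset_of[i] = name
        for i, j in zip(all_idx, all_idx[1:]):
            if sp.scaffold_of[i] == sp.scaffold_of[j]:
                assert subset_of[i] == subset_of[j]

    def test_train_fraction_near_target(self):
        ds = self._dataset(100, seed=7)
        sp = scaffold_split(ds, seed=0)
        assert 0.7 <= len(sp.train) / len(ds) <= 0.9

    def test_too_small_dataset_rejected(self):
        ds = generate_synthetic_labels(["CCO", "CCN"], "classification")
        with pytest.raises(ValueError):
            scaffold_split(ds)
        with pytest.raises(ValueError):
            random_split(ds)

    def test_random_split_sizes_and_determinism(self):
        ds = self._dataset(100, seed=2)
        a = random_split(ds, seed=5)
        b = random_split(ds, seed=5)
        assert (a.train, a.valid, a.test) == (b.train, b.valid, b.test)
        assert (len(a.train), len(a.valid), len(a.test)) == (80, 10, 10)
        c = random_split(ds, seed=6)
        assert a.train != c.train

    def test_split_frame_layout(self, tmp_path):
        ds = self._dataset(20, seed=3)
        df = random_split(ds, seed=0).to_frame(ds.smiles)
        assert list(df.columns) == ["index", "smiles", "subset"]
        assert len(df) == 20


class TestCorpusLoader:
    def test_drops_bad_and_overlength_lines(self, tmp_path):
        p = tmp_path / "corpus.smi"
        p.write_text("CCO\n\nnot_a_smiles\n" + "C" * 99 + "\nCCN\n")
        assert load_corpus(p, max_len=50) == ["CCO", "CCN"]
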