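import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from potn import feature_engine as fe
from potn.peptide_io import AMINO_ACIDS, LabeledPeptideSet, PeptideRecord

PEPTIDES = st.text(alphabet=AMINO_ACIDS, min_size=9, max_size=9)


@pytest.fixture(scope="module")
def tables():
    return fe.load_property_tables()


class TestPropertyTables:
    def test_defaults_cover_all_scales(self, tables):
        expected = {"ASA", "charge", "ECI", "entropy", "hydrophobicity",
                    "ISA", "Mw", "organic_solvent_water", "PI", "polarity"}
        assert expected <= set(tables)
        for t in tables.values():
            assert len(t.values) == 20
            assert all(np.isfinite(v) for v in t.values.values())

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError):
            fe.PropertyTable("bad", {"A": 1.0})

    def test_custom_file_override(self, tmp_path, tables):
        path = tmp_path / "props.tsv"
        header = "property_name\t" + "\t".join(AMINO_ACIDS)
        row = "myscale\t" + "\t".join(str(i) for i in range(20))
        path.write_text(header + "\n" + row + "\n")
        loaded = fe.load_property_tables(path)
        assert loaded["myscale"]["C"] == 1.0


class TestPositionFrequencies:
    def test_single_peptide(self):
        fm = fe.position_frequencies(["AAAAAAAAA"])
        assert (fm.freq.loc["A"] == 1.0).all()
        assert fm.freq.drop(index="A").to_numpy().sum() == 0

    def test_direct_count(self):
        fm = fe.position_frequencies(["ALAAAAAAV", "GLAAAAAAL"])
        assert fm.freq.at["L", "P2"] == 1.0
        assert fm.freq.at["V", "P9"] == 0.5

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(7)
        peps = ["".join(rng.choice(list(AMINO_ACIDS), 9)) for _ in range(50)]
        fm = fe.position_frequencies(peps)
        for aa in AMINO_ACIDS:            # independent counting oracle
            for j in range(9):
                expected = sum(p[j] == aa for p in peps) / 50
                assert fm.freq.at[aa, f"P{j + 1}"] == pytest.approx(expected)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(8)
        peps = ["".join(rng.choice(list(AMINO_ACIDS), 9)) for _ in range(31)]
        fm = fe.position_frequencies(peps)
        assert np.allclose(fm.freq.sum(axis=0), 1.0, atol=1e-12)

    def test_empty_collection_is_error(self):
        with pytest.raises(ValueError):
            fe.position_frequencies([])


def freq_from(peps):
    return fe.position_frequencies(peps)


class TestResiduePropensity:
    def test_toy_sets_equal_per_cell_arithmetic(self):
        pos = ["ALAAAAAAV", "GLGAAAAAV", "ALGAAAAAL"]
        neg = ["KLAAAAAAV", "KLKAAAAAV", "ALKAAAAAL"]
        m = fe.residue_propensity(freq_from(pos), freq_from(neg))
        pf, nf = freq_from(pos).freq, freq_from(neg).freq
        for aa in AMINO_ACIDS:            # brute-force per-cell oracle
            for col in pf.columns:
                p, n = pf.at[aa, col], nf.at[aa, col]
                expected = 0.0 if p + n == 0 else (p - n) / (p + n)
                assert m.scores.at[aa, col] == pytest.approx(expected)

    def test_boundary_values(self):
        pos = ["ALAAAAAAV"]                # A present only in positives at P1
        neg = ["KLAAAAAAV"]
        m = fe.residue_propensity(freq_from(pos * 2), freq_from(neg * 2))
        assert m.scores.at["A", "P1"] == 1.0
        assert m.scores.at["K", "P1"] == -1.0
        assert m.scores.at["L", "P2"] == 0.0     # equal frequencies
        assert m.scores.at["W", "P5"] == 0.0     # absent from both -> default

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        pos = ["".join(rng.choice(list(AMINO_ACIDS), 9)) for _ in range(20)]
        neg = ["".join(rng.choice(list(AMINO_ACIDS), 9)) for _ in range(25)]
        a = fe.residue_propensity(freq_from(pos), freq_from(neg)).scores
        b = fe.residue_propensity(freq_from(neg), freq_from(pos)).scores
        assert np.allclose(a.to_numpy(), -b.to_numpy())

    def test_range_bounded(self):
        rng = np.random.default_rng(4)
        pos = ["".join(rng.choice(list(AMINO_ACIDS), 9)) for _ in range(15)]
        neg = ["".join(rng.choice(list(AMINO_ACIDS), 9)) for _ in range(15)]
        m = fe.residue_propensity(freq_from(pos), freq_from(neg)).scores
        assert (m.to_numpy() >= -1).all() and (m.to_numpy() <= 1).all()

    def test_scale_invariance_of_frequency_units(self):
        """Multiplying both frequency matrices by one positive constant
        (the x100 of percentage units) leaves the scores unchanged."""
        pos, neg = freq_from(["ALAAAAAAV"] * 3), freq_from(["KLCAAAAAV"] * 3)
        base = fe.residue_propensity(pos, neg).scores
        pos.freq *= 100
        neg.freq *= 100
        scaled = fe.residue_propensity(pos, neg).scores
        assert np.allclose(base.to_numpy(), scaled.to_numpy())

    def test_tsv_round_trip(self, tmp_path):
        m = fe.residue_propensity(freq_from(["ALAAAAAAV"] * 2),
                                  freq_from(["KLCAAAAAV"] * 2))
        path = tmp_path / "prop.tsv"
        m.to_tsv(path)
        again = fe.PropensityMatrix.from_tsv(path)
        assert np.allclose(m.scores.to_numpy(), again.scores.to_numpy())


class TestPropensityFeatures:
    def test_zero_matrix_gives_zeros(self):
        m = fe.PropensityMatrix(scores=pd.DataFrame(
            0.0, index=list(AMINO_ACIDS), columns=fe.POSITIONS))
        feats = fe.propensity_features("ALAAAAAAV", m)
        assert all(v == 0.0 for v in feats.values())

    def test_single_hot_cell(self):
        df = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=fe.POSITIONS)
        df.at["L", "P2"] = 1.0
        feats = fe.propensity_features(
            "ALAAAAAAA", fe.PropensityMatrix(scores=df))
        assert feats["propensity@P2"] == 1.0
        assert feats["propensity@sum"] == 1.0

    @settings(max_examples=25, deadline=None)
    @given(pep=PEPTIDES, seed=st.integers(0, 2**20))
    def test_sum_equals_direct_summation(self, pep, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.uniform(-1, 1, (20, 9)),
                          index=list(AMINO_ACIDS), columns=fe.POSITIONS)
        m = fe.PropensityMatrix(scores=df)
        feats = fe.propensity_features(pep, m)
        oracle = sum(df.at[pep[j], f"P{j + 1}"] for j in range(9))
        assert feats["propensity@sum"] == pytest.approx(oracle)


class TestPhyschemFeatures:
    def test_uniform_peptide_takes_table_value(self, tables):
        feats = fe.physchem_features("AAAAAAAAA", tables)
        for (name, _), key in zip(fe.DEFAULT_PHYSCHEM_SPEC, feats):
            assert feats[key] == tables[name]["A"]

    def test_lookup_position_semantics(self, tables):
        feats = fe.physchem_features("AALAAAAAA", tables)
        assert feats["hydrophobicity@P3"] == tables["hydrophobicity"]["L"]

    def test_full_spec_equals_dict_lookup_oracle(self, tables):
        rng = np.random.default_rng(5)
        peps = ["".join(rng.choice(list(AMINO_ACIDS), 9)) for _ in range(10)]
        for pep in peps:
            feats = fe.physchem_features(pep, tables)
            assert len(feats) == 11
            for name, pos in fe.DEFAULT_PHYSCHEM_SPEC:
                assert feats[f"{name}@P{pos}"] == tables[name].values[pep[pos - 1]]

    def test_unknown_table_is_error(self, tables):
        with pytest.raises(KeyError):
            fe.physchem_features("AAAAAAAAA", tables, spec=[("nope", 3)])


class TestExternalFeatures:
    def _write(self, path, rows):
        header = "peptide\t" + "\t".join(fe.EXTERNAL_COLUMNS)
        path.write_text("\n".join([header] + rows) + "\n")

    def test_full_coverage_join(self, tmp_path):
        p = tmp_path / "ext.tsv"
        self._write(p, ["AAAAAAAAA\t" + "\t".join("1234567"),
                        "CCCCCCCCC\t" + "\t".join("7654321")])
        ext = fe.import_external_features(p)
        joined, coverage = fe.join_external(["AAAAAAAAA", "CCCCCCCCC"], ext)
        assert coverage == 1.0
        assert not joined.isna().any().any()

    def test_zero_coverage_flags_core_mode(self, tmp_path):
        p = tmp_path / "ext.tsv"
        self._write(p, ["AAAAAAAAA\t" + "\t".join("1234567")])
        ext = fe.import_external_features(p)
        joined, coverage = fe.join_external(["CCCCCCCCC"], ext)
        assert coverage == 0.0
        assert joined.isna().all().all()

    def test_conflicting_duplicate_is_error(self, tmp_path):
        p = tmp_path / "ext.tsv"
        self._write(p, ["AAAAAAAAA\t1\t2\t3\t4\t5\t6\t7",
                        "AAAAAAAAA\t9\t2\t3\t4\t5\t6\t7"])
        with pytest.raises(ValueError, match="conflicting"):
            fe.import_external_features(p)


class TestBuildFeatureTable:
    def test_full_mode_has_28_columns(self, benchmark):
        matrix = fe.fit_propensity(benchmark.train)
        table = fe.build_feature_table(
            benchmark.train.sequences, matrix, fe.load_property_tables(),
            external=benchmark.external)
        assert table.shape[1] == 28

    def test_core_mode_has_21_columns(self, benchmark):
        matrix = fe.fit_propensity(benchmark.train)
        table = fe.build_feature_table(
            benchmark.train.sequences, matrix, fe.load_property_tables())
        assert table.shape[1] == 21

    def test_single_row_composes_lookup_oracles(self, tables):
        pset = LabeledPeptideSet([PeptideRecord("ALGAAAAAV", 1),
                                  PeptideRecord("KLCAAAAAV", 0)])
        matrix = fe.fit_propensity(pset)
        table = fe.build_feature_table(["ALGAAAAAV"], matrix, tables)
        row = table.iloc[0]
        expected = fe.physchem_features("ALGAAAAAV", tables)
        expected.update(fe.propensity_features("ALGAAAAAV", matrix))
        for k, v in expected.items():
            assert row[k] == pytest.approx(v)


class TestSelectFeatures:
    def test_printed_two_group_fixture(self):
        """Groups (1,2,3) vs (4,5,6): pooled t = -3/sqrt(2/3), df = 4."""
        from scipy import stats

        table = pd.DataFrame({"x": [1, 2, 3, 4, 5, 6]})
        labels = [1, 1, 1, 0, 0, 0]
        t_oracle = -3.0 / np.sqrt(2.0 / 3.0)
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df=4)
        res = fe.select_features(table, labels, alpha=0.05)
        assert res.pvalues["x"] == pytest.approx(p_oracle)
        assert res.retained["x"] == (p_oracle < 0.05)

    def test_identical_groups_not_retained(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 1.0, 2.0]})
        res = fe.select_features(table, [1, 1, 0, 0], alpha=0.05)
        assert res.pvalues["x"] == pytest.approx(1.0)
        assert not res.retained["x"]

    def test_constant_column_p_one(self):
        table = pd.DataFrame({"x": [5.0] * 6})
        res = fe.select_features(table, [1, 1, 1, 0, 0, 0])
        assert res.pvalues["x"] == 1.0

    def test_alpha_near_one_retains_non_degenerate(self):
        table = pd.DataFrame({"x": [1, 2, 3, 4, 5, 6.0]})
        res = fe.select_features(table, [1, 1, 1, 0, 0, 0], alpha=1 - 1e-9)
        assert res.retained["x"]

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(rng.normal(size=(30, 8)),
                             columns=[f"f{i}" for i in range(8)])
        labels = [1] * 15 + [0] * 15
        prev: set = set()
        for alpha in (0.01, 0.05, 0.2, 0.8):
            res = fe.select_features(table, labels, alpha=alpha)
            current = set(res.selected_features)
            assert prev <= current
            prev = current

    def test_small_class_is_error(self):
        table = pd.DataFrame({"x": [1, 2, 3.0]})
        with pytest.raises(ValueError):
            fe.select_features(table, [1, 0, 0])


class TestStandardize:
    def test_two_point_column_uses_sample_sd(self):
        table = pd.DataFrame({"x": [0.0, 10.0]})
        scaled, _ = fe.standardize(table)
        assert np.allclose(scaled["x"], [-0.7071067811865475, 0.7071067811865475])

    def test_fit_rows_give_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(5, 3, size=(40, 3)), columns=list("abc"))
        scaled, _ = fe.standardize(table)
        assert np.allclose(scaled.mean(), 0, atol=1e-12)
        assert np.allclose(scaled.std(ddof=1), 1, atol=1e-12)

    def test_held_out_rows_use_train_statistics(self):
        rng = np.random.default_rng(6)
        train = pd.DataFrame({"x": rng.normal(size=20)})
        test = pd.DataFrame({"x": rng.normal(size=10)})
        scaled, scaler = fe.standardize(test, fit_rows=train)
        oracle = (test["x"] - train["x"].mean()) / train["x"].std(ddof=1)
        assert np.allclose(scaled["x"], oracle)

    def test_zero_variance_maps_to_zero(self):
        table = pd.DataFrame({"x": [3.0, 3.0, 3.0]})
        scaled, _ = fe.standardize(table)
        assert (scaled["x"] == 0).all()


class TestParameterRecovery:
    def test_planted_enrichment_recovered_and_monotone(self):
        """An injected positive-class enrichment of R at P3 yields a
        positive fitted propensity cell that grows with the effect size."""
        from potn import synthetic as syn

        values = []
        for factor in (2.0, 4.0, 8.0):
            spec = syn.GeneratorSpec(
                n_positive=500, n_negative=500,
                class_bias=((3, "R", factor),), seed=77)
            pset = syn.generate_peptides(spec)
            m = fe.fit_propensity(pset)
            values.append(m.score("R", 3))
        assert all(v > 0 for v in values)
        assert values[0] < values[1] < values[2]
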