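import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synsign import (
    CurationEdit,
    ExpressionDB,
    apply_curation_edits,
    binarize_expression,
    expression_summary,
    neuron_nt_profile,
    neuron_receptor_classes,
)
from synsign.expression import UnknownNeuronError, expand_neuron_group
from synsign.receptors import ALL_CLASSES, ReceptorClass


def make_db(nt_rows, receptor_rows, genes):
    neurons = list(nt_rows)
    nt = pd.DataFrame(
        [nt_rows[n] for n in neurons], index=neurons,
        columns=["glutamate", "acetylcholine", "GABA"], dtype=np.int8,
    )
    rec = pd.DataFrame(
        [receptor_rows[n] for n in neurons], index=neurons, columns=genes, dtype=np.int8
    )
    return ExpressionDB(nt=nt, receptors=rec)


@pytest.fixture
def small_db():
    genes = ["glr-1", "glr-2", "unc-49", "acr-16"]
    return make_db(
        nt_rows={"AVAL": [1, 0, 0], "RIBL": [0, 1, 0], "DD1": [0, 0, 1], "BLANK": [0, 0, 0]},
        receptor_rows={
            "AVAL": [1, 1, 0, 0], "RIBL": [0, 0, 0, 1],
            "DD1": [0, 0, 1, 1], "BLANK": [0, 0, 0, 0],
        },
        genes=genes,
    )


class TestBinarize:
    def test_all_zero_stays_zero(self):
        m = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        assert binarize_expression(m, 0.0).to_numpy().sum() == 0

    def test_threshold_zero_is_positivity_indicator(self):
        m = pd.DataFrame({"a": [0.0, 5.0], "b": [5.0, 0.0]})
        out = binarize_expression(m, 0.0)
        assert out.to_numpy().tolist() == [[0, 1], [1, 0]]

    def test_matches_per_cell_oracle_on_random_matrix(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.random((20, 8)) * 10)
        t = 3.5
        out = binarize_expression(m, t)
        for i in range(m.shape[0]):
            for j in range(m.shape[1]):
                assert out.iat[i, j] == (1 if m.iat[i, j] > t else 0)

    def test_idempotent_at_zero_threshold(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.random((10, 4)))
        once = binarize_expression(m, 0.0)
        assert binarize_expression(once.astype(float), 0.0).equals(once)

    def test_negative_values_rejected(self):
        m = pd.DataFrame({"a": [1.0, -0.1]})
        with pytest.raises(ValueError, match="negative"):
            binarize_expression(m, 0.0)


def test_nt_matrix_survives_file_round_trip(tmp_path, small_db):
    """Column-name casing must not silently drop transmitter calls."""
    from synsign import load_expression_matrix

    p = tmp_path / "nt.csv"
    small_db.nt.rename_axis("neuron").to_csv(p)
    reloaded = ExpressionDB(nt=load_expression_matrix(p),
                            receptors=small_db.receptors.copy())
    pd.testing.assert_frame_equal(
        reloaded.nt, small_db.nt, check_dtype=False)


def test_unknown_nt_columns_rejected():
    nt = pd.DataFrame({"glutamate": [1], "serotonin": [0]}, index=["N"])
    with pytest.raises(ValueError, match="serotonin"):
        ExpressionDB(nt=nt, receptors=pd.DataFrame(index=["N"]))


class TestCuration:
    def test_empty_edit_list_is_identity(self, small_db):
        out, audit = apply_curation_edits(small_db, [])
        assert out.receptors.equals(small_db.receptors)
        assert audit.empty

    def test_group_add_flips_only_missing_cells(self, small_db):
        # glr-1: AVAL already positive -> adding to the AVA group via explicit
        # members flips exactly the cells that were 0
        edit = CurationEdit(group="X", target="glr-2", action="add",
                            neurons=("RIBL", "AVAL"))
        out, audit = apply_curation_edits(small_db, [edit])
        assert len(audit) == 1
        assert audit.iloc[0]["neuron"] == "RIBL"
        assert out.receptors.at["RIBL", "glr-2"] == 1

    def test_delete_then_add_restores_original(self, small_db):
        edits = [
            CurationEdit(group="AVAL", target="glr-1", action="delete"),
            CurationEdit(group="AVAL", target="glr-1", action="add"),
        ]
        out, _ = apply_curation_edits(small_db, edits)
        assert out.receptors.equals(small_db.receptors)
        assert out.nt.equals(small_db.nt)

    def test_unknown_neuron_listed_in_error(self, small_db):
        edit = CurationEdit(group="X", target="glr-1", action="add", neurons=("NOPE",))
        with pytest.raises(UnknownNeuronError, match="NOPE"):
            apply_curation_edits(small_db, [edit])

    def test_adding_excluded_gene_rejected(self, small_db, table):
        edit = CurationEdit(group="AVAL", target="acc-4", action="add")
        with pytest.raises(ValueError, match="excluded"):
            apply_curation_edits(small_db, [edit], table=table)

    def test_nt_scope_edits_touch_nt_matrix(self, small_db):
        edit = CurationEdit(group="BLANK", target="GABA", action="add",
                            scope="neurotransmitter")
        out, audit = apply_curation_edits(small_db, [edit])
        assert out.nt.at["BLANK", "GABA"] == 1
        assert audit.iloc[0]["scope"] == "neurotransmitter"

    def test_group_expansion_uses_positional_suffixes(self):
        neurons = ["AIYL", "AIYR", "AIZL", "VA1", "VA10", "VAB"]
        assert expand_neuron_group("AIY", neurons) == ["AIYL", "AIYR"]
        assert expand_neuron_group("VA", neurons) == ["VA1", "VA10"]


class TestProfiles:
    def test_glutamate_cation_only_from_two_genes(self, small_db, table):
        assert neuron_receptor_classes("AVAL", small_db, table) == {
            ReceptorClass("glutamate", "cation")
        }

    def test_no_receptor_genes_gives_empty_set(self, small_db, table):
        assert neuron_receptor_classes("BLANK", small_db, table) == frozenset()

    def test_one_gene_per_class_yields_all_six(self, table):
        genes = ["glr-1", "acr-16", "exp-1", "glc-3", "acc-1", "unc-49"]
        db = make_db({"N": [0, 0, 0]}, {"N": [1] * 6}, genes)
        assert neuron_receptor_classes("N", db, table) == frozenset(ALL_CLASSES)

    def test_nt_profile_cases(self, small_db):
        assert neuron_nt_profile("DD1", small_db) == {"GABA"}
        assert neuron_nt_profile("BLANK", small_db) == frozenset()

    def test_unknown_neuron_raises(self, small_db, table):
        with pytest.raises(UnknownNeuronError):
            neuron_nt_profile("ZZZ", small_db)
        with pytest.raises(UnknownNeuronError):
            neuron_receptor_classes("ZZZ", small_db, table)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_receptor_classes_monotone_under_added_expression(self, seed):
        from synsign import default_receptor_class_table

        table = default_receptor_class_table()
        rng = np.random.default_rng(seed)
        genes = ["glr-1", "acr-16", "exp-1", "glc-3", "acc-1", "unc-49"]
        row = rng.integers(0, 2, size=6)
        db = make_db({"N": [0, 0, 0]}, {"N": row.tolist()}, genes)
        before = neuron_receptor_classes("N", db, table)
        zeros = np.flatnonzero(row == 0)
        if len(zeros) == 0:
            return
        row2 = row.copy()
        row2[rng.choice(zeros)] = 1
        db2 = make_db({"N": [0, 0, 0]}, {"N": row2.tolist()}, genes)
        after = neuron_receptor_classes("N", db2, table)
        assert before <= after


class TestSummary:
    def test_counts_equal_brute_force_on_random_db(self, table, synthetic_dataset):
        _, (_, db, _) = synthetic_dataset
        s = expression_summary(db, table)
        # independent per-neuron loop straight off the matrices
        n_nt = {0: 0, 1: 0, 2: 0}
        same_both = 0
        mix = {"cation_only": 0, "anion_only": 0, "mixed": 0, "none": 0}
        overlap = {0: 0, 1: 0, 2: 0, 3: 0}
        for n in db.neurons:
            k = int(db.nt.loc[n].sum())
            n_nt[k] += 1
            cls = {table.entries[g] for g in db.receptors.columns
                   if db.receptors.at[n, g] == 1 and g in table.entries}
            overlap[len({c.ligand for c in cls})] += 1
            chans = {c.channel for c in cls}
            key = ("none" if not chans else "cation_only" if chans == {"cation"}
                   else "anion_only" if chans == {"anion"} else "mixed")
            mix[key] += 1
            if any((l, "cation") in cls and (l, "anion") in cls
                   for l in ("glutamate", "acetylcholine", "GABA")):
                same_both += 1
        assert s.nt_category_counts == {k: v for k, v in n_nt.items()}
        assert s.receptor_ligand_overlap_counts == overlap
        assert s.polarity_mix_counts == mix
        assert s.same_nt_both_polarity_count == same_both
        total_cells = int(db.receptors.to_numpy().sum())
        assert s.mean_receptor_genes_per_neuron == pytest.approx(total_cells / len(db.neurons))

    def test_partitions_sum_to_neuron_count(self, table, synthetic_dataset):
        _, (_, db, _) = synthetic_dataset
        s = expression_summary(db, table)
        assert sum(s.nt_category_counts.values()) == s.n_neurons
        assert sum(s.polarity_mix_counts.values()) == s.n_neurons
        assert sum(s.receptor_ligand_overlap_counts.values()) == s.n_neurons

    def test_empty_db_all_zero(self, table):
        db = make_db({}, {}, [])
        s = expression_summary(db, table)
        assert s.n_neurons == 0
        assert s.mean_receptor_genes_per_neuron == 0.0
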