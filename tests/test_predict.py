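"""Rule-engine tests, including an independent brute-force oracle.

The oracle re-derives every label straight from the raw matrices and the
packaged class CSV (read with the stdlib csv module), bypassing the
package's profile and classification machinery entirely.
"""

import csv
from importlib import resources

import pandas as pd
import pytest

from synsign import (
    PolarityLabel,
    chemical_subnetwork,
    matched_channel_types,
    predict_all,
)
from synsign.predict import (
    METHOD_NT_ONLY,
    METHOD_NT_R,
    METHOD_R_ONLY,
    label_nt_only,
    label_nt_r,
    label_r_only,
    resolve_method,
)
from synsign.receptors import ReceptorClass

NTS = ["glutamate", "acetylcholine", "GABA"]


from functools import lru_cache


@lru_cache(maxsize=1)
def _raw_gene_classes():
    ref = resources.files("synsign.data") / "receptor_classes.csv"
    with resources.as_file(ref) as path, open(path) as fh:
        rows = list(csv.DictReader(fh))
    return {r["gene"]: (r["ligand"], r["channel"]) for r in rows if r["excluded"] == "0"}


def oracle_label(pre, post, db, method):
    """Straight-line reimplementation of the three rules for one edge."""
    gene_cls = _raw_gene_classes()
    pre_nts = set()
    if pre in db.nt.index:
        pre_nts = {t for t in NTS if db.nt.at[pre, t] == 1}
    post_channels = set()
    matched_channels = set()
    if post in db.receptors.index:
        for g in db.receptors.columns:
            if db.receptors.at[post, g] == 1 and g in gene_cls:
                ligand, channel = gene_cls[g]
                post_channels.add(channel)
                if ligand in pre_nts:
                    matched_channels.add(channel)
    if method == METHOD_NT_ONLY:
        if not pre_nts:
            return "unpredicted_no_nt"
        exc = bool(pre_nts & {"acetylcholine", "glutamate"})
        inh = "GABA" in pre_nts
        return "complex" if exc and inh else "excitatory" if exc else "inhibitory"
    channels = matched_channels if method == METHOD_NT_R else post_channels
    if method == METHOD_NT_R and not pre_nts:
        return "unpredicted_no_nt"
    if channels == {"cation"}:
        return "excitatory"
    if channels == {"anion"}:
        return "inhibitory"
    if channels == {"cation", "anion"}:
        return "complex"
    return "unpredicted_no_match"


GLU_CAT = ReceptorClass("glutamate", "cation")
GLU_AN = ReceptorClass("glutamate", "anion")
ACH_CAT = ReceptorClass("acetylcholine", "cation")
ACH_AN = ReceptorClass("acetylcholine", "anion")
GABA_CAT = ReceptorClass("GABA", "cation")


class TestMatchedChannelTypes:
    def test_single_match(self):
        assert matched_channel_types({"acetylcholine"}, {ACH_CAT}) == {"cation"}

    def test_disjoint_ligands_empty(self):
        assert matched_channel_types({"GABA"}, {GLU_AN}) == frozenset()

    def test_double_nt_unions_over_transmitters(self):
        assert matched_channel_types(
            {"acetylcholine", "glutamate"}, {ACH_CAT, GLU_AN}) == {"cation", "anion"}

    def test_equals_pairwise_brute_force(self):
        import itertools
        classes = [ReceptorClass(l, c) for l in NTS for c in ("cation", "anion")]
        for nts in [set(c) for r in range(4) for c in itertools.combinations(NTS, r)]:
            for k in range(len(classes) + 1):
                for sub in itertools.combinations(classes, k) if k <= 2 else []:
                    expect = {c.channel for c in sub if c.ligand in nts}
                    assert matched_channel_types(nts, set(sub)) == expect


class TestRuleEngines:
    def test_cholinergic_onto_cation_class_excites(self):
        assert label_nt_r(frozenset({"acetylcholine"}), frozenset({ACH_CAT})) \
            == PolarityLabel.EXCITATORY

    def test_gabaergic_onto_gaba_cation_class_excites(self):
        # GABA-gated cation channels invert the transmitter's classical sign
        assert label_nt_r(frozenset({"GABA"}), frozenset({GABA_CAT})) \
            == PolarityLabel.EXCITATORY

    def test_no_receptors_is_unpredicted_no_match(self):
        assert label_nt_r(frozenset({"acetylcholine"}), frozenset()) \
            == PolarityLabel.UNPREDICTED_NO_MATCH

    def test_no_transmitter_is_unpredicted_no_nt(self):
        assert label_nt_r(frozenset(), frozenset({ACH_CAT})) \
            == PolarityLabel.UNPREDICTED_NO_NT

    @pytest.mark.parametrize("nts, expected", [
        ({"acetylcholine"}, PolarityLabel.EXCITATORY),
        ({"glutamate"}, PolarityLabel.EXCITATORY),
        ({"GABA"}, PolarityLabel.INHIBITORY),
        ({"glutamate", "GABA"}, PolarityLabel.COMPLEX),
        ({"acetylcholine", "glutamate"}, PolarityLabel.EXCITATORY),
        (set(), PolarityLabel.UNPREDICTED_NO_NT),
    ])
    def test_nt_only_rule(self, nts, expected):
        assert label_nt_only(frozenset(nts)) == expected

    def test_r_only_ignores_ligand_and_pre(self):
        assert label_r_only(frozenset({ACH_AN})) == PolarityLabel.INHIBITORY
        assert label_r_only(frozenset({ACH_CAT, GLU_AN})) == PolarityLabel.COMPLEX
        assert label_r_only(frozenset()) == PolarityLabel.UNPREDICTED_NO_MATCH

    def test_r_only_never_unpredicted_no_nt(self):
        import itertools
        classes = [ReceptorClass(l, c) for l in NTS for c in ("cation", "anion")]
        for k in range(3):
            for sub in itertools.combinations(classes, k):
                assert label_r_only(frozenset(sub)) != PolarityLabel.UNPREDICTED_NO_NT


class TestWorkedExample:
    def test_nt_r_splits_the_two_targets(self, worked_example, table):
        conn, db, _ = worked_example
        preds = predict_all(conn, db, table, method="ntr").set_index("post")
        assert preds.at["RIB", "label"] == PolarityLabel.EXCITATORY
        assert preds.at["AIZ", "label"] == PolarityLabel.INHIBITORY

    def test_nt_only_calls_both_excitatory(self, worked_example, table):
        conn, db, _ = worked_example
        preds = predict_all(conn, db, table, method="nt")
        assert (preds["label"] == PolarityLabel.EXCITATORY).all()

    def test_r_only_recovers_the_split_without_pre(self, worked_example, table):
        conn, db, _ = worked_example
        preds = predict_all(conn, db, table, method="r").set_index("post")
        assert preds.at["RIB", "label"] == PolarityLabel.EXCITATORY
        assert preds.at["AIZ", "label"] == PolarityLabel.INHIBITORY


class TestPredictAll:
    def test_empty_connectome_gives_empty_table(self, table, worked_example):
        from synsign.connectome import Connectome
        conn = Connectome(edges=pd.DataFrame(columns=["pre", "post", "kind", "weight"]))
        _, db, _ = worked_example
        assert predict_all(conn, db, table).empty

    def test_rejects_mixed_kind_connectome(self, table, worked_example, toy_edge_file):
        from synsign import load_connectome
        conn = load_connectome(toy_edge_file(["A,B,electrical,1"]))
        _, db, _ = worked_example
        with pytest.raises(ValueError, match="chemical_subnetwork"):
            predict_all(conn, db, table)

    @pytest.mark.parametrize("method", [METHOD_NT_R, METHOD_NT_ONLY, METHOD_R_ONLY])
    def test_matches_independent_oracle_on_synthetic_data(
            self, table, synthetic_dataset, method):
        _, (conn, db, _) = synthetic_dataset
        preds = predict_all(chemical_subnetwork(conn), db, table, method=method)
        for row in preds.itertuples(index=False):
            assert str(row.label) == oracle_label(row.pre, row.post, db, method), \
                f"{row.pre}->{row.post} under {method}"

    def test_label_partition_conservation(self, table, synthetic_dataset):
        _, (conn, db, _) = synthetic_dataset
        chem = chemical_subnetwork(conn)
        preds = predict_all(chem, db, table)
        assert len(preds) == len(chem.edges)
        assert preds["weight"].sum() == chem.total_synapses

    def test_no_nt_flavor_agrees_between_nt_r_and_nt_only(self, table, synthetic_dataset):
        _, (conn, db, _) = synthetic_dataset
        chem = chemical_subnetwork(conn)
        a = predict_all(chem, db, table, method="ntr")["label"]
        b = predict_all(chem, db, table, method="nt")["label"]
        assert ((a == PolarityLabel.UNPREDICTED_NO_NT)
                == (b == PolarityLabel.UNPREDICTED_NO_NT)).all()

    def test_missing_endpoints_fall_through_to_unpredicted(self, table, worked_example,
                                                           toy_edge_file):
        from synsign import load_connectome
        _, db, _ = worked_example
        conn = load_connectome(toy_edge_file(["GHOST,RIB,chemical,2"]))
        preds = predict_all(conn, db, table)
        assert preds["label"].iloc[0] == PolarityLabel.UNPREDICTED_NO_NT


class TestMonotonicity:
    def test_adding_post_classes_never_definite_nor_unpredicts(self):
        # growing the matched class set can only move a label toward complex
        import itertools
        classes = [ReceptorClass(l, c) for l in NTS for c in ("cation", "anion")]
        nts = frozenset({"acetylcholine", "glutamate"})
        for k in range(len(classes)):
            for sub in itertools.combinations(classes, k):
                base = label_nt_r(nts, frozenset(sub))
                for extra in classes:
                    grown = label_nt_r(nts, frozenset(sub) | {extra})
                    if base == PolarityLabel.COMPLEX:
                        assert grown == PolarityLabel.COMPLEX
                    if base.predicted:
                        assert grown.predicted


def test_method_aliases_resolve():
    assert resolve_method("NTR") == METHOD_NT_R
    assert resolve_method("nt-only") == METHOD_NT_ONLY
    with pytest.raises(ValueError, match="unknown prediction method"):
        resolve_method("ml")
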