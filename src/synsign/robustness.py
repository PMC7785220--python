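"""Perturbation robustness and consistency against reference polarity sets.

Two questions: (1) does the network's sign balance survive perturbations —
dropping weak (single-synapse) links, removing the pharyngeal nervous
system, ignoring synapse weights, excluding an expression source, or
swapping in an alternative reconstruction?  (2) do per-connection labels
agree with independent references — earlier computational sign assignments
or direct experimental measurements?

Reference label vocabulary: ``+`` maps to excitatory, ``-`` to inhibitory;
``complex`` agrees only with complex.  Connections unpredicted on either
side are dropped from comparison denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .balance import EIBalance, label_distribution
from .connectome import Connectome, chemical_subnetwork, filter_edges
from .expression import ExpressionDB
from .predict import METHOD_NT_R, PolarityLabel, predict_all
from .receptors import ReceptorClassTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationSpec:
    """A named, deterministic transformation of the analysis inputs.

    ``edge_filters`` is an ordered list of (filter name, params) applied to
    the connectome; ``connectome_override`` swaps in an alternative
    reconstruction; ``db_override`` swaps the expression database (e.g. one
    built without the RNA-seq source).
    """

    name: str
    edge_filters: tuple = ()
    connectome_override: Connectome | None = None
    db_override: ExpressionDB | None = None


def standard_perturbations() -> list[PerturbationSpec]:
    """The stock network variants: weak links dropped, pharynx dropped, unweighted."""
    return [
        PerturbationSpec("weak_links_deleted", edge_filters=(("min_weight", {"k": 2}),)),
        PerturbationSpec("pharyngeal_deleted", edge_filters=(("drop_pharyngeal", {}),)),
        PerturbationSpec("unweighted", edge_filters=(("unweight", {}),)),
    ]


def perturbation_suite(
    connectome: Connectome,
    db: ExpressionDB,
    table: ReceptorClassTable,
    specs: Sequence[PerturbationSpec] = (),
    *,
    method: str = METHOD_NT_R,
    level: str = "synapse",
) -> pd.DataFrame:
    """Predict under the baseline and every perturbation; tabulate balances.

    Returns one row per variant (baseline always first) with label counts,
    the E:I ratio and the predicted share, plus ``ratio_min``/``ratio_max``
    in ``DataFrame.attrs`` summarizing the spread over variants with a
    defined ratio.
    """
    rows = []
    for spec in [PerturbationSpec("baseline"), *specs]:
        conn = spec.connectome_override if spec.connectome_override is not None else connectome
        conn = chemical_subnetwork(conn)
        for fname, params in spec.edge_filters:
            conn = filter_edges(conn, fname, **params)
        variant_db = spec.db_override if spec.db_override is not None else db
        preds = predict_all(conn, variant_db, table, method=method)
        bal = label_distribution(preds, level=level)
        rows.append({
            "variant": spec.name, **bal.as_dict(),
            "predicted_share": bal.predicted_share,
            "n_connections": len(preds),
        })
    out = pd.DataFrame(rows)
    defined = out["ratio"].dropna()
    out.attrs["ratio_min"] = float(defined.min()) if len(defined) else None
    out.attrs["ratio_max"] = float(defined.max()) if len(defined) else None
    return out


# ---------------------------------------------------------------------------
# consistency against other prediction sets
# ---------------------------------------------------------------------------

_REFERENCE_VOCAB = {
    "+": "excitatory", "excitatory": "excitatory", "e": "excitatory",
    "-": "inhibitory", "−": "inhibitory", "inhibitory": "inhibitory", "i": "inhibitory",
    "complex": "complex", "c": "complex",
    "unknown": "unpredicted", "unpredicted": "unpredicted", "?": "unpredicted",
}


def _canonical_labels(table: pd.DataFrame) -> pd.Series:
    def canon(l) -> str:
        if isinstance(l, PolarityLabel):
            return l.headline
        tok = str(l).strip().lower()
        if tok in _REFERENCE_VOCAB:
            return _REFERENCE_VOCAB[tok]
        return PolarityLabel(tok).headline  # raises on garbage
    s = table.set_index(["pre", "post"])["label"].map(canon)
    if s.index.has_duplicates:
        raise ValueError("duplicate (pre, post) rows in comparison table")
    return s


@dataclass(frozen=True)
class ConsistencyReport:
    """Agreement between two per-connection label sets.

    Comparison runs over connections present in both tables with a definite
    (non-unpredicted) label on both sides; synapse-level counts weight each
    connection by its synapse number.
    """

    n_compared_connections: int
    n_same_connections: int
    n_compared_synapses: int
    n_same_synapses: int
    agreement: pd.DataFrame = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        assert self.n_same_connections <= self.n_compared_connections
        assert self.n_same_synapses <= self.n_compared_synapses

    @property
    def connection_agreement(self) -> float:
        return (self.n_same_connections / self.n_compared_connections
                if self.n_compared_connections else 0.0)

    @property
    def synapse_agreement(self) -> float:
        return (self.n_same_synapses / self.n_compared_synapses
                if self.n_compared_synapses else 0.0)


def compare_predictions(a: pd.DataFrame, b: pd.DataFrame) -> ConsistencyReport:
    """Score label agreement of two prediction/reference tables.

    Both tables need ``pre, post, label`` columns; ``weight`` (synapse
    count, taken from *a* then *b*) defaults to 1.  Reference vocabularies
    using ``+``/``-`` are normalized.  Raises when the tables share no
    comparably labeled connection.
    """
    la, lb = _canonical_labels(a), _canonical_labels(b)
    common = la.index.intersection(lb.index)
    la, lb = la.loc[common], lb.loc[common]
    definite = (la != "unpredicted") & (lb != "unpredicted")
    la, lb = la[definite], lb[definite]
    if la.empty:
        raise ValueError("no comparably labeled connections shared by the two tables")
    if "weight" in a.columns:
        weights = a.set_index(["pre", "post"])["weight"].reindex(la.index)
    elif "weight" in b.columns:
        weights = b.set_index(["pre", "post"])["weight"].reindex(la.index)
    else:
        weights = pd.Series(1, index=la.index)
    weights = weights.fillna(1).astype(int)
    same = la == lb
    agreement = pd.DataFrame({
        "pre": [p for p, _ in la.index], "post": [q for _, q in la.index],
        "label_a": la.to_numpy(), "label_b": lb.to_numpy(),
        "weight": weights.to_numpy(), "same": same.to_numpy(),
    })
    return ConsistencyReport(
        n_compared_connections=int(len(la)),
        n_same_connections=int(same.sum()),
        n_compared_synapses=int(weights.sum()),
        n_same_synapses=int(weights[same].sum()),
        agreement=agreement,
    )


def broadcast_group_reference(
    reference: pd.DataFrame, group_members: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Expand a group-level reference (rows: group pre/post) to neuron pairs.

    References built over neuron *groups* (e.g. a 7-group locomotion-circuit
    model) are broadcast to every ordered member pair before comparison.
    """
    rows = []
    for row in reference.itertuples(index=False):
        pres = group_members.get(row.pre, [row.pre])
        posts = group_members.get(row.post, [row.post])
        for p in pres:
            for q in posts:
                rows.append({"pre": str(p).upper(), "post": str(q).upper(), "label": row.label})
    return pd.DataFrame(rows).drop_duplicates(subset=["pre", "post"])


# ---------------------------------------------------------------------------
# experimental validation
# ---------------------------------------------------------------------------

VERDICTS = ("validated", "partially_validated", "opposed", "uncomparable")


def validate_against_experiments(
    predictions: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Per-connection verdicts against experimentally measured polarities.

    *reference* rows carry ``pre, post, polarity`` (and typically a
    ``source`` citation).  A connection is ``validated`` when prediction and
    reference polarity agree and both are definite excitatory/inhibitory;
    ``partially_validated`` when either side is complex or uncertain;
    ``opposed`` on a definite excitatory-vs-inhibitory contradiction;
    ``uncomparable`` when the prediction table lacks the connection.
    """
    pred = _canonical_labels(predictions)
    weights = (predictions.set_index(["pre", "post"])["weight"]
               if "weight" in predictions.columns else None)
    rows = []
    for row in reference.itertuples(index=False):
        key = (str(row.pre).strip().upper(), str(row.post).strip().upper())
        ref_label = _REFERENCE_VOCAB.get(str(row.polarity).strip().lower(), "unpredicted")
        rec = {"pre": key[0], "post": key[1], "reference": ref_label,
               "source": getattr(row, "source", "")}
        if key not in pred.index:
            rec.update(predicted="", verdict="uncomparable", weight=0)
        else:
            p = pred.loc[key]
            w = int(weights.loc[key]) if weights is not None else 1
            definite = {"excitatory", "inhibitory"}
            if p in definite and ref_label in definite:
                verdict = "validated" if p == ref_label else "opposed"
            else:
                verdict = "partially_validated"
            rec.update(predicted=p, verdict=verdict, weight=w)
        rows.append(rec)
    out = pd.DataFrame(rows, columns=["pre", "post", "reference", "predicted",
                                      "verdict", "weight", "source"])
    return out
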