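"""The three polarity rule engines: NT+R, NT-only and R-only.

Every chemical connection gets exactly one label per method:

* **NT+R** — the headline method.  Collect the channel types (cation/anion)
  of every postsynaptic receptor class whose ligand matches a transmitter
  the presynaptic neuron expresses.  Only cation -> excitatory, only anion
  -> inhibitory, both -> complex, none -> unpredicted.  A presynaptic
  neuron with no known transmitter is unpredicted for a different reason,
  and the two unpredicted flavours stay distinguishable.
* **NT-only** — the classical assumption: transmitter identity alone.
  Acetylcholine and/or glutamate -> excitatory, GABA -> inhibitory, an
  excitatory transmitter together with GABA -> complex.
* **R-only** — postsynaptic channel types alone, ligand ignored.

Edges whose endpoints are missing from the expression database are treated
as expressing nothing, so they fall through to an unpredicted label rather
than raising (such synapses stay in every denominator).
"""

from __future__ import annotations

import logging
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .connectome import CHEMICAL, Connectome
from .expression import ExpressionDB, neuron_nt_profile, neuron_receptor_classes
from .receptors import ReceptorClass, ReceptorClassTable

logger = logging.getLogger(__name__)


class PolarityLabel(str, Enum):
    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"
    COMPLEX = "complex"
    UNPREDICTED_NO_NT = "unpredicted_no_nt"
    UNPREDICTED_NO_MATCH = "unpredicted_no_match"

    @property
    def predicted(self) -> bool:
        return self in (self.EXCITATORY, self.INHIBITORY, self.COMPLEX)

    @property
    def headline(self) -> str:
        """Collapse the two unpredicted flavours for summary statistics."""
        return "unpredicted" if not self.predicted else self.value

    def __str__(self) -> str:
        return self.value


METHOD_NT_R = "NT+R"
METHOD_NT_ONLY = "NT-only"
METHOD_R_ONLY = "R-only"
METHODS = (METHOD_NT_R, METHOD_NT_ONLY, METHOD_R_ONLY)

_METHOD_ALIASES = {
    "nt+r": METHOD_NT_R, "ntr": METHOD_NT_R,
    "nt-only": METHOD_NT_ONLY, "nt": METHOD_NT_ONLY,
    "r-only": METHOD_R_ONLY, "r": METHOD_R_ONLY,
}


def resolve_method(method: str) -> str:
    m = _METHOD_ALIASES.get(method.strip().lower())
    if m is None:
        raise ValueError(f"unknown prediction method {method!r}; known: {METHODS}")
    return m


def matched_channel_types(
    pre_nts: Iterable[str], post_classes: Iterable[ReceptorClass]
) -> frozenset[str]:
    """Channel types of postsynaptic classes whose ligand the pre releases."""
    nts = set(pre_nts)
    return frozenset(c.channel for c in post_classes if c.ligand in nts)


def _label_from_channels(channels: frozenset[str], *, no_nt: bool) -> PolarityLabel:
    if no_nt:
        return PolarityLabel.UNPREDICTED_NO_NT
    if channels == {"cation"}:
        return PolarityLabel.EXCITATORY
    if channels == {"anion"}:
        return PolarityLabel.INHIBITORY
    if channels == {"cation", "anion"}:
        return PolarityLabel.COMPLEX
    return PolarityLabel.UNPREDICTED_NO_MATCH


def label_nt_r(
    pre_nts: frozenset[str], post_classes: frozenset[ReceptorClass]
) -> PolarityLabel:
    """NT+R rule on precomputed profiles."""
    if not pre_nts:
        return PolarityLabel.UNPREDICTED_NO_NT
    return _label_from_channels(matched_channel_types(pre_nts, post_classes), no_nt=False)


def label_nt_only(pre_nts: frozenset[str]) -> PolarityLabel:
    """NT-only rule: the presynaptic transmitter decides everything."""
    if not pre_nts:
        return PolarityLabel.UNPREDICTED_NO_NT
    excitatory = bool(pre_nts & {"acetylcholine", "glutamate"})
    inhibitory = "GABA" in pre_nts
    if excitatory and inhibitory:
        return PolarityLabel.COMPLEX
    return PolarityLabel.EXCITATORY if excitatory else PolarityLabel.INHIBITORY


def label_r_only(post_classes: frozenset[ReceptorClass]) -> PolarityLabel:
    """R-only rule: the postsynaptic channel types decide, ligand ignored."""
    channels = frozenset(c.channel for c in post_classes)
    return _label_from_channels(channels, no_nt=False)


def _profiles(neuron, db, table):
    if neuron in db:
        return neuron_nt_profile(neuron, db), neuron_receptor_classes(neuron, db, table)
    return frozenset(), frozenset()


def predict_nt_r(edge, db: ExpressionDB, table: ReceptorClassTable) -> PolarityLabel:
    """NT+R label for a single chemical edge (pre, post, ...)."""
    pre_nts, _ = _profiles(edge.pre, db, table)
    _, post_classes = _profiles(edge.post, db, table)
    return label_nt_r(pre_nts, post_classes)


def predict_nt_only(edge, db: ExpressionDB) -> PolarityLabel:
    pre_nts = neuron_nt_profile(edge.pre, db) if edge.pre in db else frozenset()
    return label_nt_only(pre_nts)


def predict_r_only(edge, db: ExpressionDB, table: ReceptorClassTable) -> PolarityLabel:
    _, post_classes = _profiles(edge.post, db, table)
    return label_r_only(post_classes)


PREDICTION_COLUMNS = ["pre", "post", "weight", "method", "label", "matched_classes", "pre_nts"]


def predict_all(
    connectome: Connectome,
    db: ExpressionDB,
    table: ReceptorClassTable,
    method: str = METHOD_NT_R,
) -> pd.DataFrame:
    """Label every chemical connection of *connectome* under one method.

    Returns a prediction table with one row per connection: ``pre, post,
    weight, method, label, matched_classes, pre_nts``.  ``matched_classes``
    lists the ligand-matched postsynaptic classes (NT+R) or the full
    postsynaptic class set (R-only); ``pre_nts`` the presynaptic
    transmitters.  Raises if non-chemical edges are present — call
    ``chemical_subnetwork`` first.
    """
    method = resolve_method(method)
    non_chem = connectome.edges["kind"] != CHEMICAL
    if non_chem.any():
        raise ValueError(
            f"{int(non_chem.sum())} non-chemical edges present; "
            "apply chemical_subnetwork() before predicting"
        )
    # precompute per-neuron profiles vectorized: expression lookups dominate
    # the per-edge cost on large networks
    involved = set(connectome.edges["pre"]) | set(connectome.edges["post"])
    known = [n for n in db.nt.index if n in involved]
    missing = involved - set(known)
    nt_mat = db.nt.loc[known].to_numpy(dtype=bool)
    nt_names = list(db.nt.columns)
    nt_map: dict[str, frozenset[str]] = {
        n: frozenset(t for t, b in zip(nt_names, row) if b)
        for n, row in zip(known, nt_mat)
    }
    class_list = sorted({c for c in table.entries.values()})
    gene_cols = {
        cls: [g for g in db.receptors.columns if table.entries.get(g) == cls]
        for cls in class_list
    }
    if known:
        rec = db.receptors.loc[known]
        indicator = np.column_stack([
            rec[cols].to_numpy(dtype=bool).any(axis=1) if cols
            else np.zeros(len(known), dtype=bool)
            for cls, cols in gene_cols.items()
        ]) if class_list else np.zeros((len(known), 0), dtype=bool)
    else:
        indicator = np.zeros((0, len(class_list)), dtype=bool)
    cls_map: dict[str, frozenset[ReceptorClass]] = {
        n: frozenset(c for c, b in zip(class_list, row) if b)
        for n, row in zip(known, indicator)
    }
    empty: frozenset = frozenset()

    rows = []
    for e in connectome.edges.itertuples(index=False):
        pre_nts = nt_map.get(e.pre, empty)
        post_classes = cls_map.get(e.post, empty)
        if method == METHOD_NT_R:
            label = label_nt_r(pre_nts, post_classes)
            matched = frozenset(c for c in post_classes if c.ligand in pre_nts)
        elif method == METHOD_NT_ONLY:
            label = label_nt_only(pre_nts)
            matched = frozenset()
        else:
            label = label_r_only(post_classes)
            matched = post_classes
        rows.append({
            "pre": e.pre, "post": e.post, "weight": int(e.weight),
            "method": method, "label": label,
            "matched_classes": matched, "pre_nts": pre_nts,
        })
    if missing:
        logger.warning(
            "%d edge endpoints missing from the expression DB (treated as "
            "expressing nothing): %s", len(missing), sorted(missing)[:10],
        )
    out = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    out.attrs["method"] = method
    return out


def prediction_table_to_tsv(predictions: pd.DataFrame, path) -> None:
    """Serialize a prediction table with set-valued columns flattened."""
    out = predictions.copy()
    out["label"] = out["label"].map(str)
    out["matched_classes"] = out["matched_classes"].map(
        lambda s: ";".join(sorted(f"{c.ligand}/{c.channel}" for c in s))
    )
    out["pre_nts"] = out["pre_nts"].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path, sep="\t", index=False)
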