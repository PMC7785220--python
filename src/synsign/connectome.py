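"""Directed weighted connectome reconstructions: parsing, filtering, export.

A connectome is a directed multigraph over named neurons.  Each edge is a
*connection* — an ordered (presynaptic, postsynaptic) neuron pair of a given
kind (chemical or electrical) — whose integer weight counts the anatomical
synapses it bundles.  Reciprocal connections are distinct edges.  Duplicate
rows for the same (pre, post, kind) triple are summed on load.

Edge tables are plain pandas DataFrames with columns
``pre, post, kind, weight``; neuron metadata (modality, pharyngeal flag,
anatomical group) rides along in a separate DataFrame indexed by neuron.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, NamedTuple

import networkx as nx
import pandas as pd

from .expression import normalize_neuron
from .receptors import pharyngeal_neurons

logger = logging.getLogger(__name__)

CHEMICAL = "chemical"
ELECTRICAL = "electrical"

_KIND_ALIASES = {
    "chemical": CHEMICAL, "c": CHEMICAL, "chem": CHEMICAL, "send": CHEMICAL,
    "electrical": ELECTRICAL, "e": ELECTRICAL, "gap": ELECTRICAL,
    "gapjunction": ELECTRICAL, "gap_junction": ELECTRICAL, "gj": ELECTRICAL,
}

EDGE_COLUMNS = ["pre", "post", "kind", "weight"]


class SynapseEdge(NamedTuple):
    pre: str
    post: str
    kind: str
    weight: int


@dataclass
class Connectome:
    """Aggregated directed connectome plus neuron metadata.

    ``edges`` holds at most one row per ordered (pre, post, kind) triple.
    ``metadata`` is indexed by neuron with (at least) columns ``modality``
    and ``pharyngeal`` where available; neurons appearing only in edges are
    still part of :attr:`neurons`.
    """

    edges: pd.DataFrame
    metadata: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["modality", "pharyngeal"])
    )
    filters_applied: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.edges = self.edges.reindex(columns=EDGE_COLUMNS).reset_index(drop=True)

    @property
    def neurons(self) -> list[str]:
        names = set(self.edges["pre"]) | set(self.edges["post"]) | set(self.metadata.index)
        return sorted(names)

    @property
    def total_synapses(self) -> int:
        return int(self.edges["weight"].sum())

    @property
    def n_connections(self) -> int:
        return len(self.edges)

    def connected_neurons(self, kind: str | None = None) -> set[str]:
        e = self.edges if kind is None else self.edges[self.edges["kind"] == kind]
        return set(e["pre"]) | set(e["post"])

    def isolated_neurons(self, kind: str | None = None) -> set[str]:
        """Metadata neurons touching no edge (of *kind*, when given)."""
        return set(self.metadata.index) - self.connected_neurons(kind)

    def iter_edges(self) -> Iterable[SynapseEdge]:
        for row in self.edges.itertuples(index=False):
            yield SynapseEdge(row.pre, row.post, row.kind, int(row.weight))


def _aggregate(edges: pd.DataFrame, warn: bool = True) -> pd.DataFrame:
    dup = edges.duplicated(subset=["pre", "post", "kind"], keep=False)
    if dup.any() and warn:
        pairs = edges.loc[dup, ["pre", "post"]].drop_duplicates()
        logger.warning("summed %d duplicate (pre, post, kind) rows", int(dup.sum()))
    out = (
        edges.groupby(["pre", "post", "kind"], as_index=False, sort=True)["weight"]
        .sum()
    )
    return out[EDGE_COLUMNS]


def load_connectome(
    path: str | Path,
    *,
    dialect: str = "generic",
    metadata: pd.DataFrame | None = None,
    omit_isolated: bool = False,
) -> Connectome:
    """Load an edge list (CSV/TSV/XLSX) into an aggregated :class:`Connectome`.

    The generic dialect expects columns ``pre, post, kind, weight`` (header
    required for CSV/TSV; synonyms like ``send``/``gj`` are accepted for the
    kind).  Neuron names are canonicalized to upper-case.  Duplicate rows
    are summed with a warning; non-integer weights and unknown kind tokens
    raise with the offending line number.

    ``omit_isolated`` drops metadata-only neurons that touch no edge at all
    (the canal-associated pair CANL/CANR is isolated in the reference
    reconstruction and typically omitted).
    """
    if dialect not in ("generic", "wormwiring"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        raw = pd.read_csv(path, sep=sep)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    required = {"pre", "post", "kind", "weight"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    kinds = []
    for i, tok in enumerate(raw["kind"]):
        k = _KIND_ALIASES.get(str(tok).strip().lower())
        if k is None:
            raise ValueError(f"{path}: line {i + 2}: unknown kind token {tok!r}")
        kinds.append(k)
    weights = []
    for i, w in enumerate(raw["weight"]):
        try:
            wf = float(w)
        except (TypeError, ValueError):
            raise ValueError(f"{path}: line {i + 2}: non-numeric weight {w!r}") from None
        if wf != int(wf):
            raise ValueError(f"{path}: line {i + 2}: non-integer weight {w!r}")
        if wf < 1:
            raise ValueError(f"{path}: line {i + 2}: weight must be >= 1, got {w!r}")
        weights.append(int(wf))

    edges = pd.DataFrame({
        "pre": [normalize_neuron(str(n)) for n in raw["pre"]],
        "post": [normalize_neuron(str(n)) for n in raw["post"]],
        "kind": kinds,
        "weight": weights,
    })
    edges = _aggregate(edges)
    if metadata is None:
        metadata = pd.DataFrame(columns=["modality", "pharyngeal"])
    else:
        metadata = metadata.copy()
        metadata.index = [normalize_neuron(str(n)) for n in metadata.index]
    conn = Connectome(edges=edges, metadata=metadata)
    if omit_isolated:
        isolated = conn.isolated_neurons()
        if isolated:
            logger.info("omitting %d isolated neurons: %s", len(isolated), sorted(isolated))
            conn = replace(conn, metadata=metadata.drop(index=sorted(isolated)))
    lonely = conn.isolated_neurons()
    if lonely:
        logger.info("isolated neurons retained: %s", sorted(lonely))
    return conn


def chemical_subnetwork(connectome: Connectome) -> Connectome:
    """Restrict to chemical edges (the sign-predictable subset)."""
    edges = connectome.edges[connectome.edges["kind"] == CHEMICAL].reset_index(drop=True)
    return replace(connectome, edges=edges,
                   filters_applied=connectome.filters_applied + ("chemical_subnetwork",))


FILTERS = ("min_weight", "drop_pharyngeal", "unweight", "drop_neurons")


def filter_edges(connectome: Connectome, name: str, **params) -> Connectome:
    """Apply a named edge filter; the composition order is recorded.

    * ``min_weight`` (k): drop edges with weight < k
    * ``drop_pharyngeal``: drop edges touching any pharyngeal neuron (the
      packaged 20-neuron roster, or metadata ``pharyngeal`` flags, or an
      explicit ``neurons=`` set)
    * ``unweight``: set every weight to 1
    * ``drop_neurons`` (neurons): drop edges touching the listed neurons
    """
    edges = connectome.edges
    if name == "min_weight":
        k = int(params["k"])
        edges = edges[edges["weight"] >= k]
        tag = f"min_weight({k})"
    elif name == "drop_pharyngeal":
        roster = params.get("neurons")
        if roster is None:
            if "pharyngeal" in connectome.metadata.columns and connectome.metadata["pharyngeal"].any():
                roster = set(connectome.metadata.index[connectome.metadata["pharyngeal"].astype(bool)])
            else:
                roster = pharyngeal_neurons()
        roster = {normalize_neuron(n) for n in roster}
        edges = edges[~(edges["pre"].isin(roster) | edges["post"].isin(roster))]
        tag = "drop_pharyngeal"
    elif name == "unweight":
        edges = edges.assign(weight=1)
        tag = "unweight"
    elif name == "drop_neurons":
        roster = {normalize_neuron(n) for n in params["neurons"]}
        edges = edges[~(edges["pre"].isin(roster) | edges["post"].isin(roster))]
        tag = f"drop_neurons({len(roster)})"
    else:
        raise ValueError(f"unknown filter {name!r}; known: {FILTERS}")
    return replace(connectome, edges=edges.reset_index(drop=True),
                   filters_applied=connectome.filters_applied + (tag,))


# ---------------------------------------------------------------------------
# signed-network export
# ---------------------------------------------------------------------------

SIGNED_TSV_COLUMNS = ["pre", "post", "weight", "label"]


def export_signed_network(
    connectome: Connectome,
    predictions: pd.DataFrame,
    path: str | Path,
    fmt: str = "tsv",
) -> Path:
    """Write the chemical network with per-edge polarity labels.

    *predictions* must cover every chemical edge (columns ``pre, post,
    label``).  ``fmt='tsv'`` writes a stable, documented four-column edge
    list; ``fmt='graphml'`` writes GraphML with modality/pharyngeal node
    attributes and weight/polarity edge attributes.
    """
    path = Path(path)
    chem = connectome.edges[connectome.edges["kind"] == CHEMICAL]
    labels = predictions.set_index(["pre", "post"])["label"]
    if labels.index.has_duplicates:
        raise ValueError("predictions contain duplicate (pre, post) rows")
    key = pd.MultiIndex.from_frame(chem[["pre", "post"]])
    missing = key[~key.isin(labels.index)]
    if len(missing):
        raise ValueError(
            f"{len(missing)} chemical edges lack polarity labels, e.g. {list(missing[:5])}"
        )
    out = chem[["pre", "post", "weight"]].copy()
    out["label"] = [str(labels.loc[(p, q)]) for p, q in zip(out["pre"], out["post"])]
    out = out.sort_values(["pre", "post"]).reset_index(drop=True)

    if fmt == "tsv":
        out.to_csv(path, sep="\t", index=False, columns=SIGNED_TSV_COLUMNS)
    elif fmt == "graphml":
        g = nx.DiGraph()
        meta = connectome.metadata
        for n in sorted(set(out["pre"]) | set(out["post"])):
            attrs = {}
            if n in meta.index:
                for col in meta.columns:
                    val = meta.at[n, col]
                    if pd.notna(val):
                        attrs[col] = str(val)
            g.add_node(n, **attrs)
        for row in out.itertuples(index=False):
            g.add_edge(row.pre, row.post, weight=int(row.weight), polarity=row.label)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def load_signed_network(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    """Read back a signed edge list written by :func:`export_signed_network`."""
    path = Path(path)
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        rows = [
            {"pre": u, "post": v, "weight": int(d["weight"]), "label": d["polarity"]}
            for u, v, d in g.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=SIGNED_TSV_COLUMNS).sort_values(
            ["pre", "post"]
        ).reset_index(drop=True)
    raise ValueError(f"unknown format {fmt!r}")
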