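"""Synthetic connectome + expression datasets with known statistics.

The generator draws, independently per neuron, a transmitter category and a
set of functional receptor classes, and, independently per ordered neuron
pair, a directed chemical connection with an integer synapse count.  The
defaults mimic the empirical shape of the worm data this package analyses:
roughly 300 neurons of which ~85% express exactly one of the three fast
transmitters, ~4% two and ~11% none; receptor classes common enough that
about half the neurons express both cation- and anion-channel genes; a mean
out-degree near 12 with geometric synapse counts averaging ~5.7.

Because transmitter and receptor indicators are independent, the NT+R label
probability of a random edge has a closed form
(:func:`expected_label_probabilities`, exact enumeration over transmitter
categories x the 64 receptor-class subsets), which parameter-recovery tests
compare against Monte-Carlo runs of the full pipeline.

Receptor classes are realized as one canonical gene per class (glr-1,
acr-16, exp-1, glc-3, acc-1, unc-49) so synthetic data exercises the real
gene-to-class machinery rather than bypassing it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .connectome import CHEMICAL, Connectome
from .expression import ExpressionDB, NT_COLUMNS
from .predict import PolarityLabel, label_nt_r
from .receptors import ALL_CLASSES, ReceptorClass

#: canonical representative gene per functional class
CLASS_GENES: dict[ReceptorClass, str] = {
    ReceptorClass("glutamate", "cation"): "glr-1",
    ReceptorClass("acetylcholine", "cation"): "acr-16",
    ReceptorClass("GABA", "cation"): "exp-1",
    ReceptorClass("glutamate", "anion"): "glc-3",
    ReceptorClass("acetylcholine", "anion"): "acc-1",
    ReceptorClass("GABA", "anion"): "unc-49",
}

NT_CATEGORIES = ("glutamate", "acetylcholine", "GABA", "double", "none")

#: which transmitter pair a "double" neuron carries, and with what probability
DEFAULT_DOUBLE_COMPOSITION: dict[frozenset, float] = {
    frozenset({"acetylcholine", "glutamate"}): 0.5,
    frozenset({"glutamate", "GABA"}): 0.25,
    frozenset({"acetylcholine", "GABA"}): 0.25,
}


def _default_nt_probs() -> dict[str, float]:
    # ~256/302 single (split ACh-heavy as in the worm), 12/302 double, 34/302 none
    single = 256 / 302
    return {
        "acetylcholine": single * 0.60,
        "glutamate": single * 0.30,
        "GABA": single * 0.10,
        "double": 12 / 302,
        "none": 34 / 302,
    }


def _default_class_probs() -> dict[ReceptorClass, float]:
    return {
        ReceptorClass("glutamate", "cation"): 0.45,
        ReceptorClass("acetylcholine", "cation"): 0.55,
        ReceptorClass("GABA", "cation"): 0.15,
        ReceptorClass("glutamate", "anion"): 0.25,
        ReceptorClass("acetylcholine", "anion"): 0.20,
        ReceptorClass("GABA", "anion"): 0.35,
    }


def _default_modality_probs() -> dict[str, float]:
    return {"sensory": 0.30, "inter": 0.27, "motor": 0.38, "polymodal": 0.05}


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic dataset generator.

    ``edge_density`` is the expected out-degree; ``weight_law`` names the
    synapse-count distribution (``geometric`` with success probability
    ``p``, or ``constant`` with ``value``).
    """

    n_neurons: int = 300
    nt_probs: Mapping[str, float] = field(default_factory=_default_nt_probs)
    class_probs: Mapping[ReceptorClass, float] = field(default_factory=_default_class_probs)
    double_composition: Mapping[frozenset, float] = field(
        default_factory=lambda: dict(DEFAULT_DOUBLE_COMPOSITION))
    edge_density: float = 12.0
    weight_law: Mapping[str, float | str] = field(
        default_factory=lambda: {"name": "geometric", "p": 0.177})
    modality_probs: Mapping[str, float] = field(default_factory=_default_modality_probs)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in (("nt_probs", self.nt_probs),
                            ("double_composition", self.double_composition),
                            ("modality_probs", self.modality_probs)):
            vec = np.array(list(probs.values()), dtype=float)
            if (vec < 0).any() or (vec > 1).any():
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if not np.isclose(vec.sum(), 1.0):
                raise ValueError(f"{name} must sum to 1, got {vec.sum():.4f}")
        if set(self.nt_probs) != set(NT_CATEGORIES):
            raise ValueError(f"nt_probs must cover exactly {NT_CATEGORIES}")
        cvec = np.array([self.class_probs[c] for c in ALL_CLASSES], dtype=float)
        if (cvec < 0).any() or (cvec > 1).any():
            raise ValueError("class_probs entries must lie in [0, 1]")
        if self.n_neurons < 2:
            raise ValueError("need at least 2 neurons")
        if self.edge_density <= 0:
            raise ValueError("edge_density must be positive")


def _draw_weights(rng: np.random.Generator, n: int, law: Mapping) -> np.ndarray:
    name = law["name"]
    if name == "geometric":
        return rng.geometric(float(law["p"]), size=n)
    if name == "constant":
        return np.full(n, int(law["value"]))
    raise ValueError(f"unknown weight law {name!r}")


def _draw_expression(
    params: SynthParams, rng: np.random.Generator, neurons: list[str]
) -> ExpressionDB:
    n = len(neurons)
    cats = list(params.nt_probs)
    cat_draw = rng.choice(len(cats), size=n, p=[params.nt_probs[c] for c in cats])
    combos = list(params.double_composition)
    combo_p = [params.double_composition[c] for c in combos]
    nt = pd.DataFrame(0, index=neurons, columns=NT_COLUMNS, dtype=np.int8)
    for i, ci in enumerate(cat_draw):
        cat = cats[ci]
        if cat == "none":
            continue
        if cat == "double":
            pair = combos[rng.choice(len(combos), p=combo_p)]
            for t in pair:
                nt.iat[i, NT_COLUMNS.index(t)] = 1
        else:
            nt.iat[i, NT_COLUMNS.index(cat)] = 1

    genes = [CLASS_GENES[c] for c in ALL_CLASSES]
    pvec = np.array([params.class_probs[c] for c in ALL_CLASSES])
    receptors = pd.DataFrame(
        (rng.random((n, len(genes))) < pvec).astype(np.int8),
        index=neurons, columns=genes,
    )
    return ExpressionDB(nt=nt, receptors=receptors)


def _draw_metadata(
    params: SynthParams, rng: np.random.Generator, neurons: list[str]
) -> pd.DataFrame:
    mods = list(params.modality_probs)
    mod_draw = rng.choice(len(mods), size=len(neurons),
                          p=[params.modality_probs[m] for m in mods])
    metadata = pd.DataFrame({
        "modality": [mods[i] for i in mod_draw],
        "pharyngeal": False,
    }, index=pd.Index(neurons, name="neuron"))
    metadata.attrs["synth_params"] = params
    return metadata


def generate_synthetic_dataset(
    params: SynthParams, seed: int | None = None
) -> tuple[Connectome, ExpressionDB, pd.DataFrame]:
    """Draw a (connectome, expression DB, neuron metadata) triple.

    Deterministic for a fixed seed (``seed`` overrides ``params.seed``).
    Neuron transmitter sets, receptor-class indicators, directed
    Erdos-Renyi edges (no self-connections) and integer weights are drawn
    independently as specified; the metadata frame records modality, a
    pharyngeal flag (always False for synthetic neurons) and the generator
    parameters in ``DataFrame.attrs``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_neurons
    neurons = [f"SYN{i:04d}" for i in range(n)]
    db = _draw_expression(params, rng, neurons)

    p_edge = min(1.0, params.edge_density / (n - 1))
    mask = rng.random((n, n)) < p_edge
    np.fill_diagonal(mask, False)
    pre_idx, post_idx = np.nonzero(mask)
    weights = _draw_weights(rng, len(pre_idx), params.weight_law)
    edges = pd.DataFrame({
        "pre": [neurons[i] for i in pre_idx],
        "post": [neurons[j] for j in post_idx],
        "kind": CHEMICAL,
        "weight": weights.astype(int),
    })

    metadata = _draw_metadata(params, rng, neurons)
    return Connectome(edges=edges, metadata=metadata), db, metadata


def sample_independent_edges(
    params: SynthParams, n_edges: int, seed: int | None = None
) -> tuple[Connectome, ExpressionDB]:
    """Draw *n_edges* chemical edges with mutually independent endpoints.

    Each edge gets its own freshly drawn presynaptic and postsynaptic
    neuron (2 * n_edges neurons in total), so edge labels are i.i.d. and
    binomial standard errors apply exactly — the sampling regime
    :func:`expected_label_probabilities` is validated against.  An
    Erdos-Renyi draw would not do: there, edges share neurons and their
    labels are correlated through the shared expression profiles.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    neurons = [f"SYN{i:06d}" for i in range(2 * n_edges)]
    db = _draw_expression(params, rng, neurons)
    weights = _draw_weights(rng, n_edges, params.weight_law)
    edges = pd.DataFrame({
        "pre": neurons[:n_edges],
        "post": neurons[n_edges:],
        "kind": CHEMICAL,
        "weight": weights.astype(int),
    })
    return Connectome(edges=edges, metadata=_draw_metadata(params, rng, neurons)), db


def expected_label_probabilities(params: SynthParams) -> dict[PolarityLabel, float]:
    """Exact NT+R label distribution of a random generated edge.

    Enumerates every presynaptic transmitter set (weighted by its category
    probability) against all 2^6 postsynaptic receptor-class subsets
    (product of independent per-class probabilities) and applies the NT+R
    rule to each combination.  Valid because the generator draws the pre
    and post profiles of an edge independently.
    """
    nt_sets: list[tuple[frozenset[str], float]] = [
        (frozenset(), params.nt_probs["none"]),
        (frozenset({"glutamate"}), params.nt_probs["glutamate"]),
        (frozenset({"acetylcholine"}), params.nt_probs["acetylcholine"]),
        (frozenset({"GABA"}), params.nt_probs["GABA"]),
    ]
    for pair, w in params.double_composition.items():
        nt_sets.append((frozenset(pair), params.nt_probs["double"] * w))

    class_subsets: list[tuple[frozenset[ReceptorClass], float]] = []
    probs = [params.class_probs[c] for c in ALL_CLASSES]
    for bits in itertools.product((0, 1), repeat=len(ALL_CLASSES)):
        p = 1.0
        members = []
        for c, b, pc in zip(ALL_CLASSES, bits, probs):
            p *= pc if b else (1.0 - pc)
            if b:
                members.append(c)
        if p > 0.0:
            class_subsets.append((frozenset(members), p))

    out = {label: 0.0 for label in PolarityLabel}
    for nts, p_nt in nt_sets:
        if p_nt == 0.0:
            continue
        for classes, p_cls in class_subsets:
            out[label_nt_r(nts, classes)] += p_nt * p_cls
    return out


def make_worked_example_fixture() -> tuple[Connectome, ExpressionDB, pd.DataFrame]:
    """The three-neuron acetylcholine worked example.

    The cholinergic interneuron AIY synapses onto RIB, which expresses only
    an acetylcholine-gated cation channel (acr-16), and onto AIZ, which
    expresses only an acetylcholine-gated anion channel (acc-1) — the same
    transmitter thus excites one target and inhibits the other.  The
    fixture is fully deterministic.
    """
    neurons = ["AIY", "RIB", "AIZ"]
    nt = pd.DataFrame(0, index=neurons, columns=NT_COLUMNS, dtype=np.int8)
    nt.at["AIY", "acetylcholine"] = 1
    receptors = pd.DataFrame(0, index=neurons, columns=["acr-16", "acc-1"], dtype=np.int8)
    receptors.at["RIB", "acr-16"] = 1
    receptors.at["AIZ", "acc-1"] = 1
    db = ExpressionDB(nt=nt, receptors=receptors)
    edges = pd.DataFrame({
        "pre": ["AIY", "AIY"], "post": ["RIB", "AIZ"],
        "kind": CHEMICAL, "weight": [1, 1],
    })
    metadata = pd.DataFrame(
        {"modality": "inter", "pharyngeal": False},
        index=pd.Index(neurons, name="neuron"),
    )
    return Connectome(edges=edges, metadata=metadata), db, metadata
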