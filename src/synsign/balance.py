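"""Sign-balance statistics over prediction tables.

The central quantity is the excitatory:inhibitory (E:I) ratio — the
quotient of excitatory over inhibitory counts, computed at the *synapse*
level (counts weighted by synapse number) or the *connection* level (each
ordered neuron pair counts once).  Complex and unpredicted connections are
excluded from the quotient but always reported alongside it; when the
inhibitory count is zero the ratio is undefined (``None``), never an
infinity smuggled into arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

import pandas as pd

from .predict import PolarityLabel

LEVELS = ("synapse", "connection")

MODALITIES = ("sensory", "inter", "motor", "polymodal")


@dataclass(frozen=True)
class EIBalance:
    """Label counts at one level plus the derived E:I ratio."""

    excitatory: int
    inhibitory: int
    complex: int
    unpredicted: int
    level: str = "synapse"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        for name in ("excitatory", "inhibitory", "complex", "unpredicted"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be non-negative")

    @property
    def total(self) -> int:
        return self.excitatory + self.inhibitory + self.complex + self.unpredicted

    @property
    def predicted(self) -> int:
        return self.excitatory + self.inhibitory + self.complex

    @property
    def predicted_share(self) -> float:
        """Fraction of all items (including unpredicted) with a definite label."""
        return self.predicted / self.total if self.total else 0.0

    @property
    def ratio(self) -> float | None:
        """E:I quotient; ``None`` (undefined) when the inhibitory count is 0."""
        if self.inhibitory == 0:
            return None
        return self.excitatory / self.inhibitory

    def as_dict(self) -> dict:
        return {
            "excitatory": self.excitatory, "inhibitory": self.inhibitory,
            "complex": self.complex, "unpredicted": self.unpredicted,
            "level": self.level, "ratio": self.ratio,
        }


def ei_ratio(balance: EIBalance) -> float | None:
    """E:I ratio of a balance (``None`` when undefined)."""
    return balance.ratio


def nearest_simple_ratio(x: float, max_denominator: int = 10) -> str:
    """Display rendering of a ratio as the nearest small fraction, e.g. ``4:1``.

    Used only for presentation; statistics always carry the decimal.
    """
    frac = Fraction(x).limit_denominator(max_denominator)
    exact = abs(float(frac) - x) < 1e-9
    tag = "" if exact else " (approx.)"
    return f"{frac.numerator}:{frac.denominator}{tag}"


def _check_single_method(predictions: pd.DataFrame) -> str:
    methods = predictions["method"].unique()
    if len(methods) > 1:
        raise ValueError(f"prediction table mixes methods {sorted(methods)}")
    return methods[0] if len(methods) else ""


def _tally(predictions: pd.DataFrame, level: str) -> dict[str, int]:
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    counts = {"excitatory": 0, "inhibitory": 0, "complex": 0, "unpredicted": 0}
    if predictions.empty:
        return counts
    w = predictions["weight"] if level == "synapse" else pd.Series(1, index=predictions.index)
    headline = predictions["label"].map(lambda l: PolarityLabel(l).headline)
    for lab, total in w.groupby(headline.to_numpy()).sum().items():
        counts[str(lab)] = int(total)
    return counts


def label_distribution(predictions: pd.DataFrame, level: str = "synapse") -> EIBalance:
    """Label counts of a single-method prediction table at the given level.

    Shares are normalized over *all* connections, unpredicted included, so
    ``predicted_share`` is the fraction of the network the method labels.
    """
    _check_single_method(predictions)
    return EIBalance(level=level, **_tally(predictions, level))


def breakdown_by_presynaptic_nt(
    predictions: pd.DataFrame, level: str = "synapse"
) -> pd.DataFrame:
    """Label distribution per presynaptic transmitter.

    A connection contributes to the row of every transmitter its
    presynaptic neuron expresses, so connections from double-transmitter
    neurons are counted once per transmitter (rows are therefore not a
    partition of the network; a ``multi_counted`` column flags the overlap).
    """
    _check_single_method(predictions)
    rows = {}
    for nt in ("glutamate", "acetylcholine", "GABA"):
        mask = predictions["pre_nts"].map(lambda s: nt in s)
        sub = predictions[mask]
        counts = _tally(sub, level)
        multi = sub["pre_nts"].map(lambda s: len(s) > 1)
        weight = sub["weight"] if level == "synapse" else 1
        counts["multi_counted"] = int((multi * weight).sum()) if len(sub) else 0
        rows[nt] = counts
    out = pd.DataFrame(rows).T
    out.index.name = "presynaptic_nt"
    totals = out[["excitatory", "inhibitory", "complex", "unpredicted"]].sum(axis=1)
    for lab in ("excitatory", "inhibitory", "complex", "unpredicted"):
        out[f"share_{lab}"] = (out[lab] / totals.replace(0, float("nan"))).astype(float)
    return out


def modality_group_balance(
    predictions: pd.DataFrame,
    metadata: pd.DataFrame,
    level: str = "synapse",
) -> dict[tuple[str, str], EIBalance]:
    """E:I balance per ordered (source modality, target modality) pair.

    Every neuron appearing in the prediction table must carry a modality in
    *metadata* (column ``modality``; polymodal is its own category).  Cell
    counts over all ordered pairs sum to the network totals.
    """
    _check_single_method(predictions)
    if "modality" not in metadata.columns:
        raise ValueError("metadata must have a 'modality' column")
    modality = metadata["modality"]
    involved = sorted(set(predictions["pre"]) | set(predictions["post"]))
    missing = [n for n in involved if n not in modality.index or pd.isna(modality.get(n))]
    if missing:
        raise ValueError(f"neurons lacking a modality: {missing}")
    cells: dict[tuple[str, str], EIBalance] = {}
    src = predictions["pre"].map(modality)
    tgt = predictions["post"].map(modality)
    for (s, t), sub in predictions.groupby([src.to_numpy(), tgt.to_numpy()]):
        cells[(str(s), str(t))] = EIBalance(level=level, **_tally(sub, level))
    return cells


def group_balance_frame(cells: Mapping[tuple[str, str], EIBalance]) -> pd.DataFrame:
    """Tabular rendering of a modality-pair balance map with direction calls."""
    rows = []
    for (s, t), bal in sorted(cells.items()):
        ratio = bal.ratio
        direction = (
            "undefined" if ratio is None
            else "excitatory_excess" if ratio > 1
            else "inhibitory_excess" if ratio < 1
            else "balanced"
        )
        rows.append({
            "source": s, "target": t, **{k: v for k, v in bal.as_dict().items() if k != "level"},
            "direction": direction,
        })
    return pd.DataFrame(rows)


def subnetwork_extract(predictions: pd.DataFrame, neuron_list: Iterable[str]) -> pd.DataFrame:
    """Rows whose pre *and* post both belong to *neuron_list*.

    An empty result is legal (logged by callers as a warning, not an error):
    circuit rosters routinely miss a network's neurons entirely.
    """
    roster = {str(n).strip().upper() for n in neuron_list}
    mask = predictions["pre"].isin(roster) & predictions["post"].isin(roster)
    out = predictions[mask].reset_index(drop=True)
    out.attrs.update(predictions.attrs)
    return out
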