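"""Functional classification of ionotropic neurotransmitter receptor genes.

The worm genome carries 62 ionotropic postsynaptic receptor genes for the
three fast neurotransmitters glutamate, acetylcholine and GABA.  Each gene is
assigned to one of six functional classes, the cross product of its ligand
and the ion selectivity of the channel it encodes:

* cation channels depolarize the postsynaptic neuron (excitatory effect);
* anion channels hyperpolarize it (inhibitory effect).

Glutamate- and acetylcholine-gated *anion* channels and GABA-gated *cation*
channels mediate "unconventional" signaling: an effect with the opposite
sign to the transmitter's textbook one.  Two acetylcholine-gated chloride
channel genes (``acc-4`` and ``lgc-46``) are believed to act presynaptically
and are therefore carried in the table but never matched to a postsynaptic
neuron.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

LIGANDS = ("glutamate", "acetylcholine", "GABA")
CHANNELS = ("cation", "anion")

#: ligand aliases accepted in input files (normalized on load)
_LIGAND_ALIASES = {
    "glutamate": "glutamate", "glu": "glutamate",
    "acetylcholine": "acetylcholine", "ach": "acetylcholine",
    "gaba": "GABA",
}
_CHANNEL_ALIASES = {
    "cation": "cation", "+": "cation",
    "anion": "anion", "-": "anion", "−": "anion",
}


class ReceptorClass(NamedTuple):
    """One of the six (ligand, channel) functional receptor classes."""

    ligand: str
    channel: str

    @property
    def conventional(self) -> bool:
        """True when the channel sign matches the transmitter's classical one.

        Glutamate and acetylcholine are classically excitatory (cation),
        GABA classically inhibitory (anion).
        """
        if self.ligand == "GABA":
            return self.channel == "anion"
        return self.channel == "cation"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.ligand}/{self.channel}"


#: all six classes in a stable order (cation classes first)
ALL_CLASSES: tuple[ReceptorClass, ...] = tuple(
    ReceptorClass(ligand, channel) for channel in CHANNELS for ligand in LIGANDS
)


class UnknownGeneError(KeyError):
    """Raised when a gene is absent from the classification table."""


class ExcludedGeneError(ValueError):
    """Raised when a presynaptically expressed gene is used postsynaptically."""


def normalize_gene(name: str) -> str:
    """Canonical gene spelling: lower-case, hyphenated (``glr-1``)."""
    return name.strip().lower().replace("_", "-")


@dataclass(frozen=True)
class ReceptorClassTable:
    """Gene -> functional class mapping plus the presynaptic exclusion set.

    ``entries`` holds only matchable (postsynaptic) genes; ``excluded_genes``
    lists genes known to the table but barred from matching, with their
    nominal class kept in ``excluded_classes`` for reporting.
    """

    entries: Mapping[str, ReceptorClass]
    excluded_genes: frozenset[str] = frozenset()
    excluded_classes: Mapping[str, ReceptorClass] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return normalize_gene(gene) in self.entries

    def classify(self, gene: str) -> ReceptorClass:
        """Return the unique (ligand, channel) class of *gene*.

        Raises :class:`ExcludedGeneError` for presynaptic genes and
        :class:`UnknownGeneError` for genes not in the table.
        """
        g = normalize_gene(gene)
        if g in self.excluded_genes:
            raise ExcludedGeneError(
                f"gene {g!r} is excluded from postsynaptic matching "
                "(suggested presynaptic expression)"
            )
        try:
            return self.entries[g]
        except KeyError:
            raise UnknownGeneError(f"gene {g!r} not in receptor class table") from None

    def genes_in_class(self, cls: ReceptorClass) -> tuple[str, ...]:
        return tuple(g for g, c in self.entries.items() if c == cls)

    def class_sizes(self) -> dict[ReceptorClass, int]:
        """Number of matchable genes per functional class."""
        sizes = {cls: 0 for cls in ALL_CLASSES}
        for cls in self.entries.values():
            sizes[cls] += 1
        return sizes

    def unconventional_genes(self) -> tuple[str, ...]:
        """Genes encoding sign-inverting channels (Glu/ACh anion, GABA cation)."""
        return tuple(g for g, c in self.entries.items() if not c.conventional)


def load_receptor_class_table(path: str | Path) -> ReceptorClassTable:
    """Read a receptor classification table from CSV.

    Expected header: ``gene,ligand,channel,excluded`` where ``excluded`` is
    0/1.  Ligand and channel tokens are case-insensitive; ``+``/``-`` are
    accepted for the channel.  Duplicate genes and unknown tokens are
    reported with the offending gene / line number.
    """
    entries: dict[str, ReceptorClass] = {}
    excluded: set[str] = set()
    excluded_classes: dict[str, ReceptorClass] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return ReceptorClassTable(entries={})
        for lineno, row in enumerate(reader, start=2):
            gene = normalize_gene(row["gene"])
            ligand = _LIGAND_ALIASES.get(row["ligand"].strip().lower())
            channel = _CHANNEL_ALIASES.get(row["channel"].strip().lower())
            if ligand is None:
                raise ValueError(
                    f"{path}:{lineno}: unknown ligand token {row['ligand']!r}"
                )
            if channel is None:
                raise ValueError(
                    f"{path}:{lineno}: unknown channel token {row['channel']!r}"
                )
            if gene in entries or gene in excluded:
                raise ValueError(f"duplicate gene in class table: {gene!r}")
            cls = ReceptorClass(ligand, channel)
            flag = str(row.get("excluded", "0")).strip().lower()
            if flag in ("1", "true", "yes"):
                excluded.add(gene)
                excluded_classes[gene] = cls
            else:
                entries[gene] = cls
    return ReceptorClassTable(
        entries=entries,
        excluded_genes=frozenset(excluded),
        excluded_classes=excluded_classes,
    )


def default_receptor_class_table() -> ReceptorClassTable:
    """The packaged 62-gene table (plus the two excluded presynaptic genes)."""
    ref = resources.files("synsign.data") / "receptor_classes.csv"
    with resources.as_file(ref) as path:
        return load_receptor_class_table(path)


def classify_receptor_gene(gene: str, table: ReceptorClassTable) -> ReceptorClass:
    """Functional class of *gene* under *table* (see ``ReceptorClassTable.classify``)."""
    return table.classify(gene)


def pharyngeal_neurons() -> frozenset[str]:
    """The packaged 20-neuron pharyngeal nervous system roster."""
    ref = resources.files("synsign.data") / "pharyngeal_neurons.csv"
    with resources.as_file(ref) as path, open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return frozenset(r["neuron"].strip().upper() for r in rows)
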