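"""Binary neuron x gene expression data: loading, curation, and summaries.

An :class:`ExpressionDB` couples two binary matrices indexed by neuron name:
neurotransmitter identity (three columns: glutamate, acetylcholine, GABA) and
ionotropic receptor gene expression (one column per gene).  A neuron is
scored positive for a functional receptor class when it expresses at least
one non-excluded gene of that class.

Quantitative (e.g. single-cell RNA-seq) values enter through
:func:`binarize_expression` with an explicit threshold; curation edits from
the literature are applied through :func:`apply_curation_edits`, which
expands neuron-group names (``AIY`` -> ``AIYL``, ``AIYR``) and keeps an audit
trail of every cell it flips.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .receptors import (
    LIGANDS,
    ALL_CLASSES,
    ReceptorClass,
    ReceptorClassTable,
    normalize_gene,
)

logger = logging.getLogger(__name__)

NT_COLUMNS = list(LIGANDS)

#: accepted spellings for neurotransmitter matrix columns / edit targets
NT_ALIASES = {
    "glutamate": "glutamate", "glu": "glutamate",
    "acetylcholine": "acetylcholine", "ach": "acetylcholine",
    "gaba": "GABA",
}


def canon_nt(name: str) -> str | None:
    """Canonical transmitter name for any accepted spelling, else None."""
    return NT_ALIASES.get(str(name).strip().lower())

#: lateral / dorsoventral / numeric suffixes used when a curation edit names
#: a neuron group rather than individual cells
_GROUP_SUFFIX = re.compile(r"^(?:[LR]|[DV][LR]?|\d{1,2})?$")


class UnknownNeuronError(KeyError):
    """Raised when a neuron name is absent from the expression database."""


def normalize_neuron(name: str) -> str:
    """Canonical neuron spelling: trimmed, upper-case (``AIYL``)."""
    return name.strip().upper()


@dataclass
class ExpressionDB:
    """Binary neurotransmitter and receptor-gene expression matrices.

    ``nt`` is neurons x {glutamate, acetylcholine, GABA}; ``receptors`` is
    neurons x gene with 0/1 entries.  ``provenance`` optionally tags each
    receptor cell with its evidence source (e.g. ``bulk`` or ``rnaseq``).
    """

    nt: pd.DataFrame
    receptors: pd.DataFrame
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        renames = {c: canon_nt(c) for c in self.nt.columns}
        unknown = [c for c, v in renames.items() if v is None]
        if unknown:
            raise ValueError(f"unknown neurotransmitter columns: {unknown}")
        self.nt = self.nt.rename(columns=renames)
        self.nt = self.nt.reindex(columns=NT_COLUMNS, fill_value=0)
        for name, mat in (("nt", self.nt), ("receptors", self.receptors)):
            if mat.index.has_duplicates:
                dupes = mat.index[mat.index.duplicated()].unique().tolist()
                raise ValueError(f"duplicate neuron names in {name} matrix: {dupes}")
            vals = mat.to_numpy()
            if vals.size and not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{name} matrix entries must be binary 0/1")
        if not self.receptors.index.equals(self.nt.index):
            self.receptors = self.receptors.reindex(self.nt.index, fill_value=0)

    @property
    def neurons(self) -> list[str]:
        return list(self.nt.index)

    def __contains__(self, neuron: str) -> bool:
        return normalize_neuron(neuron) in self.nt.index

    def _require(self, neuron: str) -> str:
        n = normalize_neuron(neuron)
        if n not in self.nt.index:
            raise UnknownNeuronError(f"neuron {n!r} not in expression database")
        return n

    def copy(self) -> "ExpressionDB":
        return ExpressionDB(
            nt=self.nt.copy(),
            receptors=self.receptors.copy(),
            provenance=None if self.provenance is None else self.provenance.copy(),
        )


def binarize_expression(values: pd.DataFrame, threshold: float = 0.0) -> pd.DataFrame:
    """Threshold a non-negative quantitative matrix into 0/1 calls.

    An entry is scored positive iff its value is strictly greater than
    *threshold*.  The threshold is a deliberate, recorded parameter: the cut
    applied to quantitative evidence (e.g. single-cell RNA-seq counts)
    changes every downstream prediction, so it must never be implicit.
    """
    arr = values.to_numpy()
    if arr.size and (arr < 0).any():
        bad = values.columns[(arr < 0).any(axis=0)].tolist()
        raise ValueError(f"negative expression values in columns {bad}")
    out = (values > threshold).astype(np.int8)
    out.attrs["binarize_threshold"] = threshold
    return out


def load_expression_matrix(path: str | Path, sheet: str | int = 0) -> pd.DataFrame:
    """Read a neuron x gene matrix from CSV/TSV/XLSX (first column = neuron).

    Neuron names are upper-cased and gene columns normalized to the
    ``glr-1`` spelling.  Values are returned as given (binarize separately
    if quantitative).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet, index_col=0)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = [normalize_neuron(str(n)) for n in df.index]
    df.columns = [normalize_gene(str(c)) for c in df.columns]
    return df


def build_expression_db(
    nt: pd.DataFrame,
    receptors: pd.DataFrame,
    *,
    rnaseq_receptors: pd.DataFrame | None = None,
    include_rnaseq: bool = True,
    table: ReceptorClassTable | None = None,
) -> ExpressionDB:
    """Assemble an :class:`ExpressionDB` from binary source matrices.

    Bulk-curated and RNA-seq evidence are OR-combined per cell;
    ``include_rnaseq=False`` drops the RNA-seq layer entirely (used to test
    sensitivity of conclusions to that data source).  Receptor columns
    absent from *table* are retained but flagged with a warning — they are
    carried through but never contribute to class calls.
    """
    receptors = receptors.copy()
    provenance = pd.DataFrame("bulk", index=receptors.index, columns=receptors.columns)
    provenance = provenance.where(receptors > 0, "")
    if rnaseq_receptors is not None and include_rnaseq:
        rnaseq = rnaseq_receptors.reindex(
            index=receptors.index.union(rnaseq_receptors.index),
            columns=receptors.columns.union(rnaseq_receptors.columns),
            fill_value=0,
        )
        receptors = receptors.reindex(index=rnaseq.index, columns=rnaseq.columns, fill_value=0)
        provenance = provenance.reindex(index=rnaseq.index, columns=rnaseq.columns, fill_value="")
        newly = (rnaseq > 0) & (receptors == 0)
        provenance = provenance.mask(newly, "rnaseq")
        receptors = ((receptors > 0) | (rnaseq > 0)).astype(np.int8)
        nt = nt.reindex(receptors.index, fill_value=0)
    if table is not None:
        unknown = [
            g for g in receptors.columns
            if g not in table.entries and g not in table.excluded_genes
        ]
        if unknown:
            logger.warning(
                "%d receptor columns not in class table (ignored by class "
                "mapping): %s", len(unknown), ", ".join(sorted(unknown)[:10]),
            )
    return ExpressionDB(nt=nt.astype(np.int8), receptors=receptors.astype(np.int8),
                        provenance=provenance)


# ---------------------------------------------------------------------------
# curation edits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurationEdit:
    """One literature-driven edit to the bulk expression matrix.

    ``group`` names either a neuron, or a neuron group expanded over the
    database (``AIY`` -> AIYL, AIYR; ``VA`` -> VA1..VA12); an explicit
    ``neurons`` list overrides expansion.  ``scope`` selects the matrix the
    edit touches.
    """

    group: str
    target: str  # gene (receptor scope) or neurotransmitter name
    action: str  # "add" | "delete"
    scope: str = "receptor"  # "receptor" | "neurotransmitter"
    neurons: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.action not in ("add", "delete"):
            raise ValueError(f"action must be add/delete, got {self.action!r}")
        if self.scope not in ("receptor", "neurotransmitter"):
            raise ValueError(f"scope must be receptor/neurotransmitter, got {self.scope!r}")


def expand_neuron_group(group: str, neurons: Iterable[str]) -> list[str]:
    """All database neurons belonging to *group*.

    A neuron matches if its name equals the group name or extends it by a
    standard positional suffix (L/R, D/V, DL/DR/VL/VR, or a number), so
    ``AIY`` matches AIYL and AIYR and ``VB`` matches VB1..VB11 but not
    VB1's lookalike ``VB12X``.
    """
    g = normalize_neuron(group)
    return [n for n in neurons if n.startswith(g) and _GROUP_SUFFIX.match(n[len(g):])]


def apply_curation_edits(
    db: ExpressionDB,
    edits: Sequence[CurationEdit],
    *,
    table: ReceptorClassTable | None = None,
) -> tuple[ExpressionDB, pd.DataFrame]:
    """Apply *edits* in order; return the edited DB and a cell-level audit log.

    The audit log has one row per changed cell (neuron, target, scope,
    action, before, after).  Edits addressing unknown neurons raise; adding
    an excluded (presynaptic) receptor gene raises.
    """
    out = db.copy()
    audit: list[dict] = []
    for i, edit in enumerate(edits):
        if edit.neurons is not None:
            members = [normalize_neuron(n) for n in edit.neurons]
            unknown = [n for n in members if n not in out.nt.index]
            if unknown:
                raise UnknownNeuronError(f"edit {i}: unknown neurons {unknown}")
        else:
            members = expand_neuron_group(edit.group, out.nt.index)
            if not members:
                raise UnknownNeuronError(
                    f"edit {i}: group {edit.group!r} matches no database neuron"
                )
        value = 1 if edit.action == "add" else 0
        if edit.scope == "neurotransmitter":
            target = canon_nt(edit.target)
            if target is None:
                raise ValueError(f"edit {i}: unknown neurotransmitter {edit.target!r}")
            matrix = out.nt
        else:
            target = normalize_gene(edit.target)
            if table is not None and target in table.excluded_genes:
                raise ValueError(
                    f"edit {i}: gene {target!r} is excluded (presynaptic); refusing to add"
                )
            if target not in out.receptors.columns:
                # a curation edit may introduce a gene not yet in the matrix
                out.receptors[target] = np.int8(0)
            matrix = out.receptors
        for n in members:
            before = int(matrix.at[n, target])
            if before != value:
                matrix.at[n, target] = value
                audit.append({
                    "neuron": n, "target": target, "scope": edit.scope,
                    "action": edit.action, "before": before, "after": value,
                })
    audit_df = pd.DataFrame(
        audit, columns=["neuron", "target", "scope", "action", "before", "after"]
    )
    return out, audit_df


# ---------------------------------------------------------------------------
# per-neuron profiles and the neuron-level summary
# ---------------------------------------------------------------------------

def neuron_nt_profile(neuron: str, db: ExpressionDB) -> frozenset[str]:
    """Set of neurotransmitters a neuron expresses (may be empty)."""
    n = db._require(neuron)
    row = db.nt.loc[n]
    return frozenset(c for c in NT_COLUMNS if row[c] == 1)


def neuron_receptor_classes(
    neuron: str, db: ExpressionDB, table: ReceptorClassTable
) -> frozenset[ReceptorClass]:
    """Functional receptor classes for which a neuron expresses >= 1 gene.

    Excluded (presynaptic) genes and genes unknown to the table never
    contribute.
    """
    n = db._require(neuron)
    row = db.receptors.loc[n]
    classes = set()
    for gene, value in row.items():
        if value == 1 and gene in table.entries:
            classes.add(table.entries[gene])
    return frozenset(classes)


@dataclass(frozen=True)
class NeuronExpressionSummary:
    """Neuron-level tallies of transmitter and receptor-class expression."""

    n_neurons: int
    nt_category_counts: dict[int, int]  # neurons expressing 0 / 1 / 2 transmitters
    receptor_ligand_overlap_counts: dict[int, int]  # receptor ligands covered: 0..3
    polarity_mix_counts: dict[str, int]  # cation_only / anion_only / mixed / none
    same_nt_both_polarity_count: int
    mean_receptor_genes_per_neuron: float

    def __post_init__(self) -> None:
        for part in (self.nt_category_counts, self.receptor_ligand_overlap_counts,
                     self.polarity_mix_counts):
            assert sum(part.values()) == self.n_neurons, "partition must cover all neurons"


def expression_summary(db: ExpressionDB, table: ReceptorClassTable) -> NeuronExpressionSummary:
    """Summarize transmitter and receptor-class expression across all neurons."""
    n_nt = {0: 0, 1: 0, 2: 0, 3: 0}
    overlap = {0: 0, 1: 0, 2: 0, 3: 0}
    polarity = {"cation_only": 0, "anion_only": 0, "mixed": 0, "none": 0}
    same_nt_both = 0
    class_genes = [g for g in db.receptors.columns if g in table.entries]
    positives = int(db.receptors[class_genes].to_numpy().sum()) if class_genes else 0
    for neuron in db.neurons:
        nts = neuron_nt_profile(neuron, db)
        n_nt[len(nts)] += 1
        classes = neuron_receptor_classes(neuron, db, table)
        ligands = {c.ligand for c in classes}
        overlap[len(ligands)] += 1
        channels = {c.channel for c in classes}
        if not channels:
            polarity["none"] += 1
        elif channels == {"cation"}:
            polarity["cation_only"] += 1
        elif channels == {"anion"}:
            polarity["anion_only"] += 1
        else:
            polarity["mixed"] += 1
        if any(
            ReceptorClass(lig, "cation") in classes and ReceptorClass(lig, "anion") in classes
            for lig in ligands
        ):
            same_nt_both += 1
    n = len(db.neurons)
    mean_genes = positives / n if n else 0.0
    return NeuronExpressionSummary(
        n_neurons=n,
        nt_category_counts={k: v for k, v in n_nt.items() if k <= 2 or v},
        receptor_ligand_overlap_counts=overlap,
        polarity_mix_counts=polarity,
        same_nt_both_polarity_count=same_nt_both,
        mean_receptor_genes_per_neuron=mean_genes,
    )
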