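"""End-to-end pipeline: load -> curate -> predict -> stats -> robustness.

A :class:`RunConfig` names the inputs and choices; :func:`run_pipeline`
executes the stages in order and writes a self-describing output bundle
(prediction TSV per method, a JSON stats summary, the resolved config and a
log).  Every output file carries the package version and a hash of the
resolved configuration so a bundle can always be traced to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .balance import breakdown_by_presynaptic_nt, label_distribution
from .connectome import chemical_subnetwork, load_connectome
from .expression import (
    CurationEdit,
    apply_curation_edits,
    binarize_expression,
    build_expression_db,
    load_expression_matrix,
)
from .predict import predict_all, prediction_table_to_tsv, resolve_method
from .receptors import default_receptor_class_table, load_receptor_class_table
from .robustness import perturbation_suite, standard_perturbations

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved inputs and options of one pipeline run."""

    connectome: str
    nt_expression: str
    receptor_expression: str
    out_dir: str
    class_table: str | None = None  # packaged default when None
    metadata: str | None = None
    edits: str | None = None
    methods: tuple[str, ...] = ("ntr",)
    binarize_threshold: float = 0.0
    include_rnaseq: bool = True
    rnaseq_expression: str | None = None
    run_perturbations: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_curation_edits(path: str | Path) -> list[CurationEdit]:
    """Read curation edits from YAML (list of mappings) or CSV."""
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or []
    else:
        raw = pd.read_csv(path).to_dict("records")
    edits = []
    for row in raw:
        neurons = row.get("neurons")
        if isinstance(neurons, str):
            neurons = tuple(n.strip() for n in neurons.split(";") if n.strip())
        elif neurons is not None:
            neurons = tuple(neurons)
        edits.append(CurationEdit(
            group=str(row["group"]), target=str(row["target"]),
            action=str(row["action"]), scope=str(row.get("scope", "receptor")),
            neurons=neurons,
        ))
    return edits


def _stamp(config: RunConfig) -> str:
    return f"# synsign {__version__} config={config.config_hash}\n"


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; return the JSON-ready summary.

    Stage order: load class table and connectome; assemble and curate the
    expression DB; predict under each configured method; tabulate balances;
    optionally run the stock perturbation suite.  Any stage error
    propagates annotated with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(config)
    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash,
        "config": config.to_dict(),
        "stages": [],
    }

    def stage(name):
        summary["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("load_class_table")
        table = (load_receptor_class_table(config.class_table)
                 if config.class_table else default_receptor_class_table())

        stage("load_connectome")
        metadata = None
        if config.metadata:
            metadata = pd.read_csv(config.metadata, index_col=0)
        conn = load_connectome(config.connectome, metadata=metadata)
        chem = chemical_subnetwork(conn)
        summary["connectome"] = {
            "connections": int((conn.edges["kind"] == "chemical").sum()),
            "synapses": int(chem.edges["weight"].sum()),
            "neurons_connected": len(chem.connected_neurons("chemical")),
        }

        stage("build_expression_db")
        nt = load_expression_matrix(config.nt_expression)
        receptors = load_expression_matrix(config.receptor_expression)
        rnaseq = (load_expression_matrix(config.rnaseq_expression)
                  if config.rnaseq_expression else None)
        if rnaseq is not None:
            rnaseq = binarize_expression(rnaseq, config.binarize_threshold)
        db = build_expression_db(
            nt=binarize_expression(nt, config.binarize_threshold),
            receptors=binarize_expression(receptors, config.binarize_threshold),
            rnaseq_receptors=rnaseq, include_rnaseq=config.include_rnaseq,
            table=table,
        )

        if config.edits:
            stage("apply_curation_edits")
            edits = load_curation_edits(config.edits)
            db, audit = apply_curation_edits(db, edits, table=table)
            with open(out_dir / "curation_audit.tsv", "w") as fh:
                fh.write(stamp)
                audit.to_csv(fh, sep="\t", index=False)
            summary["curation"] = {"edits": len(edits), "cells_changed": len(audit)}

        stage("predict")
        summary["methods"] = {}
        predictions = {}
        for m in config.methods:
            method = resolve_method(m)
            preds = predict_all(chem, db, table, method=method)
            predictions[method] = preds
            slug = method.lower().replace("+", "_").replace("-", "_")
            path = out_dir / f"predictions_{slug}.tsv"
            with open(path, "w") as fh:
                fh.write(stamp)
                prediction_table_to_tsv(preds, fh)
            bal_syn = label_distribution(preds, level="synapse")
            bal_conn = label_distribution(preds, level="connection")
            summary["methods"][method] = {
                "synapse": bal_syn.as_dict(),
                "connection": bal_conn.as_dict(),
                "predicted_share_synapse": bal_syn.predicted_share,
            }
            if method in ("NT+R", "NT-only"):
                bd = breakdown_by_presynaptic_nt(preds)
                summary["methods"][method]["by_presynaptic_nt"] = {
                    str(k): {c: (None if pd.isna(v) else float(v) if "share" in c else int(v))
                             for c, v in row.items()}
                    for k, row in bd.iterrows()
                }

        if config.run_perturbations:
            stage("robustness")
            suite = perturbation_suite(conn, db, table, standard_perturbations())
            with open(out_dir / "perturbation_suite.tsv", "w") as fh:
                fh.write(stamp)
                suite.to_csv(fh, sep="\t", index=False)
            summary["robustness"] = {
                "ratio_min": suite.attrs["ratio_min"],
                "ratio_max": suite.attrs["ratio_max"],
                "variants": suite["variant"].tolist(),
            }
    except Exception as exc:
        failed = summary["stages"][-1] if summary["stages"] else "init"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    with open(out_dir / "config.yaml", "w") as fh:
        fh.write(stamp)
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
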