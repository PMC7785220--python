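#!/usr/bin/env python
"""Sign-balance structure of the predicted synthetic network.

Reads the NT+R prediction table from 03_predict.py and computes (1) the
label distribution per presynaptic transmitter, (2) the E:I balance matrix
over ordered modality pairs, and (3) a subnetwork extraction over a random
neuron roster, writing each as TSV under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from synsign import breakdown_by_presynaptic_nt, modality_group_balance, subnetwork_extract
from synsign.balance import group_balance_frame, nearest_simple_ratio

RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_predictions(path: Path) -> pd.DataFrame:
    preds = pd.read_csv(path, sep="\t")
    preds["pre_nts"] = preds["pre_nts"].fillna("").map(
        lambda s: frozenset(t for t in str(s).split(";") if t))
    return preds


def main() -> None:
    preds = load_predictions(RESULTS / "predictions_nt_r.tsv")
    metadata = pd.read_csv(RESULTS / "synthetic_inputs" / "metadata.csv", index_col=0)

    by_nt = breakdown_by_presynaptic_nt(preds)
    by_nt.to_csv(RESULTS / "breakdown_by_nt.tsv", sep="\t")
    print("label shares by presynaptic transmitter (synapse level):")
    print(by_nt[["share_excitatory", "share_inhibitory", "share_complex"]].round(3))

    cells = modality_group_balance(preds, metadata)
    frame = group_balance_frame(cells)
    frame.to_csv(RESULTS / "modality_balance.tsv", sep="\t", index=False)
    defined = frame.dropna(subset=["ratio"])
    lo = defined.loc[defined["ratio"].idxmin()]
    hi = defined.loc[defined["ratio"].idxmax()]
    print(
        f"\nmodality-pair E:I ratios span {lo['ratio']:.2f} "
        f"({lo['source']}->{lo['target']}) to {hi['ratio']:.2f} "
        f"({hi['source']}->{hi['target']}); "
        f"network-wide ratio ~ {nearest_simple_ratio(float(preds_ratio(preds)), 6)}"
    )

    rng = np.random.default_rng(1)
    roster = sorted(rng.choice(metadata.index.to_numpy(), size=40, replace=False))
    sub = subnetwork_extract(preds, roster)
    sub_out = sub.copy()
    sub_out["pre_nts"] = sub_out["pre_nts"].map(lambda s: ";".join(sorted(s)))
    sub_out.to_csv(RESULTS / "subnetwork_40.tsv", sep="\t", index=False)
    print(f"40-neuron subnetwork retains {len(sub)} of {len(preds)} connections")


def preds_ratio(preds: pd.DataFrame) -> float:
    from synsign import label_distribution

    return label_distribution(preds, "synapse").ratio


if __name__ == "__main__":
    main()
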