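#!/usr/bin/env python
"""Generate the synthetic study dataset used by the downstream drivers.

Draws a worm-scale dataset (300 neurons, expected out-degree 12, geometric
synapse counts) at the generator's default transmitter/receptor-class
marginals, and writes it in the same text formats the package's readers
consume, under results/synthetic_inputs/.
"""

import json
from pathlib import Path

from synsign import SynthParams, default_receptor_class_table, expression_summary, \
    generate_synthetic_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    params = SynthParams(seed=SEED)
    conn, db, metadata = generate_synthetic_dataset(params)
    out = RESULTS / "synthetic_inputs"
    out.mkdir(parents=True, exist_ok=True)
    conn.edges.to_csv(out / "connectome.csv", index=False)
    db.nt.rename_axis("neuron").to_csv(out / "nt_expression.csv")
    db.receptors.rename_axis("neuron").to_csv(out / "receptor_expression.csv")
    metadata.to_csv(out / "metadata.csv")

    summary = expression_summary(db, default_receptor_class_table())
    info = {
        "seed": SEED,
        "neurons": params.n_neurons,
        "connections": int(len(conn.edges)),
        "synapses": conn.total_synapses,
        "nt_category_counts": summary.nt_category_counts,
        "polarity_mix_counts": summary.polarity_mix_counts,
    }
    (out / "dataset_info.json").write_text(json.dumps(info, indent=2))
    print(json.dumps(info, indent=2))
    print(f"\nwrote synthetic inputs to {out}")


if __name__ == "__main__":
    main()
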