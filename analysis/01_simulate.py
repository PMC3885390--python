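"""Generate the synthetic study: network, TF activities, expression.

Writes the static network (SIF), replicated expression (TSV) and the
ground-truth control strengths / activities used later as recovery
oracles.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, STUDY

from dynregnet.io import write_network, write_replicated_expression, write_table
from dynregnet.simulate import generate_expression, make_ground_truth


def main() -> None:
    out = RESULTS / "simulated"
    truth = make_ground_truth(
        n_tfs=STUDY["n_tfs"],
        n_tgs=STUDY["n_tgs"],
        targets_per_tf=STUDY["targets_per_tf"],
        tf_tf_edges=STUDY["tf_tf_edges"],
        noise_sd=STUDY["noise_sd"],
        seed=SEED,
    )
    expr = generate_expression(truth, STUDY["n_replicates"])

    write_network(truth.network, out / "network.sif")
    write_replicated_expression(expr, out / "expression.tsv")
    write_table(
        pd.DataFrame(
            truth.T_true,
            index=pd.Index(truth.tf_ids, name="tf"),
            columns=[f"time_{t:g}" for t in truth.timepoints],
        ),
        out / "true_activities.tsv",
    )
    rows, cols = np.nonzero(truth.C_true)
    write_table(
        pd.DataFrame(
            {
                "gene": [truth.gene_ids[i] for i in rows],
                "tf": [truth.tf_ids[j] for j in cols],
                "strength": truth.C_true[rows, cols],
            }
        ),
        out / "true_control_strengths.tsv",
        index=False,
    )
    print(
        f"simulated {len(truth.gene_ids)} genes x {len(truth.timepoints)} "
        f"time points x {STUDY['n_replicates']} replicates; "
        f"network: {len(truth.network.tfs)} TFs, {len(truth.network.tgs)} TGs, "
        f"{truth.network.n_edges} edges -> {out}"
    )


if __name__ == "__main__":
    main()
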