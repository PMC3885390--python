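"""Shared configuration for the analysis drivers.

One synthetic study is threaded through all numbered scripts: a regulatory
network of 10 TFs and 150 target genes (8 targets per TF, 10 TF-TF
interactions), TF activities peaking across the four post-stimulus ranges,
and two replicates of noisy expression at 11 time points over 14 h.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2024

STUDY = dict(
    n_tfs=10,
    n_tgs=150,
    targets_per_tf=8,
    tf_tf_edges=10,
    n_replicates=2,
    noise_sd=0.05,
)
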