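# dynregnet

Dynamics of transcriptional regulatory networks from time-series
expression. Given (a) a genes × time-points expression matrix with
replicates and (b) a static directed regulatory network of transcription
factors (TFs) and target genes (TGs), the package reconstructs hidden TF
activity profiles, partitions the network into four time-range **active
sub-networks** — immediate-early (IE), mid-early (ME), mid-late (ML) and
very-late (VL) — and characterizes each sub-network by topology metrics
against a size-matched random null and by 3/4/5-node network-motif
enrichment. It is aimed at systems biologists analyzing stimulus-response
experiments (hormone or growth-factor treatments sampled densely over
hours) with known TF→TG connectivity.

## The model

**Network component analysis (NCA).** Expression is modeled as

```
E = C · T + ε,        E: N×M,  C: N×L,  T: L×M
```

where `C` holds signed control strengths whose sparsity pattern is pinned
to the known TF→TG connectivity `Z0`, and `T` holds the hidden TF
activities over the M time points. `C` and `T` are estimated by
alternating least squares (full least-squares for `T`, per-gene
support-restricted least squares for `C`), minimizing `‖E − CT‖²_F` subject
to `support(C) ⊆ Z0`, with seeded random restarts. The decomposition is
unique up to a diagonal rescaling `(C, T) → (C S⁻¹, S T)` exactly when the
identifiability criteria hold: `Z0` has full column rank, removing any TF
and all its targets leaves full column rank, and `M ≥ L`. The package
checks these criteria, greedily prunes TFs until they hold, and fixes the
scale by giving each column of `C` unit norm and a positive dominant entry.

**Active sub-networks.** Each profile (smoothed TG expression, or
reconstructed TF activity) is summarized by its peak time
`argmax_t |x(t) − x(0)|` and a scale-free amplitude
`max_t |x(t) − x(0)| / SD(x − x(0))`. Nodes above an amplitude threshold
are binned into IE (0–1 h], ME (1–3 h], ML (3–8 h] or VL (8–14 h] by peak
time, and each range's sub-network is the induced subgraph of the static
network.

**Topology and motifs.** Per-node degree, directed clustering coefficient
`E_n/(k(k−1))`, normalized betweenness, closeness over reachable nodes,
plus network-level diameter, average path length, and Freeman degree
centralization — each sub-network compared to 100 random sub-networks of
the same TF/TG composition. Motif enrichment uses an exact ESU census of
induced connected k-subgraphs (k = 3, 4, 5) and a degree-preserving
edge-switch null: `Z = (N_real − mean N_rand)/SD(N_rand)` with an add-one
empirical p-value.

## Worked example

The numbered drivers under `analysis/` run one synthetic study end to end
(10 TFs, 150 TGs, 8 targets per TF, 11 time points over 14 h, two
replicates, 5% noise):

```
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_nca.py
python analysis/04_subnetworks.py
python analysis/05_topology.py
python analysis/06_motifs.py
```

The preprocessing step prints

```
55 of 150 genes differentially expressed (p<0.05 at >=3 time points vs t=0)
```

— genes whose baseline t-test is significant at three or more time points.
The NCA step prints

```
fit 51 genes x 10 TFs (criteria compliant: True); final objective 10.47;
mean |r| vs truth = 0.9312
```

i.e. the reconstructed activity profiles correlate (in absolute value,
since activities are only identified up to scale and sign) at 0.93 on
average with the simulated ground truth after the full
normalize-test-smooth-fit pipeline. The sub-network step prints the
composition of the four time ranges:

```
range interval_h  active_tfs  active_tgs  edges  isolated
   IE     (0, 1]           1           4      4         0
   ME     (1, 3]           5          25     30         5
   ML     (3, 8]           2          10     10         0
   VL    (8, 14]           2          12     10         3
```

and the topology table shows, for example, that the ME sub-network has
twice the average degree (2.40) of its size-matched random null
(1.20 ± 0.20). A single-call alternative is
`dynregnet.run_pipeline(dynregnet.PipelineConfig(...))`, which writes the
same artifacts plus a manifest and is byte-reproducible per seed.

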