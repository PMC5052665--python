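# respnet

Stimulation-evoked responsive-network analysis on whole-brain connectome
models.

`respnet` simulates focal stimulation of a brain network in which every node is
a two-variable oscillator parameterized just below an Andronov–Hopf bifurcation
(natural frequency ≈ 42 Hz). Nodes are coupled through two structural routes:

- **short-range (homogeneous) connectivity** — a translation-invariant Gaussian
  kernel on each hemispheric surface, instantaneous, with no interhemispheric
  links and incoming weights normalized to unit sum;
- **long-range (heterogeneous) connectivity** — a sparse directed area-to-area
  graph transmitting delayed area-mean activity (finite speed, default 6 m/s),
  normalized to unity maximum in-strength.

Because the in-strength never exceeds 1 < γ = 1.21, every node stays
subcritical: the network is silent at rest and dissipates stimulus energy as
damped oscillations. The package decomposes that dissipation into up to three
principal spatial patterns per stimulation condition (>99 % variance), clusters
the patterns across sites into a repertoire of *responsive networks*, and
matches them against three-level resting-state-network masks using the
Bhattacharyya coefficient with permutation statistics (p = (n+1)/(N+1),
Bonferroni–Holm corrected), graph metrics of the long-range connectivity, and
cortical/subcortical distribution tests.

Everything runs on a fully synthetic brain (two triangulated spherical
hemispheres + point-like subcortical areas), so no external data is required.
Real connectomes in the standard zip/directory dialect (`weights.txt`,
`tract_lengths.txt`, `centres.txt`) and meshes as TSV tables are also accepted.

## Layout

| module | role |
| --- | --- |
| `respnet.synthetic_brain` | geometry, parcellation, both connectivities, file IO |
| `respnet.node_dynamics` | isolated node flow, linearization, stimulus calibration |
| `respnet.network_simulator` | delayed network Heun integration, reference subtraction |
| `respnet.transient_estimator` | activation-cascade (cellular automaton) transient bound |
| `respnet.response_decomposition` | envelope utilities, response PCA |
| `respnet.responsive_networks` | subspace similarity, gap-statistic clustering, Procrustes averaging |
| `respnet.rsn_matching` | coarse-graining, Bhattacharyya/permutation/Holm statistics, graph metrics, stimulation map |
| `respnet.pipeline_cli` | orchestration, fixtures, CLI |

## CLI

```bash
# build a synthetic brain bundle on disk
respnet fixture small --seed 1 --out bundle/

# simulate one condition, store HDF5, decompose a window
respnet simulate --bundle bundle/ --site 0 --alpha 0.6 --duration 0.6 --out run.h5
respnet decompose --result run.h5 --start 0.1 --length 0.5 --out vecs.txt

# transient estimate of a connectome (zip or directory)
respnet transient --connectome bundle/connectome

# full sweep: simulate -> decompose -> cluster -> match -> map
respnet sweep --bundle bundle/ --sites 0,1,2 --alphas 0.0,0.6,1.0 --seed 1 --out sweep/
```

Sweep outputs are TSV tables (`repertoire.tsv`, `matches.tsv`,
`stimulation_map.tsv`) plus an HDF5 archive of eigenspaces; every artifact
carries the configuration hash, so runs are replayable from config + seed.

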