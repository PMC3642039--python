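# rhythmscan

Rhythmicity detection and comparison for expression time courses sampled
every 4 hours over 48 hours (13 timepoints, 2 replicates) under light:dark
(LD) or constant-dark (DD) regimes.

Four detectors are implemented, each with the statistic used for calling:

| Detector | Statistic | Call rule (defaults) |
| --- | --- | --- |
| Cosine goodness-of-fit (`rhythmscan.cosopt`) | permutation pMMCβ, averaged over replicates | pMMCβ < 0.2, best period inside the regime window in both replicates |
| Rank-based period/phase test (`rhythmscan.jtk`) | Benjamini–Hochberg q-value | q < 0.1 (or 0.05), period in window |
| DFT relative amplitude (`rhythmscan.dft`) | s = X[2]/‖X‖ of the 24-hr bin, replicate mean | s > 0.3 |
| Pulsatile template matching (`rhythmscan.pulse`) | max sliding-correlation score c | c > 1.6 and peak-to-trough fold > 1.5 in both replicates |

Period windows default to 20–28 hr (LD) and 18.5–26.5 hr (DD); probes must
have mean fluorescence intensity > 20 in every replicate before detection.

On top of the detectors:

- `rhythmscan.consensus` — Venn partition of the probe universe by the
  three sinusoidal detectors, newly-rhythmic lists, threshold sweeps.
- `rhythmscan.downstream` — peak-phase distributions, peak/nadir amplitude
  with the 8–16 hr interval rule, LD-vs-DD mean-expression fold changes,
  LD→DD transition typing (types I/II/III), hierarchical clustering
  (log2 / mean-center / unit-SS, centroid linkage), Z-scored profiles.
- `rhythmscan.motifs` — IUPAC consensus-element scanning (E boxes, W box,
  CRE, PERR, TER, PDP1 site) of upstream regions at 1 kb / 5 kb windows.
- `rhythmscan.orthologs` — two-species rhythmic-ortholog matching by
  percent identity, category count tables, circular phase concordance.
- `rhythmscan.simulate` — ground-truth-labelled synthetic matrices
  (sinusoidal / pulsatile / arrhythmic probes, paired LD/DD time courses
  with the three transition types) and promoters with planted motifs, so
  the whole pipeline is testable without any external data.

## CLI

The `rhythmscan` command orchestrates
`simulate → detect → consensus → downstream → motifs → compare` from a
single YAML config with one global seed; every stage writes TSV/FASTA/
Newick outputs plus a `manifest.json` with content hashes. Reruns with the
same config are byte-identical.

```sh
# end-to-end demo on synthetic data
rhythmscan --seed 7 --outdir demo_out all

# individual stages, custom config
rhythmscan --config run.yaml simulate
rhythmscan --config run.yaml detect
```

A config file can either describe a simulation or point at input TSVs
(wide format, `probe_id` plus `T<hr>_r<rep>` columns), but not both:

```yaml
seed: 7
outdir: demo_out
simulation:
  n_sinusoidal: 30
  n_arrhythmic: 40
  rel_amplitude: 0.8
  noise_sigma: 0.05
thresholds:
  cosopt_p_max: 0.2
  jtk_q_max: 0.1
  dft_s_min: 0.3
cosopt:
  n_scrambles: 200
```

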