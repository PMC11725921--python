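# quasormod

Optical quantal analysis of synapse-specific neuromodulation at the
*Drosophila* larval neuromuscular junction (NMJ).

Tonic (Ib) and phasic (Is) glutamatergic motor neurons innervate the same
muscle alongside octopaminergic type II neurons. Octopamine (OA), acting
through the Gq-coupled OAMB receptor and DAG modulation of the priming
protein Unc13A, potentiates release at Ib synapses — selectively at
Unc13A-rich sites — while Is synapses and Unc13A-poor Ib synapses are left
untouched. Testing that kind of synapse-by-synapse claim requires measuring
release probability

    P_r = (evoked events at one active zone) / (number of stimuli)

at hundreds of individually identified active zones (AZs) before and after
drug application, then relating the change in P_r to each AZ's protein
content. `quasormod` implements that entire measurement chain as a tested,
reusable pipeline, together with a synthetic-data generator that reproduces
the statistical structure of such experiments so every stage can be
validated against ground truth without any microscope:

- **simulate** — ground-truth NMJs (AZ geometry, correlated Brp/Unc13A
  content, basal P_r spanning two orders of magnitude, receptor-gated
  sigmoidal modulation ΔP_r(x) = A/(1+exp(−(x−x0)k))), Bernoulli release,
  ΔF/F movies with Gaussian PSF and noise, fixation-distorted 3-channel
  structural volumes, and larval behavior traces;
- **detect** — template-based stimulus-locked quantal event detection with
  the 0.04–0.05 ΔF/F + 1.5–2×SD dual threshold;
- **localize** — sub-diffraction event coordinates by 2D Gaussian fitting,
  coordinate-density maps, and synapse ROIs with a 350 nm exclusion radius;
- **segment** — 3D AZ calling (150 nm minimum separation) and per-AZ
  Brp/Unc13A quantification;
- **match** — global stretch correction, one-to-one AZ-ROI matching, a
  locally weighted mean overlay transform, and event-to-AZ assignment;
- **stats** — P_r tables, quantal density (events/stimulus/µm²), response
  classification, equal-count binned modulation curves, multistart sigmoid
  fits, and the standard hypothesis tests;
- **behavior** — centroid tracking, dark/light epoch displacement, bout
  detection, and type II firing / Ib transmission bout coupling.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate and analyze three wild-type NMJs through the full imaging chain
(movies → detection → localization → ROIs → structural volume →
segmentation → matching → statistics), with octopamine applied between the
two epochs:

```python
from quasormod import SimConfig, run_pipeline

cfg = SimConfig(n_stimuli_pre=50, n_stimuli_post=50,
                n_boutons_ib=3, n_boutons_is=2, az_per_bouton=5,
                frames_per_trial=25)
manifest, report = run_pipeline(cfg, "wt+OA", seed=7, n_nmjs=3)

print(report["qd"]["Ib_pre"]["mean"], report["qd"]["Ib_post"]["mean"])
print(report["tests"]["qd_paired_t_Ib"])
print(report["tests"]["qd_paired_t_Is"])
```

prints (abridged):

```
0.083 0.1366
{'design': 'paired_t', 'statistic': -4.508, 'p_value': 0.0458, 'n': [3, 3], 'stars': '*'}
{'design': 'paired_t', 'statistic': -0.358, 'p_value': 0.7546, 'n': [3, 3], 'stars': 'n.s.'}
```

The Ib quantal density (mean events per stimulus per µm² of NMJ footprint)
rises from 0.083 to 0.137 and the paired t-test across the three NMJs calls
the increase significant, while the Is terminals on the same muscles show
no change — the synapse-type-specific potentiation the pipeline is built to
measure. The report also carries the pooled per-AZ P_r table summary, the
fraction of AZs whose P_r increased/decreased, the change in P_r binned by
normalized Unc13A content, and the sigmoid fit to that curve.

The same stages are available from the shell:

```bash
quasormod simulate --scenario wt+OA --seed 7 --out data/
quasormod detect   --movie data/movie_pre.tif --out events.csv
quasormod quasor   --movie data/movie_pre.tif --events events.csv --out quasor/
quasormod segment  --volume data/structure --out az.csv
quasormod match    --az az.csv --rois quasor/rois.csv --out match/
quasormod run      --scenario wt+OA --seed 7 --n-nmjs 6 --out run1/
```

Scenario labels combine a genotype (`wt`, `oamb_rnai`, `unc13_rnai`,
`unc13a_rnai`, `unc13b_rnai`, `unc13a_h1723k`) with a drug (`none`, `OA`,
`PdBU`), e.g. `unc13b_rnai+PdBU`.

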