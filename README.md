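# vigilnet

Vigilance-state effects on MEG/EEG spectra, functional connectivity and
network topology.

Subjects drift into drowsiness during eyes-closed resting-state
recordings far more often than protocols assume, and they open their eyes
when told not to.  `vigilnet` is a tested, reusable pipeline for asking
how much that matters: starting from source-space ROI time series (78
cortical AAL regions, 13.1072-s epochs of 4,096 samples at 312.5 Hz), it
scores each epoch as eyes-open (EO), alert eyes-closed (A-EC) or drowsy
eyes-closed (D-EC), and compares between states:

* **spectral measures** — relative power in delta/theta/alpha1/alpha2/
  beta/gamma from a brickwall (FFT zeroing) decomposition, and the peak
  frequency in 4–13 Hz;
* **functional connectivity** — the phase lag index
  `PLI = |⟨sign sin(φ_i − φ_j)⟩|`, insensitive to zero-lag (volume
  conduction) coupling, and the corrected amplitude envelope correlation
  (AECc): pairwise orthogonalization of analytic signals, Pearson
  correlation of Hilbert envelopes, both directions averaged, mapped to
  [0, 1];
* **network topology** — the minimum spanning tree over the 77 strongest
  connections of each 78-ROI matrix, summarized by leaf fraction
  `Lf = L/(n−1)`, tree hierarchy `Th = L/(2(n−1)·BC_max)` and normalized
  betweenness centrality (star hub = 1, leaf = 0).

Group comparisons use within-subject paired t-tests on global metrics and
per-ROI tests with Benjamini–Hochberg FDR correction over the 78 regions.

Because the underlying human recordings are not public, the package ships
a first-class synthetic-data generator that emulates the study conditions
(posterior ~10 Hz rhythm, drowsy theta elevation with transient alpha
dropout, eyes-open alpha suppression with blinks, slow EOG waves) and
plants phase-lag and envelope-share couplings with known ground truth.
See `docs/methods.md` for the model and every numerical convention.

## Worked example

Simulate a 19-subject cohort (5 epochs per state each, 20 ROIs,
2,048-sample epochs to keep it quick) and run the between-state study with
theta-band connectivity:

```python
import vigilnet as v
from vigilnet.core_io import BAND_BY_NAME, PipelineConfig

cfg = PipelineConfig(epoch_length=2048)
cohort = v.simulate_cohort(19, config=cfg, seed=1,
                           roi_labels=v.AAL78_LABELS[::4])
res = v.run_study(cohort, cfg, fc_bands=[BAND_BY_NAME["theta"]])
print(res.table1.round(3))
```

prints (abridged):

```
                mean_EO  mean_A-EC  mean_D-EC  p_A_EC_vs_EO  p_A_EC_vs_D_EC
power_theta       0.227      0.187      0.575         0.000           0.000
power_alpha2      0.050      0.183      0.071         0.000           0.000
peak_frequency    5.728      9.128      6.089         0.000           0.000
fc_PLI_theta      0.133      0.131      0.131         0.190           0.863
fc_AECc_theta     0.500      0.499      0.499         0.159           0.739
```

Reading it: drowsy epochs show strongly elevated relative theta power
(0.575 vs 0.187 alert) with alpha2 and peak frequency pulled down, and
eyes opening suppresses alpha — while theta-band PLI sits at its
finite-sample floor and AECc at its 0.5 baseline in every state, with no
significant state effect.  The MST table (`res.table2`) shows the same
dissociation for leaf fraction, tree hierarchy and maximum betweenness:
state changes move the spectrum, not the connectivity or the network
backbone.

The same pipeline is scriptable from the shell:

```sh
vigilnet simulate --seed 1 --subjects 1 --out data/
vigilnet score --in data/sim000 --eo-epochs 5 --out labels.tsv --report report.json
vigilnet spectral --in data/sim000 --out power.tsv
vigilnet connectivity --in data/sim000 --measure pli --band theta --out fc.tsv
vigilnet mst --in data/sim000 --measure pli --band theta --out mst.tsv
vigilnet study --simulate --subjects 19 --seed 1 --fc-bands theta --out results/
```

Recordings on disk are plain text: a tab-delimited channels × samples
matrix plus a JSON sidecar with sampling rate, labels, EOG index and
subject id.

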