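# cofluct

Dynamic-connectomics analysis of parcellated resting-state BOLD: edge-centre
time series (eTS) co-fluctuation dynamics, pairwise time-delay (TD) mapping,
amplitude-conditioned somatomotor–default-mode (SMN–DMN) connectivity, and
the covariate-adjusted cohort statistics built on top of them — plus a
synthetic-cohort generator with recorded ground truth so the entire pipeline
is testable without any imaging data.

The package is aimed at researchers studying temporal dysregulation in
clinical cohorts (here: psychomotor agitation in major depression, where the
agitated subgroup is defined by HAMD-17 item 9 ≥ 2), and at anyone who wants
a tested, reusable reference implementation of these estimators.

## The quantities computed

For z-scored parcel signals `z_i(t)` (population convention, denominator T):

* **Edge time series**: for each pair (i, j), `e_ij(t) = z_i(t)·z_j(t)`.
  Its time-average equals the Pearson correlation r_ij exactly.
* **RSS**: `RSS(t) = sqrt(Σ_{i<j} e_ij(t)²)` — whole-brain co-fluctuation
  amplitude per frame. Two temporal summaries are derived from its strict
  local extrema: the **mean trough-to-trough duration** (TR units; short
  duration = fast switching between brain states) and the **mean peak
  height**.
* **Time delay**: the lagged cross-covariance
  `c_ij(Δ) = (1/(T−|Δ|)) Σ_t z_i(t) z_j(t+Δ)` is evaluated on Δ = −L..L TR
  (L = 3 by default); the extremum of |c| is refined by three-point
  parabolic interpolation,
  `τ̂ = TR·[Δ_peak + (c_{peak−1} − c_{peak+1}) / (2(c_{peak−1} − 2c_peak + c_{peak+1}))]`.
  Column-averaging the antisymmetric TD matrix gives a projection map
  (positive = the parcel's signal leads the brain-wide average); averaging
  the map over SMN parcels gives the per-subject **SMN time delay**.
* **Amplitude-conditioned FC**: the SMN–DMN connection (mean Pearson r over
  all SMN×DMN pairs) recomputed on the frames with the top / bottom 10% RSS
  values — the high- and low-amplitude connectivity.
* **Cohort statistics**: OLS group contrasts adjusted for age, gender and
  education (plus HAMA total and a HAMD depression sub-dimension for the
  patient-subgroup contrast), Benjamini–Hochberg FDR within each metric's
  three-contrast family, agitation regressions on centered variables,
  17-item HAMD comparisons, and severity-regrouping control analyses.

## Worked example

One synthetic subject at study scale (214 parcels, 240 frames, TR = 2 s)
with a 1.0 s SMN lead, events every ~10 TR, and SMN–DMN coupling 0.25:

```python
from cofluct.io import RunConfig
from cofluct.pipeline import subject_metrics
from cofluct.synthetic import GroupSpec, default_partition, gen_subject_signals

part = default_partition(214)
spec = GroupSpec("demo", 1, smn_lead=1.0, inter_event_interval_mean=10.0,
                 smn_dmn_coupling=0.25)
sub = gen_subject_signals(part, t=240, tr=2.0, spec=spec, seed=7)
row = subject_metrics(sub.signals, part, RunConfig(seed=7))
```

prints (via the loop in `scripts/`-style reporting):

```
mean_trough_duration: 6.4706     # TR units between successive RSS troughs
mean_peak_height: 259.8638       # RSS units at the detected peaks
td_smn: 0.6214                   # s; positive = SMN leads (true lead 1.0 s,
                                 #    diluted by zero-lag SMN-SMN pairs)
fc_static: 0.3379                # mean SMN-DMN Pearson r, all frames
fc_high: 0.6394                  # ... over the 24 highest-RSS frames
fc_low: 0.0131                   # ... over the 24 lowest-RSS frames
n_pairs: 782                     # 34 SMN x 23 DMN parcels
```

The high/low split shows the event structure doing its work: coupling is
concentrated in high-amplitude co-fluctuation frames.

## Command-line pipeline

```bash
cofluct simulate --preset smoke --out run/bundle --seed 3
cofluct metrics  --bundle run/bundle --out run/metrics
cofluct stats    --metrics run/metrics/metrics.tsv \
                 --phenotypes run/bundle/phenotypes.csv --out run/stats
# or all three stages at once:
cofluct all --preset paper --out run --seed 3
```

Stages communicate only through files (TSV/CSV/JSON with manifests), so a
run is restartable, inspectable, and byte-reproducible for a given seed.

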