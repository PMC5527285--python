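# nucmorph

Quantification toolkit for fluorescence microscopy of the cell nucleus,
aimed at studies of nuclear dysmorphia and nuclear-envelope integrity —
for example, cells in which deregulated actomyosin contractility deforms
and transiently ruptures the nucleus.

Altered nuclear shape is a hallmark of cancer cells, and transient loss of
the nucleocytoplasmic barrier has direct consequences for genome stability.
`nucmorph` implements the measurements such studies rely on:

* **Nuclear morphometry** — per-nucleus area, perimeter, aspect ratio and
  circularity, `C = 4π·A / P²` (1 for a perfect disk, falling with
  irregularity).  Perimeters come from a sub-pixel marching-squares contour
  with arc-length smoothing, so a digitised disk scores ≈ 1 rather than the
  ≈ 0.79 that naive boundary-pixel counting produces.
* **Segmentation and phenotype calls** — nuclei are segmented from the DNA
  channel (Gaussian smoothing, Otsu-seeded hysteresis threshold, 8-connected
  labelling so thin chromatin bridges keep extruded lobes attached), then
  classified: *deformed* when circularity falls below a calibrated cutoff,
  *ruptured* when the envelope-marker rim is absent over a sufficient arc of
  the nuclear boundary.  Cohorts are summarised as fractions per class.
* **Rupture-event detection** — in dual-reporter time series (an NLS-tagged
  reporter marking the nucleoplasm, an NES-tagged reporter marking the
  cytoplasm), envelope rupture appears as a sudden collapse of the
  nuclear/cytoplasmic intensity ratio `R(t)` towards 1, followed by
  re-accumulation after resealing.  The detector finds event start
  (sudden drop below a baseline-relative threshold), end (sustained rise as
  re-import resumes), vetoes mitotic frames, cross-checks NES influx, and
  reports per-cohort event rates and mean durations.
* **Trajectory dynamics** — per-cell mean and sample variance of perimeter,
  circularity and aspect ratio over k traced timepoints; high variance marks
  dynamically deforming nuclei.
* **DNA-damage markers** — background-subtracted per-nucleus γ-H2AX-style
  mean intensity normalised to a control group, 53BP1-style focus counting
  (positive at strictly more than five foci) and cytoplasmic aggregate
  scoring (0.1–1 µm bodies outside the nucleus), all via
  Laplacian-of-Gaussian blob detection in physical units.
* **Synthetic data** — every assay has a generator with known ground truth
  (phenotype labels, injected rupture events, true spot counts), so the
  entire pipeline is verifiable without external data.

## Worked example

Simulate a barrier-assay cohort that mirrors a myosin-phosphatase-depletion
experiment — 292 cells imaged every 2 min for 4 h at an event rate
calibrated to 56 events per cohort with 15-min mean duration — and run the
detector:

```python
from nucmorph import synthetic, rupture

spec = synthetic.depleted_trace_spec(seed=1)   # 292 cells, 4 h, 2-min frames
traces, truth = synthetic.generate_reporter_traces(spec)
events = [e for t in traces for e in rupture.detect_rupture_events(t)]
summary = rupture.cohort_event_summary(traces, events)
print(f"injected events : {len(truth)}")
print(f"detected events : {summary.n_events}  ({summary.n_truncated} truncated)")
print(f"rate            : {summary.events_per_cell_hour:.4f} events/cell-hour")
print(f"mean duration   : {summary.mean_duration_min:.1f} min")
```

```
injected events : 51
detected events : 50  (1 truncated)
rate            : 0.0432 events/cell-hour
mean duration   : 15.3 min
```

For this seed the simulator injected 51 rupture events (the Poisson draw
around the calibrated expectation of 56); the detector recovered 50 of them,
one still open when the recording ended (excluded from the duration mean),
and the mean detected duration matches the 15-min event model.

The same workflow is available from the shell:

```bash
nucmorph simulate-traces --n-cells 292 --event-rate 0.04795 --seed 1 --out traces/
nucmorph detect-ruptures traces/traces.csv --out ruptures/
nucmorph compare --test chi_square --table "90,10;70,30"
```

`nucmorph run --config run.yaml` executes the full staged pipeline
(simulate → segment → classify → detect → summarise) and writes per-stage
CSV/JSON tables plus a provenance-stamped `report.json`.

## Layout

| module | contents |
| --- | --- |
| `nucmorph.shape` | circularity, contour metrics, trajectory statistics |
| `nucmorph.segmentation` | nucleus segmentation, envelope coverage, phenotype calls, cohort scoring |
| `nucmorph.rupture` | ratio traces, rupture-event detection, cohort event summaries |
| `nucmorph.damage` | nuclear intensity, normalisation, focus and aggregate counting |
| `nucmorph.synthetic` | ground-truth generators for every assay |
| `nucmorph.stats` | χ² and Welch/paired t comparisons |
| `nucmorph.pipeline` / `nucmorph.cli` | staged orchestration, YAML config, `nucmorph` command |

See `docs/methods.md` for the models, parameter choices and their
rationale, and known limitations.
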