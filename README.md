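# cardioperf

Pharmacodynamic analysis of perfused-heart contraction-frequency
recordings, as used in semi-isolated insect-heart bioassays:

* **synthetic data** — seeded generator for contraction-frequency series
  and raw densitometric traces with reversible, concentration-dependent
  bradycardia under arbitrary perfusion protocols (continuous-perfusion
  and pulse-application variants, additive/antagonistic mixtures);
* **signal processing** — beat detection on raw traces (prominence
  threshold + refractory constraint, parabolic apex interpolation) and
  binned frequency extraction;
* **per-recording metrics** — percent change against the first-minute
  baseline, per-interval slope coefficient `a = (y2 − y1)/(x2 − x1)`,
  maximal effect, effect at reporting minutes, time to half-maximal
  effect (t50) and recovery half-time (RT50), each with an
  interpolation-based and a mono-exponential-fit estimator;
* **dose–response** — Hill/4PL least-squares fitting on log-dose with
  deterministic multi-start (IC50, slope, asymptotes) and closed-form
  inversion (EC75);
* **interaction analysis** — toxic index `TI = E_mix/(E_a + E_b)` and
  toxic units `TU = E_mix/E_a + E_mix/E_b` with
  antagonism/additivity/synergism classification against the additive
  expectation.

## CLI

```sh
cardioperf fixtures  --out fixtures/                      # worked-example files
cardioperf simulate  --protocol proto.yaml --params params.yaml \
                     --seed 1 --out rec.csv --trace-out trace.csv
cardioperf beats     --trace trace.csv --beats-out beats.csv \
                     --recording-out rec.csv
cardioperf analyze   --recordings rec.csv --protocol proto.yaml --out summary.csv
cardioperf doseresponse --table dose_effect.csv --e-bottom -100 --out fit.csv
cardioperf interact  --arm-a ver.csv --arm-b sol.csv --arm-mix mix.csv \
                     --protocol proto.yaml --out interactions.csv
cardioperf run       --config experiment.yaml --out results/ --seed 1
```

Protocols are flat YAML (ordered, contiguous perfusion segments covering
`[0, total_duration]`, optional bolus pulses); recordings are delimited
text (tidy `time_min,freq[,preparation_id]` or wide matrices) with
`# key: value` metadata headers.  `cardioperf run` drives a whole
experiment (simulated arms, metrics, dose–response fits, interaction
report) from one config file and writes a manifest whose hash is
reproducible under a fixed seed.

## Layout

```
src/cardioperf/
  core_io.py            domain types, CSV/YAML readers & writers, reports
  synthetic.py          PD simulator (frequency series, raw traces)
  signal_processing.py  beat detection, frequency binning
  pd_metrics.py         percent change, slopes, t50/RT50, Hill fitting
  interaction.py        toxic index / toxic units, classification
  pipeline.py           config-driven runs, fixtures, manifests
  cli.py                click CLI
tests/                  unit, property and acceptance suites
scripts/acceptance.py   acceptance-target report
```
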