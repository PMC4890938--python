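# anonprev

Contamination-aware drug-prevalence estimation for sequentially collected
anonymous urine samples.

## The problem

Hidden automatic samplers installed on urinals can collect individual urine
samples blindly and anonymously — a way to measure how common drug use is in
a population (e.g. high-altitude climbers passing through mountain huts)
without the selection bias of asking for consent. The price of the hardware
is a statistical nuisance: consecutive samples are drawn through shared
suction tubing that retains a few millilitres of residual liquid (≈4 ml
against a mean 67 ml draw), so a drug detected in one sample can reappear,
diluted, in the next slot of the same 24-slot cassette.

The conservative remedy implemented here never tries to subtract the
carryover; it discards what it cannot distinguish. Per substance, a sample's
status within its cassette sequence is

* **negative** — nothing detected (concentration 0 or below the reporting
  limit);
* **contaminated** — detected, but the concentration is less than or equal
  to the one measured in the previous sample of the same cassette (slot 1 is
  never contaminated: the tube is rinsed between cassettes);
* **positive** — detected and impossible to explain as carryover.

The adjusted prevalence of substance *s* and its 95% confidence interval are

```
p̂_s = n_positive / (n_total − n_contaminated)          (× 100%)
CI   = p̂ ± z_0.975 · sqrt(p̂ (1 − p̂) / (n_total − n_contaminated))
```

the large-sample normal (Wald) approximation, clipped to [0, 100]. A whole
sample is positive if any substance is positive (regardless of other
substances possibly contaminating it), negative if nothing was detected at
all, contaminated otherwise.

The package provides, as importable modules with a thin CLI on top:

* `anonprev.classify` — the sequential rule, sample-level aggregation, and
  metabolite collapsing (co-detected pairs such as prednisone→prednisolone
  count once, under the primary name);
* `anonprev.prevalence` — adjusted prevalences with Wald CIs at substance,
  class and sample level; drug-combination tables; concentration summaries;
* `anonprev.precision` — a-priori CI half-width of a planned campaign and
  its inverse (minimal n for a target half-width);
* `anonprev.simulate` — a generative model of the sampler (cassettes,
  log-normal urinary concentrations, residual-volume carryover, detection
  limits, repeat visitors) plus the two-sample titration experiment;
* `anonprev.experiments` — Monte-Carlo recovery experiments comparing the
  conservative (adjusted), naive and oracle estimators against latent truth;
* `anonprev.fixtures` — synthetic reconstructions of the published summary
  tables used by the tests.

The `analysis/` directory holds numbered drivers that run the whole
pipeline on a simulated campaign and write their tables under `results/`.

## Worked example

```python
import anonprev as ap

# 430-sample two-hut campaign with the volumetric carryover fraction 4/71
config = ap.mont_blanc_study_config(seed=2013)
dataset, truth = ap.simulate_study(config)

substance_status, sample_status = ap.classify_dataset(dataset, config.panel)
for name, est in ap.sample_level_rates(sample_status).items():
    pct, low, high = est.rounded()
    print(f"{name:>12}: {est.n_positive:3d} samples, {pct}% ({low}-{high}%)")

est = ap.substance_prevalence(substance_status, "acetazolamide")
print("acetazolamide:", est.rounded())
```

prints

```
    positive: 160 samples, 37.2% (32.6-41.8%)
    negative: 183 samples, 42.6% (37.9-47.2%)
contaminated:  87 samples, 20.2% (16.4-24.0%)
acetazolamide: (20.7, 16.4, 25.0)
```

Of 430 simulated samples, 160 contain at least one substance classified
positive; 87 are discarded as possibly contaminated. The adjusted
acetazolamide prevalence, 20.7% (16.4–25.0%), recovers the latent use
probability of 20.6% built into the generator even though 92 of the 430
samples were contaminated for that substance. The same pipeline is
available from the shell:

```sh
anonprev simulate --seed 2013 --out out/sim
anonprev classify out/sim/samples.csv --out out/cls
anonprev prevalence out/cls/substance_status.csv --out out/prev
anonprev precision -n 400 -p 0.4
```

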