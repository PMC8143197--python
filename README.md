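# tautrace

Longitudinal single-cell analysis of seeded tau-biosensor aggregation and
neuronal survival in live-imaging experiments — together with a fully
ground-truthed synthetic microscopy simulator that makes every stage of the
analysis testable without any imaging data.

## The problem

Human iPSC-derived neurons expressing a tau repeat-domain (TauRD) YFP
biosensor do not aggregate it spontaneously; adding brain-lysate-derived
misfolded tau "seeds" to the medium templates aggregation in a subset of
neurons. Imaging two channels (the YFP reporter and a far-red vital
nuclear dye that flashes brightly on cell lysis) every 2 h for 7 d yields,
per neuron: the time its soma first bears a persistent aggregate (onset),
the time it dies (nuclear flash), or the time it is censored (leaves the
field of view or survives to the end). The scientific questions are then
survival-analytic:

- Do aggregate-bearing neurons die faster than aggregate-free neighbours
  in the same well? (Kaplan–Meier, log-rank, Cox with Efron ties.)
- Does a disease mutation accelerate aggregation, post-aggregation death,
  or both? (Cumulative-onset curves vs post-onset-clock survival — the
  dissociation between kinetics and toxicity.)
- Does seeding scale with lysate dose? (Neurite punctum counts over time,
  baseline-subtracted, trapezoidal AUC, two-way line x dose ANOVA.)
- Do aggregate morphologies ("strains": Ordered condensations, Disordered
  puncta, nuclear Speckles, Other) differ in frequency and toxicity?

`tautrace` implements the full pipeline: punctum detection with local-
background thresholding and size gating (0.1–4 µm, >10,000 gray levels
above local background), single-cell tracking with nuclear-flash death
calling and censoring, the Initial+End+Survival cell-class grammar
(e.g. `O+A+D`), the survival/seeding statistics, and rule-based strain
classification — plus a simulator whose exponential event clocks make all
of it checkable against closed forms.

## Worked example

```python
from tautrace import PipelineConfig, run_pipeline
from tautrace.config import SimulationConfig
from tautrace.pipeline import Condition

config = PipelineConfig(
    base=SimulationConfig(n_cells_per_well=40, image_size_px=224),
    conditions=[
        Condition("control", "seed", 10.0, 2),
        Condition("mutant", "seed", 10.0, 2),
        Condition("control", "none", 0.0, 1),
        Condition("mutant", "none", 0.0, 1),
    ],
    seed=1,
)
bundle = run_pipeline(config, outdir="report")
r = bundle.results
print(len(bundle.event_table), "tracked neurons")
print("early aggregators vs others:", r["early_vs_others"].p)
print("onset by line:", r["onset_by_line"].p)
print("post-onset survival by line:", r["post_onset_by_line"].p)
```

Output from this exact configuration:

```
239 tracked neurons
early aggregators vs others: 4.857407659568814e-08
onset by line: 0.022902230125551783
post-onset survival by line: 0.4033421522343945
```

Reading: neurons that formed soma aggregates within 48 h of seed addition
die much faster than their neighbours (p ≈ 5e-8); the simulated mutant
line aggregates earlier (p ≈ 0.02); but once an aggregate has formed, the
two lines survive equally long (p ≈ 0.4) — reduced average survival in the
mutant is explained by accelerated aggregation, not by faster
post-aggregation death. The accompanying Cox model (in
`bundle.results["cox"]`) shows the same thing as hazard ratios: not
having an early aggregate is protective, line identity is not.

`run_pipeline` also writes `event_table.csv`, `seed_counts.csv`, KM/Cox/
ANOVA tables, morphology calls, a `summary.md` and a reproducibility
manifest (config hash + master seed). The same pipeline is available from
the shell:

```bash
tautrace run --seed 1 --out report/        # full demo pipeline
tautrace simulate --seed 1 --out sim/      # TIFF stacks + ground truth
tautrace validate --report report/         # score tracking vs ground truth
```

## Layout

| module | contents |
| --- | --- |
| `tautrace.config` | `SimulationConfig`: hazards, doses, rendering, seeds |
| `tautrace.simulate` | two-channel renderer, ground truth, event-level simulation |
| `tautrace.detect` | local background, neurite-seed puncta, soma aggregates, neurite area |
| `tautrace.track` | linking, death/onset calling, censoring, cell classes |
| `tautrace.survival` | KM, log-rank (+permutation), Cox, onset curves, AUC/ANOVA/slopes, correlations |
| `tautrace.morphology` | strain features, rule-based classification, strain statistics |
| `tautrace.pipeline` / `tautrace.cli` | orchestration, reports, `tautrace` command |

See `docs/methods.md` for the model, parameter choices, and limitations.
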