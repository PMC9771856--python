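# polyrep

Stochastic simulation of DNA replication initiation in a band/interband
(polytene-style) chromosome fragment.

A chromosome fragment is modeled as an ordered run of segments — decondensed
interbands, gray bands of two compaction classes, and highly compacted black
flanking bands — each with a DNA content (kbp) and an axial width, linked by a
piecewise-linear genomic↔axial coordinate map. On each of N identical
chromatids exactly one replication origin fires at a random interband position,
either synchronously or at a time uniform over a 10/30/60-min window, and
launches two divergent forks whose trajectories through the compaction profile
are computed in closed form. Snapshot "dot" patterns (active fork positions),
axial density profiles, summary statistics (edge concentration, fraction
initiated), a synthetic-microscopy noise model (detection dropout + axial
localization jitter) and a scenario-recovery classifier sit on top.

The built-in default fragment is a 52-kbp initiation zone — six 2-kbp
interbands alternating with four 5-kbp gray bands and one 20-kbp middle gray
band — between two 100-kbp black bands, simulated over N = 1024 chromatids
with 2 kbp/min forks.

## Library quick start

```python
import polyrep as pr

model = pr.build_paper_int(black_flank_kbp=100.0)        # 13-segment fragment
scenario = pr.InitiationScenario.uniform_window(30.0)    # or .synchronous()
records = pr.simulate(model, scenario, n_chromatids=1024, seed=1)

snap = pr.snapshot(records, model, t=5.0)                # active fork dots
profile = pr.density_profile(snap, model, bin_width=0.1)
pr.edge_concentration_index(snap, model, margin_kbp=75.0)

best, distances = pr.classify_scenario(
    [profile], list(pr.paper_scenarios()), model, n_reference_sims=4, seed=2
)
```

Two fork-speed interpretations are available on the model
(`speed_mode="dna"`, the default: constant genomic speed everywhere;
`speed_mode="stated"`: axial speed fixed per segment kind at 1, 1/5, 1/20,
1/50 of the interband speed). A brute-force time-stepping oracle
(`pr.fork_position_stepper`) cross-checks the closed-form dynamics.

## CLI

```sh
polyrep make-model --out model.tsv                 # write/validate segment table
polyrep simulate --out-dir run/ --seed 1           # records/snapshots/profiles TSVs
polyrep profile --snapshots run/snapshots.tsv --out profiles.tsv
polyrep classify --observed run/profiles.tsv --out report.tsv
```

`simulate` accepts a YAML config (`--config`) whose keys mirror the flags; all
times are minutes, all genomic lengths kbp, and identical configs reproduce
outputs byte-for-byte.

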