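# vocalnet

Semi-automated analysis of **group vocal networks** from multichannel
aviary recordings.

Studying who-responds-to-whom in a group of songbirds requires knowing,
for hours of recording, *which* bird vocalized *when*. `vocalnet` targets
the setup where each group member sits in its own cage — for example four
zebra finches at the corners of a 1 m square — with one microphone above
each cage, all channels recorded synchronously. Because every microphone
hears every bird, the package:

1. **detects** sound events per channel on a high-pass-filtered
   short-time energy envelope (threshold peaks, grow each event while the
   envelope stays ≥ 10% of its peak, merge overlaps);
2. **attributes** each physical call to its emitter by collapsing its
   cross-channel copies, exploiting that the emitter's own microphone
   receives the highest energy and the earliest onset (energy- and
   delay-gated greedy clustering);
3. **filters** non-vocal noise (cage knocks, wing flutter) with a random
   forest on fixed-size 50 ms spectrogram features restricted to
   500–6000 Hz;
4. **quantifies** the group's dynamics.

From the attributed event stream it computes:

- **vocal activity**: overall rate, per-bird counts, and vocal *bursts* —
  periods where the rate in 60 s windows (30 s step) exceeds 110% of the
  session mean — summarized by six metrics (count, rate in bursts, mean
  and total duration, inter-burst interval, latency to first burst);
- **synchrony networks**: per dyad, the zero-lag Pearson
  cross-correlation of the two birds' 500 ms-binned binary vocal signals,

  `cc = mean[(S₁ − mean S₁)(S₂ − mean S₂)] / (σ(S₁)·σ(S₂))`,

  which is independent of the total number of vocalizations;
- **turn-taking networks**: the caller sequence is modeled as a
  first-order Markov chain; the matrix entry (i, j) is the probability
  that bird j calls right after bird i, and the undirected dyad weight is
  `max(p(i→j), p(j→i))`.

A ground-truthed **synthetic-data generator** renders multichannel
sessions for the same geometry (parametric tet- and distance-call-like
sounds, 1/distance attenuation, physical delays, cage-click noise), so
every stage is testable end-to-end without any recordings.

## Worked example

Simulate a 3-minute session of four birds (0.25 calls/s each, uniform
turn-taking) and run the full pipeline:

```python
from vocalnet import SimulationConfig, simulate_session, run_pipeline
from vocalnet.synthetic_data import save_simulation

config = SimulationConfig(seed=11, duration_s=180.0, call_rate_hz=0.25)
session, truth = simulate_session(config)          # 191 ground-truth calls
save_simulation(session, truth, "demo/session")    # 4 WAVs + truth CSV

run_pipeline({"seed": 11, "session": {"audio": {
    f"bird{i}": f"demo/session/bird{i}.wav" for i in range(1, 5)}}},
    "demo/out")
```

`demo/out/attributed_events.csv` starts:

```
bird_id   start_s     end_s  duration_s  peak_energy
bird3    3.213152  3.365079    0.151927      507.459
bird2    5.158730  5.308390    0.149660     2181.730
bird4    5.614512  5.902494    0.287982      838.799
```

i.e. bird3 called at 3.21 s for 152 ms; onsets agree with the generator's
ground truth to a few milliseconds. Per-bird counts
(`bird1: 51, bird2: 47, bird3: 30, bird4: 56`) partition the 184
attributed events, and `burst_metrics.csv` reports one burst:

```
n_bursts,mean_rate_in_bursts,mean_burst_duration_s,total_burst_duration_s,mean_interburst_interval_s,latency_to_first_burst_s
1,1.133333,60.0,60.0,,30.0
```

one 60 s high-activity period starting 30 s in, at 1.13 voc/s against a
session mean of ~1.0 voc/s (the empty inter-burst field is the undefined
flag: there is only one burst). The two networks land in
`cc_network.csv` and `max_transition_network.csv`:

```
source,target,weight,weight_type
bird2,bird4,0.0285564466112,cross_correlation
...
bird2,bird4,0.347826086957,max_transition
```

With a uniform coupling matrix all six max-transition weights hover near
0.25–0.35 and the cross-correlations near 0, as they should for
independent callers; correlated calling raises the corresponding dyads.

The same stages are available from a shell via the `vocalnet` CLI
(`simulate`, `detect`, `attribute`, `train-classifier`, `filter`,
`activity`, `network`, `run`).

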