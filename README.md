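# p300baseline

Baseline-correction strategies for P300 detection under **continuous 400 ms
oddball stimulation**, with a seeded synthetic-EEG simulator so the whole
pipeline is testable without recordings.

P300 spellers and related assistive brain–computer interfaces flash stimuli
every 200–400 ms to keep selections fast. At that pace a new stimulus arrives
before the EEG has settled from the previous one, so the classic ERP recipe —
epoch the EEG around each flash, subtract a pre-stimulus *baseline reference*,
average per stimulus, and pick the stimulus whose averaged waveform has the
largest positive peak near 300 ms — depends critically on *which* pre-stimulus
quantity serves as the reference. This package implements and compares the
three candidates:

1. **Single-time-point**: the amplitude at one instant, e.g. −100 ms
   (`correct_single_point`);
2. **Time-range-averaged**: the mean over a pre-stimulus interval, e.g.
   [−200, 0) ms (`correct_range_average`);
3. **Multi-time-point voting**: every instant t_b on a 1 ms grid over
   [−200, 0) ms serves as a reference in turn. For each t_b the provisional
   target is

   i(t_b) = argmax_i max_{t ∈ [300, 370]} [ S_i(t) − S_i(t_b) ],

   where S_i is the averaged waveform of stimulus i; the votes
   C_i = Σ_{t_b} δ(i(t_b), i) are tallied over the 200 grid points and the
   final call is i\* = argmax_i C_i (`classify_multi_point`).

Around the classifiers sit the standard pipeline stages (0.05 Hz zero-phase
Butterworth high-pass, −1000…+500 ms epochs, ±100 µV artifact rejection), the
characterisation sweeps (baseline point, range end, range start, detection
window width, non-target/target amplitude-ratio envelopes), paired Wilcoxon
signed-rank comparisons with Holm adjustment and effect size r = |Z|/√n, and
an oddball-session generator that emulates the design: 9 stimuli, 400 ms ISI,
no immediate repeats, 100 presentations each, 10 s rest every 36 flashes, a
~10 Hz narrowband background rhythm, 1/f broadband noise, a 5 µV Gaussian
P300 bump after attended flashes, plus optional slow drift and blinks.

## Worked example

```python
from p300baseline import (SessionSpec, NoiseModel, generate_session,
                          prepare_epochs, classify_multi_point,
                          average_epochs, recover_bump)

rec, events, truth = generate_session(SessionSpec(), NoiseModel(), seed=0)
epochs = prepare_epochs(rec, events)     # filter -> epoch -> reject

for n in (10, 40, 100):
    res = classify_multi_point(epochs, n_per_label=n)
    top = sorted(res.vote_counts.items(), key=lambda kv: -kv[1])[:3]
    print(f"n={n:3d}  final={res.final_label}  correct={res.correct}  top votes={top}")

print("recovered bump:", recover_bump(average_epochs(epochs, 100), NoiseModel()))
```

prints

```
n= 10  final=3  correct=True  top votes=[(3, 101), (9, 72), (1, 19)]
n= 40  final=3  correct=True  top votes=[(3, 150), (9, 39), (1, 4)]
n=100  final=3  correct=True  top votes=[(3, 200), (1, 0), (2, 0)]
recovered bump: (328.0, 5.636889016067597)
```

The attended stimulus was 3. At 10-epoch averaging the background rhythm
still leaks votes to competitors (101 of 200 grid points vote correctly); by
100 averages the vote is unanimous. The template fit recovers the injected
5 µV / 330 ms bump from the averaged target waveform to within 0.7 µV and
2 ms.

The same run is available from the shell:

```bash
p300 simulate --out-dir session --seed 0
p300 detect session/recording.csv session/events.tsv --method multi --n-average 40
p300 sweep  session/recording.csv session/events.tsv --kind point --n-average 40 --out sweep.tsv
```

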