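# vocrecall

Tools for studying discourse recall under cochlear-implant-simulated
(noise-band vocoded) speech with self-paced listening: the vocoder
itself, stimulus segmentation and counterbalanced design construction,
propositional scoring of free-recall transcripts at three semantic
hierarchy levels, a calibrated synthetic-data generator, and the
mixed-effects analysis pipeline.

## Who this is for

Hearing scientists and psycholinguists running (or re-analyzing)
discourse-recall experiments in which passages are presented clear or
vocoded, continuously or in listener-paced segments, and recall is
scored as the proportion of propositions reproduced at each level of
the semantic hierarchy (main ideas > mid-level information > details —
the classic "levels effect"). Because raw data from such studies are
rarely shareable, the package includes a generator that emulates the
full statistical structure of a 24-participant × 8-passage
2 (format) × 2 (clarity) × 2 (predictability) within-subject design, so
every stage of the pipeline is testable end to end.

## The core pieces

**Vocoder.** 6-channel (configurable) noise-band vocoding: 80–8000 Hz
split into logarithmically spaced bands with 3rd-order Butterworth
band-passes (18 dB/octave), per-band envelopes via half-wave
rectification + 300 Hz low-pass, envelopes modulating band-limited
white-noise carriers, output RMS-matched to the input.

**Scoring.** Propositions are predicate–argument units that may take
other propositions as arguments; roots are main ideas, propositions
referencing a main are mid-level, the rest details. Binary credit with
an explicit synonym lexicon; order-free matching of lemmatized
transcripts.

**Generator.** A linear-probability model on the percentage scale whose
cell means are built so that each marginal contrast of the balanced
design *equals* its calibration parameter: predictability +7.85 pp,
main−mid +9.78 pp, mid−detail +5.61 pp, self-paced−continuous
+6.83 pp, clear−vocoded +4.78 pp, with the hierarchy slope attenuated
(×0.55) under low predictability. Participant/item intercepts, an
item-by-level slope, binomial trial noise, R-span-correlated
participant effects, and lognormal pauses (mean 2.43 s, SD 2.71 s)
coupled to recall between and within participants.

**Analysis.** Linear mixed models (statsmodels MixedLM, ML) with
participant and item intercepts plus an item-by-level random slope;
reverse selection over interactions; likelihood-ratio tests with the
df bookkeeping that removes a main effect together with its retained
interactions; raw-cell-mean marginal effects with participant-bootstrap
CIs; hierarchy-slope contrasts; pause and covariate analyses.

## Worked example

```python
import vocrecall as vr

ds = vr.simulate_dataset(n_participants=24, seed=1)
table = ds.cell_table()

for factor in ("predictability", "format", "clarity"):
    me = vr.marginal_effect(table, factor, n_boot=200, seed=0)
    print(f"{factor:>15}: {me.estimate:+.2f} pp  (95% CI {me.ci[0]:+.2f} to {me.ci[1]:+.2f})")
for pred in ("high", "low"):
    print(f"hierarchy slope ({pred}): {vr.hierarchy_slope(table, predictability=pred):.2f} pp/level")

spec = vr.ModelSpec(("hierarchy", "clarity", "format", "predictability",
                     "hierarchy:predictability"))
for predictor in ("hierarchy", "clarity", "format", "predictability"):
    r = vr.lrt(table, spec, predictor)
    print(f"LRT {predictor:>15}: chi2({r.df}) = {r.chisq:6.2f}, p = {r.p:.4g}")
```

prints

```
 predictability: +16.06 pp  (95% CI +14.39 to +17.74)
         format: +7.89 pp  (95% CI +4.71 to +10.98)
        clarity: +3.26 pp  (95% CI -0.11 to +6.51)
hierarchy slope (high): 11.72 pp/level
hierarchy slope (low): 6.09 pp/level
LRT       hierarchy: chi2(4) =  36.00, p = 2.891e-07
LRT         clarity: chi2(1) =   9.22, p = 0.002394
LRT          format: chi2(1) =  51.84, p = 6.027e-13
LRT  predictability: chi2(3) =  23.79, p = 2.764e-05
```

Reading this: the format and clarity estimates sit near their
generating values (+6.83, +4.78); the predictability estimate is far
from its +7.85 truth in this *single* dataset because predictability is
carried by only 4 + 4 passages — item sampling scatters it by ≈ 3.8 pp
per dataset (and the participant-bootstrap CI does not cover item
uncertainty). Averaged over replicates it is unbiased, which is what
the recovery checks below verify. The hierarchy slope is visibly
shallower for low- than high-predictability passages (the generator's
×0.55 attenuation), and the LRT df show the Table-1-style bookkeeping
(hierarchy 2 + 2 df, predictability 1 + 2 df with the interaction
retained).

The same stages are scriptable from the shell:

```sh
vocrecall vocode --in clear.wav --out vocoded.wav --channels 6 --seed 1
vocrecall simulate --n-participants 24 --seed 1 --out-dir sim/
vocrecall analyze --trials sim/trials.csv --pauses sim/pauses.csv \
    --participants sim/participants.csv --out-dir results/
```

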