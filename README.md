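# larvaquant

Quantification pipelines for *Drosophila* muscle-identity studies: larval
crawling kinematics from spine-tracking tables, nascent-transcript FISH
intensity ratios from two-channel image stacks, and per-segment muscle
phenotype proportion tallies — each paired with a ground-truth-known
synthetic data generator so every measurement can be validated by
parameter recovery.

## Who this is for

Groups analysing FIM/FIMTrack-style larval locomotion recordings or
smFISH quantifications of muscle lineage transcription (e.g. *collier*
regulatory mutants with DA3→DA2 muscle transformations and branched
muscles), who want the bespoke measurements of such studies as tested,
reusable, scriptable components instead of one-off analysis code.

## The measurements

**Crawling kinematics.** A tracker provides five spine points
p₁…p₅(t) per larva (head to tail, mm, 5 frames/s for 20 s). The spine
length L(t) = Σᵢ |pᵢ₊₁ − pᵢ| oscillates once per peristaltic
contraction; its smoothed derivative dL/dt oscillates around zero, and
successive positive-going zero crossings (sub-frame interpolated)
delimit peristalsis cycles. Per cycle *j*: stride length
Sⱼ = |p₃(tⱼ₊₁) − p₃(tⱼ)| (net centroid displacement) and stride
duration Tⱼ = tⱼ₊₁ − tⱼ. The walking rate v is the mean per-frame
centroid displacement rate over the whole record. All three are averaged
per larva; genotypes are compared with an OLS linear model (genotype
fixed effect, larva as the statistical unit).

**FISH ratio.** Per two-channel z-stack: sum-slices projection per
channel, per-channel percentile threshold with soft background
subtraction, then the ratio R = I_col / I_nau of integrated intensities
inside each nuclear ROI — the nascent *collier* transcription level with
*nautilus* as internal reference, one focus per active nucleus. Group
means ± SEM, unpaired t-tests.

**Phenotype tallies.** Per-segment categorical calls (normal DA3 /
branched / DA3→DA2 transformed / absent) are tallied per genotype into
proportions with Wilson 95% intervals, at segment level and averaged per
embryo.

The packaged YAML presets (`larvaquant/configs/`) carry the published
group conditions (cohort sizes, generating means, noise levels) per
genotype; `larvaquant.study` re-runs each condition end to end.

## Worked example

```python
import larvaquant as lq
from larvaquant.presets import kinematic_preset

ps = kinematic_preset("kin_control")          # published control condition
tracks, meta = lq.simulate_cohort(25, ps.params, seed=11, genotype="control")
per_larva, per_cycle = lq.analyze_cohort(tracks)
print(per_larva.head(3).round(3))
```

```
   larva_id genotype  walking_rate  stride_length_mean  stride_duration_mean  n_cycles
control_000  control         1.226               1.307                 1.082        16
control_001  control         1.239               1.308                 1.086        16
control_002  control         1.220               1.274                 1.096        17
```

Cohort means ± SEM over the 25 simulated larvae (405 detected cycles):

```
walking_rate:          1.138 +/- 0.014   (generating value 1.15 mm/s)
stride_length_mean:    1.177 +/- 0.015   (generating value 1.17 mm)
stride_duration_mean:  1.103 +/- 0.006   (generating value 1.09 s)
```

Each pipeline-recovered mean lies within two SEM of the value the
generator was told to produce — the package's core validation pattern.

The same flows are available from the shell:

```sh
larvaquant simulate-tracks --preset kin_control --n 25 --seed 11 \
    --tracks-out tracks.csv --meta-out meta.csv
larvaquant analyze-tracks --tracks tracks.csv --meta meta.csv --out metrics.csv
larvaquant report --metrics metrics.csv --out report/ --reference control
larvaquant simulate-fish --preset fish_wt_fc --seed 7 \
    --stack-out s.tif --mask-out m.tif --truth-out truth.csv
larvaquant quantify-fish --stack s.tif --mask m.tif --out measurements.csv
```

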