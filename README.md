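# occupre

Comparative ChIP-seq occupancy analysis at Polycomb Response Elements
(PREs) — and, more generally, at any fixed catalog of ~1 kb regulatory
elements assayed in two genotypes.

Polycomb Repressive Complexes PRC1 and PRC2 are recruited to PREs, and a
central question in the field is how far the recruitment of one complex
depends on the other. The experimental design this package analyzes is:
ChIP-seq of a PRC2 (or PRC1) subunit in a control cell line and in a line
ablated for the other complex, with replicate libraries and matched
chromatin-input controls. `occupre` quantifies how much binding each
element retains in the mutant, classifies elements by their recruitment
dependence, and measures whether binding is lost preferentially at a
distance from binding-site summits — the signature of H3K27me3-mediated
looping contacts between PRE-anchored complexes and surrounding
chromatin.

## The statistics at the core

**Element score.** For each library, an element's occupancy score is the
mean read density of the 6 consecutive positions with the highest counts
inside its 1 kb interval, depth-normalized to reads per million:

```
score = max_i  (x_i + ... + x_{i+5}) / 6  ·  10^6 / D
```

Replicate scores (gated at Pearson r > 0.90) are averaged per genotype.

**Relative difference and classification.** Mutant (m) and control (c)
genotype means are contrasted by the symmetric relative difference and
the companion ratio,

```
RD = 2 (m − c) / (m + c)  ∈ (−2, 2),        ratio = m / c,
```

and elements are classified as *dependent* (RD < −1.0), *independent*
(RD > −0.5) or *intermediate*. The catalog is first filtered for elements
overlapping genotype-specific deletions and for weak control signal
(lower 30% of the score dynamic range). The ChIP RD distribution is
compared with the input RD distribution by a two-sided Wilcoxon rank-sum
test.

**Peaks and profiles.** Peaks are clusters of coordinates exceeding three
standard deviations above the genomic mean, merged across gaps of at most
500 bp; the summit is the center of the best 6-coordinate window, and
peaks with no neighbor within 10 kb are *isolated*. Occupancy around
isolated summits is averaged in 100 bp bins over ±5 kb, loess-smoothed
(span 0.1, locally quadratic), and the two genotypes are differenced at
50 evenly spaced offsets (loess span 0.2) after scaling each curve to its
own summit excess over a randomized genomic background (999 random 100 bp
bins outside bound regions). Preferential distal loss shows up as a
difference whose magnitude at 2–5 kb exceeds that at the summit.

Because the study's sequencing data are not public, the package ships a
first-class synthetic coverage generator (`occupre.simulate`) with known
per-element ground truth — class labels, amplitudes, tail parameters —
against which the whole pipeline is validated.

## Worked example

```python
from occupre import PREDependenceModel, PeakProfileModel
from occupre.simulate import SimulationConfig, simulate_tracks

sim = simulate_tracks(SimulationConfig(seed=1))   # 60 elements, 2 Mb, 2 reps
res = PREDependenceModel(sim.catalog, sim.chip_tracks, sim.input_tracks).fit()
print(res.summary())
```

```
Element dependence analysis
====================================================
catalog size:        60
classified:          23   (filtered out: 37)
scoring window:      6 consecutive positions
RD formula:          RD = 2*(mutant - control)/(mutant + control)
class thresholds:    dependent RD < -1.0, independent RD > -0.5

class counts:
  dependent         6   (26.1%)
  intermediate      9   (39.1%)
  independent       8   (34.8%)

fraction independent (RD > -0.5): 0.348
median RD:           -0.699
median ratio:        0.482

replicate concordance (Pearson r):
  control_rep1:control_rep2    0.9794
  mutant_rep1:mutant_rep2      0.9849

ChIP RD vs input RD (Wilcoxon rank sum, two-sided):
  median ChIP RD  = -0.699
  median input RD = +0.080
  W = 14.0, p = 3.967e-08
```

Reading the output: 37 of the 60 simulated elements are filtered (weak
control signal under the dynamic-range rule), and every surviving element
receives its true class. The classified median ratio of 0.48 says the
typical element retains about half its occupancy in the mutant, and the
tiny Wilcoxon p-value confirms the ChIP losses far exceed input
variability. The profile contrast runs the same way:

```python
prof = PeakProfileModel(sim.chip_tracks["control"], sim.chip_tracks["mutant"]).fit(seed=1)
print(prof.summary())     # 60 peaks, all isolated; |diff| at summit vs 2-5 kb
prof.plot()               # fitted curves, background lines, 95% bands
```

A command-line interface mirrors the library
(`occupre simulate | coverage | score | classify | callpeaks | profile |
report`); `occupre report --config analysis.yaml` runs everything and
writes the score table, class summary JSON, peak BED, profile matrices
and fitted curves into one reproducible bundle.

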