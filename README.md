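# txpause

Stochastic simulation and statistical detection of **sequence-dependent
transcriptional pause sites** from RNA and protein number time series.

In prokaryotes, RNA polymerases pause during elongation: short
"ubiquitous" pauses (~3 s) occur anywhere, while long pauses (tens of
seconds, e.g. the *his*-pause: mean 47 s, efficiency up to 0.8) occur
at specific sequences and shape expression noise and RNAP traffic.
Identifying pause-prone sequences currently requires laborious in vitro
single-molecule assays.  `txpause` implements, end to end, a method
stack for finding them *in silico* from the kind of data modern
single-molecule microscopy produces in vivo: time series of RNA and
protein counts for a gene.

For: systems/computational biologists studying transcription kinetics,
and methodologists who need a realistic nucleotide-resolution gene
expression simulator with exact delayed-SSA semantics.

## What it does

1. **Simulate** — a delayed stochastic simulation algorithm (exact SSA
   plus a waiting list for arbitrarily distributed delays) drives a
   nucleotide/codon-resolution model of one gene: promoter binding with
   a normally distributed open-complex delay, stepwise elongation of
   25-nt-footprint RNAPs with pausing, collisions, arrests, editing,
   backstepping, premature termination; co-transcriptional translation
   by 31-nt-footprint ribosomes with codon-specific rates, drop-off and
   trans-translation; folding delays and first-order degradation.  A
   pause site of efficiency ε at nucleotide n enters the paused state at

       k_p^n = k_a(n) · (1/ε − 1)^(−1),

   so that k_p^n / (k_p^n + k_a(n)) = ε, and releases exponentially
   with mean τ_p^n.  A compiled (numba) event-driven kernel runs
   ~5–8 × 10³ simulated seconds per wall second at 1 Hz sampling.

2. **Detect** — given F×L count matrices from two genes/models, draw S
   windowed means (window = ΔL+1 samples, uniformly placed), compare the
   profiles with Welch's t-test, repeat N times; a median p < α flags a
   kinetic difference (e.g. a pause site).

3. **Classify** — compute 10 features per replicate (lag-weighted
   mean/SD of autocorrelations of RNA and protein, of cross-correlations
   of (RNA, protein) and (protein, cumulative protein), and mean/SD of
   RNA decay-run lengths; K = 300 lags), z-transform, cluster with
   Manhattan distance + McQuitty linkage, and estimate a random-forest
   misclassification error over bootstrap resamples.

4. **Locate** — treat the pause position θ as a parameter: simulate
   reference data along a grid of θ, score each feature by the overlap
   coefficient p_j(θ) = ∫ min{f_j, g_j} dx of Gaussian KDEs of observed
   vs simulated feature values, profile the approximate log-likelihood
   log L(θ) = S·Σ_j log p_j(θ), and bootstrap the argmax for an SD and
   95% CI of the pause position.

## Worked example

```python
import numpy as np
from txpause import make_model, simulate_expression

template, params = make_model("B", rng=np.random.default_rng(0))
res = simulate_expression(template, params, t_end=30_000.0, seed=1)
print(res.rna[5000:].mean(), res.rna_completed[5000:].mean())
```

Running `python examples/01_simulate_gene.py` prints:

```
gene: 1000 nt, 333 codons, pause site at 500 (eff 0.8, mean 47.0 s)
mean RNA (nascent+completed): 1.514
mean completed mRNA:          0.480
mean protein number:          59.4
proteins produced in total:   5125
```

The completed-mRNA mean (~0.5) is promoter-limited production (≈0.0125
transcripts/s) times the 40 s mRNA lifetime, and is nearly the same
with or without the pause.  The transcripts-present count (RNA counted
from promoter clearance, as single-molecule tagging sees it) includes
the pause's residence time and rises to ~1.5 — that shift is the
detection signal.  `python examples/02_detect_pause.py` then prints:

```
A vs B: median p = 2.74e-05, 100% of 50 p-values < 0.05
A vs A: median p = 0.547 (no false detection)
```

i.e. the pause-carrying gene separates from the pause-free control
while comparing two pause-free data sets stays at chance.  Examples
03 and 04 demonstrate model classification and pause localisation the
same way.

A thin CLI mirrors the library: `txpause simulate|detect|features|
classify|locate|fixture --help`.

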