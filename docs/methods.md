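# Methods

## The model

`txpause` simulates expression of a single prokaryotic gene at
nucleotide and codon resolution with a delayed stochastic simulation
algorithm (delayed SSA): an exact Gillespie direct method extended with
a waiting list that releases selected reaction products after
arbitrarily distributed delays.  A delayed event `A -> B + C(tau)`
produces `B` at the firing time and `C` at `t + tau`, with `tau` drawn
afresh at every firing.  Two delays are non-exponential: open-complex
formation, `tau_oc ~ N(40, 4^2)` s, and protein folding,
`tau_fold ~ N(420, 100^2)` s; both are kept non-negative by rejection
resampling (clipping would put an atom at zero and bias the mean; with
these parameters the rejection probability is ~1e-23).

### Transcription

The RNA polymerase (RNAP) binds the promoter at `k_tc = 0.0245 /s`,
forms the open complex after the `tau_oc` delay, and clears the
promoter at `k_m = 150 /s` once the first `delta_P + 1` template
positions are free.  An elongating RNAP occupies `2*delta_P + 1 = 25`
nucleotides (`delta_P = 12`).  At each nucleotide n it activates at
`k_a = 150 /s` (30 /s for n <= 10) and then steps forward at `k_m`,
freeing one position at its back and exposing one ribonucleotide of the
nascent transcript.  Competing with activation are:

- **ubiquitous pauses**: entry `k_p = 0.55 /s` at every nucleotide,
  exponential release with mean `tau_p = 3` s;
- **sequence-dependent pauses** at designated sites: entry rate
  `k_p^n = k_a(n) * (1/eps - 1)^-1`, so that the entry/activation
  competition equals the pause efficiency `eps`; exponential release
  with mean `tau_p^n` (his-pause kinetics: eps = 0.8, 47 s);
- **collisions**: a trailing activated RNAP in contact with a paused
  leader releases it at `0.8*k_m`, or pauses an unactivated leader at
  `0.2*k_m`;
- **arrests** (`k_ar = 2.78e-4 /s`, mean 100 s), **editing excursions**
  (`k_ed = 0.009 /s`, mean 5 s), **premature termination**
  (`k_pre = 1.9e-4 /s`, destroys the nascent transcript), and
  **pyrophosphorolysis** (`k_pyr = 0.75 /s`, a single-nucleotide
  backstep possible only when the position behind is free and the
  ribonucleotide to be re-covered is not occupied by a ribosome).

Termination at the last nucleotide (`k_f = 2 /s`) releases the RNAP and
turns the nascent transcript into a completed mRNA, which degrades at
`k_dr = 0.025 /s` (40 s mean lifetime).

### Translation

Translation is co-transcriptional: ribonucleotides of the nascent chain
become available as the RNAP advances, so ribosomes ride the nascent
transcript and stall wherever the RNAP is stalled.  A ribosome occupies
`2*delta_R + 1 = 31` ribonucleotides (`delta_R = 15`; this footprint is
not fixed by the source kinetics and is configurable).  Initiation
(`k_tl = 0.53 /s`) requires the first `delta_R + 1` ribonucleotides
free; each codon is activated at a codon-class rate (`k_trA = 35`,
`k_trB = 8`, `k_trC = 4.5 /s`) and translocated in three `k_tm = 1e4 /s`
stages that consume three ribonucleotides ahead and release three
behind.  Back-translocation (`k_bt = 1.5 /s`), drop-off
(`k_drop = 1.14e-4 /s`) and trans-translation (`k_tt`, which degrades
the mRNA and recycles its ribosomes) compete.  Completion of the last
codon (`k_tlf = 2 /s`) releases the ribosome and produces a protein
after the folding delay; proteins degrade at `k_dp = 0.0029 /s`.

Codon sequences are drawn i.i.d. from a bundled approximate E. coli
K-12 codon-usage table (stop codons excluded — the model has no
stop-codon mechanism).  Codons map to rate classes by abundance
terciles (most abundant third fastest); the true assignment of the
source model is unknown and a user-supplied map can replace the
default.  Each replicate regenerates the codon sequence unless a fixed
sequence is requested.

### Footprint-edge semantics

Reactant/product index sets at the template ends are resolved with
explicit occupied intervals `[back, front]`: promoter clearance places
the RNAP covering `[1, delta_P + 1]` and the footprint grows to 25 as
it moves in (mirrored at the 3' end); ribosome initiation covers
`[1, delta_R + 1]`, growing to 31.  Each forward step consumes the next
position(s) at the front and releases at the back, clipped to the
template.  A backstep reverses this exactly.

### Design choices that were genuinely open

- **mRNA degradation vs bound ribosomes.**  Degradation fires at `k_dr`
  regardless of ribosome load; bound ribosomes return to the free pool
  without producing protein (the same bookkeeping as trans-translation
  and premature termination).  The alternative — blocking degradation
  while any ribosome is bound — was rejected because, at these rates, a
  transcript is ribosome-free with probability ~2e-10, so degradation
  would essentially never fire and the stationary state (40 s mean mRNA
  lifetime) would be lost.
- **What the RNA observable counts.**  The RNA count `R` includes
  nascent transcripts from promoter clearance onwards, matching
  single-molecule RNA detection during elongation.  This matters: the
  completed-mRNA production flux is promoter-limited and essentially
  pause-independent (paused and queued states are not subject to
  premature termination), so by Little's law the mean completed-mRNA
  count barely distinguishes a gene with a pause from one without.  The
  *residence time* of a transcript does change — a pause adds its mean
  occupied duration — so counting nascent transcripts makes the mean
  shift the detection procedure relies on.  The completed-only count is
  emitted alongside (`rna_completed`).
- **Free pools.**  RNAP and ribosome pool sizes are not part of the
  source kinetics; `k_tc` and `k_tl` are treated as pseudo-first-order
  rates gated on pool availability, with default pools (30 RNAP, 500
  ribosomes) large enough never to be limiting.  They exist so that
  conservation can be asserted.
- **`k_tt`** is sequence dependent in the source model with no value
  given; the constant default `2e-5 /s` is a stand-in, and 0 disables
  the channel.
- **Drop-off and back-translocation** act on codon-boundary states
  only; the mid-translocation states at `k_tm = 1e4 /s` carry ~1e-4 of
  the occupancy, so the approximation is negligible and it keeps the
  two execution paths identical.

### Two execution paths

`expression_model.build_reaction_system` emits the model as generic
reaction objects for the object-level delayed-SSA engine.  This path is
exact for transcription (per-position species are exclusive even with
several RNAPs on the template) but instantiates translation machinery
per transcript only at completion: species-level mass action cannot
attribute a shared per-position ribonucleotide to the correct
transcript while several coexist.  The production path, `engine`,
is an event-driven compiled (numba) kernel that tracks every RNAP and
ribosome as an agent with identical kinetics plus exact
co-transcriptional coupling.  The two paths are cross-validated on
small genes in the test suite (stationary RNA statistics agree within
Monte-Carlo error).  Typical kernel throughput is ~5,000-8,000
simulated seconds per wall second for the default gene.

## Statistics

### Detection

For two data sets, `S` windowed means are drawn (replicate row and
window start uniform at random; a window covers `dL + 1` consecutive
1-s samples) and the two S-long profiles are compared by Welch's
two-sided t-test; repeating `N` times yields a p-value population whose
median summarises detectability.  Degenerate (zero-variance) draws are
excluded and counted, never coerced to a p-value.  Analyses use only
the weakly stationary part of a series (burn-in 50,000 s at full
scale); weak stationarity is checked by a two-sample t-test on
`n_sample = 10` ensemble means drawn from the first and last thirds of
the span.  The check needs enough replicates and span relative to the
protein correlation time (~400 s); with too-small data it reports
failures that reflect its own resolution, not a trend.

### Features

Ten statistics per replicate: lag-weighted mean and SD of the
autocorrelation function of RNA and of protein (lags 1..K, `K = 300`),
of the cross-correlation of (RNA, protein) and of (protein, cumulative
protein), and the mean and SD of RNA "decay times" (lengths of maximal
runs of consecutive non-increasing steps).  The correlation summaries
multiply `r(l)` by the lag `l` before averaging —
`m = (1/K) sum_l r(l) l`, with the matching `(K-1)`-normalised SD —
which is the statistic's definition, not a weighting choice of ours.
An empty decay vector (possible only for pathological inputs) yields
(0, 0) by convention.  Feature samples larger than the replicate count
are obtained by drawing (replicate, window) pairs; windows of ~40,000
samples keep the feature noise below the between-model signal at
reduced scale.

### Classification

Feature collections are z-transformed per component, clustered with
Manhattan distance and McQuitty (WPGMA) linkage (height inversions are
possible; only tree validity is asserted), and classified with a
random forest (5,000 trees, sqrt-V features per split, unlimited depth)
whose error is the mean over 100 bootstrap resamples, evaluated on the
out-of-resample items.  Feature complementarity is quantified by the
matrix of two-sided p-values of Pearson zero-correlation tests.

### Localisation

The pause position `theta` is profiled over a grid (default every
50 nt).  Per feature `j`, the overlap coefficient
`p_j(theta) = int min{f_j, g_j} dx` between Gaussian KDEs of observed
and simulated feature values (Silverman bandwidths; trapezoidal
integral on 512 points spanning both samples ± 3 bandwidths) enters
`log L(theta) = S * sum_j log p_j(theta)`; overlaps below 1e-12 are
floored before the log and the raw zero-overlap event is recorded.
The logarithmic relative likelihood `LRL(theta) = log L(theta) -
log L(theta_hat)` is 0 at the estimate (ties resolve to the smallest
theta) and negative elsewhere.  The bootstrap resamples observed
feature rows with replacement `B = 50,000` times against cached
simulated references; observed KDE bandwidths are frozen at their
full-sample values so each resampled density on the fixed grid is a
matrix product of precomputed per-row kernel columns with multinomial
weights, which is what makes `B = 50,000` tractable.

## Numerical conventions

- Sampling: the sample at grid time g reflects the state after all
  events with event-time <= g.
- Waiting-list ties against reaction firings resolve release-first.
- One seedable generator per run; replicate seeds are spawned from the
  experiment seed and recorded in all output metadata.
- `unif(1:x)` draws are discrete and inclusive of both endpoints.

## Reduced problem sizes

The full study simulates 10 replicates of 10^6 s per model.  The test
suite uses: 4 replicates x 60,000 s per model for features and
classification (feature windows of 40,000 samples); the detection check
at its stated sizes (2 replicates x 200,000 s per model, dL = 1,000,
S = 10, N = 50); null calibration on two independent 2 x 60,000-s
model-A sets; and the locator on a 1,000-nt gene with a 125-nt grid
step, references of 2 x 60,000 s per candidate position and ten
observed sets of 3 x 60,000 s each, B = 1,000.

## What the generator emulates, and what it does not

The simulator produces exactly the kind of data the statistics are
designed for — integer molecule counts at 1 Hz from a single gene with
known pause configuration — so passing tests demonstrate internal
consistency of method and model, not performance on measurements.
Real data would add detection noise and photobleaching, cell division
and partitioning, extrinsic rate fluctuations, RNA secondary structure
(explicitly not modelled here: pause stabilisation by hairpins enters
only through the pause-site parameters), regulated promoters, and
sequence-dependent trans-translation.  None of these are emulated.

## Known limitations

- At reduced scale the percentile bootstrap CI of the pause position
  undercovers (observed feature rows share overlapping windows and are
  positively correlated); nominal 95% coverage needs full-scale, less
  correlated feature samples.  The test asserts coverage in the
  majority of repetitions.
- Unsupervised cluster branches are "not without error": at reduced
  scale one of the three major branches typically remains mixed even
  when the supervised error is ~10%; the tests assert one essentially
  pure branch and above-chance mean purity.
- The codon-class assignment and the trans-translation rate of the
  source model are unknown; defaults are documented stand-ins.
- The object-level path couples translation at transcript completion
  only; co-transcriptional coupling lives in the compiled kernel.
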