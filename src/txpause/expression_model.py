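"""Nucleotide/codon-resolution model of prokaryotic gene expression.

The model covers transcription — promoter binding with a normally
distributed open-complex delay, promoter clearance, per-nucleotide
activation and stepwise elongation of an RNA polymerase (RNAP) with a
25-nt footprint, ubiquitous and sequence-dependent pausing, RNAP-RNAP
collisions that release or induce pauses, arrests, editing excursions,
premature termination, pyrophosphorolysis and termination — and
translation: ribosome binding, codon-class-dependent activation,
three-stage translocation with a 31-nt footprint, back-translocation,
drop-off, trans-translation, completion with a folding delay, and mRNA
and protein degradation.

A sequence-dependent pause site at nucleotide n with efficiency eps and
mean duration tau replaces the ubiquitous pause channel there with entry
rate ``k_p^n = k_a(n) * (1/eps - 1)^-1`` (so the entry/activation
competition equals eps) and exponential release at 1/tau.

Two execution paths exist: :func:`build_reaction_system` emits the model
as generic :class:`~txpause.delayed_ssa.DelayedReaction` objects for the
delayed-SSA engine (exact for transcription; translation machinery is
instantiated per transcript when it completes), and
:mod:`txpause.engine` runs the same kinetics in an event-driven compiled
kernel with full co-transcriptional coupling for production-scale runs.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .delayed_ssa import ConfigurationError, DelayDistribution, DelayedReaction

__all__ = [
    "ModelParameters",
    "PauseSite",
    "GeneTemplate",
    "MODEL_LABELS",
    "load_codon_table",
    "codon_class_map",
    "generate_codon_sequence",
    "pause_rate",
    "make_gene_template",
    "make_model",
    "build_reaction_system",
    "simulate_pause_entry",
]

MODEL_LABELS = ("A", "B", "C", "D", "E", "F")

#: his-pause kinetics used by the standard pause-site models.
HIS_PAUSE_EFFICIENCY = 0.8
HIS_PAUSE_MEAN_DURATION = 47.0


@dataclass(frozen=True)
class ModelParameters:
    """All kinetic constants of the expression model (rates in 1/s, delays s).

    The RNAP occupies ``2*delta_P + 1`` template nucleotides (25 by
    default) and the ribosome ``2*delta_R + 1`` ribonucleotides (31 by
    default; the ribosome footprint is not fixed by the source model and
    is configurable).  ``k_tt`` (trans-translation) is sequence dependent
    in the source model with no value given; the constant default here is
    a stand-in and 0 disables the channel.  Free RNAP and ribosome pool
    sizes are bookkeeping only: promoter binding and translation
    initiation are pseudo-first-order (rate applies whenever the promoter
    or ribosome-binding site is available and the pool is non-empty).
    """

    k_tc: float = 0.0245        # promoter binding
    tau_oc_mean: float = 40.0   # open-complex formation delay ~ N(mean, sd^2)
    tau_oc_sd: float = 4.0
    k_m: float = 150.0          # promoter clearance / elongation step
    k_a_fast: float = 150.0     # nucleotide activation, n > k_a_slow_limit
    k_a_slow: float = 30.0      # nucleotide activation, n <= k_a_slow_limit
    k_a_slow_limit: int = 10
    k_p: float = 0.55           # ubiquitous pause entry
    tau_p: float = 3.0          # ubiquitous pause mean duration
    k_ar: float = 2.78e-4       # arrest entry
    tau_ar: float = 100.0       # arrest mean duration
    k_ed: float = 0.009         # editing excursion entry
    d_ed: float = 5.0           # editing mean duration
    k_pre: float = 1.9e-4       # premature termination
    k_pyr: float = 0.75         # pyrophosphorolysis (single-nt backstep)
    k_f: float = 2.0            # termination
    k_dr: float = 0.025         # mRNA degradation
    k_tl: float = 0.53          # translation initiation
    k_trA: float = 35.0         # codon activation, abundant-codon class
    k_trB: float = 8.0
    k_trC: float = 4.5
    k_tm: float = 10_000.0      # translocation stage
    k_bt: float = 1.5           # back-translocation
    k_drop: float = 1.14e-4     # ribosome drop-off
    k_tt: float = 2e-5          # trans-translation (stand-in constant)
    k_tlf: float = 2.0          # translation completion
    tau_fold_mean: float = 420.0  # protein folding delay ~ N(mean, sd^2)
    tau_fold_sd: float = 100.0
    k_dp: float = 0.0029        # protein degradation
    delta_P: int = 12           # RNAP half-footprint (nt)
    delta_R: int = 15           # ribosome half-footprint (nt)
    n_rnap: int = 30            # free RNAP pool (bookkeeping)
    n_rib: int = 500            # free ribosome pool (bookkeeping)

    def __post_init__(self) -> None:
        for name in ("k_tc", "k_m", "k_a_fast", "k_a_slow", "k_p", "k_ar",
                     "k_ed", "k_pre", "k_pyr", "k_f", "k_dr", "k_tl", "k_trA",
                     "k_trB", "k_trC", "k_tm", "k_bt", "k_drop", "k_tt",
                     "k_tlf", "k_dp", "tau_p", "tau_ar", "d_ed"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.delta_P < 1 or self.delta_R < 1:
            raise ConfigurationError("footprints must be positive")

    def k_a(self, n: int) -> float:
        """Nucleotide activation rate at (1-based) template position n."""
        return self.k_a_slow if n <= self.k_a_slow_limit else self.k_a_fast

    @property
    def rnap_footprint(self) -> int:
        return 2 * self.delta_P + 1

    @property
    def ribosome_footprint(self) -> int:
        return 2 * self.delta_R + 1

    def codon_rate(self, rate_class: str) -> float:
        return {"A": self.k_trA, "B": self.k_trB, "C": self.k_trC}[rate_class]


def pause_rate(k_a_at_n: float, efficiency: float) -> float:
    """Pause-entry rate giving the requested pause efficiency.

    ``k_p^n = k_a(n) * (1/eps - 1)^-1`` so that the entry/activation
    competition k_p^n / (k_p^n + k_a(n)) equals eps.  eps = 0 gives 0;
    eps >= 1 is a configuration error (infinite rate).
    """
    if not 0.0 <= efficiency < 1.0:
        raise ConfigurationError("pause efficiency must lie in [0, 1)")
    if efficiency == 0.0:
        return 0.0
    return k_a_at_n * efficiency / (1.0 - efficiency)


@dataclass(frozen=True)
class PauseSite:
    """A sequence-dependent pause site (1-based nucleotide position)."""

    position: int
    efficiency: float = HIS_PAUSE_EFFICIENCY
    mean_duration: float = HIS_PAUSE_MEAN_DURATION

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ConfigurationError("pause position must be >= 1")
        if not 0.0 <= self.efficiency < 1.0:
            raise ConfigurationError("pause efficiency must lie in [0, 1)")
        if self.mean_duration <= 0:
            raise ConfigurationError("pause mean duration must be > 0")

    def entry_rate(self, params: ModelParameters) -> float:
        return pause_rate(params.k_a(self.position), self.efficiency)


def load_codon_table(path=None) -> dict[str, float]:
    """Load a codon -> relative frequency table (2-column TSV).

    With no path, the bundled approximate E. coli K-12 table is used.
    """
    if path is None:
        text = (resources.files("txpause") / "data" / "codon_usage_ecoli.tsv"
                ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        codon, freq = line.split("\t")
        table[codon] = float(freq)
    if not table:
        raise ConfigurationError("empty codon table")
    return table


def codon_class_map(table: Mapping[str, float] | None = None) -> dict[str, str]:
    """Assign translation-rate classes A/B/C by codon-abundance terciles.

    The most abundant third of codons translate fastest (class A), the
    rarest third slowest (class C).  The true assignment of the source
    model is unknown; this tercile rule is the documented default and a
    user map (2-column TSV codon -> class) can replace it.
    """
    table = load_codon_table() if table is None else table
    ranked = sorted(table, key=lambda c: (-table[c], c))
    n = len(ranked)
    out = {}
    for i, codon in enumerate(ranked):
        out[codon] = "A" if i < n / 3 else ("B" if i < 2 * n / 3 else "C")
    return out


def generate_codon_sequence(n_codons: int, table: Mapping[str, float],
                            rng: np.random.Generator) -> tuple[str, ...]:
    """Draw n_codons i.i.d. codons with probabilities from the table."""
    if n_codons < 0:
        raise ConfigurationError("n_codons must be >= 0")
    codons = sorted(table)
    freqs = np.array([table[c] for c in codons], dtype=float)
    if np.any(freqs < 0) or freqs.sum() <= 0:
        raise ConfigurationError("codon frequencies must be non-negative, sum > 0")
    if n_codons == 0:
        return ()
    idx = rng.choice(len(codons), size=n_codons, p=freqs / freqs.sum())
    return tuple(codons[i] for i in idx)


@dataclass(frozen=True)
class GeneTemplate:
    """Per-nucleotide / per-codon layout of one gene.

    A gene of ``length`` nucleotides carries ``length // 3`` codons (any
    final partial codon is dropped, so the default 1,000-nt gene
    translates 333 codons) and zero or more sequence-dependent pause
    sites.  Each codon maps to exactly one translation-rate class.
    """

    length: int
    codons: tuple[str, ...]
    codon_classes: tuple[str, ...]
    pause_sites: tuple[PauseSite, ...] = ()
    codon_table_name: str = "bundled-ecoli"

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ConfigurationError("gene must be at least one codon long")
        if len(self.codons) != self.length // 3:
            raise ConfigurationError("codon count must equal length // 3")
        if len(self.codon_classes) != len(self.codons):
            raise ConfigurationError("every codon needs exactly one rate class")
        if any(c not in "ABC" for c in self.codon_classes):
            raise ConfigurationError("rate classes must be A, B or C")
        positions = [s.position for s in self.pause_sites]
        if any(not 1 <= p <= self.length for p in positions):
            raise ConfigurationError("pause positions must lie in [1, length]")
        if len(set(positions)) != len(positions):
            raise ConfigurationError("duplicate pause-site positions")

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    def pause_entry_rates(self, params: ModelParameters) -> np.ndarray:
        """Per-nucleotide pause entry rate (index 0 unused; 1..length)."""
        rates = np.full(self.length + 1, params.k_p)
        rates[0] = 0.0
        for site in self.pause_sites:
            rates[site.position] = site.entry_rate(params)
        return rates

    def pause_release_rates(self, params: ModelParameters) -> np.ndarray:
        """Per-nucleotide pause release rate (1/mean duration)."""
        rates = np.full(self.length + 1, 1.0 / params.tau_p)
        rates[0] = 0.0
        for site in self.pause_sites:
            rates[site.position] = 1.0 / site.mean_duration
        return rates


def make_gene_template(length: int = 1000,
                       pause_sites: Iterable[PauseSite] = (),
                       rng: np.random.Generator | None = None,
                       codons: Iterable[str] | None = None,
                       codon_table: Mapping[str, float] | None = None,
                       class_map: Mapping[str, str] | None = None) -> GeneTemplate:
    """Build a gene template, generating a random codon sequence if needed."""
    table = load_codon_table() if codon_table is None else dict(codon_table)
    cmap = codon_class_map(table) if class_map is None else dict(class_map)
    if codons is None:
        rng = np.random.default_rng() if rng is None else rng
        codons = generate_codon_sequence(length // 3, table, rng)
    codons = tuple(codons)
    classes = tuple(cmap[c] for c in codons)
    return GeneTemplate(length=length, codons=codons, codon_classes=classes,
                        pause_sites=tuple(pause_sites))


def _standard_sites(label: str, length: int) -> tuple[PauseSite, ...]:
    scale = length / 1000.0

    def pos(p: int) -> int:
        return max(1, min(length, int(round(p * scale))))

    if label == "A":
        return ()
    if label == "B":
        return (PauseSite(pos(500)),)
    if label == "C":
        return (PauseSite(pos(250)),)
    if label == "D":
        return (PauseSite(pos(750)),)
    if label == "E":
        return (PauseSite(pos(500), mean_duration=23.5),)
    if label == "F":
        return (PauseSite(pos(500), mean_duration=94.0),)
    raise ConfigurationError(f"unknown model label {label!r}")


def make_model(label: str, length: int = 1000,
               rng: np.random.Generator | None = None,
               params: ModelParameters | None = None,
               ) -> tuple[GeneTemplate, ModelParameters]:
    """One of the six standard models A-F.

    A has ubiquitous pauses only; B/C/D put a his-like pause site
    (efficiency 0.8, mean 47 s) at nucleotide 500/250/750; E and F put a
    site at 500 with mean duration 23.5 s and 94 s.  For a non-default
    gene length the site positions scale proportionally.
    """
    label = label.upper()
    if label not in MODEL_LABELS:
        raise ConfigurationError(f"unknown model label {label!r}")
    params = ModelParameters() if params is None else params
    template = make_gene_template(length=length,
                                  pause_sites=_standard_sites(label, length),
                                  rng=rng)
    return template, params


# ---------------------------------------------------------------------------
# Generic reaction-system construction (delayed-SSA object path)

def _consume_pool(state, species: str) -> None:
    state.counts[species] = state.counts.get(species, 0) - 1


def _decrement(state, *species: str) -> None:
    for sp in species:
        state.counts[sp] = state.counts.get(sp, 0) - 1


def build_reaction_system(template: GeneTemplate, params: ModelParameters,
                          translation: bool = True,
                          ) -> tuple[list[DelayedReaction], dict[str, int]]:
    """Emit the full reaction network as generic delayed-SSA reactions.

    Species conventions: ``U{n}`` template-position availability,
    ``O{n}`` / ``A{n}`` / ``Op{n}`` / ``Oar{n}`` / ``Ocorr{n}`` the RNAP
    at position n (elongation-competent, activated, paused, arrested,
    editing), ``RNA`` the number of transcripts present (nascent +
    completed), ``mRNA`` completed transcripts, ``P`` folded proteins and
    ``E`` the cumulative number of proteins made.  Promoter binding and
    translation initiation are pseudo-first-order in the promoter/RBS
    with a pool-availability guard (pool sizes are not part of the
    source kinetics).

    Translation reactions are instantiated per transcript when the
    transcript completes: at species level a shared per-position
    ribonucleotide cannot be attributed to the right transcript while
    several coexist, so the object path couples translation at transcript
    completion.  The compiled kernel (:mod:`txpause.engine`) implements
    co-transcriptional coupling exactly and is the production path.
    """
    L = template.length
    dP = params.delta_P
    kp = template.pause_entry_rates(params)
    krel = template.pause_release_rates(params)
    reactions: list[DelayedReaction] = []
    counter = {"tx": 0}

    def U_range(a: int, b: int) -> dict[str, int]:
        return {f"U{n}": 1 for n in range(max(1, a), min(L, b) + 1)}

    # 1. promoter binding with open-complex delay (pseudo-first-order in Pro)
    reactions.append(DelayedReaction(
        "bind", reactants={"Pro": 1},
        delayed_products=[("RpPro", 1, DelayDistribution.normal(
            params.tau_oc_mean, params.tau_oc_sd))],
        rate=params.k_tc,
        guard=lambda s: s.counts.get("Rp", 0) >= 1,
        on_fire=lambda s: _consume_pool(s, "Rp")))

    # 2. promoter clearance: consume the footprint flags U[1, dP+1]
    reactions.append(DelayedReaction(
        "clear", reactants={"RpPro": 1, **U_range(1, dP + 1)},
        products={"O1": 1, "Pro": 1, "RNA": 1}, rate=params.k_m))

    spawn_translation = _translation_spawner(template, params, counter) \
        if translation else None

    for n in range(1, L + 1):
        o, a = f"O{n}", f"A{n}"
        # 3. activation
        reactions.append(DelayedReaction(
            f"act{n}", reactants={o: 1}, products={a: 1}, rate=params.k_a(n)))
        # 4. elongation (move n -> n+1); termination replaces it at n = L
        if n < L:
            reactants = {a: 1}
            if n + dP + 1 <= L:
                reactants[f"U{n + dP + 1}"] = 1
            products = {f"O{n + 1}": 1}
            if n - dP >= 1:
                products[f"U{n - dP}"] = 1
            reactions.append(DelayedReaction(
                f"elong{n}", reactants=reactants, products=products,
                rate=params.k_m))
        else:
            # 12. termination: free the trailing footprint, release the RNAP,
            # the transcript becomes a completed mRNA
            reactions.append(DelayedReaction(
                "terminate", reactants={a: 1},
                products={"Rp": 1, "mRNA": 1, **U_range(L - dP, L)},
                rate=params.k_f, on_fire=spawn_translation))
        # 5. pausing (sequence-dependent rates substituted at pause sites)
        if kp[n] > 0:
            reactions.append(DelayedReaction(
                f"pause{n}", reactants={o: 1}, products={f"Op{n}": 1},
                rate=float(kp[n])))
        reactions.append(DelayedReaction(
            f"unpause{n}", reactants={f"Op{n}": 1}, products={o: 1},
            rate=float(krel[n])))
        # 6./7. collision-mediated release and induction (follower exactly
        # one footprint behind, activated)
        if n - (2 * dP + 1) >= 1:
            follower = f"A{n - (2 * dP + 1)}"
            reactions.append(DelayedReaction(
                f"bump_release{n}", reactants={f"Op{n}": 1, follower: 1},
                products={o: 1, follower: 1}, rate=0.8 * params.k_m))
            reactions.append(DelayedReaction(
                f"bump_pause{n}", reactants={o: 1, follower: 1},
                products={f"Op{n}": 1, follower: 1}, rate=0.2 * params.k_m))
        # 8. arrest
        reactions.append(DelayedReaction(
            f"arrest{n}", reactants={o: 1}, products={f"Oar{n}": 1},
            rate=params.k_ar))
        reactions.append(DelayedReaction(
            f"unarrest{n}", reactants={f"Oar{n}": 1}, products={o: 1},
            rate=1.0 / params.tau_ar))
        # 9. editing excursion
        reactions.append(DelayedReaction(
            f"edit{n}", reactants={o: 1}, products={f"Ocorr{n}": 1},
            rate=params.k_ed))
        reactions.append(DelayedReaction(
            f"unedit{n}", reactants={f"Ocorr{n}": 1}, products={o: 1},
            rate=1.0 / params.d_ed))
        # 10. premature termination: release the whole footprint (the RNA
        # transcript counter is bookkeeping, decremented out of band so it
        # never enters the mass-action propensity)
        reactions.append(DelayedReaction(
            f"pre{n}", reactants={o: 1},
            products={"Rp": 1, **U_range(n - dP, n + dP)}, rate=params.k_pre,
            on_fire=lambda s: _decrement(s, "RNA")))
        # 11. pyrophosphorolysis: single-nucleotide backstep (frees the
        # front-edge position n + dP; requires the position behind free)
        if n - dP - 1 >= 1:
            products = {f"O{n - 1}": 1}
            if n + dP <= L:
                products[f"U{n + dP}"] = 1
            reactions.append(DelayedReaction(
                f"pyr{n}", reactants={o: 1, f"U{n - dP - 1}": 1},
                products=products, rate=params.k_pyr))

    if not translation:
        # without per-transcript instances, degradation acts on the pooled
        # completed-mRNA count directly
        reactions.append(DelayedReaction(
            "degrade", reactants={"mRNA": 1}, rate=params.k_dr,
            on_fire=lambda s: _decrement(s, "RNA")))
        if params.k_tt > 0:
            reactions.append(DelayedReaction(
                "transtl", reactants={"mRNA": 1}, rate=params.k_tt,
                on_fire=lambda s: _decrement(s, "RNA")))

    initial = {"Pro": 1, "Rp": params.n_rnap, "Rib": params.n_rib,
               "RNA": 0, "mRNA": 0, "P": 0, "E": 0}
    for n in range(1, L + 1):
        initial[f"U{n}"] = 1
    return reactions, initial


def _translation_spawner(template: GeneTemplate, params: ModelParameters,
                         counter: dict):
    """Factory for per-transcript translation reaction sets.

    Footprint-edge semantics: a ribosome whose leading codon boundary is
    at ribonucleotide m occupies [max(1, m - dR), min(L, m + dR)]; each
    translocation consumes the next three ribonucleotides at the front
    and releases three at the back, so boundary positions clip naturally.
    """
    L = template.length
    dR = params.delta_R
    n_codons = template.n_codons
    boundaries = [1 + 3 * c for c in range(n_codons)]
    last = boundaries[-1]

    def spawn(state):
        j = counter["tx"]
        counter["tx"] += 1
        pfx = f"tx{j}:"
        alive = f"{pfx}alive"
        nribs = f"{pfx}nribs"
        state.counts[alive] = 1
        for m in range(1, L + 1):
            state.counts[f"{pfx}UR{m}"] = 1

        def alive_guard(s, _a=alive):
            return s.counts.get(_a, 0) >= 1

        def release_all(s, _pfx=pfx, _alive=alive, _nribs=nribs):
            bound = s.counts.get(_nribs, 0)
            s.counts["Rib"] = s.counts.get("Rib", 0) + bound
            s.counts[_nribs] = 0
            for key in list(s.counts):
                if key.startswith(_pfx):
                    s.counts[key] = 0
            _decrement(s, "mRNA", "RNA")
            return None

        def rib_guard(s, _a=alive):
            return s.counts.get(_a, 0) >= 1 and s.counts.get("Rib", 0) >= 1

        def take_rib(s, _nribs=nribs):
            _consume_pool(s, "Rib")
            s.counts[_nribs] = s.counts.get(_nribs, 0) + 1
            return None

        def drop_rib(s, _nribs=nribs):
            s.counts["Rib"] = s.counts.get("Rib", 0) + 1
            s.counts[_nribs] = s.counts.get(_nribs, 0) - 1
            return None

        new: list[DelayedReaction] = []
        # 13. mRNA degradation: fires regardless of ribosome load; bound
        # ribosomes are recycled to the pool (see module docs)
        new.append(DelayedReaction(
            f"{pfx}degrade", reactants={alive: 1},
            rate=params.k_dr, on_fire=release_all))
        # 21. trans-translation
        if params.k_tt > 0:
            new.append(DelayedReaction(
                f"{pfx}transtl", reactants={alive: 1},
                rate=params.k_tt, on_fire=release_all))
        # 14. initiation: consume ribonucleotides [1, dR+1]
        new.append(DelayedReaction(
            f"{pfx}init",
            reactants={f"{pfx}UR{m}": 1 for m in range(1, dR + 2)},
            products={f"{pfx}Or1": 1}, rate=params.k_tl,
            guard=rib_guard, on_fire=take_rib))
        for c, m in enumerate(boundaries):
            orm, arm = f"{pfx}Or{m}", f"{pfx}Ar{m}"
            # 15. codon activation
            new.append(DelayedReaction(
                f"{pfx}ract{m}", reactants={orm: 1}, products={arm: 1},
                rate=params.codon_rate(template.codon_classes[c]),
                guard=alive_guard))
            if m != last:
                # 16-18. three-stage translocation m -> m+3
                stage1_reactants = {arm: 1}
                for q in range(m + dR + 1, m + dR + 4):
                    if q <= L:
                        stage1_reactants[f"{pfx}UR{q}"] = 1
                new.append(DelayedReaction(
                    f"{pfx}tm1_{m}", reactants=stage1_reactants,
                    products={f"{pfx}Or{m + 1}": 1}, rate=params.k_tm,
                    guard=alive_guard))
                new.append(DelayedReaction(
                    f"{pfx}tm2_{m}", reactants={f"{pfx}Or{m + 1}": 1},
                    products={f"{pfx}Or{m + 2}": 1}, rate=params.k_tm,
                    guard=alive_guard))
                stage3_products = {f"{pfx}Or{m + 3}": 1}
                for q in range(m - dR, m - dR + 3):
                    if q >= 1:
                        stage3_products[f"{pfx}UR{q}"] = 1
                new.append(DelayedReaction(
                    f"{pfx}tm3_{m}", reactants={f"{pfx}Or{m + 2}": 1},
                    products=stage3_products, rate=params.k_tm,
                    guard=alive_guard))
            else:
                # 22. completion with folding delay (the bookkeeping species
                # Pnew converts to P + E effectively instantaneously)
                released = {f"{pfx}UR{q}": 1
                            for q in range(max(1, m - dR), L + 1)}
                new.append(DelayedReaction(
                    f"{pfx}complete", reactants={arm: 1},
                    products={"Rib": 1, **released},
                    delayed_products=[("Pnew", 1, DelayDistribution.normal(
                        params.tau_fold_mean, params.tau_fold_sd))],
                    rate=params.k_tlf, guard=alive_guard,
                    on_fire=lambda s, _n=nribs: (
                        s.counts.__setitem__(_n, s.counts.get(_n, 0) - 1))))
            # 19. back-translocation m -> m-3 (inverse of 16-18)
            if m - dR - 3 >= 1:
                bt_reactants = {orm: 1}
                for q in range(m - dR - 3, m - dR):
                    bt_reactants[f"{pfx}UR{q}"] = 1
                bt_products = {f"{pfx}Ar{m - 3}": 1}
                for q in range(m + dR - 2, m + dR + 1):
                    if q <= L:
                        bt_products[f"{pfx}UR{q}"] = 1
                new.append(DelayedReaction(
                    f"{pfx}bt{m}", reactants=bt_reactants,
                    products=bt_products, rate=params.k_bt,
                    guard=alive_guard))
            # 20. drop-off (codon-boundary states; mid-stage occupancy at
            # k_tm = 10^4 is negligible)
            freed = {f"{pfx}UR{q}": 1
                     for q in range(max(1, m - dR), min(L, m + dR) + 1)}
            new.append(DelayedReaction(
                f"{pfx}drop{m}", reactants={orm: 1}, products=freed,
                rate=params.k_drop, guard=alive_guard, on_fire=drop_rib))
        return new

    return spawn


def finishing_reactions(params: ModelParameters) -> list[DelayedReaction]:
    """Bookkeeping channels shared by every system: Pnew -> P + E and
    protein degradation."""
    return [
        DelayedReaction("fold_book", reactants={"Pnew": 1},
                        products={"P": 1, "E": 1}, rate=1e9),
        DelayedReaction("pdeg", reactants={"P": 1}, rate=params.k_dp),
    ]


def full_system(template: GeneTemplate, params: ModelParameters,
                translation: bool = True):
    """Reaction system plus initial counts, including bookkeeping channels."""
    reactions, initial = build_reaction_system(template, params, translation)
    reactions.extend(finishing_reactions(params))
    initial["Pnew"] = 0
    return reactions, initial


def simulate_pause_entry(params: ModelParameters, site: PauseSite,
                         n_passages: int,
                         rng: np.random.Generator) -> float:
    """Fraction of single-RNAP passages over ``site`` that pause.

    Each passage places one RNAP in the elongation-competent state at the
    pause nucleotide and follows the embedded jump chain of its competing
    channels (activation, pause entry, arrest, editing, premature
    termination, pyrophosphorolysis) until it either enters the paused
    state or activates; arrest/editing/backstep excursions return to the
    race, premature termination ends the passage without a pause.
    """
    n = site.position
    k_act = params.k_a(n)
    k_pause = site.entry_rate(params)
    channels = np.array([k_act, k_pause, params.k_ar, params.k_ed,
                         params.k_pre, params.k_pyr])
    probs = channels / channels.sum()
    paused = 0
    for _ in range(n_passages):
        while True:
            c = rng.choice(6, p=probs)
            if c == 0:  # activated: passage proceeds without pausing
                break
            if c == 1:  # entered the paused state
                paused += 1
                break
            if c == 4:  # premature termination: passage over, no pause
                break
            # arrest / editing / backstep excursions return to the race
    return paused / n_passages
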