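"""Forward Wright-Fisher simulation of epistatic and balancing selection.

Individual-based, biallelic, finite-sites simulator: a population of N
haploid (or diploid) individuals with L sites evolves by fitness-
proportional parent sampling, reversible per-site mutation (0 <-> 1 with
probability mu per site per generation), and optional recombination.
Sites are classed synonymous (neutral) or nonsynonymous (selected), two
nonsynonymous sites for every synonymous one, laid out codon-style with
every third position synonymous.

Fitness combines additively across loci: each deleterious site carried
contributes s (haploid, or homozygote; h*s in heterozygotes), each
epistatic pair whose two mutations co-occur on the same haplotype adds
epsilon (full compensation: epsilon = -2*s, so the double mutant returns
to fitness 1), a negative frequency-dependent site contributes
s_max*(1 - 2p) at population frequency p, and fitness is floored at a
small positive value.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYN = 0
NONSYN = 1


def default_site_classes(L: int) -> np.ndarray:
    """Codon-style class layout: every third site synonymous (ratio 2:1)."""
    cls = np.full(L, NONSYN, dtype=np.uint8)
    cls[2::3] = SYN
    return cls


@dataclass
class FitnessModel:
    """Per-site and pairwise fitness effects on an L-site sequence.

    ``s_site`` holds the per-carrier selection coefficient of each site
    (0 for synonymous sites).  ``pairs``/``epsilon`` encode pairwise
    epistasis evaluated per haplotype.  ``h_site`` holds per-site
    dominance coefficients (diploid mode only).
    """

    s_site: np.ndarray
    h_site: np.ndarray
    pairs: np.ndarray | None = None          # (P, 2) site indices
    epsilon: np.ndarray | None = None        # (P,)
    nfds_site: int | None = None
    nfds_s_max: float = 0.01
    fitness_floor: float = 1e-6

    @property
    def is_neutral(self) -> bool:
        return (not np.any(self.s_site) and self.pairs is None
                and self.nfds_site is None)


def build_fitness_model(kind: str, site_classes: np.ndarray,
                        s_nonsyn: float = -0.01, h: float = 0.5,
                        compensation: float = 1.0,
                        pair_shape: str = "peaks",
                        nfds: bool = False, nfds_s_max: float = 0.01,
                        aod: bool = False, n_aod: int = 10,
                        aod_s: float = -0.0025,
                        rng: np.random.Generator | None = None) -> FitnessModel:
    """Assemble a fitness model over a given site-class layout.

    ``kind``: 'neutral', 'additive' (non-epistatic deleterious), or
    'pairwise_epistasis'.  Under pairwise epistasis all nonsynonymous
    sites are split into disjoint pairs; ``compensation`` in [0, 1]
    scales the double-mutant rescue (1 = full compensation, double
    mutant fitness 1).  ``pair_shape='ridge'`` makes one member of each
    pair individually neutral while the double mutant stays neutral
    (three of the four allele combinations confer high fitness).
    Optional NFDS places a frequency-dependent site with
    s(p) = s_max*(1 - 2p); optional AOD makes ``n_aod`` random sites
    fully recessive (h = 0) weakly deleterious (diploid mode).
    """
    rng = rng or np.random.default_rng(0)
    site_classes = np.asarray(site_classes)
    L = site_classes.size
    s_site = np.zeros(L)
    h_site = np.full(L, h)
    pairs = None
    eps = None
    nonsyn_idx = np.flatnonzero(site_classes == NONSYN)
    if kind == "neutral":
        pass
    elif kind == "additive":
        s_site[nonsyn_idx] = s_nonsyn
    elif kind == "pairwise_epistasis":
        s_site[nonsyn_idx] = s_nonsyn
        paired = nonsyn_idx[: 2 * (len(nonsyn_idx) // 2)]
        pairs = paired.reshape(-1, 2)
        if pair_shape == "peaks":
            eps = np.full(len(pairs), -2.0 * s_nonsyn * compensation)
        elif pair_shape == "ridge":
            s_site[pairs[:, 0]] = 0.0          # single mutant A neutral
            eps = np.full(len(pairs), -s_nonsyn * compensation)
        else:
            raise ValueError(f"unknown pair_shape {pair_shape!r}")
    else:
        raise ValueError(f"unknown fitness model kind {kind!r}")

    nfds_site = None
    if nfds:
        candidates = np.setdiff1d(np.arange(L),
                                  pairs.ravel() if pairs is not None else [])
        nfds_site = int(rng.choice(candidates if candidates.size else
                                   np.arange(L)))
        s_site[nfds_site] = 0.0
    if aod:
        taken = set([nfds_site] if nfds_site is not None else [])
        free = np.array([i for i in range(L) if i not in taken])
        aod_sites = rng.choice(free, size=min(n_aod, free.size),
                               replace=False)
        s_site[aod_sites] = aod_s
        h_site[aod_sites] = 0.0
    return FitnessModel(s_site=s_site, h_site=h_site, pairs=pairs,
                        epsilon=eps, nfds_site=nfds_site,
                        nfds_s_max=nfds_s_max)


@dataclass
class SimConfig:
    """One Wright-Fisher run specification."""

    ploidy: str = "haploid"
    N: int = 200
    L: int = 99
    mu: float = 2.5e-4
    recombination: float = 0.0   # expected crossovers per offspring per gen
    generations: int | None = None   # default 100 * N
    site_classes: np.ndarray | None = None
    fitness_model: FitnessModel | None = None
    sample_n: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2 or self.L < 1 or not 0 <= self.mu < 1:
            raise ValueError("invalid SimConfig")
        if self.site_classes is None:
            self.site_classes = default_site_classes(self.L)
        if self.generations is None:
            self.generations = 100 * self.N


@dataclass
class SimResult:
    """Sampled haploid genotypes and summary statistics of one run."""

    sample: np.ndarray          # (sample_n, L) uint8
    site_classes: np.ndarray
    pi: float
    sfs: np.ndarray             # minor-allele count spectrum in the sample
    config: SimConfig


def genotype_fitness(states: np.ndarray, model: FitnessModel,
                     freqs: np.ndarray) -> np.ndarray:
    """Fitness of each individual under the additive-across-loci model.

    ``states`` is (N, L) for haploids or (N, 2, L) for diploids;
    ``freqs`` is the current population allele-frequency vector.
    """
    if states.ndim == 2:
        w = 1.0 + states @ model.s_site
        if model.pairs is not None:
            both = states[:, model.pairs[:, 0]] & states[:, model.pairs[:, 1]]
            w += both @ model.epsilon
        if model.nfds_site is not None:
            p = freqs[model.nfds_site]
            w += states[:, model.nfds_site] * model.nfds_s_max * (1 - 2 * p)
    elif states.ndim == 3:
        g = states.sum(axis=1)          # 0/1/2 copies
        hom = (g == 2).astype(float)
        het = (g == 1).astype(float)
        w = 1.0 + hom @ model.s_site + het @ (model.h_site * model.s_site)
        if model.pairs is not None:
            for hap in range(2):
                both = (states[:, hap, model.pairs[:, 0]] &
                        states[:, hap, model.pairs[:, 1]])
                w += both @ model.epsilon
        if model.nfds_site is not None:
            p = freqs[model.nfds_site]
            coeff = model.nfds_s_max * (1 - 2 * p)
            k = model.nfds_site
            w += coeff * (hom[:, k] + model.h_site[k] * het[:, k])
    else:
        raise ValueError("states must be 2-D (haploid) or 3-D (diploid)")
    return np.maximum(w, model.fitness_floor)


def _sample_parents(w: np.ndarray, size: int,
                    rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(w)
    return np.searchsorted(cdf, rng.random(size) * cdf[-1], side="right")


def run_wright_fisher(config: SimConfig) -> SimResult:
    """Run one forward simulation from a monomorphic start.

    Parents are sampled with probability proportional to fitness each
    generation; mutation flips each allele with probability mu
    (reversible); recombination applies at most one crossover per
    recombining offspring (haploid outcrossing) or per meiosis (diploid),
    occurring with the Poisson probability implied by the map length.
    Fully reproducible from ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    N, L = config.N, config.L
    model = config.fitness_model
    neutral = model is None or model.is_neutral
    diploid = config.ploidy == "diploid"
    pop = np.zeros((N, 2, L) if diploid else (N, L), dtype=np.uint8)
    r = config.recombination
    p_rec = 1.0 - np.exp(-r) if r > 0 else 0.0
    n_cells = pop.size
    for _ in range(config.generations):
        if neutral:
            w = None
            parents = rng.integers(0, N, size=N)
        else:
            freqs = pop.mean(axis=(0, 1)) if diploid else pop.mean(axis=0)
            w = genotype_fitness(pop, model, freqs)
            parents = _sample_parents(w, N, rng)
        if diploid:
            parents2 = (rng.integers(0, N, size=N) if neutral
                        else _sample_parents(w, N, rng))
            new = np.empty_like(pop)
            for slot, par in ((0, parents), (1, parents2)):
                which = rng.integers(0, 2, size=N)
                gam = pop[par, which]
                if p_rec > 0:
                    rec = rng.random(N) < p_rec
                    if rec.any():
                        cuts = rng.integers(1, L, size=int(rec.sum()))
                        other = pop[par[rec], 1 - which[rec]]
                        gam = gam.copy()
                        for k, (row, cut) in enumerate(
                                zip(np.flatnonzero(rec), cuts)):
                            gam[row, cut:] = other[k, cut:]
                new[:, slot] = gam
        else:
            new = pop[parents]
            if p_rec > 0:
                rec = np.flatnonzero(rng.random(N) < p_rec)
                if rec.size:
                    partners = rng.integers(0, N, size=rec.size) if neutral \
                        else _sample_parents(w, rec.size, rng)
                    cuts = rng.integers(1, L, size=rec.size)
                    for row, par2, cut in zip(rec, partners, cuts):
                        new[row, cut:] = pop[par2, cut:]
        k = rng.binomial(n_cells, config.mu)
        if k:
            idx = rng.integers(0, n_cells, size=k)
            new.reshape(-1)[idx] ^= 1
        pop = new

    chroms = pop.reshape(-1, L) if diploid else pop
    sample_n = min(config.sample_n, chroms.shape[0])
    sel = rng.choice(chroms.shape[0], size=sample_n, replace=False)
    sample = chroms[sel]
    counts = sample.sum(axis=0)
    minor = np.minimum(counts, sample_n - counts)
    s = sample_n
    pi = float((2 * counts * (s - counts) / (s * (s - 1))).mean())
    sfs = np.bincount(minor, minlength=s // 2 + 1)
    return SimResult(sample=sample, site_classes=config.site_classes,
                     pi=pi, sfs=sfs, config=config)


@dataclass
class LdSummary:
    pi: float
    ld_syn: float
    ld_nonsyn: float
    n_syn: int
    n_nonsyn: int

    @property
    def excess(self) -> float:
        return self.ld_nonsyn - self.ld_syn


def summarize_ld(result: SimResult, maf_min: float = 0.05) -> LdSummary:
    """Mean within-class r^2 over qualifying SNPs in the sampled genotypes.

    Qualifying SNPs are polymorphic in the sample with minor-allele
    frequency > ``maf_min``; a class with fewer than two such SNPs gets
    NaN.
    """
    from .ld import mean_pairwise_r2

    sample = result.sample
    s = sample.shape[0]
    counts = sample.sum(axis=0)
    freq = counts / s
    maf = np.minimum(freq, 1 - freq)
    qualify = (counts > 0) & (counts < s) & (maf > maf_min)
    out = {}
    for label, cls in (("ld_syn", SYN), ("ld_nonsyn", NONSYN)):
        sites = np.flatnonzero(qualify & (result.site_classes == cls))
        out[label] = (mean_pairwise_r2(sample[:, sites].T)
                      if sites.size >= 2 else float("nan"))
        out["n_syn" if cls == SYN else "n_nonsyn"] = int(sites.size)
    return LdSummary(pi=result.pi, ld_syn=out["ld_syn"],
                     ld_nonsyn=out["ld_nonsyn"], n_syn=out["n_syn"],
                     n_nonsyn=out["n_nonsyn"])


def replicate_experiment(conditions: dict[str, SimConfig],
                         n_replicates: int = 20,
                         rng_seed: int = 0,
                         maf_min: float = 0.05) -> pd.DataFrame:
    """Replicate runs over a grid of conditions.

    Returns one row per condition x replicate with pi, within-class LD
    and the nonsynonymous excess; replicate seeds are derived from
    ``rng_seed``.
    """
    seeder = np.random.default_rng(rng_seed)
    rows = []
    for name, config in conditions.items():
        seeds = seeder.integers(0, 2 ** 31 - 1, size=n_replicates)
        for rep, seed in enumerate(seeds):
            cfg = replace(config, rng_seed=int(seed))
            summ = summarize_ld(run_wright_fisher(cfg), maf_min=maf_min)
            rows.append((name, rep, summ.pi, summ.ld_syn, summ.ld_nonsyn,
                         summ.excess, summ.n_syn, summ.n_nonsyn))
    return pd.DataFrame(rows, columns=["condition", "replicate", "pi",
                                       "ld_syn", "ld_nonsyn", "excess",
                                       "n_syn", "n_nonsyn"])


def ld_contrast_experiment(config: SimConfig, n_replicates: int = 20,
                           rng_seed: int = 0,
                           maf_min: float = 0.05) -> dict:
    """Replicated nonsyn-vs-syn LD contrast under one condition.

    Returns both the mean of per-replicate excesses (replicates with
    fewer than two qualifying SNPs in a class contribute nothing) and
    the pooled contrast (mean r^2 over all qualifying same-class pairs
    pooled across replicates), which is better behaved when qualifying
    nonsynonymous SNPs are rare.
    """
    from .ld import pairwise_r2

    seeder = np.random.default_rng(rng_seed)
    pooled: dict[int, list] = {SYN: [], NONSYN: []}
    per_rep = []
    pis = []
    for _ in range(n_replicates):
        cfg = replace(config, rng_seed=int(seeder.integers(0, 2 ** 31 - 1)))
        res = run_wright_fisher(cfg)
        pis.append(res.pi)
        smp = res.sample
        s = smp.shape[0]
        counts = smp.sum(axis=0)
        maf = np.minimum(counts, s - counts) / s
        qualify = (counts > 0) & (counts < s) & (maf > maf_min)
        rep_mean = {}
        for cls in (SYN, NONSYN):
            sites = np.flatnonzero(qualify & (res.site_classes == cls))
            if sites.size >= 2:
                r2 = pairwise_r2(smp[:, sites].T)
                vals = r2[np.triu_indices(sites.size, 1)]
                pooled[cls].extend(vals)
                rep_mean[cls] = float(np.mean(vals))
        if SYN in rep_mean and NONSYN in rep_mean:
            per_rep.append(rep_mean[NONSYN] - rep_mean[SYN])
    out = {
        "pi_mean": float(np.mean(pis)),
        "n_replicates": n_replicates,
        "n_defined": len(per_rep),
        "excess_per_replicate_mean": (float(np.mean(per_rep))
                                      if per_rep else float("nan")),
        "excess_per_replicate_se": (float(np.std(per_rep, ddof=1)
                                          / np.sqrt(len(per_rep)))
                                    if len(per_rep) > 1 else float("nan")),
        "ld_syn_pooled": (float(np.mean(pooled[SYN]))
                          if pooled[SYN] else float("nan")),
        "ld_nonsyn_pooled": (float(np.mean(pooled[NONSYN]))
                             if pooled[NONSYN] else float("nan")),
        "n_pairs_syn": len(pooled[SYN]),
        "n_pairs_nonsyn": len(pooled[NONSYN]),
    }
    out["excess_pooled"] = out["ld_nonsyn_pooled"] - out["ld_syn_pooled"]
    return out


# desk-scale study conditions: haploid analogues of the original diploid
# (drift-scaled selection, N*s preserved) and haploid-with-recombination
# simulation setups; see docs/methods.md for the derivation


def neutral_condition(N: int = 200, L: int = 99,
                      mu: float = 2.5e-4) -> SimConfig:
    """Neutral control at the pi-targeting mutation rate."""
    return SimConfig(N=N, L=L, mu=mu)


def hill_robertson_condition(N: int = 200, L: int = 99, mu: float = 5e-4,
                             s_nonsyn: float = -0.05) -> SimConfig:
    """Non-epistatic deleterious model, no recombination.

    Interference among linked deleterious alleles drives repulsion, so
    LD_nonsyn falls below LD_syn.
    """
    classes = default_site_classes(L)
    model = build_fitness_model("additive", classes, s_nonsyn=s_nonsyn)
    return SimConfig(N=N, L=L, mu=mu, recombination=0.0,
                     site_classes=classes, fitness_model=model)


def compensation_nfds_condition(N: int = 200, L: int = 99, mu: float = 5e-4,
                                s_nonsyn: float = -0.1,
                                nfds_s_max: float = 0.05,
                                recombination: float = 0.05,
                                nfds: bool = True,
                                model_seed: int = 1) -> SimConfig:
    """Full pairwise compensation with (optional) balancing selection.

    Strong purging keeps lone deleterious mutants below the MAF filter,
    so the qualifying nonsynonymous variants are the mutually
    compensated pairs held at intermediate frequency by the balanced
    polymorphism; light recombination dissipates background LD (and
    load-fluctuation interference) without breaking the selected pairs.
    """
    classes = default_site_classes(L)
    model = build_fitness_model(
        "pairwise_epistasis", classes, s_nonsyn=s_nonsyn, nfds=nfds,
        nfds_s_max=nfds_s_max, rng=np.random.default_rng(model_seed))
    return SimConfig(N=N, L=L, mu=mu, recombination=recombination,
                     site_classes=classes, fitness_model=model)


def diversity_grid_condition(mu: float, N: int = 200, L: int = 99,
                             s_nonsyn: float = -0.05,
                             nfds_s_max: float = 0.05,
                             model_seed: int = 1) -> SimConfig:
    """Compensation + NFDS, no recombination, at a given mutation rate.

    Used along an increasing-mu grid: the nonsynonymous LD excess rises
    with diversity (the hyperpolymorphism effect).
    """
    classes = default_site_classes(L)
    model = build_fitness_model(
        "pairwise_epistasis", classes, s_nonsyn=s_nonsyn, nfds=True,
        nfds_s_max=nfds_s_max, rng=np.random.default_rng(model_seed))
    return SimConfig(N=N, L=L, mu=mu, recombination=0.0,
                     site_classes=classes, fitness_model=model)


# ---------------------------------------------------------------------------
# scaling helpers


def scaled_mutation_rate(pi_target: float, N: int) -> float:
    """The pi-targeting mutation-rate scaling mu = pi / (2N)."""
    return pi_target / (2 * N)


def expected_neutral_diversity(n_chromosomes: int, mu: float) -> float:
    """Equilibrium pi under symmetric biallelic mutation, no selection.

    From the pairwise coalescent: two lineages coalesce after
    T ~ Exp(1/Nc) generations and differ at a site with probability
    (1 - exp(-4 mu T)) / 2, giving E[pi] = 2 Nc mu / (1 + 4 Nc mu).
    """
    theta = n_chromosomes * mu
    return 2 * theta / (1 + 4 * theta)


def mutation_rate_for_diversity(pi: float, n_chromosomes: int) -> float:
    """Invert :func:`expected_neutral_diversity` for mu."""
    if not 0 < pi < 0.5:
        raise ValueError("pi must be in (0, 0.5)")
    return pi / (2 * n_chromosomes * (1 - 2 * pi))
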