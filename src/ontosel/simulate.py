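"""Stochastic individual-based simulation of the sexual-niche model.

Validates the analytic predictions (convergence to the singular strategy,
evolutionary branching of the male trait) with explicit diploid or
haplodiploid genetics and mutation.  The scheme is a fixed-step
tau-leaping-style update:

* every individual dies with probability ``mu_j(z_j) * dt``;
* survivors' sizes take one Euler step of ``dx/da = z_j - alpha x``;
* each female produces a ``Poisson(f_f * dt)`` number of eggs, with
  ``f_f = x_f * max(0, 1 - N/K)`` using the live head-count ``N`` (the
  finite-population analogue of the equilibrium density feedback);
* each egg's sire is drawn among living males with probability proportional
  to the size-matching kernel ``exp(-kappa (x_m - x_f)^2)``;
* offspring are male with probability ``c``; inheritance is one random
  allele per parent (diploid), or mother-only for haplodiploid sons;
* every transmitted allele component mutates with a configured probability
  by a Gaussian increment, reflected at zero.

An allele carries one value per sex (its effect if expressed in a female or
male carrier), or a single shared value under the pleiotropic constraint.
Expressed traits are the allelic average over the carrier's copies for its
own sex (haploid males express their single allele directly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sexual_niche import FEMALE, MALE, SexualNicheParams, resident_demography

__all__ = ["SimConfig", "SimTrace", "simulate", "summarize"]


@dataclass
class SimConfig:
    """Run configuration for the individual-based simulation."""

    params: SexualNicheParams
    genetics_kind: str = "diploid_two_sex"  # or "haplodiploid_two_sex"
    shared_trait: bool = False
    dt: float = 0.2  # time step (time units)
    duration: float = 1e4  # total simulated time
    mutation_prob: float = 1e-2  # per transmitted allele component
    mutation_sd: float = 1e-2  # Gaussian kernel width (trait units)
    initial_allele: tuple[float, float] = (0.5, 0.5)  # (female, male) values
    initial_popsize: int = 5000
    max_popsize: int = 200_000  # hard cap; exceeding it aborts the run
    record_every: float = 10.0  # recording cadence (time units)
    n_allele_samples: int = 100  # allele copies sampled per sex per record
    hist_window: tuple[float, float] | None = None  # histogram averaging window
    n_bins: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.genetics_kind not in ("diploid_two_sex", "haplodiploid_two_sex"):
            raise ValueError(f"unsupported genetics kind {self.genetics_kind!r}")


@dataclass
class SimTrace:
    """Recorded time series and windowed size histograms."""

    config: SimConfig
    times: np.ndarray
    pop_size: np.ndarray
    mean_trait: np.ndarray  # (2, n_records) expressed-trait means per sex
    allele_samples: list  # per record: (female_alleles, male_alleles) arrays
    hist_bins: np.ndarray
    hist_counts: np.ndarray  # (2, n_bins) accumulated over the window
    extinct: bool
    aborted: str | None = None

    def size_histograms(self) -> tuple[np.ndarray, np.ndarray]:
        """Normalised (density) female and male size histograms."""
        width = np.diff(self.hist_bins)
        out = []
        for j in (FEMALE, MALE):
            total = self.hist_counts[j].sum()
            out.append(self.hist_counts[j] / (total * width) if total > 0
                       else np.zeros_like(width))
        return out[0], out[1]


class _Population:
    """Flat-array population state."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        p = cfg.params
        n = cfg.initial_popsize
        demo = resident_demography(p, cfg.initial_allele)
        self.haplodiploid = cfg.genetics_kind == "haplodiploid_two_sex"
        self.shared = cfg.shared_trait
        self.n_components = 1 if cfg.shared_trait else 2
        sex = (rng.random(n) < demo.secondary_sex_ratio).astype(np.int8)
        ages = rng.exponential(1.0 / demo.mortality[sex])
        x = np.empty(n)
        for j in (FEMALE, MALE):
            mask = sex == j
            x[mask] = cfg.initial_allele[j] * \
                (1.0 - np.exp(-p.alpha * ages[mask])) / p.alpha
        init = (np.full(self.n_components, np.mean(cfg.initial_allele))
                if cfg.shared_trait else np.asarray(cfg.initial_allele, float))
        alleles = np.tile(init, (n, 2, 1))
        if self.haplodiploid:
            alleles[sex == MALE, 1, :] = np.nan
        self.sex = sex
        self.x = x
        self.alleles = alleles

    @property
    def size(self) -> int:
        return self.sex.size

    def expressed(self) -> np.ndarray:
        """Expressed growth trait of every individual."""
        comp = np.zeros(self.size, dtype=np.intp) if self.shared else \
            self.sex.astype(np.intp)
        vals = self.alleles[np.arange(self.size), :, comp]  # (n, 2)
        if self.haplodiploid:
            out = np.where(self.sex == MALE, vals[:, 0],
                           np.nanmean(vals, axis=1))
        else:
            out = vals.mean(axis=1)
        return out

    def keep(self, mask: np.ndarray) -> None:
        self.sex = self.sex[mask]
        self.x = self.x[mask]
        self.alleles = self.alleles[mask]

    def append(self, sex, x, alleles) -> None:
        self.sex = np.concatenate([self.sex, sex])
        self.x = np.concatenate([self.x, x])
        self.alleles = np.concatenate([self.alleles, alleles])


def _mutate(alleles: np.ndarray, prob: float, sd: float,
            rng: np.random.Generator) -> np.ndarray:
    """Mutate transmitted allele components in place (reflected at 0)."""
    if prob <= 0 or sd <= 0:
        return alleles
    hits = rng.random(alleles.shape) < prob
    n_hits = int(hits.sum())
    if n_hits:
        alleles[hits] = np.abs(alleles[hits] + rng.normal(0.0, sd, n_hits))
    return alleles


def simulate(config: SimConfig) -> SimTrace:
    """Run the individual-based simulation and return its trace."""
    p = config.params
    rng = np.random.default_rng(config.seed)
    pop = _Population(config, rng)
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    record_stride = max(1, int(round(config.record_every / dt)))
    window = config.hist_window or (0.5 * config.duration, config.duration)
    # shared size bin grid: generous multiple of the initial maximum size
    top = 2.0 * max(config.initial_allele) / p.alpha + 1e-9
    bins = np.linspace(0.0, top, config.n_bins + 1)
    hist_counts = np.zeros((2, config.n_bins))
    mu_e = np.array([p.mu_e_f, p.mu_e_m])
    beta = np.array([p.beta_f, p.beta_m])

    times, popsize, meantrait, allele_samples = [], [], [], []
    extinct = False
    aborted = None
    for step in range(n_steps + 1):
        t = step * dt
        if pop.size == 0:
            extinct = True
            break
        z = pop.expressed()
        if step % record_stride == 0:
            times.append(t)
            popsize.append(pop.size)
            mt = np.full(2, np.nan)
            samples = []
            for j in (FEMALE, MALE):
                mask = pop.sex == j
                mt[j] = float(z[mask].mean()) if mask.any() else np.nan
                comp = 0 if config.shared_trait else j
                vals = pop.alleles[mask][:, :, comp].reshape(-1)
                vals = vals[~np.isnan(vals)]
                k = min(config.n_allele_samples, vals.size)
                samples.append(rng.choice(vals, size=k, replace=False)
                               if k else np.empty(0))
            meantrait.append(mt)
            allele_samples.append(tuple(samples))
            if window[0] <= t <= window[1]:
                for j in (FEMALE, MALE):
                    counts, _ = np.histogram(pop.x[pop.sex == j], bins=bins)
                    hist_counts[j] += counts
        if step == n_steps:
            break
        # deaths
        mu = mu_e[pop.sex] + beta[pop.sex] * z**2
        event_prob = mu * dt
        if event_prob.max() >= 0.5:
            aborted = ("per-step death probability exceeded 0.5; "
                       "reduce dt for these rates")
            break
        survive = rng.random(pop.size) > event_prob
        pop.keep(survive)
        if pop.size == 0:
            extinct = True
            break
        z = z[survive]
        # growth (Euler)
        pop.x += (z - p.alpha * pop.x) * dt
        # births
        females = np.flatnonzero(pop.sex == FEMALE)
        males = np.flatnonzero(pop.sex == MALE)
        if females.size == 0 or males.size == 0:
            continue
        density = max(0.0, 1.0 - pop.size / p.K)
        rates = pop.x[females] * density * dt
        n_eggs = rng.poisson(np.clip(rates, 0.0, None))
        total = int(n_eggs.sum())
        if total == 0:
            continue
        if pop.size + total > config.max_popsize:
            aborted = "population size cap exceeded"
            break
        mothers = np.repeat(females, n_eggs)
        # sire draw: Gumbel-max over the size-matching log-weights
        logw = -p.kappa * (pop.x[males][None, :] - pop.x[mothers][:, None]) ** 2
        gumbel = rng.gumbel(size=logw.shape)
        sires = males[np.argmax(logw + gumbel, axis=1)]
        child_sex = (rng.random(total) < p.c).astype(np.int8)
        nC = pop.alleles.shape[2]
        child_alleles = np.empty((total, 2, nC))
        m_pick = rng.integers(0, 2, total)
        child_alleles[:, 0, :] = pop.alleles[mothers, m_pick, :]
        if config.genetics_kind == "diploid_two_sex":
            f_pick = rng.integers(0, 2, total)
            child_alleles[:, 1, :] = pop.alleles[sires, f_pick, :]
        else:  # haplodiploid: fathers are haploid; sons get no paternal allele
            child_alleles[:, 1, :] = pop.alleles[sires, 0, :]
            child_alleles[child_sex == MALE, 1, :] = np.nan
        live = ~np.isnan(child_alleles)
        muts = child_alleles[live]
        _mutate(muts, config.mutation_prob, config.mutation_sd, rng)
        child_alleles[live] = muts
        pop.append(child_sex, np.zeros(total), child_alleles)

    return SimTrace(
        config=config,
        times=np.asarray(times),
        pop_size=np.asarray(popsize, dtype=float),
        mean_trait=np.asarray(meantrait).T if meantrait else np.zeros((2, 0)),
        allele_samples=allele_samples,
        hist_bins=bins,
        hist_counts=hist_counts,
        extinct=extinct,
        aborted=aborted,
    )


# ---------------------------------------------------------------------------
# summaries: histograms, KL divergence, branching verdict
# ---------------------------------------------------------------------------

def _two_means_gap(values: np.ndarray) -> tuple[float, float]:
    """Optimal 1-D two-cluster split: (between-centre gap, pooled within sd).

    Exact for one dimension: scan all sorted split points minimising the
    within-cluster sum of squares.
    """
    v = np.sort(values)
    n = v.size
    if n < 4:
        return 0.0, np.inf
    csum = np.cumsum(v)
    csq = np.cumsum(v**2)
    ks = np.arange(1, n)
    left_ss = csq[ks - 1] - csum[ks - 1] ** 2 / ks
    right_n = n - ks
    right_sum = csum[-1] - csum[ks - 1]
    right_ss = (csq[-1] - csq[ks - 1]) - right_sum**2 / right_n
    tot = left_ss + right_ss
    k = int(ks[np.argmin(tot)])
    m1, m2 = csum[k - 1] / k, (csum[-1] - csum[k - 1]) / (n - k)
    within_sd = float(np.sqrt(max(tot[k - 1], 0.0) / n))
    return float(abs(m2 - m1)), within_sd


def kl_divergence(p_counts: np.ndarray, q_counts: np.ndarray,
                  smoothing: float = 0.5) -> float:
    """KL(P || Q) between histogram counts with additive smoothing."""
    p = np.asarray(p_counts, dtype=float) + smoothing
    q = np.asarray(q_counts, dtype=float) + smoothing
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def branching_verdict(
    trace: SimTrace,
    sex: int = MALE,
    tail_fraction: float = 0.2,
    gap_ratio: float = 4.0,
    persistence: float = 0.8,
) -> dict:
    """Detect persistent bimodality of allelic values late in the run.

    For every record in the final ``tail_fraction`` of the trace the sampled
    allelic values of ``sex`` are split by exact 1-D two-means; a record is
    'split' when the between-cluster gap exceeds ``gap_ratio`` times the
    pooled within-cluster standard deviation.  The verdict is positive when
    at least ``persistence`` of the tail records are split.
    """
    n = len(trace.allele_samples)
    if n == 0:
        return {"branched": False, "split_fraction": 0.0, "n_records": 0}
    start = int(np.floor(n * (1.0 - tail_fraction)))
    flags = []
    gaps = []
    for rec in trace.allele_samples[start:]:
        vals = rec[sex]
        if vals.size < 4:
            continue
        gap, within = _two_means_gap(vals)
        gaps.append(gap)
        flags.append(gap > gap_ratio * max(within, 1e-12))
    frac = float(np.mean(flags)) if flags else 0.0
    return {
        "branched": bool(flags and frac >= persistence),
        "split_fraction": frac,
        "n_records": len(flags),
        "median_gap": float(np.median(gaps)) if gaps else 0.0,
    }


def summarize(trace: SimTrace, window: tuple[float, float] | None = None) -> dict:
    """Histograms, male-female KL divergence and the branching verdict.

    ``window`` must lie within the trace's histogram-accumulation window
    (histograms are accumulated online; an explicit sub-window only checks
    containment).
    """
    if window is not None:
        lo, hi = window
        if hi <= lo or hi > trace.times[-1] + trace.config.record_every:
            raise ValueError(f"invalid or empty summary window {window}")
    f_hist, m_hist = trace.size_histograms()
    out = {
        "window": window or (trace.config.hist_window
                             or (0.5 * trace.config.duration,
                                 trace.config.duration)),
        "female_size_density": f_hist,
        "male_size_density": m_hist,
        "bins": trace.hist_bins,
        "kl_male_female": kl_divergence(trace.hist_counts[MALE],
                                        trace.hist_counts[FEMALE]),
        "mean_final_traits": trace.mean_trait[:, -1] if
        trace.mean_trait.size else np.full(2, np.nan),
        "extinct": trace.extinct,
    }
    out.update({"branching": branching_verdict(trace)})
    return out
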