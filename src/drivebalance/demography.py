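"""Sex-structured, discrete-generation life cycle with density dependence.

Two life stages (juveniles, adults), non-overlapping generations, and
density-dependent mortality acting on juveniles.  Counts are normalized so
the wild-type equilibrium has one adult female and one adult male.  Each
generation runs through ordered phases:

1. released males are injected into the mating pool;
2. every fertile female mates once, the father drawn in proportion to
   fertile-male counts (count times fertility component);
3. each mated female produces ``2 * Rm`` zygotes, distributed over offspring
   genotypes by the genetics engine;
4. early-acting genetic deaths;
5. uniform density-dependent juvenile survival
   ``sigma = 1 / (1 + (Rm - 1) * (J / J0) ** dd_exponent)`` with ``J`` the
   surviving juvenile total and ``J0 = 2 * Rm`` its wild-type equilibrium
   value (Beverton-Holt when the exponent is 1);
6. late-acting genetic deaths;
7. survivors become the next adult generation (released adults are not
   carried over: generations do not overlap).

The recursion is a deterministic expected-value model of an effectively
infinite population; there is no demographic stochasticity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import (
    FEMALE,
    MALE,
    Architecture,
    ConfigError,
    GeneticParams,
    Genotype,
    ModelError,
    X_CLASS,
    Y_CLASS,
    gamete_distribution,
    offspring_distribution,
    viability,
    wildtype,
)

__all__ = [
    "LifeCycle",
    "PopulationState",
    "ReleaseSchedule",
    "CompiledModel",
    "equilibrium_state",
    "step",
    "run",
    "TimeSeries",
]

#: genotype counts below this are treated as extinct lineages and dropped
COUNT_TOL = 1e-300


@dataclass(frozen=True)
class LifeCycle:
    """Demographic parameters.

    ``Rm`` is the intrinsic (low-density) per-generation rate of increase;
    ``dd_exponent`` shapes the density dependence (1 = Beverton-Holt).
    """

    Rm: float
    dd_exponent: float = 1.0

    def __post_init__(self):
        if not self.Rm > 1.0:
            raise ConfigError(f"Rm must exceed 1, got {self.Rm}")
        if not self.dd_exponent > 0.0:
            raise ConfigError("dd_exponent must be positive")


@dataclass
class PopulationState:
    """Adult census at one generation: per-sex genotype counts."""

    generation: int
    females: dict
    males: dict

    @property
    def female_count(self) -> float:
        return float(sum(self.females.values()))

    @property
    def male_count(self) -> float:
        return float(sum(self.males.values()))

    def allele_frequencies(self, arch: Architecture) -> dict:
        """Pooled adult allele frequencies per locus, keyed (locus, allele)."""
        counts: dict = {}
        totals = [0.0] * arch.n_loci
        for pool in (self.females, self.males):
            for g, c in pool.items():
                for hap in g.haplotypes:
                    for i, a in enumerate(hap):
                        counts[(arch.loci[i].name, a)] = (
                            counts.get((arch.loci[i].name, a), 0.0) + c
                        )
                        totals[i] += c
        name_to_i = {l.name: i for i, l in enumerate(arch.loci)}
        return {
            k: (v / totals[name_to_i[k[0]]] if totals[name_to_i[k[0]]] > 0 else 0.0)
            for k, v in counts.items()
        }

    def haplotype_frequencies(self) -> dict:
        """Pooled adult haplotype frequencies."""
        counts: dict = {}
        total = 0.0
        for pool in (self.females, self.males):
            for g, c in pool.items():
                for hap in g.haplotypes:
                    counts[hap] = counts.get(hap, 0.0) + c
                    total += c
        return {h: c / total for h, c in counts.items()} if total > 0 else {}


@dataclass(frozen=True)
class ReleaseSchedule:
    """Releases of a fixed genotype as a proportion of the original males.

    ``rho`` is measured against the pre-release male equilibrium (M0 = 1).
    ``cadence`` is ``"every"`` (each generation from ``start`` to ``stop``
    inclusive) or ``"single"`` (the ``start`` generation only).
    """

    genotype: Genotype | None = None
    rho: float = 0.0
    cadence: str = "every"
    start: int = 0
    stop: int | None = None

    def __post_init__(self):
        if self.rho < 0.0:
            raise ConfigError("release proportion must be non-negative")
        if self.cadence not in ("every", "single"):
            raise ConfigError(f"unknown cadence {self.cadence!r}")
        if self.genotype is not None and self.genotype.sex != MALE:
            raise ConfigError("only male releases are modeled")

    def active(self, generation: int) -> bool:
        if self.genotype is None or self.rho <= 0.0:
            return False
        if self.cadence == "single":
            return generation == self.start
        if generation < self.start:
            return False
        return self.stop is None or generation <= self.stop


# --- compiled model -------------------------------------------------------


def _sex_valid_pairs(haps, arch):
    si = arch.sex_index
    for h1, h2 in itertools.combinations_with_replacement(sorted(haps), 2):
        pair = tuple(sorted((h1, h2)))
        if si is None:
            yield Genotype(pair, FEMALE)
            yield Genotype(pair, MALE)
        else:
            n_y = sum(1 for h in pair if h[si] in Y_CLASS)
            if n_y == 0:
                yield Genotype(pair, FEMALE)
            elif n_y == 1:
                yield Genotype(pair, MALE)


class CompiledModel:
    """Pre-computed offspring tensor and viability vectors for fast stepping.

    The reachable haplotype set is closed under gamete formation starting
    from the wild types plus any seed genotypes (e.g. the release genotype);
    all sex-valid haplotype pairs over that set are enumerated, and the
    offspring distribution of every (mother, father) pair is stored as a
    dense tensor so that one generation is a single tensor contraction.
    """

    def __init__(self, arch: Architecture, params: GeneticParams,
                 seeds: tuple = ()):
        params.validate()
        self.arch = arch
        self.params = params
        haps = {h for g in seeds for h in g.haplotypes}
        for sex in (FEMALE, MALE):
            haps.update(wildtype(arch, sex).haplotypes)
        # close the haplotype set under gamete formation
        while True:
            new = set()
            for g in _sex_valid_pairs(haps, arch):
                new.update(gamete_distribution(g, arch, params).keys())
            if new <= haps:
                break
            haps |= new
        self.genotypes = sorted(
            _sex_valid_pairs(haps, arch), key=lambda g: (g.sex, g.haplotypes)
        )
        self.index = {g: i for i, g in enumerate(self.genotypes)}
        n = len(self.genotypes)
        self.female_pos = np.array(
            [i for i, g in enumerate(self.genotypes) if g.sex == FEMALE], int
        )
        self.male_pos = np.array(
            [i for i, g in enumerate(self.genotypes) if g.sex == MALE], int
        )
        viab = [viability(g, arch, params) for g in self.genotypes]
        self.early = np.array([v.early_survival for v in viab])
        self.late = np.array([v.late_survival for v in viab])
        self.fert = np.array([v.fertility for v in viab])
        nf, nm = len(self.female_pos), len(self.male_pos)
        self.T = np.zeros((nf, nm, n))
        for i, fi in enumerate(self.female_pos):
            mother = self.genotypes[fi]
            if viab[fi].fertility == 0.0:
                continue
            for j, mj in enumerate(self.male_pos):
                father = self.genotypes[mj]
                if viab[mj].fertility == 0.0:
                    continue
                for child, p in offspring_distribution(
                    mother, father, arch, params
                ).items():
                    self.T[i, j, self.index[child]] = p
        # expected genetic survival of a brood per (mother, father) pair
        self.brood_surv = self.T @ (self.early * self.late)

    # -- vector/state conversions --

    def to_vectors(self, state: PopulationState):
        f = np.zeros(len(self.female_pos))
        m = np.zeros(len(self.male_pos))
        fidx = {self.genotypes[p]: k for k, p in enumerate(self.female_pos)}
        midx = {self.genotypes[p]: k for k, p in enumerate(self.male_pos)}
        for g, c in state.females.items():
            if g not in fidx:
                raise ConfigError(f"genotype {g.label()} not in compiled model")
            f[fidx[g]] += c
        for g, c in state.males.items():
            if g not in midx:
                raise ConfigError(f"genotype {g.label()} not in compiled model")
            m[midx[g]] += c
        return f, m

    def to_state(self, generation, f, m) -> PopulationState:
        females = {
            self.genotypes[p]: float(f[k])
            for k, p in enumerate(self.female_pos) if f[k] > COUNT_TOL
        }
        males = {
            self.genotypes[p]: float(m[k])
            for k, p in enumerate(self.male_pos) if m[k] > COUNT_TOL
        }
        return PopulationState(generation, females, males)

    def step_vectors(self, f, m, lc: LifeCycle, release_vec=None):
        """One generation on count vectors; returns (f', m', load)."""
        if np.any(f < -1e-12) or np.any(m < -1e-12):
            raise ModelError("negative adult counts")
        m_pool = m if release_vec is None else m + release_vec
        weights = m_pool * self.fert[self.male_pos]
        wsum = weights.sum()
        brood = f * self.fert[self.female_pos] * (2.0 * lc.Rm)
        n = len(self.genotypes)
        if wsum <= 0.0 or brood.sum() <= 0.0:
            juveniles = np.zeros(n)
            load_t = 1.0 if f.sum() > 0 else 0.0
        else:
            w_hat = weights / wsum
            juveniles = np.einsum("i,j,ijc->c", brood, w_hat, self.T)
            denom = 2.0 * lc.Rm * f.sum()
            load_t = 1.0 - float(brood @ self.brood_surv @ w_hat) / denom
        juveniles *= self.early
        j_total = juveniles.sum()
        j0 = 2.0 * lc.Rm  # wild-type equilibrium juvenile production (F0 = 1)
        sigma = 1.0 / (1.0 + (lc.Rm - 1.0) * (j_total / j0) ** lc.dd_exponent)
        juveniles *= sigma
        juveniles *= self.late
        return juveniles[self.female_pos], juveniles[self.male_pos], load_t

    def release_vector(self, release: ReleaseSchedule):
        vec = np.zeros(len(self.male_pos))
        if release.genotype is not None:
            midx = {self.genotypes[p]: k for k, p in enumerate(self.male_pos)}
            if release.genotype not in midx:
                raise ConfigError("release genotype not in compiled model")
            vec[midx[release.genotype]] = release.rho
        return vec


_MODEL_CACHE: dict = {}


def compiled_model(arch: Architecture, params: GeneticParams,
                   seeds: tuple = ()) -> CompiledModel:
    key = (arch, params, tuple(seeds))
    model = _MODEL_CACHE.get(key)
    if model is None:
        model = CompiledModel(arch, params, seeds)
        if len(_MODEL_CACHE) > 128:
            _MODEL_CACHE.clear()
        _MODEL_CACHE[key] = model
    return model


# --- public operations ----------------------------------------------------


def equilibrium_state(lc: LifeCycle, arch: Architecture) -> PopulationState:
    """All-wild-type adult state with one female and one male.

    This state is a fixed point of :func:`step` for every ``Rm > 1`` by
    the normalization ``J0 = 2 * Rm``.
    """
    return PopulationState(
        generation=0,
        females={wildtype(arch, FEMALE): 1.0},
        males={wildtype(arch, MALE): 1.0},
    )


def step(state: PopulationState, lc: LifeCycle, arch: Architecture,
         params: GeneticParams,
         release: ReleaseSchedule | None = None) -> PopulationState:
    """Advance the adult census by one generation."""
    release = release or ReleaseSchedule()
    seeds = tuple(state.females) + tuple(state.males)
    if release.genotype is not None:
        seeds += (release.genotype,)
    model = compiled_model(arch, params, seeds)
    f, m = model.to_vectors(state)
    rvec = (
        model.release_vector(release)
        if release.active(state.generation) else None
    )
    f2, m2, _ = model.step_vectors(f, m, lc, rvec)
    return model.to_state(state.generation + 1, f2, m2)


@dataclass
class TimeSeries:
    """Per-generation records of a simulated release program."""

    table: pd.DataFrame
    arch: Architecture
    haplotype_frequencies: list = field(default_factory=list)

    @property
    def females_rel(self) -> np.ndarray:
        return self.table["females_rel"].to_numpy()

    def first_passage(self, threshold: float):
        """First generation with relative female count <= threshold, or None."""
        below = self.table.index[self.table["females_rel"] <= threshold]
        return int(below[0]) if len(below) else None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")


def run(lc: LifeCycle, arch: Architecture, params: GeneticParams,
        release: ReleaseSchedule | None = None, horizon: int = 0,
        initial: PopulationState | None = None) -> TimeSeries:
    """Simulate ``horizon`` generations and record the adult census.

    The record at generation 0 is the initial state (the wild-type
    equilibrium unless ``initial`` is given); releases begin according to
    the schedule.  Columns: generation, females_rel, males_rel, load, one
    frequency column per (locus, allele) seen, with counts relative to the
    wild-type equilibrium (F0 = M0 = 1).
    """
    if horizon < 0:
        raise ConfigError("horizon must be >= 0")
    release = release or ReleaseSchedule()
    state0 = initial or equilibrium_state(lc, arch)
    seeds = tuple(state0.females) + tuple(state0.males)
    if release.genotype is not None:
        seeds += (release.genotype,)
    model = compiled_model(arch, params, seeds)
    f, m = model.to_vectors(state0)
    rvec_full = model.release_vector(release)

    records = []
    hap_freqs = []
    state = model.to_state(state0.generation, f, m)
    load_prev = 0.0
    for t in range(horizon + 1):
        gen = state0.generation + t
        rec = {
            "generation": gen,
            "females_rel": state.female_count,
            "males_rel": state.male_count,
            "load": load_prev,
        }
        for (locus, allele), freq in sorted(
            state.allele_frequencies(arch).items()
        ):
            rec[f"freq_{locus}_{allele}"] = freq
        records.append(rec)
        hap_freqs.append(state.haplotype_frequencies())
        if t == horizon:
            break
        rvec = rvec_full if release.active(gen) else None
        f, m, load_prev = model.step_vectors(f, m, lc, rvec)
        state = model.to_state(gen + 1, f, m)

    table = pd.DataFrame(records).fillna(0.0)
    return TimeSeries(table=table, arch=arch, haplotype_frequencies=hap_freqs)
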