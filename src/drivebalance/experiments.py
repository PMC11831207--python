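"""Headline analyses: release-threshold searches, sweeps, and scans.

The central quantity is the minimal per-generation release proportion
``rho*`` (released males as a fraction of the original male population)
that drives the adult female count below a suppression target within a
horizon.  Suppression is monotone in the release proportion for every
registered strategy, so ``rho*`` is found by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .demography import LifeCycle, ReleaseSchedule, run
from .genetics import (
    CONSTRUCT,
    CONSTRUCT_CLASS,
    LOF_BOTH,
    LOF_CAS9,
    LOF_GRNA,
    ModelError,
)
from .strategies import StrategySpec

__all__ = [
    "SearchResult",
    "min_release_rate",
    "fold_efficiency",
    "parameter_sweep",
    "linkage_correlation",
    "lof_derivative_scan",
]

#: absolute bisection tolerance on the release proportion
RHO_TOL = 1e-4
#: default upper bracket; targets unreachable here are reported unattainable
RHO_MAX = 20.0
_MAX_BISECT = 60


@dataclass(frozen=True)
class SearchResult:
    """Minimal release proportion achieving a suppression goal."""

    strategy: str
    Rm: float
    target: float
    horizon: int
    rho: float | None
    attained: bool
    first_passage: int | None = None

    @property
    def unattainable(self) -> bool:
        return not self.attained


def _suppression_ok(spec: StrategySpec, lc: LifeCycle, rho: float,
                    target: float, horizon: int, mode: str) -> tuple:
    release = ReleaseSchedule(genotype=spec.release_genotype, rho=rho)
    ts = run(lc, spec.arch, spec.params, release, horizon)
    threshold = 1.0 - target
    if mode == "first_passage":
        fp = ts.first_passage(threshold)
        return fp is not None, fp
    final = float(ts.females_rel[-1])
    return final <= threshold, (horizon if final <= threshold else None)


def min_release_rate(spec: StrategySpec, lc: LifeCycle, target: float,
                     horizon: int, *, rho_max: float = RHO_MAX,
                     tol: float = RHO_TOL,
                     mode: str = "first_passage") -> SearchResult:
    """Bisection for the minimal release proportion reaching ``target``.

    ``target`` is the fractional reduction of the adult female count
    relative to the pre-release equilibrium (0.95 = 95% suppression).
    ``mode`` is ``"first_passage"`` (reach the threshold at any generation
    up to the horizon) or ``"at_horizon"`` (the value at the final
    generation).  Targets unreachable at ``rho_max`` are reported with
    ``attained=False`` rather than raising.
    """
    if not 0.0 < target < 1.0:
        raise ModelError(f"target {target} outside (0, 1)")
    if horizon < 1:
        raise ModelError("horizon must be >= 1")
    if mode not in ("first_passage", "at_horizon"):
        raise ModelError(f"unknown mode {mode!r}")

    ok0, fp0 = _suppression_ok(spec, lc, 0.0, target, horizon, mode)
    if ok0:
        return SearchResult(spec.name, lc.Rm, target, horizon, 0.0, True, fp0)
    ok_hi, fp_hi = _suppression_ok(spec, lc, rho_max, target, horizon, mode)
    if not ok_hi:
        return SearchResult(spec.name, lc.Rm, target, horizon, None, False)

    lo, hi = 0.0, rho_max
    for _ in range(_MAX_BISECT):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        ok, fp = _suppression_ok(spec, lc, mid, target, horizon, mode)
        if ok:
            hi, fp_hi = mid, fp
        else:
            lo = mid
    return SearchResult(spec.name, lc.Rm, target, horizon, hi, True, fp_hi)


def fold_efficiency(a: SearchResult, b: SearchResult) -> float:
    """Ratio of minimal release rates, ``a.rho / b.rho``.

    Both results must come from the same demography, target and horizon;
    dividing by a zero or unattained denominator is an error.
    """
    if (a.Rm, a.target, a.horizon) != (b.Rm, b.target, b.horizon):
        raise ModelError("fold efficiency requires matching search settings")
    if not (a.attained and b.attained):
        raise ModelError("fold efficiency undefined for unattained searches")
    if not b.rho:
        raise ModelError("fold efficiency undefined: zero denominator")
    return a.rho / b.rho


def parameter_sweep(spec: StrategySpec, variable: str, grid,
                    lc: LifeCycle, target: float, horizon: int,
                    **search_kwargs) -> pd.DataFrame:
    """Release-threshold search along a grid of one genetic parameter.

    Returns a table with one row per grid value: the minimal release
    proportion, its first-passage generation, and an ``attained`` flag
    (False where the strategy fails at every release rate up to the cap).
    """
    if not hasattr(spec.params, variable):
        raise ModelError(f"unknown sweep variable {variable!r}")
    rows = []
    for value in grid:
        swept = spec.with_params(**{variable: value})
        res = min_release_rate(swept, lc, target, horizon, **search_kwargs)
        rows.append({
            "strategy": spec.name, variable: value, "Rm": lc.Rm,
            "target": target, "horizon": horizon, "rho": res.rho,
            "attained": res.attained, "first_passage": res.first_passage,
        })
    return pd.DataFrame(rows)


def linkage_correlation(hap_freqs: dict, is_pdne, is_booster) -> float:
    """Correlation between construct and booster presence on haplotypes.

    ``(p_GB - p_G * p_B) / sqrt(p_G (1 - p_G) p_B (1 - p_B))`` where
    ``p_GB`` is the frequency of haplotypes carrying both elements and
    ``p_G``, ``p_B`` the marginal frequencies.  ``is_pdne`` and
    ``is_booster`` are predicates on haplotypes.  Undefined (raises) when
    either element is absent or fixed.
    """
    p_g = sum(p for h, p in hap_freqs.items() if is_pdne(h))
    p_b = sum(p for h, p in hap_freqs.items() if is_booster(h))
    p_gb = sum(p for h, p in hap_freqs.items() if is_pdne(h) and is_booster(h))
    if not (0.0 < p_g < 1.0 and 0.0 < p_b < 1.0):
        raise ModelError(
            f"correlation undefined at p_G={p_g}, p_B={p_b}"
        )
    return (p_gb - p_g * p_b) / math.sqrt(
        p_g * (1.0 - p_g) * p_b * (1.0 - p_b)
    )


def lof_derivative_scan(spec: StrategySpec, lc: LifeCycle,
                        release: ReleaseSchedule, horizon: int) -> dict:
    """Trajectories of the construct and its loss-of-function derivatives.

    Simulates the release program and extracts, per generation, the pooled
    adult allele frequencies of the intact construct and each derivative
    (dead Cas9, dead gRNA, both dead).  The *release frequency* is the
    intact-construct allele frequency in the mating pool at the first
    release (adults plus released males); the scan flags whether any
    derivative ever exceeds it, which would indicate a driving derivative.
    """
    ts = run(lc, spec.arch, spec.params, release, horizon)
    locus = next(
        l.name for l in spec.arch.loci
        if l.role in ("pdne", "pdne_construct")
    )
    cols = {}
    for allele in (CONSTRUCT, LOF_CAS9, LOF_GRNA, LOF_BOTH):
        name = f"freq_{locus}_{allele}"
        cols[allele] = (
            ts.table[name].to_numpy()
            if name in ts.table else np.zeros(len(ts.table))
        )
    # allele copies injected at the first release, over the pooled mating
    # population (adults at equilibrium + released males)
    i_locus = next(
        i for i, l in enumerate(spec.arch.loci)
        if l.role in ("pdne", "pdne_construct")
    )
    copies = sum(
        1 for h in release.genotype.haplotypes
        if h[i_locus] in CONSTRUCT_CLASS
    )
    rho = release.rho
    release_frequency = (copies * rho) / (2.0 * (2.0 + rho))
    derivative_max = max(
        float(cols[a].max()) for a in (LOF_CAS9, LOF_GRNA, LOF_BOTH)
    )
    return {
        "timeseries": ts,
        "frequencies": pd.DataFrame(
            {"generation": ts.table["generation"], **cols}
        ),
        "release_frequency": release_frequency,
        "derivative_max": derivative_max,
        "derivative_exceeds_release": derivative_max > release_frequency,
    }
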