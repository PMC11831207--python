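"""Closed-form single-locus, single-sex, infinite-population model.

The model follows a construct allele G inserted into a haplosufficient gene
so that it causes recessive lethality, while its germline editor converts
wild-type alleles W into dominant lethal edits E at rate ``u``.  The life
cycle within one generation is::

    hatchling census (frequency q)  -->  viability selection on the
    construct (recessive cost s_construct, heterozygous cost
    h_construct*s_construct)  -->  germline editing and random union of
    gametes  -->  embryonic deaths of edit carriers  -->  next hatchling
    census

Frequencies are censused at the hatchling stage, after embryonic deaths.
With idealized parameters (u = 1, fully penetrant lethal construct and edit)
the construct's preferential transmission exactly cancels selection against
it: its fitness components are w_rec = 1 - q (recessive lethality),
w_dom = 1/(1 - q) (editing drive), w_total = 1 at every frequency.  Despite
this neutrality the construct imposes a reproductive load L = 2q/(1 + q).

``analytic_step`` assumes the hatchling census is at Hardy-Weinberg
proportions over {W, G}; this is exact whenever dominant edits leave no
survivors at the census (s_edit = h_edit = 1, the regime of every closed-form
result here) and an approximation otherwise.  The full-state cross-check for
general parameters is the two-sex simulator in :mod:`drivebalance.demography`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetics import GeneticParams, ModelError

__all__ = [
    "FitnessComponents",
    "fitness_components",
    "load",
    "fitness_from_frequencies",
    "no_drive_condition",
    "analytic_step",
    "analytic_trajectory",
    "adult_genotype_distribution",
    "IDEALIZED",
]

#: idealized PDNE parameters: certain editing, fully penetrant lethal edit,
#: fully penetrant recessive lethal construct with cost-free heterozygotes
IDEALIZED = GeneticParams(
    u=1.0, s_edit=1.0, h_edit=1.0, frac_recessive=0.0,
    s_construct=1.0, h_construct=0.0, mu_lof=0.0,
)

_CLIP_TOL = 1e-14


@dataclass(frozen=True)
class FitnessComponents:
    w_rec: float
    w_dom: float
    w_total: float


def fitness_components(q: float) -> FitnessComponents:
    """Fitness of the idealized construct at hatchling frequency ``q``.

    ``w_rec = 1 - q`` is the fitness due to recessive lethality alone,
    ``w_dom = 1/(1 - q)`` the fitness due to editing drive alone, and their
    product is 1: drive-selection balance.  Undefined at ``q = 1``.
    """
    if not 0.0 <= q < 1.0:
        raise ModelError(f"fitness components undefined at q={q}")
    w_rec = 1.0 - q
    w_dom = 1.0 / (1.0 - q)
    return FitnessComponents(w_rec=w_rec, w_dom=w_dom, w_total=w_rec * w_dom)


def load(q: float) -> float:
    """Reproductive load L = 2q/(1+q) at hatchling construct frequency q.

    The proportional reduction in reproductive output relative to an
    all-wild-type population over one generation: homozygote deaths
    contribute q, and the dominant lethal edits made in heterozygous
    germlines contribute the rest.
    """
    if not 0.0 <= q <= 1.0:
        raise ModelError(f"load undefined at q={q}")
    return 2.0 * q / (1.0 + q)


def fitness_from_frequencies(q_t: float, q_t1: float) -> float:
    """Realized fitness across one generation from censused frequencies.

    The odds ratio ``[q_t1/(1-q_t1)] / [q_t/(1-q_t)]``; both frequencies
    must lie strictly inside (0, 1).
    """
    for q in (q_t, q_t1):
        if not 0.0 < q < 1.0:
            raise ModelError(f"fitness undefined at boundary frequency {q}")
    return (q_t1 / (1.0 - q_t1)) / (q_t / (1.0 - q_t))


def no_drive_condition(s: float, h: float, u: float) -> bool:
    """Whether the construct is prevented from driving at every frequency.

    With fully penetrant dominant lethal edits, drive is prevented iff
    ``(s - h*s)/(1 - h*s) >= u``, where ``s`` is the construct's homozygous
    cost, ``h*s`` its heterozygous cost and ``u`` the editing rate.  A fully
    penetrant recessive lethal construct (s = 1) satisfies the condition for
    every editing rate.
    """
    for name, v in (("s", s), ("h", h), ("u", u)):
        if not 0.0 <= v <= 1.0:
            raise ModelError(f"{name}={v} outside [0, 1]")
    hs = h * s
    if hs >= 1.0:
        raise ModelError("no-drive condition undefined at h*s = 1")
    return (s - hs) / (1.0 - hs) >= u


def _one_generation(q: float, params: GeneticParams):
    """One life cycle from a Hardy-Weinberg hatchling census at frequency q.

    Returns ``(q_next, q_adult)``: the construct frequency at the next
    hatchling census and at the adult (post-selection) stage in between.
    """
    params.validate()
    if not 0.0 <= q <= 1.0:
        raise ModelError(f"frequency {q} outside [0, 1]")
    s_c, h_c = params.s_construct, params.h_construct
    u, f = params.u, params.frac_recessive

    # hatchlings at Hardy-Weinberg proportions over {W, G}
    ww = (1.0 - q) ** 2
    wg = 2.0 * q * (1.0 - q)
    gg = q * q
    # viability selection on the construct
    a_ww = ww
    a_wg = wg * (1.0 - h_c * s_c)
    a_gg = gg * (1.0 - s_c)
    wbar = a_ww + a_wg + a_gg
    if wbar <= 0.0:
        return 0.0, 0.0
    q_adult = (0.5 * a_wg + a_gg) / wbar

    # gametes; heterozygous germlines edit their wild-type allele
    g_w = a_ww + 0.5 * a_wg * (1.0 - u)
    g_g = 0.5 * a_wg + a_gg
    g_ed = 0.5 * a_wg * u * (1.0 - f)
    g_er = 0.5 * a_wg * u * f
    tot = g_w + g_g + g_ed + g_er
    g_w, g_g, g_ed, g_er = (x / tot for x in (g_w, g_g, g_ed, g_er))

    # random union of gametes; embryonic deaths of dominant-edit carriers
    # (in-cis protection never applies: E and G are alternative alleles)
    freqs = {"W": g_w, "G": g_g, "Ed": g_ed, "Er": g_er}
    surv = 0.0
    g_alleles = 0.0
    for a1, p1 in freqs.items():
        for a2, p2 in freqs.items():
            z = p1 * p2
            if z == 0.0:
                continue
            n_ed = (a1 == "Ed") + (a2 == "Ed")
            if n_ed == 2:
                z *= 1.0 - params.s_edit
            elif n_ed == 1:
                z *= 1.0 - params.h_edit * params.s_edit
            surv += z
            g_alleles += z * ((a1 == "G") + (a2 == "G")) / 2.0
    if surv <= 0.0:
        return 0.0, q_adult
    q_next = g_alleles / surv
    q_next = min(max(q_next, 0.0), 1.0)
    if q_next < _CLIP_TOL:
        q_next = 0.0 if q == 0.0 else q_next
    return q_next, q_adult


def analytic_step(q: float, params: GeneticParams) -> float:
    """Construct frequency at the next hatchling census.

    One generation of the single-sex recursion: Hardy-Weinberg hatchlings at
    frequency ``q``, construct viability selection, germline editing at rate
    ``u``, random union of gametes, and embryonic deaths of edit carriers.
    For idealized parameters this map is the identity on [0, 1).
    """
    return _one_generation(q, params)[0]


def analytic_trajectory(q0: float, params: GeneticParams, generations: int,
                        census: str = "hatchling") -> np.ndarray:
    """Iterate :func:`analytic_step` for ``generations`` steps.

    ``census="hatchling"`` records the hatchling-stage frequency each
    generation (including ``q0``); ``census="adult"`` records the
    post-selection adult frequency of each cycle.
    """
    if census not in ("hatchling", "adult"):
        raise ModelError(f"unknown census {census!r}")
    q = float(q0)
    out = []
    if census == "hatchling":
        out.append(q)
    for _ in range(generations):
        q_next, q_adult = _one_generation(q, params)
        out.append(q_adult if census == "adult" else q_next)
        q = q_next
    return np.asarray(out)


def adult_genotype_distribution(q: float, params: GeneticParams) -> dict:
    """Post-selection adult genotype frequencies {WW, WG, GG} of one cycle.

    Convenience for seeding the two-sex simulator in the exact regime (fully
    penetrant dominant edits) where hatchlings are Hardy-Weinberg over
    {W, G}.
    """
    params.validate()
    s_c, h_c = params.s_construct, params.h_construct
    a = {
        "WW": (1.0 - q) ** 2,
        "WG": 2.0 * q * (1.0 - q) * (1.0 - h_c * s_c),
        "GG": q * q * (1.0 - s_c),
    }
    tot = sum(a.values())
    if tot <= 0.0:
        raise ModelError("no surviving adults")
    return {k: v / tot for k, v in a.items()}
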