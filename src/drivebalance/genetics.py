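"""Core genetics: alleles, haplotypes, genotypes, gametes, and viability.

The engine tracks genotype frequencies over one to three autosomal loci plus
an optional sex-chromosome pair.  Each locus has a small allele alphabet and a
semantic *role* that determines how it participates in germline transmission
(editing, homing, X-shredding, loss-of-function mutation, recombination) and
in stage-specific survival and fertility.

Roles
-----
``pdne``
    Single-locus protected dominant-negative editor.  The construct ``G`` is
    inserted into a haplosufficient (HS) gene, disrupting it (recessive
    lethality when no functional copy remains) while its germline editor
    converts wild-type alleles into dominant (``E_dom``) or recessive
    (``E_rec``) edits of the same gene.  The construct haplotype is protected
    in cis by design: a construct-bearing chromosome can never express an
    edit, so no "protected edit" allele exists.
``pdne_construct`` / ``hi_target``
    Two-locus implementation: the construct (inserted into an HS gene,
    carrying a recoded rescue copy of the target) edits a separate
    haploinsufficient (HI) gene.  Death occurs when functional HI doses
    (wild-type copies plus recoded copies on construct alleles) fall below 2.
``dominant_lethal``
    A static dominant lethal allele ``D`` (SIT / RIDL / fsRIDL released
    genotypes, with timing and sex-limitation set by the strategy).
``shredder``
    Autosomal X-shredder ``Sh``: in carrier males, X-bearing gametes are
    destroyed at ``shred_rate`` (the remaining pool is renormalized, i.e.
    sperm competition makes up the numbers).
``fem_edit_target``
    Autosomal target of a Y-linked editor: carrier males convert wild-type
    alleles to the female-lethal edit ``E_fem`` in every gamete at rate ``u``.
``fs_drive``
    Female-specific dominant lethal ``D`` that homes in the male germline at
    ``homing_rate`` (fs-RIDL-drive).
``homing_booster``
    Second locus carrying a gRNA ``Hb`` that, together with Cas9 expressed
    from a full construct ``G``, cleaves the wild-type allele at the construct
    locus; cleaved alleles convert to ``G`` with probability ``homing_rate``
    and are restored to wild type otherwise.  The booster itself is inherited
    in a Mendelian fashion.
``cnr_booster`` / ``cnr_target``
    Cleave-and-rescue booster: a gRNA ``Bc`` directs the construct's Cas9 to a
    second haplosufficient gene with female-specific function; the construct
    carries a recoded rescue copy.  Females with no functional copy (counting
    the construct's rescue) die.
``sex``
    Sex-chromosome pair (``X``/``Y``/``Y_editor``); assorts independently of
    the autosomes.  When absent, offspring sex is assigned 50:50.

All distributions are exact expectations; there is no randomness anywhere in
the engine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

__all__ = [
    "ConfigError",
    "ModelError",
    "Locus",
    "Architecture",
    "GeneticParams",
    "Genotype",
    "Viability",
    "gamete_distribution",
    "viability",
    "offspring_distribution",
    "wild_haplotype",
    "wildtype",
]


class ConfigError(ValueError):
    """Invalid configuration (unknown allele, bad parameter, bad genotype)."""


class ModelError(RuntimeError):
    """Internal inconsistency (probabilities outside [0, 1], impossible state)."""


#: probabilities below this are pruned from distributions to bound state space
PRUNE_TOL = 1e-15

# --- allele symbols -------------------------------------------------------

WILD = "W"
CONSTRUCT = "G"
LOF_CAS9 = "G_dCas9"  # Cas9 component dead, gRNA intact
LOF_GRNA = "G_dgRNA"  # gRNA component dead, Cas9 intact
LOF_BOTH = "G_dBoth"
EDIT_DOM = "E_dom"
EDIT_REC = "E_rec"
X = "X"
Y = "Y"
Y_EDITOR = "Y_editor"

#: construct-class alleles: all disrupt the HS insertion gene and (two-locus
#: design) all retain the recoded rescue copy; only ``G`` can edit.
CONSTRUCT_CLASS = frozenset({CONSTRUCT, LOF_CAS9, LOF_GRNA, LOF_BOTH})
X_CLASS = frozenset({X})
Y_CLASS = frozenset({Y, Y_EDITOR})

# --- locus roles ----------------------------------------------------------

ROLE_PDNE = "pdne"
ROLE_PDNE_CONSTRUCT = "pdne_construct"
ROLE_HI_TARGET = "hi_target"
ROLE_DOMINANT_LETHAL = "dominant_lethal"
ROLE_SHREDDER = "shredder"
ROLE_FEM_EDIT = "fem_edit_target"
ROLE_FS_DRIVE = "fs_drive"
ROLE_HOMING_BOOSTER = "homing_booster"
ROLE_CNR_BOOSTER = "cnr_booster"
ROLE_CNR_TARGET = "cnr_target"
ROLE_SEX = "sex"

#: default allele alphabet per role; the wild-type allele is listed first.
ROLE_ALPHABETS = {
    ROLE_PDNE: (WILD, CONSTRUCT, LOF_CAS9, LOF_GRNA, LOF_BOTH, EDIT_DOM, EDIT_REC),
    ROLE_PDNE_CONSTRUCT: (WILD, CONSTRUCT, LOF_CAS9, LOF_GRNA, LOF_BOTH),
    ROLE_HI_TARGET: ("Wb", "Eb"),
    ROLE_DOMINANT_LETHAL: (WILD, "D"),
    ROLE_SHREDDER: (WILD, "Sh"),
    ROLE_FEM_EDIT: (WILD, "E_fem"),
    ROLE_FS_DRIVE: (WILD, "D"),
    ROLE_HOMING_BOOSTER: ("Wc", "Hb"),
    ROLE_CNR_BOOSTER: ("Wc", "Bc"),
    ROLE_CNR_TARGET: ("Wt", "Et"),
    ROLE_SEX: (X, Y, Y_EDITOR),
}

Haplotype = tuple  # tuple of allele symbols, one per locus, in locus order


@dataclass(frozen=True)
class Locus:
    """A modeled locus: a name, a role, and its allele alphabet."""

    name: str
    role: str
    alleles: tuple = ()

    def __post_init__(self):
        if self.role not in ROLE_ALPHABETS:
            raise ConfigError(f"unknown locus role {self.role!r}")
        if not self.alleles:
            object.__setattr__(self, "alleles", ROLE_ALPHABETS[self.role])

    @property
    def wild(self) -> str:
        return self.alleles[0]


@dataclass(frozen=True)
class Architecture:
    """Ordered loci shared by every individual in a simulated population.

    The locus order is fixed population-wide; when a sex-chromosome pair is
    modeled it must be the last locus and it assorts independently of the
    autosomes (effective r = 0.5 to its neighbor).
    """

    loci: tuple

    def __post_init__(self):
        roles = [l.role for l in self.loci]
        if len({l.name for l in self.loci}) != len(self.loci):
            raise ConfigError("duplicate locus names")
        if ROLE_SEX in roles and roles.index(ROLE_SEX) != len(roles) - 1:
            raise ConfigError("the sex-chromosome pair must be the last locus")
        if roles.count(ROLE_SEX) > 1:
            raise ConfigError("at most one sex-chromosome pair")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sex_index(self):
        for i, l in enumerate(self.loci):
            if l.role == ROLE_SEX:
                return i
        return None

    def index_of_role(self, role: str):
        for i, l in enumerate(self.loci):
            if l.role == role:
                return i
        return None

    def recomb_rates(self, params: "GeneticParams") -> tuple:
        """Per-adjacent-pair recombination rates (sex boundary forced to 0.5)."""
        n_pairs = self.n_loci - 1
        r = params.recomb_r
        if isinstance(r, (int, float)):
            rates = [float(r)] * n_pairs
        else:
            if len(r) != n_pairs:
                raise ConfigError(
                    f"recomb_r needs {n_pairs} rates, got {len(r)}"
                )
            rates = [float(x) for x in r]
        if self.sex_index is not None and n_pairs:
            rates[-1] = 0.5
        for x in rates:
            if not 0.0 <= x <= 0.5:
                raise ConfigError("recombination rates must lie in [0, 0.5]")
        return tuple(rates)

    def validate_haplotype(self, hap: Haplotype) -> None:
        if len(hap) != self.n_loci:
            raise ConfigError(f"haplotype {hap!r} has wrong length")
        for allele, locus in zip(hap, self.loci):
            if allele not in locus.alleles:
                raise ConfigError(
                    f"unknown allele {allele!r} at locus {locus.name!r}"
                )


@dataclass(frozen=True)
class GeneticParams:
    """Transmission and fitness parameters for one strategy.

    Parameters
    ----------
    u : float
        Probability that a wild-type target allele is edited per germline.
    s_edit, h_edit : float
        Fitness cost of the dominant edit and its dominance coefficient.
    frac_recessive : float
        Fraction of edits that are recessive (plain loss-of-function alleles
        of the disrupted gene) rather than dominant.
    s_construct, h_construct : float
        Homozygous construct cost and its dominance coefficient (leaky
        somatic expression / insertion-site effects in heterozygotes).
    mu_lof : float
        Per-component (Cas9, gRNA) per-generation loss-of-function
        probability, applied at gamete formation.
    timing : {"early", "late", "fertility"}
        Life stage at which genetic costs act: before density-dependent
        juvenile mortality, after it, or on adult fertility.
    sex_limited_edit : {"both", "female_only"}
        Whether edit-class costs are expressed in both sexes or females only.
    homing_rate : float
        Conversion probability of a cleaved wild-type allele to the construct
        (homing booster, fs-RIDL-drive).
    shred_rate : float
        Fraction of X-bearing gametes destroyed in shredder-carrying males.
    recomb_r : float or tuple
        Recombination rate(s) between adjacent loci (<= 0.5 each).
    """

    u: float = 0.0
    s_edit: float = 0.0
    h_edit: float = 1.0
    frac_recessive: float = 0.0
    s_construct: float = 0.0
    h_construct: float = 0.0
    mu_lof: float = 0.0
    timing: str = "late"
    sex_limited_edit: str = "both"
    homing_rate: float = 0.0
    shred_rate: float = 0.0
    recomb_r: object = 0.5

    def validate(self) -> None:
        for name in ("u", "s_edit", "h_edit", "frac_recessive", "s_construct",
                     "h_construct", "mu_lof", "homing_rate", "shred_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.timing not in ("early", "late", "fertility"):
            raise ConfigError(f"unknown timing {self.timing!r}")
        if self.sex_limited_edit not in ("both", "female_only"):
            raise ConfigError(
                f"unknown sex_limited_edit {self.sex_limited_edit!r}"
            )
        r = self.recomb_r
        vals = [r] if isinstance(r, (int, float)) else list(r)
        for x in vals:
            if not 0.0 <= float(x) <= 0.5:
                raise ConfigError(f"recomb_r={x} outside [0, 0.5]")


FEMALE = "f"
MALE = "m"


@dataclass(frozen=True)
class Genotype:
    """An unordered haplotype pair plus sex.

    Use :func:`genotype` to construct one with canonical haplotype ordering
    and sex consistency checks.
    """

    haplotypes: tuple  # (hap1, hap2), sorted
    sex: str

    @property
    def alleles(self):
        """Pairs of alleles per locus: tuple of (a_locus0_hap0, ...)."""
        return tuple(zip(*self.haplotypes))

    def count(self, locus_index: int, symbols) -> int:
        if isinstance(symbols, str):
            symbols = (symbols,)
        return sum(
            1 for h in self.haplotypes if h[locus_index] in symbols
        )

    def carries(self, locus_index: int, symbols) -> bool:
        return self.count(locus_index, symbols) > 0

    def label(self) -> str:
        a, b = self.haplotypes
        return "|".join("+".join(h) for h in (a, b)) + f" ({self.sex})"


def genotype(hap1: Iterable, hap2: Iterable, sex: str | None,
             arch: Architecture) -> Genotype:
    """Build a canonical :class:`Genotype`, inferring sex from sex alleles."""
    h1, h2 = tuple(hap1), tuple(hap2)
    arch.validate_haplotype(h1)
    arch.validate_haplotype(h2)
    si = arch.sex_index
    if si is not None:
        sa = {h1[si], h2[si]}
        n_y = sum(1 for h in (h1, h2) if h[si] in Y_CLASS)
        if n_y == 0:
            inferred = FEMALE
        elif n_y == 1:
            inferred = MALE
        else:
            raise ConfigError("YY genotypes are not modeled")
        if sex is not None and sex != inferred:
            raise ConfigError(
                f"sex {sex!r} inconsistent with sex alleles {sorted(sa)}"
            )
        sex = inferred
    elif sex not in (FEMALE, MALE):
        raise ConfigError("sex must be 'f' or 'm' when no sex pair is modeled")
    return Genotype(haplotypes=tuple(sorted((h1, h2))), sex=sex)


def wild_haplotype(arch: Architecture, sex_allele: str | None = None) -> Haplotype:
    hap = [l.wild for l in arch.loci]
    if arch.sex_index is not None:
        hap[arch.sex_index] = sex_allele if sex_allele is not None else X
    return tuple(hap)


def wildtype(arch: Architecture, sex: str) -> Genotype:
    """The all-wild-type genotype of the given sex."""
    if arch.sex_index is None:
        h = wild_haplotype(arch)
        return genotype(h, h, sex, arch)
    if sex == FEMALE:
        return genotype(wild_haplotype(arch, X), wild_haplotype(arch, X), None, arch)
    return genotype(wild_haplotype(arch, X), wild_haplotype(arch, Y), None, arch)


# --- gamete formation -----------------------------------------------------


def _segregate(parent: Genotype, arch: Architecture,
               params: GeneticParams) -> dict:
    """Mendelian segregation with recombination between adjacent loci."""
    h1, h2 = parent.haplotypes
    L = arch.n_loci
    if L == 1 or h1 == h2:
        if h1 == h2:
            return {h1: 1.0}
        if L == 1:
            return {h1: 0.5, h2: 0.5}
    rates = arch.recomb_rates(params)
    out: dict = {}
    pair = (h1, h2)
    for pattern in itertools.product((0, 1), repeat=L):
        p = 0.5
        for i in range(1, L):
            p *= rates[i - 1] if pattern[i] != pattern[i - 1] else 1.0 - rates[i - 1]
        gam = tuple(pair[b][i] for i, b in enumerate(pattern))
        out[gam] = out.get(gam, 0.0) + p
    return out


def _apply_allele_map(dist: dict, locus_index: int, amap: Mapping) -> dict:
    """Apply a per-allele stochastic map at one locus to every gamete."""
    out: dict = {}
    for hap, p in dist.items():
        a = hap[locus_index]
        targets = amap.get(a)
        if not targets:
            out[hap] = out.get(hap, 0.0) + p
            continue
        for b, q in targets.items():
            if q <= 0.0:
                continue
            h2 = hap[:locus_index] + (b,) + hap[locus_index + 1:]
            out[h2] = out.get(h2, 0.0) + p * q
    return out


def _branch(wild: str, outcomes: dict) -> dict:
    """Allele map for ``wild`` with the given outcome probabilities."""
    total = sum(outcomes.values())
    if total > 1.0 + 1e-12:
        raise ModelError("branch probabilities exceed 1")
    m = dict(outcomes)
    rest = 1.0 - total
    if rest > 0.0:
        m[wild] = m.get(wild, 0.0) + rest
    return {wild: m}


def gamete_distribution(parent: Genotype, arch: Architecture,
                        params: GeneticParams) -> dict:
    """Gamete haplotype distribution produced by one parent.

    Segregation with recombination is followed, in order, by: homing at the
    construct locus (booster-enabled, or fs-RIDL-drive self-homing in males),
    germline editing of wild-type target alleles, loss-of-function mutation
    of construct components, and X-shredding in carrier males (with
    renormalization).  Editing requires a construct allele with both
    components functional (``G``); LOF derivatives cannot edit.

    Returns a dict mapping haplotypes to probabilities summing to 1.
    """
    params.validate()
    for h in parent.haplotypes:
        arch.validate_haplotype(h)
    dist = _segregate(parent, arch, params)

    i_pdne = arch.index_of_role(ROLE_PDNE)
    i_cons = arch.index_of_role(ROLE_PDNE_CONSTRUCT)
    i_hi = arch.index_of_role(ROLE_HI_TARGET)
    i_construct_locus = i_pdne if i_pdne is not None else i_cons
    has_cas9_grna = (
        i_construct_locus is not None
        and parent.carries(i_construct_locus, CONSTRUCT)
    )

    # 1. homing of the construct (cleavage at the insertion site precedes
    #    editing of the same wild-type allele)
    i_boost = arch.index_of_role(ROLE_HOMING_BOOSTER)
    if (
        i_boost is not None
        and i_construct_locus is not None
        and params.homing_rate > 0.0
        and has_cas9_grna
        and parent.carries(i_boost, "Hb")
    ):
        wild = arch.loci[i_construct_locus].wild
        dist = _apply_allele_map(
            dist, i_construct_locus,
            _branch(wild, {CONSTRUCT: params.homing_rate}),
        )

    i_fs = arch.index_of_role(ROLE_FS_DRIVE)
    if (
        i_fs is not None
        and parent.sex == MALE
        and params.homing_rate > 0.0
        and parent.carries(i_fs, "D")
    ):
        dist = _apply_allele_map(
            dist, i_fs, _branch(WILD, {"D": params.homing_rate})
        )

    # 2. germline editing
    if params.u > 0.0 and has_cas9_grna:
        u, f = params.u, params.frac_recessive
        if i_pdne is not None:
            dist = _apply_allele_map(
                dist, i_pdne,
                _branch(WILD, {EDIT_DOM: u * (1.0 - f), EDIT_REC: u * f}),
            )
        if i_cons is not None and i_hi is not None:
            dist = _apply_allele_map(
                dist, i_hi, _branch("Wb", {"Eb": u})
            )
        i_cb = arch.index_of_role(ROLE_CNR_BOOSTER)
        i_ct = arch.index_of_role(ROLE_CNR_TARGET)
        if i_cb is not None and i_ct is not None and parent.carries(i_cb, "Bc"):
            dist = _apply_allele_map(
                dist, i_ct, _branch("Wt", {"Et": u})
            )

    i_fem = arch.index_of_role(ROLE_FEM_EDIT)
    if (
        i_fem is not None
        and params.u > 0.0
        and parent.sex == MALE
        and arch.sex_index is not None
        and parent.carries(arch.sex_index, Y_EDITOR)
    ):
        dist = _apply_allele_map(
            dist, i_fem, _branch(WILD, {"E_fem": params.u})
        )

    # 3. loss-of-function mutation of construct components
    if params.mu_lof > 0.0 and i_construct_locus is not None:
        mu, keep = params.mu_lof, 1.0 - params.mu_lof
        lof_map = {
            CONSTRUCT: {CONSTRUCT: keep * keep, LOF_CAS9: mu * keep,
                        LOF_GRNA: keep * mu, LOF_BOTH: mu * mu},
            LOF_CAS9: {LOF_CAS9: keep, LOF_BOTH: mu},
            LOF_GRNA: {LOF_GRNA: keep, LOF_BOTH: mu},
        }
        dist = _apply_allele_map(dist, i_construct_locus, lof_map)

    # 4. X-shredding in carrier males (destroyed sperm are made up by the
    #    remaining pool: renormalize)
    i_sh = arch.index_of_role(ROLE_SHREDDER)
    si = arch.sex_index
    if (
        i_sh is not None
        and si is not None
        and parent.sex == MALE
        and params.shred_rate > 0.0
        and parent.carries(i_sh, "Sh")
    ):
        dist = {
            hap: (p * (1.0 - params.shred_rate) if hap[si] in X_CLASS else p)
            for hap, p in dist.items()
        }

    dist = {h: p for h, p in dist.items() if p > PRUNE_TOL}
    total = sum(dist.values())
    if not dist or total <= 0.0:
        raise ModelError("gamete distribution vanished")
    dist = {h: p / total for h, p in dist.items()}
    for p in dist.values():
        if not 0.0 <= p <= 1.0 + 1e-12:
            raise ModelError(f"gamete probability {p} outside [0, 1]")
    return dist


# --- viability ------------------------------------------------------------


@dataclass(frozen=True)
class Viability:
    """Stage-specific survival/fertility multipliers for one genotype."""

    early_survival: float = 1.0
    late_survival: float = 1.0
    fertility: float = 1.0

    @property
    def total(self) -> float:
        return self.early_survival * self.late_survival * self.fertility


def _dominance_factor(n_copies: int, s: float, h: float) -> float:
    if n_copies >= 2:
        return 1.0 - s
    if n_copies == 1:
        return 1.0 - h * s
    return 1.0


def viability(g: Genotype, arch: Architecture,
              params: GeneticParams) -> Viability:
    """Survival and fertility components of one genotype.

    All genetic costs are multiplied into a single factor and routed to the
    life stage named by ``params.timing``.  Edit-class costs (dominant edits,
    haploinsufficient-dose shortfalls, dominant lethals, female-lethal edits)
    are exempted in males when ``sex_limited_edit == "female_only"``.
    """
    params.validate()
    for h in g.haplotypes:
        arch.validate_haplotype(h)
    w = 1.0
    male_exempt = params.sex_limited_edit == "female_only" and g.sex == MALE

    i_pdne = arch.index_of_role(ROLE_PDNE)
    if i_pdne is not None:
        n_func = g.count(i_pdne, WILD)  # functional copies of the HS gene
        if male_exempt:
            # female-limited designs target a gene whose disrupted function
            # is female-specific (doublesex-like): edit alleles keep full
            # male function and count as functional copies in males
            n_func += g.count(i_pdne, (EDIT_DOM, EDIT_REC))
        n_g = g.count(i_pdne, CONSTRUCT_CLASS)
        if n_func == 0:
            w *= 1.0 - params.s_construct
        elif n_g == 1:
            w *= 1.0 - params.h_construct * params.s_construct
        if not male_exempt:
            # an E_dom allele is always expressed: in this design the edit
            # and the construct are alternative alleles, so no cis silencing
            w *= _dominance_factor(
                g.count(i_pdne, EDIT_DOM), params.s_edit, params.h_edit
            )

    i_cons = arch.index_of_role(ROLE_PDNE_CONSTRUCT)
    i_hi = arch.index_of_role(ROLE_HI_TARGET)
    if i_cons is not None:
        n_func = g.count(i_cons, WILD)
        n_g = g.count(i_cons, CONSTRUCT_CLASS)
        if n_func == 0:
            w *= 1.0 - params.s_construct
        elif n_g == 1:
            w *= 1.0 - params.h_construct * params.s_construct
        if i_hi is not None and not male_exempt:
            # functional HI doses: wild-type copies + recoded rescue copies
            doses = g.count(i_hi, "Wb") + n_g
            if doses == 0:
                w *= 1.0 - params.s_edit
            elif doses == 1:
                w *= 1.0 - params.h_edit * params.s_edit

    for role in (ROLE_DOMINANT_LETHAL, ROLE_FS_DRIVE):
        i = arch.index_of_role(role)
        if i is not None and not male_exempt:
            w *= _dominance_factor(g.count(i, "D"), params.s_edit, params.h_edit)

    i_fem = arch.index_of_role(ROLE_FEM_EDIT)
    if i_fem is not None and g.sex == FEMALE:
        w *= _dominance_factor(g.count(i_fem, "E_fem"),
                               params.s_edit, params.h_edit)

    i_ct = arch.index_of_role(ROLE_CNR_TARGET)
    if i_ct is not None and g.sex == FEMALE:
        rescue = (
            g.count(i_pdne, CONSTRUCT_CLASS) if i_pdne is not None else 0
        )
        if g.count(i_ct, "Wt") + rescue == 0:
            w *= 0.0  # female-specific HS gene with no functional copy

    if not -1e-12 <= w <= 1.0 + 1e-12:
        raise ModelError(f"viability {w} outside [0, 1]")
    w = min(max(w, 0.0), 1.0)
    if params.timing == "early":
        return Viability(early_survival=w)
    if params.timing == "fertility":
        return Viability(fertility=w)
    return Viability(late_survival=w)


# --- offspring ------------------------------------------------------------


def offspring_distribution(mother: Genotype, father: Genotype,
                           arch: Architecture,
                           params: GeneticParams) -> dict:
    """Offspring genotype distribution of one mating, before viability.

    Returns an empty dict (distinct from an error) when either parent is
    fully sterile.  Sex is assigned by sex-chromosome inheritance when a sex
    pair is modeled, otherwise 50:50.
    """
    if mother.sex != FEMALE or father.sex != MALE:
        raise ConfigError("offspring_distribution needs a female and a male")
    if viability(mother, arch, params).fertility == 0.0:
        return {}
    if viability(father, arch, params).fertility == 0.0:
        return {}
    egg = gamete_distribution(mother, arch, params)
    sperm = gamete_distribution(father, arch, params)
    si = arch.sex_index
    out: dict = {}
    for ge, pe in egg.items():
        for gs, ps in sperm.items():
            p = pe * ps
            if p <= PRUNE_TOL:
                continue
            pair = tuple(sorted((ge, gs)))
            if si is not None:
                if ge[si] in Y_CLASS:
                    raise ModelError("Y-bearing egg")
                sex = MALE if gs[si] in Y_CLASS else FEMALE
                child = Genotype(pair, sex)
                out[child] = out.get(child, 0.0) + p
            else:
                for sex in (FEMALE, MALE):
                    child = Genotype(pair, sex)
                    out[child] = out.get(child, 0.0) + p * 0.5
    total = sum(out.values())
    if abs(total - 1.0) > 1e-9:
        raise ModelError(f"offspring distribution sums to {total}")
    return {g: p / total for g, p in out.items() if p > PRUNE_TOL}
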