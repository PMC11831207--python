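"""Strategy factory: named genetic-biocontrol architectures.

Maps a strategy name plus options to a complete architecture (loci and
allele alphabets), resolved :class:`~drivebalance.genetics.GeneticParams`,
and the released male genotype.  Registered strategies:

``sit``
    Males homozygous for a bisex dominant lethal acting before
    density-dependent mortality (sterile-insect technique and
    incompatible-male equivalents).
``ridl`` / ``fsridl``
    Bisex or female-specific dominant lethal acting after density-dependent
    mortality.
``xs``
    Autosomal X-shredder homozygous males; offspring are biased toward sons.
``yle``
    Y-linked editor creating dominant female-lethal edits in every gamete of
    carrier males.
``fsridl_drive``
    Autosomal female-specific dominant lethal that homes in the male
    germline; heterozygous males are released.
``pdne1`` / ``pdne``
    Single-locus protected dominant-negative editor; heterozygous males are
    released.  Options: ``booster="homing"`` adds a Mendelian gRNA locus
    that lets the construct home; ``booster="cnr"`` adds a cleave-and-rescue
    booster with its female-specific target gene.
``pdne2``
    Two-locus implementation (construct in a haplosufficient gene, edits in
    a separate haploinsufficient gene); equivalent to ``pdne1`` under
    idealized parameters.

The ``idealized`` flag (default True) sets perfect genetic efficiencies and
no unintended fitness effects: u = 1, s_edit = 1, h_edit = 1,
frac_recessive = 0, s_construct = 1, h_construct = 0, mu_lof = 0, and
homing/shredding rates of 1 where the strategy uses them.  Keyword
overrides replace individual parameters after the idealized baseline is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genetics import (
    CONSTRUCT,
    ConfigError,
    EDIT_DOM,
    GeneticParams,
    Genotype,
    Architecture,
    Locus,
    MALE,
    ROLE_CNR_BOOSTER,
    ROLE_CNR_TARGET,
    ROLE_DOMINANT_LETHAL,
    ROLE_FEM_EDIT,
    ROLE_FS_DRIVE,
    ROLE_HI_TARGET,
    ROLE_HOMING_BOOSTER,
    ROLE_PDNE,
    ROLE_PDNE_CONSTRUCT,
    ROLE_SEX,
    ROLE_SHREDDER,
    WILD,
    X,
    Y,
    Y_EDITOR,
    genotype,
)

__all__ = ["StrategySpec", "make_strategy", "strategy_names"]


@dataclass(frozen=True)
class StrategySpec:
    """A resolved strategy: architecture, parameters, released genotype."""

    name: str
    arch: Architecture
    params: GeneticParams
    release_genotype: Genotype
    options: tuple = ()  # resolved (key, value) pairs, for manifests

    def with_params(self, **changes) -> "StrategySpec":
        return replace(self, params=replace(self.params, **changes))


_PARAM_FIELDS = {
    "u", "s_edit", "h_edit", "frac_recessive", "s_construct", "h_construct",
    "mu_lof", "timing", "sex_limited_edit", "homing_rate", "shred_rate",
    "recomb_r",
}


def _resolve_params(base: GeneticParams, idealized_updates: dict,
                    overrides: dict) -> GeneticParams:
    p = replace(base, **idealized_updates)
    bad = set(overrides) - _PARAM_FIELDS
    if bad:
        raise ConfigError(f"unknown parameter overrides: {sorted(bad)}")
    p = replace(p, **overrides)
    p.validate()
    return p


def _dominant_lethal(name, timing, sex_limited, idealized, overrides):
    arch = Architecture((Locus("lethal", ROLE_DOMINANT_LETHAL),))
    ideal = dict(s_edit=1.0, h_edit=1.0) if idealized else {}
    params = _resolve_params(
        GeneticParams(timing=timing, sex_limited_edit=sex_limited),
        ideal, overrides,
    )
    release = genotype(("D",), ("D",), MALE, arch)
    return arch, params, release


def _pdne_release_haps(booster_copies: int, booster_allele: str,
                       extra_wild: tuple = ()):
    """Haplotype pair for a construct heterozygote with booster copies."""
    wild_c = "Wc"
    h1 = (CONSTRUCT, booster_allele if booster_copies >= 1 else wild_c) + extra_wild
    h2 = (WILD, booster_allele if booster_copies >= 2 else wild_c) + extra_wild
    return h1, h2


def make_strategy(name: str, idealized: bool = True, *,
                  booster: str | None = None, booster_copies: int = 1,
                  linkage_r: float | None = None,
                  release_homozygous: bool = False,
                  **overrides) -> StrategySpec:
    """Build a :class:`StrategySpec` from a registered strategy name.

    ``overrides`` are :class:`GeneticParams` field values applied after the
    idealized baseline.  ``booster`` (``"homing"`` or ``"cnr"``) is only
    valid with the single-locus PDNE; ``booster_copies`` is the number of
    booster alleles carried by released males; ``linkage_r`` sets the
    recombination rate between the construct locus and the booster locus
    (default: unlinked for the homing booster, 0.05 for cleave and rescue).
    ``release_homozygous`` releases construct homozygotes instead of
    heterozygotes where that is an option (fsridl_drive).
    """
    key = name.lower().replace("-", "_")
    if booster is not None and key not in ("pdne", "pdne1"):
        raise ConfigError("boosters require the single-locus PDNE")

    if key == "sit":
        arch, params, release = _dominant_lethal(
            key, "early", "both", idealized, overrides)
    elif key == "ridl":
        arch, params, release = _dominant_lethal(
            key, "late", "both", idealized, overrides)
    elif key == "fsridl":
        arch, params, release = _dominant_lethal(
            key, "late", "female_only", idealized, overrides)
    elif key == "xs":
        arch = Architecture((
            Locus("shredder", ROLE_SHREDDER), Locus("sex", ROLE_SEX),
        ))
        ideal = dict(shred_rate=1.0) if idealized else {}
        params = _resolve_params(GeneticParams(timing="late"), ideal, overrides)
        release = genotype(("Sh", X), ("Sh", Y), None, arch)
    elif key == "yle":
        arch = Architecture((
            Locus("edit_target", ROLE_FEM_EDIT), Locus("sex", ROLE_SEX),
        ))
        ideal = dict(u=1.0, s_edit=1.0, h_edit=1.0) if idealized else {}
        params = _resolve_params(
            GeneticParams(timing="late", sex_limited_edit="female_only"),
            ideal, overrides,
        )
        release = genotype((WILD, X), (WILD, Y_EDITOR), None, arch)
    elif key == "fsridl_drive":
        arch = Architecture((Locus("drive", ROLE_FS_DRIVE),))
        ideal = dict(s_edit=1.0, h_edit=1.0, homing_rate=1.0) if idealized else {}
        params = _resolve_params(
            GeneticParams(timing="late", sex_limited_edit="female_only"),
            ideal, overrides,
        )
        first = ("D",)
        second = ("D",) if release_homozygous else (WILD,)
        release = genotype(first, second, MALE, arch)
    elif key in ("pdne", "pdne1"):
        ideal = (
            dict(u=1.0, s_edit=1.0, h_edit=1.0, frac_recessive=0.0,
                 s_construct=1.0, h_construct=0.0, mu_lof=0.0)
            if idealized else {}
        )
        if booster is None:
            arch = Architecture((Locus("construct", ROLE_PDNE),))
            params = _resolve_params(GeneticParams(timing="late"), ideal,
                                     overrides)
            release = genotype((CONSTRUCT,), (WILD,), MALE, arch)
        elif booster == "homing":
            arch = Architecture((
                Locus("construct", ROLE_PDNE),
                Locus("booster", ROLE_HOMING_BOOSTER),
            ))
            if idealized:
                ideal["homing_rate"] = 1.0
            r = 0.5 if linkage_r is None else linkage_r
            params = _resolve_params(
                GeneticParams(timing="late", recomb_r=(r,)), ideal, overrides)
            if not 0 <= booster_copies <= 2:
                raise ConfigError("booster_copies must be 0, 1, or 2")
            h1, h2 = _pdne_release_haps(booster_copies, "Hb")
            release = genotype(h1, h2, MALE, arch)
        elif booster == "cnr":
            arch = Architecture((
                Locus("construct", ROLE_PDNE),
                Locus("booster", ROLE_CNR_BOOSTER),
                Locus("booster_target", ROLE_CNR_TARGET),
            ))
            # default per the reference design: booster linked to the
            # construct (r = 0.05), female-specific edits
            r = 0.05 if linkage_r is None else linkage_r
            params = _resolve_params(
                GeneticParams(timing="late", sex_limited_edit="female_only",
                              recomb_r=(r, 0.5)),
                ideal, overrides,
            )
            if not 0 <= booster_copies <= 2:
                raise ConfigError("booster_copies must be 0, 1, or 2")
            h1, h2 = _pdne_release_haps(booster_copies, "Bc",
                                        extra_wild=("Wt",))
            release = genotype(h1, h2, MALE, arch)
        else:
            raise ConfigError(f"unknown booster {booster!r}")
    elif key == "pdne2":
        arch = Architecture((
            Locus("construct", ROLE_PDNE_CONSTRUCT),
            Locus("hi_target", ROLE_HI_TARGET),
        ))
        ideal = (
            dict(u=1.0, s_edit=1.0, h_edit=1.0, frac_recessive=0.0,
                 s_construct=1.0, h_construct=0.0, mu_lof=0.0)
            if idealized else {}
        )
        r = 0.5 if linkage_r is None else linkage_r
        params = _resolve_params(
            GeneticParams(timing="late", recomb_r=(r,)), ideal, overrides)
        release = genotype((CONSTRUCT, "Wb"), (WILD, "Wb"), MALE, arch)
    else:
        raise ConfigError(f"unknown strategy {name!r}")

    opts = (
        ("idealized", idealized), ("booster", booster),
        ("booster_copies", booster_copies if booster else None),
        ("linkage_r", linkage_r),
        ("release_homozygous", release_homozygous),
    ) + tuple(sorted(overrides.items()))
    return StrategySpec(name=key, arch=arch, params=params,
                        release_genotype=release, options=opts)


def strategy_names() -> tuple:
    """Names accepted by :func:`make_strategy`."""
    return ("sit", "ridl", "fsridl", "xs", "yle", "fsridl_drive",
            "pdne1", "pdne2")
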