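# Methods

`drivebalance` is a deterministic population-genetics simulator for
self-limiting genetic biocontrol of pest insects.  Its central object is a
*protected dominant-negative editor* (PDNE): an autosomal construct that
(1) disrupts a haplosufficient gene, causing recessive lethality, (2)
carries a germline genomic editor (Cas9 + gRNA) that converts wild-type
target alleles into dominant lethal edits, and (3) is protected in cis
against the edits it creates.  The editor's transmission advantage (progeny
of heterozygotes that do not inherit the construct inherit a lethal edit
instead) cancels the selection against its recessive lethality, so the
construct persists at its release frequency while imposing a reproductive
load.  The package also models the self-limiting comparators SIT, RIDL,
fsRIDL, an autosomal X-shredder, a Y-linked editor, and fs-RIDL-drive, and
two booster constructs.

## Analytic single-locus model

A panmictic, single-sex, infinite population with one autosomal locus and
alleles W (wild type), G (construct), E (edit).  Frequencies are censused
at the hatchling stage, after embryonic deaths of edit carriers.  One
generation runs: census (construct frequency `q`, Hardy–Weinberg
proportions over {W, G}) → viability selection on the construct
(homozygous cost `s_construct`, heterozygous cost
`h_construct·s_construct`) → germline editing of W at rate `u` in
construct-bearing germlines → random union of gametes → embryonic deaths
of dominant-edit carriers.

With idealized parameters (`u = 1`, fully penetrant lethal edit and
construct, cost-free heterozygotes) the fitness components are

    w_rec = 1 − q        (recessive lethality)
    w_dom = 1/(1 − q)    (editing drive)
    w_total = w_rec · w_dom = 1

so the map `q → q'` is the identity: drive–selection balance.  The load is
`L = 2q/(1 + q)`.  Realized fitness between two censuses is the odds ratio
`[q'/(1−q')]/[q/(1−q)]`.  With fully penetrant dominant lethal edits, the
construct cannot increase at any frequency iff
`(s − hs)/(1 − hs) ≥ u`, where `s` and `hs` are its homozygous and
heterozygous costs; a fully penetrant recessive lethal (`s = 1`) therefore
never drives, at any editing rate.

The one-step map assumes the census is Hardy–Weinberg over {W, G}.  This
is exact whenever dominant edits leave no survivors at the census (the
regime of all closed-form results above); for partially penetrant edits it
is an approximation, and the two-sex simulator — which tracks the full
genotype distribution — is the reference.  A dedicated test confirms that
the simulator's adult-census construct frequency reproduces the analytic
chain generation by generation to 1e-10 in the exact regime.

## Genetics engine

Individuals are haplotype pairs over one to three autosomal loci plus an
optional X/Y pair (always the last locus, assorting independently).
Gamete formation applies, in order: Mendelian segregation with
recombination `r` per adjacent locus pair; homing at the construct locus;
germline editing; loss-of-function (LOF) mutation of construct components;
X-shredding.  Editing requires a construct allele with both components
functional; LOF derivatives (dead Cas9, dead gRNA, both dead) arise at
gamete formation, each component independently with probability `mu_lof`
per generation, and retain the construct's recessive cost — so no
derivative can drive.  Probabilities below 1e-15 are pruned and the
distribution renormalized, bounding the state space.

Viability multiplies cost factors and routes the product to one life stage
(`timing`: early, late, or fertility).  Single-locus PDNE: a genotype with
no functional copy of the insertion gene incurs `s_construct`; construct
heterozygotes incur `h_construct·s_construct` (leaky expression /
insertion-site effects); an expressed dominant edit incurs
`h_edit·s_edit` (one copy) or `s_edit` (two).  Recessive-class edits
(a fraction `frac_recessive` of edits) are plain loss-of-function alleles
of the insertion gene: costly only with no functional copy remaining.
Two-locus PDNE: death when functional doses of the haploinsufficient
target (wild-type copies + recoded copies on construct alleles) fall
below two.

Two design choices deserve note:

* **In-cis protection is structural.** The construct and the edit are
  alternative alleles at one locus; a construct-bearing chromosome can
  never express an edit, so no "protected edit" allele exists.
* **Female-limited designs use a doublesex-like target.** With
  `sex_limited_edit = "female_only"` the edited gene's disrupted function
  is female-specific: males are exempt from edit costs *and* edit alleles
  count as functional copies of the insertion gene in males (a G/E male
  survives).  Without this, G/E males would die of the recessive construct
  cost, and female-specific designs would need several-fold larger
  releases than bisex ones; with it they perform comparably, which is the
  intended biology of such targets.

## Demography

Discrete non-overlapping generations, two life stages, counts normalized
so the all-wild-type equilibrium has one adult female and one adult male.
Each generation: (1) released males (proportion `rho` of the *original*
male population) join the mating pool; (2) every fertile female mates
once, the father drawn proportionally to male count × fertility; (3) each
female produces `2·Rm` zygotes; (4) early-acting deaths; (5) uniform
density-dependent juvenile survival
`σ = 1/(1 + (Rm − 1)(J/J0)^β)` with `J0 = 2·Rm` (Beverton–Holt at the
default `β = 1`; the exponent is exposed for alternative shapes); (6)
late-acting deaths; (7) survivors are the next adults, sexes assigned by
sex-chromosome inheritance or 50:50.  `Rm` is the intrinsic (low-density)
per-generation rate of increase; the wild-type state is an exact fixed
point by construction.

Early-acting deaths are partially compensated by density dependence,
late-acting deaths are not — this reproduces the SIT-vs-RIDL ordering.
SIT is modeled in the standard way for this literature: released males
homozygous for a bisex dominant lethal acting *before* density dependence
(the males are fully fertile; their broods die as embryos).  Fully sterile
parents (possible with fertility-routed costs) produce an empty offspring
distribution and are excluded from the mating pool.

The recorded per-generation load is one minus the expected survival of the
generation's offspring through early and late genetic deaths (including
maternal fecundity effects), relative to an all-wild-type population with
the same number of females.  After a single release of idealized
construct heterozygotes at 100% of males, the adult construct frequency
stays constant (1/6 for that release) and the female count settles at
`(Rm(1 − L) − 1)/(Rm − 1)` with `L` the analytic load at the
corresponding hatchling frequency — a closed-form anchor used in tests.

## Strategies and boosters

Each strategy resolves to an architecture, parameters, and a released male
genotype.  The `idealized` flag sets perfect efficiencies (u = 1, fully
penetrant lethal costs, no heterozygous costs, no mutation, homing and
shredding rates of 1 where used).  Released genotypes: SIT/RIDL/fsRIDL
homozygotes, X-shredder homozygotes, Y-linked-editor carriers,
fs-RIDL-drive heterozygotes, PDNE heterozygotes.

The homing booster is a second, Mendelian locus carrying a gRNA that
directs the PDNE's Cas9 to the wild-type allele of the PDNE insertion
site.  In germlines carrying both, the wild-type allele converts to the
construct with probability `homing_rate`, and is restored to wild type
otherwise (no resistant-allele class in the idealized run).  Homing is
applied *before* editing of the same allele: cleavage at the insertion
site preempts creation of the dominant edit.  (The reverse order would
make the booster inert at `u = 1`, since every wild-type allele would
already have been edited.)  The booster itself gains nothing and is
slowly lost — it hitchhikes with construct-rich, high-load genotypes — so
boosting is transient.  The cleave-and-rescue booster targets a second,
female-specific haplosufficient gene that the PDNE rescues with a recoded
copy; its default linkage to the construct is r = 0.05, and the
coupling-phase correlation `(p_GB − p_G p_B)/√(p_G(1−p_G)p_B(1−p_B))`
decays as recombination separates the constructs.

## Release-threshold search

The minimal per-generation release proportion `rho*` reaching a
suppression target (e.g. 95% reduction of adult females) within a horizon
is found by bisection to an absolute tolerance of 1e-4, bracket [0, 20];
suppression is monotone in `rho` (asserted by bracketing and rechecked at
`rho* − 2·tol`).  "Within T generations" means first passage at any
generation ≤ T; a value-at-horizon rule is available as an option.
Targets unreachable at the bracket cap are reported as unattainable rather
than raised.  Fold efficiencies divide one strategy's `rho*` by
another's under identical demography, target and horizon.

## Problem sizes and determinism

The engine is a pure expected-value recursion: no demographic
stochasticity, no random number generator anywhere, so identical inputs
give byte-identical outputs (a `seed` config field is reserved but
unused).  State spaces are small (≤ ~160 genotypes for three-locus
booster runs); a compiled offspring tensor makes a generation one tensor
contraction, so the full release-threshold table (18 scenarios × two
strategies) runs in seconds on one core.  Default analyses use horizons
of 5–36 generations for searches and 40–100 generations for time-course
and containment checks.

## Scope and limitations

The model is deliberately the canonical theoretical setting: a single
well-mixed population, random mating, deterministic dynamics.  It
does not include spatial structure or migration, inbreeding, overlapping
generations or age structure beyond juvenile/adult, parental (maternal)
deposition of Cas9/gRNA, resistant-allele formation at the editing site,
or explicit sequence-level mistakes of the editor.  Passing tests
therefore establish the internal population-genetic and demographic logic
— neutrality, load, thresholds, orderings, containment of derivatives —
not field performance, where stochasticity in small suppressed
populations, mating ecology, and molecular imperfections beyond the
parameterized ones will matter.
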