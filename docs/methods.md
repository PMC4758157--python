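# Methods

This note documents the models, numerical choices and limitations behind
`interevol`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Contact criterion and interface definition

Two atoms on different chains are in contact when
`d < r_a + r_b + margin` with `margin = 0.5 Å`. The rule automatically
includes clashing pairs (`d < r_a + r_b`), so clashes need no separate
pathway; the clash flag is kept for reporting only — modelled side chains
may be positioned slightly into the partner chain, and such residues are
genuine interface residues. The interface between two chains is the set of
all residues owning at least one contacting atom, on both sides.

Van der Waals radii are the Bondi heavy-atom values shipped as data and
overridable per call; synthetic structures are hydrogen-free, so no
hydrogen-aware radii set is needed, and the contact criterion itself is
radius-table-agnostic. The radii table used is recorded implicitly by the
`vdw_radius` column of every atom record.

Contact search uses a k-d tree (`scipy.spatial.cKDTree`) with a cutoff of
`max(r_a) + max(r_b) + margin` followed by exact per-pair thresholding;
correctness is defined by — and tested against — the brute-force all-pairs
scan. Detection is symmetric in chain order and monotone in the margin.

## SASA and burial

Solvent-accessible surface area uses Shrake–Rupley quadrature with a
golden-spiral point set (deterministic, quasi-uniform), probe radius 1.4 Å
and 960 points per atom by default. A single isolated atom's SASA is exact
at any point count (all points exposed), so accuracy is governed by
occlusion geometry; tests check agreement with a 10× denser quadrature
within 2 %. A residue is buried when its SASA is ≤ 5 % (inclusive) of its
type's theoretical maximum (Tien et al. 2013 values, overridable). Chains
are evaluated in isolation, which is the relevant quantity for deciding
whether an interface residue's side chain faces solvent or core.

## Synthetic complexes

The generator plants unambiguous geometry rather than realistic folds. Two
chains run along parallel rails 26 Å apart with 6 Å residue spacing;
backbone atoms (N, CA, C, O) stay on the rails. Side chains are idealised
*linear* chains of the residue type's canonical heavy atoms (1.5 Å steps)
— composition is real, topology and rotamers are not. Non-interface side
chains grow away from the partner chain. At planted interface positions the
two side chains grow towards each other and the two tip atoms are pinned at
`r_a + r_b + margin/2` — inside the contact threshold, outside the clash
threshold. Every non-planted inter-chain atom pair clears the threshold by
at least 1 Å; to guarantee that margin, interface positions draw from
residue types with 2–6 side-chain heavy atoms (no GLY/ALA, whose contact
could only be backbone-mediated, and no PHE/ARG/TYR/TRP, whose long chains
would put their penultimate atoms too close to the partner tip).

Paralogue models substitute each site with its region's probability
(defaults 0.1 inside interfaces, 0.2 outside — interfaces are the more
constrained region). Each interface substitution carries a planted flag:
*preserving* substitutions keep the new side chain's tip at the template
tip position; *breaking* substitutions reorient the side chain away from
the interface (the orientation-change scenario). Deletions (probability
`p_del`, default 0) remove the residue from the model and appear as gaps.
Codon sequences are drawn uniformly from each amino acid's synonymous
codons; unchanged sites keep the template codon.

## Interaction-loss model

Both members of a duplicate pair inherit an identical ancestral partner set
whose size is `1 + Poisson(mean − 1)` (default mean 5; the degree
distribution of real interaction data is unknown to this generator and the
choice is configurable). Each (gene, partner) interaction is lost
independently with probability `loss_rate × divergence_time`; no gains are
simulated — the estimator assumes all divergence is loss. Surviving
interactions are emitted with two distinct synthetic study ids so the
multiple-confidence filter retains them. Defaults follow the studied
system: 204 whole-genome duplicate pairs, d = 100 Myr, λ = 6.0×10⁻³ losses
per PPI per Myr.

Two estimation routes are reported:

* **truth route** — `l` and `a` counted against the generator's ancestral
  sets; `(l/a)/d` is then exactly unbiased (binomial), and this is the
  route used for rate-recovery checks;
* **network route** — the ancestral set is inferred as the union `U` of the
  two members' *current* partner sets (`a = 2|U|`, one loss per
  member-partner interaction now absent). Interactions lost by both members
  vanish from `U`, so with per-interaction loss probability `p` the
  expected estimate is `(p/(1+p))/d < p/d`. This double-loss bias is a
  property of the inference, is substantial at `p = 0.6`
  (≈ 3.75×10⁻³ vs 6.0×10⁻³), and is deliberately measured, not corrected.

Counting convention: `a = 2|U|` counts gene–partner interactions, matching
the per-PPI rate unit (`a = |U|` is available as an option). Partner
matching for SIR and loss is by identity; self-interactions and
interactions with the sister paralogue count as ordinary partners.

## Divergence accounting

Alignment columns are 0-based; a column is an interface column when either
member's residue occupying it is an interface residue. Gap columns are
excluded from substitution counts and from site totals for rate
computation, but count as the 21st symbol in the substitution matrix and as
interface divergence in the 2×2 classification — an indel in an interface
nearly always changes the interaction, and the behaviour is switchable
(`count_gaps_as_divergence`).

The relative interface rate is the ratio of per-site substitution rates
(interface / non-interface). With exactly two sequences, a maximum
likelihood distance per region would be a monotone transform of mismatch
density, and only the relative rate is used — so the counting ratio stands
in for a model-based rate estimate; validation is against planted truth.
Pairs with ratio > 2 are flagged and excluded from rate summaries as
erroneous estimates. Pairwise Ka/Ks uses Nei–Gojobori pathway counting
with Jukes–Cantor correction; the uncorrected proportions are returned
alongside because the correction is undefined for saturated toy inputs.

"Diverged interaction" is operationalised as SIR < 1 on the chosen
network (the pair does not share all its interactions). When a pair has
several interfaces the pipeline makes one call per pair (any interface
divergence ⇒ diverged), configurable in principle to per-interface calls.

## Selection inference

Ancestral codons come from Fitch parsimony over the 61 sense codons with
ties broken by codon lexicographic order; polytomies are resolved
deterministically by pairing children in input order with zero-length
branches. Parsimony replaces likelihood-based ancestral reconstruction
because the downstream statistic consumes only substitution counts;
reports label the method "SLAC-style (parsimony)".

Per branch and site, codon differences are decomposed into
single-nucleotide steps averaged uniformly over all shortest pathways;
pathways through stop codons are excluded (re-admitted only if every
pathway is blocked). Expected site counts follow NG86: at each codon
position the three alternative nucleotides are classified by the universal
code, mutations to stops are excluded from both tallies, and the
nonsynonymous fraction `EN/(EN+ES)` is averaged over the codons observed
at the column (leaves and ancestors) and scaled by the observed
substitution total. The "branch correction" is thus an overall scaling
that leaves the tested proportion unchanged.

The site test is a two-tailed binomial test of `N` among `N + S` trials at
success probability `EN/(EN+ES)`, with the doubling convention
`p = min(1, 2·min(lower, upper))`; fractional pathway-averaged counts are
rounded to the nearest integers for the test. Zero substitutions is a
neutral call by definition. Group comparisons (interface/non-interface ×
interaction conserved/diverged, per-pair class proportions) use
Kruskal–Wallis with pairwise two-sided Mann–Whitney and Benjamini–Hochberg
adjustment. Positive sites are computed but excluded from the default
group comparison (too few are called to compare).

The codon simulator is an ω-thinned mutation process: each branch of
length `t` attempts `Poisson(3t)` point mutations per codon; stops are
rejected, synonymous changes always fix, nonsynonymous changes fix with
probability ω. It is not a full codon model (no transition/transversion or
codon-frequency structure), which is adequate because the inference stage
is itself a counting method. The default 10-taxon tree (the duplicate pair
plus eight deeply diverged outgroup taxa, total length ≈ 6 substitutions
per codon) reflects the deep divergence of the emulated species panel and
gives the binomial test usable power; ω defaults are 0.1 at interface
columns and 0.5 elsewhere (non-interface regions include the conserved
core, so some constraint remains).

## Contact-preservation predictor

For each substituted (or deleted) interface residue, the paralogue model —
in the template's coordinate frame — is checked for any atom of that
residue contacting the partner chain under the same criterion as interface
detection (one source of truth for "contact"). A deletion never preserves.
A pair is predicted *diverged* when any outcome fails to preserve;
otherwise *conserved* (including pairs with no interface substitutions).
Evaluation counts conserved interactions as the positive class — the
convention under which the published 14/35 precision and the printed
F-score of 0.4 are mutually consistent; both the full-precision and the
one-decimal F are reported.

## Pipeline and reproducibility

All randomness derives from `ScenarioConfig.seed` through named
substreams, so identical configs give bit-identical outputs, including PDB
bytes and the pipeline `summary.json`. Every output directory carries the
serialised config and its SHA-256 hash. Exclusions (members absent from
the network, regions without gap-free sites, pairs above the rate cap) are
counted and reported per pair, never silent.

In pipeline scenarios the interaction-loss process is independent of the
planted contact outcomes by default, so predictor scores on synthetic
cohorts reflect two independent noise sources, as in real data;
`couple_loss_to_contacts` forces interaction divergence exactly where a
non-preserving substitution was planted, which is how the F = 1 coupling
invariant is tested. The per-pair codon alignments used by the selection
stage are simulated on the fixed tree with column ω classes laid out by the
pair's interface columns; their tip sequences are not constrained to equal
the pair's structural sequences (the selection statistics depend only on
column classes, and the coupling would add plumbing without adding
information to any test).

Default problem sizes (204 pairs × 100 residues; 25–100 replicates for
rate recovery; 400–1000 sites for selection calibration) keep the full
test suite and the acceptance script to a few minutes while leaving
sampling error well inside every stated tolerance band.

## What passing tests do and do not show

The generators plant unambiguous geometry, independent Bernoulli losses
and a memoryless codon process. Passing tests therefore demonstrate that
the estimators recover what they are defined to estimate — not that real
interfaces are rail-shaped, that real interaction loss is independent
across partners, or that real selection is site-independent. Known
limitations carried over from the underlying method: interaction *gains*
are not modelled (the loss rate conflates them with losses in real data);
double losses are invisible to network inference (bias measured above);
small-scale duplicates are not dated; Probe-style dot-scoring of contact
quality, hydrogen placement, rotamer search and binding-energy estimation
are all out of scope.
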