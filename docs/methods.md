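# Methods

This note records the model, the numerical conventions, and the design
choices behind `fragrank`, in the order the pipeline applies them.

## Molecular model

Molecules are connected heavy-atom graphs; hydrogens are per-atom counts,
never graph nodes, because individual hydrogens take no part in
combinatorial bond disconnection. Aromatic systems are kekulized on
input, so every bond carries an integral order (1/2/3) usable for
enthalpy lookup. Monoisotopic atomic masses are bundled (CODATA/IUPAC
values for H, C, N, O, F, Na, Si, P, S, Cl, K, Br, I); the proton mass is
kept at 1.00728 Da internally and displayed as 1.007.

## Fragment enumeration

The fragmentation tree is built breadth-first. One *cleavage event* — one
acyclic (bridge) bond, or one unordered pair of ring bonds whose joint
removal disconnects the current subgraph — advances the tree by one depth
level. Ring pairs are not restricted to a perceived smallest-ring set; a
connectivity test decides validity, which handles fused systems
uniformly. Cut sites gain no hydrogen (rearrangements are handled by the
neutral-loss rules below). Atom subsets are integer bitmasks over the
parent's atom indices; bridges are found with an iterative lowlink pass
and ring-pair partners by re-running it with one bond removed, which
keeps enumeration comfortably fast to depth 3 on fused polycyclics.

Parameters:

| parameter | default | meaning |
|---|---|---|
| max tree depth | 2 | cleavage events from the intact structure |
| minimum fragment mass | smallest query peak, else 30 Da | fragments below it are never created |
| redundancy mode | molecular_formula | also: atom_id, isomorphism (canonical SMILES) |

Duplicate elimination keeps, for every redundancy key, the fragment with
the lowest cumulative bond dissociation enthalpy; this is extended from
the formula mode to all modes for determinism. In formula mode only one
representative per composition is expanded further, so the enumeration is
deliberately *not* exhaustive over subgraphs — the exhaustive-oracle
equivalence in the test suite therefore runs in atom_id mode, and formula
mode is checked as a subset of it. Output order is deterministic: mass
descending, then formula, then atom subset.

Bond enthalpies come from a plain-text table of literature standard
values per element pair and bond order (kJ/mol), shipped with the package
and replaceable by the user; unlisted pairs fall back to a default of
348 kJ/mol (one C–C single bond) with a once-per-pair warning.

## Neutral-loss rearrangements

Five bundled rules (H₂O, HCN, NH₃, CH₂O in both ion modes; HCOOH in
positive mode only) describe losses that are not subgraphs of the
precursor. Each rule names a heavy-atom motif — hydroxyl, terminal
nitrile, primary amine, formyl, carboxyl — defined in an extensible
registry, plus the loss composition and a maximum topological distance
(3 bonds) at which a donor hydrogen may sit. Donors are restricted to
carbon-bound hydrogens: abstracting an O–H or N–H hydrogen would leave an
under-coordinated heteroatom whose residual bond then cleaves at an
artificially low enthalpy, an artifact rather than chemistry. Application
removes the motif atoms and one donor hydrogen; the derived structure
(composition = parent − loss, verified to 0.001 Da) enters the same
processing queue at depth 0. Rules apply to the intact candidate only by
default; per-fragment application is available behind a flag but
measurably dilutes the positive predictive value (see below). Derived
structures are deduplicated by composition, so one representative per
loss survives; removals that would disconnect the heavy-atom graph are
skipped and logged.

## Spectra

Peak lists are two-column text (m/z, intensity; '#' comments; a third
column is tolerated). Multi-energy measurements are merged into a
composite spectrum: peaks are pooled, sorted, and clustered greedily in
ascending m/z with a 0.01 Th gap threshold applied transitively; each
cluster becomes one peak at the members' mean m/z with their maximum
intensity. Greedy ascending clustering makes chain cases deterministic
and reduces to the pairwise rule on well-separated data. The threshold is
a configuration constant, not scaled by instrument accuracy.

## Matching

Matching interleaves with generation. A neutral fragment is protonated
(positive mode) or deprotonated (negative mode) before comparison;
intrinsically charged fragments (net formal charge ≠ 0) are compared
as-is, with an enthalpy penalty added to their cumulative BDE — by
default the largest value of the enthalpy table, so an intrinsic charge
is never cheaper than one more cleavage. The tolerance is
mzabs + mzppm·10⁻⁶·(ion mass); the defaults 0.01 Da / 50 ppm suit older
instruments, 0 Da / 10 ppm modern QTOFs. Each measured peak is explained
at most once: the shallowest generation level reaching it wins, and
within a level the fragment with the lowest effective BDE (ties: higher
mass). One fragment may explain several peaks. Whenever the lightest
unexplained peak is accounted for, the minimum-mass cutoff rises to the
next unexplained peak, pruning the remaining enumeration; when every peak
is explained, generation stops. The *total fragments generated* count
(the PPV denominator) includes rule-derived structures but not the intact
candidate.

## Scoring

```
S_i = w_i / max(w) − e_i / (2·max(e))
w_i = Σ_{explained peaks} intensity^m · mz^n        (m = 0.6, n = 3)
e_i = Σ_{explaining fragments} cumBDE / Σ broken bonds
```

The exponents are literature values; heavy, intense peaks are more
characteristic. The penalty term uses the *per-bond mean* enthalpy: the
cumulative BDEs of the distinct explaining fragments are pooled and
divided by the total number of bonds they broke, so the score penalizes
reliance on strong bonds rather than the number of cleavage steps — a
pyranose ring that must be opened twice is not punished twice over.
Intrinsic-charge penalties enter the numerator only. Normalization puts
the weight term in [0, 1] and the penalty in [0, 0.5], hence
S ∈ [−0.5, 1]; degenerate maxima (no peak explained by any candidate, or
all-zero enthalpies) zero the respective term. Candidates explaining
nothing stay in the output with S = 0.

## Ranking and clustering

The worst-case rank of a candidate counts all strictly better candidates
plus its entire tied block. Within each tied block (score ties at 10⁻⁹ to
guard float noise), candidates with pairwise fingerprint Tanimoto
similarity ≥ 0.95 are collapsed by single linkage (complete linkage is
available); clusters never span different scores. The cluster rank
applies the worst-case convention to clusters. The fingerprint is the
RDKit path fingerprint (2048 bits), chosen because it is
connectivity-based and stereochemistry-blind: stereoisomers, which MS
cannot distinguish, map to identical bit vectors and always collapse.
Two all-zero fingerprints are defined as similarity 0, with a warning.
Rank lists are summarized by mean, median, 75 % quantile (linear
interpolation) and sample standard deviation (n−1).

The positive predictive value of a candidate's enumeration is
(fragments explaining a peak) / (fragments generated). At fixed matches
it is anti-monotone in the generated count, which is what makes deeper
trees and per-fragment rule application counterproductive: on the
simulation fixtures the mean PPV drops from depth 2 to depth 3 and when
rules are applied to every fragment.

## Synthetic data

The fixture module makes every stage testable offline.

*Toy set.* 22 named molecules spanning rings, heteroatoms and sizes from
propane to naringenin, each with its composition and monoisotopic mass
recorded in the source.

*Spectra.* A simulated spectrum draws k = 6 distinct fragments from the
depth-2 enumeration (minimum fragment mass 14 Da, so even propane yields
a peak set) and emits their protonated masses with log-uniform
intensities over two decades (floor 10) and optional Gaussian mass noise
(default 0). The heaviest fragment is always included; the others are
drawn with probability ∝ exp(−BDE/700 kJ·mol⁻¹), because
collision-induced dissociation favours energetically cheap cleavages —
the same assumption the score encodes. The softness, roughly two
single-bond enthalpies, keeps expensive fragments possible but rare.

*Decoy libraries.* Decoys stand in for the same-mass candidates a
compound database would return. They are random constitutional isomers
of the target: a random degree-constrained connected graph over the
target's heavy atoms with a random share of double bonds, hydrogens
filling remaining valence (so the composition, and hence the
monoisotopic mass, is exactly the target's). O–O bonds are excluded —
the standard structure-generator badlist entry — both for chemical
plausibility and because peroxide enthalpies would distort decoy
energetics. Decoys are deduplicated by canonical SMILES. Because the
fixture's purpose is a *positive control* (verify that the pipeline
recovers a structure from its own fragments), a decoy must be
distinguishable by the evidence the score observes: it is rejected if it
can produce the target's heaviest fragment composition (that composition
is in every simulated spectrum), or if it shares more than half of the
target's remaining expected spectrum evidence, measured as composition
overlap weighted by cubed fragment mass × sampling probability over the
same fragment universe the matcher uses (including rule-derived
structures). When the isomer space is too small (propane, ethanol) the
library is returned smaller, with a warning.

What passing the self-identification test does **not** show: real
identification rates. Real candidate lists contain chemically sensible
near-isomers that genuinely tie with or outscore the truth (that is
precisely why the worst-case and cluster ranks exist), real spectra
contain noise peaks, electronics drift, and intensity patterns no
combinatorial model reproduces. The fixtures validate the machinery, not
the biology.

## Numerical conventions and degenerate inputs

Score ties use an absolute tolerance of 10⁻⁹. Mass bookkeeping is exact
to ≤ 0.0005 Da against the bundled constants. Empty spectra match
nothing (with a warning); a candidate with no cleavable bonds yields an
empty fragment set; an empty candidate list is an error. All randomness
flows through `numpy.random.default_rng` seeded from explicit
configuration fields; fixed seeds give byte-identical outputs.

## Known limitations

- No mechanistic fragmentation chemistry: no charge-site modelling, no
  intensity prediction, no multiply charged ions, no adducts beyond ±H.
- Formula-mode redundancy conflates non-isomorphic fragments by design;
  use atom_id or isomorphism modes when subgraph identity matters.
- The per-bond-mean enthalpy penalty is a plausibility heuristic, not a
  thermochemical model; aromatic bonds are scored as their kekulized
  single/double orders.
- Stereochemistry is invisible throughout (inherent to MS data).
- The library interface is local-only; a remote database wrapper can
  implement the same contract but is out of scope.
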