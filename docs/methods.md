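# Methods

This note documents the models implemented in `npfrag`, the choices made
where the design was genuinely open, and what the shipped tests do and do
not demonstrate.

## Mass arithmetic and ion conventions

All masses are computed from a vendored table of IUPAC monoisotopic
atomic masses (6 decimal places; C 12.000000, H 1.007825, N 14.003074,
O 15.994915, P 30.973762, S 31.972071) so results are bit-stable across
platforms. Ion m/z is electron-inclusive: m/z = Σ(atomic masses) −
charge·m_e with m_e = 0.000549 Da, so [M+H]⁺ sits at M + 1.007276 and
[M−H]⁻ at M − 1.007276. Nine ESI adducts are supported ([M+H]⁺,
[M−H₂O+H]⁺, [M+Na]⁺, [M+K]⁺, [M+NH₄]⁺, [M−H]⁻, [M+FA−H]⁻, [2M−H]⁻,
[M+Cl]⁻), all singly charged; multiply charged species and elements
beyond C,H,N,O,P,S are out of scope. The supported-element restriction is
enforced at parse time with a specific error naming the offending
element.

## Fragment generation

The fragmenter operates on the heavy-atom graph with per-atom hydrogen
counts. One cleavage *event* is either

* up to two acyclic (bridge) bonds, or
* one or two ring-opening pairs, where a pair is any two ring bonds that
  form a 2-edge cut of the ring system (a single ring bond never
  disconnects a graph).

Sets that fail to disconnect the graph, or in which some cut bond does
not straddle two components, are discarded. Events that would excise a
lone interior heavy atom (two or more cuts around a single atom — e.g. a
ring oxygen leaving as atomic O) are rejected as physically implausible
one-step processes; terminal single-atom losses through one bond (CH₃•,
•OH) remain. This filter applies to fragment generation only; the public
cleavage-set enumeration keeps pure graph semantics (benzene has exactly
C(6,2) = 15 two-bond ring openings).

Hydrogen rearrangement per cleaved bond follows the rank-value rule
described in the README; aromatic and double bonds use n = 2, and only
multiples of n are allowed (intermediate single-H shifts on double bonds
are not generated). For multi-bond events the per-bond shifts are
enumerated independently and summed per component; combinations that
would drive any component's hydrogen count negative are dropped.

Charge bookkeeping is composition-level: the ±H of the precursor adduct
travels with whichever component retains the charge, so fragment ions
are exact CHNOPS compositions and every emitted ion satisfies
fragment + neutral loss = precursor ion exactly (tested to 1e−4 Da on
the m/z scale, exactly at the count level). Electron parity determines
the radical flag. Both sides of every cleavage are candidate ions; in
negative mode carbon-only ions are discarded (observed carbon-only
fragment fractions are ~24 % in positive but only ~1.5 % in negative
mode, which the implementation promotes to a hard rule). Charged
products are fragmented recursively; states are deduplicated by
(atom subset, accumulated H delta) and emitted ions by charged
composition, keeping the lowest-depth, fewest-bonds provenance.

Two tractability choices keep desk-scale enumeration fast in pure
Python, and are deliberate model restrictions rather than
optimizations of convenience:

* two ring pairs in a single event are allowed only at a *root*
  structure (the precursor or a reconstruction product); deeper
  sequential steps allow one ring pair per event, reflecting that deep
  cascades are dominated by small sequential losses;
* default recursion depth is 2 (precursor → fragment → sub-fragment);
  worked-example chains that the validation exercises use depth 3–4
  explicitly.

### Cleavage–reconstruction rules

Some experimentally prominent fragments require cleaving and re-forming
bonds. Rules are declarative: a SMARTS trigger, the match positions that
leave as the neutral piece, and the new bonds that reform the ring; atom
conservation is verified at application time and violations raise a
rule-definition error. The default registry contains the flavonoid
"1,3 elimination": on a (iso)flavone chromen-4-one core, the ring oxygen
and the carbonyl carbon+oxygen leave as CO₂ and a four-membered ring
(C2–C3–C4a–C8a) is formed. Products are themselves fragmented like
precursors and all derived ions carry a reconstruction flag.

Because the combinatorial engine is permissive (per-bond ±n H shifts,
recursion), some compositions that the reconstruction pathway produces
are also reachable through other cleavage sequences at equal depth; the
rule's value is the chemically interpretable route (and, at default
depth, peaks such as the acacetin positive-mode ion near m/z 139.056
appear only when the rule is enabled). The registry is user-extensible.

## Knowledge extraction

Annotated cleavage events (bond type as unordered element pair + order,
signed H shift, polarity, carbon-only flag) are tabulated into per-bond
pattern counts: Pattern 1 = H moves from the atom1-side to the
atom2-side fragment, Pattern 2 = homolytic, Pattern 3 = reverse. The
agreement of a table with the rank-value rule is the count-weighted
fraction of events whose pattern the rule permits. The shipped default
table carries the published corpus statistics for the three dominant
bond types (C–O, C–C, C–N; ≥97 % of observed cleavages); its rule
agreement evaluates to ≈0.94 (positive) and ≈0.96 (negative), matching
the published 93.7 %/96.2 % within 1 %. The positive-mode C–C Pattern-3
count was not published, so that bond type's total is the sum of its
known patterns — nothing is invented.

## Formula inference

De novo decomposition searches C ≤ 100, H ≤ 160, N ≤ 10, O ≤ 40, P ≤ 4,
S ≤ 4 (covering NPs to ~1500 Da), requires integer ring-plus-double-bond
equivalents ≥ 0 for the neutral molecule, and scores candidates with the
Gaussian mass-error score whose width δ is the user tolerance (score at
exactly δ is e^−0.5 ≈ 0.607). When both mDa and ppm tolerances are
given, the larger absolute window applies. The neutral-loss score scans
ordered peak pairs for differences matching a frequent-loss table
(shipped as `data/neutral_losses.tsv`: water, CO, CO₂, CH₃•, ammonia,
sugar residues, SO₃, H₃PO₄, ...; user-replaceable) and evaluates
½(Σ I_source·MES + Σ I_target·MES), capped at 1. The printed formula
juxtaposes intensity and MES without an operator; the product reading
was chosen because it keeps every term in [0,1].

## Scoring and ranking

Spectra are normalized to summed intensity 1 (not base peak 1) so that
S1 = Σ matched intensities is bounded by 1. Peak matching assigns each
peak to its nearest theoretical fragment within the MS² tolerance
(default 20 mDa or 20 ppm, larger window wins); one peak matches at most
one fragment — the one-to-one direction keeps S1 and S2 bounded — while
one fragment may explain several peaks. S0 is the precursor mass-error
score plus the neutral-loss score, each capped at 1 (cap configurable).
S3 compares the experimental spectrum against a predicted one using
matchms's greedy cosine; predicted fragment intensities are proportional
to the inverse of a random-forest regression proxy of bond dissociation
energy over (166-bit MACCS keys of the parent ‖ bond order/degree/
hydrogen features ‖ element one-hots), with multi-bond cleavages using
the summed bond predictions. The shipped trainer fits this model to a
*synthetic* label function encoding textbook trends (bond order and
aromaticity strengthen, heteroatom termini and crowding weaken) plus
seeded noise — it is a fixture for testing the interface and produces
physically plausible but not experimentally calibrated intensities;
users with measured spectra can supply their own training table. S4 is
annotation level / 5 and can be disabled for novel-discovery work
(novel candidates always score 0 there, which would bury them). S5 =
1/(1+exp(|RTexp−RTpred|/θ − 1)) with θ = 0.1 min uses the absolute RT
difference (the printed form is sign-ambiguous) and is off by default
because RT models are LC-condition-specific. Ties in the final score
break deterministically by (S1, S2, candidate id), making ranking
invariant to candidate order.

## Fragment trees

Matched fragments are inserted by decreasing mass; each attaches to the
already-inserted node with the smallest composition that elementwise
contains it (ties by node id), else to the precursor root. This greedy
deepest-parent rule is an implementation choice — no construction rule
is prescribed by the framework — and reproduces sequential-loss chains
(syringic acid: root→182→167→123→95 labeled CH₃, CH₃, CO₂, CO).
Complementary pairs whose compositions sum to the precursor within two
hydrogens are cross-linked as sibling annotations. Exports: JSON
(validated against a shipped structural schema), GraphML, DOT.

## SMILES language model

The generator is a stacked GRU/LSTM character model (embedding →
recurrent stack → softmax) implemented directly in numpy with
full-sequence backpropagation through time and Adam (β₁ = 0.9,
β₂ = 0.999). Reference defaults are 3 layers × 512 hidden units with a
128-dimensional embedding, batch 128, learning rate 1e−3; the analytic
gradients are verified against central differences in the test suite.
Sampling is autoregressive with temperature 1.0 and a 200-token cap
(neither is prescribed anywhere; both are configurable), and every
source of randomness — initialization, batch order, sampling,
augmentation — is seeded, so runs reproduce exactly. Augmentation
generates non-canonical SMILES by seeded atom renumbering; variants
always canonicalize back to the input. Evaluation reports %valid
(parseable), %unique and %novel (valid, canonical form absent from the
training corpus) plus distribution summaries of eight descriptors (MW,
logP, TPSA, sp³-carbon fraction, heteroatom fraction, ring count, QED,
BertzCT) and Wasserstein distances between sample and reference
descriptor distributions. Fréchet ChemNet distance and NP-likeness are
omitted (both depend on external pretrained scorers); the descriptor
distances serve the same comparison purpose.

## Synthetic data and what the tests show

The fixture module supplies 24 parsed structures spanning flavonoids,
isoflavonoids, phenolic and cinnamic acids, terpenoids, sugars and an
amino acid, including the worked-example molecules. Simulated spectra
take a molecule's own theoretical fragments (top peaks by predicted
intensity when a BDE model is supplied, otherwise smoothly decaying),
add seeded Gaussian m/z jitter (default study condition: 3 mDa, with one
unexplainable decoy peak) and normalize. The toy SMILES corpus for the
language model is 500 programmatically generated simple molecules
(alcohols, acids, amines, esters, phenols, small rings).

Because simulated peaks are drawn from the same fragment model used for
scoring, the self-annotation benchmark (each fixture's spectrum ranked
against the full panel of >20 decoys; rank-1 rate ≥ 80 %, observed
≈ 92 % across seeds) demonstrates internal consistency and
discriminative power of the score — not annotation accuracy on real
instrument data, which involves fragmentation physics, intensity
effects and interferences the simulator does not emulate. The residual
misses are structural twins (apigenin/genistein, glucose/fructose)
whose fragment compositions genuinely coincide at the simulated
granularity. Similarly, the corpus-scale explained-intensity and top-k
accuracy figures reported for the original large annotated datasets
require those external datasets and are not reproduced here; the
package validates against the printed worked examples (all reproduced
within 5 mDa, most within 2 mDa) and property-based invariants
(mass balance, oracle equivalence of enumeration against exhaustive
search, score bounds, statistics recovery within binomial error).

Desk-scale problem sizes used by the validation suite: fragmentation
depth 1 for the 24-molecule ranking panel, depth 3–4 for the
worked-example chains; language-model smoke runs use a 1-layer GRU with
64 hidden units, 40 epochs and learning rate 5e−3 on the 500-molecule
corpus (trained %valid ≈ 97 vs ≈ 4 untrained).

## Known limitations

* Fragment identity is compositional (formula + charge), not structural:
  isomeric fragments merge, and the engine cannot distinguish candidate
  structures whose fragment composition sets coincide.
* The combinatorial engine over-generates relative to real CID: homolytic
  options at every bond (e.g. carbonyl C=O cleavage emitting atomic-O
  losses) are grammatically legal under the rank-value rule; ranking, not
  generation, is expected to provide specificity.
* Only ±H adducts are followed through fragmentation; Na/K/NH₄/Cl/formate
  adducts are supported for precursor arithmetic, indexing and formula
  inference.
* The shipped BDE proxy is synthetic (see above); S3 with the default
  model should be treated as a smooth structural-plausibility term, not a
  quantitative intensity prediction.
* Deep recursion with multi-ring events grows combinatorially; the state
  cap (20 000 subgraph states, deterministic insertion order) bounds
  worst-case cost on large polycyclic structures.
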