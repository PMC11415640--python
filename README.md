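# npfrag

Knowledge-based in silico fragmentation and MS² annotation of natural
products.

Untargeted LC-MS/MS of plant extracts and other complex natural-product
(NP) sources produces thousands of tandem (MS²) spectra, most of which
match nothing in experimental spectral libraries. `npfrag` addresses this
by *predicting* fragmentation: candidate structures are fragmented in
silico under rules distilled from large annotated spectral corpora, and
ranked against the observed spectrum. It is aimed at metabolomics and
phytochemistry groups doing dereplication (rapid recognition of knowns)
and novel-structure discovery.

## What it does

* **Fragment generation.** A combinatorial bond-cleavage engine breaks up
  to two acyclic bonds or up to four ring bonds (as within-ring pairs)
  per event and recurses on charged products. Hydrogen rearrangement at
  each cleaved bond follows the element *rank value* rule (RV: O=2, N=1,
  C/P/S=0): for a bond X–Y of order *n* (aromatic counts as 2),

  ```
  Hx ∈ n·{−1, 0, +1}   if R(X) = R(Y)
  Hx ∈ n·{0, +1}       if R(X) > R(Y)
  Hx ∈ n·{−1, 0}       if R(X) < R(Y)
  ```

  where Hx > 0 means the X-side fragment gains hydrogens and Hx = 0 is
  homolytic cleavage into two radicals. Either side may retain the
  charge; in negative mode carbon-only fragment ions are discarded.
  Cleavage–reconstruction rules (e.g. the flavonoid "1,3 elimination":
  C-ring CO₂ loss with four-membered-ring reformation) cover
  rearrangements plain cleavage cannot reach.
* **Formula inference.** Candidate CHNOPS formulas for a precursor m/z by
  reference lookup or bounded integer decomposition, scored with the
  Gaussian mass-error score `MES = exp(−½((m_exp−m_theor)/δ)²)` (δ = 5 mDa
  by default) and a frequent-neutral-loss score.
* **Candidate ranking.** Six terms per candidate:
  `Final = S0 + α·S1 + β·S2 + γ·S3 + S4 + S5` with α = 0.1, β = 0.2,
  γ = 0.1 — formula score (precursor MES + neutral-loss score), summed
  matched intensity, mean fragment MES, cosine similarity against a
  spectrum predicted from a bond-dissociation-energy (BDE) regression
  proxy, annotation-level meta score, and an optional retention-time
  score.
* **Fragment trees.** Matched fragments linked by neutral losses, rooted
  at the precursor ion; JSON/GraphML/DOT export.
* **Structure generation.** A character-level GRU/LSTM SMILES language
  model (numpy implementation with exact, seeded training and sampling)
  plus augmentation and %valid/%novel evaluation, for enriching candidate
  databases with plausible novel NP structures.
* **I/O.** MGF and MSP spectra via matchms, MS-DIAL-style tab-separated
  exports, TSV molecule tables, on-disk fragment libraries with
  precursor-indexed retrieval, TSV annotation reports.

## Worked example

Deprotonated syringic acid (C9H10O5, [M−H]⁻ at m/z 197.0455) is a classic
negative-mode case: sequential losses of a methyl radical, a second
methyl, CO₂ and CO. Fragmenting it:

```bash
npfrag fragment "COc1cc(C(=O)O)cc(OC)c1O" --mode negative --depth 3
```

prints (top of the list; theoretical m/z, formula, neutral loss, depth):

```
183.0299  C8H7O5  -CH2   depth=1
182.0221  C8H6O5  -CH3   depth=1
181.0506  C9H9O4  -O     depth=1
180.0428  C9H8O4  -HO    depth=1
179.0350  C9H7O4  -H2O   depth=1
...
```

The CH₃•-loss radical anion at 182.0221 matches the experimental peak at
182.0217 within 0.4 mDa. Matching the four main experimental peaks
(182.0217, 166.9999, 123.0072, 95.0131) and building the fragment tree
recovers the full sequential-loss chain:

```
digraph fragment_tree {
  "precursor" [label="C9H9O5\n197.0455"];
  "f0" [label="C8H6O5\n182.0221"];
  "f1" [label="C7H3O5\n166.9986"];
  "f2" [label="C6H3O3\n123.0088"];
  "f3" [label="C5H3O2\n95.0139"];
  "precursor" -> "f0" [label="-CH3"];
  "f0" -> "f1" [label="-CH3"];
  "f1" -> "f2" [label="-CO2"];
  "f2" -> "f3" [label="-CO"];
}
```

Formula inference from an unknown precursor works the same way:

```bash
npfrag infer-formula 285.2064 --mode negative
# C16H30O4  [M-H]-  285.2071  -0.73 mDa  0.989
# ...
```

Annotation of spectrum files against a fragment library
(`npfrag build-library`, `npfrag annotate`, `npfrag annotate-batch`,
`npfrag tree`, `npfrag generate`, `npfrag knowledge`) is described in
`npfrag <command> --help`; the same functionality is available as a
library API (`import npfrag`).

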