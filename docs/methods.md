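# Methods

## Model

A phosphosite switch is an S/T/Y residue in a protein–protein interface
whose phosphorylation changes the statistical favourability of the
interface contacts. The method is template-based and additive: no 3D
model is built; instead residue–residue contacts are transferred from a
template complex to the query sequence through a pairwise alignment, and
the effect of phosphorylation is the sum of changes in a contact
pair-potential.

### Pair-potentials

The potential is quasi-chemical: for an unordered pair of residue
classes (a, b) — 23 classes, the 20 amino acids plus pS/pT/pY derived
from SEP/TPO/PTR residues — with pseudocounted contact count
n′(a,b) = n(a,b) + α and N′ = Σ over unordered pairs,

    f_obs(a,b) = n′(a,b) / N′
    g(a)       = Σ_b n′(a,b)·(1 + [a = b]) / (2 N′)
    e(a,b)     = 2 g(a) g(b)  (a ≠ b),   g(a)²  (a = b)
    s(a,b)     = ln( f_obs(a,b) / e(a,b) )

in natural log units. The random model is independence of the marginal
contact frequencies — the standard choice for interface statistics; the
original normalisation was not published in detail, so this estimator is
a documented assumption, and a precomputed matrix in the same labelled
TSV dialect can be loaded to bypass estimation entirely. The default
pseudocount α = 1 per unordered pair keeps the rare phospho classes
finite; at realistic counts (≥10³ per pair) its bias is negligible.

### Interaction Effect and S_switch

For a site mapped to a template residue, IE sums
Δ(a→pa | partner) = s(pa, partner) − s(a, partner) over the residue's
inter-chain contacts (a contact: any heavy-atom pair ≤ 5.0 Å between
residues of different chains; multiple atom pairs count once per residue
pair). At homodimeric interfaces the site is taken to be phosphorylated
in both copies: both symmetric copies are scored and summed — exactly 2×
for a perfectly symmetric interface — and a contact between the two
copies of the site itself is compared as s(p,p) − s(u,u). The 5.0 Å
heavy-atom contact definition is itself a documented assumption (the
original criterion was inherited from an interface server and never
printed).

S_switch = IE · f_ID · f_Cons, where f_ID is the minimum fraction of
identical residues between each interacting protein and its template
chain (computed over non-gap-pair columns), and f_Cons is the fraction
of sequences in the site's orthologue-group alignment carrying the wild
amino acid or Asp/Glu at the site's column (gapped sequences count in
the denominator only; the query row is included — a documented choice).
Sites in proteins covered by no group fall back to a per-species average
over all S/T/Y sites. |S_switch| ≥ 1.7 calls a switch; the threshold
corresponds to a 5% false-positive rate on a labelled benchmark.

When several templates score the same site × interactor, the score with
the largest |S_switch| wins; ties break by larger |IE|, then enabling
over disabling, then lexicographically smallest template identifier —
the original "most significant" rule does not define ties, so this
deterministic cascade is the package's own choice.

### Site annotation

- Disorder: mean per-residue disorder over an 11-residue window centred
  on the site, flagged disordered when ≥ 0.5 (inclusive). Windows are
  truncated at the termini (mean over available residues) rather than
  padded, to avoid inventing scores.
- Exposure: side-chain accessible surface area < 5 Å² is buried, exposed
  otherwise. ASA is Shrake–Rupley with probe radius 1.4 Å and 960
  deterministic (golden-spiral) sphere points per atom, computed in the
  context of the full complex; side-chain atoms are everything beyond
  the backbone, CB included; glycine is defined as 0 (always buried —
  harmless for an S/T/Y-focused method); a non-glycine residue with no
  side-chain atoms is flagged unset, never silently 0.
- Redundancy: sites are grouped by (group alignment, column); members
  whose gap fraction (gaps / ungapped member length — the denominator is
  a documented choice) is ≥ 0.09 are excluded from grouping and their
  sites stand alone. Background sites sharing a column with any
  phosphosite become ambiguous and are dropped from counts.

### Benchmark machinery

Negatives are built by shuffling each labelled positive to random S/T/Y
positions of the same protein (10 per positive), copying interactor and
effect, drawing without replacement from positions of the same
buried/exposed class (exact class matching; falls back to any S/T/Y when
the class has no alternatives). ROC curves use a threshold sweep with
trapezoidal AUC; the operating point is the smallest observed threshold
with FPR ≤ 0.05; significance at the point is a two-sided Fisher's exact
test. Signed predictors (S_switch, IE) are oriented by the annotated
effect direction — a disabling entry's score is negated — so that a
correct prediction is always high-positive; the "absolute" ROC mode
ranks by |score| instead. Logistic regression (unregularised maximum
likelihood, tolerance 1e-8) is evaluated by undersampling negatives to
the positive count, 5-fold stratified cross-validation, 100 repetitions,
averaging AUC and the threshold-at-FPR statistics, then one final fit on
the full set. Group comparisons use Wilcoxon–Mann–Whitney for continuous
properties and 2×2 chi-square (no continuity correction) for binary
ones. One master seed drives per-repetition substreams derived with
`SeedSequence.spawn`, so every run is reproducible.

## Synthetic data

The generators in `phosphoswitch.simulate` define the study conditions
for all tests:

- **Contact sampler.** Unordered class pairs drawn i.i.d. from the
  distribution whose quasi-chemical log-odds equal a planted matrix. An
  arbitrary score matrix is generally not the log-odds of any
  distribution under this estimator (estimated matrices satisfy a
  closure condition), so planted matrices are first projected onto the
  realisable family: the requested scores are treated as a tilt of the
  independent uniform contact distribution and the induced exact
  log-odds are taken as the planted truth, with a damped iteration that
  pins requested entries to their exact values. Pinned values that are
  unreachable on a small alphabet (an off-diagonal log-odds has an
  alphabet-dependent ceiling under uniform-tilt construction) raise an
  error rather than silently shifting.
- **Toy complexes.** Two chains of five-atom pseudo-residues (idealised
  single-CB side chains) spaced 10 Å apart; requested residue pairs are
  realised as 4.5 Å CB–CB contacts and nothing else comes within 5 Å.
  Sufficient for threshold/contact/ASA logic; no rotamers, no realistic
  packing. A separate dense-cluster generator fully occludes a central
  residue for burial tests.
- **Orthologue alignments.** Per-column i.i.d. composition: at the site
  column the wild residue with probability c, Asp/Glu with probability
  d, a gap with probability γ (expected f_Cons = c + d); no phylogenetic
  correlation.
- **Labelled benchmarks.** Positives draw IE from N(±effect, 1) with the
  sign set by the planted enabling/disabling label; negatives draw IE
  from N(0, 1) and inherit their source positive's effect label.
  f_ID ~ U(0.8, 1) mimics the high-identity templates that dominate real
  mappings; f_Cons ~ U(0.3, 1); 15% of interactors are flagged kinases
  to exercise the kinase filter. Defaults: 200 positives, 200 negatives,
  effect size 3.

Passing tests on these fixtures demonstrate the correctness of the
scoring arithmetic, the estimator, and the benchmark machinery — not
predictive performance on real proteomes, which depends on template
coverage, alignment quality and the realism of the pair-potential
training set, none of which the fixtures model.

## Problem sizes and numerical choices

- Pair-potential recovery is checked with 10⁵ sampled contacts. On a
  compact 4-class alphabet each unordered pair receives ~10⁴
  observations, putting the Monte-Carlo error of every score well below
  the ±0.05 check; on the full 23-class alphabet a single pair receives
  only ~400 observations (per-score σ ≈ 0.05), so full-alphabet recovery
  is asserted at a 3σ statistical tolerance instead.
- The independence null uses counts built directly as products of
  marginals at n = 10⁶, where rounding noise bounds |s| below 0.02.
- The end-to-end benchmark uses 200 + 200 entries and the full 100
  cross-validation repetitions (~3 s).
- Matrix TSV round-trips are exact to 6 decimals; asymmetry beyond 1e-6
  is rejected; comparisons in tests are on unrounded values while the
  pipeline writes 4 decimals.
- Altlocs keep the highest-occupancy conformer; residue numbering is
  author numbering with insertion codes; hydrogens are ignored
  everywhere.

## Known limitations

- The pair-potential is contact-level and distance-independent: no
  atom-level geometry, solvation, or conformational response to the
  phosphate.
- IE is additive over contacts and ignores steric clashes,
  multi-site coupling and allosteric effects.
- f_Cons treats all orthologue-group members equally (no tree
  weighting), and the species-average fallback is a single scalar.
- The interface-homology matcher requires user-supplied pairwise
  alignments; it does not align sequences itself.
- Glycine's side-chain ASA convention (0, always buried) is irrelevant
  for S/T/Y sites but would misclassify glycine exposure if reused.
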