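# Methods

`wrkyevo` models the recent evolution of the WRKY transcription-factor
family across a rice-like genus: detection and classification of WRKY
domains, orthology and duplication-mode assignment, gene-tree/species-tree
reconciliation, domain-architecture event inference, and codon-model
selection analysis.  A synthetic-genome simulator with a complete
ground-truth event log makes every stage testable end to end.  This note
records the models, the defaults and why, and what the validation
experiments do and do not show.

## Domain model and scanning

A WRKY domain is modeled as a heptapeptide (canonically `WRKYGQK`, with
variants `WRKYGEK`, `WRKYGKK` and the degenerate cores `WKKY-`, `WRMC-`,
`WSKY-`, `WVKY-`), a spacer, a zinc-finger core `C-x(4,5)-C` optionally
followed by a subgroup literal (IIa `CX5C-PVKKK[LV]Q`, IIb `CX5C-PVRKQVQ`,
IId `CX5C-PARKHVE`, IIe `CX5C-PARK[QM]V[ED]`), and an `H-x-H` (C2H2) or
`H-x-C` (C2HC) pair.  The scanner anchors on heptapeptide-class matches,
pairs each anchor with the nearest downstream zinc finger (pairing window
60 residues; 18–28 residues between the second cysteine and the first
histidine — windows chosen from the canonical ~60-residue domain length
and exposed in config), and scores the 46-residue window against a
log-odds PSSM trained on a packaged synthetic reference alignment.  The
acceptance threshold is calibrated on 10,000 shuffled decoys of realistic
composition so that at most ~1 in 1,000 shuffled sequences yields a call;
the calibration is bit-reproducible from a packaged seed.  A structurally
complete domain with an exact canonical heptapeptide is kept regardless
of score, so degraded but complete domains survive; exact heptapeptides
with no zinc finger are reported as partial motifs (Group IV evidence).

## Classification

One label per gene, from the representative isoform's domain calls: two
complete domains → Ia (both C2H2) or Ib (both C2HC); one complete C2H2
domain → IIa/IIb/IId/IIe by zinc-finger literal, IIc for a bare core; one
complete C2HC domain → III; no complete domain but partial motifs → IV.
The representative isoform is the longest, unless only a shorter isoform
carries a complete domain.  Two open cases are resolved as package
policy: mixed-finger two-domain proteins are labeled by the C-terminal
(DNA-binding) finger with a `mixed_zf` flag, and proteins with three or
more domains are labeled by their terminal pair with a `multi_domain`
flag.

## Homology

Orthologs are reciprocal best hits of exact Smith–Waterman scores
(BLOSUM62; a gap of length L costs 11 + L) against a designated reference
species; ties break by identity, then id.  Exact alignment replaces a
heuristic seeded search deliberately — proteomes here are hundreds of
sequences, so exhaustive scoring removes a heuristic confound.  Genes
failing the reciprocal test are assigned as co-orthologs to their best
reference hit; all homolog links additionally require half of the query's
self-score, because every WRKY protein shares the heptapeptide and
zinc-finger residues and a raw score floor alone would join unrelated
families.  Within-species paralog pairs (same family, alignment coverage
≥ 40%) are tandem iff they share a chromosome and lie within ≤ 5
intervening genes or ≤ 100 kb (defaults anchored to a known 19-kb tandem
pair and common practice; both config-exposed), otherwise segmental.
Chromosome positions are midpoints scaled to [0, 1] for synteny
summaries, including the distal-10% hot-spot fraction on chromosomes 11
and 12.

## Reconciliation

Gene trees come from neighbor joining on Poisson-corrected protein
distances (d = −ln(1 − p) over shared non-gap columns) with
column-resampling bootstrap, or are imported as Newick.  Rooting
minimizes reconciliation cost over all edges.  Under the duplication-loss
model, the LCA mapping assigns each internal node the LCA of its
children's images; a node is a duplication iff its image equals a child's
image; losses follow the path-depth rule; cost = 1.5·duplications +
1.0·losses.  Edges with bootstrap support below 50 (config-exposed; the
convention of hiding nodes below 50% support) may be rearranged by greedy
NNI, applying the single most cost-reducing move per round; ties keep
the current tree, so the procedure is deterministic and never increases
cost.  Exhaustive enumeration over thousands of small gene-tree ×
species-tree cases confirms the LCA mapping attains the brute-force
minimum cost over all valid monotone mappings.

## Architecture events

Each species' architecture for an ortholog group is a discrete character:
the N→C list of (zinc-finger type, clade affinity).  Affinity assigns
each domain to the reference domain set (ortholog group + terminal) with
the highest mean Smith–Waterman score; margins below 10% of the best
score are "ambiguous" and treated conservatively.  Reference sets are
pruned so each label is a distinct domain lineage: a candidate whose
alignment to an already kept set recovers ≥ 55% of its own self-score is
merged.  The threshold sits in a measured gap — one lineage diverged
across the genus keeps ratios ≳ 0.7, unrelated same-subgroup domains
(identical signatures, independent spacers) reach ~0.45–0.5 — and its
asymmetric form (candidate's own self-score, not the shorter sequence's)
prevents short references from absorbing longer ones.  This pruning is
what keeps a fusion product's borrowed domain pointing at its donor group
rather than spawning a second label.

Ancestral architectures are reconstructed by unit-cost Sankoff parsimony
on the species tree (missing species are missing data); every optimal
labeling is enumerated (capped at 64).  Each state change on an edge is
explained by the minimal event sequence among N/C-terminal domain loss,
domain tandem duplication (1 → 2 copies of the same lineage), and fusion
(1 → 2 with domains from two different groups); reconstructions in which
some change has no event explanation are discarded when an explainable
one exists.  Events present in every optimal labeling are confident;
events whose presence or placement varies are reported as one
multi-solution call with an ambiguity flag rather than guessed — root-
adjacent changes are the common case, since a change on one side of the
root is indistinguishable from its mirror on the other.

## Selection analysis

Protein alignments are column-filtered at ≥ 93% occupancy (a
column-confidence stand-in at the conventional 0.93 cutoff, documented as
such, not as an equivalent), threaded onto their true CDS codon-by-codon
(universal code; mismatch or internal stop is an error), and analyzed
under GY94-style codon models: rate κ·π or ω·κ·π per single-position
change, scaled to one expected substitution per codon, frequencies F1x4
by default.  Likelihoods use Felsenstein pruning with per-node rescaling;
gaps are missing data.  Site models: M0; M1a (p₀ with 0 ≤ ω₀ < 1, rest at
ω = 1); M2a (adds ω₂ > 1); M7 (10-class Beta quantile-midpoint
discretization, ω ≤ 1); M8 (M7 plus one class ω_s > 1).  LRTs: M1a vs M2a
and M7 vs M8 at df 2 (the df-2 convention is used at the M7/M8 boundary),
two-ratio branch model vs M0 at df 1, with foreground branches taken from
the duplication screen.  Optimization is bounded L-BFGS-B (ω ∈ [1e-4,
99], κ ∈ [0.1, 20]) with seeded random restarts (default 5; the large
simulation experiments use 1–2, where the null surface is well-behaved);
branch lengths are estimated once under M0 and fixed for the other site
models.  Per-site identification uses Naive Empirical Bayes posteriors
with 0.95/0.99 flag tiers; NEB replaces the Bayes-Empirical-Bayes
prior-averaging grid as a stated simplification with the same decision
shape.  A gene is called positively selected only if both LRT pairs are
significant at α = 0.05 and the positive-class ω exceeds 1 in both M2a
and M8 (config-switchable to either-test).

## Synthetic data

Families evolve on a packaged ultrametric 10-species tree (root 15 Myr;
the second-oldest split at 6.76 Myr mirrors an AA/BB-type genome split)
under a birth–death process with exponential waiting times per lineage
(defaults 0.02 duplications and 0.01 losses per gene per Myr; 1/3 of
duplications tandem, matching a roughly one-third tandem share among
observed paralog pairs).  All-extinct families are reported, not dropped.
Architecture events are Poisson-placed on species-tree branches (defaults
0.004 losses, 0.003 tandem domain duplications, 0.004 fusions per family
per Myr — order-of-magnitude choices, config-exposed, since no empirical
rates exist for these events); fusion picks a co-resident single-domain
Group III partner, appends its domain C-terminally, and records donor
order and the donor-side "promoter" annotation; forced-event injection
supports constructed scenarios (e.g. loss on an internal branch followed
by tandem regain in one descendant lineage).  Codon sequences evolve
along the gene trees at 0.02 expected substitutions per codon per Myr
under the same GY94 process used for inference (default site profile:
85% of sites at ω 0.2, 15% at ω 1.0).  Signature residues are frozen by
default (a flag unfreezes them), so motif-census tests have exact
expected counts; Group IV (partial-motif) families always carry a
canonical heptapeptide, since degenerate variants are observed only in
complete-domain groups and a degenerate heptapeptide with no zinc finger
would be unrecognizable as a WRKY remnant at all; intra-domain spacer sites exclude C/H/W targets, a
structural-constraint stand-in that also guarantees stochastic evolution
cannot fabricate spurious cores or anchors.  Tandem duplicate genes are
placed adjacently (6 kb apart), segmental duplicates on other
chromosomes; a quarter of families sit on the distal tips of chromosomes
11/12 and their segmental copies preferentially hop between those arms,
emulating the known inter-arm duplication hot spot.  Gene spans, isoforms
(15% of genes get a decoy isoform exercising the representative-isoform
rule) and single-exon CDS features are written as GFF3.

What the simulator does not emulate: intergenic sequence, introns,
transposable elements, polyploidy, alignment-fragmenting indel processes
inside domains, or rate variation beyond the configured site classes.
Passing closed-loop tests therefore demonstrate internal consistency of
the inference chain under the generative model, not performance on real
genome annotations.

## Validation experiment sizes

The acceptance script and test suite regenerate everything from a seed:
reconciliation oracle — exhaustive gene trees with ≤ 4 leaves on 2-, 3-
and 4-species trees plus seeded samples of 5- and 6-leaf trees (~2,500
cases) against brute-force mapping enumeration; pruning — 50 random
instances (≤ 4 leaves, ≤ 3 sites) against vectorized exhaustive state
summation; NG86 — 100 random 100-codon pairs against explicit pathway
enumeration; M0 recovery — ω ∈ {0.2, 0.5, 1, 2}, 500 codons, 8 taxa, 20
replicates, true branch lengths fixed (median ω̂ within ±20%); M1a/M2a
type-I error — 200 null replicates at 200 codons, 6 taxa; branch model —
20 replicates of foreground ω 1.0 vs background 0.4; classifier closed
loop and duplication modes — 50- and 40-family datasets; architecture
events — 50 families with one forced event each, scoring confident calls
(precision) and detectable events (recall; events observed in no
unaffected species are excluded as undetectable in principle, and
multi-solution calls are counted as covered-ambiguous, not as hits or
misses).

## Known limitations

Parsimony cannot distinguish two independent same-kind events from one
ancestral event plus a reversal when they produce identical leaf states;
such coincidences are rare at the default rates but are resolved toward
the fewer-event explanation.  The NJ + Poisson-distance gene trees are a
deliberate stand-in for full ML tree search (external ML trees can be
imported as Newick).  NEB posteriors are anti-conservative relative to
BEB when parameter estimates are poor.  The M1a/M2a LRT is strongly
conservative at the ω = 1 boundary (the chi-square reference overstates
the null tail), so the type-I experiment asserts the one-sided property
that matters — the rejection rate never exceeds the binomial envelope of
the nominal level — and reports the measured rate, which is typically
far below 5%.
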