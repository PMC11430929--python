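# Methods

## Site classification

The alignment is scanned as dinucleotide sites. The default frame is
**non-overlapping** anchored at column 0 (pairs (0,1), (2,3), ...), which
reproduces the "divide the total length by two" accounting used for
conserved-island studies; an **overlapping** frame (every adjacent column
pair) is provided because the anchor is biologically arbitrary — a CpG
straddling an odd offset is invisible to the non-overlapping frame. Every
frame-aligned CpG is also an overlapping CpG, so the overlapping CpG count
is always ≥ the non-overlapping one.

A site is `CONSISTENT_CPG` when every taxon reads CG, `VARIABLE_CPG` when
at least one but not all do, otherwise `NONCPG_VARIABLE`/`NONCPG_INVARIANT`
by whether ≥2 distinct states occur. Any gap or N in any taxon makes the
site `GAPPED` and removes it from all counts: the data never state how
indel-disrupted dinucleotides should be scored, and exclusion is the
conservative, order-independent choice. Single columns that vary outside
all CpG-class sites are tallied separately (`n_noncpg_snp_columns`) as the
conventional SNP background.

## Mutation spectrum

At each `VARIABLE_CPG` site, every **distinct** derived (non-CG) state is
counted once, regardless of how many taxa share it. This makes the six
class counts sum (plus the doubly substituted `other` bin) to at least the
number of variable sites, with equality when every variable site carries a
single derived state — the regime in which published six-class counts for
conserved islands add up exactly to total-minus-conserved CpG sites. States
one step from CG fall into CG→TG, CG→CA, CG→GG, CG→CC, CG→CT, CG→AG;
two-step states (e.g. TA) are reported in `other` rather than forced into a
class. No ancestral reconstruction is attempted: CG is taken as ancestral
wherever any taxon retains it. That is a deliberate simplification — in a
deamination-dominated regime CpG loss is far likelier than CpG gain, but
genuine gains are thereby mis-oriented.

Per-taxon perspective counts ask, for each taxon, at how many variable
sites it retains CG while ≥1 other taxon shows TG or CA (the two strands'
deamination products). Of the several readings the prose rule admits, this
one is consistent with the reported per-species extremes; it is documented
here as an interpretation.

Percentages are reported against the total CpG-site count with decimal
half-up rounding (one decimal for class percents; nearest integer for the
headline alteration rate, exact value retained alongside).

## A/T recoding

Each gap-free CpG-class site emits one binary character per taxon: `A` if
that taxon reads CG, `T` otherwise. The verbal recoding rule can be read as
assigning `T` to *every* taxon at a variable site, but that destroys all
between-taxon signal and cannot produce a resolved tree; the per-taxon
presence/absence reading implemented here is the only one that yields
informative characters and matches the published A/T illustration. It is
flagged prominently as an interpretation. Consistent sites are retained by
default as invariant all-A columns: the phylo-epigenetic tree is defined
over all consistent CpGs *and* all CpG differences, and the invariant
columns dilute p-distances, setting the pre-calibration branch-length
scale. `include_consistent=False` drops them; calibrated topologies are
unaffected (the p-distance denominator change is a global rescaling when
gaps are absent).

## Distances, UPGMA, calibration

p-distance counts mismatches over columns where neither sequence is gapped
or N; `count_gaps=True` additionally scores gap-versus-residue columns as
differences (gap-gap and N columns always excluded). Percent identity is
100·(1 − p). UPGMA is implemented directly: merge the closest pair, place
the parent at height d/2, update distances to the merged cluster by the
size-weighted arithmetic mean (UPGMA proper, not WPGMA). Ties break on the
lexicographically smallest cluster-index pair, clusters numbered in
creation order, so results are platform-independent; with distinct
distances the topology is input-order invariant. Internal edges of exactly
zero length are collapsed, so an all-zero matrix degenerates to a star tree
at height zero rather than an arbitrary binary resolution. The output is
ultrametric by construction (equal root-to-leaf heights within 1e-9).

Calibration multiplies every node height by age/h where h is the height of
the MRCA of the two named taxa, pinning that node exactly and preserving
topology and all height ratios; a zero-height calibration node is an error.
Robinson–Foulds comparison uses unrooted non-trivial bipartitions
(delegated to dendropy). No distance correction (e.g. Jukes–Cantor) is
applied by default and no bootstrap is computed; the distance choice is
isolated behind `p_distance` should a correction be wanted.

## Synthetic data generator

The simulator emulates the statistical structure the analysis assumes: a
known ultrametric tree, island-like composition, and CpG hypermutability.

**Root.** A 27,000-nt (default) sequence with 60% GC background and CpGs
planted at randomly chosen non-overlapping even offsets to a target density
`cpg_fraction = 0.18` of frame-aligned dinucleotide positions (≈ 2,430
CpGs, matching the ~2,495 observed in ~13,530 positions). The fill forbids
incidental C–G adjacencies, so the planted CpGs are the *only* root CGs and
form exact ground truth for recovery tests; chance CpGs still arise later
by substitution.

**Evolution.** Exact Gillespie simulation per branch. Non-CpG sites leave
at total rate μ split κ:1:1 between the transition and the two
transversions (κ = 2 by default). The C of a CG (and symmetrically its G)
undergoes its deamination transition at λ·μκ/(κ+2) — λ-fold the
context-free transition rate — with context re-evaluated after every
event, which produces the paired TpG/CpA pattern on the two strands without
modelling methylation state explicitly. λ = 1 reduces exactly to the
context-free model; the mechanistic range is 10–50 and the preset uses 20.
No indels are simulated, so columns are homologous by construction. Every
substitution is logged (branch, site, bases, deamination flag) and the log
replays from the root to the exact leaf sequences. Each branch draws an
independent RNG substream keyed by its descendant leaf set, so adding taxa
does not perturb existing branches.

**Hominid preset.** Topology
(((human,(neanderthal,denisovan)),(chimp,bonobo)),gorilla),orangutan with
node ages 0.43 / 0.65 / 1.7 / 5 / 8 / 14 My from the primate literature.
The absolute substitution rate of such loci is not published; the preset's
μ = 3.6e-4 subs/site/My is a free parameter calibrated so that simulated
pairwise identities span the observed conserved-island range (≈ 97.3–99.9%,
with the human–orangutan extreme at ≈ 97.3%). A single global rate cannot
simultaneously match that identity range and the observed 17% CpG
alteration rate — at these settings ≈ 29% of simulated CpG sites are
altered — and the identity range was chosen as the binding constraint
because it controls tree geometry. Passing recovery tests on this
generator therefore demonstrates correctness of the pipeline under a
clock-like, indel-free, gain-poor approximation of island evolution, not
fidelity to every observed rate.

## Problem sizes used in tests

The recovery study runs ten replicates (seeds 1–10) of the 27 kb preset —
about four seconds in total — requiring the recoded-matrix UPGMA topology
to equal the planted topology in ≥ 9/10 replicates and the calibrated
human–chimp age to fall within ±30% of its planted 5 My in ≥ 9/10 (the
chimp–bonobo calibration node rests on a handful of CpG events on two
1.7 My branches, so single replicates can land just outside). Spectrum
monotonicity in λ is checked on two-taxon 50 kb simulations at λ ∈
{1, 10, 50}; the λ = 1 context-independence check uses an elevated rate
(μ = 0.055) to collect >10⁴ events for a 3σ binomial comparison.

## Numerical choices

Newick branch lengths are written with 17 significant digits so trees
round-trip bit-faithfully; heights are recovered from edge lengths only for
ultrametric trees (tolerance 1e-6 relative on root-to-leaf spread, 1e-9 in
the strict test sense). UPGMA clamps merge-height slack below 1e-12 to
zero and raises on anything more negative. Degenerate inputs: alignments
with fewer than 2 columns or records are rejected at construction;
a taxon pair with no comparable columns is an error naming the pair;
`percent_cpg_altered` on a CpG-free alignment is NA (None/null), not zero.

## Known limitations

No indels, selection, methylation-state tracking, or rate variation across
islands in the simulator; no ancestral-state inference or CpG-gain
orientation in the spectrum; no distance correction or bootstrap in the
tree stage; region maps are carried as metadata but the analysis is not
partitioned by island.
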