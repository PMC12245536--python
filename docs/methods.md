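# Methods

## Problem setting

Public archives hold thousands of assemblies for well-studied bacterial
species, heavily skewed toward a few lineages. Dereplication selects a
subset of *representative* genomes that preserves the diversity of the
collection while discarding near-duplicates, either so that downstream
comparative analyses become affordable or so that read-mapping
references are not split across indistinguishable strains. `derepkit`
operates on two kinds of precomputed evidence: pairwise ANI/AF
estimates (the sparse triangle output of an alignment-free ANI
estimator) and protein-cluster memberships (a greedy amino-acid-level
clustering of all proteins across the collection). It does not compute
ANI or cluster proteins itself; those are upstream tools consumed
through their file formats.

## Similarity graph and score

Genomes are nodes; an undirected edge joins a pair when

* ANI ≥ `ani_cutoff` (default **99.0%**), and
* max(AF_a, AF_b) ≥ `af_cutoff` (default **90.0%**).

AF (aligned fraction) is directional — the percentage of one genome's
length aligned to the other — so each pair carries two values; using
the larger one means a pair counts as similar when *either* genome is
well covered. Comparisons are inclusive (≥): a user asking for 99.0
keeps pairs reported at exactly 99.0. All percentages are kept on the
0–100 scale exactly as upstream tools print them; nothing rescales to
0–1, which removes a whole class of double-scaling bugs.

Each genome's representativeness score is `degree × N50`, an exact
integer product (both factors are integers), so sorting is fully
reproducible. N50 is the largest contig length L such that contigs of
length ≥ L hold at least half the assembly — a standard proxy for
assembly quality. A genome with no qualifying neighbour scores 0 and
always ends up representing itself.

## Greedy selection

Genomes are traversed in descending score order (ties: larger N50, then
lexicographically smaller identifier — the tie rules are this package's
choice, made for determinism). A genome not yet disqualified becomes a
representative and disqualifies its direct neighbours. Disqualification
does not propagate through disqualified genomes. The result is a
maximal independent set of the similarity graph, which implies the
advertised guarantee: every non-representative has at least one
representative neighbour, i.e. lies within the requested ANI and AF
cutoffs of it.

## Dynamic selection

Every qualifying pair (same edge rule as above) marks exactly one of
its two genomes redundant:

* **Containment rule** — if |AF_a − AF_b| > `max_af_difference`
  (default **10.0** points; the threshold itself is exposed as a
  parameter since no canonical value exists), the genome with the
  *higher* AF is marked. A large AF asymmetry signals a smaller genome
  largely contained in a bigger one (e.g. a reduced or partial
  assembly); such genomes should not represent others.
* **Score rule** — otherwise the lower-scoring genome is marked (ties:
  smaller N50 marked, then lexicographically larger id marked).

After all pairs are assessed once, unmarked genomes are the
representatives. Marking is idempotent and never reversed, so the
representative set is independent of pair order; pairs are still
processed in canonical sorted order so that the *rule tag* recorded for
each genome (which rule marked it first) is reproducible. This
approximates single-linkage clustering — about one representative per
connected component — and deliberately gives no per-genome distance
guarantee: an indirectly connected genome can lie farther from its
representative than the cutoffs. With the containment rule active a
component can in principle lose all members (mutual containment
cycles); this is reported as a warning, never silently repaired,
because the right corrective action depends on why the data look that
way.

## Saturation selection over protein clusters

Input is a membership map genome → set of protein clusters, from either
a CD-HIT `.clstr` report (genome attribution via a configurable
delimiter in the protein headers, default `|`, since concatenated
proteomes must be tagged somehow and no convention is universal) or a
headerless two-column TSV. Selection is greedy maximum coverage:

1. start with the genome carrying the most distinct clusters;
2. repeatedly add the genome with the largest marginal gain (clusters
   not yet covered); ties: larger total cluster count, then smaller id;
3. stop when one of three criteria fires:
   * (i) *before* adding, the best candidate's gain < `X` (default 0 —
     inert, gains are never negative);
   * (ii) *after* adding, covered/total > `Y`% (default 90);
   * (iii) *after* adding, covered multi-genome clusters / total
     multi-genome clusters > `Z`% (default 100 — inert). A multi-genome
     cluster is one present in ≥ 2 genomes.

The pre/post ordering is the only one under which the default X and Z
are truly inert, leaving Y as the sole active control. Coverage
comparisons use exact rational arithmetic (`fractions.Fraction`), so a
coverage of exactly Y% never flips on float rounding. A membership with
no multi-genome clusters counts as 100% covered for criterion (iii), so
Z = 100 cannot fire vacuously. Because coverage is submodular, marginal
gains along the selection order are non-increasing; the test suite
asserts this and checks the whole procedure against a from-scratch
brute-force oracle on small instances.

An optional **incremental pass** then promotes gene-content outliers:
any non-representative sharing less than `incremental_overlap_pct`
(default 90%) of *its own* clusters with every current representative
is promoted, in rounds against the growing representative set (largest
cluster count first), so a promoted genome can absorb later candidates.

## Secondary clustering

Each non-representative is assigned to one representative.

* **ANI-tiered** (used after ANI dereplication): tier 1 considers only
  representatives meeting both cutoffs for that genome and picks the
  largest ANI (ties: larger max-AF, then smaller id); tier 2, when the
  tier-1 pool is empty, applies the same ranking over all
  representatives with any recorded pair. Genomes with no recorded pair
  to any representative are reported unassigned with a warning. An
  optional ranking by ANI × (non-representative AF) is available as an
  alternative that weighs genome coverage; the tiered largest-ANI rule
  is the default.
* **Shared-cluster** (after gene-content dereplication): assign to the
  representative maximizing |clusters(g) ∩ clusters(r)| / |clusters(g)|
  (ties: larger representative cluster count, then smaller id).

## Cutoff sweep and network export

The sweep rebuilds the graph and reruns the chosen algorithm from
scratch for every (ANI, AF) grid cell — no incremental shortcuts — so
each cell is identical by construction to an independent run, and the
tests assert exactly that. Default grids (ANI {95, 97, 98, 99, 99.5},
AF {25, 50, 75, 90}) bracket common dereplication settings. The
similarity network exports to GraphML (node attributes:
`is_representative`, `n50`, `score`, `degree`; edge attributes: `ani`,
`af_a`, `af_b`) plus a plain edge-list TSV.

## MGE masking and pipeline order

Mobile genetic elements (plasmids, prophages) evolve faster than
chromosomes and depress apparent between-strain ANI, so users may
excise predicted MGE coordinates (supplied as 0-based half-open BED;
overlapping intervals are merged on read) before ANI estimation.
Masking splits each contig at its intervals; retained segments are
written as `<contig>_part<k>` (left-to-right, an invented but sortable
convention), empty segments are dropped, a fully covered contig
disappears, and untouched contigs pass through byte-identical. No
minimum residual-segment length is enforced. Base accounting (retained
+ masked = original, per contig) is returned and asserted in tests.

Order matters: splitting scaffolds shreds N50, so N50 is computed on
the unmasked assembly and `apply_masked_roster` carries that value
forward while swapping the sequence source to the masked file —
MGE-rich genomes are not penalised as representative candidates. A
genome whose masked assembly retains no contigs is dropped with a
warning.

## Synthetic data

The generators emit exactly the formats the readers parse, with planted
truth:

* `simulate_population` plants clusters of near-identical genomes.
  Defaults: within-cluster ANI ~ Normal(99.8, 0.1) and AF ~
  Normal(95, 2), both truncated to [0, 100] (truncation matters —
  naive normal draws exceed 100 near these means); N50s log-uniform on
  [10⁴, 10⁶] bp, spanning typical draft to near-complete bacterial
  assemblies. Between-cluster pairs are *omitted* from the edge list,
  mirroring the k-mer screening step of real ANI estimators that never
  reports distant pairs (a flag can emit them, at ANI ~ Normal(85, 2),
  for stress-testing cutoff logic). A configurable fraction of genomes
  is "contained": their within-cluster pairs get AF near 99 on their
  own side and near 60 on the partner's, an asymmetry comfortably
  beyond the 10-point containment threshold.
* `simulate_pangenome` gives every genome all core clusters plus an
  independent Bernoulli subset of an accessory pool — the
  core/accessory structure that makes saturation selection meaningful.
* `simulate_toy_genomes` writes small random-sequence FASTA files
  (60-column wrapped) with at most one planted MGE interval per contig.

All generators are pure functions of parameters + seed. What they do
*not* model: actual sequence divergence (ANI is asserted, not
computed), correlated AF between pair members, assembly fragmentation
artefacts, or contamination. Passing tests therefore demonstrate the
selection logic, threshold handling and format fidelity — not the
behaviour of any upstream ANI estimator on real genomes.

## Verification sizes

The randomized suites use 500 graphs of up to 200 genomes (greedy and
dynamic structure), 200 random memberships of ≤ 10 genomes × ≤ 30
clusters against the brute-force oracle, a planted 12-cluster
population of 10–30 genomes per cluster for recovery, 1,000 random
length lists for N50, and a 2 × 5 fixture batch for sweep consistency —
sizes at which the whole suite and the acceptance script each complete
in seconds while exercising every code path at non-trivial scale.

## Known limitations

* Assembly quality enters only through N50; there is no
  contamination/completeness weighting — heavily contaminated MAGs
  should be filtered before dereplication.
* The dynamic mode's containment rule can, on adversarial inputs,
  empty a component (warned, not repaired).
* The `.clstr` genome-attribution delimiter is a convention, not a
  standard; mis-setting it fails loudly (missing-delimiter error)
  rather than mis-assigning proteins.
* Parsers accept only the sparse triangle edge-list dialect, not the
  full-matrix output of ANI estimators.
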