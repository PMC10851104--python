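# Methods

This note documents the models, rules and numerical choices behind
histonet, and what its synthetic-data tests do and do not demonstrate
about real structural data.

## Interface definition

A residue pair on two different chains is an interface contact when any
pair of their heavy (non-hydrogen, non-deuterium) atoms lies within a
distance cutoff, 5.0 Å by default. The comparison is inclusive (≤ 5.0 Å);
the choice matters only for measure-zero boundary cases, and the
synthetic generators deliberately never place atoms within ±0.1 Å of the
cutoff, so no test outcome depends on it. Elements are taken from the
coordinate records, with a fallback inference from atom-name convention
in the PDB dialect.

Contact search uses a k-d tree (`scipy.spatial.cKDTree`) over all heavy
atoms and is required — by test and by the acceptance check — to agree
exactly with a brute-force all-pairs distance scan. Per residue pair the
minimum heavy-atom distance and the number of heavy-atom pairs within the
cutoff are recorded; the latter is the "atomic contact count" used by the
hotspot profiles.

Contacts are classified by the chain roles into four classes: HHI
(histone–histone), HDI (histone–DNA), HPI (histone–partner) and DPI
(DNA–partner). Partner–partner and DNA–DNA contacts are computed (they
are cheap and occasionally useful diagnostics) but excluded from the
four-class networks; the partition invariant — every reported contact
lies in exactly one class, and the four class counts plus the excluded
counts sum to the total — is enforced in tests.

Chain roles come from a two-stage histone classifier: a case-insensitive
keyword match on the entity name (per-type keyword lists shipped as
editable YAML), then a global sequence-identity fallback (≥ 60% identity
to a bundled reference sequence per histone type, computed with
Biopython's pairwise aligner and normalized by the longer sequence).
Nucleic chains are typed by component composition; hybrid chains go to
the majority class with a logged warning. Modified amino acids listed in
the PTM component map (ALY, M3L, KCR, SEP, ...) are kept as polymer
residues so PTM-site contacts remain detectable, and HPI edges touching
them carry their PTM type.

Only the first model of a coordinate file is read, and only alternate
location 'A' or blank is kept; insertion codes are not modeled (the toy
scale never produces them, and real nucleosome depositions rarely use
them on histone chains).

## Networks and topology

Residue-level network nodes are `<protein>/<sequence position>`, where
the protein id is a UniProt accession when a residue-number mapping table
supplies one, else a slug of the entity name. Collapsing to domain or
protein granularity keeps an edge between two collapsed nodes iff at
least one residue-level edge exists between their members, with evidence
sets unioned; this soundness property is checked exhaustively against a
brute-force relation on synthetic networks. Cross-link and
high-throughput sources contribute protein-level edges only. The global
network adds one layer of partner–partner edges anchored at existing
partners; expansion never removes anything.

Maximal Clique Centrality is applied literally:
MCC(v) = Σ over maximal cliques C containing v of (|C|−1)!. An isolated
node lies in its own singleton maximal clique and scores 0! = 1; no
special case replaces MCC by degree in edge-free neighborhoods. Clique
enumeration delegates to networkx's Bron–Kerbosch-with-pivoting and is
verified against exhaustive subset enumeration on small random graphs.
Hub calling supports both an MCC threshold (default ≥ 4) and a top-N
ranking with lexicographic tie-breaking, because fixed hub counts are
also used in practice.

The topological coefficient follows the NetworkAnalyzer convention:
T(n) = mean over nodes m ≠ n sharing at least one neighbor with n of
J(n,m), divided by the degree of n, where J(n,m) counts shared neighbors
plus one when n and m are directly adjacent. Betweenness is standard
normalized Brandes on the unweighted graph.

The power-law decay check regresses the log of the per-degree mean of a
coefficient (clustering or topological) on log degree and reports the
slope together with the Spearman correlation of the per-degree means
versus degree. The per-degree mean is the decay statistic of interest: a
per-node correlation is dominated by the many low-degree nodes whose
local clustering is exactly zero and can even come out positive on
networks whose mean clustering clearly decays. At least 10 distinct
degrees are required; degenerate degree distributions raise an error.

## Representative selection and binding modes

Nucleosome complex structures pass, in order: a subnucleosomal filter
(at least 7 of the 8 core-histone chains required), a DNA-anchoring
filter (at most 20 bp of nucleosomal DNA may lack any 5 Å heavy-atom
contact with the octamer), and a partner-length filter (≥ 10 residues).
Remaining candidates are grouped per partner; within a group, structures
whose interface-residue Jaccard similarity is ≥ 0.8 are treated as the
same binding mode, and the cluster keeps its mutation-free member with
the best (numerically lowest) resolution. Distinct binding modes of one
partner each keep one structure. The 0.8 Jaccard knob quantifies
"identical binding mode"; it is configurable because no universal value
exists, and 0.8 keeps genuinely distinct modes separate on the synthetic
suites. Selection is idempotent by construction and by test. A contested
redundancy group containing a structure without a resolution is an error
rather than a silent guess.

Contacting partners partition into three binding modes from which
interface sets are non-empty: `dna_only` (DPI without HPI),
`histone_only` (HPI without DPI) and `both`. Partners with no contacts
at all are labeled `none`, warned about, and excluded from mode
fractions.

Histone hotspots are profiled on consensus coordinates: each variant's
residue position maps to its column in a per-type multiple sequence
alignment (supplied as aligned FASTA; the aligner itself is not run).
Per consensus position the profile counts distinct partner *proteins* —
a partner touching through two of its chains counts once — and the mean
heavy-atom contact count over (structure, partner) pairs that have at
least one contact there, not over all structures.

DNA hotspots are indexed by base pair relative to the dyad. Strands are
paired by reverse indexing (position i on one strand pairs with n−i+1 on
the other, n the longer strand length; mismatches beyond 4 nt are an
error), a partner touching either strand of a pair counts once, and the
dyad defaults to the midpoint base pair ((n+1)//2, i.e. bp 74 of a
147-bp duplex) unless supplied per structure. SHL is reported as the
dyad-relative index over 10. Which chain is "strand I" is decided
lexicographically; relabeling the strands therefore mirrors the signed
profile around the dyad (the unsigned |SHL| profile is invariant), which
is the strongest symmetry available without strand-orientation input.

## Mutation curation and disruption calling

The combined set keeps somatic missense records after removing
targeted-panel sequencing and somatic-unmatched samples, optionally
unioned with an external dataset and deduplicated on (gene,
protein-change, sample). The refined set then removes records from
samples with tumor mutation burden strictly greater than 10 mutations/Mb
(taken from the input column when present, else derived as per-sample
mutation count over a configurable 38 Mb callable exome territory),
removes known dbSNP variants, and keeps mutations observed in at least 3
distinct samples after those filters. The recurrence key is (gene, wt,
position, mut) across cancer types. Strict ">" applies to the TMB
cutoff and "≥" to recurrence and ΔΔG thresholds.

Physicochemical profiling uses a fixed five-way partition of the 20
standard amino acids: positive {K,R,H}, negative {D,E}, polar-uncharged
{S,T,N,Q,C}, nonpolar-aliphatic {G,A,V,L,I,M,P}, nonpolar-aromatic
{F,W,Y}. Histidine is grouped with the positives and cysteine with the
polar-uncharged residues; these assignments are conventions, stated here
because reasonable alternatives exist.

Binding free-energy changes are produced by a pluggable predictor with
the contract `predictor(structure, chain, position, wt, mut, mode) →
kcal/mol`, positive = destabilizing, mode ∈ {protein-protein,
protein-DNA}. For HHI and HDI predictions the partner chains are pruned
from the complex before the call; HPI predictions receive the full
complex. The bundled surrogate (`surrogate-physchem-v1`) is a
deterministic hydropathy/charge-difference score and is explicitly
non-physical: it exists so the calling machinery, the pruning contract
and the selection thresholds are testable and reproducible; its numbers
carry no thermodynamic meaning. Disruptive calling selects recurrent
mutations (≥ 3 samples) whose per-mutation mean ΔΔG — averaged over
structures after per-structure deduplication — is ≥ 1.0 kcal/mol for
HDI and ≥ 1.5 kcal/mol for HHI and HPI. The HDI threshold is applied to
the per-mutation mean, consistent with the other two classes.

Group comparisons of ΔΔG distributions use Tukey's honestly-significant-
difference test (statsmodels) with flags at 0.05 and 0.005. Calibration
is part of acceptance: under a seeded null the 0.05 flag fires at its
nominal rate, and a 5-sd group shift is detected essentially always at
the simulation sizes used (two groups of 10, 100 replicates).

## Synthetic data: what it does and does not emulate

The toy complexes are deliberately non-physical: poly-alanine backbones
and three-atom nucleotides on home columns 60 Å apart, 8 Å between
residues, with one designated contact atom per residue. A planted pair
moves the mover residue's contact atom to an exact distance d from the
target's contact atom along a direction orthogonal to the layout plane,
so the pair's nearest heavy-atom distance is exactly d; d ∈ [4.5, 4.9] Å
plants a contact and d ∈ [5.1, 7.0] Å a non-contact, never within 0.1 Å
of the cutoff. At most two movers may approach one target (at 0° and
25°); a wider fan would drift toward neighboring residues and break the
exact-distance contract, so a third mover is an infeasible spec. Every
generated file is re-checked by the all-pairs oracle before its truth
sidecar is written, and generation is byte-deterministic per seed.

These fixtures exercise bookkeeping exactly — contact geometry,
classification, network assembly, selection filters, hotspot counting —
but contain no superhelical DNA, no acidic-patch geometry, no crystal
contacts, no altloc/insertion-code pathology and no electron-density
noise. Passing tests therefore certify the pipeline's logic, not the
biological plausibility of any particular interface.

Synthetic mutation tables plant the exact composition the filters must
recover: per-recurrence-class mutation counts, targeted/unmatched/
nonsense records, dbSNP-flagged and hypermutator-confined mutations, and
a configurable fraction of recurrent mutations placed on planted
interface positions. The truth sidecar states the expected combined and
refined sizes and per-class mapping counts, so acceptance consumes truth
files rather than constants.

The preferential-attachment generator grows from m seed nodes, wiring
the first m added nodes to every seed so the minimum degree is m
everywhere while keeping the closed-form edge count m(n−m); plain BA
growth can leave a seed under-attached. Topology acceptance uses n=2000,
m=3 over 20 seeds — large enough for a broad degree distribution, small
enough to keep the whole acceptance run in minutes on one CPU.

## Problem sizes used in tests and acceptance

Contact-oracle equivalence: 50 random complexes of 200–2000 atoms.
Clique/MCC oracle: 100 Erdős–Rényi graphs with n ≤ 12 (exhaustive subset
enumeration stays trivial at 2^12). Collapse soundness: 20 random
residue networks over 8 proteins. Binding-mode fractions: a 20-complex
suite planted 13/4/3. Mutation recovery: one table of ~70 records plus
100 random generator specs for filter monotonicity. These sizes make the
full suite run in well under a minute apiece while leaving every check
exact rather than statistical, except where the property itself is
stochastic (scale-free decay sign, Tukey calibration).

## Known limitations

- Histone typing trusts entity names first; a mislabeled deposition
  would need the sequence fallback to catch it, and chimeric or heavily
  engineered constructs may evade both.
- DNA is represented at nucleotide granularity; at protein granularity
  all DPI edges attach to a single pseudo-node per DNA entity.
- The dyad is configuration, not inference; geometric dyad detection is
  out of scope.
- The surrogate ΔΔG predictor is non-physical by design; real disruption
  calls require wrapping a trained protein–protein and protein–DNA
  predictor behind the plugin contract.
- Cross-link and high-throughput evidence enter as protein-level edge
  lists; no mass-spectrometry or database processing is performed here.
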