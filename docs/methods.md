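# Methods

## Selection model

The engine operates on *percentage contributions*, never on absolute
expression. For a feature *i* with non-negative expression
x<sub>i1</sub>…x<sub>iK</sub> over the K facets of one panel,

p<sub>ij</sub> = 100 · x<sub>ij</sub> / Σ<sub>j</sub> x<sub>ij</sub>.

A *slider constraint* on facet *j* is a closed interval
[min%, max%] ⊆ [0, 100]; a feature passes a panel when every
constrained facet's contribution lies in its interval. Both bounds are
inclusive ("at least min and at most max"), evaluated with an absolute
tolerance of 1e-9 so that float noise at a handle position never flips
a selection; stored percentages are never rounded (rounding is a
display concern). [0, 100] is the neutral slider and imposes nothing;
[0, 0] is a negative selection excluding any activity in that facet.
Enabled panels combine by intersection (AND) or union (OR); a disabled
panel is vacuous regardless of its sliders.

Assumptions: expression values are non-negative and comparable across
the samples of a panel after whatever upstream normalization produced
them (TPM, RPKM, intensity); the engine adds no cross-platform or batch
correction, and deliberately offers no absolute-expression threshold —
specificity is always relative.

## Facet aggregation

Library-level columns are collapsed to facet columns by **sum**
(default) or mean. Sum is the default because it preserves total tag
counts for count-derived units, which makes contribution percentages
invariant to how many libraries a facet happens to be split into;
splitting a facet's libraries in two leaves every feature's
contribution unchanged. When a dataset carries several panels (e.g.
primary cells and tissues), contributions are computed per panel
independently — each panel's row sums to 100 on its own — which is what
makes panel disabling and AND/OR combination well defined.

## Zero-expression features

A feature with zero total expression over a panel has undefined
contributions. Such features are stored as all-zero rows with a cleared
`defined` flag, are **excluded** from any selection in which at least
one slider differs from [0, 100] (they carry no evidence for or against
any facet, and must not satisfy an exclusion slider "for free"), and
are **included** when every slider is at its default, where selection
is vacuous.

When different panels cover different feature universes, selection runs
on the intersection with a logged warning (an OR across unequal
universes is otherwise ill-defined); a strict mode
(`universe_mismatch="error"`) rejects the mismatch instead.

## Ordinal protein constraints

Immunohistochemistry staining is reported on the four-step ordinal
scale None < Low < Medium < High, so protein sliders are closed
intervals on that scale rather than percentages. A gene/tissue pair
with no recorded staining call fails any constraint on that tissue:
absence of evidence must not satisfy an evidence requirement. Dual
RNA + protein selection is the conjunction of the RNA percentage
selection and the protein ordinal selection, evaluated on the
intersection of the two gene universes (an empty intersection is an
error, not an empty result).

## Genomic filters

Internal coordinates are 0-based half-open (BED); VCF/dbSNP positions
are converted from 1-based at ingest, and all exports are BED. Region
filtering requires ≥1 bp interval overlap with a half-open query.
Gene-window filtering keeps features whose anchor point — interval
midpoint by default, strand-aware 5′ end selectable — lies in the
closed window [TSS − w, TSS + w], with w = 100 000 bp by default; a
gene with several annotated TSSs contributes the union of per-TSS
windows, avoiding any canonical-transcript choice. Enhancer–SNP
overlap reports a pair when midpoint-to-SNP distance is ≤ 200 bp
(default), with midpoint = floor((start + end)/2) — floor is an
arbitrary but deterministic choice for odd-length arithmetic; the
boundary is inclusive (exactly 200 bp pairs, 201 bp does not).
Enhancer–promoter association is a pass-through join of a supplied
correlation table; no correlation is computed here.

## Synthetic data

The generator emulates the two situations the engine must handle: a
fixed 3 × 4 demonstration matrix whose three textbook selections
(brain ≥ 80%; blood and heart both in [30, 45]; brain = 0 with
liver ≥ 50%) each pick exactly one gene, and planted-specificity
matrices. In the latter, background features draw their contribution
vector from a symmetric Dirichlet(α) (α = 1 ⇒ uniform on the simplex;
large α ⇒ near-uniform 100/K contributions), while each planted
feature puts Uniform[t, 100] percent in its designated facet and
spreads the remainder as a Dirichlet draw over the others, so planted
features satisfy the [t, 100] slider by construction. Rows are scaled
by a log-uniform depth in [10, 10⁴] so raw values resemble tag counts
while percentages stay exact. A single seeded NumPy generator per call
makes output byte-identical under the same seed (default 1734, an
arbitrary fixed constant).

What the generator does *not* emulate: the correlation structure
between related facets in real atlases (brain sub-regions co-vary),
library-size noise, and measurement error. Passing tests therefore
demonstrate the correctness of the selection semantics, not that any
particular slider setting is biologically meaningful on real data.

## Problem sizes and numerical choices

Randomized correctness checks run at up to 200 features × 20 facets
with hundreds of constraint-set draws, planted-recovery checks use 60
features × 10 facets over 20 seeds, and genomic oracles use 50
enhancers × 200 SNPs — sizes at which the brute-force per-feature and
all-pairs oracles are themselves trivially auditable while exercising
every code path; the vectorized engine itself handles atlas-scale
matrices (tens of thousands of features) without special handling.
Planted-recovery runs verify by direct scan that no background row
reaches the planted threshold before asserting exact recovery, and
skip the (rare) ambiguous draws rather than asserting on them.
Percentage comparisons use absolute tolerance 1e-9 throughout; matrix
TSV output uses `%.17g` and reading uses round-trip float parsing so
write→read is bit-exact.

## Known limitations

- No statistical test of specificity (no p-values or enrichment
  coloring); selection is purely deterministic set algebra on
  contributions.
- No ranking of selected features; output order is input order.
- No network fetchers for the public atlas tables; users download
  those themselves and feed the TSV/GCT/BED/VCF files in.
- No liftover between assemblies; coordinates are taken as given.
- Whether an upstream atlas's facet values are sums or means of its
  libraries is dataset-specific; both are supported, sum is the
  default.
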