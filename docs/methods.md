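# Methods

## The prioritization cascade

The cascade is a deterministic per-variant decision procedure. Variant
identity is always the tuple (chrom, pos, ref, alt); multi-allelic sites
are decomposed into one record per alternate allele before anything else
runs, and HGVS strings are carried for display only.

**Stage 1 — frequency.** A variant passes iff its population allele
frequency is strictly below `af_cutoff` (default 0.001, i.e. the 0.1%
threshold conventional for high-penetrance germline screens). A variant
absent from the population database is treated as frequency zero *at filter
time*: the parsers deliberately preserve absence (`None`) so that
missingness is never silently converted to a numeric value anywhere else.

**Stage 2 — ClinVar stratification.** `parse_clinsig` maps a raw
clinical-significance string to one of six classes. Non-conflicting P/LP
→ class 4&5; benign/likely-benign → class 1&2; VUS → class 3. Conflicting
records are split by their submitted assertions: any P/LP assertion → class
3+, conflicts confined to benign/VUS → class 2+. A conflicting record whose
assertions cannot be recovered defaults to 3+ — the conservative choice,
and the one matching the convention in this cohort's reporting, where
"conflicting interpretation" means P/LP versus VUS. The mapping is total
(unknown vocabulary warns and maps to *unknown*) and idempotent over its
own labels, so re-reading a written report cannot reclassify anything.
Class 4&5 bypasses stage 3 and is kept; classes 1&2 and 2+ bypass and are
dropped; unknown, 3 and 3+ are routed into stage 3.

**Stage 3 — routing and branch filters.** Routing looks only at the
representative transcript's consequence terms, with a fixed priority so the
branches partition each class:

1. rank-score branch (3.1) if the consequence is missense/stop-gained/
   start-lost *and* at least one of the seven tools produced a score;
2. splicing branch (3.2.1) if any splice-affecting term is present;
3. frameshift/LoF branch (3.2.2) for frameshift-type consequences;
4. otherwise the residual bucket 3.0 ("no applicable scores").

3.0 is defined operationally as *no branch applies*: this covers both
variants with no scores at all and the rare scored variant whose
consequence fits no branch, which keeps the partition invariant (every
stage-3 variant gets exactly one route) airtight. 3.0 members are counted
in the stage grid but never enter the final selection.

Branch filters:

- **3.1**: a per-class boolean expression over tool slots T1–T7,
  `clause := [Tk-cutoff-x]`, combined with `||` or `&&` (one combinator per
  expression). A clause is true iff the slot's rank score is present and
  **≥** the cutoff — a score exactly at the cutoff passes; an absent score
  makes its clause false, never true. Defaults: class-unknown
  `[T2-cutoff-0.99] || [T7-cutoff-0.8]`, class-3
  `[T6-cutoff-0.8] || [T1-cutoff-0.99]`. Class 3+ has no published
  expression of its own and reuses the class-3 one (configurable).
- **3.2.1**: max of the four SpliceAI deltas ≥ `spliceai_cutoff` (default
  0.5, the tool's published recommended threshold); absent deltas fail.
- **3.2.2**: LOFTEE confidence must equal `lof_rule` (default
  high-confidence); anything else fails.

**Tool-slot mapping.** The slot symbols T1–T7 are configuration, not code.
The default assignment is T1=REVEL, T2=ClinPred, T3=VEST4, T4=MetaSVM,
T5=BayesDel, T6=M-CAP, T7=CADD. Two published worked examples pin two
slots: a near-miss variant scored 0.78 by CADD against the class-unknown
expression's 0.8 cutoff (fixing T7=CADD, and fixing the tie rule — if the
boundary itself failed, 0.78 vs 0.8 would not be a "small margin"), and a
VUS carried through the class-3 expression by an M-CAP rank score of
0.99639 alone (fixing T6=M-CAP). The remaining slots keep the tools'
conventional listing order and are fully overridable in the config file,
where every threshold the stage counts depend on lives and is snapshotted
into the run manifest.

**Final selection.** `final_selection` defaults to {class-4&5 bypass, 3.1,
3.2.1, 3.2.2}. On the transcribed stage grid this arithmetic reproduces the
published total exactly: 68 + (81+24+22) + (90+0+1) + (58+2+0) = 346.

## Downstream operations

**Cross-referencing** matches final variants' gene symbols (and aliases,
case-insensitively) against any number of loaded gene lists; a gene's role
(oncogene / TSG / fusion / other) comes from the highest-priority matching
source under a configurable priority order. **Repeat exclusion** drops a
variant iff its anchor (leftmost, 1-based) position falls inside a BED
interval; BED's 0-based half-open convention is converted exactly once, at
this boundary. The definition of "repetitive region" is deliberately
data-driven (whatever track the user supplies), since no canonical
definition exists. **High-impact extraction** subsets variants in a named
gene panel at or above a class threshold, ordered class 3 < 3+ < 4&5; an
optional per-variant class override lets expert ACMG-AMP assignments
(packaged for the nine high-impact variants) replace the ClinVar-derived
class — necessary because one of the nine (an MMR missense VUS) is absent
from ClinVar yet expert-classified as class 3.

**VAF** is alt/(ref+alt) over informative depths, displayed to two
decimals (35,3 → 0.08), undefined when the informative depth is zero.
Depth summaries are taken over per-(variant, carrier) site depths. A
sample *carries* a variant iff its genotype has ≥ 1 alternate allele;
non-carrier calls are not materialized in memory.

## The synthetic generator

`simulate_cohort` emulates the study conditions: 48 samples of which 16
form 8 related pairs; population frequency as a mixture of a point mass of
database-absent variants (10%), a rare Beta(0.3, 800) component and a
common Beta(2, 8) component, calibrated so roughly a fifth of variants
pass the frequency gate, as in the study; ClinVar classes drawn from the
study's stage-2 breakdown (90.8% unknown, 3.3% class 3, 0.18% class 3+,
0.30% class 4&5, 3.9% class 1&2, 1.5% class 2+); consequence types 40%
missense / 8% splice / 7% frameshift / 35% synonymous / 10% other; site
depths Poisson with mean 92, matching the study's mean coverage. Each
variant carries a latent pathogenicity label (rate 5%); rank scores are
drawn per tool from Beta(8, 2) for pathogenic and Beta(1.5, 6) for benign
variants, SpliceAI deltas are elevated for pathogenic splice variants, and
LOFTEE high-confidence calls attach to pathogenic frameshifts with
probability 0.9. Related pairs share half of their rare variants. All
randomness flows from a single seeded generator with a fixed draw order,
so a seed reproduces a cohort bit-for-bit; the latent truth is emitted in
a side table, never inside the cohort or its VCF, so the cascade cannot
consume it.

What the generator does **not** emulate: linkage structure, realistic
mutation spectra or gene lengths, correlated tool errors (real predictors
err on the same hard variants; the simulated scores are conditionally
independent given the latent label), batch effects, and strand/mapping
artifacts. Passing tests therefore demonstrate the cascade's bookkeeping
and decision logic, and score-model recovery under known separation — not
the clinical accuracy of any particular threshold on real data.

Tests validate the generator against closed forms where they exist: with a
Beta(50, 1) pathogenic score model and a single-clause 0.8 cutoff, the
branch-3.1 pass rate at n = 10,000 must sit within a 4-sigma binomial band
of the analytic Beta tail, and empirical class proportions must pass a
chi-square goodness-of-fit test (alpha = 0.01) in at least 18 of 20 seeds.

## Fixtures

The four printed result tables are transcribed verbatim into packaged TSVs
(ambiguous cells such as "Y (30 s)" kept as strings), guarded by SHA-256
checksums verified at load plus internal invariants (45 distinct variants
over 32 samples; per-variant carrier counts equal to the printed
recurrence column; 9 variants in 7 genes). The 45-variant listing
identifies variants by transcript HGVS only, so `cohort_from_table3`
assigns synthetic placeholder loci — stable, one per distinct variant — to
satisfy the key-based identity used everywhere else.

## Numerical and design choices

- Cutoff comparisons: stage 1 is strict (`<`); rank-score, SpliceAI and
  class-threshold comparisons are inclusive (`≥`).
- Transcript selection: canonical flag first, then most severe consequence
  under a condensed severity ordering, then lexicographically smallest
  transcript id — deterministic and input-order independent.
- Role conflicts between gene lists: configurable source priority,
  defaulting to the order the lists are supplied in.
- Degenerate inputs: empty cohorts produce all-zero grids; zero informative
  depth yields an undefined (absent) VAF; an empty BED is the identity;
  negative depths and malformed expressions or BED lines raise.
- Problem sizes in the test suite (cohorts of 1,500–10,000 variants, 50
  seeds for the partition property) were chosen to give tight statistical
  checks while keeping the default run comfortably interactive.

## Known limitations

- The identities of slots T1, T3–T5 beyond the two pinned by worked
  examples are conventional defaults, not published fact; analyses that
  depend on them should set `tool_slot_map` explicitly.
- The class-3+ filter expression is assumed equal to the class-3 one.
- One published VAF (a maximum of 1.65) is not reproducible under any
  standard alt/(ref+alt) definition and is not emulated; the package's VAF
  is bounded by 1 by construction.
- Whether splice-affecting variants that also carry rank scores were
  originally routed to 3.1 or 3.2.1 is unstated; this package routes them
  to 3.1 (rank-score priority), which is configurable only by editing the
  consequence sets.
- Phasing and cis/trans resolution are out of scope, as is any ACMG-AMP
  criteria engine: the class override mechanism accepts expert classes, it
  does not derive them.
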