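# Methods

`gpcrvar` analyzes natural genetic variation in G-protein-coupled receptor
(GPCR) drug targets: where variants fall relative to the receptor's
functional machinery, how many people carry them, and what that implies for
drug response variability and prescription spending. This note records the
models, conventions and numerical choices the package implements.

## Generic residue numbering and cross-class translation

Receptor positions are labelled with structure-based generic numbers
(`<segment>x<index>`, e.g. `3x50`), optionally in dual notation with a
sequence-based Ballesteros–Weinstein index (`5.46x47`). Segments are the
seven transmembrane helices ("1".."7"), the inter-helix segments ("12",
"23", "34", "45", "56", "67") and helix 8 ("8").

Because the x.50 anchors differ between receptor classes, a TM index in one
class corresponds to a shifted index in another. The per-TM offsets from
class A are:

| to class | TM1 | TM2 | TM3 | TM4 | TM5 | TM6 | TM7 |
|---|---|---|---|---|---|---|---|
| B | +4 | +7 | +4 | 0 | −4 | +5 | +4 |
| C | +4 | −4 | +4 | −10 | 0 | +2 | −5 |
| F | −3 | −1 | 0 | 0 | +4 | −1 | 0 |

Translation between two non-A classes composes through class A
(`offset(X→Y) = −offset(A→X) + offset(A→Y)`), which makes translation
antisymmetric and exactly invertible. Offsets exist only for TM1–7; loop,
helix-8 and terminal labels raise an "untranslatable segment" error instead
of passing through silently. Example: class C `4x50` ↔ class A `4x60`.

Structural segments (N-term, TM1–7, ICL1–3, ECL1–3, H8, C-term) partition
the 1-based sequence into ordered, disjoint, covering ranges; residues
before TM1 are N-terminal and residues after helix 8 C-terminal.

## Variant model and landscape metrics

- **MAF** = `min(AC, AN − AC) / AN` (frequency of the less frequent allele).
- **Rare/common split** at MAF 1 × 10⁻³; a variant exactly at the threshold
  is common. The threshold is a config parameter.
- **Property change**: amino acids belong to (possibly several) classes —
  hydrophobic {A,C,F,I,L,M,V,W,Y}, aromatic {F,H,W,Y}, polar-uncharged
  {S,T,N,Q}, helix-breakers {P,G}, negative {D,E}, positive {H,K,R}. A
  substitution is "similar" when the two residues share at least one class;
  a strict mode requiring identical class sets is available.
- **MV density** = number of missense variants / receptor length.
- **Minimum LoF carriers**: with only aggregate counts (no genotypes), the
  LoF position with the highest allele count bounds the carrier number from
  below by `AC − hom_count` (each homozygote contributes two alleles but is
  one carrier).
- **z-scores** standardize each landscape category across the receptor
  panel using the sample standard deviation (ddof = 1); a degenerate
  category (sd = 0) maps to all-zero z with a warning.

## Functional sites

Known functional sites are the union of five categories:

1. **Ligand binding**: residues with any atom within 4.5 Å of a
   co-crystallized ligand, restricted to positions carrying a generic
   number (the ECL2 positions around `34x52` carry inter-helix numbers and
   enter through the same rule). Contacts come from PDB/mmCIF coordinates
   (via gemmi, minimum inter-atomic distance) or from precomputed contact
   TSVs, so the pipeline runs without a structure library. The contact
   definition is a pure distance cutoff; interaction typing
   (aromatic/polar/hydrophobic) is out of scope, which can shift interface
   membership by a small number of positions relative to typed-contact
   pipelines. A 5 Å override exists for figure-style displays only.
2. **Family inheritance**: an uncrystallized receptor inherits a
   crystallized family member's pocket at every generic position it
   possesses; ortholog donors transfer a position only when the human
   residue there is identical.
3. **Effector interfaces**: per-class unions of per-structure contact sets
   (class A G protein: 3SN6, 5G53, 3DQB, 3PQR, 4A4M; class A arrestin:
   4ZWJ, 4PXF, 5DGY; class B: 5UZ7, 5VAI). Classes C and F take the union
   of the class A and B sets translated through the offset table, dropping
   untranslatable positions with a warning.
4. **Registries** (class A only): 17 activation micro-switches (including
   R`3x50`, W`6x48` and the P-I-F motif) and the 15-position allosteric
   sodium pocket around D`2x50`.
5. **PTM sites**, keyed by residue index (most lie in termini without
   generic numbers), cross-validated against the receptor sequence: a
   record whose stated modified amino acid disagrees with the sequence is
   dropped and logged.

**Putative functional impact**: SIFT ≤ 0.05 (deleterious) or PolyPhen > 0.1
(possibly/probably damaging); a missing score contributes false. PolyPhen
exactly 0.1 is benign — the damaging band is taken as strictly greater
than 0.1.

## Population metrics

Genotypes are 0/1/2 alternate-allele counts per individual and site;
missing calls are treated as reference with a logged count. Per-individual
burden counts carried sites (genotype ≥ 1) and distinct receptors.

The four **affected-individual criteria**, from most to least conservative:
(i) homozygous at a known functional site, (ii) any allele at a known site,
(iii) homozygous at a known-or-putative site, (iv) any allele at a
known-or-putative site. Homozygous criteria require genotype 2 at a single
qualifying site — compound heterozygosity does not qualify. For
multi-target drugs an individual is affected if affected in any target
(union), so criterion fractions are monotone i ≤ ii ≤ iv and i ≤ iii ≤ iv.

The **de novo rate** divides trios by offspring carrying a new missense
variant in a target and presents "1 in ~N" with N rounded to one
significant figure (1,762 trios / 6 offspring → 293.7 → "1 in ~300").

## Drug scores and burden

- `S_polymorphic(drug) = Σ_targets fraction of known functional sites
  polymorphic` — targets default to all approved-status links (primary and
  secondary; configurable to primary-only); trial-only and discontinued
  links are excluded.
- `S_affected(drug, criterion)` delegates to the affected-fraction
  computation over the union of the drug's targets.
- **Average annual cost** sums monthly actual costs per calendar year
  inside an inclusive window (default 2013–2016) and averages over window
  years with data; boundary years with partial ledgers fall outside the
  window and are ignored.
- **Burden** = average annual cost × affected fraction, per drug and
  criterion; the panel total is the sum over drugs. Costs are carried in
  GBP; million-scale only at presentation. Drugs prescribed but absent from
  the target map are reported unscored, not dropped.
- **In vitro matching** requires identical receptor, position, wild-type
  and mutant amino acid (ortholog records only at identical human
  residues); the maximum absolute fold change over ligands is flagged at
  the 5-fold cutoff.

## Permutation statistics

Empirical p is the plain tail estimator `#{null ≥ observed} / n_iter`
without the +1 correction, reported as `< 1/n_iter` when no draw reaches
the observation. The z-score uses the null's mean and population sd
(ddof = 0); a degenerate null (sd = 0) reports z = NaN. Because the
granularity of the empirical p is 1/n_iter, a normal-tail p from the null
moments is emitted alongside. All draws are without replacement within an
iteration from a single seeded NumPy Generator, so results are
bit-reproducible given (seed, n_iter). n_iter defaults to 100,000 and is
reducible for tests.

The rank-sum comparison enumerates all group assignments exactly for
combined n ≤ 12 (midranks handle ties) and otherwise uses the tie-corrected
normal approximation with continuity correction; two identical groups
give p = 1.

## Synthetic data

The generator emulates the study's inputs with known ground truth:

- Receptor panels of 30 receptors (class mix 85% A / 5% each B, C, F),
  lengths 320–480, seven 25-residue TMs numbered x38–x62 around the x50
  anchors, loops (four mid-ICL2 residues carry 34x50–34x53), a 10-residue
  helix 8 and random termini.
- An exact plant of `round(fraction × length)` known functional sites per
  receptor (default fraction 0.15).
- Variant positions drawn with relative rate ρ inside planted sites
  (default 1); allele-frequency spectrum = 60% singletons + 2.8% common
  (MAF ≥ 10⁻³) + a Zipf(2) rare tail on an AN of 121,412 (2 × 60,706
  exomes); ~67% of variants drawn with damaging SIFT/PolyPhen scores. The
  mixture parameters are exposed; the empirical exome spectrum itself is
  not parameterized.
- Genotypes i.i.d. Binomial(2, p) per individual — exact Hardy–Weinberg at
  each site, independent across sites (no linkage disequilibrium); realized
  sample allele counts are written back for consistency. Default cohort
  2,504 individuals.
- Drug maps of 40 drugs with 1–3 targets and lognormal monthly cost
  ledgers over 2013–2016 with known annual totals, plus partial
  boundary-year months (late 2012, early 2017) that the cost averaging
  must exclude.

Because the generator assumes HWE, no LD, no population structure and
independent uniform variant placement, passing tests demonstrate the
correctness of the counting, classification and inference logic — not that
real cohorts satisfy those assumptions. Headline numbers from real
ExAC/1000 Genomes/NHS snapshots are not reproduced at this scale.

## Test and analysis problem sizes

The bundled analysis uses 30 receptors × 2,504 individuals with 10,000
permutations; the statistical acceptance checks use 500 calibration
replicates at 1,000 iterations, recovery runs at 2,500 individuals and
12-receptor panels, and Hardy–Weinberg checks at 10,000 individuals. All
stochastic assertions use four-standard-error bounds from the relevant
binomial or Monte-Carlo error.

## Known limitations

- Contact extraction is untyped distance only; Arpeggio-style typed
  contacts can differ at interface margins.
- Generic numbers are consumed as annotation, never recomputed from
  alignments or structures.
- The burden estimate deliberately ignores repeat prescriptions, dosage,
  hospital prescribing and health-economic discounting; it is a simple
  rate × cost product.
- CNV counts and LoF tables are consumed as published aggregates; no
  calling is performed.
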