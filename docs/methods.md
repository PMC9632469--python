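# Methods

## Problem and model

`soeprimer` designs the four primers needed to ligate two DNA fragments by
overlap extension PCR. The two fragments are conceptually concatenated into
the target *chimera* (fragment 1 then fragment 2 on the sense strand; the
junction index J is the first base of fragment 2; all coordinates are
0-based, half-open, on the chimera's sense strand). Four primers are
derived from that chimera:

* `gene_5` — the first n5 bases (forward end primer);
* `gene_3` — reverse complement of the last n3 bases (reverse end primer);
* `overlap_5` — forward junction primer `chimera[J−p1 : J+p2]`: p1 bases
  from the 3′ end of fragment 1, p2 from the 5′ end of fragment 2;
* `overlap_3` — reverse junction primer, the reverse complement of
  `chimera[J−q1 : J+q2]`.

The two junction primers are partially reverse-complementary: they share a
duplex `chimera[J−min(p1,q1) : J+min(p2,q2)]` and each protrudes past it as
a 3′ overhang into the partner fragment. The configuration requires
q1 ≥ p1 and p2 ≥ q2 for every enumerated combination (checked at config
construction), so neither junction primer is ever 5′-recessed and the
duplex length is simply p1 + q2.

### Search space

Part lengths are a fixed base plus a per-part offset:

| parameter | meaning | default |
|---|---|---|
| `fwd_frag1_base` + i | p1, fragment-1 part of overlap_5 | 8 + 0…3 |
| `fwd_frag2_base` + j | p2, fragment-2 part of overlap_5 | 12 + 0…3 |
| `rev_frag1_base` + k | q1, fragment-1 part under overlap_3 | 12 + 0…3 |
| `rev_frag2_base` + l | q2, fragment-2 part under overlap_3 | 8 + 0…3 |
| `end_len_min…max` | n5, n3 end-primer lengths | 14…30 |
| `tm_favorite` | preferred duplex Tm, °C | 63 |

Offsets i, j, k, l each range over 0…3, giving 4×4 = 16 forward and 16
reverse junction primers; end lengths give 17 choices each; the full space
is (4²)² × 17² = 73,984 tetrads, every one materialized with sequences,
lengths, GC, Tm, duplex Tm and score. The base part lengths are the
package's own decomposition choice: the reference tetrad's junction primers
split as 11 + 15 nt and 15 + 11 nt, which these bases reach at offsets
(3,3,3,3); all four bases are user-configurable for other dialects of the
search.

### Score

Each tetrad is scored by the Tm-balance statistic

K = 100 × ( |Tm_g5 − Tm_o3| + |Tm_o5 − Tm_g3| + |Tm_g5 − Tm_g3|
 + |(Tm_g5+Tm_g3)/2 − Tm_ov − 3| + |Tm_ov − T_fav| + |(Tm_g5+Tm_g3)/2 − T_fav| ),

kept at full floating precision for ranking and rounded to the nearest
integer for display. The last three terms satisfy
|m − v − 3| + |v − F| + |m − F| ≥ 3 by the triangle inequality
(m = end-primer mean, v = duplex Tm, F = favourite), so K ≥ 300 always;
the floor is attained only when the four primer Tms are equal and v lies in
the interval that zeroes the slack. Ties in K are broken by offset sum
i+j+k+l, then n5, then n3, then the individual offsets — an arbitrary but
fixed rule that makes ranking fully deterministic.

## Melting temperatures

Tm of every primer *and of the duplex region* is computed with the same
model: unified nearest-neighbor ΔH°/ΔS° sums (Allawi & SantaLucia
parameter table) with terminal initiation terms, the entropic salt
correction ΔS += 0.368 (N−1) ln[Na⁺], and the two-state Tm formula for a
non-self-complementary duplex. Defaults: 50 mM monovalent cation, 0 mM
Mg²⁺/dNTPs, 25 nM of each strand — the defaults of Biopython's `Tm_NN`,
which the implementation delegates to. `ThermoConditions` exposes the
table (four published sets), the salt-correction method (0–7), the
concentrations, and a Wallace-rule fallback (2 °C per A/T, 4 °C per G/C)
used only as a quick sanity estimate. Sequences shorter than 8 nt are
rejected (the NN model is unreliable there); with default part lengths the
shortest scored sequence is the 16-nt duplex.

### Calibration residual

Scoring the experimentally validated reference tetrad (dnaQ × dnaN fusion:
gene_5 `ATGAGCACTGCAATTACACGCCAGATCGTT`, overlap_3
`GCCGCGTCCATTTATGCTCGCCAGAG`, overlap_5 `GGCGAGCATAAATGGACGCGGCTACG`,
gene_3 `TCAGCCCGGCAACCGAACCGG`, 22-nt duplex) at the defaults gives
K = 584.8 → **585**; the score published for this tetrad is **583**. The
exact Tm parameterization behind the published value is not recoverable, and
no documented dialect combination (four NN tables × eight salt corrections ×
strand-concentration conventions) reproduces 583 exactly — the closest
alternative (SantaLucia–Hicks table) gives 584. The defaults are therefore
kept and the ~2-unit (0.3 %) residual is accepted and asserted as such in
the test suite; it has no effect on ranking order at this margin.

## In-silico verification

Annealing is modelled as exact 3′-anchored matching: a primer binds
wherever its 3′-terminal `min_anneal` (default 10) or more bases match a
template strand exactly; the maximal match is taken and the unmatched 5′
remainder becomes a tail that is incorporated into the product. Mismatch
tolerance, hairpins and dimers are out of scope. A primer with zero or
multiple sites fails the reaction — conservative on purpose, since multiple
priming would smear a real SOE-PCR; the failure lists the sites. Fusion is
modelled as the maximal exact suffix–prefix bridge of length ≥
`min_bridge` (default 10) between the two products, followed by fill-in:
`upstream + downstream[bridge:]`. Verification runs PCR1, PCR2, the fusion,
and optionally PCR3 with the end primers; it passes iff the reconstruction
equals fragment 1 + fragment 2 exactly, and reaction failures are reported
as structured entries rather than exceptions.

## Synthetic fixture generator

`fixtures.generate_pair` emulates the study conditions the designer is
meant for: two unique-sequence protein-coding-scale fragments. Defaults:
300 + 300 nt, GC fraction 0.5 (realized exactly — the G+C count is fixed
and positions shuffled), seeded `random.Random` stream, optional motif
planted across the junction. By default the generator additionally screens
candidates so that every decamer a candidate primer's 3′ terminus could
occupy (under the default search ranges) occurs exactly once across both
strands of the chimera, resampling from the same seeded stream otherwise
(~10–20 % of candidates are resampled at the defaults). This mirrors the
mechanistic assumption above — SOE-PCR is applied to templates with unique
priming sites — and makes the generator's pairs valid verification
templates by construction. What the generator does *not* emulate: codon
structure, GC skew along the sequence, repeats, or any real-gene homology;
passing tests therefore demonstrate algorithmic correctness on
unique-sequence templates, not primer performance on repetitive or
GC-pathological genes.

## Numerical and interface choices

* Tm values are stored at full precision and displayed to 1 decimal; GC %
  is rounded half-up to 1 decimal; K is displayed as the nearest integer.
* Reports are tab-separated with a header (name, sequence, length, GC, Tm,
  Overlap_Tm, K), four rows per tetrad in the order gene_5, overlap_3,
  overlap_5, gene_3, duplex Tm and K on the first row of each block. All
  combinations are written unless `--top N` truncates. Identical inputs and
  configuration yield byte-identical files.
* Multi-record FASTA inputs use the first record with a warning; ambiguity
  codes are rejected with a 1-based position; fragments must be ≥ 45 nt
  (a 30-nt end primer plus a 15-nt junction part must fit without
  ambiguity), with a warning below 200 nt.
* Test problem sizes: the full 73,984-tetrad default space is enumerated
  and checked exhaustively (floor, recomputability, sub-counts); bulk
  round-trip verification uses the rank-1 tetrad of 100 seeded 300 + 300 nt
  pairs, and the all-tetrad verification property uses a reduced
  64-combination space on five pairs — scaled-down but structurally
  identical sweeps of the same code paths.

## Known limitations

* No mispriming screen against the *interior* of real templates beyond the
  exact-match site census, and no hairpin/homodimer ΔG screening.
* Only two-fragment junctions; multi-fragment assembly and codon-aware
  junction placement are out of scope.
* The Tm model assumes perfect-complement duplexes; degenerate bases are
  rejected rather than expanded.
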