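# Methods

## Data model

A genotype table is a markers × samples matrix of diploid calls. A call is
an ordered pair of allele states (hap1, hap2), each one of {A, B, missing},
plus a phased flag; A is the reference/parent-1 allele, B the
alternate/parent-2 allele. Missingness is all-or-nothing per call: the
three missing tokens (`N`, `.|.`, `./.`) carry no partial information, so a
half-missing call is unrepresentable by construction.

Three encoding dialects cover the common file conventions:

- **simple** — `A`, `B`, `H`, missing `N`; no phase information.
- **phased** — `0|0`, `1|1`, `1|0`, `0|1`, missing `.|.`; haplotype order
  is preserved end to end.
- **unphased** — `0/0`, `1/1`, `1/0`, `0/1`, missing `./.`; heterozygote
  order is canonicalised to (A, B).

A table uses exactly one dialect; mixing dialects is an error rather than
an auto-coercion, because silent coercion hides upstream data problems.
Dialect detection is a set-cover check (the three token sets are pairwise
disjoint, so any non-empty token collection identifies at most one
dialect); undetectable input produces an error that points at the explicit
override. Unphased heterozygote order carries no information, so `1/0` and
`0/1` both parse to the canonical (A, B) and serialise back as `0/1`; this
is the only place round-tripping is not the literal identity. Polyploid
(≥3 allele fields) and multi-allelic (allele index ≥2) calls are rejected
everywhere with specific messages.

Marker positions are 1-based bp (the VCF convention). All layout
arithmetic happens in 0-based half-open intervals, which makes segment
lengths sum exactly to the chromosome length with no ±1 bookkeeping.

The CSV reader accepts either 3 leading metadata columns
(chromosome, marker, physical position) or 4 (chromosome, marker, genetic
position in cM, physical position), auto-detected by whether the 4th header
name is a position-like word (`position`, `pos`, `bp`, …) and overridable
with `meta_columns=`. The genetic position is carried on the marker but
never used for layout; layout is strictly physical-bp. This tolerant
two-schema reader is a deliberate design choice: both layouts occur in
circulating marker tables.

## Fill semantics

With fill on, each haplotype track of a chromosome of length L with
markers at p₁ < … < pₙ is a partition of [0, L):

- [0, p₁) and [pₙ, L) take the terminal markers' roles (chromosome ends are
  painted, matching how fully-colored ideograms are read);
- [pᵢ, pᵢ₊₁) takes a single uniform gap role: the shared role when the
  neighbouring roles agree (equal-genotype runs therefore merge into solid
  blocks), the missing role when either neighbour is missing, and otherwise
  a blend of the two roles.

A blend resolves to the per-channel arithmetic mean of the two resolved
RGB colors, rounded to nearest with ties up ((a+b+1)//2 on each channel),
which is commutative and idempotent. An alternative gap rule — splitting
the gap at the midpoint and painting each half in the nearer marker's solid
color — was considered; the uniform blend was chosen as the default because
it visually encodes "uncertain between these two states" rather than
asserting a breakpoint location the data does not support. The rule is
isolated in one function (`blend_role`) so the midpoint variant is a
five-line swap. The missing-neighbour rule (gap → missing) follows the
same logic: an interval bounded by an uncalled marker is unknown, and
unknown intervals should not inherit a parental color.

With fill off, one line segment of width max(1, round(L/1000)) bp
(overridable via `RenderConfig.marker_line_bp`) is drawn centred on each
marker, clamped inside [0, L]. The width default keeps lines ~1 pixel
visible at genome scale. A non-fatal advisory is logged when a filled
chromosome holds more than 100 markers, the density above which blended
gaps stop being readable; the threshold is strict (100 markers: no
advisory, 101: advisory).

A chromosome with zero markers is painted full-length in the missing color
rather than omitted, so multi-panel alignment never shifts. In figure
planning this case is handled at the track level; the planner itself draws
the chromosomes present in the table, ordered by the species database
entry (insertion order, not lexicographic, so Chr2 precedes Chr10).

## Drawing modes

- **normal** — one figure per sample; panels are that sample's chromosomes
  in database order, heights proportional to bp on a shared scale.
- **compare** — one figure; one panel per chromosome containing every
  sample's copy side by side.
- **zoomed** — one figure over a required (chromosome, start, end) window;
  defined by construction as interval-clipping the full-chromosome plans,
  so zoom output is consistent with the genome-wide view by definition
  (and tested across the two code paths).

Clipping intersects every segment with the half-open window and drops
marker ticks outside it; a window containing no marker still renders (as
the enclosing gap color) with a logged warning, since pure clipping has a
well-defined answer there.

## Rendering

Layout is completely backend-free; only `render_export` imports
matplotlib (Agg). Each paint segment becomes an axis-aligned rectangle
drawn with antialiasing off and zero line width, so rasterized fills carry
exactly the resolved RGB of their role — the pixel-probe tests rely on
this. Output naming: normal mode writes `<stem>_<sample>.png`,
compare/zoomed write `<stem>.png`; PNG (default 300 dpi) is always
produced and PDF is additive. Marker-name labels are drawn next to tick
marks; above 50 labels per chromosome only every k-th is drawn (k chosen
to land at ≤50) with a logged notice. Exact figure geometry (margins,
rectangle aspect) is treated as free visual parameters with defaults tuned
for legibility, since it carries no data semantics.

`render_track_png` renders a single track margin-free onto an exact pixel
grid (bp mapped linearly to image width). It is the pixel-fidelity
surface: probing the centre pixel of any segment recovers that segment's
resolved color exactly, which the test suite and the acceptance script use
to verify the full layout → color-resolution → rasterization chain.

## File formats and databases

VCF reading goes through cyvcf2 (GT subfield only; FILTER/QUAL/INFO are
ignored — variant filtering is a pre-processing concern for bcftools or
VCFtools). Conversion keeps only biallelic diploid records, counting drops
by cause in a report whose categories provably partition the record total.
A VCF mixing `|` and `/` genotype separators is rejected outright with a
pointer to re-harmonise phasing, instead of silently downgrading everything
to unphased. Marker names come from the VCF ID column, with
`<chrom>_<pos>` generated when the ID is `.` or when `--add_marker_names`
is passed.

FASTA scanning uses Bio.SeqIO: record name = header token up to the first
whitespace, length = sequence characters only. The shipped
chromosome-length database holds eight crop/model species (rice, sorghum,
maize, wheat, barley, soybean, tomato, arabidopsis) with lengths taken
once from public reference assemblies; because assembly versions drift by
a few kb, tests pin the species count and per-species chromosome counts
rather than exact bp. Databases and color sets are insertion-ordered JSON
(`{species: {chrom: bp}}` and
`{set: {"A"|"B"|"het"|"missing": "#RRGGBB"}}`); the shipped color registry
includes `normal`, `Aqua` and a grayscale `mono`. The `draw` subcommand
deliberately exposes only the documented option set and therefore always
reads the packaged databases; custom database paths are a library-level
feature (`load_chrom_length_db(path)`), and `add-species` persists to a
user-chosen JSON file.

## Synthetic data generator

`simulate_table` emulates the marker table of a biparental population.
Per sample and chromosome, each haplotype is a mosaic of alternating
parental blocks: the number of breakpoints is Poisson(crossover_rate)
(default 2.0 crossovers per chromosome per gamete, a typical per-bivalent
count for plant chromosomes), breakpoint positions are uniform, and the
starting allele is a fair coin. `het_fraction` (default 0.5) is the
probability that the second haplotype is simulated independently of the
first; otherwise it is a copy, giving a fully homozygous chromosome — a
coarse dial between inbred-like and F1-like material. Missing calls are
injected independently per cell at `missing_rate` (default 0.02). Markers
sit on an evenly spaced grid by default (mirroring clean array-style
panels), with uniform-random placement behind a flag. One integer seed
drives all randomness through a single `numpy` generator, so identical
parameters always reproduce the identical table.

What the generator does **not** emulate: crossover interference, centromere
suppression of recombination, genotyping-error miscalls (as opposed to
missingness), segregation distortion, linked marker ascertainment, and
cM-scale maps. Tests passing on this generator therefore demonstrate the
correctness of parsing, layout and rendering logic — not robustness to
every artefact of real genotyping pipelines, whose errors arrive as valid
tokens and are invisible to a visualizer by design.

The companion VCF writer emits minimal VCF v4.2 (fileformat, one FORMAT=GT
line, contig lines, `#CHROM` header; REF=A/ALT=T placeholders) so the
conversion path can be exercised round-trip without external files. The
simple dialect has no VCF genotype encoding and is rejected.

## Problem sizes and determinism

Test and acceptance runs use 2-chromosome toy genomes (0.7–1 Mb), 1–17
markers per chromosome, up to 200 randomized tables per invariant, 500
haplotypes for the crossover-rate calibration (checked within 3 standard
errors of the Poisson mean), and 50–60 dpi renders — sizes chosen so the
whole pipeline, including raster probes, runs in seconds while still
exercising every branch (both coloring modes, both fill settings, all
three drawing modes, all three dialects). Layout contains no randomness at
all: identical table + configuration yields bit-identical paint plans.

## Known limitations

- One dialect per table; no haploid, polyploid or multi-allelic calls.
- Physical-bp layout only (no cM scaling), no per-marker quality shading,
  no recombination-count annotation.
- VCF input only as plain or gzipped streams; no BCF, no VCF writing
  beyond the minimal synthetic writer.
- The compare-mode figure grows linearly in samples × chromosomes; very
  large panels produce wide figures rather than paginating.
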