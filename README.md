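# genopaint

Graphical genotypes from variant-calling data: chromosome-scale paintings
that show, along each chromosome of each sample, which parental allele every
marker carries — as two narrow haplotype tracks of colored blocks.

Graphical genotypes are the workhorse display of plant and animal breeding
and genetic mapping: in a biparental or introgression population they make
recombination blocks, donor segments and heterozygous regions visible at a
glance. `genopaint` takes a CSV marker table (or a VCF, via the built-in
converter), lays out every sample × chromosome as two haplotype tracks of
colored genomic segments, and renders genome-wide, cross-sample-comparison,
or zoomed region figures as PNG/PDF.

## The model

A diploid genotype call at marker *m* in sample *s* is an ordered pair of
allele states (*h₁*, *h₂*) with *hᵢ* ∈ {A, B, missing}, where A is the
reference/parent-1 allele and B the alternate/parent-2 allele. Three cell
encodings are accepted: `A/B/H/N` (simple), `0|0`-style (phased — haplotype
order is meaningful and preserved) and `0/0`-style (unphased — heterozygote
order is canonicalised). Polyploid (`0/0/0/1`) and multi-allelic (`0/2`)
calls are unsupported and rejected.

Layout works in 0-based half-open bp intervals. With **fill on**, a track
with markers at positions *p₁ < … < pₙ* on a chromosome of length *L* is
painted

- [0, *p₁*) and [*pₙ*, *L*) in the terminal markers' colors,
- [*pᵢ*, *pᵢ₊₁*) in a single uniform color: the two neighbours' shared color
  when their genotypes agree (so identical runs merge into solid blocks),
  otherwise the per-channel arithmetic mean of the two colors
  (ties round up: blend(#FF0000, #0000FF) = #800080),

so segment lengths always sum exactly to *L*. With **fill off**, only a
narrow line (default width max(1, L/1000) bp) is drawn at each marker. In
**2-color** mode each track carries its own haplotype's color, so phased
heterozygotes show which haplotype holds which allele; **3-color** mode
paints heterozygous calls in a dedicated third color on both tracks.

A chromosome-length database ships with entries for eight crop and model
species (rice, sorghum, maize, wheat, barley, soybean, tomato,
arabidopsis); new species are added by scanning a genome FASTA.

## Worked example

```python
from genopaint import (SimulationParams, simulate_table, ChromLengthDB,
                       RenderConfig, plan_figures, render)

table = simulate_table(SimulationParams(
    n_samples=3, chrom_lengths={"chrT1": 1_000_000, "chrT2": 700_000},
    markers_per_chrom=8, crossover_rate=2.0, seed=11))
db = ChromLengthDB(entries={"toy": {"chrT1": 1_000_000, "chrT2": 700_000}})
cfg = RenderConfig(species="toy", drawing_mode="compare")
plan = plan_figures(table, db, cfg)[0]
print(len(plan.panels), [p.label for p in plan.panels])
paint = plan.panels[0].entries[0][1]
print(paint.track1[:2])
print(sum(s.end - s.start for s in paint.track1))
render(plan, cfg, "compare_figure")
```

prints

```
2 ['chrT1', 'chrT2']
[PaintSegment(start=0, end=1000000, role=B)]
1000000
```

— two chromosome panels; sample S1's haplotype-1 track on chrT1 happens to
carry the parent-B allele at every marker under this seed, so its segments
merge into one solid parent-B block spanning the whole chromosome; and the
segment lengths sum exactly to the 1 Mb chromosome length. `render` writes
`compare_figure.png` with all three samples aligned per chromosome.

The same pipeline from the shell:

```sh
genopaint convert input.vcf table.csv --add_marker_names
genopaint draw -i table.csv -s rice --drawing_mode compare --coloring_mode 3-color
genopaint add-species --fasta genome.fa --database my_db.json --name my_species
```

`convert` prints a record-accounting report
(`records: N  kept: K  dropped multi-allelic: …`) whose categories always
sum to the record total; `draw` accepts the full option set
(`--fill on|off`, `--color_set`, `--display_marker_names`, `--chr/--start/
--end` for zoomed mode, `--dpi`, `--pdf on|off`).

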