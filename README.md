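# amplistruct

Inference of high-order gene-amplification structures from short-read
sequencing signal, on fully synthetic data.

When an unfit yeast population is forced through serial transfers, the
winning mutants often carry massive amplifications of the limiting gene:
a 30–211-kb chromosomal unit present at 3–22 copies above the diploid
baseline. The same coverage plateau on a depth plot can hide completely
different molecular architectures — a head-to-tail (direct) tandem array
that stretches one homologue into a "macrotene" chromosome, an inverted
array whose copies alternate orientation around quasi-palindromic
junctions, a circular centromeric episome, a simple segmental duplication
between dispersed repeats, or a whole-chromosome aneuploidy. Telling
these apart from short reads is the problem this package solves, end to
end, on genomes it simulates itself:

1. **synthetic genomes** — toy diploid chromosomes with planted
   centromeres, genes, LTR/transposon repeat families at controlled
   sequence identity, heterozygous variants, and any of the five
   amplification classes with exact junction geometry (microhomology of
   0–42 nt, or palindromic arms around a unique center), plus uniform
   shotgun reads and a JSON truth bundle;
2. **read-depth copy number** — its own seed-and-extend mapper, depth
   collapsed over homologues, normalization of the genome-wide mean to 2
   (diploid), 1,500/5,000-nt sliding-window smoothing, and integer-level
   segmentation with median re-centering, so a segment's level *L* reads
   off directly as *E* = *L* − 2 extra copies;
3. **junction discovery** — unmapped and clipped reads are assembled into
   contigs over a k = 17 de Bruijn graph, split-aligned back to the
   reference by exact prefix/suffix anchoring, and scored for
   microhomology (the breakpoint-ambiguity window) and quasi-palindromic
   geometry (arm + unique center + reverse-complement arm);
4. **structure classification** — segments + junctions + annotation are
   combined under the centromere rule (a centromere-containing unit
   cannot be tandemly repeated in a chromosome; it must be episomal) into
   a final structure call with a predicted karyotype size
   (base + *E* × unit), checked against pulsed-field-gel style band
   observations;
5. **population arithmetic** — serial-transfer bookkeeping
   (*n* = log₂(2000·*d*/*Ni*) generations per culture), the selection
   model in which a growth advantage *s* multiplies a mutant's frequency
   ratio by 2^(*s·n*) per transfer (12.5% doubles it over ~8
   generations), the invasion threshold 1/*Ni*, and the geometric
   stability model *p* = 1 − *C*^(1/*G*) for per-generation loss rates;
6. **gene dosage** — MA-plot transforms (M = log₂ case/control) and
   amplicon-set overexpression summaries for dosage-proportional
   expression simulations.

## Worked example

Simulate a 600-kb diploid chromosome carrying a 30-kb centromere-free
unit amplified as a direct tandem array with 12 extra copies, sequence it
at 30× with 100-nt reads and error 10⁻³, and run the full pipeline:

```python
from amplistruct.pipeline import PipelineConfig, run_end_to_end
from amplistruct.scenarios import viii_b_macrotene
from amplistruct.io import segments_to_frame, structures_to_frame

ref, specs = viii_b_macrotene(1)
res = run_end_to_end(PipelineConfig(reference=ref, amplicons=specs, seed=1))
print(segments_to_frame(res.segments).to_string(index=False))
print(structures_to_frame(res.structures).to_string(index=False))
```

```
  chrom  start    end  level  extra  mean_cn
chrVIII      0 300000      2      0   1.9970
chrVIII 300000 329994     14     12  13.9385
chrVIII 329994 600000      2      0   2.0069

        class   chrom  unit_start  unit_end  effective_unit_nt  extra_copies  centromere_in_unit predicted_kb  junctions
direct_tandem chrVIII      300000    329994              29994            12               False        959.9 contig0001
```

The segmentation reads the amplicon off the coverage plateau: one 30-kb
segment at integer level 14, i.e. 12 copies in excess of the diploid
baseline, with boundaries within a smoothing window of the truth
(300,000–330,000). One junction contig split-aligns as a direct join
from the unit's right end (329,999) back to its left start (300,000)
with a 1-nt ambiguity window, so the event is classified as a direct
tandem (macrotene) array, and the predicted homologue size is
600 kb + 12 × 30 kb ≈ 960 kb — the band a pulsed-field gel would show.

The same entry points drive the other scenarios (`viii_a_episome`,
`iv_b_inverted`, `iv_c_episome`, and the scaled-down five-class suite in
`amplistruct.scenarios`), and a thin CLI wraps each stage:

```sh
amplistruct simulate --config cfg.yaml --seed 1 --outdir sim/
amplistruct depth --reads sim/reads.fq --ref sim/reference.fa --outdir cov/
amplistruct junctions --reads sim/reads.fq --ref sim/reference.fa --outdir jx/
amplistruct popdyn lossrate -C 0.5 -G 145
```

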