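# marspace

Downstream analysis toolkit for studies of protein association with
scaffold/matrix attachment regions (S/MARs) — AT-rich chromatin-loop anchor
sites bound by organizers such as SATB1. It reimplements, as a tested and
reusable library, the bespoke computations such studies chain together
downstream of peak calling and image segmentation:

* **Peak post-processing** — BED/narrowPeak loading, input-sample
  subtraction, peak length statistics, promoter/exon/intron/intergenic
  annotation against gene models, and overlap/proximity counts between
  conditions (half-open coordinates throughout).
* **S/MAR motif scanning** — degenerate repeat-quantified patterns such as
  the SATB1 site `(A/T)₃₋₆C(A/T)₃₋ₙ` and the G-quadruplex
  `G₃₊N₁₋₂₀G₃₊N₁₋₂₀G₃₊N₁₋₂₀G₃₊`, scanned with leftmost greedy
  non-overlapping semantics on both strands, and the inverse-length-weighted
  statistic `wᵢ = 100·mᵢ/Lᵢ` (motifs per 100 nt of peak).
* **Genomic spacing periodicity** — successive inter-peak distances per
  chromosome, type-7 quantiles, and a Gaussian KDE on [0, 4 Mb] (bandwidth
  0.5 × Silverman) whose null-referenced modes indicate regular spacing.
* **Super-resolution localization analysis** — nearest-neighbour
  co-localization at ⅔ of the labelled protein size (40 nm for 60-nm
  proteins), pixel-level co-localization, a from-scratch OPTICS clustering
  with reachability-cut extraction, and FFT detection of regular
  inter-cluster spacing.
* **qPCR quantification** — ΔΔCt(ChIP−IgG) fold enrichment
  (`fold = 2^(−ΔΔCt)`) and GAPDH-normalized RT-qPCR relative expression.
* **Synthetic data** — seeded generators for every input (peaks, genomes
  with planted motifs, localization fields, Ct tables, gene models) with
  ground-truth sidecars, so the whole pipeline is testable without any
  external download.

Intended users: computational biologists post-processing ChIP-seq peak sets
and single-molecule localization data who need these small, usually ad-hoc
steps to be reproducible and verifiable. See `docs/methods.md` for the
statistical conventions and their rationale.

## Worked example

Simulate a peak set with a planted 125-kb spacing period, then measure its
spacing profile:

```python
import marspace as m
from marspace.spacing import interpeak_distances, spacing_kde, spacing_quantile

ps, truth = m.simulate_peakset(
    500, {"chr1": 80_000_000}, spacing_mode="periodic",
    period=125_000, jitter_sd=5_000, seed=42,
)
mean, sem, n = m.peak_length_stats(ps)
d = interpeak_distances(ps)
profile = spacing_kde(d)
print(f"peaks: {n}, mean length {mean:.1f} +/- {sem:.1f} nt")
print(f"75% of successive peaks closer than {spacing_quantile(d, 0.75)/1e3:.1f} kb")
print("modes:", [round(pos / 1e3, 1) for pos, _, _ in profile.modes])
```

prints

```
peaks: 500, mean length 169.5 +/- 1.7 nt
75% of successive peaks closer than 127.9 kb
modes: [125.2]
```

— the generator planted peaks every 125 ± 5 kb with ~170-nt lengths, and the
density of inter-peak distances shows a single qualifying mode at 125.2 kb
(positions are quantized to the ~7.8-kb evaluation grid), i.e. regular
genomic spacing was detected at the planted period. A `poisson` spacing mode
yields no qualifying mode instead.

ChIP-qPCR enrichment from a replicate Ct table:

```python
table, _ = m.simulate_ct_table(9.8, noise_sd=0.1, n_replicates=3, seed=7)
result = m.chip_fold_enrichment(table)
print(f"ddct {result.ddct:.3f} -> fold {result.fold_change:.2f}")
# ddct -3.185 -> fold 9.09
```

with fold = 2^(−ΔΔCt); the noiseless table recovers the planted 9.8-fold
exactly.

The same stages are scriptable from the shell, e.g.:

```sh
marspace simulate peaks --n-peaks 500 --mode periodic --seed 42 --out peaks.bed
marspace spacing --peaks peaks.bed --upper-bound 4000000 --smoothing 0.5
marspace smlm coloc --a ch1.csv --b ch2.csv --protein-size 60
marspace qpcr chip --table ct.tsv
marspace run chipseq --config run.toml --out report.json
```

All commands emit JSON reports; pipeline reports embed the exact
configuration used and are byte-stable for a fixed configuration and seed.

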