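# repliphase

Quantification toolkit for the cell-biological and biochemical readouts of
DNA-replication-initiator phase separation: recruitment of fluorescently
tagged initiation factors (ORC/Orc1, Cdc6, Cdt1) to mitotic chromosomes in
4D live-imaging movies, partitioning of proteins into DNA-driven
liquid–liquid phase-separated (LLPS) condensates, sequence analytics of the
intrinsically disordered regions (IDRs) that drive condensation, and the
binding-curve fits used to calibrate those assays.

It is aimed at labs doing live imaging of chromatin-associated factors and
in-vitro condensate biochemistry who want the bespoke quantifications of
such studies as a tested, reusable library rather than a one-off script.

## What it computes

**Chromosome recruitment (volumetric movies).** From a two-channel
time-lapse stack (histone channel + GFP-tagged factor), the pipeline
segments chromatin per frame (3D median → Gaussian filter → locally
adaptive threshold → border/size cleanup → 26-connected labels), links
nuclei across frames by gated Hungarian assignment on centroids, and
converts each track into a background-normalized fold-enrichment series

F(t) = mean in-mask intensity / median intensity outside the dilated union mask.

Traces are aligned on the smoothed GFP peak (which coincides with early
telophase) and summarized as the cohort mean ± SD of per-track maximum
fold enrichment — the headline "n-fold chromosomal enrichment" statistic.

**Chromosome recruitment (single-cell projection movies).** The confocal
variant: sum-project each z-stack, blur (radius 1 px), subtract the average
background, auto-threshold the histone channel into a per-frame ROI, and
report R(t) = GFP ROI mean at t / GFP ROI mean at the metaphase reference
frame, with the cohort mean ± SD of per-cell maxima.

**Condensate quantitation.** Droplet ROIs by auto-threshold of the DNA
channel; partition ratio E = mean(partner inside) / mean(partner outside a
2-px guard band); depletion fraction D = 1 − supernatant/load and pellet
enrichment from gel band intensities; and (protein, salt) phase diagrams
from droplet counts.

**IDR sequence analytics.** Longest disorder run (score > 0.5) from
per-residue disorder predictions; amino-acid class composition
(aromatic F/W/Y, hydrophobic A/G/I/L/M/P/V, hydrophilic C/N/Q/S/T, charged
D/E/H/K/R); isoelectric point by bisection of a Henderson–Hasselbalch net
charge model; fraction of charged residues FCR = (nD+nE+nK+nR)/L;
Wootton–Federhen compositional complexity K = log(L!/Πnᵢ!)/(L·log 20) in a
20-residue sliding window; CDK consensus scanning ([S/T]P minimal,
[S/T]PX[K/R] full); oligo GC content.

**Binding fits.** Hill fits A(c) = A0 + (Amax−A0)·cⁿ/(Kdⁿ+cⁿ) with
multi-start initialization, four-parameter-logistic competition fits
(IC50 reported as the apparent inhibition constant, Cheng–Prusoff
correction optional), and linear standard curves with inverse prediction.

Every pipeline is validated end-to-end against the package's own
synthetic-data generators (`repliphase.simulate`), which render mitosis
movies, droplet fields, titrations and sequences with known ground truth.

## Worked example

Recover a known chromosomal enrichment factor from a synthetic embryo-style
movie:

```python
from repliphase.simulate import embryo_movie_config, simulate_mitosis_movie
from repliphase.traces import EMBRYO_ANALYSIS, quantify_movie

stack, truth = simulate_mitosis_movie(embryo_movie_config(f_late=2.5, seed=11))
traces, summary = quantify_movie(stack, **EMBRYO_ANALYSIS)
print(f"{summary.max_mean:.3f} +/- {summary.max_sd:.3f} "
      f"(n = {len(summary.max_per_track)})")
```

This prints

```
2.452 +/- 0.006 (n = 20)
```

— the cohort mean ± SD of the per-track maximum fold enrichment over the
20 tracked chromatin masses (10 nuclei, two daughters each), recovering
the configured late-telophase enrichment factor of 2.5 to within 2% under
Poisson + Gaussian camera noise. The same movie analyzed with a uniform
GFP channel (`f_late=1.0`) returns 1.01, the no-enrichment null.

The CLI exposes the same stages:

```sh
repliphase simulate movie --seed 1 --n-nuclei 10 --out scratch/movie
repliphase quantify volumetric --in scratch/movie/movie.ome.tif --max-disp 4 --out scratch/out
repliphase idr cdkscan --fasta seqs.fa --region 187:548
repliphase fit hill --in curve.csv
```

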