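# sarcoquant

Quantitative readouts of skeletal-myotube maturation in vitro, for
muscle-biology groups comparing culture substrates (e.g. micropatterned
gelatin hydrogels versus unpatterned gels or plastic/glass) with C2C12 or
primary myotubes. The package implements three measurement families plus a
seeded synthetic-data generator with planted ground truth, so every
estimator can be validated end to end without downloading any dataset.

## What it computes

**Gene-set LFC shift statistics.** Given a per-gene table of log2 fold
changes (LFC) between two conditions and a gene set *S*, the shift statistic
is a difference of medians:

    shift(S) = median{ LFC_g : g in S } - median{ LFC_g : g in background }

with the background either all table genes (default) or the complement of
*S*. Applied to the 198-gene "sarcomere" GO category this is the sarcomere
log fold change (sLFC); applied to genes upregulated in vivo during the
embryonic-to-postnatal (E18 to P2) transition it is the in vivo log fold
change (vLFC). Significance of the distribution shift comes from a
two-sided Wilcoxon rank-sum test of set versus complement (exact
enumeration for small samples, tie- and continuity-corrected normal
approximation otherwise). Helpers derive the in vivo up/down sets from a
developmental differential-expression table (q < 0.05, sign of LFC), filter
sets to genes expressed in a TPM matrix, build ECDFs for cumulative-
distribution plots, and place a single shift value within a group of shift
values via a Z-score with a two-sided normal p-value.

**Sarcomere morphometry.** Fluorescently labelled Z-lines make a myotube's
intensity line profile near-periodic with period equal to the sarcomere
length. The estimator mean-subtracts the profile, zero-pads to >= 4x
length, and searches the FFT magnitude spectrum for a peak at periods
inside the physiological 1.6-3.4 um window, refining the peak frequency by
parabolic interpolation (sub-bin resolution; a noiseless 2.4 um profile is
recovered to < 1e-4 um). Striation counting reports the longest run of
consecutive intensity peaks with consistent spacing and scores the
">= 15 sarcomeres in series" criterion; group comparisons use one-way ANOVA
with Tukey HSD.

**Gel densitometry.** Lane intensity profiles from SDS-PAGE are
baseline-corrected by a recentred morphological opening, band windows for
myosin heavy chain (~220 kDa) and actin (~42 kDa) are located via a
log-linear molecular-weight ladder calibration, and integrated band amounts
are normalised to total lane protein and combined into MyHC/actin ratios.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (all inputs are generated by `analysis/01_simulate_inputs.py`; outputs
land under `results/`):

```bash
python analysis/01_simulate_inputs.py      # LFC tables, DE table, TPM, profiles, lanes
python analysis/02_sarcomere_period.py     # FFT periods, series counts, ANOVA/Tukey
python analysis/03_contractile_protein.py  # ladder calibration, band ratios
python analysis/04_geneset_shift.py        # sLFC/vLFC panel, ECDFs, Z-score
```

`02_sarcomere_period.py` prints, for profiles planted at 2.40 / 2.30 /
2.20 um with increasing noise:

```
per-substrate sarcomere readouts:
         glass: mean period 2.200 um, sarcomeric fraction 0.00 (n=8)
     patterned: mean period 2.400 um, sarcomeric fraction 1.00 (n=8)
   unpatterned: mean period 2.300 um, sarcomeric fraction 0.12 (n=8)
ANOVA across substrates: F = 26173.05, p = 2.15e-36
```

so the patterned group sits at the in vivo length-tension plateau (~2.4 um)
and is the only group whose profiles routinely pass the >= 15-striations
criterion. `04_geneset_shift.py` prints the shift panel, e.g.

```
batch1_day7_patterned_vs_unpatterned sLFC = +0.093 (Wilcoxon p = 1.07e-06, n_set = 198)
batch1_day7_patterned_vs_unpatterned vLFC = +0.285 (Wilcoxon p = 5.82e-18, n_set = 87)
...
primary-like vLFC 1.4 vs C2C12 group (mean 0.277, sd 0.087, n=4): z = 12.84, p = 9.33e-38
```

recovering the planted day-7 sarcomere-set shift of 0.1 log2 units and
flagging the primary-myotube-like sample as a strong outlier against the
C2C12 group. The same stages can be driven from one YAML config via the
CLI (`sarcoquant run --config cfg.yaml --out outdir`), which also writes a
run manifest and a markdown report.

## Layout

- `src/sarcoquant/` — the library: `geneset`, `morphometry`, `densitometry`,
  `synthetic`, `io`, `pipeline`, `report`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite (unit, property-based, and end-to-end checks).
- `docs/methods.md` — models, parameter choices, numerical details,
  limitations.
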