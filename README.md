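# spherulescope

Quantitative analysis of viral RNA replication "spherules" — the ~50 nm
membrane invaginations that positive-strand RNA viruses such as Flock house
virus (FHV) induce on outer mitochondrial membranes — as imaged by
cryo-electron tomography, rebuilt as a tested, reusable pipeline that runs
entirely on synthetic phantoms. It is intended for researchers who want to
prototype or validate subtomogram-averaging and spherule-morphometry
analyses without microscope data.

The package implements four analyses and the ground-truth generator that
feeds them:

* **Phantoms** — crowns (a 19 nm cupped "turret" with an 11 nm open channel,
  ringed by twelve "teeth" on a 35 nm circle), spherule vesicles (30–70 nm
  diameter) filled with a confined worm-like-chain dsRNA coil at 6.4 nm
  center-to-center spacing, and tomograms corrupted by a ±60° missing wedge
  and Gaussian noise at a chosen SNR.
* **Subtomogram averaging** — membrane-normal initial orientations, iterative
  cone-search alignment (60° cone narrowing to 5°, ≤12 iterations,
  wedge-masked normalized cross-correlation, bounded shifts), independent
  A/B half-set refinement, coverage-weighted averaging. No symmetry is ever
  imposed.
* **FSC** — Fourier shell correlation between half maps with 1-voxel shells,
  soft-mask logging, and resolution at the 0.5 and 0.143 crossings:
  FSC(f) = Re Σ F_A F̄_B / √(Σ|F_A|² Σ|F_B|²) per shell.
* **Symmetry** — angular intensity profiles on the teeth ring, per-particle
  rotational power spectra averaged across particles, and a prominence-based
  detector for cyclic order C_k (k = argmax of mean power over components
  2–24, preferring the fundamental over harmonics).
* **Morphometry & packing** — widest-circumference radii with V = (4/3)πr³,
  nearest-neighbor inter-filament spacing with same-strand arc exclusion,
  BIC-selected Gaussian-mixture size classes, and the parallel-cylinder
  dsRNA packing model: density ∝ 1/spacing², calibrated at
  24.7 kbp / 74,000 nm³ (334 bp/1000 nm³ at 2.7 nm spacing) and transferred
  to 6.4 nm spacing (~58 bp/1000 nm³).

See `docs/methods.md` for the model assumptions, parameter defaults and
limitations.

## Worked example

The packing chain, from its calibration inputs to per-template occupied
volumes:

```
$ spherulescope packing
reference density: 334 bp/1000 nm^3; fold: 5.80 (from spacing: 5.62); derived density: 58 bp/1000 nm^3
template  length_kbp  occupied_volume_nm3  occupied_volume_display_nm3
    RNA1         3.1         53448.275862                        53000
    RNA2         1.4         24137.931034                        24000
    RNA3         0.4          6896.551724                         7000
```

Reading: a reference dsRNA virus core packs 334 bp per 1000 nm³ at 2.7 nm
filament spacing; at the 6.4 nm spacing measured in spherules the density is
~5.8-fold lower (~58 bp/1000 nm³ — the spacing-derived fold 5.62 is printed
alongside because the two do not exactly agree), so the three replication
templates of 3.1 / 1.4 / 0.4 kbp occupy ~53,000 / ~24,000 / ~7,000 nm³ of
spherule interior respectively.

Generate a clean crown phantom and detect its symmetry:

```
$ spherulescope phantom crown --out c12.mrc
wrote crown (C12) to c12.mrc
$ spherulescope symmetry --map c12.mrc --out spectrum.tsv
symmetry: C12 (prominence 1000.0)
```

The full seeded demonstration — generate 100 noisy wedge-corrupted crowns,
align, compute FSC and symmetry, measure a spherule, fit size classes, and
emit the packing table with every intermediate artifact:

```sh
spherulescope demo --seed 7 --out demo_run/
```

The JSON report ends with `"symmetry": {"order": 12, ...}` and an FSC block
whose 0.143 crossing lands between the 2 nm voxel Nyquist limit and 10 nm;
the mixture block recovers component means near 12,000 and 108,000 nm³ from
541 draws.

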