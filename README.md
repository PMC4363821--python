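# paracellkit

Analysis toolkit for paracellular barrier physiology and tight-junction
(TJ) image quantification in cultured epithelial monolayers (MDCK-style
Transwell experiments).

Epithelial sheets separate compartments, and the tight junction sets how
leaky the space *between* cells is. Claudin family proteins form the
paracellular pores; knocking one out (e.g. claudin-2, the major cation
pore of leaky MDCK II epithelia) changes transepithelial resistance,
charge selectivity, and how TJ proteins localise at junctions between
cells of different genotype. This package implements the complete
computational chain such a study needs, from raw meter readings and
micrographs to the final statistics:

* **barrier_assays** — transepithelial electrical resistance
  (TER = (R_raw − R_blank)·A), the Goldman–Hodgkin–Katz (GHK) dilution
  potential model and its closed-form inverse
  (η = P_Na/P_Cl from a measured NaCl dilution potential), the
  Kimizuka–Koketsu conversion of TER and η into absolute permeabilities
  (P_Na + P_Cl = RT/(F²·C·TER)), and single-timepoint tracer flux
  (P = (dQ/dt)/(A·C₀) with a linear standard curve).
* **junction_quant** — 0.5-µm ribbon ROIs traced along the TJ-marker
  channel, per-side genotype classification (control/control,
  knockout/knockout, boundary), and the two relative-intensity
  statistics D_KO/D_CTL and (D_Boundary − D_KO)/(D_CTL − D_KO).
* **genotyping** — classification of nuclease-induced knockout alleles
  against a reference ORF (start-codon loss, frameshift vs in-frame
  indels), prediction of the alternative in-frame start codon and the
  average molecular mass of the truncated product.
* **stats** — mean ± SEM, Bartlett's variance gate, Bonferroni-corrected
  pairwise t tests against a reference group.
* **synthetic_data** — seeded generators for every input: Voronoi mosaic
  monolayers with genotype-dependent junction intensities, PSF blur and
  read noise; electrophysiology records around true (P_Na, P_Cl);
  tracer assays; reference ORFs with engineered alleles.
* **io / cli** — CSV/YAML/TIFF/FASTA readers and writers, run manifests,
  and the `paracellkit` command line.

## Worked example

```python
from paracellkit.barrier_assays import (IonicSolution, invert_dilution_potential,
                                        kimizuka_koketsu)

A, B = IonicSolution.solution_a(), IonicSolution.solution_b()   # 140 / 70 mM NaCl
eta = invert_dilution_potential(16.39, A, B)
print(f"eta from +16.39 mV dilution potential: {eta:.2f}")

for label, ter, eta_ in (("knockout", 3606.0, 1.40), ("control", 61.6, 18.21)):
    p_na, p_cl = kimizuka_koketsu(ter, eta_, 1.4e-4)            # C = 140 mM in mol/cm3
    print(f"{label}: P_Na = {p_na*1e6:.2f} x 1e-6 cm/s, P_Cl = {p_cl*1e6:.2f} x 1e-6 cm/s")
```

prints

```
eta from +16.39 mV dilution potential: 18.25
knockout: P_Na = 0.32 x 1e-6 cm/s, P_Cl = 0.23 x 1e-6 cm/s
control: P_Na = 30.45 x 1e-6 cm/s, P_Cl = 1.67 x 1e-6 cm/s
```

A dilution potential of +16.4 mV (full-strength bath apical) corresponds
to a strongly cation-selective monolayer (η ≈ 18); a high-resistance
knockout monolayer at TER 3606 Ω·cm² and η 1.40 has lost essentially all
of its sodium permeability (0.32 vs 30 × 10⁻⁶ cm/s).

The image pipeline on a synthetic mosaic generated with boundary
fraction f = 0.45 (boundary junctions rendered 45% of the way from
knockout background to control intensity):

```python
from paracellkit.synthetic_data import MosaicSpec, simulate_monolayer
from paracellkit.junction_quant import quantify_image

spec = MosaicSpec(n_cells=200, ko_fraction=0.5, boundary_fraction_f=0.45, seed=7)
image, genotypes, truth = simulate_monolayer(spec)
res = quantify_image(image, genotypes, n_sides=5, seed=7)
print(f"rel_ko = {res.rel_ko:.3f}, rel_boundary = {res.rel_boundary:.3f}")
```

prints

```
rel_ko = 0.153, rel_boundary = 0.498
```

`rel_ko` ≈ 0.15 reflects the knockout junction background (150/1000 in
the generator) and `rel_boundary` recovers the generated fraction
(0.498 on this image; 0.45 ± 0.05 averaged over seeds).

The same steps are available from the shell:

```sh
paracellkit simulate ephys --seed 1 --out run/
paracellkit ephys --records run/records.csv --out run/results/
paracellkit genotype --ref ref.fa --alleles alleles.fa --out calls.csv
paracellkit quantify --image img.tif --meta img.yaml --labels labels.tif \
    --n-sides 5 --seed 7 --out results/
```

Every invocation writes a `manifest.json` recording the resolved
configuration, seed, and input digests.

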