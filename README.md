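# nicklattice

Computational models of enzymatic-ligation-induced stabilization and
reconfiguration of addressable DNA nanostructure lattices.

Addressable lattices self-assemble from short synthetic strands into
grids of junction motifs (4-arm **J4**, 3-arm **J3**) or double-crossover
(**DX**) tiles. Every backbone *nick* — where a 3′-hydroxyl abuts a
5′-phosphorylated end on a continuous complementary template — can be
sealed by T4 ligase. Sealing merges the short root (11 bp) and stem
(10 bp) pairing domains flanking the nick into one continuous segment
(21 bp for the J4-I design) that cannot dissociate at temperatures where
the short domains alone would melt: the kinetically-interlocking
multi-unit (KIM) effect. This package provides, for whoever designs or
analyses such systems:

- **`lattice`** — explicit strand/domain/nick graphs built from
  declarative JSON designs (shipped: J4-I/II/III, J3, DX-I, DX-II, the
  2×2/3×3 calibration lattices and reconfiguration fixtures), with exact
  structural accounting: the 6×6 J4-I lattice has 36 motifs, 60
  intermotif edges and 120 nicks; the full series counts
  120/120/108/146/110 ligatable nicks for J4-II/J4-III/J3/DX-I/DX-II.
- **`ligation`** — per-nick Bernoulli sealing at efficiency *p*, exact
  (2^N) or Monte-Carlo covalent-product distributions, denaturing-gel
  band prediction, and efficiency calibration from the circular product
  of the 2×2 lattice: the designed cycle closes only when all *n* of its
  nicks seal, so *p̂* = *f*^(1/*n*).
- **`stability`** — lock-in classification (full via a strand's own
  terminal nicks X_I/X_II, partial via the templated nick Y), survival
  cascades at an intermediate thermal regime, and Monte-Carlo
  intact-lattice proportion as a function of *p*.
- **`melting`** — survival rates from band-intensity tables, Boltzmann
  and double-Boltzmann melting fits with Tm defined as the fitted
  S = 0.5 crossing, and ΔTm between ligated/unligated structures.
- **`reconfig`** — loss-of-function carving by phosphorylation masks,
  sheet-to-tube closure via ligatable boundary overhangs, catenated-ring
  census and chain-mail percolation, and an exonuclease survival rule.
- **`synth`** — seeded generators for survival datasets and band tables,
  enabling closed-loop parameter-recovery tests without wet-lab data.

## Worked example

Calibrate ligation efficiency from the 2×2 lattice's circular product,
then fit melting curves for an unligated/ligated pair of synthetic
survival datasets:

```python
from nicklattice import (GroundTruth, delta_tm, estimate_efficiency_from_lattice,
                         fit_boltzmann, gen_survival_dataset, product_distribution)
from nicklattice.builtin import build_design

lat = build_design("J4-I_2x2")          # 4 motifs, 8 nicks, one designed cycle
dist = product_distribution(lat, 0.89, mode="exact")
f = dist.table[dist.table.circular].frequency.sum()
print(f)                                 # 0.62742241  (= 0.89**4)
print(estimate_efficiency_from_lattice(lat, f).p_hat)   # 0.89

unlig, _ = gen_survival_dataset(GroundTruth(t_half=53.0, noise_sd=0.05, seed=7))
lig, _ = gen_survival_dataset(GroundTruth(t_half=74.0, noise_sd=0.05, seed=8))
fu, fl = fit_boltzmann(unlig), fit_boltzmann(lig)
print(round(fu.tm, 2), round(fl.tm, 2), round(delta_tm(fl, fu), 2))
# 52.92 74.16 21.25
```

The first block prints the probability that the 2×2 lattice's
four-strand cycle is fully sealed at p = 0.89 and shows the estimator
inverting it exactly. The second recovers the generated melting
temperatures from noisy triplicates — a ligated-minus-unligated Tm
increment of ≈21 °C.

The same operations are available from the command line, e.g.:

```bash
nicklattice build --design J4-I --mask fig4c_mask
nicklattice tube -p 1.0 --control noncomp
nicklattice intact --design J4-I_2x2 --grid 0:1:0.1 --reps 10000 --seed 1 --out scan.csv
```

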