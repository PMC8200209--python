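# carbsorb

Isomer-resolved physisorption of 4-methylcyclohexane methanol (MCHM) on
carbonaceous surfaces, and the Arrhenius desorption kinetics that follow
from it.

## The problem

After the 2014 Elk River chemical spill, granulated activated carbon (GAC)
filters at the Kanawha Valley water treatment plant first adsorbed MCHM and
then — months later, as river water warmed — released it back into finished
water. MCHM is a 1,4-disubstituted cyclohexane that exists as *cis* and
*trans* ring isomers with strikingly different odor thresholds (the human
nose is ~2000× more sensitive to *trans*). If the two isomers bind to
amorphous carbon with different strengths, warming water will release them
at different, strongly temperature-dependent rates.

`carbsorb` packages that analysis as a tested pipeline:

1. **Synthetic structures** — planar fused-ring PAH flakes (an idealized
   graphene-like surface, C32 in the default setting), a procedural
   hydrogen-capped amorphous carbon slab (a stand-in for GAC surfaces:
   5×5×3 nm, ~2 g/cm³, mixed sp²/sp³), and chair conformers of cis-/trans-
   MCHM (C8H16O) built from ideal geometry.
2. **Physisorption engine** — element-wise van-der-Waals interaction
   (12-6 Lennard-Jones or buffered 14-7), seeded random pose sampling over
   the central surface patch, rigid-body pattern-search minimization
   against the frozen surface, the 7.0 kcal/mol conformer retention window,
   per-isomer binding statistics Δε = ⟨E_trans⟩ − ⟨E_cis⟩, and 12 Å
   cluster carving with hydrogen capping and a charge/multiplicity screen.
3. **Desorption kinetics** — with the physisorption potential E_a acting as
   the desorption barrier:

   * relative isomer rate: `r_cis / r_trans = exp(Δε / k_B T)`,
   * fraction of adsorbed molecules able to escape:
     `frac(E_a, T) = Q(3/2, E_a / k_B T)` (the regularized upper incomplete
     gamma function — the upper tail of the Maxwell–Boltzmann kinetic-energy
     distribution), evaluated in closed form as
     `erfc(√x) + (2/√π) √x e^(−x)`,
   * enhancement factor for warming T₁ → T₂:
     `EF = frac(E_a, T₂) / frac(E_a, T₁)`, plus isomer-specific EFs from the
     rate split at each temperature.

   Two Boltzmann-constant profiles ship: `codata` (1.987204×10⁻³
   kcal mol⁻¹ K⁻¹) and `paper_effective` (≈1.8863×10⁻³, calibrated by least
   squares against a published reference table of relative desorption rates,
   which is internally consistent with a constant ~5% below the standard
   value). Every replica table records which profile produced it.
4. **Ensemble statistics** — two-sample t-tests and Cohen's d from summary
   statistics, and seasonal window statistics for daily water-temperature
   series.

## Worked example

```bash
$ carbsorb kinetics-table
# profile paper_effective, kB=1.886326e-03 kcal/mol/K
T_celsius     0.0      10.0     20.0     30.0
delta_eps
1.3           12.5     11.4     10.5     9.71
2.4            105     89.4     76.7     66.5
4.0       2.35e+03 1.79e+03 1.39e+03 1.09e+03
8.0       5.53e+06  3.2e+06 1.92e+06 1.19e+06
```

With a 2.4 kcal/mol binding difference the cis isomer desorbs ~100× faster
than trans near 0 °C, dropping to ~67× at 30 °C — warming lets the tightly
bound trans isomer "catch up".

```bash
$ carbsorb partition --total 1000 --delta-eps 2.4 --t-celsius 0
profile=paper_effective r_cis/r_trans=105.4 cis=991 trans=9
```

Of 1000 molecules desorbing at 0 °C, 991 are cis and only 9 trans. The
`replicate` command chains the worked examples (counts use the published
reference rates; EFs are ratios of rounded counts):

```bash
$ carbsorb replicate
{
  "10.0": {"total": 3000, "n_cis": 2967.0, "n_trans": 33.0,
           "EF_cis": 2.99, "EF_trans": 3.67},
  "30.0": {"total": 20000, "n_cis": 19706.0, "n_trans": 294.0,
           "EF_cis": 19.9, "EF_trans": 32.7}
}
```

So a winter-to-summer warming (0 → 30 °C) multiplies total desorption
~20-fold, but trans desorption ~33-fold — and the trans isomer is the one
people smell.

The full physisorption pipeline (generate surface → sample poses → minimize
→ filter → Δε → kinetics) runs from a YAML config:

```bash
carbsorb run --config config.yaml --out pipeline_out
```

## Acceptance script

`scripts/acceptance.py` recomputes the headline kinetics quantities from
scratch — the percent rate increase between 0 and 10 °C for a 7.2 kcal/mol
barrier, and the cis counts among 1000 (0 °C) and 3000 (10 °C) desorbing
molecules at Δε = 2.4 kcal/mol — after exercising the seeded physisorption
pipeline once:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Scope notes

Absolute binding energies from specific commercial force fields
(MMFF94x, Amber14:EHT), semi-empirical or DFT levels are *not* reproduced;
the vdW engine is a generic surrogate and its absolute well depths are
qualitative. The amorphous slab generator is an explicit procedural
stand-in with matching dimensions and density, not the tight-binding
reference model. See `docs/methods.md` for the model details, numerical
choices and limitations.
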