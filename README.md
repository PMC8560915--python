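# sedxl

Sedimentation-velocity AUC simulation and dc/dt analysis, hyperbolic
affinity fitting, and isotope-coded crosslink identification — a desk-side
toolkit for characterizing chaperone co-factor complexes such as the
nematode CDC-37 · DNJ-13 system.

## What it is for

Two orthogonal biophysical readouts establish that two proteins form a
complex, how big it is and how tightly it binds:

1. **Sedimentation-velocity analytical ultracentrifugation (SV-AUC).** A
   species with sedimentation coefficient *s* and diffusion coefficient *D*
   moves in a spinning sector cell according to the Lamm equation,

       ∂c/∂t = (1/r) ∂/∂r [ r ( D ∂c/∂r − s ω² r² c / r ) ] ,

   with zero flux at the meniscus and cell bottom. Differencing adjacent
   scans gives dc/dt, which maps onto an apparent sedimentation-coefficient
   distribution g(s\*) with s\* = ln(r/r_m)/(ω² t̄). Peak positions identify
   species (free protein vs complex); the Svedberg equation
   M = sRT / (D(1 − v̄ρ)) converts (s, D) into molar mass, and an NNLS
   decomposition over an (s, f/f₀) grid resolves heterogeneous samples.
   Titrating the unlabeled partner against a fluorescent receptor and
   fitting the highest-s peak with the rectangular hyperbola
   s(c) = s_free + (s_sat − s_free)·c/(K_D + c) yields the dissociation
   constant.

2. **Crosslinking mass spectrometry with isotope-coded linkers.** BS3 and
   DSSG bridge lysines (and the protein N-terminal α-amine); supplied as 1:1
   H/D mixes they make every crosslinked peptide pair appear in MS1 as a
   light/heavy doublet spaced by n_D × (²H−¹H)/z. The search digests the
   proteins in silico (trypsin, missed cleavages allowed), enumerates
   candidate pair masses, demands both doublet members within ±15 ppm,
   controls the FDR with reversed-sequence decoys (< 5%), refines to
   < 2 ppm, and reports residue-level links. Those links become ≤ 30 Å
   Cα–Cα distance restraints that can be checked against structural models
   and exported for docking.

Because raw scans and spectra for such studies are rarely deposited, the
package ships a first-class synthetic-data module: a finite-volume Lamm
solver for ideal and slow-exchange reacting mixtures, titration series,
MS1 peak lists with planted doublets, and toy two-chain structures with
planted distances — every analysis stage is validated by parameter
recovery against simulation ground truth.

## Worked example

Simulate the fluorescence-detected binding experiment — 300 nM labeled
receptor (2.8 S) plus 2 µM of a dimeric partner at K_D = 3.4 µM, complex at
5.3 S, 42,000 rpm and 20 °C — then recover both boundaries:

```python
import numpy as np
from sedxl import (CellGeometry, ScanSchedule, SpeciesParams,
                   BindingSystem, equilibrate_then_simulate,
                   fit_kd, TitrationPoint)
from sedxl.workflows import recover_peaks

geo = CellGeometry()                       # 6.0-7.2 cm column, 42,000 rpm, 20 C
free  = SpeciesParams("*CDC-37", s=2.8, ff0=1.4, signal={"fluorescence": 1.0})
dark  = SpeciesParams("DNJ-13 dimer", s=3.6, ff0=1.4, signal={})
bound = SpeciesParams("complex", s=5.3, ff0=1.4, signal={"fluorescence": 1.0})
system = BindingSystem(a_total=300e-9, b_total=2e-6, kd=3.4e-6,
                       species_free_a=free, species_free_b=dark,
                       species_complex=bound)
scans = equilibrate_then_simulate(
    system, geo, ScanSchedule.for_species(4.0, geo, n_scans=50))
for p in recover_peaks(scans, n_peaks=2):
    print(f"peak: center {p.center_s:.2f} S, sigma {p.sigma_s:.2f} S, "
          f"amplitude {p.amplitude:.3f}")
```

prints

```
peak: center 2.70 S, sigma 0.96 S, amplitude 0.269
peak: center 5.30 S, sigma 0.74 S, amplitude 0.188
```

— the free receptor and the complex, at their input sedimentation
coefficients, with the amplitude split reflecting the mass-action
equilibrium (about 35% of the receptor is bound under these conditions).
Fitting a noise-free titration recovers the affinity exactly:

```python
kd = 3.4e-6
conc = np.linspace(0, 10e-6, 12)
pts = [TitrationPoint(c, 2.8 + 2.5 * c / (kd + c)) for c in conc]
print(fit_kd(pts).summary())
```

```
Hyperbolic sedimentation titration fit
  n points : 12
  K_D      : 3.4 uM  (+/- 1.2e-15)
  s_free   : 2.800 S  (+/- 1.4e-16)
  s_sat    : 5.300 S  (+/- 2.8e-16)
  rmse     : 1.282e-16 S
```

The same stages are scriptable from the shell: `sedxl simulate sv`,
`sedxl dcdt`, `sedxl hydro gridfit`, `sedxl fitkd`, `sedxl dol`,
`sedxl xlsearch`, `sedxl xlmap` (see `sedxl --help`).

## Layout

| module | contents |
| --- | --- |
| `sedxl.lamm` | finite-volume Lamm solver, species/geometry/schedule types |
| `sedxl.scans` | XL-A-style ASCII scan files, `ScanSet` container |
| `sedxl.dcdt` | dc/dt curves, g(s\*) distributions, Gaussian peak fits |
| `sedxl.hydro` | Svedberg relations, (s, f/f₀) NNLS grid fit |
| `sedxl.binding` | mass-action speciation, K_D titration fit, degree of labeling |
| `sedxl.simulate` | reacting-system/titration/peak-list/structure generators |
| `sedxl.digest`, `sedxl.linkers`, `sedxl.xlsearch` | tryptic digestion, linker chemistry, MS1 doublet search with target-decoy FDR |
| `sedxl.structure` | PDB Cα parsing, restraint validation, HADDOCK-style `.tbl` output |
| `sedxl.refdata` | reported CDC-37/DNJ-13 crosslinked peptide pairs |

See `docs/methods.md` for the models, numerical choices and limitations.
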