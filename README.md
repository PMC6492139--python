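# dwires

Simulation toolkit for a question that matters when DW-MRI is proposed as a
treatment-response biomarker: **can cell radius and intracellular volume
fraction be estimated precisely enough to tell apoptotic cell shrinkage
apart from cell loss?**  Both changes raise the apparent diffusion
coefficient (ADC) of a tumour voxel, so ADC alone cannot distinguish them;
a two-compartment microstructural model can in principle — if the SNR is
high enough.  `dwires` quantifies "high enough".

It is aimed at quantitative-MRI researchers planning microstructure
studies: it simulates the full chain from acquisition protocol to
parameter-precision statement, entirely in silico.

## The model and the statistic

The normalized PGSE signal of a voxel with cell radius `R`, intracellular
volume fraction `f_i`, diffusivities `D_i`, `D_e` and relaxation time `T2`:

    S/S0 = exp(-TE/T2) [ f_i S_i(R, D_i; G, Δ, δ) + (1 − f_i) S_e(f_i, D_e; b) ]

with `S_i` the Gaussian-phase-distribution signal for diffusion restricted
in impermeable spheres and `S_e = exp(−b D_e,tort)` for the tortuous
extracellular space.  Synthetic magnitude signals carry Rician noise and
are fitted by multistart Nelder–Mead maximum likelihood; ensemble standard
deviations of the fitted values give each parameter's standard error SE_p.

A parameter change Δp is detectable (two-sample z-test, α = 0.05) when

    sqrt(SE_p1² + SE_p2²) ≤ Δp / 1.96 .

Simulating the left side across SNR, fitting `m/SNR + c`, and intersecting
with the right side yields the **SNR required to detect the change** — the
package's headline output.  Acquisition protocols can be taken from the
bundled published set (D-optimized and non-optimized, for maximum gradient
strengths of 60/80/300 mT/m) or designed from scratch with the built-in
Fisher-information genetic algorithm.

## Worked example

SNR needed to detect a 60% apoptotic volume decrease (R: 10 → 7.37 µm,
f_i: 0.60 → 0.24) with the optimized 80 mT/m protocol, diffusivities known:

```python
import numpy as np
from dwires import ChangeScenario, Tissue, resolution_analysis
from dwires.protocols import PROTOCOLS

scenario = ChangeScenario(
    baseline=Tissue(R=10.0, f_i=0.60, D_i=1.0, D_e=2.0),
    kind="shrinkage",
    v=0.60,
)
curves = resolution_analysis(
    scenario,
    PROTOCOLS["D-opt_80"],
    snr_levels=(20, 50, 80, 110),
    n_repeats=1500,
    n_starts=20,
    seed=0,
)
for param, c in curves.items():
    print(
        f"{param:>3}: threshold {c.threshold:.3f}, "
        f"fit {c.fit_m:.1f}/SNR + {c.fit_c:.4f} (r2 {c.fit_r2:.4f}), "
        f"required SNR {c.required_snr:.1f}"
    )
```

Output (about two minutes on one CPU):

```
  R: threshold 1.343, fit 68.8/SNR + -0.0012 (r2 0.9984), required SNR 51.2
f_i: threshold 0.184, fit 2.75/SNR + 0.0002 (r2 0.9997), required SNR 15.0
```

Reading: the combined standard error on `R` must shrink to 1.34 µm before
the 2.63 µm radius change is statistically visible, which takes SNR ≈ 51 —
while the volume-fraction change is already detectable at SNR ≈ 15.
Detecting the cell-size signature of apoptosis is therefore the hard part:
it needs roughly 3× the SNR of the volume-fraction change, more than most
clinical DW-MRI protocols deliver.

The same machinery is scriptable from the shell (`dwires resolution`,
`dwires accuracy-grid`, `dwires volume-sweep`, `dwires async`,
`dwires design`; each takes `--config`, `--seed`, `--scale {paper,desk}`,
`--protocol`, `--out`).

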