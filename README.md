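# nacscan

Geometric detection of catalytic water molecules in MD trajectories of
ester-hydrolysing active sites, plus the enzyme-kinetics arithmetic
(Michaelis–Menten parameters, catalytic efficiencies, discrimination
factors) that accompanies such studies.

## The problem

Editing enzymes of the translation apparatus — aminoacyl-tRNA synthetase
editing domains and the *trans*-editing factor d-aminoacyl-tRNA deacylase
(DTD) — hydrolyse the ester bond between an amino acid and the terminal
adenosine (A76) of a mischarged tRNA. The reaction is water-mediated:
hydrolysis requires a water molecule poised for nucleophilic attack on the
carbonyl carbon of the ester. Whether a given enzyme–substrate complex can
react at all is therefore visible in plain MD trajectories as the presence
or absence of *near-attack conformations*: frames in which a water sits at
attack distance and angle from the carbonyl.

`nacscan` screens every frame of a trajectory for:

* **W1, the attacking water** — its oxygen lies within **3.5 Å** of the
  carbonyl carbon (strict `<`), the **Bürgi–Dunitz angle** (the
  Nu···C=O approach angle measured at the carbonyl carbon) falls inside
  **[105°, 107°]**, and the water is *oxygen-first* oriented: the O–C
  distance is strictly smaller than every H–C distance, so the lone pairs
  face the electrophile;
* **W2, the assisting water** — a second water within **3.5 Å** of the W1
  oxygen that donates a hydrogen toward it (some W2 hydrogen strictly
  closer to O(W1) than O(W2) is), able to activate or relay a proton from
  the nucleophile;
* **activators** — protein N/O heavy atoms within **3.5 Å** of the W2
  oxygen that could polarise or anchor the assisting water.

Scanning is two-pass: waters that ever come within the W1 cutoff of the
carbonyl carbon are collected first, and only those are tested per frame.
Persistence statistics then summarise the scan at frame level: the number
of W1 frames, the percentage of them that also carry a W2, and the
occupancy of individual W1+W2 pairs over the trajectory. All cutoffs and
the angle window are configurable.

The kinetics module fits the Michaelis–Menten rate law
v = k<sub>cat</sub>[S]/(K<sub>m</sub>+[S]) by nonlinear least squares
(double-reciprocal initialisation), carries explicit concentration units,
and computes catalytic efficiencies k<sub>cat</sub>/K<sub>m</sub>,
discrimination factors
(k<sub>cat</sub>/K<sub>m</sub>)<sub>cognate</sub>/(k<sub>cat</sub>/K<sub>m</sub>)<sub>noncognate</sub>,
and N-fold change ratios.

A synthetic-trajectory generator plants waters by inverse geometry —
exact distance, angle and orientation, with optional jitter and decoys
violating exactly one criterion — so the detector is testable with exact
ground truth and no MD engine.

## Worked example

```python
import numpy as np
from nacscan import scan, summarize, fit_mm, simulate_mm_data, discrimination_factor
from nacscan.stats import format_percent
from nacscan.synthetic import PlantSchedule, w1_spec, w2_spec, decoy_spec, generate, default_site

frames = []
for i in range(20):
    specs = []
    if i % 4 != 3:                               # 15 frames carry an attacking water
        specs.append(w1_spec("A", distance=2.9 + 0.02 * i, angle_deg=105.3 + 0.08 * i))
        if i % 2 == 0:                           # half of those also an assistant
            specs.append(w2_spec("B", activator_distance=3.0))
    specs.append(decoy_spec("D", "orientation")) # never detectable
    frames.append(specs)

traj, truth = generate(PlantSchedule(20, frames, jitter_sigma=0.03, seed=42))
reports = scan(traj, default_site())
s = summarize(reports, "w1_frames")
print(f"frames: {s.n_frames_total}, W1 frames: {s.n_w1_frames}, "
      f"W1+W2 frames: {s.n_w1w2_frames} ({format_percent(s.pct_w2_of_w1)}% of W1 frames)")
```

```
frames: 20, W1 frames: 14, W1+W2 frames: 9 (64.3% of W1 frames)
```

With 0.03 Å jitter one planted water drifted out of the narrow angular
window, leaving 14 of 15 planted frames detected; 9 of those 14 W1 frames
(64.3%) also show the donor-oriented assisting water, which is what the
W2-percentage statistic reports for real trajectories. The decoy water —
at attack distance and angle but hydrogen-first — is never reported.

```python
series = simulate_mm_data(7.88, 0.139, 0.139 * np.array([0.07, 0.2, 0.5, 1, 2, 4, 8, 14]),
                          noise_sigma=0.02, seed=42, conc_unit="mM", substrate="l-Ala")
p = fit_mm(series)
print(f"kcat = {p.kcat:.2f} ± {p.kcat_se:.2f} s⁻¹, Km = {p.km:.3f} ± {p.km_se:.3f} mM, "
      f"kcat/Km = {p.efficiency:.1f} mM⁻¹s⁻¹")
print(discrimination_factor(56, 0.12))
```

```
kcat = 7.77 ± 0.15 s⁻¹, Km = 0.138 ± 0.010 mM, kcat/Km = 56.3 mM⁻¹s⁻¹
467.0
```

The fit recovers the generating parameters (k<sub>cat</sub> = 7.88 s⁻¹,
K<sub>m</sub> = 0.139 mM) to within its standard errors under 2% noise,
and the discrimination factor says the enzyme is ~467-fold more efficient
with the cognate substrate.

## Command line

```
synth-traj    --schedule schedule.yaml --seed 1 --out traj.pdb --labels labels.json
nac-scan      --traj traj.pdb --config site.yaml --out report.csv
nac-summary   --report report.csv --denominator w1_frames --n-frames 5000 --out summary.json
kinetics-fit  --input rates.csv --out params.json
kinetics-table --params params.json --cognate l-Ala
```

`site.yaml` names the ligand residue, the carbonyl C/O atom names and the
water residue name; all cutoffs can be overridden on the command line.
Trajectories are multi-model PDB (one `MODEL`/`ENDMDL` block per frame) or
concatenated GRO frames.

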