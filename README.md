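# kneedrill

Virtual femoral-tunnel drilling for anatomical single-bundle ACL
reconstruction with the transportal (medial portal) technique, on 3D knee
bone meshes.

When the femoral tunnel is drilled through a far anteromedial portal, three
things can go wrong: the tunnel can be too short for secure graft fixation
(< 25 mm), the drill can break the tunnel wall (posterior blowout at the
aperture, or loss of wall within the first 25 mm), and the graft can take a
sharp bend at the femoral aperture, concentrating bending stress. All three
depend jointly on the knee flexion angle at which the tunnel is drilled and
on the transverse drill angle of the portal. `kneedrill` simulates this
trade-off on triangulated bone surfaces: it localises the ACL footprint
centres by the quadrant method, poses the knee by rotating the tibia about
the transepicondylar axis (TEA), finds the maximum transverse drill angle
(MTA — the most medial drill that still clears the medial femoral condyle
cartilage), drills a virtual 8-mm cylinder at MTA, MTA−10° and MTA−20° for
flexion 100°–130°, and measures per condition:

- **tunnel length** `|D − B|`, from the femoral footprint centre `B` to the
  external-cortex exit `D` along the drill axis, with the < 25 mm
  short-tunnel rule;
- **wall breakage**, classified as *entrance* (no intact rim at the
  aperture) or *mid-tunnel* (intact aperture, wall lost within 25 mm);
- **graft bending angle** ∠CBD at full extension, between the tibial→femoral
  footprint line `AB` extended beyond `B` (to `C`) and the tunnel axis `BD`
  (0° = straight path, larger = sharper bend).

Results feed a repeated-measures analysis: one-way within-subject ANOVA with
Bonferroni-corrected paired post hoc tests for the continuous variables, and
Cochran's Q for the dichotomous ones.

Because no patient CT data ship with the package, a seeded parametric
generator (`kneedrill.synthetic`) produces watertight, region-labelled
distal-femur/proximal-tibia pairs (implicit-surface composition + marching
cubes) with population-scale transepicondylar distances (82.1 ± 5.7 mm) for
cohorts of any size. It is first-class, tested code — see
`docs/methods.md` for what it does and does not emulate.

## Worked example

```python
import kneedrill as kd

cohort = kd.sample_cohort(4, seed=42)          # four synthetic subjects
results = kd.run_grid(cohort)                  # 4 x 12 = 48 rows
summary = kd.summarize(results)
print(summary.length_mean.round(1))
```

prints the mean tunnel length (mm) per flexion × drill-angle cell:

```
offset_from_mta  -20.0  -10.0   0.0
flexion_deg
100.0             28.8   31.2   32.1
110.0             32.5   34.1   33.5
120.0             37.0   36.8   34.2
130.0             40.3   37.7   34.2
```

Read: at 100° of flexion the tunnels are shortest (and shorten further as
the drill moves laterally from MTA to MTA−20°), while at 120–130° the same
lateral move lengthens them — the characteristic reversal of the
flexion/drill-angle interaction. `summary.breakage_counts` splits wall
breakage into EB/MB/TB per cell, and

```python
an = kd.analyze(results)
an["length"]["across_flexion"][0.0]["anova"]
# TestResult(statistic=28.1, df=(3, 9), p_value=6.6e-05, ...)
```

runs the repeated-measures comparisons (6 pairwise post hoc tests across
flexion levels, 3 across drill angles).

The same pipeline is scriptable from the shell:

```bash
kneedrill gen-cohort --n 30 --seed 42 --out cohort/
kneedrill run --cohort cohort/ --out results.csv
kneedrill report results.csv          # Markdown summary tables
kneedrill stats results.csv           # test families as JSON
kneedrill drill femur.stl tibia.stl --flexion 120 --offset -10   # one tunnel
kneedrill config --out run.yaml       # every numeric constant, editable
```

Meshes are STL/PLY in millimetres, validated (watertight, outward-facing)
on load. The canonical frame is a right knee — +X lateral, +Y anterior,
+Z proximal — and left knees are mirrored at load time.

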