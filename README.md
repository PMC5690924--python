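# sbrtqa

Plan-quality analysis for lung stereotactic body radiotherapy (SBRT).

Medical physicists evaluating hypofractionated lung plans check them
against the RTOG 0915 dosimetric compliance criteria: how tightly the
prescription isodose conforms to the planning target volume (PTV), how far
intermediate dose spills into normal lung, and whether organ-at-risk (OAR)
doses stay under protocol limits.  `sbrtqa` implements that evaluation as
a reusable, tested pipeline:

* **DVH engine** — voxel-exact cumulative dose-volume histograms with
  `V(d)` / `D(v)` queries and DVH normalization (rescale so 95% of the
  PTV receives the prescription, D95% = Rx).
* **Spillage metrics** —
  conformity index `R100% = V(100% Rx) / V(PTV)`,
  intermediate-dose spillage `R50% = V(50% Rx) / V(PTV)`,
  `D2cm` = maximum dose ≥ 2 cm from the PTV in any direction (% of Rx),
  and normal-lung `V20`/`V5` (lungs minus the internal target volume).
* **OAR documentation** — spinal cord D0.35cc, lung D1000cc, esophagus
  D5cc, heart D15cc, and rib Dmax/D1cc/D5cc/D10cc with the 3D
  isocenter-to-rib distance.
* **Compliance classification** — per-protocol / minor / major per metric,
  with PTV-volume-interpolated bands for R50% and D2cm (the band
  `(lower, upper)` classifies as minor iff `lower < value ≤ upper`).
* **Cohort analysis** — summary statistics, deviation counts,
  distance-versus-rib-dose association, and linear-quadratic
  biologically effective dose `BED = n·d·(1 + d/(α/β))` with α/β = 3 Gy
  for ribs.
* **Synthetic phantoms** — analytic radial-falloff dose distributions
  around ellipsoidal targets whose R100/R50/D2cm are known in closed
  form, so the whole pipeline is testable without patient data.

A checksummed 20-patient peripheral lung SBRT reference cohort
(PTV 11.1–163 cc; 54 Gy/3 fx or 50 Gy/5 fx) ships with the package for
cohort-level analyses.  Plans are read from a portable directory format
(JSON header + raw arrays, lossless round trip) or imported from DICOM-RT
(RTDOSE + RTSTRUCT).

See `docs/methods.md` for conventions, numerical choices and limitations.

## Worked example

```python
import sbrtqa as s

# a synthetic plan: 15 mm spherical PTV, plateau radius 1.08 x PTV radius,
# 10 mm dose half-value distance, rib shell 30 mm from the isocenter
cfg = s.PhantomConfig(ptv_semiaxes_mm=(15, 15, 15), r100_scale=1.08,
                      g50_mm=10.0, iso_to_rib_mm=30.0,
                      half_extent_mm=85.0, patient_id="demo")
plan = s.make_phantom(cfg)

m = s.extract_metrics(plan)          # DVH-normalizes to D95% = Rx first
report = s.evaluate_plan(m, s.load_criteria())
print(f"PTV {m.ptv_cc:.1f} cc  R100 {m.r100:.3f}  R50 {m.r50:.3f} "
      f"D2cm {m.d2cm_pct:.1f}%  V20 {m.lung_v20_pct:.1f}%")
for r in report.results:
    print(f"  {r.metric:16s} {r.category}")
print("fully compliant:", report.fully_compliant)
```

prints

```
PTV 14.1 cc  R100 1.267  R50 5.353  D2cm 29.3%  V20 5.0%
  r100             minor
  r50              minor
  d2cm_pct         per_protocol
  lung_v20_pct     per_protocol
  cord_d035cc_gy   per_protocol
  esophagus_d5cc_gy not_applicable
  heart_d15cc_gy   not_applicable
  lung_d1000cc_gy  per_protocol
fully compliant: False
```

The extracted R100 of 1.267 sits within 1% of the generator's closed-form
value 1.08³ = 1.260 — the phantom's isodose surfaces are scaled spheres,
so the conformity ratios are known analytically.  R100 above the 1.2
per-protocol bound and R50 above the volume-interpolated band for a
14 cc PTV are both minor deviations, so the plan is acceptable with minor
deviations but not fully compliant; all OAR doses pass.

A command-line interface wraps the same pipeline:

```bash
sbrtqa simulate --n 5 --seed 1 --out plans/      # phantoms + ground truth
sbrtqa evaluate plans/synth-01 --out report/     # metrics + compliance
sbrtqa cohort plans/ --out cohort.csv            # cohort table + counts
sbrtqa fixtures --table 6 --out ribs.csv         # reference cohort slices
```

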