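# protonqa

Statistical patient-specific QA (PSQA) tooling for proton pencil-beam
scanning, built around the *independent dose calculation* workflow: instead
of (or alongside) measuring every plan with a detector array, the clinic
recomputes the plan with an independent engine and compares dose
distributions with the gamma index.  Before that workflow can carry clinical
weight, the facility has to know what passing rates its own process normally
produces — and set limits that separate "business as usual" from "stop and
investigate".  `protonqa` implements that pipeline end to end for medical
physicists and QA researchers:

* **Gamma engine** — the Low-type composite metric.  A reference point
  passes when some evaluated position within the search radius satisfies
  `sqrt(|Δr|²/dta² + ΔD²/dD²) ≤ 1` (dose criterion global or local,
  low-dose threshold, fine sub-voxel search; verified against an exhaustive
  brute-force oracle), plus point-dose percentage differences.
* **Synthetic PBS dose engine** — Bragg–Kleeman range-energy rule, analytic
  Bragg curves, single-energy reference fields (41 × 41 = 1681 spots,
  2 Gy at 2 cm depth), cubic SOBP plans with NNLS-flattened layer weights
  (flat within ±3%), range shifters, and a seeded perturbation model that
  manufactures the "independent recalculation" member of each QA pair.
* **SPC limits** — from per-plan passing-rate series: the confidence limit
  `CL = 100 − (|100 − x̄| + 1.96 s)`, individuals-chart tolerance limits
  `x̄ ± 2.660 m̄R`, and TG-218 action limits
  `ΔA = β√(s² + (x̄ − 100)²)`, β = 6; plus paired t-tests and one-way ANOVA
  across treatment sites.
* **Cohort generator** — site-labelled passing-rate series from a
  moment-matched upper-truncated normal, reproducing published site
  statistics of a 50-plan clinical cohort.

Dose grids travel as DICOM RT Dose (built-in minimal codec) or a plain JSON
grid format; geometry in mm, dose in Gy, beam along +z.

## Worked example

```python
>>> import protonqa as pq

# a single-energy reference field and its perturbed "recalculation"
>>> plan = pq.build_single_energy_plan(160.0)          # 1681 spots, 2 Gy @ 2 cm
>>> ref = pq.compute_dose(plan, (-70, -70, 0), (2, 2, 2), (71, 71, 100))
>>> ev = pq.perturb(ref, pq.PerturbSpec(dose_scale_percent=1.0,
...                 shift_mm=(0.5, 0, 0.5), noise_percent=0.8,
...                 range_error_mm=1.0, seed=3))
>>> plane = pq.central_slab(ref, axis=1)               # planar scoring
>>> res = pq.gamma_map(plane, ev, pq.GammaCriteria(3.0, 3.0))
>>> round(res.passing_rate, 1)
98.6

# SPC limits from a site's per-plan rates
>>> s = pq.summarize_rates([98.4, 96.2, 93.1, 95.8, 96.0, 95.1, 97.9, 94.4, 95.2, 96.1])
>>> round(pq.confidence_limit(s), 1)
92.8
>>> delta, upper, lower = pq.action_limits(s)          # beta = 6, target = 100
>>> round(lower, 1)
86.6
```

The 98.6% is the 3%/3 mm gamma passing rate of a 160 MeV field against a
realistically perturbed copy — the quantity a clinic logs per plan.  The
92.8% says the process would keep 95% of plans above that rate if it keeps
behaving as it has; the 86.6% is the TG-218 action limit below which a plan
signals a clinically relevant deviation.

## Analysis scripts

Numbered drivers under `analysis/` rebuild the commissioning exercise and
write tables to `results/`:

1. `01_point_dose.py` — point-dose differences at the six commissioning
   energies (published aggregation + synthetic re-enactment).
2. `02_simple_plans.py` — six single-energy fields, the 5-cube × 3-depth
   SOBP matrix, and the 0/2/3/5 cm range-shifter set, gamma-scored at
   3%/2 mm, 3%/3 mm and 5%/3 mm (~45 s).
3. `03_clinical_cohort.py` — five-site cohort emulation with paired t-tests
   and ANOVA.
4. `04_limits.py` — confidence/action limits in closed form from the
   published site statistics, next to the cohort-derived table.

The same flows are scriptable via the `protonqa` CLI
(`synth`, `gamma`, `limits`, `report`, `validate`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline commissioning limits — per-site confidence limits
and TG-218 action limits — from the packaged published site statistics via
the library's closed-form derivations, writes them as JSON, and runs the
seeded clinical cohort emulation end to end alongside.

`docs/methods.md` documents the models, defaults and known limitations.
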